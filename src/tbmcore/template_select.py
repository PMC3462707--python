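"""Difficulty-weighted rescoring of homology-search hits and
consensus-based multiple-template selection.

Hits are re-ranked by the rescoring function

    S = Z_seq + w * Z_ss

where Z_seq and Z_ss are Z-scores of the raw sequence- and secondary-
structure-similarity scores over the hit population, and the weight w
depends on the search probability p of the original top-ranked hit — a
proxy for target difficulty:

    w = 1.0  (p >= 90),  1.5  (80 <= p < 90),
        2.0  (60 <= p < 80),  2.6  (p < 60)

The harder the target (lower p), the more the secondary-structure channel
counts.  Template selection then proceeds on the top 20 rescored hits:
split into high-rankers (S within 95% of the top score) and low-rankers;
form a background pool (the high-rankers, or the top 3, whichever is
larger); drop candidates whose mean TM-score to the pool falls below
m_pool - alpha * sigma_pool (alpha = 1 for high-rankers, the candidate's
S-ratio to the top score for low-rankers); finally drop candidates with
TM-score < 0.5 to the top ranker, computed with the top ranker's length as
the reference length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from tbmcore.metrics import tm_score
from tbmcore.structio import HitRecord, Structure

__all__ = [
    "WeightSchedule", "SelectionParams", "PoolStats", "SimilarityMatrix",
    "zscore", "weight_factor", "rescore", "split_rankers", "background_pool",
    "pool_filter", "final_top_filter", "select_templates", "similarity_matrix",
]


@dataclass(frozen=True)
class WeightSchedule:
    """Piecewise-constant weight for the secondary-structure Z-score.

    ``bins`` are ``(inclusive lower probability bound, weight)`` pairs,
    scanned in order; the first bin whose bound the probability meets wins.
    """

    bins: tuple[tuple[float, float], ...] = (
        (90.0, 1.0), (80.0, 1.5), (60.0, 2.0), (-math.inf, 2.6))

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.bins]
        weights = [w for _, w in self.bins]
        if bounds != sorted(bounds, reverse=True):
            raise ValueError("bin bounds must be strictly decreasing")
        if weights != sorted(weights):
            raise ValueError("weights must increase as probability decreases")
        if not math.isinf(bounds[-1]):
            raise ValueError("last bin must cover all remaining probabilities")


@dataclass(frozen=True)
class SelectionParams:
    """Tunable constants of the selection procedure (defaults as published)."""

    candidate_cap: int = 20
    high_ranker_fraction: float = 0.95
    min_pool_size: int = 3
    final_tm_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.high_ranker_fraction <= 1.0):
            raise ValueError("high_ranker_fraction must be in (0, 1]")
        if self.candidate_cap < self.min_pool_size:
            raise ValueError("candidate_cap must be >= min_pool_size")


@dataclass(frozen=True)
class PoolStats:
    m_pool: float
    sigma_pool: float


class SimilarityMatrix:
    """Symmetric pairwise TM-score matrix over a set of template ids."""

    def __init__(self, ids: Sequence[str], tm: np.ndarray) -> None:
        tm = np.asarray(tm, dtype=float)
        if tm.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(tm, tm.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(tm), 1.0):
            raise ValueError("diagonal must be 1")
        self.ids = list(ids)
        self.tm = tm
        self._idx = {t: i for i, t in enumerate(self.ids)}

    def value(self, a: str, b: str) -> float:
        try:
            return float(self.tm[self._idx[a], self._idx[b]])
        except KeyError as exc:
            raise KeyError(f"similarity matrix has no id {exc.args[0]!r}") from exc


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0 / population std 1; all-equal input maps to zeros."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 values")
    std = v.std()  # population std: the hit list is the whole population
    if std == 0.0:
        return np.zeros_like(v)
    return (v - v.mean()) / std


def weight_factor(p: float, schedule: WeightSchedule = WeightSchedule()) -> float:
    """Secondary-structure weight for a top-ranker probability ``p`` (percent)."""
    if not (0.0 <= p <= 100.0):
        raise ValueError(f"probability {p} outside [0, 100]")
    for bound, w in schedule.bins:
        if p >= bound:
            return w
    raise AssertionError("schedule does not cover p")  # unreachable by invariant


def rescore(hits: Sequence[HitRecord],
            schedule: WeightSchedule = WeightSchedule()) -> list[HitRecord]:
    """Re-rank hits by S = Z_seq + w * Z_ss.

    Z-scores are computed over the input hit population; ``w`` comes from
    the probability of the original (input-order) top hit.  The returned
    list is sorted by S descending, stable in the original order for ties.
    """
    if len(hits) < 2:
        raise ValueError("need at least 2 hits to rescore")
    z_seq = zscore([h.raw_seq_score for h in hits])
    z_ss = zscore([h.raw_ss_score for h in hits])
    w = weight_factor(hits[0].probability, schedule)
    out = []
    for h, zq, zs in zip(hits, z_seq, z_ss):
        out.append(HitRecord(
            template_id=h.template_id,
            raw_seq_score=h.raw_seq_score,
            raw_ss_score=h.raw_ss_score,
            probability=h.probability,
            aligned_pairs=h.aligned_pairs,
            z_seq=float(zq), z_ss=float(zs),
            rescored=float(zq + w * zs),
        ))
    return sorted(out, key=lambda h: -h.rescored)  # sorted() is stable


def split_rankers(ranked: Sequence[HitRecord],
                  params: SelectionParams = SelectionParams()
                  ) -> tuple[set[str], set[str]]:
    """Split rescored hits into high-rankers (S within 95% of the top score)
    and low-rankers.

    The fraction rule is only meaningful for a positive top score; when
    S_top <= 0 (possible for Z-score sums) the high-ranker set degenerates
    to the top ranker alone, and the pool fallback takes over.
    """
    if not ranked:
        raise ValueError("empty hit list")
    ranked = list(ranked)[: params.candidate_cap]
    s_top = ranked[0].rescored
    if s_top is None:
        raise ValueError("hits must be rescored first")
    if s_top > 0:
        thr = params.high_ranker_fraction * s_top
        high = {h.template_id for h in ranked if h.rescored >= thr}
    else:
        high = {ranked[0].template_id}
    high.add(ranked[0].template_id)
    low = {h.template_id for h in ranked} - high
    return high, low


def background_pool(high: set[str], ranked: Sequence[HitRecord],
                    params: SelectionParams = SelectionParams()) -> set[str]:
    """The high-rankers, or the top ``min_pool_size`` rescored hits,
    whichever set is larger (all hits when fewer exist)."""
    if not ranked:
        raise ValueError("empty hit list")
    ranked = list(ranked)[: params.candidate_cap]
    if len(high) >= params.min_pool_size:
        return set(high)
    return {h.template_id for h in ranked[: params.min_pool_size]}


def pool_filter(candidates: Sequence[str], pool: set[str],
                sims: SimilarityMatrix, ranked: Sequence[HitRecord],
                params: SelectionParams = SelectionParams()) -> list[str]:
    """Remove candidates structurally dissimilar from the background pool.

    A candidate's similarity is its mean TM-score to the pool members
    (excluding itself when it belongs to the pool).  With ``m_pool`` and
    ``sigma_pool`` the mean and population standard deviation of the pool
    members' own similarities, candidate ``c`` is removed iff

        sim(c) < m_pool - alpha(c) * sigma_pool

    where alpha = 1 for high-rankers and S_c / S_top (clamped to [0, 1])
    for low-rankers.  The top ranker is never removed.  Candidate order is
    preserved.
    """
    if not pool:
        raise ValueError("empty background pool")
    if not set(pool) <= set(candidates):
        raise ValueError("pool must be a subset of the candidates")
    ranked = list(ranked)
    s_by_id = {h.template_id: h.rescored for h in ranked}
    top_id = ranked[0].template_id
    s_top = s_by_id[top_id]
    high, _low = split_rankers(ranked, params)

    def mean_sim(c: str) -> float:
        others = [q for q in pool if q != c]
        if not others:
            return 1.0  # single-member pool: a pool member is trivially similar
        return float(np.mean([sims.value(c, q) for q in others]))

    pool_sims = np.array([mean_sim(q) for q in sorted(pool)])
    m_pool = float(pool_sims.mean())
    sigma_pool = float(pool_sims.std())  # population std

    kept = []
    for c in candidates:
        if c == top_id:
            kept.append(c)
            continue
        if c in high:
            alpha = 1.0
        else:
            ratio = (s_by_id[c] / s_top) if s_top > 0 else 0.0
            alpha = min(1.0, max(0.0, ratio))
        if mean_sim(c) >= m_pool - alpha * sigma_pool:
            kept.append(c)
    return kept


def final_top_filter(candidates: Sequence[str], tm_to_top: Mapping[str, float],
                     params: SelectionParams = SelectionParams()) -> list[str]:
    """Drop candidates with TM-score < 0.5 to the top ranker.

    ``tm_to_top`` must be computed with the top ranker's sequence length as
    the reference length.  The first candidate (the top ranker) is always
    retained; order is preserved.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    top_id = candidates[0]
    kept = []
    for c in candidates:
        if c == top_id:
            kept.append(c)
            continue
        if c not in tm_to_top:
            raise KeyError(f"no TM-score to the top ranker for {c!r}")
        if tm_to_top[c] >= params.final_tm_cutoff:
            kept.append(c)
    return kept


def similarity_matrix(hits: Sequence[HitRecord],
                      structures: Mapping[str, Structure],
                      target_length: int) -> SimilarityMatrix:
    """Pairwise template TM-scores via the target-mediated correspondence.

    Two templates are compared on the residue pairs where both align to a
    common target position (their hit alignments composed through the
    target), with the target sequence length as the reference length — no
    structure aligner is run.
    """
    ids = [h.template_id for h in hits]
    by_id = {h.template_id: h for h in hits}
    n = len(ids)
    tm = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            hi, hj = by_id[ids[i]], by_id[ids[j]]
            map_i = dict(sorted(hi.aligned_pairs))   # target_pos -> template_pos
            map_j = dict(sorted(hj.aligned_pairs))
            shared = sorted(set(map_i) & set(map_j))
            if len(shared) < 3:
                val = 0.0
            else:
                pairs = [(map_i[t], map_j[t]) for t in shared]
                val = tm_score(structures[ids[i]], structures[ids[j]],
                               pairs, l_ref=target_length)
            tm[i, j] = tm[j, i] = val
    return SimilarityMatrix(ids, tm)


@dataclass
class SelectionReport:
    """Trace of the selection stages for one target."""

    ranked_ids: list[str] = field(default_factory=list)
    high: set[str] = field(default_factory=set)
    low: set[str] = field(default_factory=set)
    pool: set[str] = field(default_factory=set)
    removed_pool_stage: list[str] = field(default_factory=list)
    removed_final_stage: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    rescored: dict[str, float] = field(default_factory=dict)


def select_templates(hits: Sequence[HitRecord],
                     structures: Mapping[str, Structure],
                     target_length: int,
                     params: SelectionParams = SelectionParams(),
                     schedule: WeightSchedule = WeightSchedule(),
                     report: SelectionReport | None = None) -> list[str]:
    """Full multiple-template selection for one target.

    Composition: rescore -> truncate to the candidate cap -> high/low split
    -> background pool -> pool dissimilarity filter -> final TM-to-top
    filter.  Returns the selected template ids ordered by rescored score;
    always contains the top rescored hit.
    """
    if len(hits) == 1:
        if report is not None:
            report.ranked_ids = [hits[0].template_id]
            report.selected = [hits[0].template_id]
        return [hits[0].template_id]
    ranked = rescore(hits, schedule)[: params.candidate_cap]
    missing = [h.template_id for h in ranked if h.template_id not in structures]
    if missing:
        raise KeyError(f"structures missing for candidates: {missing}")
    high, low = split_rankers(ranked, params)
    pool = background_pool(high, ranked, params)
    candidates = [h.template_id for h in ranked]
    sims = similarity_matrix(ranked, structures, target_length)
    after_pool = pool_filter(candidates, pool, sims, ranked, params)

    top = ranked[0]
    top_len = len(structures[top.template_id])
    by_id = {h.template_id: h for h in ranked}
    tm_to_top = {}
    for c in after_pool:
        if c == top.template_id:
            tm_to_top[c] = 1.0
            continue
        map_c = dict(sorted(by_id[c].aligned_pairs))
        map_t = dict(sorted(top.aligned_pairs))
        shared = sorted(set(map_c) & set(map_t))
        if len(shared) < 3:
            tm_to_top[c] = 0.0
        else:
            pairs = [(map_c[t], map_t[t]) for t in shared]
            tm_to_top[c] = tm_score(structures[c], structures[top.template_id],
                                    pairs, l_ref=top_len)
    selected = final_top_filter(after_pool, tm_to_top, params)
    if report is not None:
        report.ranked_ids = candidates
        report.high, report.low, report.pool = high, low, pool
        report.removed_pool_stage = [c for c in candidates if c not in after_pool]
        report.removed_final_stage = [c for c in after_pool if c not in selected]
        report.selected = selected
        report.rescored = {h.template_id: h.rescored for h in ranked}
    return selected
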