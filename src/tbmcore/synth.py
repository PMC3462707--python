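"""Seeded synthetic fixtures with known ground truth for every stage.

Structures are built on ideal backbone geometry (bond lengths N-CA 1.458,
CA-C 1.525, C-N 1.329 A; helix phi/psi -57/-47 deg, extended -120/+140 deg)
with side-chain stub atoms out to the chi2-defining atom, so the dihedral
accuracy metrics have something to measure.  Template sets, homology-hit
tables and model ensembles are derived from a native structure by
controlled perturbations: Gaussian coordinate noise, rigid displacement of
chosen intervals (to create structural outliers with a known TM-score
separation), and rigid whole-model jitter plus interval-confined noise (the
statistical structure the consensus ULR detector assumes).  All generators
are pure functions of their spec: identical seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from tbmcore.ensemble import ModelEnsemble
from tbmcore.metrics import CHI1_DISTAL, CHI2_ATOMS, tm_score
from tbmcore.structio import HitRecord, Residue, Structure, write_hit_table

__all__ = ["SynthSpec", "make_structures", "make_hits", "make_ensemble",
           "ideal_backbone", "set_chi"]

# ideal geometry constants (A, degrees)
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
B_CA_CB, A_C_CA_CB, T_N_C_CA_CB = 1.521, 110.1, 122.7
B_SC, A_SC = 1.530, 114.0
TORSIONS = {"helix": (-57.0, -47.0), "extended": (-120.0, 140.0)}
OMEGA = 180.0

#: default residue palette: a mix of chi1-only, chi1+chi2 and no-chi types
PALETTE = "AVLDFKSTIEMGNQRW"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic target family.

    ``loop_intervals`` are 1-based inclusive ``(start, end)`` intervals
    that receive extra per-model Gaussian noise of ``loop_sigma`` A in
    ensembles, or large rigid displacements in decoy templates.
    """

    seed: int = 0
    target_length: int = 60
    n_templates: int = 4
    n_decoys: int = 2
    loop_intervals: tuple[tuple[int, int], ...] = ((20, 30),)
    loop_sigma: float = 3.0
    backbone_model: str = "helix"
    template_noise: float = 0.3   # A, coordinate noise on good templates
    rigid_jitter_deg: float = 5.0  # max whole-model rotation in ensembles
    rigid_jitter_trans: float = 1.0  # A, max whole-model translation

    def __post_init__(self) -> None:
        if self.backbone_model not in TORSIONS:
            raise ValueError(f"unknown backbone model {self.backbone_model!r}")
        ivals = sorted(self.loop_intervals)
        for (s, e) in ivals:
            if not (1 <= s <= e <= self.target_length):
                raise ValueError(f"interval ({s},{e}) outside [1,{self.target_length}]")
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError("loop intervals overlap")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place the next atom from three predecessors (natural extension
    reference frame): bond length from ``c``, angle b-c-new, torsion
    a-b-c-new; angle and torsion in degrees."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  -bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def ideal_backbone(sequence: str, backbone_model: str = "helix",
                   chi1: float = -60.0, chi2: float = 180.0) -> Structure:
    """Build a structure with ideal backbone geometry and side-chain stubs.

    Side chains are minimal: CB plus the chi1-defining atom for residues
    that have one, plus the chi2-defining atom where applicable, placed at
    the given torsions.  Enough for CA metrics and dihedral accuracy.
    """
    phi, psi = TORSIONS[backbone_model]
    coords: list[dict[str, np.ndarray]] = []
    # seed the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([B_N_CA, 0.0, 0.0])
    c0 = _nerf(n0 + np.array([0.0, 1.0, 0.0]), n0, ca0, B_CA_C, A_N_CA_C, psi)
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, len(sequence)):
        prev = coords[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi)
        ca = _nerf(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
        c = _nerf(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    residues = []
    for i, (aa, atoms) in enumerate(zip(sequence, coords), start=1):
        res = Residue(i, aa, dict(atoms))
        _place_sidechain(res, chi1, chi2)
        residues.append(res)
    return Structure(residues, chain_id="A", source_path="synthetic")


def _place_sidechain(res: Residue, chi1: float, chi2: float) -> None:
    if res.aa in ("G",):
        return
    a = res.atoms
    a["CB"] = _nerf(a["N"], a["C"], a["CA"], B_CA_CB, A_C_CA_CB, T_N_C_CA_CB)
    g_name = CHI1_DISTAL.get(res.aa)
    if g_name is None:
        return
    a[g_name] = _nerf(a["N"], a["CA"], a["CB"], B_SC, A_SC, chi1)
    if res.aa in CHI2_ATOMS:
        g, d = CHI2_ATOMS[res.aa]
        a[d] = _nerf(a["CA"], a["CB"], a[g], B_SC, A_SC, chi2)


def set_chi(structure: Structure, seq_pos: int,
            chi1: float | None = None, chi2: float = 180.0) -> Structure:
    """Return a copy with residue ``seq_pos``'s side chain re-placed at the
    given torsions (keeping backbone atoms untouched)."""
    out = structure.copy()
    res = out.residue_at(seq_pos)
    if res is None:
        raise KeyError(f"no residue at position {seq_pos}")
    for name in list(res.atoms):
        if name not in ("N", "CA", "C", "O"):
            del res.atoms[name]
    _place_sidechain(res, chi1 if chi1 is not None else -60.0, chi2)
    return out


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = math.radians(rng.uniform(-max_deg, max_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(ang) * k + (1 - math.cos(ang)) * (k @ k)


def _transform(structure: Structure, rot: np.ndarray, trans: np.ndarray) -> Structure:
    out = structure.copy()
    for res in out.residues:
        for name in res.atoms:
            res.atoms[name] = rot @ res.atoms[name] + trans
    return out


def _add_noise(structure: Structure, rng: np.random.Generator, sigma: float,
               positions: set[int] | None = None) -> Structure:
    out = structure.copy()
    for res in out.residues:
        if positions is not None and res.seq_pos not in positions:
            continue
        for name in res.atoms:
            res.atoms[name] = res.atoms[name] + rng.normal(0.0, sigma, 3)
    return out


def _sequence(length: int) -> str:
    return "".join(PALETTE[i % len(PALETTE)] for i in range(length))


def make_structures(spec: SynthSpec
                    ) -> tuple[Structure, dict[str, Structure], dict[str, float]]:
    """Native structure, template set, and self-consistent TM-score truth.

    Templates ``tmpl00..`` are near-copies of the native (Gaussian noise of
    ``template_noise`` A); decoys ``decoy00..`` additionally have the
    second half of the chain rigidly swung away, which drives their
    TM-score to the native below 0.5 while the templates stay well above —
    the separation the final dissimilarity filter relies on.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _sequence(spec.target_length)
    native = ideal_backbone(seq, spec.backbone_model)
    templates: dict[str, Structure] = {}
    tm_truth: dict[str, float] = {}
    all_pairs = [(i, i) for i in range(1, spec.target_length + 1)]

    for i in range(spec.n_templates):
        t = _add_noise(native, rng, spec.template_noise)
        templates[f"tmpl{i:02d}"] = t
    for i in range(spec.n_decoys):
        d = native.copy()
        half = spec.target_length // 2
        rot = _random_rotation(rng, 180.0)
        shift = rng.normal(0.0, 1.0, 3)
        shift = 25.0 * shift / np.linalg.norm(shift)
        pivot = d.residues[half - 1].ca.copy()
        for res in d.residues:
            if res.seq_pos > half:
                for name in res.atoms:
                    res.atoms[name] = rot @ (res.atoms[name] - pivot) + pivot + shift
        templates[f"decoy{i:02d}"] = _add_noise(d, rng, spec.template_noise)
    for tid, t in templates.items():
        tm_truth[tid] = tm_score(t, native, all_pairs, l_ref=spec.target_length)
    return native, templates, tm_truth


def make_hits(spec: SynthSpec, planted_order: Sequence[str],
              path: str | Path | None = None,
              scenario: str = "easy",
              score_gap: float = 4.0, score_noise: float = 0.4,
              coverage: Mapping[str, tuple[int, int]] | None = None,
              ) -> list[HitRecord]:
    """A hit table whose rescoring recovers ``planted_order``.

    Raw sequence and secondary-structure scores decrease down the planted
    order by ``score_gap`` per rank with Gaussian noise ``score_noise`` on
    each channel — a gap-to-noise ratio of 10 at the defaults, recovering
    the planted order essentially always.  ``scenario`` sets the top-ranker
    probability (easy 95, medium 75, hard 50), hence the weight bin used in
    rescoring.  Alignments cover the whole target identically unless
    ``coverage`` restricts a template to a sub-interval.  When ``path`` is
    given, the table is also written in the TSV dialect.
    """
    p_top = {"easy": 95.0, "medium": 75.0, "hard": 50.0}[scenario]
    rng = np.random.default_rng(spec.seed + 1)
    hits = []
    for rank, tid in enumerate(planted_order):
        lo, hi = (coverage or {}).get(tid, (1, spec.target_length))
        pairs = frozenset((t, t - lo + 1) for t in range(lo, hi + 1))
        prob = max(0.0, min(100.0, p_top - 2.0 * rank + rng.normal(0, 0.5)))
        hits.append(HitRecord(
            template_id=tid,
            raw_seq_score=100.0 - score_gap * rank + rng.normal(0, score_noise),
            raw_ss_score=50.0 - 0.5 * score_gap * rank + rng.normal(0, score_noise),
            probability=prob if rank > 0 else p_top,
            aligned_pairs=pairs,
        ))
    if path is not None:
        write_hit_table(hits, path)
    return hits


def make_ensemble(spec: SynthSpec, n_models: int = 20) -> ModelEnsemble:
    """An ensemble emulating a model-building run: rigid consensus core
    plus high-variance local regions.

    Each model is the native under a random whole-model rigid jitter, with
    Gaussian noise of ``loop_sigma`` A added only inside ``loop_intervals``.
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    rng = np.random.default_rng(spec.seed + 2)
    native = ideal_backbone(_sequence(spec.target_length), spec.backbone_model)
    loop_positions = {p for (s, e) in spec.loop_intervals
                      for p in range(s, e + 1)}
    models = []
    for _ in range(n_models):
        rot = _random_rotation(rng, spec.rigid_jitter_deg)
        trans = rng.uniform(-spec.rigid_jitter_trans, spec.rigid_jitter_trans, 3)
        m = _transform(native, rot, trans)
        if spec.loop_sigma > 0 and loop_positions:
            m = _add_noise(m, rng, spec.loop_sigma, loop_positions)
        models.append(m)
    return ModelEnsemble(models)
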