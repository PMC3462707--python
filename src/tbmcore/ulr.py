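"""Unreliable local regions (ULRs): detection, filtering, grafting, scoring.

A ULR is a contiguous stretch of the target — a loop or a terminus — that
varies among the generated models (large consensus fluctuation) or lacks
template coverage.  Detected regions pass a length filter (6 to 20
residues), at most 3 regions with the largest fluctuations are selected
for re-modeling, rebuilt coordinates are grafted back into the fixed core,
and each region is scored against the native structure by its CA RMSD
after superposing the *whole* structures (not the region alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from tbmcore.ensemble import FluctuationProfile
from tbmcore.metrics import kabsch
from tbmcore.structio import Residue, Structure

__all__ = ["UlrRegion", "detect", "filter_and_select", "graft", "ulr_rmsd",
           "UlrSkipped", "DEFAULT_THRESHOLD", "DEFAULT_MERGE_GAP"]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 2.0  # A; consensus fluctuation above this flags a residue
DEFAULT_MERGE_GAP = 2    # runs separated by <= this many residues are merged
MIN_ULR_LEN = 6
MAX_ULR_LEN = 20
MAX_ULR_COUNT = 3
PEPTIDE_BOND_RANGE = (1.2, 1.5)  # A, acceptable C-N junction distance


class UlrSkipped(Exception):
    """Raised when a region cannot be scored (mostly-disordered native)."""


@dataclass(frozen=True)
class UlrRegion:
    """A contiguous unreliable interval [start, end], 1-based inclusive."""

    start: int
    end: int
    kind: str  # 'loop' or 'terminus'
    reliability: float  # mean fluctuation over the region, A (larger = worse)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("require 1 <= start <= end")
        if self.kind not in ("loop", "terminus"):
            raise ValueError(f"unknown region kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


def _kind(start: int, end: int, target_length: int) -> str:
    return "terminus" if (start == 1 or end == target_length) else "loop"


def detect(profile: FluctuationProfile, threshold: float = DEFAULT_THRESHOLD,
           merge_gap: int = DEFAULT_MERGE_GAP) -> list[UlrRegion]:
    """Detect ULRs as maximal runs of residues with fluctuation >= threshold.

    Runs separated by at most ``merge_gap`` residues are merged into one
    region.  Each region's reliability score is the mean fluctuation over
    its residues; regions touching either end of the chain are termini,
    the rest loops.  Sorted by start position.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = profile.per_residue
    if len(vals) == 0:
        raise ValueError("empty fluctuation profile")
    length = len(vals)
    flagged = np.flatnonzero(vals >= threshold) + 1  # 1-based positions
    if len(flagged) == 0:
        return []
    runs: list[list[int]] = [[int(flagged[0]), int(flagged[0])]]
    for p in flagged[1:]:
        if p - runs[-1][1] - 1 <= merge_gap:
            runs[-1][1] = int(p)
        else:
            runs.append([int(p), int(p)])
    out = []
    for start, end in runs:
        rel = float(vals[start - 1: end].mean())
        out.append(UlrRegion(start, end, _kind(start, end, length), rel))
    return out


def filter_and_select(regions: Sequence[UlrRegion],
                      min_len: int = MIN_ULR_LEN,
                      max_len: int = MAX_ULR_LEN,
                      max_regions: int = MAX_ULR_COUNT) -> list[UlrRegion]:
    """Apply the ULR length filter and the selection cap.

    Regions shorter than ``min_len`` or longer than ``max_len`` residues
    are eliminated; of the survivors, the (at most) ``max_regions`` regions
    with the largest fluctuations are kept, ties going to the earlier start.
    The result is re-sorted by start position.
    """
    ordered = sorted(regions, key=lambda r: r.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(f"overlapping regions {a} and {b}")
    valid = [r for r in ordered if min_len <= r.length <= max_len]
    chosen = sorted(valid, key=lambda r: (-r.reliability, r.start))[:max_regions]
    return sorted(chosen, key=lambda r: r.start)


def graft(model: Structure,
          regions: UlrRegion | Sequence[UlrRegion],
          new_coords: Mapping[int, Mapping[str, np.ndarray]],
          ) -> tuple[Structure, list[dict]]:
    """Splice rebuilt coordinates into the fixed core of a model.

    ``new_coords`` maps each grafted residue position to its replacement
    atom coordinates.  Atoms outside all grafted regions are untouched
    (bit-identical); within a region, the residue's atoms are replaced
    wholesale.  Peptide-bond continuity at every junction is checked (C-N
    distance within 1.2-1.5 A) and reported in the returned junction list,
    never enforced.
    """
    if isinstance(regions, UlrRegion):
        regions = [regions]
    regions = sorted(regions, key=lambda r: r.start)
    for a, b in zip(regions, regions[1:]):
        if b.start <= a.end:
            raise ValueError("overlapping graft regions")
    wanted = {p for r in regions for p in r.positions}
    if set(new_coords) != wanted:
        raise ValueError(
            f"new_coords covers positions {sorted(new_coords)}, "
            f"regions require {sorted(wanted)}")
    by_pos = {r.seq_pos: r for r in model.residues}
    missing = wanted - set(by_pos)
    if missing:
        raise ValueError(f"model lacks residues at positions {sorted(missing)}")

    out = model.copy()
    for res in out.residues:
        if res.seq_pos in wanted:
            coords = new_coords[res.seq_pos]
            res.atoms = {k: np.asarray(v, dtype=float).copy()
                         for k, v in coords.items()}
            for name, xyz in res.atoms.items():
                if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                    raise ValueError(
                        f"bad coordinates for atom {name} at {res.seq_pos}")

    junctions = []
    out_by_pos = {r.seq_pos: r for r in out.residues}
    for region in regions:
        for prev_pos, next_pos in ((region.start - 1, region.start),
                                   (region.end, region.end + 1)):
            a, b = out_by_pos.get(prev_pos), out_by_pos.get(next_pos)
            if a is None or b is None or "C" not in a.atoms or "N" not in b.atoms:
                continue
            dist = float(np.linalg.norm(a.atoms["C"] - b.atoms["N"]))
            ok = PEPTIDE_BOND_RANGE[0] <= dist <= PEPTIDE_BOND_RANGE[1]
            junctions.append({"between": (prev_pos, next_pos),
                              "c_n_distance": dist, "ok": ok})
            if not ok:
                log.warning("junction %d-%d C-N distance %.2f A outside %s",
                            prev_pos, next_pos, dist, PEPTIDE_BOND_RANGE)
    return out, junctions


def ulr_rmsd(model: Structure, native: Structure, region: UlrRegion) -> float:
    """CA RMSD of a ULR after whole-structure superposition.

    The model is superposed onto the native on *all* shared, ordered,
    complete CA positions (the whole structures, not the region), then the
    RMSD is taken over the region's CA atoms with no re-superposition.
    Regions in which more than half of the native residues are disordered
    are not scored (:class:`UlrSkipped`).
    """
    if model.sequence != native.sequence:
        raise ValueError("model and native sequences differ")
    nat_by_pos = {r.seq_pos: r for r in native.residues}
    region_nat = [nat_by_pos.get(p) for p in region.positions]
    n_disordered = sum(1 for r in region_nat
                       if r is None or r.disordered or r.incomplete)
    if n_disordered * 2 > region.length:
        raise UlrSkipped(
            f"{n_disordered}/{region.length} native residues of "
            f"[{region.start},{region.end}] are disordered or missing")

    shared = [r.seq_pos for r in model.residues
              if not r.incomplete and not r.disordered
              and r.seq_pos in nat_by_pos
              and not nat_by_pos[r.seq_pos].incomplete
              and not nat_by_pos[r.seq_pos].disordered]
    outside = [p for p in shared if p not in set(region.positions)]
    if len(outside) < 3:
        raise ValueError("fewer than 3 residues outside the region to superpose on")
    mob = model.ca_coords(shared)
    fix = native.ca_coords(shared)
    sup = kabsch(mob, fix)
    moved = sup.apply(mob)
    idx = [i for i, p in enumerate(shared) if p in set(region.positions)]
    if not idx:
        raise UlrSkipped("no scorable residues inside the region")
    diff = moved[idx] - fix[idx]
    return float(np.sqrt((diff ** 2).sum() / len(idx)))
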