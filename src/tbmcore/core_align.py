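"""Core-region definition and terminus trimming around the external MSA step.

Terminus stretches of the target that no selected template aligns to carry
no template information; they are trimmed before the multiple sequence
alignment is built (so the aligner spends its effort on the reliable core)
and reattached afterwards as all-gap columns, left for the later local
re-modeling stage.  The core region itself is defined as the target
residues aligned to the single top-ranking template in the final MSA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from tbmcore.structio import AlignmentSet

__all__ = ["CoreMask", "TerminusTrim", "find_trim", "reattach", "core_mask"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoreMask:
    """Target positions (1-based) covered by the top template."""

    target_length: int
    core_positions: frozenset[int]

    def __post_init__(self) -> None:
        if self.core_positions and not (
                1 <= min(self.core_positions)
                and max(self.core_positions) <= self.target_length):
            raise ValueError("core positions outside [1, target_length]")

    @property
    def coverage(self) -> float:
        return len(self.core_positions) / self.target_length


@dataclass(frozen=True)
class TerminusTrim:
    """Terminal residues removed from the target before the MSA."""

    n_trim: int
    c_trim: int
    trimmed_seq: str
    full_seq: str

    def __post_init__(self) -> None:
        if self.n_trim < 0 or self.c_trim < 0:
            raise ValueError("trim lengths must be non-negative")
        expect = self.full_seq[self.n_trim: len(self.full_seq) - self.c_trim]
        if expect != self.trimmed_seq:
            raise ValueError("trimmed_seq inconsistent with trims and full_seq")


def find_trim(target_seq: str,
              alignments: Mapping[str, Iterable[tuple[int, int]]]) -> TerminusTrim:
    """Find the terminus stretches aligned to no template.

    ``alignments`` maps template id to its ``(target_pos, template_pos)``
    aligned pairs.  ``n_trim`` is the longest prefix 1..k of target
    positions aligned in no template; ``c_trim`` the analogous suffix.
    Interior unaligned positions are never trimmed.
    """
    if not target_seq:
        raise ValueError("empty target sequence")
    if not alignments:
        raise ValueError("need at least one template alignment")
    length = len(target_seq)
    covered = set()
    for pairs in alignments.values():
        covered.update(t for t, _ in pairs)
    n_trim = 0
    while n_trim < length and (n_trim + 1) not in covered:
        n_trim += 1
    if n_trim == length:  # nothing aligned at all: keep the sequence intact
        return TerminusTrim(0, 0, target_seq, target_seq)
    c_trim = 0
    while (length - c_trim) not in covered:
        c_trim += 1
    return TerminusTrim(n_trim, c_trim,
                        target_seq[n_trim: length - c_trim], target_seq)


def reattach(msa: AlignmentSet, trim: TerminusTrim) -> AlignmentSet:
    """Re-append trimmed termini to the MSA target row as all-gap columns.

    The trimmed residues go back as extra terminal columns gapped in every
    template row (no alignment to templates is attempted — they are left
    for local re-modeling).  Template rows are unchanged in their existing
    columns; the target row then ungaps to the full original sequence.
    """
    target_row = msa.ungapped(msa.target)
    if target_row != trim.trimmed_seq:
        raise ValueError("MSA target row does not match the trimmed sequence")
    if trim.n_trim == 0 and trim.c_trim == 0:
        return msa
    n_part = trim.full_seq[: trim.n_trim]
    c_part = trim.full_seq[len(trim.full_seq) - trim.c_trim:] if trim.c_trim else ""
    new_rows = []
    for name, row in zip(msa.names, msa.rows):
        if name == msa.target:
            new_rows.append(n_part + row + c_part)
        else:
            new_rows.append("-" * trim.n_trim + row + "-" * trim.c_trim)
    return AlignmentSet(msa.names, new_rows, target=msa.target)


def core_mask(msa: AlignmentSet, top_template: str) -> CoreMask:
    """Core region: target positions in columns where the top-template row
    is non-gap."""
    if top_template not in msa.names:
        raise KeyError(f"template {top_template!r} not in alignment")
    it = msa.names.index(msa.target)
    ik = msa.names.index(top_template)
    positions = set()
    for c in range(msa.ncol):
        pt = msa.col_to_pos[it][c]
        pk = msa.col_to_pos[ik][c]
        if pt is not None and pk is not None:
            positions.add(pt)
    length = len(msa.ungapped(msa.target))
    mask = CoreMask(length, frozenset(positions))
    if not positions:
        log.warning("top template %s aligns to no target residue: empty core",
                    top_template)
    else:
        log.info("core covers %d/%d target residues (%.0f%%)",
                 len(positions), length, 100 * mask.coverage)
    return mask
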