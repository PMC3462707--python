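"""Readers, writers and in-memory types for the formats the pipeline touches.

Conventions used throughout the package:

* Residue positions are **1-based and contiguous** over the target (or
  chain) sequence.  PDB author numbering is remapped on read; the original
  author numbers are kept in :attr:`Residue.author_num`.
* Alignment columns are 0-based; intervals are half-open ``[start, end)``.
* Coordinates are in Angstrom.

Hit tables are accepted in two dialects:

* ``hhr`` — HHsearch result files.  Only the fields the pipeline consumes
  are parsed: per-hit raw (sequence-similarity) score, secondary-structure
  score, probability, and the query-template alignment.
* ``tsv`` — a 5-column tab-separated dialect, one hit per line::

      template_id <TAB> raw_seq_score <TAB> raw_ss_score <TAB> probability <TAB> alignment

  ``alignment`` is a comma-separated list of ``target_pos:template_pos``
  pairs, both 1-based, strictly increasing in both coordinates, e.g.
  ``1:3,2:4,4:5``.  An empty alignment field is written as ``-``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Residue", "Structure", "HitRecord", "AlignmentSet",
    "read_pdb", "write_pdb",
    "read_hit_table", "write_hit_table",
    "read_alignment", "write_alignment",
]

#: three-letter -> one-letter codes for the 20 standard amino acids
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class Residue:
    """One amino-acid residue with its atom coordinates.

    ``seq_pos`` is the 1-based position in the remapped, contiguous chain
    numbering.  ``disordered`` marks residues missing from an experimental
    file (used to exclude them from metric computations); ``incomplete``
    marks residues lacking one of the N/CA/C backbone atoms.
    """

    seq_pos: int
    aa: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    disordered: bool = False
    author_num: int | None = None

    def __post_init__(self) -> None:
        if self.aa not in ONE_TO_THREE:
            raise ValueError(f"unknown amino-acid code {self.aa!r}")
        for name, xyz in self.atoms.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"atom {name!r} has non-finite or malformed coordinates")
            self.atoms[name] = arr

    @property
    def incomplete(self) -> bool:
        return any(a not in self.atoms for a in BACKBONE_ATOMS)

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class Structure:
    """An ordered chain of residues with 1-based contiguous numbering."""

    residues: list[Residue]
    chain_id: str = "A"
    source_path: str = ""

    def __post_init__(self) -> None:
        pos = [r.seq_pos for r in self.residues]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("residue seq_pos must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue_at(self, seq_pos: int) -> Residue | None:
        for r in self.residues:
            if r.seq_pos == seq_pos:
                return r
        return None

    def ca_coords(self, positions: Iterable[int] | None = None) -> np.ndarray:
        """CA coordinates for the given positions (default: all complete residues)."""
        if positions is None:
            rs = [r for r in self.residues if not r.incomplete and not r.disordered]
        else:
            wanted = set(positions)
            rs = [r for r in self.residues if r.seq_pos in wanted]
            missing = wanted - {r.seq_pos for r in rs}
            if missing:
                raise KeyError(f"positions absent from structure: {sorted(missing)}")
        return np.array([r.ca for r in rs], dtype=float)

    def copy(self) -> "Structure":
        return Structure(
            residues=[
                Residue(r.seq_pos, r.aa, {k: v.copy() for k, v in r.atoms.items()},
                        r.disordered, r.author_num)
                for r in self.residues
            ],
            chain_id=self.chain_id,
            source_path=self.source_path,
        )


@dataclass
class HitRecord:
    """One homology-search hit: raw scores and alignment to the target.

    ``aligned_pairs`` holds 1-based ``(target_pos, template_pos)`` pairs,
    one-to-one and monotone in both coordinates (no crossing pairs).
    ``z_seq``, ``z_ss`` and ``rescored`` stay ``None`` until rescoring.
    """

    template_id: str
    raw_seq_score: float
    raw_ss_score: float
    probability: float
    aligned_pairs: frozenset[tuple[int, int]] = frozenset()
    z_seq: float | None = None
    z_ss: float | None = None
    rescored: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 100.0):
            raise ValueError(f"probability {self.probability} outside [0, 100]")
        pairs = sorted(self.aligned_pairs)
        tpos = [p[0] for p in pairs]
        qpos = [p[1] for p in pairs]
        if len(set(tpos)) != len(tpos) or len(set(qpos)) != len(qpos):
            raise ValueError("aligned_pairs not one-to-one")
        if qpos != sorted(qpos):
            raise ValueError("aligned_pairs contain crossing pairs")
        self.aligned_pairs = frozenset(pairs)

    @property
    def target_positions(self) -> frozenset[int]:
        return frozenset(p[0] for p in self.aligned_pairs)


class AlignmentSet:
    """A target-plus-templates multiple alignment with column/residue maps.

    Row order is preserved from the input file; by convention the target is
    the first row unless a ``target`` name is given.  ``col_to_pos[i][c]``
    maps alignment column ``c`` (0-based) of row ``i`` to a 1-based residue
    position, or ``None`` at a gap.
    """

    def __init__(self, names: Sequence[str], rows: Sequence[str],
                 target: str | None = None) -> None:
        if len(names) != len(rows):
            raise ValueError("names and rows length mismatch")
        if len(rows) < 1:
            raise ValueError("alignment needs at least one row")
        if len(set(names)) != len(names):
            raise ValueError("duplicate row names")
        ncol = len(rows[0])
        for nm, row in zip(names, rows):
            if len(row) != ncol:
                raise ValueError(
                    f"row {nm!r} has length {len(row)}, expected {ncol}")
        self.names = list(names)
        self.rows = [r.upper() for r in rows]
        self.target = target if target is not None else self.names[0]
        if self.target not in self.names:
            raise ValueError(f"target row {self.target!r} not in alignment")
        self.col_to_pos: list[list[int | None]] = []
        for row in self.rows:
            pos = 0
            mapping: list[int | None] = []
            for ch in row:
                if ch == "-":
                    mapping.append(None)
                else:
                    pos += 1
                    mapping.append(pos)
            self.col_to_pos.append(mapping)

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def ungapped(self, name: str) -> str:
        return self.row(name).replace("-", "")

    def aligned_pairs(self, name_a: str, name_b: str) -> frozenset[tuple[int, int]]:
        """Residue-position pairs aligned between two rows (both non-gap)."""
        ia, ib = self.names.index(name_a), self.names.index(name_b)
        out = []
        for c in range(self.ncol):
            pa, pb = self.col_to_pos[ia][c], self.col_to_pos[ib][c]
            if pa is not None and pb is not None:
                out.append((pa, pb))
        return frozenset(out)


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path: str | Path, chain: str | None = None) -> Structure:
    """Read a PDB coordinate file into a :class:`Structure`.

    Only ATOM records of the first model are used; heteroatoms and waters
    are dropped.  Alternate locations are resolved to the highest-occupancy
    conformer.  Files with insertion codes are rejected: the pipeline's
    interval rules require an unambiguous sequential numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM records")
    st.setup_entities()
    model = st[0]
    chains = [ch.name for ch in model]
    if not chains:
        raise ValueError(f"{path}: no ATOM records")
    if chain is not None:
        if chain not in chains:
            raise ValueError(f"{path}: chain {chain!r} not found (has {chains})")
        sel = [ch for ch in model if ch.name == chain]
    else:
        sel = [model[0]]
    gch = sel[0]

    residues: list[Residue] = []
    seq_pos = 0
    for res in gch:
        if res.het_flag != "A":  # skip HETATM / waters
            continue
        if res.seqid.icode not in (" ", "", "\x00"):
            raise ValueError(
                f"{path}: residue {res.seqid.num}{res.seqid.icode} has an "
                "insertion code; renumber the file before use")
        aa = THREE_TO_ONE.get(res.name, "X")
        atoms: dict[str, np.ndarray] = {}
        best_occ: dict[str, float] = {}
        for atom in res:
            if atom.element.name == "H":
                continue
            occ = atom.occ
            if atom.name not in atoms or occ > best_occ[atom.name]:
                atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
                best_occ[atom.name] = occ
        if not atoms:
            continue
        seq_pos += 1
        residues.append(Residue(seq_pos, aa, atoms, author_num=res.seqid.num))
    if not residues:
        raise ValueError(f"{path}: no standard-residue ATOM records")
    return Structure(residues, chain_id=gch.name, source_path=str(path))


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a minimal PDB file (ATOM/TER/END)."""
    lines = []
    serial = 0
    for res in structure.residues:
        resname = ONE_TO_THREE[res.aa]
        num = res.author_num if res.author_num is not None else res.seq_pos
        for name in sorted(res.atoms, key=_atom_sort_key):
            serial += 1
            x, y, z = res.atoms[name]
            pad = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pad}{'':1s}{resname:>3s} "
                f"{structure.chain_id:1s}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2s}")
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _atom_sort_key(name: str) -> tuple[int, str]:
    order = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}
    return (order.get(name, 5), name)


# ---------------------------------------------------------------------------
# hit tables

def _parse_pairs(text: str) -> frozenset[tuple[int, int]]:
    if text.strip() in ("", "-"):
        return frozenset()
    pairs = []
    for tok in text.strip().split(","):
        t, q = tok.split(":")
        pairs.append((int(t), int(q)))
    return frozenset(pairs)


def _format_pairs(pairs: Iterable[tuple[int, int]]) -> str:
    ordered = sorted(pairs)
    return ",".join(f"{t}:{q}" for t, q in ordered) if ordered else "-"


def read_hit_table(path: str | Path, dialect: str = "tsv") -> list[HitRecord]:
    """Read a homology-search hit table (``tsv`` or ``hhr`` dialect).

    Hits are returned in file order with the rescoring fields unset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv_hits(path)
    if dialect == "hhr":
        return _read_hhr_hits(path)
    raise ValueError(f"unknown hit-table dialect {dialect!r}")


def _read_tsv_hits(path: Path) -> list[HitRecord]:
    hits: list[HitRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != 5:
            raise ValueError(
                f"{path}:{lineno}: expected 5 tab-separated columns, got {len(cells)}")
        try:
            hit = HitRecord(
                template_id=cells[0],
                raw_seq_score=float(cells[1]),
                raw_ss_score=float(cells[2]),
                probability=float(cells[3]),
                aligned_pairs=_parse_pairs(cells[4]),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hits in the 5-column TSV dialect (see module docstring)."""
    lines = []
    for h in hits:
        lines.append("\t".join([
            h.template_id,
            repr(h.raw_seq_score),
            repr(h.raw_ss_score),
            repr(h.probability),
            _format_pairs(h.aligned_pairs),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_hhr_hits(path: Path) -> list[HitRecord]:
    """Parse an HHsearch ``.hhr`` result file.

    Only the summary-table Prob/Score/SS columns and the Q/T alignment
    blocks are read; everything else in the format is ignored.
    """
    text = path.read_text()
    lines = text.splitlines()
    # summary table: starts after the " No Hit ..." header line
    try:
        hdr = next(i for i, l in enumerate(lines)
                   if l.lstrip().startswith("No Hit"))
    except StopIteration:
        raise ValueError(f"{path}: no HHR summary table header found")
    summary: dict[int, tuple[str, float, float, float]] = {}
    for line in lines[hdr + 1:]:
        if not line.strip():
            break
        # fixed-ish columns: " No Hit(30) Prob E-value P-value Score SS Cols ..."
        try:
            no = int(line[:4])
            hit_name = line[4:34].strip().split()[0]
            rest = line[34:].split()
            prob, _ev, _pv, score, ss = (float(rest[0]), rest[1], rest[2],
                                         float(rest[3]), float(rest[4]))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed summary line {line!r}") from exc
        summary[no] = (hit_name, prob, score, ss)

    # alignment blocks: "No <n>" then Q/T coordinate lines
    hits: list[HitRecord] = []
    i = hdr + 1
    block_no = None
    q_chunks: list[tuple[int, str]] = []
    t_chunks: list[tuple[int, str]] = []

    def flush() -> None:
        if block_no is None:
            return
        name, prob, score, ss = summary[block_no]
        pairs = _pairs_from_chunks(q_chunks, t_chunks)
        hits.append(HitRecord(name, score, ss, prob, pairs))

    for line in lines:
        s = line.strip()
        if s.startswith("No ") and s[3:].strip().isdigit():
            flush()
            block_no = int(s[3:].strip())
            q_chunks, t_chunks = [], []
        elif block_no is not None and s.startswith("Q ") and "Consensus" not in s:
            parts = s.split()
            if len(parts) >= 4 and parts[2].isdigit() and parts[1] != "ss_pred":
                q_chunks.append((int(parts[2]), parts[3]))
        elif block_no is not None and s.startswith("T ") and "Consensus" not in s:
            parts = s.split()
            if len(parts) >= 4 and parts[2].isdigit() and parts[1] not in (
                    "ss_pred", "ss_dssp", "ss_conf"):
                t_chunks.append((int(parts[2]), parts[3]))
    flush()
    if not hits:
        raise ValueError(f"{path}: no alignment blocks found")
    return hits


def _pairs_from_chunks(q_chunks: list[tuple[int, str]],
                       t_chunks: list[tuple[int, str]]) -> frozenset[tuple[int, int]]:
    pairs = []
    for (qstart, qseq), (tstart, tseq) in zip(q_chunks, t_chunks):
        if len(qseq) != len(tseq):
            raise ValueError("HHR alignment rows of unequal length")
        qi, ti = qstart, tstart
        for qc, tc in zip(qseq, tseq):
            if qc != "-" and tc != "-":
                pairs.append((qi, ti))
            if qc != "-":
                qi += 1
            if tc != "-":
                ti += 1
    return frozenset(pairs)


# ---------------------------------------------------------------------------
# alignments

def read_alignment(path: str | Path, fmt: str = "fasta",
                   target: str | None = None) -> AlignmentSet:
    """Read an aligned FASTA or CLUSTAL file into an :class:`AlignmentSet`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    aln = AlignIO.read(str(path), fmt)
    if len(aln) < 2:
        raise ValueError(f"{path}: alignment needs at least 2 rows")
    names = [rec.id for rec in aln]
    rows = [str(rec.seq) for rec in aln]
    return AlignmentSet(names, rows, target=target)


def write_alignment(aln: AlignmentSet, path: str | Path, fmt: str = "fasta") -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=name, description="")
         for name, row in zip(aln.names, aln.rows)])
    AlignIO.write(msa, str(path), fmt)
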