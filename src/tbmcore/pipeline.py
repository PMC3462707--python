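"""End-to-end orchestration of the decision pipeline.

The flow mirrors a full template-based modeling run: template selection ->
core alignment -> [external model building] -> representative selection ->
ULR detection/selection -> [external reconstruction] -> grafting.  Stages
marked external (multiple sequence alignment, model building, loop
reconstruction) are file-level slots: the pipeline consumes their outputs
when supplied and otherwise records them as ``SKIPPED(external)``.
Every run writes a JSON report listing, for each stage, the rule that
fired and the ids going in and out; re-running with the same config and
inputs reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from tbmcore import core_align, ensemble as ens_mod, template_select, ulr as ulr_mod
from tbmcore.structio import (
    AlignmentSet, Structure, read_alignment, read_hit_table, read_pdb, write_pdb,
)
from tbmcore.template_select import SelectionParams, SelectionReport, WeightSchedule

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and tunables for one pipeline run (fully serializable)."""

    hits_path: str = ""
    hits_dialect: str = "tsv"
    structures_dir: str = ""
    target_sequence: str = ""       # one-letter codes; or read from target_fasta
    target_fasta: str = ""
    msa_path: str = ""              # external aligner output (aligned FASTA)
    models_dir: str = ""            # external model-building output (PDB files)
    loop_coords_dir: str = ""       # external reconstruction output, <start>_<end>.pdb
    out_dir: str = "tbm_out"
    seed: int = 0

    candidate_cap: int = 20
    high_ranker_fraction: float = 0.95
    min_pool_size: int = 3
    final_tm_cutoff: float = 0.5
    detection_threshold: float = ulr_mod.DEFAULT_THRESHOLD
    merge_gap: int = ulr_mod.DEFAULT_MERGE_GAP
    min_ulr_len: int = ulr_mod.MIN_ULR_LEN
    max_ulr_len: int = ulr_mod.MAX_ULR_LEN
    max_ulr_count: int = ulr_mod.MAX_ULR_COUNT
    cluster_cutoff: float = ens_mod.DEFAULT_CLUSTER_CUTOFF
    weight_bins: list = field(default_factory=lambda: [
        [90.0, 1.0], [80.0, 1.5], [60.0, 2.0], [None, 2.6]])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def selection_params(self) -> SelectionParams:
        return SelectionParams(
            candidate_cap=self.candidate_cap,
            high_ranker_fraction=self.high_ranker_fraction,
            min_pool_size=self.min_pool_size,
            final_tm_cutoff=self.final_tm_cutoff)

    def weight_schedule(self) -> WeightSchedule:
        bins = tuple((float("-inf") if b is None else float(b), float(w))
                     for b, w in self.weight_bins)
        return WeightSchedule(bins=bins)


def _read_target_sequence(config: PipelineConfig) -> str:
    if config.target_sequence:
        return config.target_sequence
    if config.target_fasta:
        from Bio import SeqIO
        rec = next(SeqIO.parse(config.target_fasta, "fasta"))
        return str(rec.seq)
    raise ValueError("config needs target_sequence or target_fasta")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the implemented stages in order; returns the run report.

    Side effects under ``config.out_dir``: ``templates.tsv``,
    ``core_mask.tsv``, ``ulr_regions.tsv``, ``final_model.pdb`` (when loop
    coordinates are supplied) and ``report.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": []}

    def stage(name: str, **payload) -> None:
        report["stages"].append({"stage": name, **payload})
        log.info("stage %s: %s", name,
                 payload.get("status", payload.get("rule", "")))

    target_seq = _read_target_sequence(config)

    # --- 1. template selection -------------------------------------------
    if not config.hits_path:
        raise FileNotFoundError("template selection needs hits_path")
    hits = read_hit_table(config.hits_path, config.hits_dialect)
    structures: dict[str, Structure] = {}
    sdir = Path(config.structures_dir)
    for h in hits[: config.candidate_cap]:
        p = sdir / f"{h.template_id}.pdb"
        if not p.exists():
            raise FileNotFoundError(
                f"template selection: expected structure file {p}")
        structures[h.template_id] = read_pdb(p)
    sel_report = SelectionReport()
    selected = template_select.select_templates(
        hits, structures, target_length=len(target_seq),
        params=config.selection_params(), schedule=config.weight_schedule(),
        report=sel_report)
    with open(out_dir / "templates.tsv", "w") as fh:
        fh.write("template_id\thhsearch_rank\trescored_S\tselected_flag\tremoval_stage\n")
        hh_rank = {h.template_id: i + 1 for i, h in enumerate(hits)}
        for tid in sel_report.ranked_ids or selected:
            removal = ("pool" if tid in sel_report.removed_pool_stage else
                       "final_tm" if tid in sel_report.removed_final_stage else "-")
            s_val = sel_report.rescored.get(tid)
            fh.write(f"{tid}\t{hh_rank[tid]}\t"
                     f"{'' if s_val is None else f'{s_val:.6f}'}\t"
                     f"{int(tid in selected)}\t{removal}\n")
    stage("template_selection", status="DONE",
          rule="rescore->top20->split->pool->pool_filter->final_tm_filter",
          ids_in=[h.template_id for h in hits], selected=selected,
          high=sorted(sel_report.high), pool=sorted(sel_report.pool),
          removed_pool=sel_report.removed_pool_stage,
          removed_final=sel_report.removed_final_stage)

    # --- 2. terminus trim + core alignment -------------------------------
    by_id = {h.template_id: h for h in hits}
    trim = core_align.find_trim(
        target_seq, {tid: sorted(by_id[tid].aligned_pairs) for tid in selected})
    stage("terminus_trim", status="DONE",
          rule="termini aligned to no selected template are deferred",
          n_trim=trim.n_trim, c_trim=trim.c_trim)

    mask = None
    if config.msa_path:
        msa = read_alignment(config.msa_path, "fasta")
        if msa.ungapped(msa.target) == trim.trimmed_seq and (
                trim.n_trim or trim.c_trim):
            msa = core_align.reattach(msa, trim)
        mask = core_align.core_mask(msa, selected[0])
        with open(out_dir / "core_mask.tsv", "w") as fh:
            fh.write("target\tstart0\tend\tlabel\n")
            for s, e in _runs(sorted(mask.core_positions)):
                fh.write(f"target\t{s - 1}\t{e}\tcore\n")
        stage("core_alignment", status="DONE",
              rule="core = target residues aligned to the top template",
              coverage=round(mask.coverage, 4))
    else:
        stage("core_alignment", status="SKIPPED(external)",
              expected="msa_path (aligned FASTA from an external aligner)")

    # --- 3. model building (external) + representative -------------------
    rep_idx = None
    ensemble = None
    if config.models_dir:
        mdir = Path(config.models_dir)
        paths = sorted(mdir.glob("*.pdb"))
        if len(paths) < 2:
            raise FileNotFoundError(
                f"representative selection: need >=2 model PDBs in {mdir}")
        ensemble = ens_mod.ModelEnsemble([read_pdb(p) for p in paths])
        rep_idx = ens_mod.representative(ensemble, config.cluster_cutoff)
        stage("representative", status="DONE",
              rule="member of the largest cluster nearest its center",
              model=paths[rep_idx].name, index=rep_idx, n_models=len(paths))
    else:
        stage("model_building", status="SKIPPED(external)",
              expected="models_dir (directory of candidate model PDBs)")

    # --- 4. ULR detection and selection ----------------------------------
    regions = []
    if ensemble is not None:
        profile = ens_mod.fluctuation(ensemble, reference=rep_idx)
        detected = ulr_mod.detect(profile, config.detection_threshold,
                                  config.merge_gap)
        regions = ulr_mod.filter_and_select(
            detected, config.min_ulr_len, config.max_ulr_len,
            config.max_ulr_count)
        with open(out_dir / "ulr_regions.tsv", "w") as fh:
            fh.write("start\tend\tlength\tkind\treliability\n")
            for r in regions:
                fh.write(f"{r.start}\t{r.end}\t{r.length}\t{r.kind}\t"
                         f"{r.reliability:.4f}\n")
        stage("ulr_detection", status="DONE",
              rule="consensus fluctuation >= threshold; keep length 6-20; "
                   "up to 3 with largest fluctuation",
              detected=[[r.start, r.end] for r in detected],
              selected=[[r.start, r.end] for r in regions])
    else:
        stage("ulr_detection", status="SKIPPED(external)",
              expected="models_dir (ensemble required for consensus detection)")

    # --- 5. reconstruction (external) + grafting --------------------------
    if regions and config.loop_coords_dir and ensemble is not None:
        ldir = Path(config.loop_coords_dir)
        new_coords = {}
        grafted_regions = []
        for r in regions:
            p = ldir / f"{r.start}_{r.end}.pdb"
            if not p.exists():
                stage("grafting", status="ERROR",
                      expected=f"loop coordinates file {p}")
                raise FileNotFoundError(f"grafting: expected loop file {p}")
            loop = read_pdb(p)
            if len(loop) != r.length:
                raise ValueError(f"{p}: {len(loop)} residues, region needs {r.length}")
            for res, pos in zip(loop.residues, r.positions):
                new_coords[pos] = dict(res.atoms)
            grafted_regions.append(r)
        rep_model = ensemble.models[rep_idx]
        final, junctions = ulr_mod.graft(rep_model, grafted_regions, new_coords)
        write_pdb(final, out_dir / "final_model.pdb")
        stage("grafting", status="DONE",
              rule="replace region atoms; core untouched; junction C-N checked",
              regions=[[r.start, r.end] for r in grafted_regions],
              junctions=junctions)
    elif regions:
        stage("loop_reconstruction", status="SKIPPED(external)",
              expected="loop_coords_dir with <start>_<end>.pdb per region")

    report["representative_index"] = rep_idx
    report["selected_templates"] = selected
    report["ulr_regions"] = [[r.start, r.end] for r in regions]
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _runs(sorted_positions: list[int]) -> list[tuple[int, int]]:
    if not sorted_positions:
        return []
    runs = [[sorted_positions[0], sorted_positions[0]]]
    for p in sorted_positions[1:]:
        if p == runs[-1][1] + 1:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    return [tuple(r) for r in runs]
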