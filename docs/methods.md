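# Methods

This note documents the models and procedures `tbmcore` implements, the
defaults it ships, the design choices that were genuinely open, and what
the synthetic test bed does and does not demonstrate.

## Scope and architecture

`tbmcore` is the decision layer of a template-based modeling (TBM)
pipeline. It deliberately excludes the compute-heavy stages — profile
search, multiple sequence alignment, restraint-based model building, and
ab initio loop sampling — which are consumed as file-level inputs
(hit tables, aligned FASTA, directories of model PDBs, rebuilt loop
coordinates). The pipeline report marks those stages `SKIPPED(external)`
when their outputs are absent. This keeps the package pure Python,
deterministic, and testable end to end against synthetic ground truth.

Residue indexing is 1-based and contiguous over the target sequence; PDB
author numbering is remapped on read (originals retained as metadata)
because every selection rule in the pipeline — length bounds, termini,
region intervals — is a sequence-interval rule. Alignment columns are
0-based, intervals half-open internally; user-facing regions are 1-based
inclusive. Heteroatoms, waters and hydrogens are dropped on read;
residues missing any of N/CA/C are flagged incomplete and excluded from
all metric computations, as are residues flagged disordered.

## Hit rescoring

Hits are re-ranked by `S = Z_seq + w·Z_ss`. Both Z-scores are computed
over the full input hit population with the *population* standard
deviation (the hit list is the entire population of interest, and
selection pools can be as small as 3, where the n−1 estimator is noisy);
an all-equal channel maps to zeros rather than dividing by zero. The
weight `w` is a piecewise-constant function of the probability `p`
(percent) reported for the original, pre-rescoring top hit:
1.0 for p ≥ 90, 1.5 for 80 ≤ p < 90, 2.0 for 60 ≤ p < 80, 2.6 for p < 60,
with inclusive lower bounds. These four bins are shipped as constants;
re-fitting them is out of scope. Ties in `S` preserve the original search
rank (stable sort), so equal-score inputs produce identical output in any
input order.

## Multiple-template selection

The procedure operates on the top 20 rescored hits:

1. **Split.** High-rankers are hits with `S ≥ 0.95·S_top`. The 95%
   fraction rule is only meaningful for a positive top score; Z-score
   sums can make `S_top ≤ 0`, in which case the high-ranker set
   degenerates to the top hit alone and the pool fallback (step 2) takes
   over. This preserves the "whichever is greatest" intent of the rule.
2. **Background pool.** The high-rankers, or the top 3 rescored hits,
   whichever set is larger (all hits when fewer than 3 exist). The top-3
   fallback uses *rescored* rank, consistent with re-ranking preceding
   every later stage.
3. **Pool dissimilarity filter.** A candidate's similarity is its mean
   TM-score to pool members; a pool member is excluded from its own mean
   (self-similarity of 1 would bias pool members upward). With `m_pool`
   and `σ_pool` the mean and population standard deviation of the pool
   members' similarities, candidate `c` is removed iff
   `sim(c) < m_pool − α(c)·σ_pool`, with α = 1 for high-rankers and the
   ratio `S_c/S_top` for low-rankers, clamped to [0, 1] (a negative or
   >1 ratio would invert the removal logic). The top hit is never
   removed. Because low-rankers with non-positive `S` get α = 0, their
   cutoff is the pool mean itself — the filter is intentionally strict
   for weakly-scoring candidates.
4. **Final dissimilarity filter.** Candidates with TM-score < 0.5 to the
   top hit are removed, the top hit's sequence length serving as the
   TM-score reference length. This runs after the pool filter, following
   the procedure's stated order.

Pairwise template TM-scores are computed on residue pairs where both
templates align to a common target position (their hit alignments
composed through the target), with the target sequence length as the
reference length. This is the only correspondence available without
running a structure aligner, and it matches the stated convention for
within-pipeline TM-scores.

## Structural metrics

**Kabsch superposition** is the standard SVD solution with the reflection
branch excluded; collinear or coincident point sets raise an error rather
than returning an arbitrary in-plane orientation.

**TM-score** uses `d0 = 1.24·(L_ref − 15)^⅓ − 1.8` Å, floored at 0.5 Å
(the formula is non-positive for L_ref ≲ 20; for L_ref ≤ 15 the floor
applies directly). The reference length is an explicit argument because
the pipeline uses different conventions at different stages (target
length for template-template comparisons, top-ranker length for the final
filter). The search protocol seeds superpositions from all gapless
aligned fragments of lengths L, L/2, L/4 (minimum 4 residues), then
alternates "superpose on residues within d0, rescore" to convergence and
reports the maximum. This closely reproduces the published TM-score
search at the problem sizes handled here; it is not a sequence-independent
structure aligner.

**GDT-TS** is the mean over 1/2/4/8 Å thresholds of the maximal
percentage of paired CA atoms superposable under each threshold,
normalized by the number of usable reference residues. Exact GDT is
exponential; the search extends the TM-score heuristic with a hill climb
over k-nearest-residue selections, which reaches non-contiguous optima a
pure distance-cut iteration misses. An exhaustive-subset oracle bounds
the heuristic in the test suite at toy scale (10 residues, all 2^10
subsets); the full-pair-set superposition is always among the candidates,
so the heuristic never scores below the naive single-fit answer. Only the
TS variant is implemented.

**χ accuracy** counts residues whose χ1 (or both χ1 and χ2) lie within
30° of the reference value, over residues possessing the dihedral(s) in
both structures, using circular differences. Terminal groups with
180°-symmetric tips (ASP, PHE, TYR χ2) are compared modulo 180°, per
standard assessment practice. Structures with no χ-bearing residues raise
an error rather than returning an arbitrary percentage.

**Paired t-test** is the two-tailed Student's test on paired differences
with n−1 degrees of freedom and the sample (n−1) standard deviation,
delegated to `scipy.stats.ttest_rel` and cross-checked against hand
arithmetic in the tests.

## Ensemble consensus

The clustering behind representative selection is single linkage on the
pairwise full-chain CA-RMSD matrix with a 2.0 Å default cutoff; no
specific algorithm is mandated by the procedure this implements, and
single linkage with a documented default is reproducible and testable
against an independent hierarchical-clustering oracle. The representative
is the member of the largest cluster (ties: the cluster containing the
lowest index) minimizing mean RMSD to its co-members (ties: lowest
index).

The fluctuation profile is the mean per-residue CA deviation from the
representative after superposing each model on the *consensus core*: an
iterative fit that, up to 10 times, drops residues deviating by more than
twice the median deviation and refits (never below 4 residues). A
consensus-based quality estimate could equally be built from pairwise
model-model distances; the deviation-from-reference form was chosen as
the simplest estimator consistent with "fluctuation among models", and
the detector's parameter-recovery tests exercise exactly this choice.

## ULR detection and handling

Residues with fluctuation ≥ 2.0 Å (default) form maximal runs; runs
separated by ≤ 2 residues are merged. The threshold and merge gap are
configurable; the defaults recover planted flexible intervals of σ = 3 Å
in the synthetic ensembles while leaving rigid regions unflagged.
Regions touching position 1 or L are termini, others loops. The length
filter (6–20 residues) and the selection cap (up to 3 regions, largest
mean fluctuation first, ties to the earlier start) are applied uniformly
to loops and termini; a config flag can exempt termini from the upper
length bound, documenting the ambiguity, but the default applies the rule
to all regions.

Grafting replaces the atoms of the selected regions wholesale and
guarantees bit-identical coordinates everywhere else. Peptide-bond
continuity at junctions (C–N distance within 1.2–1.5 Å) is checked and
reported, never enforced — junction repair belongs to the external
reconstruction method.

ULR accuracy is the CA RMSD over the region *after superposing the whole
structures* on all shared ordered residues, with no re-superposition on
the region; this keeps local errors visible instead of letting the region
fit itself. Regions in which more than half of the native residues are
disordered are skipped (signalled via an exception), mirroring the
exclusion used when evaluating against experimental structures.

## Synthetic test bed

The generator builds natives from ideal backbone geometry (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å; helix φ/ψ −57°/−47°, extended −120°/140°,
ω 180°) with side-chain stubs out to the χ2-defining atom. Templates are
natives plus 0.3 Å Gaussian coordinate noise; decoys additionally have
the second half of the chain rigidly rotated and displaced 25 Å, which
pins their TM-score to the native below 0.5 while templates stay above
0.9 — the separation the final filter needs. Hit tables plant a known
order with a gap-to-noise ratio of 10 (4.0 score units per rank, σ 0.4),
so rescoring recovers the planted order in ≥ 95% of seeds. Ensembles are
natives under small whole-model rigid jitter (≤ 5°, ≤ 1 Å) plus σ = 3 Å
noise confined to declared loop intervals — precisely the rigid-core /
flexible-local structure the consensus detector assumes. All generators
are pure functions of their spec and seed.

What passing these tests shows: the decision rules are implemented
exactly (bin boundaries, strict inequalities, caps), the filters agree
with brute-force transcriptions, and the detector recovers planted
flexibility under its own statistical assumptions. What it does not show:
performance on real homology hits (whose score distributions are not
Gaussian), real model ensembles (whose errors are correlated along the
chain and coupled to secondary structure), or experimental structures
(alternate conformations, real disorder). Problem sizes in the tests and
the acceptance script (targets of 30–60 residues, ensembles of 6–10
models, families of 4–8 candidates) were chosen as the smallest sizes at
which every rule — pool statistics, cluster structure, interval merging —
is non-trivially exercised.

## Numerical conventions

Population standard deviation in Z-scores and pool statistics; sample
standard deviation in the t-test (its definition). Strict `<` in both
removal rules, so boundary candidates (TM exactly 0.5; similarity exactly
at the cutoff) are retained. Stable sorts with documented tie-breaks
everywhere a rank is taken. σ_pool = 0 (all pool similarities equal)
makes the cutoff equal the common value, removing nothing, by the strict
inequality. PDB coordinates round-trip at the format's 10⁻³ Å precision;
determinism claims for written files are at byte level.

## Known limitations

- The TM-score/GDT heuristics are documented approximations; the GDT
  oracle equivalence is established at toy scale only.
- The target-mediated template-template correspondence understates the
  similarity of template pairs whose alignments to the target barely
  overlap; such pairs score near 0 and are handled by the filters'
  strict-inequality conventions.
- mmCIF, insertion codes, multi-model NMR files beyond the first model,
  and sequence-independent structure alignment are unsupported.
- The χ-accuracy metric requires identical sequences; it is a model
  metric, not a template metric.
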