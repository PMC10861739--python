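# Methods

This note documents the models, parameters and design choices behind
`modpanel`, and what the synthetic benchmark does and does not establish.

## Module response statistic

For a module *m* with constitutive gene set *G(m)* and a per-gene
differential-expression call vector, the response is

    response(m) = 100 · (#up − #down) / |G(m)|   ∈ [−100, +100].

The netting rule `%up − %down` was adopted for mixed modules because it is
the only deterministic reduction that reproduces both endpoints (+100 when
every transcript increases, −100 when every one decreases) and leaves no
tie ambiguity when retaining a "dominant" direction. Constitutive genes
missing from the expression matrix count as null calls and are logged.

### Differential-expression calls

*Group level* (per timepoint vs. the postpartum reference):

- Test: Welch two-sample *t*-test between the timepoint's samples and the
  reference samples. A one-sample variant (timepoint samples against the
  per-gene reference mean treated as a constant) exists behind
  `one_sample=True` for fidelity experiments; Welch is the default because
  the reference mean has sampling variance of its own.
- Gates: fold change ≥ `fc_group` (default 1.5) or ≤ its reciprocal —
  fold changes being ratios, "|FC| > c" is read as FC > c or FC < 1/c —
  and raw p < `p_group` (default 0.1). A Benjamini–Hochberg variant is
  available behind `bh_correct=True`, default off.
- Fold change is computed on the linear normalized scale. On the counts
  platform a pseudocount of 1 is added to both means to guard zero
  denominators; on the intensity platform (background-subtracted values) no
  pseudocount is used and non-positive reference means produce a flagged
  null call. Tests run on linear values by default; `log_transform=True`
  switches the *t*-test to log2(x+1).

*Individual sample level*: a conjunction of fixed cut-offs, value/reference
> `fc_indiv` (1.5, strict) AND value − reference > `diff_indiv` (10, in the
dataset's own normalized units; the cut-off is a config default, not a
constant), symmetric for down-calls.

The baseline is the arithmetic per-gene mean over the reference-timepoint
samples (three-month postpartum for the counts cohort, postpartum for the
intensity cohort).

## Set delineation

Trajectories used for clustering are the per-timepoint *signed module
responses* over the pregnancy timepoints (postpartum excluded). Responses,
rather than raw expression, are clustered because the whole selection
narrative is response-driven; raw-expression clustering would conflate
baseline abundance with trajectory shape.

- Aggregate filter: default rule retains an aggregate iff at least one
  constitutive module reaches 10% mean |response|; an alternative rule
  (mean over the aggregate's modules ≥ 10%) is selectable via
  `aggregate_rule="aggregate_mean"`. Both are legitimate readings of the
  filter; divergent outcomes are logged.
- Ranking: modules with mean |response| strictly above 10%, best first,
  truncated to the top 10; ties break on module id.
- Clustering: agglomerative, distance 1 − Pearson *r*, average linkage,
  tree cut at cophenetic distance 0.5, per cohort independently. These
  three are config keys: correlation distance matches the goal of grouping
  coherent expression patterns, and average linkage is the conservative
  default for correlation distances. Constant trajectories have no defined
  correlation and are set aside as singletons with a warning.
- Sets: blocks of the meet of the two cohort partitions (co-clustered in
  both cohorts) with ≥ 2 modules are candidates. A singleton block is also
  a candidate when it forms a distinct (singleton) cluster in the primary
  cohort's dendrogram — this is what admits legitimate one-module sets
  while keeping modules whose placement simply disagrees across cohorts in
  the NS bucket; judging distinctness in either cohort instead
  (`singleton_rule="any"`) would promote every cross-cohort disagreement
  to its own set. Candidates are ranked by size (ties: smallest module
  id), the top `max_sets=3` become S1–S3, everything else is NS. NS
  modules do not enter gene selection.

## Gene screening cascade

- **Abundance**: median of normalized counts over all samples of the
  counts cohort; genes with median < 50 are excluded (exactly 50 passes).
  The intensity platform has no counts, so this screen runs on the counts
  cohort only.
- **Correlation**: a gene's trajectory is its per-timepoint mean expression
  across samples (all timepoints including postpartum), per cohort —
  per-timepoint means rather than per-sample values because the intensity
  cohort is unpaired across timepoints (a per-sample mode would have no
  sample correspondence). The module-set mean excludes the gene under
  evaluation (leave-one-out) to avoid self-correlation inflation; the
  effect is negligible for large sets. Exclusion if *r* < 0.5 or
  *p* > 0.05 (two-sided, *t*-distribution on n−2 df) in either cohort;
  both boundaries pass. Survivors get `R = mean(r_a, r_b)`.
- **Literature**: consumed from a precomputed annotation TSV (a live
  database query would not be reproducible); the search string used is
  stored as provenance. Title hit → 2, abstract-only → 1, else 0; genes
  without a row score 0.
- **Selection**: per set, rank by final score (= literature + R)
  descending, ties by R then gene id; cap at 4 per set
  (ranking-then-cap). Sets with fewer survivors contribute all of them and
  are flagged short; sets with none are flagged empty.

### Supplementation and housekeeping

Supplements fill the panel to `target_test_size` (176): one gene per
excluded aggregate, one per empty set, then extras from short sets. The
ranking within each supplement pool — literature score descending, then
median count descending, then gene id — is this package's concretization
of "expression magnitude and literature profiling"; pools are restricted
to genes passing a relaxed abundance gate
(`relaxed_median_factor × min_median`, default 10). Failure to reach the
target is a hard error listing the shortfall; supplements never duplicate
a gene already in the panel.

Housekeeping genes (8): the first 4 prior-panel genes present in both
cohorts, the 2 genes minimizing the mean of the two per-dataset %CV values
(100·sd/mean, sample sd) among genes not already used, and 2
literature-nominated genes.

## Synthetic data

The generator emulates the study conditions end to end:

- **Repertoire**: 38 aggregates / 382 modules / 10 genes per module by
  default (two aggregates carry an eleventh module so the counts divide).
- **Cohorts**: a counts cohort with timepoints T1, T2, T3, D, P1, P2 and
  15/15/15/15/13/15 subjects (88 profiles), negative-binomial noise
  (dispersion 0.1) around log-normal baselines (meanlog 6, sdlog 1.5 on
  the natural-log scale — median ≈ 400 counts); and an unpaired intensity
  cohort with four gestational windows plus postpartum and 38/37/37/35/17
  samples, log2-normal noise (sd 0.15).
- **Trajectory shapes** (log2 effects over the four pregnancy stages,
  postpartum fixed at 0 so the baseline is well defined):
  down-then-rebound (−0.2, −0.65, −1.0, −1.3), up-peaking-in-T3
  (0.2, 0.65, 1.0, 0.8), a transient mid-pregnancy shape
  (0.25, 1.0, 0.5, 0.1) used for planted singleton sets, and null. The
  graded magnitudes make the per-timepoint % response non-constant (a
  saturated ±100-everywhere module would have an undefined trajectory
  correlation); per-gene effect jitter U(0.8, 1.2) is shared across
  cohorts so co-clustering and cross-cohort correlation are real signals.
- **Planted truth**: 22 of 38 aggregates responsive, each with a 3-module
  and a 2-module set of opposed shapes (two aggregates add a singleton
  transient set, giving 46 sets); per-set panel genes with title-level
  literature hits and high baselines; planted low-abundance genes; 6
  planted empty sets (all genes below the abundance gate), 6 three-gene
  and 1 two-gene set. Class baselines are chosen so the abundance-gate
  outcome is invariant to the planted trajectory (the median multiplier
  across samples stays within [0.58, 1.7]).

A separate **noise-free selection scenario** reproduces the published
design arithmetic exactly (46 single-module sets of 55 genes; 2,530
candidates, 894 below the gate; survivor counts 5/3/2/0 across 33/6/1/6
sets; 16 quiet aggregates; deterministic supplement and housekeeping
picks). Gene values are exact trajectory multiples, so every screening
count is a reproducible consequence of running the screening code.

### What the benchmark does not show

Samples are independent draws per timepoint: there is no subject-level
longitudinal autocorrelation, no batch effects, and no read-level
sequencing artifacts. Module gene sets are disjoint and noise is
homoscedastic within platform. Passing the planted-recovery tests
demonstrates that the pipeline's logic is faithful and stable under
realistic noise magnitudes — not that real cohorts would yield the same
set counts, which are data-dependent.

## Numerical choices and degenerate inputs

- Zero-variance genes in the *t*-test produce NaN p-values, treated as 1
  (no evidence).
- Undefined correlations (constant trajectories) exclude the gene with
  reason "constant" rather than erroring.
- All rankings use stable sorts with explicit, documented tie-breaks
  (scores descending, then gene/module id ascending), making every output
  a pure function of inputs + config; reruns are byte-identical.
- Problem sizes in the test suite: unit tests run on miniature repertoires
  (≤ 40 genes) and a 6-aggregate study; the recovery and calibration tests
  run one published-scale simulation (382 modules, 88 + 164 samples),
  which completes in seconds.

## Known limitations

- The group-level screen implements the *t*-test/fold-change path; a
  negative-binomial GLM path (DESeq2-style, FDR-based) is intentionally
  out of scope — normalized matrices are expected as inputs.
- Literature scoring is only as good as the supplied annotation table and
  inherits its publication bias toward well-characterized genes.
- Combining the literature score and R score by simple addition is not
  derived from a formal framework; it is the documented ranking rule.
- With exactly two cohorts, the cross-cohort consistency criterion is the
  partition meet; consensus across more than two cohorts is not
  implemented.
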