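# Methods

`mirvalid` implements the computational arc of a tissue miRNA biomarker
study: small-RNA-seq differential expression on a two-group count
matrix, selection of endogenous reference (normalizer) miRNAs from the
sequencing data, GeNorm stability statistics for those references, ΔΔCT
relative quantification of a custom RT-qPCR panel, cross-platform and
cross-tissue concordance, and hypergeometric pathway over-representation
of predicted targets. A synthetic-data generator plants known truth at
every stage so each operation can be tested for recovery rather than
only for internal consistency.

## Synthetic cohort model

`simdata.simulate_counts` draws a miRNA × sample matrix of
negative-binomial counts with variance μ + αμ². Defaults mirror the
motivating study design: 453 detected miRNAs, 18 tumor vs 6 control
samples, and log-uniform library sizes between 17 and 49 million reads.
Base relative abundances are log-normal (σ = 2), matching the
heavy-tailed composition of real miRNA pools. Per-miRNA dispersions are
log-normal around a global α (default 0.15, a typical bulk small-RNA-seq
value).

A fraction `frac_de` of miRNAs (default 67/453) is planted as
differentially expressed: the case-group mean is multiplied by
2^log2FC with |log2FC| uniform in `lfc_range` (default 1–4) and random
sign. The multiplier is applied against a fixed control-side
denominator, so planted group-mean ratios are exactly 2^log2FC.
`n_stable` miRNAs (default 30) are planted as normalizer-like:
log2FC = 0 and near-Poisson dispersion (α = 10⁻⁶).

Planting is abundance-stratified: DE effects go preferentially into the
lower-abundance half of the pool and stable miRNAs into the upper half.
The first choice prevents planted fold changes from shifting per-sample
totals, which would leak a compositional group effect into every CPM
value and make *no* miRNA proportion-stable; the second reflects that a
usable endogenous control must be well expressed — at low abundance
Poisson noise alone inflates its CV beyond any biological stability.
These are properties real data share: the most abundant miRNAs of a
tissue are rarely the strongly dysregulated ones, and practical
normalizers are drawn from the well-expressed fraction.

`simulate_ct` maps each assay's relative abundance a (its share of the
miRNA pool) to CT = `ct_offset` − log2(a) + N(0, `ct_noise_sd`), with
defaults offset 12 cycles and noise 0.25 cycles, yielding CTs in the
practically observed 15–35 range for abundances of 10⁻⁷–10⁻¹. CT values
above `ct_limit` (default 40) are censored and flagged undetermined.
Because CT derives from proportions, it is independent of sequencing
depth — qPCR input mass is fixed regardless of library size.
Undetermined CTs are excluded from group means rather than imputed.
Technical replicates default to one per (sample, assay); replicate rows,
when present, are averaged before ΔCT.

What the generator does **not** emulate: isomiR structure, UMI/adapter
artifacts, amplification-efficiency differences between assays,
FFPE-specific RNA fragmentation, batch effects, and biological
covariates (age, treatment). Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
noise model, not robustness to every failure mode of archival tissue
data.

## Differential expression

Normalization is median-of-ratios: factor_s = median over all-positive
miRNAs of count_{m,s}/geomean_m(count), rescaled to geometric mean 1.
CPM (count/library·10⁶) is used where the downstream step expects it
(the CV screen).

log2 fold change is computed from size-factor-normalized group means
with a pseudocount of 0.5 (avoids infinities on zero rows). The default
test is a Wald test on log2FC: each group's variance is modeled as
μ + αμ² with α estimated per miRNA and group by method of moments,
floored at 10⁻⁸ so the variance never drops below the Poisson term; the
delta method transfers that variance to the log2 scale
(Var(log2(μ+c)) ≈ Var(μ̂)/((μ+c)ln2)²). The statistic is referred to a
t distribution with Welch–Satterthwaite degrees of freedom rather than a
normal: with six samples per group the normal reference is visibly
anti-conservative (≈8–9% rejections at nominal 5% in null simulations),
while the t reference restores the nominal rate. A label-permutation
alternative (two-sided, ≥1000 permutations, add-one correction) is
provided as a model-free cross-check; its p-values agree with the Wald
test in rank order on simulated data.

This is deliberately a simplified two-group NB test, not a
reimplementation of edgeR's exact test or DESeq2's shrunken Wald test
(the study applied those vendor pipelines to different tissues, and
which one underlay each validated call is not recoverable without the
original data). Correctness is asserted through simulation: type-I error
at the nominal rate on null matrices, planted |log2FC| = 2 recovered
within ±0.5 at 6 vs 6 with low dispersion, and zero direction flips.

Calls use |log2FC| ≥ 1 and BH-FDR < 0.01, both overridable. BH
adjustment delegates to `statsmodels` and is tested against a
brute-force step-up enumeration.

Candidate ranking for the validation panel averages the rank of |log2FC|
(descending) and the rank of FDR (ascending) over DE-called miRNAs, with
optional pathway-annotation counts and then lexicographic ID as
tie-breaks.

## Normalizer selection

Four stages over the count matrix plus its DE table:

1. keep miRNAs with FDR **strictly** > 0.05 (not significantly DE);
2. rank by fold-change proximity to 1, i.e. |log2FC| ascending — ties
   broken by FDR descending (least evidence of change first), then ID.
   The alternative reading "ascending fold change" would favor the most
   down-regulated miRNA, contradicting the stated goal of minimal
   between-group variation, so proximity governs;
3. compute mean, SD (n−1) and CV of CPM across **all** samples (groups
   pooled) and keep the lowest-CV ⌈m/2⌉ candidates (round-up is the
   inclusive default);
4. remove IDs on a user-supplied exclusion list (case-insensitive
   match). The list stands in for a literature review of
   cancer-implicated miRNAs, which is not reproducible computation.

No cut is applied at the proximity-ranking stage (the published
procedure names no survivor count there); the 50% cut lives at the CV
stage and is configurable. The final trio (n = 3 by default, matching
the published panel) is the lowest-CV survivors. The report records
per-stage survivor counts, which are non-increasing by construction.

## GeNorm

For genes j, k on a positive linear scale, V_jk = SD over samples of
log2(q_j/q_k) (n−1 denominator); M_j = mean of V_jk over k ≠ j. Genes
are ranked by iteratively removing the highest-M gene (ties up to
floating tolerance 10⁻⁹ break by ID, later one first) until two remain;
the final pair is reported first in ID order. V(n, n+1) is the SD over
samples of log2(NF_n/NF_{n+1}) where NF_n is the per-sample geometric
mean of the top-n genes; the recommended reference count is the smallest
n with V strictly below 0.15, the threshold proposed with the original
algorithm (the study states none). CT input converts via quantity =
E^(−CT) with E = 2 (100% efficiency) by default; per-assay efficiencies
are a config hook. All statistics are verified against loop-based
brute-force recomputation on matrices up to 5 × 6.

## ΔΔCT quantification

Per sample, ΔCT = CT_target − mean(CT of determined references);
averaging reference CTs on the cycle scale equals a geometric mean of
linear quantities. Samples with no determined reference are dropped with
a warning. ΔΔCT = mean ΔCT(case) − mean ΔCT(control); FC = 2^(−ΔΔCT);
fold regulation = FC if FC ≥ 1 else −1/FC, the signed convention of
commercial analysis portals (magnitude always ≥ 1; FC = 1 maps to
FR = 1). Group comparison is a two-sided Welch t-test on per-sample ΔCT
by default — the portal that produced the published p-values does not
document its test, so the standard small-sample choice for this design
is used and stated here prominently; testing on linear 2^(−ΔCT)
quantities and a permutation test are exposed as options. Volcano
classes: up if FR ≥ 2 and p < 0.05, down if FR ≤ −2 and p < 0.05, else
ns (both cuts configurable; the FR cut is inclusive, the p cut strict).

## Concordance

`summarize_validation` counts non-ns volcano classes.
`overlap_sets` partitions two signed call sets into concordant (same
direction), discordant (opposite), and unique IDs.
`direction_concordance` reports, among miRNAs significant on both
platforms, the fraction whose sequencing call direction matches the
qPCR fold-regulation direction. "Validated" at the cross-platform level
means significant on both platforms in the same direction; the pure
qPCR summaries do not impose the sequencing condition.

## Enrichment

Predicted-target tables (mirna_id, gene_symbol, target_score 0–100) are
filtered at score ≥ 60 (inclusive) and the unique gene union forms the
query. Symbols are upper-cased before matching to absorb cross-species
case drift. With universe size N, set size K, query size n and overlap
k, p = P(X ≥ k) under hypergeometric(N, K, n) (scipy), verified against
exhaustive pmf enumeration for all N ≤ 30; fold enrichment =
(k/n)/(K/N); FDR is BH across sets. Set-size bounds (default 2–2000)
are exposed rather than guessing any web tool's internal defaults. If
no universe is supplied, the union of set genes is used with a warning
that this differs from a genome background. The prediction algorithm
itself is out of scope — target tables are inputs, and the synthetic
generator (`pipeline.simulate_target_table`) emits plausible
score-distributed tables over a 6 000-gene symbolic universe with three
planted enriched pathways.

## Pipeline, seeding, problem sizes

`run_pipeline` chains simulate → DE → normalizer selection → panel
construction → CT simulation → GeNorm → ΔΔCT → concordance →
enrichment, writing every table plus a manifest (thresholds, per-stage
seeds and record counts, truth-recovery metrics) to a run directory.
The global seed fans out through
`SeedSequence(entropy=seed, spawn_key=(stage_index,))` with fixed stage
indices, so adding a stage never perturbs earlier draws; runs are
bit-reproducible given seed and config.

Threshold defaults are the study's published values throughout:
|log2FC| ≥ 1 with FDR < 0.01 for sequencing calls, FDR > 0.05 for
normalizer candidacy, 50% CV retention, target score ≥ 60, |FR| ≥ 2
with p < 0.05 for qPCR volcano calls, GeNorm V < 0.15.

Simulation-based checks use deliberately modest matrices — 300–3000
miRNAs, 6–18 samples per group, 20 seeds per recovery claim — sized so
the full suite runs in well under a minute while keeping Monte-Carlo
error small relative to the tolerances asserted (e.g. the null
rejection-rate check uses 3000 null miRNAs, giving a 3σ band of ±0.012
around 0.05). The full-scale defaults (453 × 24) run in the analysis
scripts.

## Known limitations

- The DE test has no dispersion shrinkage; at very low counts its power
  is below edgeR/DESeq2, and log2FC estimates for near-zero rows are
  pulled toward 0 by the pseudocount.
- Welch-on-ΔCT p-values are a documented choice, not a reproduction of
  the vendor portal's (unknown) test; published p-values are treated as
  data, never recomputed.
- GeNorm assumes references are not co-regulated; planted stable miRNAs
  satisfy this by construction, real candidates may not.
- The sequencing-scale published counts (453 detected, 67/71 DE, 18
  shared) depend on the original raw data and two distinct vendor
  pipelines and are intentionally not reproduced here.
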