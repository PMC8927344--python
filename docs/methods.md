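# Methods

## Scope and data model

The package analyses nCounter-style digital count profiles measured in
two zones of each tumour — the invasive front (TF, near the invasive
border) and the tumour centre (TC) — across two clinical arms:
non-metastatic (cSI) and metastatic (cSII/III) at diagnosis. The central
object is a probes × samples `CountMatrix` with one of four probe
classes per row: Endogenous (assay genes), Housekeeping (candidate
references), and spiked Positive/Negative controls. Counts are strictly
integer on input; normalized matrices are real-valued and carry a
`normalized` flag so a matrix is never normalized twice. Sample
annotations map each sample to a patient, zone and arm; each
(patient, zone) pair occurs at most once.

## Normalization

Steps run sequentially; each stage consumes the previous stage's output.

1. **Background.** Per sample, `T_s = m·(mean + 2·SD)` of the
   negative-control counts with the sample (n−1) SD and multiplier
   `m = 2` by default. The multiplier is configurable
   (`background_multiplier`): `m = 1` gives the common nSolver default
   `mean + 2·SD`, `m = 2` the convention adopted here. Subtraction
   applies only to Endogenous and Housekeeping rows and floors at 0
   (whether a floor of 0 or 1 is used downstream matters little because
   tests run on log2(x+1); flooring at 0 keeps absent genes absent).
2. **Positive-control factor.** `f_pos,s = mean_t(g_t)/g_s` with `g_s`
   the geometric mean of the positive probes in sample s. Factors
   outside the acceptance band [0.3, 3.0] are flagged and reported, not
   dropped: QC gating is a cohort-level decision left to the user.
3. **Housekeeping factor.** Same construction over the geNorm-selected
   references, computed **on the positive-normalized scale** (the
   reference counts are multiplied by `f_pos` first). This matters: both
   factors are applied multiplicatively at the end, so computing the
   housekeeping factor on raw-scale counts would correct the per-sample
   scale twice and roughly double the within-group log-variance of every
   gene. Zero reference counts (possible after background subtraction)
   enter the geometric mean as 1 for the factor computation only.

**geNorm.** Stability `M_j` is the mean, over all other candidates k, of
the across-sample SD of `log2 x_j − log2 x_k`; the least stable candidate
is excluded and M recomputed until the stop rule holds. Two stop rules:
the default keeps excluding while any `M ≥ 0.5` (the conventional
stability cut-off), never going below 3 genes; `keep_n` reproduces a
fixed reference count. Ties on the maximal M are broken lexicographically
by probe name, so selection is deterministic even on degenerate input.

**Presence filter.** A gene is expressed if ≥ `min_count` (40) counts in
≥ `min_frac` (0.25, compared with ≥) of the samples of at least one arm
of the contrast. The filter is applied per contrast, and the
multiple-testing correction spans exactly the genes tested.

## Differential expression

Per zone, cSI vs cSII/III on the expressed genes: Welch t-test
(Satterthwaite df) on log2(normalized + 1); a pooled-variance option
exists (`de.pooled`). Fold changes are computed on linear normalized
group means with the signed convention r if r ≥ 1 else −1/r, so
"FC > ±2" reads |FC| > 2; group means are floored at 1 normalized count
before the ratio, since background subtraction can zero a group mean.
Degenerate rows (zero variance in both groups) give t = 0, p = 1 when
means agree. BH q-values use the standard step-up. Three selection
regimes are flagged per gene: |FC| ≥ 1.5 & p ≤ 0.05 (inclusive),
|FC| > 2 & p < 0.05 (strict), q < 0.05 & |FC| > 1.5.

## Pathway and regulator statistics

The knowledge-base content is user-supplied: gene sets in GMT, a signed
regulator→target network as a 3-column TSV (optional positive weights).
Symbol matching is exact after whitespace stripping — silent fuzzy
matching breeds irreproducibility.

- **Enrichment**: overlap ratio (both against the full set size, the
  convention of printed pathway tables, and against the set restricted
  to the universe) and the right-tailed hypergeometric p on the 2×2 of
  set × dataset membership. The default universe is the contrast's
  expressed endogenous genes — the defensible choice when the reference
  set of the original knowledge base is unknowable.
- **Activation z.** Over the n edges whose targets are in the regulated
  selection, agreement `aᵢ = signᵢ·dirᵢ` and `z = Σ wᵢaᵢ/√(Σ wᵢ²)`
  (unit weights unless given). `n = 0` yields NaN, never an exception.
  |z| ≥ 2 calls Activated/Inhibited; otherwise Undetermined.
- **Upstream regulators** are scored on the |FC| > 2 & p < 0.05
  selection with directions `sign(FC)`, plus the Fisher overlap p of the
  regulator's target set; sorted by z descending, NaN last, ties by name.
- **Comparison** across zones: a set counts as significant in a contrast
  when |z| > 2 and p < 0.05 there; the classification is the join of the
  significant contrasts ("TF", "TC", "TC+TF", "none").

## Clinical statistics

Two-sided Fisher exact p follows the minimum-likelihood rule (sum of the
probabilities of all margin-consistent tables no more probable than the
observed table). This rule — not Pearson χ² with or without continuity
correction — reproduces the published characteristics-table p-values
(0.028, 0.019, 0.056, 0.511) from their printed 2×2 counts, which is why
it is the default; an empty margin gives p = 1 by convention. The
summary t-test defaults to pooled-variance Student, which reproduces the
published tumour-size p (0.079) where Welch gives 0.124. Mann–Whitney
uses exact enumeration when both groups have n ≤ 8 and the tie-corrected
normal approximation otherwise. The table builder substitutes the exact
test for 2×2 categorical variables whenever an expected cell is < 5.
ΔΔCT: `FC = 2^(−((CT_t−CT_r)_case − (CT_t−CT_r)_control))`.

## Synthetic cohorts

The generator emulates the study design the analysis assumes — 21 cSI
and 14 cSII/III patients, one TF and one TC sample each (70 samples),
on a panel of 740 endogenous, 30 housekeeping, 6 positive and 8 negative
probes — with every random quantity needed by recovery tests recorded as
planted truth. Draws are split across independent seeded streams
(cohort / counts / network), so outputs are byte-identical for identical
(config, seed).

- Negatives ~ Poisson(λ = 6): a realistic low background giving
  thresholds around 20 counts.
- Positives: the standard six-level geometric titration
  (128…0.125, × 200 counts) times the sample's scale factor; only ratios
  matter to the factor computation.
- Per-sample scale factors are log-uniform on [0.4, 2.5], so most
  samples fall inside the 0.3–3.0 positive-factor band with occasional
  flagged outliers, exercising the QC path.
- Housekeeping genes: lognormal baselines (log2 mean 9 ± 1) with
  per-gene log2 noise SD 0.05 for the 23 stable and 1.0 for the 7
  unstable candidates — a ≥ 5× separation that makes "stable" a
  well-defined planted property.
- Endogenous genes: negative-binomial with per-gene baseline
  (log2 mean 7.5 ± 2, spanning filtered-out to abundant) and per-gene
  dispersion φ ~ Gamma(2, 0.05) (mean 0.1, i.e. ~32 % biological CV —
  moderate inter-tumour variability); mean = baseline × scale ×
  2^effect.
- Planted effects: 10 % of genes, |log2 FC| = 1, 90 % up-regulated
  (matching the strongly up-skewed direction balance such contrasts
  show); every planted gene carries the effect in TF and a 50 % subset
  also in TC, giving the TF-enriched structure the comparison analysis
  looks for. Effects are planted only in genes with detectable baselines
  (log2 ≥ 6), mirroring the fact that reported effects concern expressed
  genes.
- Network: 5 active regulators with 20 targets each (the typical count
  of listed target molecules in published upstream-regulator tables),
  edge signs agreeing with the planted direction with probability 0.9;
  15 decoys with random targets and signs. Gene sets: 5 signal sets
  (half planted genes) and 10 null sets of 20 genes; sets also
  contribute signed membership edges (signal sets direction-consistent
  at 0.9, null sets random) so set-level activation z-scores are
  defined.

What the generator does **not** model: probe cross-hybridization, lane
position effects, FFPE degradation, correlated genes (co-expression
modules), or patient-level TF/TC correlation. Passing recovery tests
therefore show the pipeline's statistics behave correctly under the
stated generative assumptions, not that real cohorts of this size yield
comparable power.

## Benchmarks and problem sizes

`zonalde.benchmarks` runs the calibration/recovery experiments used by
the test suite and the reproduction script. Chosen problem sizes: DE
recovery uses 50 replicate cohorts of 300 endogenous genes at the full
70-sample design (the per-gene statistics are independent of panel size,
so a reduced panel estimates the same sensitivity with tighter runtime);
type-I error pools ~5,000 presence-filtered genes from three null
cohorts; regulator recovery uses 200 replicate truth/network draws
scored on the planted directions; geNorm recovery uses 100 replicate
10-sample cohorts. Replicate seeds derive as `seed·1009 + r (mod 2³¹)`.

## Numerical conventions

- Geometric means of counts error on zero positives (controls must be
  positive); housekeeping zeros enter as 1 for factor computation only.
- SDs use the n−1 denominator throughout.
- Tie-breaks (geNorm exclusion, regulator ordering, enrichment sorting)
  are lexicographic, making every report deterministic.
- p-values are carried at full precision; comparisons to printed values
  are made at the printed number of decimals.
- The pipeline manifest records the config hash (SHA-256 of the
  key-sorted JSON), per-stage record counts and warnings; TSV outputs
  use a fixed `%.6g` float format so identical (config, seed) runs are
  byte-identical.

## Known limitations

- The panel size, filter denominator and reference-gene count of the
  motivating study (760/770 vs 747 probes; 687 expressed; 23/30
  references) cannot all be reconciled from the published text; the
  generator parameterizes probe counts instead of fixing one value, and
  no test asserts those cohort-specific numbers.
- GSEA-style rank-based enrichment is not implemented; selection is
  threshold-based throughout.
- No paired TF-vs-TC modelling within patients; the two zones are
  analysed as separate contrasts.
- The χ² test refuses tables with zero expected counts rather than
  approximating; use the exact test.
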