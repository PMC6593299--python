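# Methods

## Scope and data model

`circmir` implements the statistical core of a serum circulating-miRNA
case-control analysis. It starts from a mature-miRNA (or precursor-level)
integer count matrix — not FASTQ reads — together with sample metadata
(group label, age, optional sex/BMI), a miRNA → validated-target-gene
table, and a GMT gene-set collection. Counts attributed to different
genomic precursors of the same mature miRNA are summed per sample before
any statistics (first-appearance order of mature IDs is preserved; ties are
never broken by hashing).

The abundance filter removes miRNAs whose total count over all samples is
strictly below 200; a total of exactly 200 is retained. Filtering is
applied after mature-level merging and before size-factor estimation, so
every downstream quantity is a function of retained features only; the
pipeline config exposes `size_factors_on: filtered|all` for the alternative
ordering.

## Normalization

Size factors are DESeq2-style median-of-ratios: over features positive in
every sample, the median of each sample's ratio to the feature-wise
geometric mean, rescaled to geometric mean 1 (so they are unique up to a
constant and scale-equivariant). If no feature is everywhere positive the
estimator refuses by default; the `poscounts` fallback forms the reference
geometric mean over positive samples only.

FPM is defined as size-factor-normalized counts rescaled so the **mean**
per-sample total is 10⁶: FPM_ij = 10⁶ (K_ij/s_j)/m, m = mean_j Σ_i K_ij/s_j.
This is stated explicitly so results are bit-for-bit reproducible. The log
transform defaults to base 2 with pseudocount 1, both configurable; base 2
keeps the transform in the same units as the reported LFCs. With a single
sample FPM reduces to counts per million.

`MedianOfRatiosNormalizer` exposes the same computation as an sklearn
transformer (samples × features): `fit` stores the per-feature log
geometric mean as a frozen reference and the mean normalized library size,
and `transform` computes each sample's size factor against that reference —
so new samples can be projected onto the training normalization.

## Differential expression

Each miRNA is modelled as K_j ~ NB(μ_j, α) with Var = μ + αμ² and natural-log
link, log μ_j = log s_j + β₀ + β₁x_j + β₂·age_j (x = case indicator). Age
enters in raw years by default (`standardize_covariates` optionally centres
and scales it; the group coefficient is unaffected either way).

* **Dispersion.** Per-gene Cox–Reid-adjusted profile maximum likelihood:
  for candidate α the GLM is refit and ℓ(α) = logL_NB − ½ log det(XᵀWX) is
  maximized over α ∈ [10⁻⁸, 10] on the log scale (bounded scalar search,
  tolerance 10⁻⁴ in log α). There is **no** empirical-Bayes shrinkage
  toward a mean–dispersion trend; with ~650 genes at n = 21 this is the
  main way gene lists here can differ from shrinkage-based analyses of
  comparable data, and exact replication of any particular study's gene
  list is not claimed. If the optimizer fails, a small-sample-corrected
  method-of-moments estimate is used and flagged.
* **GLM fit.** IRLS with working weights μ/(1+αμ); coefficients and
  standard errors (inverse Fisher information) are reported in log₂ units
  (natural-log estimates divided by ln 2), so the group coefficient is the
  LFC. Divergence (|β| > 50 on the natural-log scale, e.g. complete
  separation) flags the fit as non-converged; such genes get NA statistics
  and do not enter the BH denominator.
* **Testing.** Wald z = LFC/SE against the standard normal, two-sided;
  Benjamini–Hochberg step-up adjustment (via statsmodels) across converged
  fits. DE calling uses **raw** p ≤ 0.01 and |LFC| ≥ 2: at these sample
  sizes BH-adjusted values survive no conventional threshold, so the raw-p
  rule is the operational definition and the adjusted values are reported
  for transparency. On null simulations at n = 10 vs 11 the raw-p ≤ 0.01
  fraction sits near 0.02–0.025 — the per-gene NB Wald test is mildly
  anti-conservative at this n (dispersion estimation noise), which is why
  the calibration band asserted in tests is [0.005, 0.03] rather than a
  point at 0.01, and why the observed FDR of the raw-p rule is reported
  rather than assumed controlled.

`lfc_to_fold_change` maps LFC to the linear scale as 2^|LFC| (≥ 1), the
convention used when quoting fold-change ranges.

## Risk score and ROC

The polygenic score is the LFC-weighted sum of log₂(FPM+1) over the DE
panel; a single-miRNA panel with unit weight is exactly that miRNA's
log-FPM. AUC follows the midrank Mann–Whitney convention with **no**
silent orientation flip in the low-level `auc` function (cases are expected
to score higher; predominantly negative weights produce an anti-oriented
score). The curve/estimator layer auto-detects direction, records it
(`orientation_`), and reports AUC ≥ 0.5 in the detected direction rather
than flipping signs silently.

Operating points are computed by direct counting at thresholds placed at
midpoints between consecutive distinct scores plus ±∞; the trapezoidal area
of those points equals the midrank AUC exactly, including ties (within
equal FPR the curve is ordered by ascending sensitivity, the vertical
segment). The Youden cutoff maximizes J = sens + spec − 1 with ties broken
by higher sensitivity then lower cutoff — a screening-oriented choice, and
configurable in the sense that the full operating-point table is exposed.
The CI is DeLong's structural-components normal approximation truncated to
[0,1] (a seeded stratified bootstrap is available); a degenerate AUC of
exactly 0/1 at tiny n has zero DeLong variance, in which case the CI is
widened using a conservative variance floor and a warning logged.

Because the weights are plug-in LFC estimates from the same samples used
for evaluation, the in-sample AUC is optimistic; pipeline summaries carry
an explicit `in_sample_evaluation` flag instead of pretending otherwise.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
(scipy's survival function) per set, with k = |query ∩ set|, K = |set|,
n = |query|, N = background. N defaults to 20,000 (an approximate
protein-coding universe) and is deliberately an explicit, required notion:
web-tool backgrounds vary by release, so published enrichment p-values are
generally not reproducible without knowing N, and results here report N
alongside every p. Both Bonferroni (headline by default) and BH-adjusted
values are reported. Note the tail probability *decreases* as N grows at
fixed (k, K, n): a fixed overlap is more surprising against a larger
background.

## Synthetic data

`simulate_dataset` draws K_ij ~ NB(s_j·q_i·2^(β_i x_j + γ_i(age_j − mean age)), α_i):

| parameter | default | rationale |
|---|---|---|
| n_case / n_control | 10 / 11 | the emulated study design |
| n_features | 756 | abundant-miRNA count of the emulated design |
| frac_de | 0.02 | a small planted-signal fraction (~15 miRNAs): enough to measure recovery without distorting normalization |
| planted \|LFC\| | Uniform(2, 4.26), sign ± 1:1 | spans the effect sizes the DE rule targets |
| dispersion α_i | log-normal, median 0.3, log-sd 0.5 | serum small-RNA counts are overdispersed; median 0.3 puts SEs in a regime where \|LFC\| = 2 effects are detectable but not trivial |
| baseline q_i | log-normal, median 50, log-sd 1.5 | right-skewed abundances; with 21 samples most features clear the total ≥ 200 filter, a minority do not |
| size factors s_j | log-normal, log-sd 0.3, geomean 1 | realistic library-size spread |
| ages | case N(47.10, 6.45²), control N(63.45, 4.25²), truncated [18, 90] | reproduces the group–age confounding so the adjustment path is genuinely exercised |
| γ_i (age effect) | 0 (preset `confounded_params`: sd 0.02 log₂/yr) | no age-effect sizes are available to emulate; the preset lets tests induce true confounding |

Age is centred inside the generator so q_i remains the interpretable
baseline mean. `simulate_low_abundance_mix` additionally forces a chosen
fraction of features to expected totals uniform on [2, 150], emulating the
drop from the full detected complement to the abundant subset, and records
the planted-low flag and realized totals in the truth table.
`make_target_fixture` builds a synthetic target table and gene-set
collection with an exact prescribed overlap structure (defaults: 55-gene
union, 41 genes unique to the leading miRNA, 4-of-11 pathway overlap, plus
zero-overlap decoy sets).

What the generator does **not** emulate: compositional coupling between
miRNAs, batch or extraction effects, zero-inflation beyond NB sampling,
medication covariates, and any real serum abundance spectrum (the
log-normal is a modelling choice). Passing tests therefore demonstrate the
statistics are implemented correctly and calibrated under the assumed NB
model, not that any particular clinical result replicates.

## Numerical choices and degenerate inputs

* IRLS convergence: max |Δβ| < 10⁻¹⁰, ≤ 100 iterations; fitted means
  clipped to [10⁻¹⁰, 10¹²] for stability.
* Dispersion bounds [10⁻⁸, 10]; α at the floor behaves as Poisson.
* Readers reject rather than coerce: negative, non-integer or missing
  counts, duplicate feature/sample IDs, unknown group labels and short GMT
  lines are hard errors naming the offending cell/line.
* Empty DE panel: the pipeline completes, skipping the risk-score and
  enrichment stages with a logged notice.
* All randomness uses numpy's PCG64 (`default_rng`) with explicit seeds;
  fixed seed ⇒ byte-identical TSV outputs.

## Problem sizes used in the checks

The test-suite simulations use 10-vs-11-sample designs throughout: 500
single-gene replicates for effect recovery, a 2,000-gene null for
calibration, 200 replicates at n = 200 samples for dispersion recovery,
and 120–756-feature matrices for end-to-end runs — sizes chosen to make
Monte-Carlo error small relative to the asserted bands while the whole
suite stays interactive.

## Known limitations

* No dispersion shrinkage, independent filtering, outlier replacement or
  LFC shrinkage; gene lists will differ from pipelines that use them.
* The risk score's weights are not cross-validated; the known circularity
  of in-sample evaluation is reproduced deliberately and flagged.
* Enrichment p-values depend on the declared background N and the gene-set
  collection; they are comparable across runs of this package, not across
  web tools with unknown universes.
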