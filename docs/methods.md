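# Methods

This note documents the models, the numerical conventions, the synthetic
data generator, and the open design choices made in this package. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Single-sample enrichment

**ssGSEA.** Within each sample, genes are ranked by expression (average
ranks for ties; the walk order breaks ties lexicographically by gene ID so
results are deterministic). With rank values ρ on the ascending 1..N scale,
walk positions `pos` (1 = highest expression), set S of size m and weight
exponent α (default 0.25), the enrichment score is the sum over all list
positions of the difference between the weighted cumulative hit fraction and
the uniform cumulative miss fraction. Because each gene contributes its
increment once per remaining position, the implementation uses the
algebraically identical closed form

    ES = Σ_{g∈S} ρ_g^α (N − pos_g + 1) / Σ_{g∈S} ρ_g^α
       − Σ_{g∉S} (N − pos_g + 1) / (N − m),

which is O(N) per signature and sample; the test suite verifies it against a
literal running-sum oracle to 1e−10. Scores depend only on within-sample
ranks, so any strictly increasing per-sample transform of expression leaves
them unchanged. No final normalization by the score range is applied by
default (`normalize=False`); when enabled it divides the whole score matrix
by its range.

**GSVA.** Per gene, a Gaussian-kernel CDF across samples
(`z_ij = mean_k Φ((x_ij − x_ik)/h_i)`, bandwidth `h_i = sd_i/4`, sample sd
with ddof = 1; constant genes get z = 0.5). Per sample, genes are ordered by
decreasing z, given the symmetric rank statistic `|N/2 − position|^τ`
(τ = 1), and a weighted KS random walk is taken down the list. The score is
the max.diff convention: max(0, max walk) + min(0, min walk). GSVA requires
≥ 3 samples because the kernel CDF is estimated across samples; smaller
inputs are directed to ssGSEA.

The pipeline default is GSVA with ssGSEA selectable by configuration; the
large simulation studies in the tests and acceptance script use ssGSEA,
whose closed form scales linearly, while GSVA (quadratic in sample count per
gene) is exercised at oracle scale. The choice is recorded in every run
manifest.

**NES.** Each signature row is z-scaled across the samples of one cohort
(ddof = 1). Rows with zero variance become all-zero and are flagged. Scaling
is strictly within-cohort: cohorts are scored on their own scale before any
cross-cohort synthesis, and a frozen signature list applied to a new cohort
(the validation use case) recomputes NES within that cohort. Whether pooled
or per-cohort scaling was "the" intended convention is genuinely open;
per-cohort is implemented and documented rather than guessed.

## Survival machinery

Implemented from first principles and cross-checked against lifelines:

* **Kaplan–Meier** product-limit estimator; subjects censored at an event
  time remain in that time's risk set (events processed first).
* **Log-rank** with the hypergeometric variance, p from χ² (1 df).
* **Cox PH, binary covariate** (high = 1): Newton–Raphson on the partial
  log-likelihood, Efron tie correction by default (Breslow available),
  convergence |Δβ| < 1e−8, max 50 iterations, SE from observed information.
  For a binary covariate the risk-set sums reduce to counts, so each
  iteration is a vectorized pass over distinct event times. Under monotone
  likelihood (|β| diverging past 20) the fit is flagged non-converged,
  log HR is reported as a signed infinity, and the p-value falls back to the
  score test at β = 0 — which, with Breslow ties, coincides with the
  log-rank χ² (an identity the tests verify to 1e−8 on tie-free data).

Median dichotomization sends values strictly above the median to "high" and
ties at the median to "low" (deterministic; matches the convention that only
scores *higher* than the median are high). A constant vector is an error,
never silently one group.

The two-group comparison used throughout is the Mann–Whitney rank-sum test.
The commonly cited "Wilcoxon signed-rank" name for independent-group
comparisons describes a paired test; a genuinely paired signed-rank variant
is available via `two_group_test(..., paired=True)`, but independent groups
(the only case this pipeline produces) use the rank-sum test.

## Meta-analysis and selection

Per signature, converged per-cohort Cox estimates are pooled by inverse
variance. The default is random-effects with the DerSimonian–Laird moment
estimator, τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), truncated at zero;
fixed-effects results are always recorded alongside. I² = max(0,
(Q−(k−1))/Q)·100. Cohorts where a signature's fit failed are dropped from
that signature's pooling, never imputed. Selection uses the default model's
two-sided p at raw α = 0.05 — no multiple-testing correction, mirroring the
raw-threshold rule; a Benjamini–Hochberg switch exists but is off by
default. Direction: good ⇔ pooled HR < 1, bad ⇔ pooled HR > 1. Random
effects was chosen as the default because the cohorts being pooled
(different platforms, centers, endpoints) are heterogeneous by construction;
whether fixed or random effects was "the" original convention is not
determinable, so both are reported.

## IRScore

IRScore = Σ NES(good) − Σ NES(bad) per sample; equivalently a dot product of
the NES matrix with a ±1 direction vector (the tests pin this to 1e−12,
along with the constant-shift and direction-flip invariances it implies).
Grouping is at the scored cohort's own median. The verdict list is
serialized as JSON with every run so scoring is exactly reproducible.

## Cell-level analyses

Cluster/patient scores use arithmetic mean expression profiles per label.
Per-cell scoring runs ssGSEA over each cell's *detected* (nonzero) genes by
default, because zero-inflation makes full-list ranks degenerate (most genes
tie at zero); a rank-all-genes mode exists and agrees with the dense path on
matrices without zeros. Cells where a signature matches fewer than two
detected genes contribute a zero raw score and are logged.

The DP/DN/SP gate on CD103 (*ITGAE*) and CD39 (*ENTPD1*) uses positivity
threshold 0 on normalized counts — any detected transcript counts as
expressing. The threshold is a configuration field recorded in the manifest:
it is a documented default, not a known ground truth. Per-label enrichment
contrasts DP against DN membership in vs out of the label with log2 odds
ratios (Haldane–Anscombe +0.5 applied only when a zero cell exists, so
finite ORs are unperturbed) and two-sided Fisher exact p-values; SP cells do
not enter the contrast.

## Cytometry preprocessing

Raw intensities → `asinh(x/5)` → per-marker rescale to [0, 1] with the 99th
percentile as cap (linear-interpolation percentile, the common "type 7"
convention — the percentile convention is not uniquely determined and is
logged in the manifest) and the observed minimum as floor (post-arcsinh
values can be negative, so a fixed floor of 0 would clip signal).
Per-sample subsampling is uniform without replacement, reproducible under a
seed. Cluster labels are consumed as input; SOM/consensus metaclustering is
out of scope. Cluster frequencies are computed within a declared parent
population and sum to 1 per sample; composite populations are label unions
whose frequencies are the member sums. FCS containers are not parsed; the
supported event-table input is CSV with marker columns and a `sample_id`
column, which carries identical information.

## Synthetic data generator

The generator defines the study conditions the pipeline is validated under.

**Bulk cohorts.** K = 7 cohorts × n = 200 samples; 20 good + 20 bad + 60
null signatures of 10 genes each, plus 500 unassigned background genes.
Every signature s has latent activity a_sj ~ N(0,1) per sample; its genes
read μ_g + λ·a_sj + ε with λ = 1, ε ~ N(0, 1), and gene baselines
μ_g ~ N(6, 1) (log2-microarray-like levels). Survival is proportional
hazards with exponential baseline h0 = 0.1: η_j = Σ_s d_s·β·a_sj with
β = 0.8, d_s = −1 for good and +1 for bad signatures (so planted "good"
signatures produce pooled HR < 1 *through the pipeline*, not by fiat), event
times by inverse transform, independent Exp(0.05) censoring; with these
defaults roughly 60 % of samples are events. Signature size (10 genes) and
background size (500 genes) are the generator's own realism choices — small
curated immune signatures and a gene universe large enough that a
signature's genes are a small minority. One global seed expands into
per-cohort substreams keyed by cohort index, so regeneration is exact and
adding a cohort never perturbs earlier ones.

**What the generator does not emulate:** platform/batch effects, probe
collapsing artifacts, correlated (overlapping) signatures, non-proportional
hazards, informative censoring, and cohort-size imbalance. Passing the
recovery and calibration tests therefore demonstrates correctness of the
machinery under its stated model, not robustness to those real-data
complications.

**Single cells.** Negative-binomial counts (dispersion r = 2) with
lognormal cluster-specific means; a planted DP fraction carries marker means
of 5 on ITGAE/ENTPD1 (guaranteed ≥ 1 count, so the threshold-0 gate recovers
the planted classes exactly — the markers are noiseless in the gating sense)
and a 4-fold up-shift on a 20-gene cytotoxic/exhausted block; all other
cells have exactly zero marker means.

**Cytometry.** Cluster frequencies per sample from Dirichlet(200·π); the
high group's target-cluster mean frequency is raised by Δ (default planted
shift 0.15) with proportional renormalization of the rest; intensities are
lognormal per cluster and marker.

## Problem sizes and tolerances

* Oracle-equivalence tests run at 10–20 genes × 4–5 samples (1e−8), the Cox
  grid search on 8-subject toys (1e−6), the DL oracle at k = 3 (1e−10), and
  the IRScore algebra at 1e−12.
* Null calibration: 50 replicates of the full seven-cohort study with β = 0
  (selection rate over the 60 null signatures), and 2000 log-rank
  replicates at n = 60.
* Recovery: 50 replicates at the full design conditions; the acceptance
  script uses 20 replicates for its point estimates, 100 cytometry
  replicates, and one 500-cell single-cell study — sizes chosen so the
  whole script completes comfortably on one CPU while keeping Monte-Carlo
  error well inside the margins being tested.
* The exhaustive Fisher check covers every 2×2 table with total ≤ 40
  against a margin-cached hypergeometric enumeration.

## Known limitations

* Bulk inputs must be pre-collapsed to unique gene IDs; probe-level
  microarray handling is out of scope. Gene matching is exact-string and
  case-sensitive, with a per-signature overlap report always emitted.
* The Cox implementation covers the single binary covariate the pipeline
  needs; it is not a general regression engine.
* GSVA's kernel CDF is O(n²) per gene; very large cohorts should prefer
  ssGSEA.
* The DP gate at threshold 0 is sensitive to dropout in real single-cell
  data; the threshold is configurable for that reason.
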