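# irscore

Immune-related signature scoring for tumor cohorts: a tested, reusable
implementation of an IRScore-style pipeline for stratifying patients by the
prognostic immune content of their transcriptomes.

**Who it is for.** Computational oncology groups who have (i) several bulk
expression cohorts with recurrence-free or overall survival, (ii) a catalogue
of immune-related gene signatures, and optionally (iii) single-cell RNA-seq
or mass-cytometry data from the same tumor type, and who want a single
per-sample score that summarizes prognostically favorable versus unfavorable
immune activity.

## The method

1. **Single-sample enrichment.** For each cohort, every signature is scored
   per sample by ssGSEA (rank-weighted running sum, weight `|rank|^alpha`,
   `alpha = 0.25`) or GSVA (Gaussian-kernel expression CDF, symmetric rank
   statistic, weighted Kolmogorov–Smirnov walk, max.diff scoring). Scores are
   z-scaled across each cohort's samples into a normalized enrichment score
   (NES), so every cohort lives on its own scale.
2. **Signature selection.** Per cohort and signature, samples are split at
   the NES median and a univariate Cox proportional-hazards model (high vs
   low, Efron ties) gives a log hazard ratio. Per signature, the K cohort
   estimates are pooled by inverse-variance random-effects meta-analysis
   (DerSimonian–Laird τ²). Signatures with pooled *P* < 0.05 are kept and
   classified *good* (pooled HR < 1) or *bad* (HR > 1).
3. **IRScore.** For each sample,

   `IRScore = Σ_{i=1..M} NES_i − Σ_{j=1..N} NES_j`

   over the M good and N bad signatures. Samples are stratified into
   high/low IRScore groups at their cohort's median and the contrast is
   evaluated by Kaplan–Meier curves, the log-rank test, and the two-group
   Cox HR.
4. **Cell-level companions.** The same signed-sum score at cluster, patient
   and cell resolution (per-cell ssGSEA over detected genes); a CD103
   (*ITGAE*) / CD39 (*ENTPD1*) double-positive gate with per-cluster log2
   odds ratios and Fisher exact *p*-values; and CyTOF preprocessing
   (arcsinh with cofactor 5, 99th-percentile rescale to [0, 1], per-sample
   subsampling, cluster-frequency comparisons).

Kaplan–Meier, the log-rank test, the binary-covariate Cox fit and the
DerSimonian–Laird pooling are implemented from first principles and verified
in the test suite against independent oracles (brute-force likelihood
search, hand computations, lifelines and statsmodels).

## Worked example

```python
from irscore import IRScorer, evaluate_stratification
from irscore.simulate import SimulationConfig, generate_cohorts

# seven synthetic cohorts of 200 patients; 20 protective + 20 deleterious
# + 60 null signatures planted with known ground truth
cohorts, truth = generate_cohorts(SimulationConfig(seed=7))

scorer = IRScorer(gene_sets=truth.signatures, method="ssgsea").fit(cohorts)
print(scorer.n_good_, scorer.n_bad_)

table = scorer.score_cohort(cohorts[0].expression)
report = evaluate_stratification(table, cohorts[0].survival)
print(round(report.hr, 3), f"{report.logrank_p:.2e}")
```

prints

```
19 21
0.094 7.67e-36
```

i.e. the selection step recovered 19 good and 21 bad signatures (of 20 + 20
planted: one good signature missed, one null false positive classified bad),
and in the first cohort the high-IRScore half of the patients has ~0.09
times the recurrence hazard of the low half, log-rank *p* ≈ 8 × 10⁻³⁶.
(Scoring a cohort that also served in selection overstates the contrast;
the held-out evaluation in `scripts/acceptance.py` is the honest version.)

The same pipeline is available from a shell:

```bash
irscore simulate --out sim --seed 7
irscore select   --out sel --data-dir sim --gmt sim/signatures.gmt
irscore score    --out sco --expression sim/expression_cohort_1.tsv \
                 --gmt sim/signatures.gmt --verdicts sel/verdicts.json
irscore evaluate --out ev  --irscore sco/irscore.tsv \
                 --survival sim/survival_cohort_1.tsv
```

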