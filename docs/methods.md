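# Methods

## The measurement and the scale

Circulating tumor cells (CTCs) are immunoisolated from peripheral blood
(EpCAM capture) and a seven-gene signature — *GAPDH*, *VIL1*, *CLU*,
*TIMP1*, *TLN1*, *LOXL3*, *ZEB2* — is quantified by RT-qPCR in duplicate at
three timepoints: before first-line treatment (baseline), after one
chemotherapy cycle (week 4) and, conditionally, before cycle 5 (week 16).
Because the captured fraction always contains leukocytes, *PTPRC* (CD45)
serves as reference, and expression is reported as

    delta_cq = (40 − Cq_target) − (40 − Cq_PTPRC)

in PCR cycles, with 40 the maximum cycle number. Higher values mean more
target transcript relative to the leukocyte background. A well that never
crosses the fluorescence threshold ("undetermined") is imputed at Cq = 40,
which maps absent transcript to the floor of the scale; an undetermined
*reference* makes the whole sample unusable and the sample is flagged and
excluded rather than imputed. For numeric inputs the two 40s cancel, so the
choice of maximum cycle number only matters for sentinel handling.

Replicates are collapsed by arithmetic mean on the Cq scale (a
geometric-equivalent collapse on the 2^−Cq scale is selectable).
The downstream classifier only compares values to a percentile cutoff, a
rank-based operation that mean-on-Cq preserves for tight duplicates.
Replicate pairs more than 1.5 cycles apart trigger a QC warning; the
threshold is configurable and is a declared convention, not an inferred one.

## The classifier

For every marker and timepoint, a cutoff is placed at the 75th percentile of
the cohort delta-Cq distribution (linear interpolation between order
statistics at position 1 + (n−1)p/100, the Hyndman–Fan type-7 convention;
the quantile method is configurable). A marker is called **high** when its
value is *strictly* above the cutoff; equality scores low. The strict rule
caps the per-marker high fraction at 25% of the cohort, which is the reading
consistent with the observed size of high-CTC groups. Cutoffs may
alternatively be supplied from a file (provenance `supplied`), supporting a
frozen-cutoff workflow where values from a prior study are reused; both
modes are first-class because either reading of the original protocol is
defensible.

The panel call is a majority vote: **high-CTC** when ≥ 4 of 7 markers are
high, **low-CTC** when ≥ 4 are low, **unevaluable** when missing markers
starve both counts. The vote is monotone: flipping one marker low→high can
never demote the panel call.

Response classification reads the panel group at baseline and week 4:

| baseline → week 4 | label |
|---|---|
| low → low | responder |
| high → high | non-responder |
| low → high | non-responder |
| high → low | provisional responder; week 16 confirms (low → responder, high → reclassified non-responder) |

Patients on the high→low branch with no week-16 sample stay
`needs_confirmation` and are excluded from final responder/non-responder
contrasts with a logged warning; the handling of such patients was genuinely
open and this is the conservative choice. "Increase/decrease of CTC
levels" is operationalized purely as the discrete group transition, not as a
change in the high-marker count or in continuous expression. Patients
lacking a baseline or week-4 sample are `unclassifiable` — excluded from
response contrasts but retained for baseline-only analyses. The cohort
report exposes both the provisional tally (high→low counted as responder)
and the final tally after confirmation.

## Survival analysis

Kaplan–Meier estimation and the log-rank test are delegated to lifelines.
The per-stratum "mean survival" is the restricted mean survival time
(RMST): the area under the KM curve up to a truncation time, by default the
largest observed time in the stratum (configurable). Its standard error is
the standard area-based variance
`sum_i A_i² d_i / (n_i (n_i − d_i))` with `A_i` the area under S from the
i-th event time to the truncation point; confidence intervals are
mean ± 1.96·SE. The truncation convention behind any published "mean" is
rarely stated, so numeric equality with published means is not asserted
anywhere — RMST values are reported with their own convention logged.

The Cox proportional-hazards fitter is implemented in this package
(Newton–Raphson with step-halving on the partial likelihood) because the
required default tie-handling is Breslow — the default of the legacy
statistical software this analysis style comes from — while lifelines
implements only Efron. Both methods are available; they agree exactly on
untied data (tested) and the Efron path is cross-checked against lifelines.
A monotone partial likelihood (a covariate that perfectly separates event
order) is detected by estimate divergence and flagged
(`monotone_likelihood=True`, `converged=False`) instead of returning a
silently huge coefficient. The score test of the univariate Cox model at
β = 0 equals the log-rank chi-square on untied data, which is used as an
internal consistency check.

Covariate dichotomizations for clinical Cox models (age at 66 years, CEA at
10 ng/mL, ECOG 2 vs ≤ 1, N stage 2 vs ≤ 1, T stage 4 vs ≤ 3, ≥ 2 metastatic
sites) are data-preparation conventions applied by the caller, not baked
into the fitter.

## Concordance and the 2×2 reconstruction

The positive class is *non-responder* throughout: sensitivity is the
probability of catching a true non-responder, PPV the probability that a
panel non-responder call is right, and "global efficiency" is plain
accuracy. Percentages are rounded half-up (decimal quantization, not
binary-float rounding) to one decimal by default; the rounding mode matters
because the integer-table reconstruction inverts it.

`reconstruct_confusion` recovers the integer 2×2 table behind a published
report from its prediction margins (predicted positives = tp+fp, predicted
negatives = fn+tn) and its rounded sensitivity and specificity, by
exhaustive search over all (tp, tn) pairs. It errors if no table is
consistent and lists all candidates if more than one is — uniqueness is a
property of the data, not an assumption. With margins 22/70, sensitivity
60.0% and specificity 89.6% the unique table is (tp, fp, fn, tn) =
(15, 7, 10, 60), from which PPV 68.2%, NPV 85.7%, false-negative rate 40.0%
and accuracy 81.5% follow.

## The synthetic cohort generator

No patient-level data is published for this kind of study, so the generator
produces cohorts with the structure the analysis assumes:

* a latent non-responder subpopulation (prevalence default 25/92 ≈ 0.27,
  the truth margin implied by the reconstructed 2×2 table);
* marker delta-Cq as correlated multivariate normal per timepoint — mean
  −10 cycles, SD 3, equicorrelation 0.4, non-responder shift +2 cycles at
  baseline. These four numbers are invented defaults (no distributions are
  published) and are declared, not fitted;
* week-4 drift of −1.5 cycles for latent responders and +1.5 for
  non-responders (noise SD 1), continued to week 16, so group transitions
  carry signal;
* Cq synthesis: reference Cq ~ N(26, 1.5²), target Cq = reference − delta,
  duplicates jittered with SD 0.15 cycles; targets at ≥ 40 cycles become
  undetermined;
* survival: exponential conditioned on the *latent* label (not on the panel
  call), responder medians 14.4 / 24.7 months (PFS/OS, taken from the
  published responder means used as medians) and hazard ratios 1.88 / 3.83.
  Because hazards follow the latent truth, classifier errors attenuate the
  hazard ratio observed through the panel grouping — deliberate realism;
* PFS is min(progression, death), so OS ≥ PFS holds by construction;
  censoring is administrative, uniform over a 30-month follow-up window;
* an imperfect CT classifier flips the latent truth with the configured
  sensitivity (default 0.174) and specificity (default 0.985);
* whole samples go missing at a configurable rate (default 0.02).

Everything is driven by one `numpy` Generator seed; identical seeds give
byte-identical CSV output. For pure survival experiments,
`simulate_survival_cohort` draws a fixed 22/70 two-group exponential cohort
with uniform censoring whose window is solved numerically (closed-form
mixture censoring probability, Brent root-finding) to hit an exact expected
censoring fraction, keeping censoring independent of group and time.

What the generator does **not** emulate: between-marker mean/variance
heterogeneity, non-normal heavy-tailed expression, informative censoring,
correlation between PFS and OS beyond the min() coupling, time-varying
hazards, and CT errors correlated with tumor burden. Passing tests
therefore demonstrate the pipeline's arithmetic and its behaviour under the
assumed structure, not clinical performance on real cohorts.

A separate deterministic, hand-constructed (not sampled) 94-patient bundle
(`fixed_count_fixture`) uses exactly two expression levels (−10 / −4 cycles)
chosen so the 75th-percentile cutoff is the low level at every timepoint,
making panel calls exact by construction; its block design fixes the count
structure (64 LL / 8 HH / 13 LH / 7 HL with one week-16 reclassification / 2
missing week-4), the CT cross-tab 66/2/17/1 with 8 uncompared, 71 of 94
progressing, and an adjudicated-truth layout giving the panel the 2×2 table
(15, 7, 10, 60). Its bytes are checksum-pinned in the test suite.

## Numerical choices and known limitations

* Percentile: type-7 interpolation; ties at the cutoff score low.
* Rounding of reported percentages: decimal half-up, configurable precision.
* Cox: Newton with step-halving, tolerance 1e-10 on the step, divergence
  declared at |β| > 15; covariates are centered internally for exp()
  stability (centering does not change the estimate).
* Simulation sizes: recovery experiments use 200 replicates at n = 92
  (22/70 split) and null-calibration experiments 500 seeds of the full
  94-patient pipeline; these sizes give Monte-Carlo standard errors small
  enough to resolve the effects being checked while keeping the default
  suite quick.
* Small-sample bias: at n = 92 with ~74 events the Cox log-HR MLE is biased
  away from zero by ≈ +0.04 (measured by simulation; the estimate is
  consistent at large n). Geometric-mean hazard-ratio recoveries at this
  design size therefore land a few percent above the generating value; this
  is a property of the estimator, not of the simulator.
* The log-rank wrapper requires both groups non-empty and at least one
  event; the RMST requires the truncation time within follow-up.
* All-censored strata produce a flat KM curve whose restricted mean equals
  the truncation time and is flagged truncation-limited.
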