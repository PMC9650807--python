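# Methods

## Scope and data model

The package estimates improvement MIDs and PASS thresholds for bounded
outcome instruments against a 7-level ordinal satisfaction anchor
(level 1 best). The analysis unit for MID is the *change pair*: one
participant's (anchor transition, outcome change) between two
consecutive scheduled visits, with the change always computed as the
later score minus the earlier score. A skipped visit breaks the chain —
no pair spans a gap — and a pair exists only when both endpoints have a
non-missing anchor and a non-missing score (complete-case per pair; no
imputation). PASS uses single-visit states: the current score and
whether the anchor is at or below the satisfied cut (level 2 by
default). All primary analyses pool pairs/records across visits;
per-interval MID and per-visit PASS runs are available as secondary
analyses.

Two different improvement dichotomies coexist deliberately: the ROC and
predictive methods define "improved" as *any* anchor improvement
(Δa ≤ −1), while the two mean-based methods use *exactly one* level
(Δa = −1), so their improver counts differ. The "not better" group
(Δa ≥ 0, i.e. unchanged or worse) is shared by all methods, and
worsening pairs are never dropped.

## ROC machinery

Candidate thresholds are the midpoints between consecutive distinct
pooled values, plus one sentinel beyond each extreme so the curve always
contains (sens, spec) = (0, 1) and (1, 0). Midpoints make the curve
insensitive to the choice of strict vs weak inequality on tied data; on
small samples they can differ from observed-value thresholds by up to
half the score resolution, which is the resolution limit of any
empirical cut-point. The cut-off criterion is closest-to-top-left:
minimise (1 − sens)² + (1 − spec)². Ties are resolved deterministically
— higher sensitivity first (an MID should favour detecting improvement),
then the threshold nearest the pooled median — so bootstrap replicates
of the same data always select the same cut.

AUC is the Mann-Whitney concordance probability with ties counted as ½,
computed from pooled mid-ranks. Two AUC intervals are offered: a
percentile bootstrap (default, 2000 stratified resamples) and the DeLong
asymptotic-normal interval from the structural-components variance
estimator; both appear because the two are frequently conflated in
applied reports, and they agree closely away from the AUC = 1 boundary.

Cut-off CIs are percentile bootstrap intervals over stratified resamples
(resampling within the improved and not-better groups separately, which
preserves the group ratio). Resamples whose pooled values collapse to a
single point carry no threshold information and are redrawn (counted in
the run log). The percentile method (not BCa) is used throughout for
consistency across cut-offs, correlations and the predictive MID.

## Predictive MID

Logit P(improved) = C + B·Δx is fitted by Newton-Raphson maximum
likelihood on the standardised predictor (an in-package solver: the
bootstrap and calibration studies need ~10⁵ refits, so per-fit overhead
matters; the solver is verified against statsmodels to 1e-6 in the test
suite). The MID is the change score at which the likelihood ratio of
belonging to the improved vs not-better group equals 1:

    MID = (ln(p/(1−p)) − C) / B,   p = observed improved fraction.

For Gaussian equal-variance change distributions the true coefficients
are B = (μ₁−μ₀)/σ² and C = ln(p/(1−p)) + (μ₀²−μ₁²)/(2σ²), so the
prior-odds terms cancel and the estimand is exactly the midpoint
(μ₀+μ₁)/2 at any improved fraction — the analytic target used in the
recovery tests. Complete or quasi-separation (no MLE) raises an error
that points the user to the ROC method. Later small-sample "adjusted"
variants of the predictive MID are out of scope; only the
likelihood-ratio definition above is implemented.

CIs are pair-level percentile bootstrap. Pairs from the same participant
at different intervals are treated as independent in estimation and in
resampling, matching a pooled-pairs primary analysis; a participant-level
cluster bootstrap is available as a sensitivity option for users worried
about within-participant correlation.

## Anchor credibility

Spearman's rho (mid-rank based) is computed between the anchor change
and (i) the outcome change, (ii) the pre-interval score, (iii) the
post-interval score, each with a 1000-resample percentile bootstrap CI.
The gate is |rho_change| ≥ 0.3 (configurable), with descriptive bands
poor < 0.3 ≤ moderate < 0.5 ≤ good — a documented convention, not a
universal standard. The gate *withholds* rather than deletes: failed
instruments keep their correlation row and their MID/PASS cells read
"withheld (anchor correlation below threshold)", so a weak anchor is
visible in the output. Moderate correlations pass with a logged caution.

## PASS estimators

The ROC PASS applies the identical cut-off machinery to current scores
with "satisfied" (anchor ≤ 2) as the positive class; on a
higher-is-worse scale satisfied patients have low scores, so the
positive direction flips with the instrument. The percentile PASS is the
75th percentile of the score among satisfied patients for
higher-is-worse instruments and the 25th for higher-is-better; quantiles
interpolate linearly between order statistics at h = q·(n−1). Both PASS
estimators report bootstrap CIs; for the percentile method this is an
extension beyond the usual point-estimate-only reporting.

## Synthetic cohort generator

The trial-like generator emulates recovery after a humeral shaft
fracture: a latent disability L_it = m_t + b_i + e_it on a 0–100
(DASH-like) scale with population curve m = (46, 33, 25, 20, 17) over
visits at 6 weeks and 3/6/12/24 months, participant effect
b_i ~ N(0, 15²), visit noise e_it ~ N(0, 8²). The anchor is an ordinal
cut of L + N(0, 5²) at cutpoints (0, 20, 40, 58, 74, 88); each
instrument is an affine map of L plus noise, rounded to its resolution
and clipped to its bounds; cells are deleted completely at random
(rate 0.04 per cell).

Defaults were calibrated once, against the study conditions the
generator is meant to emulate: first-visit moments (DASH-like 46 (19),
Constant-like 35 (20), pain-on-activities 4.9 (2.6), pain-at-rest
1.8 (1.9)), roughly 420 usable pairs out of 124 × 4 intervals with ~40%
of intervals showing anchor improvement, anchor-change correlations
near 0.5 (DASH-like), −0.4 (Constant-like), 0.37 (pain on activities),
and below 0.1 for the deliberately mis-anchored pain-at-rest instrument
(loading 0.02, large noise). MCAR is the only missingness mechanism —
real cohorts lose visits for outcome-related reasons; nothing here
probes robustness to informative dropout. Likewise the generator's
anchor is a noisy cut of the same latent state that drives the scores,
so it cannot exhibit real-anchor pathologies (response shift, recall
effects, idiosyncratic satisfaction standards). Passing tests therefore
demonstrate estimator correctness under a well-specified latent model,
not robustness to anchor misbehaviour in field data.

The two-group generator is the oracle harness: change scores drawn
directly from improver/non-improver Gaussians with known analytic
targets — midpoint for ROC and predictive, μ₁ for mean change, μ₁ − μ₀
for the mean difference — used for parameter-recovery and CI-calibration
studies.

## Numerical and design choices

* Seeds are explicit parameters everywhere; composite runs derive child
  seeds via `SeedSequence.spawn`, so whole-pipeline reruns are
  byte-identical.
* Mean-change CI uses the t distribution; mean-difference CI is Welch
  (unequal variances) — chosen over pooled-variance because group
  spreads routinely differ between improvers and non-improvers.
* `n_boot = 0` is a supported diagnostic mode that skips bootstrap CIs
  without touching point estimates.
* Degenerate inputs fail loudly: empty ROC classes, constant correlation
  vectors, too-few improvers, and logistic separation each raise typed
  errors naming the counts involved; the pipeline captures these per
  cell so one fragile estimator does not abort a run.
* Problem sizes in the validation suite — 200 random oracle instances,
  5000-per-group analytic-limit runs, 200 datasets × 5 configs for
  parameter recovery, 500 replicates × 400 bootstrap resamples for CI
  coverage — were chosen as the smallest sizes at which the targeted
  effects are measurably separated from Monte-Carlo noise.

## Known limitations

* Empirical closest-to-top-left cut-point selection carries a
  finite-sample bias away from the population optimum when the improved
  fraction departs from 50% (measured ≈ −0.07 points on a −5 target at
  n = 400, improved fraction 0.3). This is a property of the method —
  ROC-based MIDs are known to be biased under unbalanced improvement —
  and is visible in the parameter-recovery study, where the ROC
  estimator's mean can sit just outside 2 Monte-Carlo standard errors of
  the analytic midpoint at the smallest improved fraction.
* Percentile bootstrap intervals undercover slightly at small n
  (empirically 93–96% at n = 150 for nominal 95%); BCa or studentised
  intervals are not implemented.
* Anchor levels are assumed pre-coded with 1 best; reverse-coded
  dialects must be mapped before ingestion. Retrospective
  ("compared to baseline") anchors are unsupported by design — the
  analysis targets a current-state anchor.
* Deterioration MIDs are out of scope; all improvement dichotomies are
  one-sided.
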