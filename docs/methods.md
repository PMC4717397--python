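# Methods

## Two-compartment voxel-fraction model

Postcontrast T1-weighted fat-suppressed images show enhancing synovium
bright and synovial fluid dark. Inside the segmented synovial space, after
cartilage exclusion, each voxel is modelled as a linear mixture of the two
compartments: tissue fraction `P = (I − m_f)/(m_s − m_f)` truncated to
[0, 1], where `m_f < m_s` are the mean fluid and tissue intensities.
Volumes are fraction sums times the voxel volume (the product of the NIfTI
header spacings), so the partition identity `stv + fluid + cartilage =
segmented` holds to machine precision and is enforced as an invariant.

Choices where the procedure is genuinely open:

- **Intensity model estimation.** How m_f and m_s are obtained is not
  prescribed anywhere; the default fits a two-component Gaussian mixture
  to the non-cartilage segmented intensities per scan and assigns the
  lower mean to fluid. Estimation refuses to guess on unimodal or
  degenerate regions (the two fitted means must be ≥ 2 pooled SDs apart);
  the user can always pass (m_f, m_s) explicitly.
- **Cartilage threshold.** Otsu's method on the precontrast intensities
  restricted to the segmented region, with a user-supplied fixed threshold
  as override. On phantoms with ≥ 6 noise-SDs of cartilage/soft contrast
  the misclassified-voxel rate is well below 1 %.
- **Truncation order.** The ratio is computed first, then clipped — the
  formula as stated. Under zero-mean noise, clipping biases pure-tissue
  voxels down and pure-fluid voxels up by the same expected amount, so the
  net STV bias scales with the tissue/fluid *imbalance* of the region. In
  vivo the two volumes are nearly equal (medians 8177 vs 8158 mm³), which
  is the regime the default phantom reproduces; in strongly tissue-
  dominated regions the truncation causes a systematic underestimate of
  order `0.4·σ/(m_s−m_f)` times the imbalance.
- **Masks are binary and voxels counted whole**; sub-voxel mask handling
  is out of scope. Co-registration is assumed: a shape mismatch is a hard
  error, registration is never attempted.

## Phantom generator

Parametric solids with exact ground truth: an ellipsoidal synovial shell
around an ellipsoidal fluid pool containing a box-shaped cartilage plate.
Default semi-axes put roughly equal volume in shell and pool (see above).
Intensities are compartment means plus iid Gaussian noise; default means
(post: tissue 300, fluid 100, cartilage 60; pre: cartilage 200, soft 50)
give a 200-unit tissue/fluid contrast, and "10 % noise" in the validation
studies means SD 20. An optional mixing mode supersamples voxels on the
tissue–fluid interface (3× per axis) and blends intensities by sub-voxel
occupancy; the ground-truth STV is then the occupancy sum, which the
quantifier recovers exactly at zero noise because the mixture model is the
generator inverted. Rician noise is noted as an extension, not
implemented: the additive Gaussian model is sufficient to exercise the
mixture estimator and keeps ground truth exact.

`perturb_segmentation` flips boundary-rim voxels (6-connectivity, inner
and outer rim) at a given rate to emulate intra-observer re-segmentation.
Differences between two independently perturbed contours are mean-zero by
exchangeability; a perturbed contour is *not* unbiased against the
original, because added outer-rim voxels sit on background intensity and
contribute almost no tissue fraction.

## Outcome rules

KOOS pain: nine 0–4 items, score `100 − 25·mean(items)`, up to two
missing items tolerated by mean substitution (the standard rule), more is
an explicit error. Eligibility: moderate pain > 48 h in the last two
weeks, or P2–P9 sum > 7 of 32.

Responder rule, with KOOS increase = improvement: criterion (ii) is a
relative improvement ≥ 50 %; criterion (i) is ≥ 20 % plus global
improvement on a 5-category transition item; both carry the conditional
clause "absolute change ≥ 3 if baseline ≤ 15", implemented literally as
printed (it differs from some statements of the canonical OMERACT-OARSI
thresholds, where the absolute clause applies throughout). Open choices
and how they are resolved:

- **Relative-change denominator**: the baseline score (literal reading of
  "% change in score"); `denominator="scale"` switches to percent of the
  100-point range. A baseline of 0 makes the ratio undefined; such
  subjects are classified on the absolute clause alone and flagged.
- **Global improvement**: the five category labels are not enumerated in
  the source; the package uses worse/slightly worse/unchanged/slightly
  better/much better and counts the top two as improvement
  (configurable).
- **Six months** is operationalised as 183 days; relapse is assessed at
  the resolution of the biweekly telephone schedule, taking the first
  record whose score falls to ≤ 1.2× baseline.

## Panel statistics

`fit_fixed_effects` demeans outcome, STV/1000 and visit dummies within
subject and solves the within regression by least squares. Residual df is
`N_obs − N_subjects − k`, i.e. the absorbed subject means are counted;
standard errors are conventional homoskedastic within-estimator SEs (no
clustering — nothing in the source analysis suggests robust SEs), CIs and
p-values are t-based and two-sided, with no multiplicity adjustment.
"Overall R²" follows the convention of standard fixed-effects software:
the squared correlation between the observed outcome and fitted values
including the recovered subject effects `α̂_i = ȳ_i − x̄_i′β̂`; the
within-R² is also reported. ΔR² is the overall-R² gain of the STV model
over the visit-only model on the identical sample, non-negative for these
nested least-squares fits. The standardised β uses pooled overall SDs,
`β_std = b·SD(x)/SD(y)`. Identity with dummy-variable OLS is enforced by
test to 1e-8 on balanced and unbalanced panels.

ICC for repeat segmentation defaults to the two-way absolute-agreement
single-measure form ICC(A,1) with the McGraw–Wong F-based CI
(Satterthwaite df); the one-way ICC(1,1) is selectable because the source
form is unknown. Spearman's ρ uses average ranks with a Fisher-z CI and
the Bonett–Wright variance `(1 + ρ²/2)/(n − 3)`. Paired changes are mean
difference with t-based CI; the all-zero-difference edge case returns
(0, [0,0], p=1). The change-by-group interaction test is the pooled-
variance two-sample comparison of change scores (identical to the group-
coefficient p in a linear model of change on group), with Welch as the
alternative convention.

## Cohort simulator

Emulates an open-label injection trial: baseline MRI + scores, follow-up
at ~8 days (lognormal, median 8, IQR ≈ 7–13.5), response classification,
biweekly telephone KOOS for responders, final MRI at relapse or 183 days.
Defaults are the published cohort conditions: n = 120; baseline KOOS
~ N(45.6, 14.6²) truncated to [0,100]; VAS ~ (6.53, 1.8²); baseline STV
lognormal matched to median 8177 and IQR 5743–13 056 (σ from the quartile
ratio, so the median is exact and the IQR is matched in ratio — the
printed quartiles are individually reproduced to within ~7 %, the
limitation of a two-parameter fit to an asymmetric IQR); within-subject
slopes −1.13 KOOS and +0.17 VAS per 1000 mm³; follow-up STV change
−1071 mm³; responder target 85/120; relapse intent 57/80.

Generating equations (the fixed-effects model's world):

    KOOS_it = α_i + improvement_i(t) + β_K·STV_it/1000 + ε_it
    VAS_it  = a_i + improvement_i^v(t) + β_V·STV_it/1000 + e_it

Design decisions that keep these equations *well-specified* for the
within estimator — the property the slope-recovery studies require:

- **STV trajectories are independent of response intent.** Visit effects
  on STV are multiplicative lognormal factors shared by all subjects
  (means matched to the published overall changes; factor log-SD 0.35
  reproduces the CI-implied change SD of ≈ 4100 mm³). Consequence: the
  simulator reproduces the overall STV changes but not the responder/
  relapser *splits* of those changes — coupling STV dynamics to intent
  would correlate the pain-equation error with STV and bias the estimator
  the studies are validating.
- **Response heterogeneity lives in the improvement term**, a latent
  intent (responder/non-responder, relapser/persistent) driving pain
  boosts proportional to the subject's headroom (distance of α_i from the
  no-pain bound), which keeps emitted scores in range without distorting
  the linear model. The final-visit level follows relapse *intent*; the
  emitted relapse label is still computed from the generated call scores.
- **Variance split**: within-subject correlation of scores across visits
  defaults to 0.5 (not reported in the source; configurable), so occasion
  noise is `14.6/√2` KOOS points; the subject-effect SD absorbs what the
  noise and the STV coupling leave of the printed marginal SD.
- **Bounded scales**: simulated STV is a cap-truncated lognormal
  (30 000 mm³) — the unbounded upper tail of a median/IQR-matched
  lognormal would push a linear pain coupling off the 0–10 VAS scale —
  and VAS occasion noise tapers near its anchors (floor/ceiling
  compression of single-item scales; mean-zero given STV, so exogenous).
  Residual clipping of emitted scores affects well under 2 % of records.
- **Labels are classified, never assigned**: responder, relapse and
  persistence come from running the outcomes module on the generated
  scores, so simulator truth and classifier output agree by construction.
  Because classification of noisy scores is asymmetric, the latent intent
  rate (0.65) was calibrated once so the *classified* responder fraction
  equals the published 70.8 %. The realized relapse fraction drifts above
  its 57/80 intent rate (noisy biweekly calls cross the within-20 %
  threshold early for some persistent-intent subjects); it is not a
  calibrated quantity. Relapse status inferred from the three-visit CSV
  alone (single final score) is noisier than the simulator's call-level
  truth.
- Global change is a noisy ordinal function of the realized KOOS change
  (thresholds ±3/±10, reporting noise SD 3) — the source never links the
  two quantitatively. Covariates (crystals 9/64 of the ~50 % aspirated,
  K–L grades 38.5/55.1/6.4 % of 115/120 graded, 7.5 % missing MRI) are
  independent dressing for the report tables.

What passing tests therefore show: the estimators recover their
generating values on data with the published moments and trial structure.
What they do not show: robustness to real-MRI artefacts (bias fields,
Rician noise, registration error), to pain dynamics that are nonlinear in
STV, or to informative missingness — none of which the generators emulate.

## Validation studies and problem sizes

`scripts/acceptance.py` and `tests/test_acceptance.py` use: 200 replicate
cohorts of n = 120 for slope recovery (mean recovered slope within
Monte-Carlo error of the generating value; 95 % CI coverage within
0.92–0.97); 200 replicates of paired draws (n = 111 STV, n = 120 KOOS,
n = 48 relapser rebound) whose difference SDs are backed out of the
published t-based CIs; 500 measurement pairs at generating ICC 0.94
(tolerance ±0.02); 20 phantoms at 10 %-of-contrast noise for the < 2 %
mean STV-recovery bound; a 101×101×5 exhaustive truth-table comparison of
the responder rule against an independently coded oracle; and 50 seeded
panels for the within-vs-dummy-OLS identity at 1e-8. These sizes keep the
whole suite under a minute while leaving Monte-Carlo error well below
each tolerance.
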