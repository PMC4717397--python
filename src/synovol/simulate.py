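"""Synthetic longitudinal cohorts emulating an open-label steroid-injection trial.

Structure emulated per subject: a baseline visit (contrast-enhanced MRI +
KOOS/VAS), a post-injection follow-up at ~8 days, OARSI-OMERACT response
classification, biweekly telephone KOOS for responders, and a final visit
at relapse or at 6 months (183 days).

Generating model (the panel model's world):

    KOOS_it = alpha_i + improvement_i(t) + beta_K * STV_it / 1000 + eps_it
    VAS_it  = a_i    + improvement_i^v(t) + beta_V * STV_it / 1000 + e_it

Subject effects ``alpha_i`` and STV trajectories are drawn independently
of the latent response intent; response heterogeneity enters only through
the intent-driven improvement terms, which are independent of STV.  The
pain equations are therefore well-specified for the fixed-effects within
estimator, whose slope-recovery behaviour this simulator exists to test.

STV evolves multiplicatively (lognormal visit factors), which keeps
volumes positive and yields the published mean changes.  Improvement is
proportional to a subject's pain headroom (distance of the subject effect
from the no-pain bound), so emitted scores rarely hit the 0/100 bounds.

Response/relapse labels are never assigned directly: they are obtained by
running the outcomes module on the generated scores, so simulator output
is self-consistent with the classifier by construction.  Because
classification is applied to noisy scores, a latent-intent rate is
calibrated (deconvolution at the default noise level) so the *classified*
responder fraction matches the published 70.8%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .outcomes import (
    GlobalChange,
    RelapseStatus,
    VisitRecord,
    classify_persistent,
    classify_responder,
    global_change_from_delta,
    RELAPSE_WINDOW_DAYS,
)

_Z_QUARTILE = 0.6744897501960817  # standard normal upper-quartile


def lognormal_from_median_iqr(median: float, iqr: tuple[float, float]):
    """(mu, sigma) of a lognormal matched to a printed median and IQR.

    mu = log(median); sigma from the q3/q1 ratio (the right-skew is
    carried entirely by sigma, so the median is exact and the quartiles
    are matched in ratio).
    """
    q1, q3 = iqr
    if not (0 < q1 < median < q3):
        raise ValueError(f"need 0 < q1 < median < q3, got {q1}, {median}, {q3}")
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2 * _Z_QUARTILE)
    return mu, sigma


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters; defaults reproduce the published cohort."""

    n_subjects: int = 120
    # baseline pain
    koos_baseline_mean: float = 45.6
    koos_baseline_sd: float = 14.6
    vas_baseline_mean: float = 6.53
    vas_baseline_sd: float = 1.8
    #: share of baseline pain variance that is occasion noise (1 - within-
    #: subject correlation across visits; correlation defaults to 0.5)
    within_subject_corr: float = 0.5
    # baseline volumes (lognormal, matched to median / IQR)
    stv_median: float = 8177.0
    stv_iqr: tuple[float, float] = (5743.0, 13056.0)
    #: physiological cap on simulated volumes; a lognormal matched to the
    #: printed median/IQR overshoots in the far upper tail, where a linear
    #: pain coupling would leave the bounded pain scales
    stv_max: float = 30000.0
    fluid_median: float = 8158.0
    fluid_iqr: tuple[float, float] = (5699.0, 12457.0)
    # within-subject pain-volume coupling (per 1000 mm^3)
    slope_koos_per_1000: float = -1.13
    slope_vas_per_1000: float = 0.17
    # visit effects on STV: multiplicative factors with these mean changes
    stv_followup_change_mean: float = -1071.0
    stv_followup_factor_sd: float = 0.35
    #: final-visit change averaged over relapsers and persistent responders
    #: (57*1220 + 23*(-202)) / 80 — STV dynamics are intent-independent
    stv_final_change_mean: float = 811.0
    stv_final_factor_sd: float = 0.35
    # response process
    responder_probability: float = 85.0 / 120.0
    #: latent intent rate; None = deconvolution-calibrated for default noise
    responder_intent_rate: Optional[float] = None
    koos_boost_responders: float = 33.6
    koos_boost_nonresponders: float = 0.5
    vas_boost_responders: float = -4.2
    vas_boost_nonresponders: float = -0.7
    # relapse process
    relapse_probability: float = 57.0 / 80.0
    koos_final_boost_relapsers: float = 2.8
    koos_final_boost_persistent: float = 30.4
    vas_final_boost_relapsers: float = -0.09
    vas_final_boost_persistent: float = -2.9
    call_interval_days: int = 14
    # logistics
    followup_day_median: float = 8.0
    followup_day_iqr: tuple[float, float] = (7.0, 13.5)
    p_return_final: float = 80.0 / 85.0
    missing_mri_rate: float = 9.0 / 120.0
    global_change_noise_sd: float = 3.0
    # covariates
    aspiration_rate: float = 64.0 / 127.0
    crystal_rate_aspirated: float = 9.0 / 64.0
    kl_grade_probs: tuple[float, float, float] = (0.385, 0.551, 0.064)
    kl_known_rate: float = 115.0 / 120.0
    seed: int = 0

    def validate(self) -> None:
        probs = [self.responder_probability, self.relapse_probability,
                 self.p_return_final, self.missing_mri_rate,
                 self.aspiration_rate, self.crystal_rate_aspirated,
                 self.kl_known_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0.0 < self.within_subject_corr < 1.0:
            raise ValueError("within_subject_corr must be in (0, 1)")
        if abs(sum(self.kl_grade_probs) - 1.0) > 1e-9:
            raise ValueError("kl_grade_probs must sum to 1")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        lognormal_from_median_iqr(self.stv_median, self.stv_iqr)
        sd_eps = self.koos_baseline_sd * math.sqrt(1 - self.within_subject_corr)
        if self.koos_boost_responders - self.koos_boost_nonresponders < sd_eps:
            raise ValueError(
                "responder/non-responder KOOS boosts are closer than the "
                "occasion noise SD; the target responder probability is "
                "unreachable by classification"
            )


#: latent-intent rate that makes the *classified* responder fraction equal
#: the default responder_probability (0.708) at the default noise level;
#: solved once by stochastic root-finding over large simulated cohorts.
_RESPONDER_INTENT_CALIBRATION = 0.65


@dataclass
class SubjectTruth:
    """Generating-side bookkeeping for one subject (not observable data)."""

    subject_id: str
    alpha_koos: float
    alpha_vas: float
    intent_responder: bool
    intent_relapse: Optional[bool]
    responder: Optional[bool] = None
    relapse: Optional[RelapseStatus] = None


@dataclass
class Cohort:
    """Simulated cohort: per-visit records plus generating-side truth."""

    records: list[VisitRecord]
    truth: list[SubjectTruth]
    calls: dict[str, list[VisitRecord]]
    params: CohortParams
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {
                "subject_id": r.subject_id, "visit": r.visit,
                "days_since_injection": r.days_since_injection,
                "koos_pain": r.koos_pain, "vas_na": r.vas_na,
                "vas_week": r.vas_week,
                "global_change": None if r.global_change is None else int(r.global_change),
                "stv_mm3": r.stv_mm3, "fluid_mm3": r.fluid_mm3,
                "crystal_present": r.crystal_present, "kl_grade": r.kl_grade,
            }
            rows.append(d)
        return pd.DataFrame(rows)


def _clip(v, lo, hi):
    return float(min(max(v, lo), hi))


def _pain_sigmas(total_sd: float, corr: float, slope: float, var_x1000: float):
    """Split a marginal baseline SD into subject-effect and occasion parts.

    The coupling term ``slope * STV/1000`` contributes variance too; the
    subject-effect SD absorbs what remains after occasion noise and
    coupling so the marginal baseline SD matches the printed value.
    """
    var_eps = total_sd ** 2 * (1 - corr)
    var_alpha = total_sd ** 2 - var_eps - slope ** 2 * var_x1000
    if var_alpha <= 0:
        var_alpha = 1e-6
    return math.sqrt(var_alpha), math.sqrt(var_eps)


def simulate_cohort(params: CohortParams | None = None,
                    seed: Optional[int] = None) -> Cohort:
    """Generate one cohort; deterministic for a fixed seed.

    ``seed`` overrides ``params.seed`` when given.
    """
    params = params or CohortParams()
    params.validate()
    seed = params.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    p = params

    mu_stv, sg_stv = lognormal_from_median_iqr(p.stv_median, p.stv_iqr)
    mu_fl, sg_fl = lognormal_from_median_iqr(p.fluid_median, p.fluid_iqr)
    # moments of the cap-truncated lognormal baseline STV
    from scipy.stats import norm as _norm
    zc = (math.log(p.stv_max) - mu_stv) / sg_stv
    denom = _norm.cdf(zc)
    e_stv = math.exp(mu_stv + sg_stv ** 2 / 2) * _norm.cdf(zc - sg_stv) / denom
    m2 = math.exp(2 * mu_stv + 2 * sg_stv ** 2) * _norm.cdf(zc - 2 * sg_stv) / denom
    var_x1000 = (m2 - e_stv ** 2) / 1e6

    sd_a_k, sd_e_k = _pain_sigmas(p.koos_baseline_sd, p.within_subject_corr,
                                  p.slope_koos_per_1000, var_x1000)
    sd_a_v, sd_e_v = _pain_sigmas(p.vas_baseline_sd, p.within_subject_corr,
                                  p.slope_vas_per_1000, var_x1000)
    mean_a_k = p.koos_baseline_mean - p.slope_koos_per_1000 * e_stv / 1000.0
    mean_a_v = p.vas_baseline_mean - p.slope_vas_per_1000 * e_stv / 1000.0

    # multiplicative STV visit factors: lognormal with the target mean change
    f2_mean = 1.0 + p.stv_followup_change_mean / e_stv
    e_stv_followup = e_stv * f2_mean
    f3_mean = 1.0 + p.stv_final_change_mean / e_stv_followup

    def _factor(mean, sd_log):
        return float(np.exp(rng.normal(math.log(mean) - sd_log ** 2 / 2, sd_log)))

    # Headroom scalings for the intent-driven improvement terms.  Targets
    # are mean observed changes, so the STV-coupling contribution to the
    # mean change is netted out; headroom is measured from the mean
    # subject effect (100 - alpha for KOOS, alpha for VAS).
    e_stv_final = e_stv_followup * f3_mean
    dx2 = (e_stv_followup - e_stv) / 1000.0  # expected change, baseline->followup
    dx3 = (e_stv_final - e_stv) / 1000.0  # expected change, baseline->final
    head_k_mean = 100.0 - mean_a_k
    head_v_mean = mean_a_v
    g_resp = (p.koos_boost_responders - p.slope_koos_per_1000 * dx2) / head_k_mean
    g_final_rel = (p.koos_final_boost_relapsers
                   - p.slope_koos_per_1000 * dx3) / head_k_mean
    g_final_per = (p.koos_final_boost_persistent
                   - p.slope_koos_per_1000 * dx3) / head_k_mean
    gv_resp = -(p.vas_boost_responders - p.slope_vas_per_1000 * dx2) / head_v_mean
    gv_final_rel = -(p.vas_final_boost_relapsers
                     - p.slope_vas_per_1000 * dx3) / head_v_mean
    gv_final_per = -(p.vas_final_boost_persistent
                     - p.slope_vas_per_1000 * dx3) / head_v_mean

    mu_d2, sg_d2 = lognormal_from_median_iqr(
        p.followup_day_median,
        (p.followup_day_iqr[0], p.followup_day_iqr[1]),
    )

    intent_rate = p.responder_intent_rate
    if intent_rate is None:
        if abs(p.responder_probability - 85.0 / 120.0) < 1e-9:
            intent_rate = _RESPONDER_INTENT_CALIBRATION
        else:
            intent_rate = p.responder_probability

    records: list[VisitRecord] = []
    truths: list[SubjectTruth] = []
    calls_by_subject: dict[str, list[VisitRecord]] = {}

    for i in range(p.n_subjects):
        sid = f"S{i + 1:03d}"
        z = rng.normal()
        x1 = math.exp(mu_stv + sg_stv * z)
        while x1 > p.stv_max:  # truncated lognormal (resampling)
            z = rng.normal()
            x1 = math.exp(mu_stv + sg_stv * z)
        zf = 0.8 * z + math.sqrt(1 - 0.64) * rng.normal()
        fl1 = math.exp(mu_fl + sg_fl * zf)
        f2 = _factor(f2_mean, p.stv_followup_factor_sd)
        while x1 * f2 > p.stv_max:
            f2 = _factor(f2_mean, p.stv_followup_factor_sd)
        x2 = x1 * f2
        fl2 = fl1 * f2 * float(np.exp(rng.normal(-0.01125, 0.15)))

        alpha_k = rng.normal(mean_a_k, sd_a_k)
        alpha_v = rng.normal(mean_a_v, sd_a_v)
        head_k = max(100.0 - alpha_k, 0.0)
        head_v = max(alpha_v, 0.0)

        intent_resp = rng.random() < intent_rate
        crystal = None
        if rng.random() < p.aspiration_rate:
            crystal = bool(rng.random() < p.crystal_rate_aspirated)
        kl = None
        if rng.random() < p.kl_known_rate:
            kl = int(rng.choice((2, 3, 4), p=p.kl_grade_probs))

        def koos_at(x, boost):
            return _clip(alpha_k + boost + p.slope_koos_per_1000 * x / 1000.0
                         + rng.normal(0, sd_e_k), 0.0, 100.0)

        def vas_at(x, boost):
            # Single-item VAS shows floor/ceiling compression: occasion
            # noise shrinks near the anchors.  The taper depends only on
            # the latent mean (mean-zero noise given STV), so the panel
            # slope stays unbiased (heteroskedastic but exogenous).
            m = alpha_v + boost + p.slope_vas_per_1000 * x / 1000.0
            taper = min(1.0, max(m, 0.0) / (2 * sd_e_v),
                        max(10.0 - m, 0.0) / (2 * sd_e_v))
            return _clip(m + rng.normal(0, sd_e_v * max(taper, 0.05)), 0.0, 10.0)

        koos1 = koos_at(x1, 0.0)
        vas1 = vas_at(x1, 0.0)
        vweek1 = _clip(vas1 + rng.normal(0, 0.8), 0.0, 10.0)
        miss1 = rng.random() < p.missing_mri_rate
        baseline = VisitRecord(
            subject_id=sid, visit="baseline", days_since_injection=0.0,
            koos_pain=koos1, vas_na=vas1, vas_week=vweek1,
            stv_mm3=None if miss1 else x1, fluid_mm3=None if miss1 else fl1,
            crystal_present=crystal, kl_grade=kl,
        )

        d2 = float(np.round(np.exp(rng.normal(mu_d2, sg_d2))))
        d2 = min(max(d2, 5.0), 20.0)
        boost2 = g_resp * head_k if intent_resp else rng.normal(p.koos_boost_nonresponders, 2.0)
        vboost2 = -gv_resp * head_v if intent_resp else rng.normal(p.vas_boost_nonresponders, 0.4)
        koos2 = koos_at(x2, boost2)
        vas2 = vas_at(x2, vboost2)
        vweek2 = _clip(vas2 + rng.normal(0, 0.8), 0.0, 10.0)
        gchange = global_change_from_delta(
            koos2 - koos1, float(rng.normal(0, p.global_change_noise_sd))
        )
        miss2 = rng.random() < p.missing_mri_rate
        followup = VisitRecord(
            subject_id=sid, visit="followup", days_since_injection=d2,
            koos_pain=koos2, vas_na=vas2, vas_week=vweek2, global_change=gchange,
            stv_mm3=None if miss2 else x2, fluid_mm3=None if miss2 else fl2,
            crystal_present=crystal, kl_grade=kl,
        )
        records.extend([baseline, followup])

        status = classify_responder(baseline, followup)
        truth = SubjectTruth(sid, alpha_k, alpha_v, intent_resp, None,
                             responder=bool(status))
        truths.append(truth)
        if not status.responder:
            continue  # non-responders are not followed up

        intent_rel = rng.random() < p.relapse_probability
        truth.intent_relapse = intent_rel
        t_relapse = rng.uniform(p.call_interval_days, 170.0) if intent_rel else math.inf

        def call_boost(day: float) -> float:
            if day >= t_relapse:
                return g_final_rel * head_k
            w = (day - d2) / max(RELAPSE_WINDOW_DAYS - d2, 1.0)
            g = g_resp + (g_final_per - g_resp) * min(max(w, 0.0), 1.0)
            return g * head_k

        calls = []
        day = float(p.call_interval_days)
        while day <= RELAPSE_WINDOW_DAYS:
            calls.append(VisitRecord(
                subject_id=sid, visit="call", days_since_injection=day,
                koos_pain=koos_at(x2, call_boost(day)),
            ))
            day += p.call_interval_days
        calls_by_subject[sid] = calls
        relapse = classify_persistent(calls, baseline)
        truth.relapse = relapse

        if rng.random() >= p.p_return_final:
            continue  # responder lost before the final MRI
        # The final pain level follows the latent disease trajectory
        # (relapse intent); the classified relapse label is an observable
        # consequence of the generated scores, never a cause of them —
        # this keeps the pain-equation error independent of STV.
        if relapse.relapsed:
            d3 = min(relapse.relapse_day + 7.0, float(RELAPSE_WINDOW_DAYS))
        else:
            d3 = float(RELAPSE_WINDOW_DAYS)
        if intent_rel:
            boost3, vboost3 = g_final_rel * head_k, -gv_final_rel * head_v
        else:
            boost3, vboost3 = g_final_per * head_k, -gv_final_per * head_v
        f3 = _factor(f3_mean, p.stv_final_factor_sd)
        while x2 * f3 > p.stv_max:
            f3 = _factor(f3_mean, p.stv_final_factor_sd)
        x3 = x2 * f3
        fl3 = fl2 * f3 * float(np.exp(rng.normal(-0.01125, 0.15)))
        koos3 = koos_at(x3, boost3)
        vas3 = vas_at(x3, vboost3)
        miss3 = rng.random() < p.missing_mri_rate
        records.append(VisitRecord(
            subject_id=sid, visit="final", days_since_injection=d3,
            koos_pain=koos3, vas_na=vas3,
            vas_week=_clip(vas3 + rng.normal(0, 0.8), 0.0, 10.0),
            stv_mm3=None if miss3 else x3, fluid_mm3=None if miss3 else fl3,
            crystal_present=crystal, kl_grade=kl,
        ))

    return Cohort(records=records, truth=truths, calls=calls_by_subject,
                  params=params, seed=seed)


def simulate_koos_items(score: float, seed: int = 0):
    """Nine KOOS pain item responses consistent with a 0-100 subscale score.

    The item sum is fixed to ``round(9 * (100 - score) / 25)`` and spread
    randomly over the items (each 0-4), so re-scoring the items recovers
    the target score up to the 25/9-point granularity of the subscale.
    """
    from .outcomes import KoosPainItems

    if not 0.0 <= score <= 100.0:
        raise ValueError("score must be in [0, 100]")
    rng = np.random.default_rng(seed)
    total = int(round(9 * (100.0 - score) / 25.0))
    items = [0] * 9
    while total > 0:
        candidates = [i for i in range(9) if items[i] < 4]
        items[int(rng.choice(candidates))] += 1
        total -= 1
    return KoosPainItems(tuple(items))


def simulate_measurement_pairs(true_icc: float, n_pairs: int, seed: int = 0,
                               mean: float = 9000.0, scale: float = 3000.0):
    """Repeat-segmentation pairs from a one-way variance-components model.

    Between-target and within-target variances are set so the population
    intraclass correlation equals ``true_icc``; ``mean``/``scale`` place
    the values on an STV-like mm^3 scale (the ICC is scale-invariant).
    """
    if not 0.0 <= true_icc <= 1.0:
        raise ValueError("true_icc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, math.sqrt(true_icc), size=(n_pairs, 1))
    w = rng.normal(0.0, math.sqrt(1.0 - true_icc), size=(n_pairs, 2))
    return mean + scale * (b + w)


def cohort_to_csv(cohort: Cohort, path, *, write_params: bool = True) -> None:
    """Write the per-visit table; optionally a YAML params/seed snapshot."""
    df = cohort.to_frame()
    df.to_csv(path, index=False)
    if write_params:
        import yaml
        from pathlib import Path

        snap = {"seed": cohort.seed, "params": asdict(cohort.params)}
        Path(str(path) + ".params.yaml").write_text(
            yaml.safe_dump(snap, default_flow_style=None)
        )
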