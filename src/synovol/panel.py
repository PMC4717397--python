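"""Within-subject panel regression and the surrounding statistical toolkit.

The centrepiece is the fixed-effects (within) estimator for the model

    y_it = beta * (STV_it / 1000) + gamma' visit_it + alpha_i + u_it

where ``alpha_i`` is a subject fixed effect absorbed by demeaning every
variable within subject.  Degrees of freedom account for the absorbed
subject means (df = N_obs - N_subjects - k).  The "overall R^2" follows
the convention of standard fixed-effects software output: the squared
correlation between the observed outcome and fitted values that include
the recovered subject effects.

Also here: intraclass correlation for segmentation repeatability
(two-way absolute-agreement ICC(A,1) by default, one-way ICC(1,1)
selectable), Spearman correlation with a Fisher-z CI, paired change
scores with t-based inference, Pearson chi-square independence tests and
a change-by-group interaction test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class IdentificationError(ValueError):
    """The requested estimate is not identified on the given data."""


@dataclass(frozen=True)
class FixedEffectsFit:
    """Within-subject estimate of the STV coefficient.

    ``b`` is in outcome units per ``scale_mm3`` mm^3 of STV.
    """

    b: float
    se: float
    ci95: tuple[float, float]
    p: float
    beta_std: float
    r2_overall: float
    r2_within: float
    delta_r2: float
    df_resid: int
    n_obs: int
    n_subjects: int
    scale_mm3: float


def make_panel(
    visits: pd.DataFrame,
    outcome: str = "koos_pain",
    *,
    subject: str = "subject_id",
    visit: str = "visit",
    stv: str = "stv_mm3",
) -> pd.DataFrame:
    """Build a (subject, visit, y, stv) panel from a per-visit table.

    Rows with a missing outcome or STV are dropped; subjects must not
    contribute duplicated (subject, visit) cells.
    """
    df = visits[[subject, visit, outcome, stv]].dropna()
    df = df.rename(columns={subject: "subject", visit: "visit",
                            outcome: "y", stv: "stv"})
    if df.duplicated(["subject", "visit"]).any():
        raise ValueError("duplicated (subject, visit) rows in panel")
    return df.reset_index(drop=True)


def _within_demean(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    g = df.groupby("subject")[list(cols)]
    return df[list(cols)] - g.transform("mean")


def _fe_design(panel: pd.DataFrame, scale_mm3: float, with_stv: bool):
    """Demeaned design matrix (+ raw matrix) for the within regression."""
    df = panel.copy()
    df["x_stv"] = df["stv"] / scale_mm3
    dummies = pd.get_dummies(df["visit"], prefix="visit", dtype=float)
    # drop the first visit level as the reference
    dummies = dummies.iloc[:, 1:]
    cols = (["x_stv"] if with_stv else []) + list(dummies.columns)
    for c in dummies.columns:
        df[c] = dummies[c]
    X_raw = df[cols].to_numpy(dtype=float)
    demeaned = _within_demean(df, ["y"] + cols)
    y_dm = demeaned["y"].to_numpy(dtype=float)
    X_dm = demeaned[cols].to_numpy(dtype=float)
    return df, cols, X_raw, X_dm, y_dm


def _fe_solve(panel: pd.DataFrame, scale_mm3: float, with_stv: bool):
    """Solve the within regression; returns coefficients and fit summaries."""
    df, cols, X_raw, X_dm, y_dm = _fe_design(panel, scale_mm3, with_stv)
    n_obs = len(df)
    n_subj = df["subject"].nunique()
    k = len(cols)
    XtX = X_dm.T @ X_dm
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise IdentificationError(f"singular within design: {exc}") from None
    beta = XtX_inv @ (X_dm.T @ y_dm)
    resid = y_dm - X_dm @ beta
    ssr = float(resid @ resid)
    df_resid = n_obs - n_subj - k
    if df_resid <= 0:
        raise IdentificationError("not enough observations for the within fit")
    sigma2 = ssr / df_resid
    cov = sigma2 * XtX_inv
    # recover subject effects: alpha_i = mean(y_i) - mean(X_i) beta
    y = df["y"].to_numpy(dtype=float)
    subj_mean_y = df.groupby("subject")["y"].transform("mean").to_numpy()
    subj_mean_Xb = (
        pd.Series(X_raw @ beta, index=df.index)
        .groupby(df["subject"]).transform("mean").to_numpy()
    )
    fitted = X_raw @ beta + (subj_mean_y - subj_mean_Xb)
    r2_overall = float(np.corrcoef(y, fitted)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    sst_within = float(y_dm @ y_dm)
    r2_within = 1.0 - ssr / sst_within if sst_within > 0 else 0.0
    return df, cols, beta, cov, df_resid, r2_overall, r2_within, n_obs, n_subj


def fit_fixed_effects(
    panel: pd.DataFrame, scale_mm3: float = 1000.0
) -> FixedEffectsFit:
    """Fixed-effects regression of the outcome on STV and visit dummies.

    ``panel`` needs columns ``subject``, ``visit``, ``y``, ``stv``
    (see :func:`make_panel`).  Subjects with fewer than two usable visits
    drop out of the within estimator.  ``delta_r2`` is the gain in overall
    R^2 from adding STV to the visit-only model on the same sample.
    """
    counts = panel.groupby("subject")["y"].size()
    keep = counts[counts >= 2].index
    panel = panel[panel["subject"].isin(keep)].reset_index(drop=True)
    if panel["subject"].nunique() < 2:
        raise IdentificationError("need >= 2 subjects with >= 2 visits")
    within_var = panel.groupby("subject")["stv"].var(ddof=0)
    if not (within_var > 0).any():
        raise IdentificationError("STV is constant within every subject; slope unidentified")

    df, cols, beta, cov, df_resid, r2_full, r2_within, n_obs, n_subj = _fe_solve(
        panel, scale_mm3, with_stv=True
    )
    *_, r2_reduced, _, _, _ = _fe_solve(panel, scale_mm3, with_stv=False)

    i = cols.index("x_stv")
    b = float(beta[i])
    se = float(np.sqrt(cov[i, i]))
    tcrit = stats.t.ppf(0.975, df_resid)
    tval = b / se
    p = float(2.0 * stats.t.sf(abs(tval), df_resid))
    sd_x = float(df["x_stv"].std(ddof=1))
    sd_y = float(df["y"].std(ddof=1))
    beta_std = b * sd_x / sd_y if sd_y > 0 else float("nan")
    return FixedEffectsFit(
        b=b, se=se, ci95=(b - tcrit * se, b + tcrit * se), p=p,
        beta_std=beta_std, r2_overall=r2_full, r2_within=r2_within,
        delta_r2=r2_full - r2_reduced, df_resid=df_resid,
        n_obs=n_obs, n_subjects=n_subj, scale_mm3=scale_mm3,
    )


# ---------------------------------------------------------------------------
# Intraclass correlation (segmentation repeatability)
# ---------------------------------------------------------------------------

def icc_intraobserver(
    pairs: Iterable[tuple[float, float]],
    *,
    form: str = "A1",
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """ICC for repeated measurements of the same targets by one observer.

    ``form="A1"`` (default) is the two-way mixed, absolute-agreement,
    single-measure ICC; ``form="1"`` is the one-way random ICC(1,1).
    The 95% CI is F-based (Satterthwaite df for the A1 form).
    """
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected a sequence of (m1, m2) pairs")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 pairs")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise IdentificationError("zero total variance; ICC undefined")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))

    if form == "1":
        icc = (msr - msw) / (msr + (k - 1) * msw)
        f = msr / msw
        fl = f / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        fu = f * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(icc), (float(lo), float(hi))
    if form != "A1":
        raise ValueError(f"unknown ICC form {form!r}; use 'A1' or '1'")

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if icc >= 1.0 - 1e-12:  # perfect agreement: degenerate CI
        return 1.0, (1.0, 1.0)
    # McGraw & Wong F-based CI with Satterthwaite degrees of freedom
    a = (k * icc) / (n * (1 - icc))
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    nu = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, nu)
    f_u = stats.f.ppf(1 - alpha / 2, nu, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Correlation, change scores, contingency, interaction
# ---------------------------------------------------------------------------

def spearman_ci(x, y, *, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Average ranks are used for ties.  The CI uses the Bonett-Wright
    large-sample variance ``(1 + rho^2 / 2) / (n - 3)`` on the z scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0 - 1e-12:
        rho = float(np.sign(rho))
        return rho, (rho, rho)
    z = np.arctanh(rho)
    se = math.sqrt((1 + rho ** 2 / 2) / (n - 3))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return rho, (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))


def paired_change(before, after, *, alpha: float = 0.05):
    """Mean within-pair change (after - before) with t-based 95% CI and p.

    Degenerate all-zero differences return (0, (0, 0), 1).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be 1-D and paired")
    n = len(before)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = after - before
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return mean, (mean, mean), (1.0 if mean == 0 else 0.0)
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return mean, (mean - tcrit * se, mean + tcrit * se), p


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must contain nonnegative integer counts")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def change_by_group_interaction(change, group, *, welch: bool = False) -> float:
    """Two-sided p for a group difference in change scores.

    Equivalent to the p of the group coefficient in a linear regression of
    change on the group indicator (pooled-variance t); ``welch=True``
    switches to the unequal-variance convention.
    """
    change = np.asarray(change, dtype=float)
    group = np.asarray(group, dtype=bool)
    a, b = change[group], change[~group]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)
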