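"""Within estimator, ICC, correlation, change scores, contingency tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synovol.panel import (
    IdentificationError,
    change_by_group_interaction,
    chisq_independence,
    fit_fixed_effects,
    icc_intraobserver,
    make_panel,
    paired_change,
    spearman_ci,
)
from synovol.simulate import simulate_measurement_pairs


def _random_panel(seed, n_subj=15, balanced=True):
    rng = np.random.default_rng(seed)
    rows = []
    alphas = rng.normal(50, 12, n_subj)
    effects = {"v1": 0.0, "v2": 18.0, "v3": 4.0}
    for i in range(n_subj):
        visits = ["v1", "v2", "v3"] if balanced else \
            ["v1", "v2", "v3"][: rng.choice([2, 3])]
        for v in visits:
            x = rng.lognormal(9.0, 0.6)
            y = alphas[i] - 1.13 * x / 1000 + effects[v] + rng.normal(0, 8)
            rows.append({"subject": f"S{i}", "visit": v, "stv": x, "y": y})
    return pd.DataFrame(rows)


class TestFixedEffects:
    def test_noiseless_slope_identified_exactly(self):
        rows = []
        for i in range(3):
            for v, x in [("v1", 5000.0 + 1000 * i), ("v2", 8000.0 + 500 * i)]:
                rows.append({"subject": f"P{i}", "visit": v, "stv": x,
                             "y": 5.0 - 1.13 * x / 1000 + 10.0 * i})
        fit = fit_fixed_effects(pd.DataFrame(rows))
        assert fit.b == pytest.approx(-1.13, abs=1e-10)
        assert fit.r2_within == pytest.approx(1.0)

    @pytest.mark.parametrize("balanced", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_dummy_variable_ols(self, seed, balanced):
        import statsmodels.formula.api as smf

        panel = _random_panel(seed, balanced=balanced)
        fit = fit_fixed_effects(panel)
        df = panel.copy()
        df["x"] = df["stv"] / 1000
        ols = smf.ols("y ~ x + C(visit) + C(subject)", data=df).fit()
        assert fit.b == pytest.approx(ols.params["x"], abs=1e-8)
        assert fit.se == pytest.approx(ols.bse["x"], abs=1e-8)
        assert fit.p == pytest.approx(ols.pvalues["x"], abs=1e-8)

    def test_subject_level_shift_leaves_slope_unchanged(self):
        panel = _random_panel(7)
        fit = fit_fixed_effects(panel)
        shifted = panel.copy()
        mask = shifted["subject"] == "S0"
        shifted.loc[mask, "y"] += 500.0
        fit2 = fit_fixed_effects(shifted)
        assert fit2.b == pytest.approx(fit.b, abs=1e-10)

    def test_delta_r2_nonnegative(self):
        for seed in range(5):
            fit = fit_fixed_effects(_random_panel(seed))
            assert fit.delta_r2 >= -1e-12

    def test_ci_is_t_based_around_b(self):
        fit = fit_fixed_effects(_random_panel(3))
        tcrit = stats.t.ppf(0.975, fit.df_resid)
        assert fit.ci95[0] == pytest.approx(fit.b - tcrit * fit.se)
        assert fit.ci95[1] == pytest.approx(fit.b + tcrit * fit.se)

    def test_within_constant_stv_unidentified(self):
        rows = [{"subject": s, "visit": v, "stv": 8000.0, "y": float(i + j)}
                for i, s in enumerate("AB") for j, v in enumerate(["v1", "v2"])]
        with pytest.raises(IdentificationError):
            fit_fixed_effects(pd.DataFrame(rows))

    def test_make_panel_drops_missing_and_rejects_duplicates(self):
        visits = pd.DataFrame({
            "subject_id": ["A", "A", "B", "B"],
            "visit": ["baseline", "followup", "baseline", "followup"],
            "koos_pain": [40.0, None, 50.0, 60.0],
            "stv_mm3": [8000.0, 7000.0, 9000.0, 8000.0],
        })
        panel = make_panel(visits)
        assert len(panel) == 3
        dup = pd.concat([visits, visits.iloc[[0]]])
        with pytest.raises(ValueError):
            make_panel(dup)


class TestICC:
    def test_identical_pairs_give_one(self):
        pairs = np.column_stack([np.arange(10.0), np.arange(10.0)])
        icc, ci = icc_intraobserver(pairs)
        assert icc == 1.0 and ci == (1.0, 1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        pairs = rng.normal(size=(4000, 2))
        icc, _ = icc_intraobserver(pairs)
        assert abs(icc) < 0.05

    def test_recovers_generating_icc(self):
        pairs = simulate_measurement_pairs(0.94, 500, seed=11)
        icc, ci = icc_intraobserver(pairs)
        assert icc == pytest.approx(0.94, abs=0.02)
        assert ci[0] < icc < ci[1]

    def test_affine_invariance(self):
        pairs = simulate_measurement_pairs(0.8, 100, seed=2)
        icc1, _ = icc_intraobserver(pairs)
        icc2, _ = icc_intraobserver(3.7 * pairs - 120.0)
        assert icc2 == pytest.approx(icc1, rel=1e-10)

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        pairs = simulate_measurement_pairs(0.7, 60, seed=5)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(60), 2),
            "raters": np.tile([0, 1], 60),
            "scores": pairs.ravel(),
        })
        ref = pg.intraclass_corr(df, "targets", "raters", "scores")
        ref = ref.set_index("Type")["ICC"]
        icc_a1, _ = icc_intraobserver(pairs, form="A1")
        icc_1, _ = icc_intraobserver(pairs, form="1")
        assert icc_a1 == pytest.approx(ref["ICC(A,1)"], abs=1e-9)
        assert icc_1 == pytest.approx(ref["ICC(1,1)"], abs=1e-9)

    def test_zero_variance_undefined(self):
        with pytest.raises(IdentificationError):
            icc_intraobserver(np.full((5, 2), 3.0))


class TestSpearman:
    def test_monotone_relationship_is_one(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman_ci(x, np.exp(x))[0] == 1.0
        assert spearman_ci(x, -x)[0] == -1.0

    def test_ties_match_brute_force_average_ranks(self):
        def brute_rho(x, y):
            def avg_ranks(v):
                order = sorted(range(len(v)), key=lambda i: v[i])
                ranks = [0.0] * len(v)
                i = 0
                while i < len(v):
                    j = i
                    while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                        j += 1
                    for k in range(i, j + 1):
                        ranks[order[k]] = (i + j) / 2 + 1
                    i = j + 1
                return ranks

            rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
            mx, my = np.mean(rx), np.mean(ry)
            num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
            den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                            * sum((b - my) ** 2 for b in ry))
            return num / den

        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.integers(0, 4, 12).astype(float)
            y = rng.integers(0, 4, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_ci(x, y)
            assert rho == pytest.approx(brute_rho(x, y), abs=1e-12)

    def test_ci_covers_generating_rho(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            x = rng.normal(size=60)
            y = 0.7 * x + rng.normal(size=60) * math.sqrt(1 - 0.49)
            rho_true = 6 / math.pi * math.asin(0.7 / 2)  # Pearson->Spearman
            _, (lo, hi) = spearman_ci(x, y)
            hits += lo <= rho_true <= hi
        assert hits >= 85


class TestPairedChange:
    def test_identical_vectors(self):
        mean, ci, p = paired_change([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (mean, ci, p) == (0.0, (0.0, 0.0), 1.0)

    def test_hand_computed_n2_case(self):
        # diffs {1, 3}: mean 2, sd sqrt(2), se 1, t(1) 97.5% = 12.7062
        mean, (lo, hi), p = paired_change([0.0, 0.0], [1.0, 3.0])
        assert mean == 2.0
        assert lo == pytest.approx(2.0 - 12.706204736 * 1.0, abs=1e-6)
        assert hi == pytest.approx(2.0 + 12.706204736 * 1.0, abs=1e-6)
        assert p == pytest.approx(2 * stats.t.sf(2.0, 1), abs=1e-12)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(size=30)
        mean, _, p = paired_change(a, b)
        ref = stats.ttest_rel(b, a)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        assert mean == pytest.approx(float(np.mean(b - a)))


class TestChisq:
    def test_proportional_table_is_zero(self):
        chi2, df, p = chisq_independence([[10, 20, 30], [20, 40, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2 and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        chi2, df, p = chisq_independence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20.0 / 3.0, abs=1e-12)
        assert df == 1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        table = rng.integers(5, 40, (3, 4)).astype(float)
        chi2, df, _ = chisq_independence(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert chi2 == pytest.approx(float(((table - expected) ** 2 / expected).sum()))
        assert df == 6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chisq_independence([[1, -2], [3, 4]])


class TestInteraction:
    def test_equivalent_to_two_sample_t(self):
        rng = np.random.default_rng(1)
        change = rng.normal(size=40)
        group = np.arange(40) < 18
        p = change_by_group_interaction(change, group)
        ref = stats.ttest_ind(change[group], change[~group], equal_var=True)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_distributions_usually_nonsignificant(self):
        rng = np.random.default_rng(2)
        hits = sum(
            change_by_group_interaction(rng.normal(size=60), np.arange(60) < 30) < 0.05
            for _ in range(100)
        )
        assert hits <= 12  # ~5% type-I error

    def test_5sd_shift_is_highly_significant(self):
        rng = np.random.default_rng(3)
        change = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        group = np.arange(100) >= 50
        assert change_by_group_interaction(change, group) < 0.001
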