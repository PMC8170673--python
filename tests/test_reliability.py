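"""Test-retest statistics against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from fus3d.errors import TooFewConditionsError
from fus3d.reliability import (
    TestRetestDataset as TRDataset,
    compare_methods,
    friedman_test,
    icc_2_1,
    mann_whitney,
    pearson_fmt,
    rate_icc,
    reliability_report,
    sem_from_anova,
    test_retest_differences as session_differences,
    variation_from_sds,
    variation_summary,
)

# ---------------------------------------------------------------------------
# independent oracles (direct summation / counting, no shared code paths)


def anova_oracle(X):
    """Two-way ANOVA mean squares by explicit loops."""
    X = np.asarray(X, float)
    n, k = X.shape
    grand = sum(X[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = sum(k * (sum(X[i]) / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (sum(X[:, j]) / n - grand) ** 2 for j in range(k))
    ss_tot = sum((X[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc21_oracle(X):
    msr, msc, mse = anova_oracle(X)
    n, k = np.asarray(X).shape
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def mw_u_oracle(x, y):
    """O(nm) pairwise counting: wins of x plus half-ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def friedman_oracle(X):
    """Hand-computed rank statistic (no ties in the fixture)."""
    X = np.asarray(X, float)
    n, m = X.shape
    ranks = np.zeros_like(X)
    for i in range(n):
        order = sorted(range(m), key=lambda j: X[i][j])
        for r, j in enumerate(order, start=1):
            ranks[i][j] = r
    rank_sums = ranks.sum(axis=0)
    return 12.0 / (n * m * (m + 1)) * sum(rank_sums**2) - 3.0 * n * (m + 1)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


# ---------------------------------------------------------------------------


def make_dataset(rng, n_legs=10, methods=("MMP",), group="lean", noise=1.0):
    rows = []
    for i in range(n_legs):
        true = rng.normal(scale=20.0, size=3)
        for m in methods:
            s1 = true + rng.normal(scale=noise, size=3)
            s2 = true + rng.normal(scale=noise, size=3)
            rows.append({
                "subject_id": f"S{i // 2}", "side": "left" if i % 2 == 0 else "right",
                "group": group, "method": m, "fmt": float(rng.uniform(5, 50)),
                "ap_test": s1[1], "ml_test": s1[0], "si_test": s1[2],
                "ap_retest": s2[1], "ml_retest": s2[0], "si_retest": s2[2],
            })
    return TRDataset.from_frame(pd.DataFrame(rows))


class TestDifferences:
    def test_axis_and_euclidean_example(self):
        df = pd.DataFrame([{
            "subject_id": "a", "side": "left", "group": "lean", "method": "MMP",
            "fmt": 20.0,
            "ap_test": 0.0, "ml_test": 0.0, "si_test": 0.0,
            "ap_retest": 3.0, "ml_retest": 4.0, "si_retest": 0.0,
        }])
        out = session_differences(TRDataset(df))
        assert out.loc[0, ["d_ap", "d_ml", "d_si"]].tolist() == [3.0, 4.0, 0.0]
        assert out.loc[0, "eucl"] == pytest.approx(5.0)

    def test_identical_sessions_all_zero(self, rng):
        ds = make_dataset(rng, noise=0.0)
        out = session_differences(ds)
        assert np.allclose(out[["d_ap", "d_ml", "d_si", "eucl"]], 0.0)

    def test_matches_per_row_loop_oracle(self, rng):
        ds = make_dataset(rng, n_legs=20)
        out = session_differences(ds)
        for i, row in out.iterrows():
            d = [row["ap_retest"] - row["ap_test"], row["ml_retest"] - row["ml_test"],
                 row["si_retest"] - row["si_test"]]
            assert row["eucl"] == pytest.approx(math.sqrt(sum(v * v for v in d)), abs=1e-12)

    def test_missing_session_rows_dropped_and_counted(self, rng):
        ds = make_dataset(rng, n_legs=6)
        df = ds.data.copy()
        df.loc[0, "ap_retest"] = np.nan
        ds2 = TRDataset.from_frame(df)
        assert ds2.n_dropped == 1 and ds2.n_rows == 5


FIXTURE_6x2 = np.array(
    [[10.0, 11.0], [12.0, 12.5], [8.0, 9.5], [15.0, 14.0], [11.0, 11.5], [9.0, 8.5]]
)


class TestIcc:
    def test_perfect_agreement(self):
        X = np.column_stack([FIXTURE_6x2[:, 0], FIXTURE_6x2[:, 0]])
        res = icc_2_1(X)
        assert res.icc == pytest.approx(1.0)
        assert res.rating == "excellent"

    def test_fixture_matches_direct_summation_oracle(self):
        res = icc_2_1(FIXTURE_6x2)
        assert res.icc == pytest.approx(icc21_oracle(FIXTURE_6x2), abs=1e-9)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(50, 8, size=(12, 1)) + rng.normal(0, 2, size=(12, 2))
        res = icc_2_1(X)
        df = pd.DataFrame({
            "t": np.repeat(np.arange(12), 2), "r": np.tile([0, 1], 12), "y": X.ravel()
        })
        tab = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
        row = tab[tab["Type"] == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(tab["Type"]) \
            else tab[tab["Type"] == "ICC2"].iloc[0]
        assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        ci = row[tab.columns[-1]]
        assert res.ci_low == pytest.approx(float(ci[0]), abs=5e-3)
        assert res.ci_high == pytest.approx(float(ci[1]), abs=5e-3)

    @pytest.mark.parametrize("icc,expected", [
        (0.3, "poor"), (0.5, "moderate"), (0.74, "moderate"), (0.75, "good"),
        (0.77, "good"), (0.90, "good"), (0.92, "excellent"),
    ])
    def test_rating_bands(self, icc, expected):
        assert rate_icc(icc) == expected

    def test_invariant_to_affine_rescaling(self):
        base = icc_2_1(FIXTURE_6x2).icc
        shifted = icc_2_1(FIXTURE_6x2 + 100.0).icc
        scaled = icc_2_1(FIXTURE_6x2 * 3.5).icc
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_degenerate_constant_matrix_flagged(self):
        res = icc_2_1(np.full((6, 2), 3.0))
        assert res.undefined and math.isnan(res.icc)

    def test_ci_brackets_estimate(self, rng):
        for _ in range(10):
            X = rng.normal(0, 5, size=(10, 1)) + rng.normal(0, 2, size=(10, 2))
            res = icc_2_1(X)
            assert res.ci_low <= res.icc <= res.ci_high


class TestSem:
    def test_zero_when_retest_equals_test(self):
        X = np.column_stack([FIXTURE_6x2[:, 0], FIXTURE_6x2[:, 0]])
        assert sem_from_anova(X).sem == pytest.approx(0.0, abs=1e-12)

    def test_fixture_matches_sqrt_mse_oracle(self):
        _, _, mse = anova_oracle(FIXTURE_6x2)
        assert sem_from_anova(FIXTURE_6x2).sem == pytest.approx(math.sqrt(mse), abs=1e-9)

    def test_scales_linearly(self):
        s1 = sem_from_anova(FIXTURE_6x2).sem
        s2 = sem_from_anova(FIXTURE_6x2 * 4.0).sem
        assert s2 == pytest.approx(4.0 * s1, rel=1e-9)

    def test_recovers_known_error_sd(self, rng):
        true = rng.normal(0, 15, size=(500, 1))
        X = true + rng.normal(0, 2.0, size=(500, 2))
        assert 1.8 <= sem_from_anova(X).sem <= 2.2

    def test_variance_component_recovery(self, rng):
        """n=1000: ICC -> sr^2/(sr^2+se^2), SEm -> se within 5% relative."""
        sr, se = 8.0, 3.0
        X = rng.normal(0, sr, size=(1000, 1)) + rng.normal(0, se, size=(1000, 2))
        target = sr**2 / (sr**2 + se**2)
        assert icc_2_1(X).icc == pytest.approx(target, rel=0.05)
        assert sem_from_anova(X).sem == pytest.approx(se, rel=0.05)


FRIEDMAN_4x3 = np.array(
    [[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0], [1.0, 2.0, 3.0]]
)


class TestFriedman:
    def test_identical_conditions_null(self):
        res = friedman_test(np.tile([[4.0]], (5, 3)))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_fixture_matches_hand_ranked_oracle(self):
        res = friedman_test(FRIEDMAN_4x3)
        assert res.chi2 == pytest.approx(friedman_oracle(FRIEDMAN_4x3), abs=1e-9)
        assert res.df == 2

    def test_df_for_four_conditions(self, rng):
        res = friedman_test(rng.normal(size=(8, 4)))
        assert res.df == 3

    def test_invariant_to_monotone_transform(self, rng):
        X = rng.normal(size=(10, 4))
        a = friedman_test(X)
        b = friedman_test(np.exp(X))
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-9)

    def test_two_conditions_rejected(self, rng):
        with pytest.raises(TooFewConditionsError):
            friedman_test(rng.normal(size=(5, 2)))

    def test_matches_scipy(self, rng):
        scipy_stats = pytest.importorskip("scipy.stats")
        X = rng.normal(size=(12, 4))
        res = friedman_test(X)
        ref = scipy_stats.friedmanchisquare(*X.T)
        assert res.chi2 == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)


class TestMannWhitney:
    def test_identical_samples_null(self):
        x = np.arange(8, dtype=float)
        res = mann_whitney(x, x)
        assert res.z == 0.0 and res.p == 1.0

    def test_complete_separation_gives_zero_u(self):
        x = np.arange(10, dtype=float)
        y = x + 100.0
        assert mann_whitney(x, y).u == 0.0

    def test_u_matches_counting_oracle(self, rng):
        x = rng.integers(0, 20, size=15).astype(float)
        y = rng.integers(0, 20, size=12).astype(float)
        assert mann_whitney(x, y).u == pytest.approx(mw_u_oracle(x, y), abs=1e-12)

    def test_u_plus_u_prime_is_nm(self, rng):
        x, y = rng.normal(size=14), rng.normal(size=9)
        assert mann_whitney(x, y).u + mann_whitney(y, x).u == pytest.approx(14 * 9)

    def test_matches_scipy_asymptotic(self, rng):
        scipy_stats = pytest.importorskip("scipy.stats")
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=15)
        res = mann_whitney(x, y)
        ref = scipy_stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
        assert res.u == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_fmt(2 * x, x).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_fmt(-x, x).r == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert pearson_fmt(x, y).r == pytest.approx(pearson_oracle(x, y), abs=1e-9)

    def test_recovers_injected_correlation(self, rng):
        n, rho = 70, 0.6
        x = rng.normal(size=n)
        y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=n)
        res = pearson_fmt(y, x)
        assert res.r == pytest.approx(rho, abs=0.2)
        assert res.n == n

    def test_zero_variance_flagged(self):
        res = pearson_fmt(np.full(5, 2.0), np.arange(5, dtype=float))
        assert res.undefined


class TestVariation:
    @pytest.mark.parametrize("lean,obese,abs_d,rel_d", [
        (8.3, 13.2, 4.9, 159),   # ASIS via freehand ultrasound, Euclidean
        (8.9, 15.5, 6.6, 174),   # hip joint center via freehand ultrasound
        (5.0, 5.0, 0.0, 100),
    ])
    def test_group_contrast_arithmetic(self, lean, obese, abs_d, rel_d):
        a, r = variation_from_sds(lean, obese)
        assert a == pytest.approx(abs_d, abs=1e-12)
        assert r == rel_d

    def test_summary_table_structure(self, rng):
        ds_lean = make_dataset(rng, n_legs=10, group="lean")
        ds_obese = make_dataset(rng, n_legs=10, group="obese", noise=3.0)
        ds = TRDataset(pd.concat([ds_lean.data, ds_obese.data],
                                         ignore_index=True))
        tab = variation_summary(ds)
        assert set(tab["axis"]) == {"ant-post", "med-lat", "sup-inf", "Eucl. dist."}
        assert not tab["partial"].any()
        # noisier obese group must show larger SDs here
        assert (tab["obese_sd_mm"] > tab["lean_sd_mm"]).all()
        assert (tab["rel_diff_pct"] > 100).all()

    def test_missing_group_flags_partial(self, rng):
        ds = make_dataset(rng, n_legs=10, group="lean")
        tab = variation_summary(ds)
        assert tab["partial"].all()
        assert tab["abs_diff_mm"].isna().all()


class TestReportBattery:
    def test_report_runs_end_to_end(self, rng):
        frames = []
        for grp, noise in (("lean", 1.0), ("obese", 3.0)):
            frames.append(
                make_dataset(rng, n_legs=12, methods=("MMP", "IPT", "3DFUS"),
                             group=grp, noise=noise).data
            )
        ds = TRDataset(pd.concat(frames, ignore_index=True))
        rep = reliability_report(ds)
        assert {"icc", "sem", "distances", "variation", "friedman", "pearson"} <= set(rep)
        assert len(rep["icc"]) == 3 * 2 * 3  # methods x groups x axes
        assert set(rep["pearson"]) == {"MMP", "IPT", "3DFUS"}

    def test_compare_methods_runs_posthoc_when_significant(self, rng):
        base = rng.normal(10, 1, size=40)
        data = {"A": base, "B": base + 0.1, "C": base + 5.0}
        res = compare_methods(data)
        assert res.friedman.df == 2
        assert res.friedman.p < 0.05
        assert len(res.pairwise) == 3
        assert res.corrected is False
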