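"""Statistics checked against independent textbook-formula oracles.

The oracles here are deliberately written from first principles (hand ranks,
explicit ANOVA sums of squares, the plain 1.96-SD formula, enumeration-free
library routines) so they exercise a different code path from the package.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tumorvol import (
    bland_altman,
    diagnostic_accuracy,
    diameter_volume_analysis,
    ellipsoidity_error_correlation,
    evaluate_method,
    icc_2_1,
    mann_whitney_u,
    spearman_rs,
    subset_evaluate,
    volume_differences,
)
from tumorvol.errors import StatisticsError
from tumorvol.estimators import METHOD_NAMES

# ---------------------------------------------------------------------------
# oracles


def hand_ranks(v):
    """Average ranks computed directly from sorted positions."""
    v = np.asarray(v, dtype=float)
    ranks = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def hand_spearman(x, y):
    rx, ry = hand_ranks(x), hand_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def hand_icc_2_1(x, y):
    """ICC(2,1) from explicit two-way ANOVA sums of squares."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * sum((data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def hand_percentile(v, p):
    """Type-7 (linear interpolation) percentile, written out by hand."""
    v = np.sort(np.asarray(v, dtype=float))
    pos = (len(v) - 1) * p / 100.0
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


# ---------------------------------------------------------------------------
# frozen 10-row fixture

V_PLAN = np.array([5.2, 8.9, 12.4, 15.0, 21.7, 26.6, 33.1, 41.8, 55.3, 72.9])
V_EST = np.array([5.9, 8.1, 13.8, 14.2, 24.0, 27.7, 31.0, 45.5, 52.8, 80.1])


@pytest.fixture()
def fixture_frame():
    frame = pd.DataFrame({"case_id": [f"c{i}" for i in range(10)], "v_plan": V_PLAN})
    frame["v_12abc"] = V_EST
    for m, col in [("1/3ABC", "v_13abc"), ("2/3ABC", "v_23abc"), ("1/3SH", "v_13sh"),
                   ("1/2SH", "v_12sh"), ("2/3SH", "v_23sh")]:
        frame[col] = V_EST * {"1/3ABC": 2 / 3, "2/3ABC": 4 / 3, "1/3SH": 0.9,
                              "1/2SH": 1.35, "2/3SH": 1.8}[m]
    frame["max_diameter"] = (6 * V_PLAN / math.pi) ** (1 / 3)
    frame["ellipsoidity"] = np.linspace(0.5, 0.9, 10)
    return frame


class TestVolumeDifferences:
    @pytest.mark.parametrize(
        "v_est,v_plan,expected",
        [
            (21.0, 20.0, (1.0, 5.0, 1.0, 5.0)),
            (20.0, 20.0, (0.0, 0.0, 0.0, 0.0)),
            (15.0, 20.0, (-5.0, -25.0, 5.0, 25.0)),
        ],
    )
    def test_signs_and_magnitudes(self, v_est, v_plan, expected):
        d = volume_differences(v_est, v_plan)
        assert (d.vd, d.pvd, d.avd, d.apvd) == pytest.approx(expected)

    def test_nonpositive_planimetry_rejected(self):
        with pytest.raises(StatisticsError):
            volume_differences(1.0, 0.0)


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman_rs([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman_rs([1, 2, 3, 4], [-1, -2, -3, -4])[0] == pytest.approx(-1.0)

    def test_hand_rank_difference_formula(self):
        # sum d^2 = 2 -> rs = 1 - 6*2/(4*15) = 0.8
        rs, _, _ = spearman_rs([1, 2, 3, 4], [1, 3, 2, 4])
        assert rs == pytest.approx(0.8)

    def test_matches_hand_oracle_with_ties(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0]
        assert spearman_rs(x, y)[0] == pytest.approx(hand_spearman(x, y), abs=1e-6)

    def test_fisher_ci_formula(self):
        rs, lo, hi = spearman_rs(V_PLAN, V_EST)
        z = math.atanh(hand_spearman(V_PLAN, V_EST))
        half = stats.norm.ppf(0.975) / math.sqrt(10 - 3)
        assert lo == pytest.approx(math.tanh(z - half), abs=1e-6)
        assert hi == pytest.approx(math.tanh(z + half), abs=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(StatisticsError):
            spearman_rs([1, 1, 1, 1], [1, 2, 3, 4])


class TestICC:
    def test_perfect_agreement(self):
        icc, lo, hi = icc_2_1([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert icc == pytest.approx(1.0)

    def test_anova_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 3.0, 4.0, 5.0, 6.0]
        assert icc_2_1(x, y)[0] == pytest.approx(hand_icc_2_1(x, y), abs=1e-9)

    def test_offset_penalised_below_correlation(self):
        x = np.arange(1.0, 11.0)
        icc, _, _ = icc_2_1(x, x + 20.0)
        assert icc < 0.2  # Pearson correlation would be 1

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        x = rng.uniform(5, 60, 25)
        y = x * 1.1 + rng.normal(0, 3, 25)
        icc, lo, hi = icc_2_1(x, y)
        long = pd.DataFrame({
            "targets": np.tile(np.arange(25), 2),
            "raters": np.repeat(["a", "b"], 25),
            "scores": np.concatenate([x, y]),
        })
        ref = pingouin.intraclass_corr(long, "targets", "raters", "scores")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin rounds its CI to 2 decimals
        assert (lo, hi) == pytest.approx(tuple(row["CI95"]), abs=6e-3)


class TestBlandAltman:
    def test_hand_formula(self):
        plan = np.zeros(5)
        est = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mean, lo, hi, n_out, pct = bland_altman(est, plan)
        sd = math.sqrt(sum((d - 3.0) ** 2 for d in est) / 4)
        assert mean == pytest.approx(3.0)
        assert lo == pytest.approx(3.0 - 1.96 * sd, abs=1e-9)
        assert hi == pytest.approx(3.0 + 1.96 * sd, abs=1e-9)
        assert (n_out, pct) == (0, 0.0)
        assert lo == pytest.approx(-0.0990, abs=1e-4)
        assert hi == pytest.approx(6.0990, abs=1e-4)

    def test_extreme_point_inside_wide_limits(self):
        est = np.array([0.0, 0, 0, 0, 10.0])
        mean, lo, hi, n_out, _ = bland_altman(est, np.zeros(5))
        assert mean == pytest.approx(2.0)
        assert hi == pytest.approx(2 + 1.96 * 4.47213595, abs=1e-6)
        assert n_out == 0  # 10 < 10.765

    def test_degenerate_all_zero(self):
        mean, lo, hi, n_out, pct = bland_altman([1.0, 1, 1], [1.0, 1, 1])
        assert (mean, lo, hi, n_out, pct) == (0, 0, 0, 0, 0)


class TestDiagnosticAccuracy:
    def test_counting(self):
        acc = diagnostic_accuracy([5, 15, 25, 35])
        assert acc == {10.0: 25.0, 20.0: 50.0, 30.0: 75.0}

    def test_strict_inequality_at_boundary(self):
        assert diagnostic_accuracy([10.0], thresholds=(10,)) == {10.0: 0.0}

    def test_all_perfect(self):
        acc = diagnostic_accuracy([0.0, 0.0])
        assert all(v == 100.0 for v in acc.values())

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        apvd = rng.exponential(15, 200)
        acc = diagnostic_accuracy(apvd, thresholds=(5, 10, 20, 30, 50))
        vals = list(acc.values())
        assert vals == sorted(vals)


class TestMannWhitney:
    def test_exact_enumeration_separated_groups(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.10)

    def test_identical_samples_p_one(self):
        assert mann_whitney_u([1.0, 2, 3, 4], [1.0, 2, 3, 4]) == 1.0

    def test_symmetry_under_swap(self):
        x = [1.2, 3.4, 2.2, 5.0]
        y = [2.0, 4.4, 6.1]
        assert mann_whitney_u(x, y) == pytest.approx(mann_whitney_u(y, x))

    def test_exact_matches_scipy_without_ties(self):
        x = [1.0, 4.0, 6.0, 9.0, 12.0]
        y = [2.0, 3.0, 7.0, 8.0]
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mann_whitney_u(x, y) == pytest.approx(ref, abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.uniform(0, 30, 40), 1)
        y = np.round(rng.uniform(5, 35, 35), 1)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert mann_whitney_u(x, y) == pytest.approx(ref, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(StatisticsError):
            mann_whitney_u([], [1.0])


class TestEvaluateMethod:
    def test_perfect_method(self, fixture_frame):
        frame = fixture_frame.copy()
        frame["v_12abc"] = frame["v_plan"]
        rep = evaluate_method(frame, "1/2ABC")
        assert rep.rs == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0)
        assert rep.vd.median == rep.vd.p25 == rep.vd.p75 == 0.0
        assert all(v == 100.0 for v in rep.diag_accuracy.values())

    def test_constant_relative_error(self, fixture_frame):
        frame = fixture_frame.copy()
        frame["v_12abc"] = 1.5 * frame["v_plan"]
        rep = evaluate_method(frame, "1/2ABC")
        for q in (rep.pvd.p25, rep.pvd.median, rep.pvd.p75):
            assert q == pytest.approx(50.0)
        assert all(v == 0.0 for v in rep.diag_accuracy.values())

    def test_fixture_matches_hand_computed_table(self, fixture_frame):
        """Every report field equals the spreadsheet-style oracle to 1e-6."""
        rep = evaluate_method(fixture_frame, "1/2ABC")
        vd = V_EST - V_PLAN
        pvd = vd / V_PLAN * 100
        for got_q, vals in [
            (rep.volume, V_EST), (rep.vd, vd), (rep.pvd, pvd),
            (rep.avd, np.abs(vd)), (rep.apvd, np.abs(pvd)),
        ]:
            assert got_q.p25 == pytest.approx(hand_percentile(vals, 25), abs=1e-6)
            assert got_q.median == pytest.approx(hand_percentile(vals, 50), abs=1e-6)
            assert got_q.p75 == pytest.approx(hand_percentile(vals, 75), abs=1e-6)
        assert rep.rs == pytest.approx(hand_spearman(V_EST, V_PLAN), abs=1e-6)
        assert rep.icc == pytest.approx(hand_icc_2_1(V_EST, V_PLAN), abs=1e-6)
        mean, sd = vd.mean(), vd.std(ddof=1)
        assert rep.ba_mean == pytest.approx(mean, abs=1e-6)
        assert rep.ba_lower_loa == pytest.approx(mean - 1.96 * sd, abs=1e-6)
        assert rep.ba_upper_loa == pytest.approx(mean + 1.96 * sd, abs=1e-6)
        assert rep.diag_accuracy[20.0] == pytest.approx(
            100 * np.mean(np.abs(pvd) < 20), abs=1e-6
        )

    def test_order_permutation_invariant(self, fixture_frame):
        shuffled = fixture_frame.sample(frac=1, random_state=9).reset_index(drop=True)
        r1 = evaluate_method(fixture_frame, "2/3SH")
        r2 = evaluate_method(shuffled, "2/3SH")
        assert r1.as_row() == pytest.approx(r2.as_row())

    def test_ratio_structure_propagates_to_vd(self, fixture_frame):
        """v_23abc = 2 * v_13abc per case, so their VDs differ by v_13abc."""
        f = fixture_frame
        vd13 = f["v_13abc"] - f["v_plan"]
        vd23 = f["v_23abc"] - f["v_plan"]
        assert np.allclose(vd23 - vd13, f["v_13abc"], rtol=1e-12)

    def test_too_few_records(self, fixture_frame):
        with pytest.raises(StatisticsError):
            evaluate_method(fixture_frame.head(3), "1/2ABC")


class TestSubsetAndGroupAnalyses:
    def test_subset_strict_filter(self, fixture_frame):
        rep = subset_evaluate(fixture_frame, "2/3SH", v_max=22.0)
        assert rep.subset_size == 5  # volumes 5.2, 8.9, 12.4, 15.0, 21.7
        assert rep.subset_fraction == pytest.approx(0.5)
        assert rep.n == 5

    def test_subset_infinite_equals_full(self, fixture_frame):
        full = evaluate_method(fixture_frame, "2/3SH")
        sub = subset_evaluate(fixture_frame, "2/3SH", v_max=float("inf"))
        assert sub.n == full.n
        assert sub.rs == pytest.approx(full.rs)
        assert sub.icc == pytest.approx(full.icc)

    def test_subset_empty_rejected(self, fixture_frame):
        with pytest.raises(StatisticsError):
            subset_evaluate(fixture_frame, "2/3SH", v_max=1.0)

    def test_diameter_binning(self, fixture_frame):
        frame = fixture_frame.copy()
        frame.loc[:2, "max_diameter"] = [0.5, 1.2, 2.3]
        groups, (rs, _, _) = diameter_volume_analysis(frame)
        counts = dict(zip(groups["diameter_bin_cm"], groups["n"]))
        assert counts["[0,1)"] == 1 and counts["[1,2)"] == 1
        assert -1 <= rs <= 1

    def test_sphere_cohort_diameter_volume_monotone(self):
        diam = np.linspace(1.0, 8.0, 20)
        frame = pd.DataFrame({
            "case_id": [f"s{i}" for i in range(20)],
            "max_diameter": diam,
            "v_plan": math.pi / 6 * diam**3,
        })
        groups, (rs, _, _) = diameter_volume_analysis(frame)
        assert rs == pytest.approx(1.0)
        # for spheres the within-bin spread is bounded by the analytic bin width
        for _, row in groups.iterrows():
            b = int(row["diameter_bin_cm"].strip("[)").split(",")[0])
            assert row["v_plan_range"] <= math.pi / 6 * ((b + 1) ** 3 - b**3) + 1e-9

    def test_ellipsoidity_correlation_range(self, fixture_frame):
        rs, lo, hi = ellipsoidity_error_correlation(fixture_frame, "1/2ABC")
        assert -1 <= lo <= rs <= hi <= 1

    def test_ellipsoidity_correlation_degenerate_apvd(self, fixture_frame):
        frame = fixture_frame.copy()
        frame["v_12abc"] = frame["v_plan"]  # perfect method -> constant zero APVD
        with pytest.raises(StatisticsError):
            ellipsoidity_error_correlation(frame, "1/2ABC")

    def test_ellipsoidity_correlation_constant_shape(self, fixture_frame):
        frame = fixture_frame.copy()
        frame["ellipsoidity"] = 0.8
        with pytest.raises(StatisticsError):
            ellipsoidity_error_correlation(frame, "1/2ABC")
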