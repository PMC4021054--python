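"""Agreement statistics: Spearman + Fisher CI, Bland-Altman, ICC, RMS %CV, power."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from trabmorph import (
    PairedMeasurements,
    bland_altman,
    compute_agreement,
    compute_reliability,
    icc_3_1,
    load_cadaveric_bvtv,
    rms_percent_cv,
    sample_size_for_correlation,
    spearman_ci_fisher,
    spearman_rho,
    subgroup_correlations,
)
from trabmorph.agreement import round_half_up


def anova_icc_oracle(m):
    """From-scratch two-way ANOVA mean squares for the consistency ICC."""
    n, k = m.shape
    grand = m.mean()
    bms = k * sum((row.mean() - grand) ** 2 for row in m) / (n - 1)
    jms = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    total = sum((x - grand) ** 2 for x in m.ravel())
    ems = (total - bms * (n - 1) - jms * (k - 1)) / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestSpearman:
    def test_monotone_orderings(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, [2.0, 3.0, 7.0, 20.0]) == pytest.approx(1.0)
        assert spearman_rho(x, [8.0, 4.0, 2.0, 1.0]) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_including_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=12).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=12).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        assert spearman_rho(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_classic_formula_without_ties(self, rng):
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        d = stats.rankdata(x) - stats.rankdata(y)
        classic = 1 - 6 * (d**2).sum() / (10 * 99)
        assert spearman_rho(x, y) == pytest.approx(classic, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            spearman_rho([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="3"):
            spearman_rho([1, 2], [1, 2])

    @given(st.permutations(list(range(6))))
    def test_invariant_under_monotone_transform(self, perm):
        x = np.arange(6, dtype=float)
        y = np.asarray(perm, dtype=float)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x / 3), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, y**3 + 2) == pytest.approx(base, abs=1e-12)


class TestFisherCI:
    def test_matches_closed_form(self):
        rho, n = 0.9, 5
        lo, hi = spearman_ci_fisher(rho, n)
        half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
        assert lo == pytest.approx(math.tanh(math.atanh(rho) - half))
        assert hi == pytest.approx(math.tanh(math.atanh(rho) + half))

    def test_interval_shrinks_like_sqrt_n_at_zero(self):
        lo1, hi1 = spearman_ci_fisher(0.0, 103)
        lo2, hi2 = spearman_ci_fisher(0.0, 403)
        assert lo1 == pytest.approx(-hi1) and lo2 == pytest.approx(-hi2)
        assert hi2 == pytest.approx(hi1 / 2, rel=0.02)

    def test_nesting_of_confidence_levels(self):
        lo95, hi95 = spearman_ci_fisher(0.6, 20, level=0.95)
        lo99, hi99 = spearman_ci_fisher(0.6, 20, level=0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_bonett_wright_is_wider_for_nonzero_rho(self):
        lo_f, hi_f = spearman_ci_fisher(0.8, 10)
        lo_b, hi_b = spearman_ci_fisher(0.8, 10, method="bonett_wright")
        assert lo_b < lo_f

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            spearman_ci_fisher(1.0, 10)
        with pytest.raises(ValueError):
            spearman_ci_fisher(0.5, 3)


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_constant_offset(self):
        x = np.array([1.0, 4.0, 9.0])
        ba = bland_altman(x, x + 5)
        assert ba.bias == pytest.approx(5.0)
        assert ba.sd_diff == 0.0

    def test_limits_are_bias_pm_196_sd(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        ba = bland_altman(x, y)
        d = y - x
        assert ba.bias == pytest.approx(d.mean())
        assert ba.sd_diff == pytest.approx(d.std(ddof=1))
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd_diff)

    def test_limits_cover_about_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(77)
        x = rng.normal(10, 2, size=4000)
        y = x + rng.normal(1.0, 0.5, size=4000)
        ba = bland_altman(x, y)
        coverage = ((ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high)).mean()
        assert 0.93 < coverage < 0.97

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestICC:
    def test_identical_columns_give_one(self):
        m = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_3_1(m) == pytest.approx(1.0)

    def test_consistency_ignores_fixed_offset(self):
        a = np.arange(6.0)
        assert icc_3_1(np.column_stack([a, a + 10])) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_anova_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(6, 2))
        assert icc_3_1(m) == pytest.approx(anova_icc_oracle(m), abs=1e-12)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        m = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="target", raters="rater", ratings="score")
        # single-measurement consistency ICC: labelled ICC(C,1) / ICC3 depending on version
        icc3 = ref.loc[ref["Type"].isin(["ICC(C,1)", "ICC3"]), "ICC"].item()
        assert icc_3_1(m) == pytest.approx(icc3, abs=1e-9)

    def test_recovers_population_icc_from_simulated_components(self):
        """y_ij = t_i + r_j + e_ij with var_t = 4, var_e = 1: consistency
        ICC = 4 / 5 = 0.8, recovered within Monte-Carlo error at n = 200."""
        rng = np.random.default_rng(3)
        n, k = 200, 3
        m = (
            rng.normal(0, 2, size=(n, 1))
            + np.array([[0.0, 1.0, -0.5]])
            + rng.normal(0, 1, size=(n, k))
        )
        assert icc_3_1(m) == pytest.approx(0.8, abs=0.05)

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            icc_3_1(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc_3_1(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestRMSCV:
    def test_identical_pairs_give_zero(self):
        assert rms_percent_cv([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_single_pair_hand_arithmetic(self):
        # pair (1, 3): sd = |d| / sqrt(2) = sqrt(2), mean = 2, CV = 0.7071
        assert rms_percent_cv([1.0], [3.0]) == pytest.approx(70.7107, abs=1e-3)

    def test_scale_invariance(self, rng):
        a = rng.uniform(1, 10, size=8)
        b = a * rng.uniform(0.8, 1.2, size=8)
        assert rms_percent_cv(7 * a, 7 * b) == pytest.approx(rms_percent_cv(a, b))

    def test_n_divisor_variant_is_smaller(self):
        assert rms_percent_cv([1.0], [3.0], divisor="n") == pytest.approx(50.0)

    def test_rejects_nonpositive_means(self):
        with pytest.raises(ValueError, match="positive"):
            rms_percent_cv([1.0], [-1.0])


class TestSampleSize:
    def test_detecting_08_needs_ten(self):
        assert sample_size_for_correlation(0.80) == 10

    def test_formula_floor_as_rho_approaches_one(self):
        assert sample_size_for_correlation(0.9999) == 4

    def test_independent_closed_form_at_05(self):
        za, zb = stats.norm.ppf(0.975), stats.norm.ppf(0.80)
        expect = math.ceil((za + zb) ** 2 / math.atanh(0.5) ** 2 + 3)
        assert sample_size_for_correlation(0.5) == expect == 30

    def test_rejects_impossible_alternatives(self):
        with pytest.raises(ValueError):
            sample_size_for_correlation(0.5, rho_null=0.6)
        with pytest.raises(ValueError):
            sample_size_for_correlation(1.5)


class TestReportsAndFixture:
    def test_subgroup_skips_small_sides(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "id": [1, 2, 3, 4, 5],
                "side": ["right"] * 3 + ["left"] * 2,
                "microct_bvtv_percent": [10.0, 20.0, 30.0, 5.0, 6.0],
                "mr_bvtv_percent": [1.0, 2.0, 3.0, 0.5, 0.6],
            }
        )
        with pytest.warns(UserWarning, match="left"):
            out = subgroup_correlations(PairedMeasurements(df))
        assert set(out) == {"right"}
        assert out["right"] == pytest.approx(1.0)

    def test_reliability_report_fields(self, rng):
        a = rng.uniform(1, 5, size=10)
        b = a + rng.normal(0, 0.01, size=10)
        rep = compute_reliability(a, b)
        assert rep.icc_3_1 > 0.99
        assert rep.diff_min <= rep.diff_max
        assert rep.rms_percent_cv < 1.0

    def test_round_half_up_matches_printed_convention(self):
        assert round_half_up(0.825) == 0.83
        assert round_half_up(-24.444) == -24.44
        assert round_half_up(0.5, 0) == 1.0

    def test_fixture_bias_matches_direct_arithmetic(self):
        data = load_cadaveric_bvtv()
        ba = bland_altman(data.microct, data.mr)
        assert ba.bias == pytest.approx(-24.443, abs=1e-10)

    def test_agreement_report_serializes(self):
        rep = compute_agreement(load_cadaveric_bvtv())
        d = rep.to_dict()
        assert d["n"] == 10
        assert set(d["by_side"]) == {"left", "right"}
        assert d["bland_altman"]["loa_low"] < d["bland_altman"]["bias"]
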