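import numpy as np
import pandas as pd
import pytest

import lesionvario as lv
from lesionvario.stats import box_summary, normality_report


class TestBoxSummary:
    def test_arithmetic_sequence_quantiles(self):
        """1..99 under linear order-statistic interpolation."""
        s = box_summary(np.arange(1.0, 100.0))
        assert s.median == pytest.approx(50.0)
        assert s.whisker_low == pytest.approx(5.9)
        assert s.whisker_high == pytest.approx(94.1)

    def test_single_value(self):
        s = box_summary([3.5])
        assert (s.median, s.q25, s.q75, s.whisker_low, s.whisker_high) == (
            3.5, 3.5, 3.5, 3.5, 3.5,
        )
        assert s.outliers.size == 0

    def test_extreme_point_flagged_as_outlier(self):
        values = list(np.linspace(0, 1, 50)) + [10.0]
        s = box_summary(values)
        assert 10.0 in s.outliers

    def test_ordering_invariant(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=200)
        s = box_summary(v)
        assert s.whisker_low <= s.q25 <= s.median <= s.q75 <= s.whisker_high

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            box_summary([])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        H, p = lv.kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert H == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_constant_convention(self):
        H, p = lv.kruskal_wallis([5, 5], [5, 5, 5])
        assert (H, p) == (0.0, 1.0)

    def test_separated_groups_significant(self):
        H, p = lv.kruskal_wallis([1, 2, 3, 4], [10, 11, 12, 13], [20, 21, 22, 23])
        assert p < 0.01

    def test_h_ordering_matches_permutation_oracle(self):
        """Small-sample H orders group separations like exhaustive relabelling."""
        from itertools import combinations

        g1, g2 = [1.0, 2.0], [10.0, 11.0]
        H_obs, _ = lv.kruskal_wallis(g1, g2)
        pooled = np.array(g1 + g2)
        n_ge = 0
        perms = list(combinations(range(4), 2))
        for idx in perms:
            a = pooled[list(idx)]
            b = np.delete(pooled, list(idx))
            H, _ = lv.kruskal_wallis(a, b)
            if H >= H_obs - 1e-12:
                n_ge += 1
        # only the observed split and its mirror reach the maximal H
        assert n_ge == 2
        assert n_ge / len(perms) == pytest.approx(1 / 3)


class TestMannWhitney:
    def test_exact_small_sample_enumeration(self):
        """U = 0 for fully separated pairs; p = 2/6 by enumerating orderings."""
        U, p = lv.mann_whitney([1, 2], [3, 4])
        assert U == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        _, p = lv.mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        U12, _ = lv.mann_whitney(g1, g2)
        U21, _ = lv.mann_whitney(g2, g1)
        assert U12 + U21 == pytest.approx(len(g1) * len(g2))

    def test_label_swap_preserves_p(self):
        rng = np.random.default_rng(8)
        g1, g2 = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        _, p12 = lv.mann_whitney(g1, g2)
        _, p21 = lv.mann_whitney(g2, g1)
        assert p12 == pytest.approx(p21)


class TestMarginalDensity:
    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        grid, dens = lv.marginal_density(rng.normal(size=500))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_sample_two_maxima(self):
        """Mixture of two archetype A-levels shows two density modes."""
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(1.8, 0.1, 200), rng.normal(3.1, 0.15, 80)]
        )
        grid, dens = lv.marginal_density(values)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        assert interior.sum() == 2

    def test_symmetric_sample_symmetric_density(self):
        v = np.concatenate([np.linspace(-3, 3, 101)])
        grid, dens = lv.marginal_density(v)
        assert dens[np.argmin(np.abs(grid + 1))] == pytest.approx(
            dens[np.argmin(np.abs(grid - 1))], rel=1e-6
        )

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lv.marginal_density([1.0, 1.0, 1.0])


def _simulate_lmm(
    seed,
    beta=(1.8, -0.25, -0.3, 0.0),
    n_f=7,
    n_m=6,
    sd_int=0.3,
    sd_slope=0.1,
    sd_eps=0.1,
):
    """Longitudinal two-gender design with random intercept+slope."""
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for gender, n in (("F", n_f), ("M", n_m)):
        for _ in range(n):
            sid += 1
            b0 = rng.normal(0, sd_int)
            b1 = rng.normal(0, sd_slope)
            male = 1.0 if gender == "M" else 0.0
            for tp in (1, 2, 3, 4):
                t_c = tp - 2.5
                y = (
                    beta[0]
                    + beta[1] * t_c
                    + beta[2] * male
                    + beta[3] * t_c * male
                    + b0
                    + b1 * t_c
                    + rng.normal(0, sd_eps)
                )
                rows.append(
                    {"subject_id": f"s{sid}", "timepoint": tp, "gender": gender, "A": y}
                )
    return pd.DataFrame(rows)


class TestLongitudinalModel:
    def test_noiseless_recovery(self):
        """With zero noise the fixed effects are recovered exactly."""
        df = _simulate_lmm(0, sd_int=0.0, sd_slope=0.0, sd_eps=0.0)
        res = lv.fit_longitudinal_model(df, response="A")
        fe = res.fixed_effects["estimate"]
        assert fe["intercept"] == pytest.approx(1.8, abs=1e-6)
        assert fe["time"] == pytest.approx(-0.25, abs=1e-6)
        assert fe["gender"] == pytest.approx(-0.3, abs=1e-6)
        assert fe["time:gender"] == pytest.approx(0.0, abs=1e-6)
        assert res.singular  # no subject-level variation to estimate

    def test_gender_offset_sign_convention(self):
        """Male-lower simulations give a negative gender coefficient."""
        df = _simulate_lmm(3)
        res = lv.fit_longitudinal_model(df)
        assert res.gender_offset < 0
        lo, hi = res.gender_offset_ci()
        assert lo < res.gender_offset < hi

    def test_centered_time_midpoint(self):
        """Centring puts t_c = 0 between the 2nd and 3rd timepoints, so the
        intercept estimates the female level there."""
        df = _simulate_lmm(1, sd_int=0.0, sd_slope=0.0, sd_eps=0.0)
        res = lv.fit_longitudinal_model(df)
        female = df[(df.gender == "F")].groupby("timepoint")["A"].mean()
        midpoint = (female[2] + female[3]) / 2
        assert res.fixed_effects.loc["intercept", "estimate"] == pytest.approx(
            midpoint, abs=1e-6
        )

    def test_requires_both_genders(self):
        df = _simulate_lmm(0)
        with pytest.raises(ValueError, match="genders"):
            lv.fit_longitudinal_model(df[df.gender == "F"])

    def test_interaction_near_zero_in_balanced_design(self):
        """When the true interaction is 0, dropping it barely moves the
        gender offset (balanced design orthogonality)."""
        df = _simulate_lmm(11, beta=(1.8, -0.25, -0.3, 0.0))
        full = lv.fit_longitudinal_model(df)
        import statsmodels.formula.api as smf

        d = df.copy()
        d["t_c"] = d["timepoint"] - d["timepoint"].mean()
        d["male"] = (d["gender"] == "M").astype(float)
        reduced = smf.mixedlm(
            "A ~ t_c + male", d, groups=d["subject_id"], re_formula="~t_c"
        ).fit(reml=True)
        assert full.gender_offset == pytest.approx(reduced.fe_params["male"], abs=0.02)


class TestNormalityReport:
    def test_reports_three_diagnostics(self):
        rng = np.random.default_rng(0)
        rep = normality_report(rng.normal(size=80))
        assert list(rep["test"]) == ["shapiro_wilk", "anderson_darling", "lilliefors"]
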