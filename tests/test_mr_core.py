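"""Univariable MR estimators against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrmediate import (MRModel, cochran_q, fixed_effect_meta, i2_from_q,
                       subtype_heterogeneity, wald_ratio)
from mrmediate.mr import InsufficientInstrumentsError, MRResults


def model_from(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    if sx is None:
        sx = np.full_like(bx, 0.01)
    return MRModel.from_arrays(bx, sx, by, sy)


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

class TestWald:
    def test_direct_ratio(self):
        r = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert np.isclose(r.estimate, 0.5) and np.isclose(r.se, 0.1)

    def test_null_numerator(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01).estimate == 0.0

    def test_negative_ratio_scaling(self):
        r = wald_ratio(0.2, 0.01, -0.1, 0.02)
        assert np.isclose(r.estimate, -0.5) and np.isclose(r.se, 0.1)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

class TestIVW:
    def test_collinear_ratios(self):
        m = model_from([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.1] * 3)
        res = m.fit_ivw()
        assert np.isclose(res.estimate, 0.5)
        assert np.isclose(res.Q, 0.0, atol=1e-25)
        assert res.I2 == 0.0

    def test_weighted_least_squares_oracle(self):
        m = model_from([0.1, 0.2, 0.3], [0.06, 0.08, 0.17], [0.1] * 3)
        res = m.fit_ivw(weighting="fixed")
        assert np.isclose(res.estimate, 0.073 / 0.14, atol=1e-12)

    def test_single_snp_equals_wald(self):
        m = model_from([0.1], [0.05], [0.01])
        res = m.fit_ivw()
        w = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert np.isclose(res.estimate, w.estimate)
        assert np.isclose(res.se, w.se)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(0)
        bx = rng.normal(0.1, 0.05, 10)
        by = 0.4 * bx + rng.normal(0, 0.01, 10)
        sy = np.full(10, 0.02)
        flip = rng.random(10) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        a = model_from(bx, by, sy).fit_ivw(weighting="fixed")
        b = model_from(bx * sgn, by * sgn, sy).fit_ivw(weighting="fixed")
        assert np.isclose(a.estimate, b.estimate, atol=1e-14)
        assert np.isclose(a.Q, b.Q, atol=1e-12)

    def test_fixed_ivw_equals_meta_of_wald_ratios(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 15)
        by = rng.normal(0.1 * bx, 0.02)
        sy = rng.uniform(0.01, 0.05, 15)
        ivw = model_from(bx, by, sy).fit_ivw(weighting="fixed")
        pooled = fixed_effect_meta(by / bx, sy / np.abs(bx))
        assert np.isclose(ivw.estimate, pooled.estimate, atol=1e-10)
        assert np.isclose(ivw.se, pooled.se, atol=1e-10)

    def test_mre_se_inflation_bounded_below(self):
        # heterogeneous data: MRE se > fixed se; homogeneous: identical
        m = model_from([0.1, 0.2, 0.3, 0.15], [0.2, 0.02, 0.3, 0.01], [0.02] * 4)
        assert m.fit_ivw(weighting="multiplicative_random_effects").se \
            > m.fit_ivw(weighting="fixed").se
        hom = model_from([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.1] * 3)
        assert np.isclose(
            hom.fit_ivw(weighting="multiplicative_random_effects").se,
            hom.fit_ivw(weighting="fixed").se)


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------

class TestHeterogeneity:
    def test_i2_from_study_scale_q(self):
        # Q = 262 over 195 instruments reproduces the reported 26%
        assert np.isclose(i2_from_q(262.0, 194), 25.954198, atol=1e-4)
        assert round(i2_from_q(262.0, 194)) == 26

    def test_no_heterogeneity(self):
        Q, df, p, i2 = cochran_q([0.1, 0.2], [0.05, 0.10], [0.1, 0.1], 0.5)
        assert np.isclose(Q, 0, atol=1e-30) and i2 == 0.0

    def test_truncation_at_expectation(self):
        assert i2_from_q(5.0, 5) == 0.0

    def test_qpval_chi2(self):
        Q, df, p, _ = cochran_q([0.1, 0.2, 0.3], [0.06, 0.08, 0.17],
                                [0.1] * 3, 0.073 / 0.14)
        assert np.isclose(p, stats.chi2.sf(Q, 2))

    def test_subtype_heterogeneity(self):
        # five subtype estimates engineered to give Q = 5.4 on 4 df
        est = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        base = np.sum(est**2)  # Q at unit weights, mean 0
        se = np.full(5, np.sqrt(base / 5.4))
        results = [MRResults("ivw_fixed", e, s, 10) for e, s in zip(est, se)]
        Q, df, p, i2 = subtype_heterogeneity(results)
        assert np.isclose(Q, 5.4) and df == 4
        assert np.isclose(i2, 100 * 1.4 / 5.4, atol=1e-8)

    def test_subtype_identical_and_extreme(self):
        same = [MRResults("ivw_fixed", 0.5, 0.1, 10) for _ in range(3)]
        assert subtype_heterogeneity(same)[3] == 0.0
        far = [MRResults("ivw_fixed", 0.0, 1e-4, 10),
               MRResults("ivw_fixed", 1.0, 1e-4, 10)]
        assert subtype_heterogeneity(far)[3] > 99.9


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

class TestEgger:
    def test_exact_affine_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.02 + 0.5 * bx
        slope, inter = model_from(bx, by, [0.05] * 4).fit_egger()
        assert np.isclose(slope.estimate, 0.5, atol=1e-12)
        assert np.isclose(inter.estimate, 0.02, atol=1e-12)

    def test_normal_equations_oracle(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.06, 0.08, 0.17])
        sy = np.array([0.1, 0.12, 0.08])
        slope, inter = model_from(bx, by, sy).fit_egger()
        # independent oracle: explicit weighted normal equations
        w = 1 / sy**2
        X = np.column_stack([np.ones(3), bx])
        XtWX = X.T * w @ X
        coef = np.linalg.solve(XtWX, X.T @ (w * by))
        assert np.isclose(inter.estimate, coef[0], atol=1e-10)
        assert np.isclose(slope.estimate, coef[1], atol=1e-10)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            model_from([0.1, 0.2], [0.05, 0.1], [0.1, 0.1]).fit_egger()

    def test_null_pleiotropy_intercept_coverage(self):
        """With zero pleiotropy the intercept should rarely exceed 3 SE."""
        rng = np.random.default_rng(42)
        n_reps, hits = 500, 0
        for _ in range(n_reps):
            bx = rng.uniform(0.05, 0.3, 20)
            sy = np.full(20, 0.02)
            by = rng.normal(0.3 * bx, sy)
            _, inter = model_from(bx, by, sy).fit_egger()
            if abs(inter.estimate) < 3 * inter.se:
                hits += 1
        assert hits / n_reps >= 0.99


# ---------------------------------------------------------------------------
# weighted median / mode
# ---------------------------------------------------------------------------

class TestWeightedMedian:
    def test_degenerate_distribution(self):
        m = model_from([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.1] * 3)
        assert np.isclose(m.fit_weighted_median(n_boot=0).estimate, 0.5)

    def test_robust_to_one_invalid_of_three(self):
        # ratios (0.5, 0.5, 5.0) with equal ratio weights
        bx = np.array([0.2, 0.2, 0.2])
        by = np.array([0.1, 0.1, 1.0])
        m = model_from(bx, by, [0.1] * 3)
        assert np.isclose(m.fit_weighted_median(n_boot=0).estimate, 0.5)

    def test_interpolation_oracle(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = np.array([0.03, 0.09, 0.12])
        sy = np.array([0.02, 0.05, 0.03])
        est = model_from(bx, by, sy).fit_weighted_median(n_boot=0).estimate
        # independent oracle via numpy interp on the cumulative weight curve
        ratios = by / bx
        w = bx**2 / sy**2
        order = np.argsort(ratios)
        r, wn = ratios[order], w[order] / w.sum()
        cum = np.cumsum(wn) - wn / 2
        assert np.isclose(est, np.interp(0.5, cum, r), atol=1e-12)

    def test_seeded_bootstrap_reproducible(self):
        m = model_from([0.1, 0.2, 0.3], [0.06, 0.08, 0.17], [0.1] * 3)
        a = m.fit_weighted_median(n_boot=100, seed=5)
        b = m.fit_weighted_median(n_boot=100, seed=5)
        assert a.se == b.se


class TestWeightedMode:
    def test_plurality_cluster(self):
        bx = np.full(4, 0.2)
        by = np.array([0.1, 0.1, 0.1, 0.6])   # ratios 0.5,0.5,0.5,3.0
        m = model_from(bx, by, [0.1] * 4)
        est = m.fit_weighted_mode(n_boot=0).estimate
        assert abs(est - 0.5) < 0.1

    def test_point_mass_any_bandwidth(self):
        m = model_from([0.1, 0.2, 0.4], [0.07, 0.14, 0.28], [0.1] * 3)
        for phi in (0.5, 1.0, 2.0):
            assert np.isclose(m.fit_weighted_mode(phi=phi, n_boot=0).estimate,
                              0.7, atol=1e-3)

    def test_doubling_bandwidth_keeps_plurality_mode(self):
        bx = np.full(4, 0.2)
        by = np.array([0.1, 0.1, 0.1, 0.6])
        m = model_from(bx, by, [0.1] * 4)
        for phi in (1.0, 2.0):
            assert abs(m.fit_weighted_mode(phi=phi, n_boot=0).estimate - 0.5) < 0.25


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

class TestMeta:
    def test_symmetry(self):
        r = fixed_effect_meta([0.1, 0.3], [0.2, 0.2])
        assert np.isclose(r.estimate, 0.2)
        assert np.isclose(r.se, 0.2 / np.sqrt(2))

    def test_single_estimate_identity(self):
        r = fixed_effect_meta([0.42], [0.1])
        assert np.isclose(r.estimate, 0.42) and np.isclose(r.se, 0.1)

    def test_closed_form(self):
        r = fixed_effect_meta([0.0, 0.4], [0.1, 0.3])
        assert np.isclose(r.estimate, 0.04, atol=1e-10)
        assert np.isclose(r.se, 0.0949, atol=1e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fixed_effect_meta([0.1, 0.2], [0.1])


# ---------------------------------------------------------------------------
# result object + properties
# ---------------------------------------------------------------------------

def test_odds_ratio_only_for_binary_outcomes():
    r = MRResults("ivw_fixed", -0.0726, 0.03, 100, outcome_binary=True)
    assert np.isclose(r.odds_ratio, np.exp(-0.0726))
    assert r.ci_low < r.estimate < r.ci_high
    r2 = MRResults("ivw_fixed", -0.0726, 0.03, 100, outcome_binary=False)
    assert np.isnan(r2.odds_ratio)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_ivw_scale_equivariance(seed):
    """Scaling the outcome betas (and ses) by c scales the IVW estimate by c;
    the weighted median of ratios lies within the ratio range."""
    rng = np.random.default_rng(seed)
    L = rng.integers(3, 12)
    bx = rng.uniform(0.05, 0.4, L)
    by = rng.normal(0.2 * bx, 0.03)
    sy = rng.uniform(0.01, 0.08, L)
    m = model_from(bx, by, sy)
    c = 2.5
    m2 = model_from(bx, c * by, c * sy)
    assert np.isclose(m2.fit_ivw(weighting="fixed").estimate,
                      c * m.fit_ivw(weighting="fixed").estimate, atol=1e-10)
    med = m.fit_weighted_median(n_boot=0).estimate
    ratios = by / bx
    assert ratios.min() - 1e-12 <= med <= ratios.max() + 1e-12
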