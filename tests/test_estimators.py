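"""Estimator unit tests and invariants.

Independent oracles: the Eq.-style closed-form weighted average of ratio
estimates for IVW, statsmodels WLS for both regressions, and term-by-term
summation for Cochran's Q.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mregger import (
    MRDataset,
    cochran_q,
    ivw,
    maf_corrected_strength,
    mean_f_statistic,
    mr_egger,
    orient,
    ratio_estimates,
)


def _dataset_from_seed(seed, n=10, oriented=True):
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.05, 0.6, n)
    return MRDataset.from_arrays(
        beta_exposure=gamma,
        se_exposure=rng.uniform(0.01, 0.08, n),
        beta_outcome=rng.normal(0.4 * gamma, 0.08),
        se_outcome=rng.uniform(0.02, 0.12, n),
        oriented=oriented,
    )


# ---------------------------------------------------------------------------
# ratio estimates
# ---------------------------------------------------------------------------


def test_ratio_estimate_direct_substitution():
    ds = MRDataset.from_arrays([0.5, 0.3], [0.05, 0.05], [1.0, 0.0], [0.2, 0.1])
    r = ratio_estimates(ds)
    assert r[0].estimate == pytest.approx(2.0)
    assert r[0].se == pytest.approx(0.4)
    assert r[0].weight == pytest.approx(0.5**2 / 0.2**2)
    assert r[1].estimate == 0.0  # null numerator


def test_ratio_estimate_zero_denominator_names_variant():
    ds = MRDataset.from_arrays([0.5, 0.0], [0.05, 0.05], [1.0, 0.2], [0.2, 0.1],
                               variant_ids=["rs_ok", "rs_zero"])
    with pytest.raises(ValueError, match="rs_zero"):
        ratio_estimates(ds)


@pytest.mark.parametrize("seed", range(3))
def test_ratio_estimates_match_elementwise_oracle(seed):
    ds = _dataset_from_seed(seed, n=5)
    got = ratio_estimates(ds)
    for v, r in zip(ds, got):
        assert r.estimate == pytest.approx(v.beta_outcome / v.beta_exposure, rel=1e-14)
        assert r.se == pytest.approx(v.se_outcome / abs(v.beta_exposure), rel=1e-14)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


def test_ivw_exact_proportionality():
    ds = MRDataset.from_arrays(
        [0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.10, 0.15], [1.0, 1.0, 1.0]
    )
    est = ivw(ds)
    assert est.slope == pytest.approx(0.5, abs=1e-15)
    assert est.method == "IVW"
    assert est.intercept is None
    assert est.df == 2


@pytest.mark.parametrize("seed", range(5))
def test_ivw_equals_weighted_average_of_ratio_estimates(seed):
    """Closed-form oracle: sum(w_j b_j)/sum(w_j) with w_j = gamma^2/sigma^2."""
    ds = _dataset_from_seed(seed)
    ratios = ratio_estimates(ds)
    w = np.array([r.weight for r in ratios])
    b = np.array([r.estimate for r in ratios])
    expected = np.sum(w * b) / np.sum(w)
    assert abs(ivw(ds).slope - expected) <= 1e-10 * abs(expected)


@pytest.mark.parametrize("seed", range(3))
def test_ivw_matches_statsmodels_wls(seed):
    ds = _dataset_from_seed(seed)
    fit = sm.WLS(
        ds.beta_outcome, ds.beta_exposure[:, None], weights=ds.se_outcome**-2.0
    ).fit()
    est = ivw(ds)
    assert est.slope == pytest.approx(fit.params[0], rel=1e-12)
    assert est.slope_se == pytest.approx(fit.bse[0], rel=1e-12)
    assert est.slope_p == pytest.approx(fit.pvalues[0], rel=1e-10)
    lo, hi = fit.conf_int()[0]
    assert est.slope_ci_lower == pytest.approx(lo, rel=1e-10)
    assert est.slope_ci_upper == pytest.approx(hi, rel=1e-10)


def test_ivw_needs_two_variants():
    ds = MRDataset.from_arrays([0.2], [0.05], [0.1], [0.04])
    with pytest.raises(ValueError):
        ivw(ds)


def test_fixed_se_model_uses_known_variance_and_normal_reference():
    ds = _dataset_from_seed(7)
    est = ivw(ds, se_model="fixed")
    w = ds.se_outcome**-2.0
    assert est.slope_se == pytest.approx(
        np.sqrt(1.0 / np.sum(w * ds.beta_exposure**2)), rel=1e-12
    )
    # point estimate is the same under either convention
    assert est.slope == pytest.approx(ivw(ds).slope, rel=1e-14)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def test_egger_recovers_exact_affine_data(affine_dataset):
    est = mr_egger(affine_dataset)
    assert est.intercept == pytest.approx(0.1, abs=1e-12)
    assert est.slope == pytest.approx(2.0, abs=1e-12)
    assert est.df == 3


def test_egger_constrained_intercept_reproduces_ivw(random_dataset_factory):
    ds = random_dataset_factory(8)
    constrained = mr_egger(ds, constrain_intercept=True)
    reference = ivw(ds)
    assert constrained.slope == reference.slope
    assert constrained.slope_se == reference.slope_se
    assert constrained.intercept == 0.0


@pytest.mark.parametrize("seed", range(3))
def test_egger_matches_statsmodels_wls(seed):
    ds = _dataset_from_seed(seed, n=8)
    design = sm.add_constant(ds.beta_exposure)
    fit = sm.WLS(ds.beta_outcome, design, weights=ds.se_outcome**-2.0).fit()
    est = mr_egger(ds)
    assert est.intercept == pytest.approx(fit.params[0], rel=1e-12)
    assert est.slope == pytest.approx(fit.params[1], rel=1e-12)
    assert est.intercept_se == pytest.approx(fit.bse[0], rel=1e-12)
    assert est.slope_se == pytest.approx(fit.bse[1], rel=1e-12)
    assert est.intercept_p == pytest.approx(fit.pvalues[0], rel=1e-10)
    assert est.slope_p == pytest.approx(fit.pvalues[1], rel=1e-10)


def test_egger_requires_oriented_dataset():
    ds = _dataset_from_seed(0, oriented=False)
    with pytest.raises(ValueError, match="orient"):
        mr_egger(ds)


def test_egger_needs_three_variants():
    ds = MRDataset.from_arrays(
        [0.2, 0.3], [0.05, 0.05], [0.1, 0.2], [0.04, 0.04], oriented=True
    )
    with pytest.raises(ValueError):
        mr_egger(ds)


# ---------------------------------------------------------------------------
# Cochran's Q
# ---------------------------------------------------------------------------


def test_q_is_zero_for_identical_ratio_estimates():
    gamma = np.array([0.1, 0.2, 0.4])
    ds = MRDataset.from_arrays(gamma, [0.02] * 3, 0.7 * gamma, [0.05] * 3)
    het = cochran_q(ds)
    assert het.q_statistic == pytest.approx(0.0, abs=1e-20)
    assert het.p_value == pytest.approx(1.0)
    assert het.df == 2


def test_q_two_variant_hand_formula():
    # equal weights w: Q = w (b1 - b2)^2 / 2
    ds = MRDataset.from_arrays([0.2, 0.2], [0.02] * 2, [0.10, 0.16], [0.05, 0.05])
    w = 0.2**2 / 0.05**2
    b1, b2 = 0.10 / 0.2, 0.16 / 0.2
    assert cochran_q(ds).q_statistic == pytest.approx(w * (b1 - b2) ** 2 / 2, rel=1e-12)


@pytest.mark.parametrize("seed", range(3))
def test_q_matches_term_by_term_summation(seed):
    ds = _dataset_from_seed(seed)
    ratios = ratio_estimates(ds)
    w = np.array([r.weight for r in ratios])
    b = np.array([r.estimate for r in ratios])
    pooled = ivw(ds).slope
    expected = sum(wj * (bj - pooled) ** 2 for wj, bj in zip(w, b))
    assert cochran_q(ds).q_statistic == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# MAF correction and mean F
# ---------------------------------------------------------------------------


def test_maf_correction_values():
    ds = MRDataset.from_arrays(
        [1.0, 0.2], [0.05] * 2, [0.5, 0.1], [0.04] * 2, eaf=[0.5, 0.3]
    )
    got = maf_corrected_strength(ds)
    assert got[0] == pytest.approx(np.sqrt(0.5))
    assert got[1] == pytest.approx(0.2 * np.sqrt(0.42))


def test_maf_correction_vanishes_as_frequency_goes_to_zero():
    ds = MRDataset.from_arrays([1.0], [0.05], [0.5], [0.04], eaf=[1e-8])
    assert maf_corrected_strength(ds)[0] == pytest.approx(0.0, abs=1e-3)


def test_maf_correction_lists_missing_variants():
    ds = MRDataset.from_arrays(
        [1.0, 0.2], [0.05] * 2, [0.5, 0.1], [0.04] * 2,
        variant_ids=["rs_a", "rs_b"],
    )
    with pytest.raises(ValueError, match="rs_a, rs_b"):
        maf_corrected_strength(ds)


def test_mean_f_statistic_examples():
    ds1 = MRDataset.from_arrays([0.3], [0.1], [0.1], [0.04])
    assert mean_f_statistic(ds1) == pytest.approx(9.0)
    ds2 = MRDataset.from_arrays([0.2, 0.4], [0.1, 0.1], [0.1, 0.1], [0.04] * 2)
    assert mean_f_statistic(ds2) == pytest.approx((4.0 + 16.0) / 2.0)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.floats(0.1, 50.0))
def test_scale_equivariance_of_outcome_units(seed, k):
    """Multiplying all outcome associations and SEs by k scales the
    estimates and SEs by k and leaves p-values unchanged."""
    ds = _dataset_from_seed(seed, n=8)
    scaled = MRDataset.from_arrays(
        ds.beta_exposure, ds.se_exposure, k * ds.beta_outcome, k * ds.se_outcome,
        oriented=True,
    )
    for fit in (ivw, mr_egger):
        a, b = fit(ds), fit(scaled)
        assert b.slope == pytest.approx(k * a.slope, rel=1e-9)
        assert b.slope_se == pytest.approx(k * a.slope_se, rel=1e-9)
        assert b.slope_p == pytest.approx(a.slope_p, rel=1e-9)
    ea, eb = mr_egger(ds), mr_egger(scaled)
    assert eb.intercept == pytest.approx(k * ea.intercept, rel=1e-9)
    assert eb.intercept_se == pytest.approx(k * ea.intercept_se, rel=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.floats(0.1, 20.0))
def test_common_weight_rescaling_leaves_everything_unchanged(seed, k):
    """A common factor on all outcome SEs cancels from the weights: point
    estimates are unchanged, and under regression-output inference so are the
    SEs (the residual scale absorbs the factor)."""
    ds = _dataset_from_seed(seed, n=8)
    rescaled = MRDataset.from_arrays(
        ds.beta_exposure, ds.se_exposure, ds.beta_outcome, k * ds.se_outcome,
        oriented=True,
    )
    for fit in (ivw, mr_egger):
        a, b = fit(ds), fit(rescaled)
        assert b.slope == pytest.approx(a.slope, rel=1e-9)
        assert b.slope_se == pytest.approx(a.slope_se, rel=1e-9)
        assert b.slope_p == pytest.approx(a.slope_p, rel=1e-9)


@pytest.mark.parametrize("seed", range(3))
def test_sign_flip_invariance_of_ivw_q_and_mean_f(seed):
    """Flipping any variant's (gamma, Gamma) pair leaves IVW, Q and mean F
    unchanged; MR-Egger after orient() is identical under any input coding."""
    rng = np.random.default_rng(seed)
    ds = _dataset_from_seed(seed, oriented=False)
    flips = np.where(rng.random(len(ds)) < 0.5, -1.0, 1.0)
    flipped = MRDataset.from_arrays(
        flips * ds.beta_exposure,
        ds.se_exposure,
        flips * ds.beta_outcome,
        ds.se_outcome,
    )
    assert ivw(flipped).slope == pytest.approx(ivw(ds).slope, rel=1e-12)
    assert cochran_q(flipped).q_statistic == pytest.approx(
        cochran_q(ds).q_statistic, rel=1e-12
    )
    assert mean_f_statistic(flipped) == pytest.approx(mean_f_statistic(ds), rel=1e-12)
    a, b = mr_egger(orient(ds)), mr_egger(orient(flipped))
    assert b.slope == pytest.approx(a.slope, rel=1e-12)
    assert b.intercept == pytest.approx(a.intercept, rel=1e-12)
    assert b.slope_se == pytest.approx(a.slope_se, rel=1e-12)


def test_exact_affine_fit_has_zero_residual_and_certain_pvalues(affine_dataset):
    est = mr_egger(affine_dataset)
    assert est.slope_se == pytest.approx(0.0, abs=1e-12)
    assert est.slope_p < 1e-30
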