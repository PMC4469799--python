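"""Summary-data Mendelian randomization estimators and diagnostics.

Given per-variant association estimates ``(gamma_hat_j, Gamma_hat_j)`` with
outcome standard errors ``sigma_Yj``, the causal effect of the exposure on the
outcome is estimated by

* the per-variant **ratio (Wald) estimate** ``Gamma_hat_j / gamma_hat_j``;
* the **inverse-variance weighted (IVW) estimate** — the weighted average of
  the ratio estimates with weights ``gamma_hat_j**2 / sigma_Yj**2``,
  equivalently the weighted regression of ``Gamma_hat`` on ``gamma_hat``
  through the origin with weights ``sigma_Yj**-2``;
* **MR-Egger regression** — the same weighted regression with an
  unconstrained intercept.  The intercept estimates the average direct
  (pleiotropic) effect of the variants on the outcome; testing it against
  zero is the MR-Egger test for directional pleiotropy.  Under the InSIDE
  assumption (instrument strength independent of direct effect) the slope is
  a consistent estimate of the causal effect even when every variant is an
  invalid instrument.

Two inference conventions are supported through ``se_model``:

``"regression-output"`` (default)
    Standard errors, p-values and confidence intervals come straight from the
    weighted least-squares fit, including the estimated residual scale, with a
    t reference distribution on the residual degrees of freedom (J-1 for IVW,
    J-2 for MR-Egger).

``"fixed"``
    Fixed-effect meta-analysis convention: the outcome standard errors are
    treated as known, the residual scale is fixed at 1 and inference uses the
    normal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import MRDataset

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "HeterogeneityResult",
    "ratio_estimates",
    "ivw",
    "mr_egger",
    "cochran_q",
    "maf_corrected_strength",
    "mean_f_statistic",
]

SE_MODELS = ("regression-output", "fixed")


@dataclass(frozen=True)
class RatioEstimate:
    """Single-variant causal estimate Gamma_hat_j / gamma_hat_j.

    ``se`` is the first-order delta-method standard error
    ``sigma_Yj / |gamma_hat_j|`` (uncertainty in the gene-exposure association
    is ignored); ``weight`` is the matching inverse-variance weight
    ``gamma_hat_j**2 / sigma_Yj**2``.
    """

    variant_id: str
    estimate: float
    se: float
    weight: float


@dataclass(frozen=True)
class MREstimate:
    """Result of an IVW or MR-Egger fit.

    ``intercept`` and its inference fields are ``None`` for IVW, whose
    intercept is zero by construction.
    """

    method: str  # "IVW" or "MR-Egger"
    slope: float
    slope_se: float
    slope_p: float
    slope_ci_lower: float
    slope_ci_upper: float
    df: int
    n_variants: int
    se_model: str = "regression-output"
    ci_level: float = 0.95
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"residual degrees of freedom must be >= 1, got {self.df}")
        # exact-fit data gives a zero residual scale and a degenerate CI
        if self.slope_se > 0:
            if not (self.slope_ci_lower < self.slope < self.slope_ci_upper):
                raise ValueError("confidence interval does not bracket the estimate")
        elif not (self.slope_ci_lower <= self.slope <= self.slope_ci_upper):
            raise ValueError("confidence interval does not bracket the estimate")


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity test of the per-variant ratio estimates."""

    q_statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.q_statistic < 0:
            raise ValueError("Q statistic must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# weighted least squares on (gamma_hat, Gamma_hat)
# ---------------------------------------------------------------------------


def _check_se_model(se_model: str) -> None:
    if se_model not in SE_MODELS:
        raise ValueError(f"se_model must be one of {SE_MODELS}, got {se_model!r}")


def _reference(se_model: str, df: int):
    """t on the residual df for regression-output inference, normal for fixed."""
    if se_model == "regression-output":
        return stats.t(df)
    return stats.norm()


def _wls_through_origin(x, y, w, se_model: str, ci_level: float):
    """Weighted regression of y on x through the origin.

    Closed form: slope = sum(w x y) / sum(w x^2).  Residual df is J - 1.
    """
    j = len(x)
    sxx = np.sum(w * x * x)
    if sxx <= 0:
        raise ValueError("all exposure associations are zero; slope undefined")
    slope = np.sum(w * x * y) / sxx
    df = j - 1
    rss = np.sum(w * (y - slope * x) ** 2)
    if se_model == "regression-output":
        if df < 1:
            raise ValueError(
                "regression-output standard errors need at least 2 variants"
            )
        scale = rss / df
    else:
        scale = 1.0
    slope_se = float(np.sqrt(scale / sxx))
    ref = _reference(se_model, df)
    p = _two_sided_p(ref, slope, slope_se)
    half = ref.ppf(0.5 + ci_level / 2.0) * slope_se
    return float(slope), slope_se, float(p), float(slope - half), float(slope + half), df


def _two_sided_p(ref, estimate: float, se: float) -> float:
    if se == 0.0:  # exact fit: the null is either impossible or trivially true
        return 0.0 if estimate != 0.0 else 1.0
    return float(2.0 * ref.sf(abs(estimate / se)))


def _wls_with_intercept(x, y, w, se_model: str, ci_level: float):
    """Weighted regression of y on x with a free intercept (2x2 normal equations)."""
    j = len(x)
    sw = np.sum(w)
    swx = np.sum(w * x)
    swx2 = np.sum(w * x * x)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    delta = sw * swx2 - swx**2
    if delta <= 0:
        raise ValueError("exposure associations are constant; slope undefined")
    slope = (sw * swxy - swx * swy) / delta
    intercept = (swx2 * swy - swx * swxy) / delta
    df = j - 2
    rss = np.sum(w * (y - intercept - slope * x) ** 2)
    if se_model == "regression-output":
        if df < 1:
            raise ValueError(
                "regression-output standard errors need at least 3 variants"
            )
        scale = rss / df
    else:
        scale = 1.0
    slope_se = float(np.sqrt(scale * sw / delta))
    intercept_se = float(np.sqrt(scale * swx2 / delta))
    ref = _reference(se_model, df)
    slope_p = _two_sided_p(ref, slope, slope_se)
    intercept_p = _two_sided_p(ref, intercept, intercept_se)
    half = ref.ppf(0.5 + ci_level / 2.0) * slope_se
    return (
        float(slope),
        slope_se,
        float(slope_p),
        float(slope - half),
        float(slope + half),
        df,
        float(intercept),
        intercept_se,
        float(intercept_p),
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def ratio_estimates(dataset: MRDataset) -> list[RatioEstimate]:
    """Per-variant ratio (Wald) estimates with first-order standard errors."""
    zero = [v.variant_id for v in dataset if v.beta_exposure == 0]
    if zero:
        raise ValueError(
            "ratio estimate undefined for variants with zero exposure "
            f"association: {', '.join(zero)}"
        )
    return [
        RatioEstimate(
            variant_id=v.variant_id,
            estimate=v.beta_outcome / v.beta_exposure,
            se=v.se_outcome / abs(v.beta_exposure),
            weight=v.beta_exposure**2 / v.se_outcome**2,
        )
        for v in dataset
    ]


def ivw(
    dataset: MRDataset,
    se_model: str = "regression-output",
    ci_level: float = 0.95,
) -> MREstimate:
    """Inverse-variance weighted causal estimate.

    Computed as the weighted regression of the outcome associations on the
    exposure associations through the origin, weighting by ``se_outcome**-2``;
    the slope equals the inverse-variance weighted average of the per-variant
    ratio estimates.
    """
    _check_se_model(se_model)
    if len(dataset) < 2:
        raise ValueError("IVW needs at least 2 variants for residual inference")
    x = dataset.beta_exposure
    y = dataset.beta_outcome
    w = dataset.se_outcome**-2.0
    slope, se, p, lo, hi, df = _wls_through_origin(x, y, w, se_model, ci_level)
    return MREstimate(
        method="IVW",
        slope=slope,
        slope_se=se,
        slope_p=p,
        slope_ci_lower=lo,
        slope_ci_upper=hi,
        df=df,
        n_variants=len(dataset),
        se_model=se_model,
        ci_level=ci_level,
    )


def mr_egger(
    dataset: MRDataset,
    se_model: str = "regression-output",
    ci_level: float = 0.95,
    constrain_intercept: bool = False,
) -> MREstimate:
    """MR-Egger regression: weighted regression with an unconstrained intercept.

    The dataset must be oriented (all exposure associations non-negative):
    unlike IVW, the MR-Egger fit is not invariant to the allele coding of
    individual variants.  ``intercept_p`` is the MR-Egger test for directional
    pleiotropy.

    With ``constrain_intercept=True`` the intercept is forced to zero, which
    reproduces the IVW estimator exactly (provided for auditing the nesting of
    the two models; the result is still labelled "MR-Egger").
    """
    _check_se_model(se_model)
    if not dataset.oriented:
        raise ValueError(
            "MR-Egger requires an oriented dataset (call orient() first); "
            "its fit depends on the allele coding"
        )
    x = dataset.beta_exposure
    y = dataset.beta_outcome
    w = dataset.se_outcome**-2.0
    if constrain_intercept:
        if len(dataset) < 2:
            raise ValueError("constrained MR-Egger needs at least 2 variants")
        slope, se, p, lo, hi, df = _wls_through_origin(x, y, w, se_model, ci_level)
        return MREstimate(
            method="MR-Egger",
            slope=slope,
            slope_se=se,
            slope_p=p,
            slope_ci_lower=lo,
            slope_ci_upper=hi,
            df=df,
            n_variants=len(dataset),
            se_model=se_model,
            ci_level=ci_level,
            intercept=0.0,
        )
    if len(dataset) < 3:
        raise ValueError("MR-Egger needs at least 3 variants for residual inference")
    slope, se, p, lo, hi, df, b0, b0_se, b0_p = _wls_with_intercept(
        x, y, w, se_model, ci_level
    )
    return MREstimate(
        method="MR-Egger",
        slope=slope,
        slope_se=se,
        slope_p=p,
        slope_ci_lower=lo,
        slope_ci_upper=hi,
        df=df,
        n_variants=len(dataset),
        se_model=se_model,
        ci_level=ci_level,
        intercept=b0,
        intercept_se=b0_se,
        intercept_p=b0_p,
    )


def cochran_q(dataset: MRDataset) -> HeterogeneityResult:
    """Cochran's Q test of heterogeneity among per-variant ratio estimates.

    Q = sum_j w_j (ratio_j - ivw)^2 with the first-order inverse-variance
    weights w_j = gamma_hat_j**2 / sigma_Yj**2, referred to chi-square on
    J - 1 degrees of freedom.  Large Q casts doubt on all variants
    identifying a common causal effect (an over-identification test).
    """
    if len(dataset) < 2:
        raise ValueError("Cochran's Q needs at least 2 variants")
    ratios = ratio_estimates(dataset)
    b = np.array([r.estimate for r in ratios])
    w = np.array([r.weight for r in ratios])
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(dataset) - 1
    p = float(stats.chi2(df).sf(q))
    return HeterogeneityResult(q_statistic=q, df=df, p_value=p)


def maf_corrected_strength(dataset: MRDataset) -> np.ndarray:
    """Allele-frequency corrected instrument strength gamma_hat_j * sqrt(2 p_j (1-p_j)).

    Under Hardy-Weinberg equilibrium ``2 p (1-p)`` is the genotype variance, so
    the corrected association is on a common per-SD-of-genotype scale.  When
    the outcome associations are estimated on common individuals this
    correction is proportional to weighting by ``se_outcome**-2``, which the
    regressions use directly; the corrected values serve as the funnel-plot
    strength axis.
    """
    missing = [v.variant_id for v in dataset if v.eaf is None]
    if missing:
        raise ValueError(
            f"MAF correction requires eaf for every variant; missing for: "
            f"{', '.join(missing)}"
        )
    p = dataset.eaf
    return dataset.beta_exposure * np.sqrt(2.0 * p * (1.0 - p))


def mean_f_statistic(dataset: MRDataset) -> float:
    """Mean per-variant F statistic (gamma_hat_j / se_exposure_j)**2.

    Indicates average instrument strength; values near 10 are conventionally
    regarded as the weak-instrument borderline.
    """
    t = dataset.beta_exposure / dataset.se_exposure
    return float(np.mean(t**2))
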