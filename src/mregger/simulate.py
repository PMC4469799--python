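"""Two-sample generative model for summary-data Mendelian randomization.

Individual-level data are generated under a linear structural model with J
bi-allelic variants, a single unobserved confounder U and unit-normal noise:

    X_i = sum_j gamma_j G_ij + U_i + eps_Xi
    Y_i = sum_j alpha_j G_ij + beta X_i + U_i + eps_Yi

Genotypes G_ij are Binomial(2, p_j) under Hardy-Weinberg equilibrium.  The
``gamma_j`` are the instrument effects on the exposure, the ``alpha_j`` are
direct (pleiotropic) effects on the outcome, and ``beta`` is the causal
effect of interest.  Four pleiotropy scenarios are supported:

(a) no pleiotropy: all alpha_j = 0;
(b) balanced pleiotropy: alpha_j ~ U(-c, c), InSIDE holds;
(c) directional pleiotropy: alpha_j ~ U(0, c), drawn independently of the
    gamma_j, so InSIDE still holds;
(d) directional pleiotropy violating InSIDE: alpha_j ~ U(0, c) and each
    variant additionally influences the confounder with coefficient
    2.5 * alpha_j, correlating instrument strength with the effective direct
    effects.

Two non-overlapping cohorts of N individuals each are simulated; the
gene-exposure associations are estimated in the first, the gene-outcome
associations in the second (the two-sample design, under which
weak-instrument bias acts towards the null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .data import MRDataset

__all__ = [
    "ScenarioSpec",
    "SimulationParams",
    "Effects",
    "CohortData",
    "draw_effects",
    "simulate_cohort",
    "summarize",
    "simulate_summary_dataset",
    "calibrate_strength",
    "expected_mean_f",
    "theoretical_bias",
]

SCENARIO_LABELS = ("a", "b", "c", "d")

#: Ratio of the per-variant confounder effect to the direct effect under
#: scenario (d).
CONFOUNDER_MULTIPLIER_D = 2.5


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four pleiotropy scenarios (a)-(d)."""

    label: str
    confounder_multiplier: float

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise ValueError(f"scenario label must be one of {SCENARIO_LABELS}")
        if self.label != "d" and self.confounder_multiplier != 0.0:
            raise ValueError("confounder path is nonzero only under scenario (d)")

    @classmethod
    def from_label(cls, label: str) -> "ScenarioSpec":
        label = str(label).lower()
        mult = CONFOUNDER_MULTIPLIER_D if label == "d" else 0.0
        return cls(label=label, confounder_multiplier=mult)

    def draw_alpha(self, scale: float, n_variants: int, rng: np.random.Generator):
        """Direct effects alpha_j for this scenario at pleiotropy scale c."""
        if self.label == "a":
            return np.zeros(n_variants)
        if self.label == "b":
            return rng.uniform(-scale, scale, n_variants)
        return rng.uniform(0.0, scale, n_variants)  # (c) and (d)


@dataclass(frozen=True)
class SimulationParams:
    """Full specification of one simulated two-sample MR dataset.

    ``n_per_sample`` is the size of EACH of the two non-overlapping cohorts.
    ``gamma_scale`` multiplies the base instrument-effect law
    ``U(gamma_range)`` and is what :func:`calibrate_strength` adjusts to hit a
    target mean F statistic.  ``pleiotropy_scale`` is the scenario scale c.
    """

    n_per_sample: int
    scenario: ScenarioSpec = field(default_factory=lambda: ScenarioSpec.from_label("a"))
    n_variants: int = 25
    beta: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_range: tuple[float, float] = (0.5, 1.5)
    gamma_scale: float = 1.0
    pleiotropy_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_per_sample < 10:
            raise ValueError("n_per_sample must be >= 10")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("minor allele frequencies must lie in (0, 0.5]")
        if self.gamma_scale < 0:
            raise ValueError("gamma_scale must be non-negative")


@dataclass(frozen=True)
class Effects:
    """Per-dataset draw of variant-level parameters (shared by both cohorts)."""

    gamma: np.ndarray  # instrument effects on the exposure
    alpha: np.ndarray  # direct effects on the outcome
    confounder_path: np.ndarray  # per-variant effect on the confounder U
    maf: np.ndarray  # minor allele frequencies p_j


@dataclass(frozen=True)
class CohortData:
    """Individual-level data for one cohort."""

    genotypes: np.ndarray  # (N, J), entries in {0, 1, 2}
    exposure: np.ndarray
    outcome: np.ndarray
    confounder: np.ndarray
    eps_x: np.ndarray
    eps_y: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        n, j = self.genotypes.shape
        for name in ("exposure", "outcome", "confounder", "eps_x", "eps_y"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} length inconsistent with genotype matrix")
        if self.maf.shape != (j,):
            raise ValueError("maf length inconsistent with genotype matrix")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]


def draw_effects(params: SimulationParams, rng: np.random.Generator) -> Effects:
    """Draw gamma, alpha, the confounder path and the MAFs for one dataset.

    gamma_j are uniform on ``gamma_range`` scaled by ``gamma_scale`` (all
    positive); alpha_j follow the scenario's law at scale ``pleiotropy_scale``,
    drawn independently of gamma; under scenario (d) the confounder path is
    2.5 * alpha_j, otherwise zero.
    """
    j = params.n_variants
    maf = rng.uniform(*params.maf_range, j)
    gamma = params.gamma_scale * rng.uniform(*params.gamma_range, j)
    alpha = params.scenario.draw_alpha(params.pleiotropy_scale, j, rng)
    confounder_path = params.scenario.confounder_multiplier * alpha
    return Effects(gamma=gamma, alpha=alpha, confounder_path=confounder_path, maf=maf)


def simulate_cohort(
    params: SimulationParams, effects: Effects, rng: np.random.Generator
) -> CohortData:
    """Simulate one cohort of ``n_per_sample`` individuals under the model."""
    n, j = params.n_per_sample, params.n_variants
    g = rng.binomial(2, effects.maf, size=(n, j)).astype(float)
    u = g @ effects.confounder_path + rng.standard_normal(n)
    eps_x = rng.standard_normal(n)
    eps_y = rng.standard_normal(n)
    x = g @ effects.gamma + u + eps_x
    y = g @ effects.alpha + params.beta * x + u + eps_y
    return CohortData(
        genotypes=g,
        exposure=x,
        outcome=y,
        confounder=u,
        eps_x=eps_x,
        eps_y=eps_y,
        maf=effects.maf,
    )


def _per_variant_regressions(g: np.ndarray, trait: np.ndarray):
    """Univariate OLS of trait on each genotype column (closed-form sums)."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    sxx = np.einsum("ij,ij->j", gc, gc)
    if np.any(sxx <= 0):
        idx = np.flatnonzero(sxx <= 0)
        raise ValueError(
            f"monomorphic simulated variant(s) at index {idx.tolist()}: "
            "all genotypes equal; increase the sample size or the MAF"
        )
    tc = trait - trait.mean()
    sxy = gc.T @ tc
    syy = tc @ tc
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    return beta, se


def summarize(exposure_cohort: CohortData, outcome_cohort: CohortData) -> MRDataset:
    """Reduce two cohorts to per-variant summary statistics.

    The gene-exposure associations come from simple linear regressions of X on
    each genotype in the exposure cohort; the gene-outcome associations from
    regressions of Y on each genotype in the outcome cohort.  ``eaf`` is set
    to the simulated allele frequency.  The dataset is returned unoriented.
    """
    if exposure_cohort.n_variants != outcome_cohort.n_variants:
        raise ValueError("cohorts disagree on the number of variants")
    bx, sx = _per_variant_regressions(
        exposure_cohort.genotypes, exposure_cohort.exposure
    )
    by, sy = _per_variant_regressions(outcome_cohort.genotypes, outcome_cohort.outcome)
    return MRDataset.from_arrays(
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        eaf=exposure_cohort.maf,
    )


def simulate_summary_dataset(
    params: SimulationParams, seed_seq: np.random.SeedSequence | None = None
) -> tuple[MRDataset, Effects]:
    """Draw effects, simulate both cohorts and summarize, in one call.

    The two cohorts use independent random streams spawned from a single
    parent seed, so identical seeds give bit-identical results.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(params.seed)
    ss_effects, ss_sample1, ss_sample2 = seed_seq.spawn(3)
    effects = draw_effects(params, np.random.default_rng(ss_effects))
    cohort_x = simulate_cohort(params, effects, np.random.default_rng(ss_sample1))
    cohort_y = simulate_cohort(params, effects, np.random.default_rng(ss_sample2))
    return summarize(cohort_x, cohort_y), effects


# ---------------------------------------------------------------------------
# instrument-strength calibration
# ---------------------------------------------------------------------------


def _uniform_moments(lo: float, hi: float) -> tuple[float, float]:
    mean = (lo + hi) / 2.0
    second = (lo * lo + lo * hi + hi * hi) / 3.0
    return mean, second


def expected_mean_f(gamma_scale: float, params: SimulationParams) -> float:
    """Analytic approximation to the expected per-variant F statistic.

    For variant j, F_j ~ 1 + N gamma_j^2 v_j / resid_j with genotype variance
    v_j = 2 p_j (1 - p_j) and residual exposure variance
    resid_j = sum_{k != j} gamma_k^2 v_k + var(U) + var(eps_X); expectations of
    the uniform gamma and MAF laws are plugged in.
    """
    _, e_g2 = _uniform_moments(*params.gamma_range)
    e_p, e_p2 = _uniform_moments(*params.maf_range)
    e_v = 2.0 * (e_p - e_p2)
    h = gamma_scale**2 * e_g2 * e_v  # per-variant explained exposure variance
    resid = (params.n_variants - 1) * h + 2.0  # + var(U)=1 + var(eps_X)=1
    return 1.0 + params.n_per_sample * h / resid


def calibrate_strength(
    target_mean_f: float,
    params: SimulationParams,
    pilot_reps: int = 100,
    pilot_tolerance: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Find the ``gamma_scale`` at which the expected mean F hits the target.

    Root-finding on the analytic approximation of :func:`expected_mean_f`,
    then verified by a pilot simulation (``pilot_reps`` replicate datasets);
    the pilot mean F must land within ``pilot_tolerance`` (relative) of the
    target.  Set ``pilot_reps=0`` to skip verification.  ``target_mean_f=1``
    corresponds to null instruments and returns 0.
    """
    if target_mean_f < 1.0:
        raise ValueError("mean F statistic cannot be below 1 in expectation")
    if target_mean_f == 1.0:
        return 0.0
    # attainability: expected_mean_f is bounded above by 1 + N/(J-1) as scale grows
    if params.n_variants > 1:
        supremum = 1.0 + params.n_per_sample / (params.n_variants - 1)
        if target_mean_f >= supremum:
            raise ValueError(
                f"target mean F {target_mean_f} unattainable: the analytic "
                f"expectation is bounded above by {supremum:.2f} at "
                f"N={params.n_per_sample}, J={params.n_variants}"
            )
    hi = 1.0
    while expected_mean_f(hi, params) < target_mean_f:
        hi *= 2.0
    scale = float(
        brentq(lambda s: expected_mean_f(s, params) - target_mean_f, 0.0, hi)
    )
    if pilot_reps > 0:
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        from dataclasses import replace

        from .estimators import mean_f_statistic

        pilot_params = replace(params, gamma_scale=scale)
        fs = []
        for _ in range(pilot_reps):
            seed_seq = np.random.SeedSequence(int(rng.integers(2**31)))
            dataset, _ = simulate_summary_dataset(pilot_params, seed_seq)
            fs.append(mean_f_statistic(dataset))
        pilot = float(np.mean(fs))
        if abs(pilot - target_mean_f) > pilot_tolerance * target_mean_f:
            raise RuntimeError(
                f"pilot mean F {pilot:.2f} misses target {target_mean_f:.2f} "
                f"by more than {100 * pilot_tolerance:.0f}%"
            )
    return scale


def theoretical_bias(
    gamma: np.ndarray, alpha: np.ndarray, weights: np.ndarray
) -> float:
    """Asymptotic IVW bias for known effects.

    Bias(alpha, gamma) = sum_j gamma_j w_j alpha_j / sum_j gamma_j^2 w_j —
    the amount by which the IVW estimand exceeds the causal effect beta when
    the direct effects alpha are nonzero.
    """
    gamma = np.asarray(gamma, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (gamma.shape == alpha.shape == weights.shape):
        raise ValueError("gamma, alpha and weights must share one length")
    denom = np.sum(gamma**2 * weights)
    if denom == 0:
        raise ValueError("all instrument effects are zero; bias undefined")
    return float(np.sum(gamma * weights * alpha) / denom)
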