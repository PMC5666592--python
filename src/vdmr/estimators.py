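"""Causal-effect estimators for two-sample summary-data Mendelian randomisation.

All estimators consume a :class:`~vdmr.summary_io.HarmonizedInstrument`
holding per-variant exposure effects γ̂_j (nmol/L of 25(OH)D per allele,
oriented positive) with SEs σ_xj, and outcome log odds ratios Γ̂_j with SEs
σ_yj. The causal parameter θ is a log-OR per nmol/L; reports rescale it to a
conventional increment (25 nmol/L ≈ 1 SD of circulating 25(OH)D).

Methods
-------
wald_ratio
    Per-variant ratio Γ̂_j/γ̂_j, first-order delta-method SE σ_yj/|γ̂_j|.
ivw
    Fixed-effect inverse-variance weighted average of the Wald ratios;
    algebraically, weighted least squares of Γ̂ on γ̂ through the origin.
likelihood_estimate
    Maximum likelihood under the bivariate measurement-error model
    γ̂_j ~ N(γ_j, σ_xj²), Γ̂_j ~ N(θγ_j, σ_yj²); unlike IVW it honours the
    uncertainty in the SNP-exposure estimates.
mr_egger
    Weighted regression with a free intercept; the intercept estimates the
    average directional (horizontal) pleiotropy, the slope is a
    pleiotropy-adjusted causal effect.
weighted_median
    Median of the Wald ratios on the inverse-variance weight scale;
    consistent when valid instruments carry at least half the weight.
score_subset_estimate
    IVW restricted to the vitamin D synthesis (CYP2R1, DHCR7/NADSYN1) or
    metabolism (GC, CYP24A1) allele score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm, t as t_dist

from .summary_io import HarmonizedInstrument, HarmonizedRecord

__all__ = [
    "MREstimate",
    "EggerResult",
    "EstimationError",
    "wald_ratio",
    "ivw",
    "likelihood_estimate",
    "mr_egger",
    "weighted_median",
    "score_subset_estimate",
    "rescale_estimate",
    "SYNTHESIS_SCORE",
    "METABOLISM_SCORE",
]

#: Vitamin D synthesis-pathway allele score (CYP2R1, DHCR7/NADSYN1).
SYNTHESIS_SCORE = ("rs10741657", "rs12785878")
#: Vitamin D metabolism-pathway allele score (GC, CYP24A1).
METABOLISM_SCORE = ("rs2282679", "rs6013897")

_Z975 = norm.ppf(0.975)


class EstimationError(RuntimeError):
    """An estimator could not produce a valid result."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its uncertainty.

    ``beta`` is a log-OR per 1 exposure unit; ``scale`` records how many
    exposure units one *reported* increment spans, so the reported odds
    ratio is ``exp(beta * scale)``. ``direction`` is +1 for "per increase"
    and -1 after rescaling to "per decrease".
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    scale: float = 1.0
    exposure_unit: str = "nmol/L"

    def __post_init__(self) -> None:
        if not self.ci_low < self.ci_high:
            raise EstimationError(
                f"{self.method}: ci_low must be below ci_high "
                f"({self.ci_low} >= {self.ci_high})"
            )
        if not self.scale != 0:
            raise EstimationError("scale must be non-zero")

    @property
    def odds_ratio(self) -> float:
        """OR per ``scale`` exposure units."""
        return float(np.exp(self.beta * self.scale))

    @property
    def or_ci(self) -> tuple[float, float]:
        lo = np.exp(self.ci_low * self.scale)
        hi = np.exp(self.ci_high * self.scale)
        return (float(min(lo, hi)), float(max(lo, hi)))


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the pleiotropy-intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def _wald_estimate(method: str, beta: float, se: float, n: int) -> MREstimate:
    if not np.isfinite(beta) or not (np.isfinite(se) and se > 0):
        raise EstimationError(f"{method}: non-finite estimate (beta={beta}, se={se})")
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z975 * se),
        ci_high=float(beta + _Z975 * se),
        pvalue=float(2.0 * norm.sf(abs(beta) / se)),
        n_variants=n,
    )


# ---------------------------------------------------------------------------
# Wald ratio and IVW
# ---------------------------------------------------------------------------

def wald_ratio(pair: HarmonizedRecord) -> MREstimate:
    """Per-variant causal estimate Γ̂/γ̂ with delta-method SE σ_y/|γ̂|.

    The first-order SE ignores the exposure-side uncertainty, matching the
    weighting convention of the IVW estimator; the likelihood estimator is
    the route that accounts for σ_x.
    """
    if pair.exposure_beta == 0:
        raise EstimationError(f"{pair.rsid}: exposure beta is 0; ratio undefined")
    beta = pair.outcome_beta / pair.exposure_beta
    se = pair.outcome_se / abs(pair.exposure_beta)
    return _wald_estimate("wald", beta, se, 1)


def ivw(instrument: HarmonizedInstrument) -> MREstimate:
    """Fixed-effect inverse-variance weighted estimate.

    θ̂ = Σ γ̂_j Γ̂_j / σ_yj² ÷ Σ γ̂_j² / σ_yj², with SE (Σ γ̂_j²/σ_yj²)^(-1/2):
    weighted least squares of the outcome effects on the exposure effects
    through the origin, no residual-variance inflation.
    """
    if len(instrument) < 1:
        raise EstimationError("IVW requires at least one variant")
    g, sy, G = instrument.gamma, instrument.outcome_se, instrument.outcome_beta
    w = sy ** -2.0
    denom = np.sum(w * g * g)
    beta = np.sum(w * g * G) / denom
    se = denom ** -0.5
    return _wald_estimate("ivw", beta, se, len(instrument))


# ---------------------------------------------------------------------------
# Bivariate likelihood
# ---------------------------------------------------------------------------

def _profile_m2ll(theta: float, g, G, sx, sy) -> float:
    """-2 log-likelihood profiled over the per-variant true effects γ_j."""
    gam = (g / sx ** 2 + theta * G / sy ** 2) / (1.0 / sx ** 2 + theta ** 2 / sy ** 2)
    return float(np.sum((g - gam) ** 2 / sx ** 2 + (G - theta * gam) ** 2 / sy ** 2))


def likelihood_estimate(
    instrument: HarmonizedInstrument,
    exposure_ses: Sequence[float] | None = None,
    ci_method: str = "wald",
    xtol: float = 1e-12,
    maxiter: int = 500,
) -> MREstimate:
    """Maximum-likelihood causal estimate under the bivariate normal model.

    The model is γ̂_j ~ N(γ_j, σ_xj²) and Γ̂_j ~ N(θ·γ_j, σ_yj²) with the two
    samples independent. For fixed θ each nuisance γ_j has the closed-form
    profile value (γ̂_j/σ_xj² + θΓ̂_j/σ_yj²)/(1/σ_xj² + θ²/σ_yj²); θ̂ maximises
    the resulting profile likelihood (Brent's method started at the IVW
    estimate). The SE comes from the numerical curvature of the profile
    log-likelihood; ``ci_method="profile"`` instead inverts the likelihood
    ratio at the 95% chi-square(1) cutoff.

    As all σ_x → 0 ("no measurement error"), θ̂ converges to the IVW
    estimate.
    """
    if len(instrument) < 1:
        raise EstimationError("likelihood estimator requires at least one variant")
    if ci_method not in ("wald", "profile"):
        raise ValueError(f"ci_method must be 'wald' or 'profile', got {ci_method!r}")
    g = instrument.gamma
    G = instrument.outcome_beta
    sy = instrument.outcome_se
    sx = np.asarray(
        exposure_ses if exposure_ses is not None else instrument.gamma_se, dtype=float
    )
    if sx.shape != g.shape or np.any(sx <= 0):
        raise EstimationError("exposure SEs must be positive, one per variant")

    start = ivw(instrument).beta
    span = 10.0 * (abs(start) + ivw(instrument).se) + 1e-3
    result = minimize_scalar(
        _profile_m2ll,
        args=(g, G, sx, sy),
        bracket=(start - span, start, start + span),
        method="brent",
        options={"xtol": xtol, "maxiter": maxiter},
    )
    if not result.success or not np.isfinite(result.x):
        raise EstimationError(
            f"profile-likelihood optimisation failed after {maxiter} iterations: "
            f"{getattr(result, 'message', '')}"
        )
    theta = float(result.x)

    # curvature of the profile log-likelihood l = -m2ll/2
    h = 1e-5 * (1.0 + abs(theta))
    second = (
        _profile_m2ll(theta + h, g, G, sx, sy)
        - 2.0 * _profile_m2ll(theta, g, G, sx, sy)
        + _profile_m2ll(theta - h, g, G, sx, sy)
    ) / (2.0 * h * h)  # d²(m2ll/2)/dθ² = -l''
    if not second > 0:
        raise EstimationError("profile likelihood is not locally concave at the MLE")
    se = second ** -0.5

    est = _wald_estimate("likelihood", theta, se, len(instrument))
    if ci_method == "profile":
        cutoff = _profile_m2ll(theta, g, G, sx, sy) + 3.841458820694124  # chi2(1) 95%
        def deficit(x: float) -> float:
            return _profile_m2ll(x, g, G, sx, sy) - cutoff
        lo_bracket, hi_bracket = theta - 20 * se, theta + 20 * se
        while deficit(lo_bracket) < 0:
            lo_bracket -= 20 * se
        while deficit(hi_bracket) < 0:
            hi_bracket += 20 * se
        ci_low = brentq(deficit, lo_bracket, theta)
        ci_high = brentq(deficit, theta, hi_bracket)
        est = replace(est, ci_low=float(ci_low), ci_high=float(ci_high))
    return est


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(
    instrument: HarmonizedInstrument, intercept_dist: str = "normal"
) -> EggerResult:
    """Weighted regression of Γ̂_j on γ̂_j with a free intercept.

    Weights are σ_yj⁻²; the exposure-increasing orientation required for the
    intercept to be identifiable is guaranteed by harmonization. Parameter
    SEs use multiplicative residual overdispersion floored at 1 (the usual
    convention: under-dispersion never tightens the fixed-effect SEs). The
    intercept test is normal by default, or Student-t with J-2 df
    (``intercept_dist="t"``); with four variants the two differ noticeably.
    """
    J = len(instrument)
    if J < 3:
        raise EstimationError(f"MR-Egger needs >= 3 variants, got {J}")
    if intercept_dist not in ("normal", "t"):
        raise ValueError(f"intercept_dist must be 'normal' or 't', got {intercept_dist!r}")
    g = instrument.gamma
    if np.ptp(g) == 0:
        raise EstimationError("no spread in exposure effects; Egger slope unidentifiable")
    G = instrument.outcome_beta
    w = instrument.outcome_se ** -2.0
    fit = sm.WLS(G, sm.add_constant(g), weights=w).fit()
    sigma2 = float(fit.mse_resid)  # weighted residual variance (df = J-2)
    inflation = max(1.0, sigma2)
    base_cov = fit.cov_params() / sigma2  # fixed-effect covariance
    se_int, se_slope = np.sqrt(np.diag(base_cov * inflation))
    intercept, slope = fit.params

    slope_est = _wald_estimate("egger_slope", slope, se_slope, J)
    z = abs(intercept) / se_int
    if intercept_dist == "t":
        p_int = float(2.0 * t_dist.sf(z, J - 2))
    else:
        p_int = float(2.0 * norm.sf(z))
    return EggerResult(
        slope=slope_est,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_pvalue=p_int,
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median_value(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50%-crossing of the cumulative weight with linear interpolation.

    Breakpoints sit at (cumulative weight) - (half the variant's own
    weight), so with equal weights and odd J this is the plain median.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    breaks = np.cumsum(w) - 0.5 * w
    if 0.5 <= breaks[0]:
        return float(r[0])
    if 0.5 >= breaks[-1]:
        return float(r[-1])
    return float(np.interp(0.5, breaks, r))


def weighted_median(
    instrument: HarmonizedInstrument,
    bootstrap_reps: int = 2000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Ratios are weighted by the inverse variance of each Wald ratio. The SE
    resamples (γ̂_j, Γ̂_j) from normals at their stated SEs ``bootstrap_reps``
    times; a seed is required for reproducibility.
    """
    J = len(instrument)
    if J < 3:
        raise EstimationError(f"weighted median needs >= 3 variants, got {J}")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    if bootstrap_reps < 100:
        warnings.warn(
            f"bootstrap_reps={bootstrap_reps} is very small; SE will be noisy",
            stacklevel=2,
        )
    g, sx = instrument.gamma, instrument.gamma_se
    G, sy = instrument.outcome_beta, instrument.outcome_se
    ratios = G / g
    if not np.all(np.isfinite(ratios)):
        raise EstimationError("non-finite Wald ratio in weighted median input")
    weights = (sy / np.abs(g)) ** -2.0
    beta = _weighted_median_value(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        gb = rng.normal(g, sx)
        Gb = rng.normal(G, sy)
        rb = Gb / gb
        wb = (sy / np.abs(gb)) ** -2.0
        boot[b] = _weighted_median_value(rb, wb)
    se = float(np.std(boot, ddof=1))
    if se == 0:
        # degenerate spread (e.g. all ratios identical and SEs tiny)
        se = np.finfo(float).tiny ** 0.5
    est = _wald_estimate("weighted_median", beta, se, J)
    return est


# ---------------------------------------------------------------------------
# Allele-score subsets and rescaling
# ---------------------------------------------------------------------------

def score_subset_estimate(
    instrument: HarmonizedInstrument, subset: str
) -> MREstimate:
    """IVW restricted to a named pathway allele score.

    ``subset`` is ``"synthesis"`` (rs10741657 + rs12785878) or
    ``"metabolism"`` (rs2282679 + rs6013897). A missing member is an error
    naming the absent rsids.
    """
    scores = {"synthesis": SYNTHESIS_SCORE, "metabolism": METABOLISM_SCORE}
    if subset not in scores:
        raise ValueError(f"subset must be one of {sorted(scores)}, got {subset!r}")
    members = scores[subset]
    missing = [r for r in members if r not in instrument.rsids]
    if missing:
        raise EstimationError(
            f"{subset} score members absent from instrument: {missing}"
        )
    est = ivw(instrument.subset(members))
    return replace(est, method=f"score_{subset}")


def rescale_estimate(
    est: MREstimate, target_increment: float, direction: str = "increase"
) -> MREstimate:
    """Re-express an estimate per ``target_increment`` exposure units.

    The reported OR becomes exp(±increment·beta), with the sign negated for
    ``direction="decrease"`` (and the CI bounds swapped so the lower stays
    below the upper). ``est`` must be on the per-1-unit scale.
    """
    if not target_increment > 0:
        raise ValueError(f"target_increment must be > 0, got {target_increment}")
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    if est.scale != 1.0:
        raise ValueError("rescale_estimate expects a per-1-unit estimate (scale == 1)")
    if direction == "decrease":
        return replace(
            est,
            beta=-est.beta,
            ci_low=-est.ci_high,
            ci_high=-est.ci_low,
            scale=target_increment,
        )
    return replace(est, scale=target_increment)
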