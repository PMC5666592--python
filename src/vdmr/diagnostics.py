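"""Instrument-validity diagnostics: heterogeneity, over-identification,
and cross-method consistency.

With several genetic instruments the causal model is over-identified: every
variant should imply the same causal effect. Cochran's Q on the
variant-specific Wald ratios against the IVW pooled value measures how far
that holds; the same statistic doubles as the regression goodness-of-fit
test and as the over-identification test (a Sargan-type test is equivalent
up to parameterization in the fixed-effect summary-data setting), so a
single implementation serves both report labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .estimators import MREstimate, ivw
from .summary_io import HarmonizedInstrument

__all__ = [
    "DiagnosticResult",
    "cochran_q",
    "over_identification",
    "consistency_report",
]


@dataclass(frozen=True)
class DiagnosticResult:
    """Outcome of a heterogeneity or pleiotropy test."""

    statistic_name: str
    statistic: float
    df: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if self.statistic < 0:
            raise ValueError(f"statistic must be >= 0, got {self.statistic}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must lie in (0, 1], got {self.pvalue}")


def cochran_q(
    instrument: HarmonizedInstrument,
    pooled: MREstimate | None = None,
    label: str = "cochran_q",
) -> DiagnosticResult:
    """Cochran's Q over the per-variant Wald ratios.

    Q = Σ w_j (θ_j − θ_pooled)² with w_j = γ̂_j²/σ_yj² (the IVW weights) and
    θ_j = Γ̂_j/γ̂_j; df = J−1, p from the chi-square upper tail. ``pooled``
    defaults to the IVW estimate on the same instrument and must be an
    IVW-family estimate on the per-unit scale.
    """
    J = len(instrument)
    if J < 2:
        raise ValueError(f"Cochran's Q needs >= 2 variants, got {J}")
    if pooled is None:
        pooled = ivw(instrument)
    elif pooled.scale != 1.0:
        raise ValueError("pooled estimate must be on the per-1-unit scale")
    g, sy, G = instrument.gamma, instrument.outcome_se, instrument.outcome_beta
    ratios = G / g
    w = (g / sy) ** 2.0
    q = float(np.sum(w * (ratios - pooled.beta) ** 2))
    df = J - 1
    return DiagnosticResult(
        statistic_name=label,
        statistic=q,
        df=df,
        pvalue=float(chi2.sf(q, df)),
    )


def over_identification(instrument: HarmonizedInstrument) -> DiagnosticResult:
    """Test that all instruments imply the same causal effect.

    Realized as Cochran's Q on the variant-specific ratios (df = J−1);
    shares the single Q implementation with :func:`cochran_q` under its own
    report label.
    """
    return cochran_q(instrument, label="overid")


def consistency_report(estimates: list[MREstimate]) -> pd.DataFrame:
    """Side-by-side comparison of estimates on the same instrument/outcome.

    Returns one row per method with OR, CI and P at 2-decimal report
    rounding, the absolute OR difference from the first method, and a flag
    for any pair differing by more than 0.01 on the rounded OR scale. Mixed
    scale descriptors are an error: comparing a per-1-unit OR with a
    per-25-unit OR is meaningless.
    """
    if len(estimates) < 1:
        raise ValueError("consistency_report needs at least one estimate")
    scales = {(e.scale, e.exposure_unit) for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"estimates are on mixed scales: {sorted(scales)}")
    rows = []
    reference_or = round(estimates[0].odds_ratio, 2)
    for est in estimates:
        or_rounded = round(est.odds_ratio, 2)
        lo, hi = est.or_ci
        rows.append({
            "method": est.method,
            "or": or_rounded,
            "ci_low": round(lo, 2),
            "ci_high": round(hi, 2),
            "pvalue": round(est.pvalue, 2),
            "abs_or_diff": round(abs(or_rounded - reference_or), 2),
            "flagged": abs(or_rounded - reference_or) > 0.01 + 1e-12,
        })
    return pd.DataFrame(rows)
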