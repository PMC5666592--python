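"""Power and minimum-detectable-OR calculation for binary-outcome
Mendelian randomisation.

For a case-control design with N subjects, case fraction K, and a genetic
instrument explaining a fraction R² of the exposure variance, the two-sided
Wald test of the causal log odds ratio (per 1 SD of exposure) has
approximate power

    power = Φ( √(N·R²·K·(1−K)) · |ln OR| − z_{1−α/2} )

— the non-centrality of the IV estimator in the logistic model. Inverting
at a target power gives the minimum detectable OR symmetrically on the log
scale, so the protective and risk-direction bounds are exact reciprocals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PowerSpec",
    "PowerResult",
    "mr_power",
    "minimum_detectable_or",
    "table1_report",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a binary-outcome MR power calculation."""

    n_cases: int
    n_controls: int
    r2: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError(f"r2 must lie in (0, 1), got {self.r2}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 < self.target_power < 1.0):
            raise ValueError(f"target_power must lie in (0, 1), got {self.target_power}")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


@dataclass(frozen=True)
class PowerResult:
    """Minimum detectable ORs per 1 SD exposure increase (reciprocal pair)."""

    min_or_protective: float
    min_or_risk: float
    power_at: dict[float, float] = field(default_factory=dict)


def _noncentrality_scale(spec: PowerSpec) -> float:
    k = spec.case_fraction
    return float(np.sqrt(spec.n_total * spec.r2 * k * (1.0 - k)))


def mr_power(spec: PowerSpec, or_alt: float) -> float:
    """Power to detect a causal OR of ``or_alt`` per 1 SD exposure increase."""
    if not or_alt > 0:
        raise ValueError(f"or_alt must be > 0, got {or_alt}")
    z_alpha = norm.isf(spec.alpha / 2.0)
    return float(norm.cdf(_noncentrality_scale(spec) * abs(np.log(or_alt)) - z_alpha))


def minimum_detectable_or(spec: PowerSpec, rounding: int | None = None) -> PowerResult:
    """Smallest effect detectable at the spec's power and size.

    |ln OR| = (z_{1−α/2} + z_power) / √(N·R²·K(1−K)); the protective and
    risk bounds exp(∓|ln OR|) are reciprocals before any display rounding.
    """
    z_alpha = norm.isf(spec.alpha / 2.0)
    z_power = norm.ppf(spec.target_power)
    log_or = (z_alpha + z_power) / _noncentrality_scale(spec)
    protective, risk = float(np.exp(-log_or)), float(np.exp(log_or))
    if rounding is not None:
        protective, risk = round(protective, rounding), round(risk, rounding)
    return PowerResult(min_or_protective=protective, min_or_risk=risk)


def table1_report(
    rows: list[dict],
    r2_values: tuple[float, ...] = (0.03, 0.05),
    alpha: float = 0.05,
    target_power: float = 0.80,
    rounding: int = 2,
) -> pd.DataFrame:
    """Batch minimum-detectable-OR report in the "low/high" display format.

    ``rows`` are dicts with keys ``cancer``, ``study``, ``n_cases``,
    ``n_controls``; one output column per requested R² value.
    """
    if not rows:
        raise ValueError("table1_report needs at least one row")
    out = []
    for row in rows:
        rec = {
            "cancer": row.get("cancer", ""),
            "study": row.get("study", ""),
            "n_cases": int(row["n_cases"]),
            "n_controls": int(row["n_controls"]),
        }
        for r2 in r2_values:
            spec = PowerSpec(
                n_cases=rec["n_cases"], n_controls=rec["n_controls"],
                r2=r2, alpha=alpha, target_power=target_power,
            )
            res = minimum_detectable_or(spec, rounding=rounding)
            rec[f"min_or_r2_{r2:g}"] = (
                f"{res.min_or_protective:.{rounding}f}/{res.min_or_risk:.{rounding}f}"
            )
        out.append(rec)
    return pd.DataFrame(out)
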