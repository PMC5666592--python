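"""End-to-end analysis workflow: harmonize, estimate, diagnose, report.

One run takes a single SNP-exposure table and any number of labelled
SNP-outcome tables (one per cancer / subtype / consortium), and produces per
outcome: the harmonization log, causal estimates from the requested methods
rescaled to a conventional exposure increment (default 25 nmol/L of
25(OH)D), heterogeneity and pleiotropy diagnostics, allele-score subset
estimates, a display table in "OR (95% CI); P" form, and per-variant scatter
data (exposure vs outcome effects with 95% CIs plus the fitted slope).

Display rounding is 2 decimals; machine-readable outputs keep full
precision alongside. Re-running with the same config and seed yields
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import DiagnosticResult, cochran_q, over_identification
from .estimators import (
    EggerResult,
    EstimationError,
    MREstimate,
    ivw,
    likelihood_estimate,
    mr_egger,
    rescale_estimate,
    score_subset_estimate,
    weighted_median,
)
from .summary_io import (
    HarmonizedInstrument,
    SummaryStatsError,
    harmonize,
    read_associations,
)

__all__ = [
    "AnalysisConfig",
    "OutcomeResult",
    "AnalysisReport",
    "ScatterData",
    "run_analysis",
    "export_scatter_data",
    "format_estimate",
]

logger = logging.getLogger("vdmr")

_Z975 = 1.959963984540054  # norm.ppf(0.975), frozen for byte-stable output

VALID_METHODS = ("ivw", "likelihood", "egger", "weighted_median", "score_subsets")


@dataclass(frozen=True)
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    exposure_path: str | Path
    outcome_paths: dict[str, str | Path]
    scale_increment: float = 25.0
    methods: tuple[str, ...] = VALID_METHODS
    bootstrap_reps: int = 2000
    seed: int | None = None
    output_dir: str | Path | None = None
    rounding: int = 2

    def __post_init__(self) -> None:
        if not self.outcome_paths:
            raise ValueError("at least one outcome table is required")
        unknown = set(self.methods) - set(VALID_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if not self.scale_increment > 0:
            raise ValueError("scale_increment must be > 0")
        if "weighted_median" in self.methods and self.seed is None:
            raise ValueError("a seed is required when weighted_median is requested")


@dataclass
class ScatterData:
    """Per-variant figure data plus the fitted IVW slope."""

    points: pd.DataFrame
    slope: MREstimate


@dataclass
class OutcomeResult:
    label: str
    instrument: HarmonizedInstrument
    estimates: dict[str, MREstimate]
    egger: EggerResult | None
    diagnostics: list[DiagnosticResult]
    table: pd.DataFrame
    scatter: ScatterData


@dataclass
class AnalysisReport:
    outcomes: dict[str, OutcomeResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def format_estimate(est: MREstimate, rounding: int = 2) -> str:
    """Display form "OR (CI_low to CI_high); P" at report rounding."""
    lo, hi = est.or_ci
    return (
        f"{est.odds_ratio:.{rounding}f} "
        f"({lo:.{rounding}f} to {hi:.{rounding}f}); "
        f"{est.pvalue:.{rounding}f}"
    )


def export_scatter_data(instrument: HarmonizedInstrument) -> ScatterData:
    """Figure data: per-variant effect pairs with 95% CIs and the IVW slope."""
    slope = ivw(instrument)
    points = pd.DataFrame({
        "rsid": instrument.rsids,
        "exposure_beta": instrument.gamma,
        "exposure_ci_half": _Z975 * instrument.gamma_se,
        "outcome_beta": instrument.outcome_beta,
        "outcome_ci_half": _Z975 * instrument.outcome_se,
        "slope": slope.beta,
        "slope_ci_low": slope.ci_low,
        "slope_ci_high": slope.ci_high,
    })
    return ScatterData(points=points, slope=slope)


def _estimate_outcome(
    instrument: HarmonizedInstrument, config: AnalysisConfig
) -> tuple[dict[str, MREstimate], EggerResult | None]:
    estimates: dict[str, MREstimate] = {}
    egger_result: EggerResult | None = None
    inc = config.scale_increment
    if "ivw" in config.methods:
        estimates["ivw"] = rescale_estimate(ivw(instrument), inc)
    if "likelihood" in config.methods:
        estimates["likelihood"] = rescale_estimate(likelihood_estimate(instrument), inc)
    if "egger" in config.methods:
        try:
            egger_result = mr_egger(instrument)
            estimates["egger_slope"] = rescale_estimate(egger_result.slope, inc)
        except EstimationError as exc:
            logger.warning("MR-Egger skipped: %s", exc)
    if "weighted_median" in config.methods:
        try:
            estimates["weighted_median"] = rescale_estimate(
                weighted_median(
                    instrument, bootstrap_reps=config.bootstrap_reps, seed=config.seed
                ),
                inc,
            )
        except EstimationError as exc:
            logger.warning("weighted median skipped: %s", exc)
    if "score_subsets" in config.methods:
        for name in ("synthesis", "metabolism"):
            try:
                estimates[f"score_{name}"] = rescale_estimate(
                    score_subset_estimate(instrument, name), inc
                )
            except EstimationError as exc:
                logger.warning("%s score skipped: %s", name, exc)
    return estimates, egger_result


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the full workflow; outcomes that fail harmonization are skipped.

    Raises ``SummaryStatsError`` only when every outcome fails.
    """
    exposure = read_associations(config.exposure_path, role="exposure")
    report = AnalysisReport(provenance=_provenance(config))

    for label, path in config.outcome_paths.items():
        try:
            outcome = read_associations(path, role="outcome")
            instrument = harmonize(exposure, outcome)
        except SummaryStatsError as exc:
            logger.error("outcome %s failed harmonization: %s", label, exc)
            report.failures[label] = str(exc)
            continue
        estimates, egger_result = _estimate_outcome(instrument, config)
        diagnostics = [cochran_q(instrument), over_identification(instrument)]
        if egger_result is not None:
            diagnostics.append(DiagnosticResult(
                statistic_name="egger_intercept",
                statistic=(egger_result.intercept / egger_result.intercept_se) ** 2,
                df=1,
                pvalue=egger_result.intercept_pvalue,
            ))
        table = pd.DataFrame([
            {
                "outcome": label,
                "method": est.method,
                "n_variants": est.n_variants,
                "or": est.odds_ratio,
                "or_ci_low": est.or_ci[0],
                "or_ci_high": est.or_ci[1],
                "pvalue": est.pvalue,
                "display": format_estimate(est, config.rounding),
            }
            for est in estimates.values()
        ])
        report.outcomes[label] = OutcomeResult(
            label=label,
            instrument=instrument,
            estimates=estimates,
            egger=egger_result,
            diagnostics=diagnostics,
            table=table,
            scatter=export_scatter_data(instrument),
        )

    if not report.outcomes:
        raise SummaryStatsError(
            f"all outcomes failed harmonization: {report.failures}"
        )
    if config.output_dir is not None:
        _write_report(report, config)
    return report


def _provenance(config: AnalysisConfig) -> dict:
    blob = json.dumps(
        {
            "exposure_path": str(config.exposure_path),
            "outcome_paths": {k: str(v) for k, v in config.outcome_paths.items()},
            "scale_increment": config.scale_increment,
            "methods": list(config.methods),
            "bootstrap_reps": config.bootstrap_reps,
            "seed": config.seed,
            "rounding": config.rounding,
        },
        sort_keys=True,
    )
    return {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "vdmr_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }


def _write_report(report: AnalysisReport, config: AnalysisConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# vdmr analysis report"]
    lines += [f"# {k}: {v}" for k, v in report.provenance.items()]
    for label, res in report.outcomes.items():
        safe = label.replace("/", "_").replace(" ", "_")
        res.table.to_csv(out / f"{safe}_estimates.tsv", sep="\t", index=False)
        res.scatter.points.to_csv(out / f"{safe}_scatter.tsv", sep="\t", index=False)
        pd.DataFrame(res.instrument.orientation_log).to_csv(
            out / f"{safe}_harmonization_log.tsv", sep="\t", index=False
        )
        lines.append(f"\n## {label} ({len(res.instrument)} variants)")
        for est in res.estimates.values():
            lines.append(
                f"{est.method}: {format_estimate(est, config.rounding)} "
                f"per {config.scale_increment:g} {est.exposure_unit} increase"
            )
        for diag in res.diagnostics:
            lines.append(
                f"{diag.statistic_name}: statistic={diag.statistic:.3f} "
                f"df={diag.df} p={diag.pvalue:.3f}"
            )
    for label, msg in report.failures.items():
        lines.append(f"\n## {label}: FAILED — {msg}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
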