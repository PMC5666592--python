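"""Synthetic two-sample GWAS summary statistics for the vitamin D instrument.

The estimators assume exactly this generative model, so simulating at the
summary-statistic level (normal noise around true per-variant effects) is
both faithful and desk-scale:

    γ̂_j ~ Normal(γ_j, σ_xj²)                 SNP-exposure estimate
    α_j  = 0 | Normal(0, sd²) | Normal(m, sd²)   horizontal pleiotropy
    Γ̂_j ~ Normal(θ·γ_j + α_j, σ_yj²)         SNP-outcome estimate

Defaults mirror the published four-variant 25(OH)D instrument: true γ of
(4.67, 1.72, 2.11, 0.98) nmol/L per allele in exposure-increasing
orientation, exposure SEs reconstructed from the printed genome-wide
p-values, and a constant per-allele outcome log-OR SE of 0.018 — typical of
case-control GWAS with a few tens of thousands of subjects, and giving a
pooled IVW CI width on the per-25-nmol/L scale comparable to the published
cancer analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .summary_io import (
    HarmonizedInstrument,
    VariantAssociation,
    harmonize,
    read_associations,
    se_from_pvalue,
)

__all__ = [
    "SimulationConfig",
    "SimulatedReplicate",
    "simulate_summary_pair",
    "make_fixture_instrument",
    "published_exposure_associations",
    "INSTRUMENT_RSIDS",
    "INSTRUMENT_GAMMA",
    "INSTRUMENT_PVALUES",
    "DEFAULT_OUTCOME_SE",
]

#: The four 25(OH)D variants (GC, CYP2R1, DHCR7/NADSYN1, CYP24A1).
INSTRUMENT_RSIDS = ("rs2282679", "rs10741657", "rs12785878", "rs6013897")
#: True per-allele exposure effects, nmol/L, exposure-increasing orientation.
INSTRUMENT_GAMMA = (4.67, 1.72, 2.11, 0.98)
#: Published two-sided association p-values (the 3.4e-302 is a printed bound).
INSTRUMENT_PVALUES = (3.4e-302, 6.5e-81, 6.4e-129, 3.4e-17)
#: Default per-allele outcome log-OR SE (shared across variants).
DEFAULT_OUTCOME_SE = 0.018

#: Exposure SEs implied by the printed betas and p-values.
INSTRUMENT_GAMMA_SE = tuple(
    se_from_pvalue(b, p) for b, p in zip(INSTRUMENT_GAMMA, INSTRUMENT_PVALUES)
)

# Allele codings used for generated tables. Alleles are synthetic but
# non-palindromic by default so harmonization is exact without frequencies.
_DEFAULT_ALLELES = (("G", "A"), ("G", "A"), ("G", "T"), ("A", "C"))
_DEFAULT_EAF = (0.28, 0.40, 0.32, 0.21)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one batch of simulated summary-statistic pairs.

    ``theta`` is the causal log-OR per nmol/L of 25(OH)D. Pleiotropy modes:
    ``"none"`` (α_j = 0), ``"balanced"`` (mean 0), ``"directional"``
    (mean ``pleiotropy_mean``). ``allele_flip_fraction`` codes that share of
    outcome rows on the other allele (betas negated) to exercise
    harmonization; all flips are recovered exactly by :func:`harmonize`.
    """

    theta: float
    seed: int
    gammas: tuple[float, ...] = INSTRUMENT_GAMMA
    exposure_ses: tuple[float, ...] = INSTRUMENT_GAMMA_SE
    outcome_ses: tuple[float, ...] = (DEFAULT_OUTCOME_SE,) * 4
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_replicates: int = 1
    allele_flip_fraction: float = 0.0
    rsids: tuple[str, ...] = INSTRUMENT_RSIDS

    def __post_init__(self) -> None:
        J = len(self.gammas)
        if not (len(self.exposure_ses) == len(self.outcome_ses) == len(self.rsids) == J):
            raise ValueError("gammas, exposure_ses, outcome_ses, rsids must share length")
        if any(s < 0 for s in self.exposure_ses + self.outcome_ses):
            raise ValueError("standard errors must be >= 0")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "none" and (
            self.pleiotropy_mean != 0.0 or self.pleiotropy_sd != 0.0
        ):
            raise ValueError("pleiotropy_mode='none' forces mean = sd = 0")
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0.0:
            raise ValueError("balanced pleiotropy forces mean = 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 <= self.allele_flip_fraction <= 1.0):
            raise ValueError("allele_flip_fraction must lie in [0, 1]")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")


@dataclass(frozen=True)
class SimulatedReplicate:
    """One simulated exposure/outcome table pair plus the generating truth."""

    exposure: list[VariantAssociation]
    outcome: list[VariantAssociation]
    theta: float
    alphas: tuple[float, ...]


def _alleles_for(config: SimulationConfig) -> tuple[tuple[str, str], ...]:
    J = len(config.rsids)
    base = list(_DEFAULT_ALLELES)
    while len(base) < J:
        base.append(("G", "A"))
    return tuple(base[:J])


def simulate_summary_pair(config: SimulationConfig) -> list[SimulatedReplicate]:
    """Draw ``config.n_replicates`` exposure/outcome summary-table pairs.

    Output tables conform to the summary-statistics schema with consistent
    allele codings and are byte-identical across runs with the same config.
    Zero SEs are allowed as a degenerate testing device (noise-free limit).
    """
    rng = np.random.default_rng(config.seed)
    g = np.asarray(config.gammas, dtype=float)
    sx = np.asarray(config.exposure_ses, dtype=float)
    sy = np.asarray(config.outcome_ses, dtype=float)
    J = g.size
    alleles = _alleles_for(config)
    eafs = (_DEFAULT_EAF * ((J // len(_DEFAULT_EAF)) + 1))[:J]

    replicates: list[SimulatedReplicate] = []
    for _ in range(config.n_replicates):
        gamma_hat = rng.normal(g, sx)
        if config.pleiotropy_mode == "none":
            alphas = np.zeros(J)
        else:
            alphas = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=J)
        outcome_mean = config.theta * g + alphas
        outcome_hat = rng.normal(outcome_mean, sy)
        flip = rng.random(J) < config.allele_flip_fraction

        exposure, outcome = [], []
        for j in range(J):
            ea, oa = alleles[j]
            exposure.append(VariantAssociation(
                rsid=config.rsids[j], effect_allele=ea, other_allele=oa,
                eaf=eafs[j], beta=float(gamma_hat[j]),
                se=float(sx[j]) if sx[j] > 0 else 1e-12,
            ))
            if flip[j]:
                out_ea, out_oa, out_beta, out_eaf = oa, ea, -outcome_hat[j], 1 - eafs[j]
            else:
                out_ea, out_oa, out_beta, out_eaf = ea, oa, outcome_hat[j], eafs[j]
            outcome.append(VariantAssociation(
                rsid=config.rsids[j], effect_allele=out_ea, other_allele=out_oa,
                eaf=out_eaf, beta=float(out_beta),
                se=float(sy[j]) if sy[j] > 0 else 1e-12,
            ))
        replicates.append(SimulatedReplicate(
            exposure=exposure, outcome=outcome,
            theta=config.theta, alphas=tuple(float(a) for a in alphas),
        ))
    return replicates


def published_exposure_associations() -> list[VariantAssociation]:
    """The published four-variant 25(OH)D instrument, from the shipped table.

    Betas are negative as printed (the coded allele lowers 25(OH)D);
    harmonization reorients them.
    """
    fixture = resources.files("vdmr") / "data" / "vitamin_d_instrument.tsv"
    with resources.as_file(fixture) as path:
        return read_associations(Path(path), role="exposure")


def make_fixture_instrument(
    outcome: list[VariantAssociation] | None = None,
) -> HarmonizedInstrument:
    """Harmonized instrument built on the published exposure table.

    Exposure betas come out positive (4.67, 1.72, 2.11, 0.98) with SEs
    derived from the printed p-values. ``outcome`` defaults to a synthetic
    null outcome (log-OR 0 at SE ``DEFAULT_OUTCOME_SE`` per variant) so the
    exposure side can be exercised without real cancer data; pass a real or
    simulated outcome table to analyse it.
    """
    exposure = published_exposure_associations()
    if outcome is None:
        outcome = [
            VariantAssociation(
                rsid=r.rsid, effect_allele=r.effect_allele,
                other_allele=r.other_allele, beta=0.0, se=DEFAULT_OUTCOME_SE,
            )
            for r in exposure
        ]
    return harmonize(exposure, outcome)
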