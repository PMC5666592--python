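"""Summary-statistic data model, tab-delimited I/O, and allele harmonization.

Two-sample Mendelian randomisation works on per-variant association
estimates taken from published GWAS: a SNP-exposure table (here, effects on
circulating 25-hydroxyvitamin D in nmol/L per allele) and a SNP-outcome
table (log odds ratios for a cancer). Before any estimator can run, the two
tables must be paired on rsID and expressed on a common effect allele, with
the convention that every exposure effect is positive (the
"exposure-increasing" orientation).

The exchange format is UTF-8 tab-delimited text with a named header drawn
from::

    rsid  chr  locus  effect_allele  other_allele  eaf  beta  se  pvalue
    n_cases  n_controls

Columns beyond this schema are ignored; either ``se`` or ``pvalue`` may be
omitted (but not both), since published instrument tables often print only a
p-value next to the point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "VariantAssociation",
    "HarmonizedRecord",
    "HarmonizedInstrument",
    "SummaryStatsError",
    "read_associations",
    "write_associations",
    "se_from_pvalue",
    "pvalue_from_estimate",
    "harmonize",
]

#: Columns understood by the reader, in canonical order.
SCHEMA_COLUMNS = (
    "rsid", "chr", "locus", "effect_allele", "other_allele", "eaf",
    "beta", "se", "pvalue", "n_cases", "n_controls",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: |eaf - 0.5| must exceed this on both sides for a palindromic variant to
#: be considered strand-resolvable from allele frequency alone.
PALINDROMIC_EAF_THRESHOLD = 0.08


class SummaryStatsError(ValueError):
    """Malformed or internally inconsistent summary-statistic input."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's estimated per-allele effect on a trait.

    ``beta`` is in exposure units per allele (nmol/L of 25(OH)D) for
    exposure tables and a per-allele log odds ratio for outcome tables.
    Exactly which applies is decided by the caller's ``role``; the record
    itself is role-agnostic.
    """

    rsid: str
    effect_allele: str
    beta: float
    se: float | None = None
    pvalue: float | None = None
    other_allele: str | None = None
    chromosome: str | None = None
    locus: str | None = None
    eaf: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise SummaryStatsError("rsid must be non-empty")
        if self.se is None and self.pvalue is None:
            raise SummaryStatsError(
                f"{self.rsid}: at least one of se / pvalue is required"
            )
        if self.se is not None and not self.se > 0:
            raise SummaryStatsError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise SummaryStatsError(
                f"{self.rsid}: pvalue must lie in (0, 1], got {self.pvalue}"
            )
        if self.other_allele is not None and self.effect_allele == self.other_allele:
            raise SummaryStatsError(
                f"{self.rsid}: effect and other allele are identical"
            )
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise SummaryStatsError(
                f"{self.rsid}: eaf must lie strictly inside (0, 1), got {self.eaf}"
            )
        for name in ("n_cases", "n_controls"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise SummaryStatsError(f"{self.rsid}: {name} must be >= 0")

    @property
    def resolved_se(self) -> float:
        """The stated SE, or one reconstructed from (beta, pvalue)."""
        if self.se is not None:
            return self.se
        return se_from_pvalue(self.beta, self.pvalue)

    def is_palindromic(self) -> bool:
        """True when the allele pair is its own strand complement (A/T, G/C)."""
        if self.other_allele is None:
            return False
        return {self.effect_allele, self.other_allele} in _PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedRecord:
    """Matched exposure/outcome pair on a common, exposure-increasing allele."""

    rsid: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float
    outcome_se: float


@dataclass
class HarmonizedInstrument:
    """The unit of analysis for every estimator.

    Invariants: rsids unique, every ``exposure_beta`` strictly positive,
    every SE strictly positive.
    """

    records: list[HarmonizedRecord]
    orientation_log: list[dict] = field(default_factory=list)
    exposure_unit: str = "nmol/L"

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            raise SummaryStatsError("duplicate rsid in harmonized instrument")
        for r in self.records:
            if not r.exposure_beta > 0:
                raise SummaryStatsError(
                    f"{r.rsid}: exposure beta must be positive after harmonization"
                )
            if not (r.exposure_se > 0 and r.outcome_se > 0):
                raise SummaryStatsError(f"{r.rsid}: standard errors must be > 0")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    # np.asarray views used throughout the estimators
    @property
    def gamma(self) -> np.ndarray:
        """Per-allele exposure effects (all > 0)."""
        return np.array([r.exposure_beta for r in self.records])

    @property
    def gamma_se(self) -> np.ndarray:
        return np.array([r.exposure_se for r in self.records])

    @property
    def outcome_beta(self) -> np.ndarray:
        """Per-allele outcome log odds ratios."""
        return np.array([r.outcome_beta for r in self.records])

    @property
    def outcome_se(self) -> np.ndarray:
        return np.array([r.outcome_se for r in self.records])

    def subset(self, rsids: Sequence[str]) -> "HarmonizedInstrument":
        """Restrict to the given rsids, preserving order; missing ids raise."""
        missing = [r for r in rsids if r not in self.rsids]
        if missing:
            raise SummaryStatsError(f"rsids absent from instrument: {missing}")
        keep = [r for r in self.records if r.rsid in set(rsids)]
        return HarmonizedInstrument(
            records=keep,
            orientation_log=list(self.orientation_log),
            exposure_unit=self.exposure_unit,
        )


# ---------------------------------------------------------------------------
# p-value <-> standard error conversion
# ---------------------------------------------------------------------------

def se_from_pvalue(beta: float, pvalue: float) -> float:
    """Reconstruct a standard error from an estimate and its two-sided p.

    Instrument tables often print only ``beta`` and ``p``; under the normal
    approximation se = |beta| / z with z the upper-tail quantile at p/2.
    ``scipy``'s inverse survival function is accurate down to the smallest
    representable p (~1e-308), which covers genome-wide association p-values
    such as 3.4e-302. Printed bounds ("<3.4e-302") are treated as equalities.
    """
    if beta == 0:
        raise SummaryStatsError("se_from_pvalue undefined for beta = 0")
    if not (0.0 < pvalue <= 1.0):
        raise SummaryStatsError(f"pvalue must lie in (0, 1], got {pvalue}")
    z = norm.isf(pvalue / 2.0)
    if not z > 0:
        raise SummaryStatsError(
            f"pvalue {pvalue} gives non-positive z; cannot derive an SE"
        )
    return abs(beta) / z


def pvalue_from_estimate(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se; inverse of :func:`se_from_pvalue`."""
    if not se > 0:
        raise SummaryStatsError(f"se must be > 0, got {se}")
    return 2.0 * norm.sf(abs(beta) / se)


# ---------------------------------------------------------------------------
# Tab-delimited reader / writer
# ---------------------------------------------------------------------------

_FLOAT_FIELDS = {"eaf", "beta", "se", "pvalue"}
_INT_FIELDS = {"n_cases", "n_controls"}
_COLUMN_TO_ATTR = {
    "rsid": "rsid", "chr": "chromosome", "locus": "locus",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "eaf": "eaf", "beta": "beta", "se": "se", "pvalue": "pvalue",
    "n_cases": "n_cases", "n_controls": "n_controls",
}


def _parse_cell(column: str, raw) -> object | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in {"na", "nan", "."}:
        return None
    # printed bounds like "<3.4e-302" are read at their bound value
    if column == "pvalue" and text.startswith("<"):
        text = text[1:]
    if column in _FLOAT_FIELDS:
        # tolerate the unicode minus that appears in typeset tables
        return float(text.replace("−", "-"))
    if column in _INT_FIELDS:
        return int(float(text))
    return text


def read_associations(path: str | Path, role: str) -> list[VariantAssociation]:
    """Read a tab-delimited summary-statistics table.

    ``role`` ("exposure" or "outcome") documents the beta semantics of the
    table; it does not change parsing, but is validated to catch swapped
    arguments early.
    """
    if role not in ("exposure", "outcome"):
        raise ValueError(f"role must be 'exposure' or 'outcome', got {role!r}")
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    known = [c for c in frame.columns if c in _COLUMN_TO_ATTR]
    if "rsid" not in known or "beta" not in known or "effect_allele" not in known:
        raise SummaryStatsError(
            f"{path}: header must include at least rsid, effect_allele, beta "
            f"(found {list(frame.columns)})"
        )
    records: list[VariantAssociation] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        kwargs = {}
        try:
            for column in known:
                kwargs[_COLUMN_TO_ATTR[column]] = _parse_cell(column, row[column])
            record = VariantAssociation(**kwargs)
        except (ValueError, TypeError) as exc:
            raise SummaryStatsError(f"{path}, line {line_no}: {exc}") from exc
        if record.rsid in seen:
            raise SummaryStatsError(
                f"{path}, line {line_no}: duplicate rsid {record.rsid}"
            )
        seen.add(record.rsid)
        records.append(record)
    return records


def write_associations(
    records: Iterable[VariantAssociation], path: str | Path
) -> None:
    """Write records back to the tab-delimited exchange format."""
    rows = []
    for r in records:
        rows.append({
            "rsid": r.rsid, "chr": r.chromosome, "locus": r.locus,
            "effect_allele": r.effect_allele, "other_allele": r.other_allele,
            "eaf": r.eaf, "beta": r.beta, "se": r.se, "pvalue": r.pvalue,
            "n_cases": r.n_cases, "n_controls": r.n_controls,
        })
    frame = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _log(log: list[dict], rsid: str, action: str, detail: str) -> None:
    log.append({"rsid": rsid, "action": action, "detail": detail})


def _align_outcome(
    exp: VariantAssociation, out: VariantAssociation, log: list[dict]
) -> VariantAssociation | None:
    """Re-express the outcome record on the exposure's effect allele.

    Returns None when the allele pair is irreconcilable or a palindromic
    variant cannot be resolved; the exclusion is logged either way.
    """
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    def flipped(record: VariantAssociation) -> VariantAssociation:
        return replace(
            record,
            effect_allele=e_ea,
            other_allele=e_oa,
            beta=-record.beta,
            eaf=None if record.eaf is None else 1.0 - record.eaf,
        )

    palindromic = exp.is_palindromic() or out.is_palindromic()
    if palindromic:
        # Strand cannot be inferred from the alleles; keep only if both
        # allele frequencies are informative and concordant. Complementing a
        # palindromic pair never yields new alleles, so the two pairs must
        # already agree as sets (when both are complete) to be the same variant.
        if e_oa is not None and o_oa is not None and {o_ea, o_oa} != {e_ea, e_oa}:
            _log(log, exp.rsid, "exclude",
                 f"irreconcilable alleles: exposure {e_ea}/{e_oa} vs outcome {o_ea}/{o_oa}")
            return None
        if o_ea == e_ea:
            aligned = out
        elif o_ea == e_oa:
            aligned = flipped(out)
            _log(log, exp.rsid, "flip", "outcome re-coded onto exposure effect allele")
        else:
            _log(log, exp.rsid, "exclude", "palindromic with non-matching alleles")
            return None
        if exp.eaf is None or aligned.eaf is None:
            _log(log, exp.rsid, "exclude", "palindromic without allele frequencies")
            return None
        informative = (
            abs(exp.eaf - 0.5) > PALINDROMIC_EAF_THRESHOLD
            and abs(aligned.eaf - 0.5) > PALINDROMIC_EAF_THRESHOLD
        )
        concordant = (exp.eaf - 0.5) * (aligned.eaf - 0.5) > 0
        if informative and concordant:
            _log(log, exp.rsid, "keep", "palindromic retained: eaf informative and concordant")
            return aligned
        _log(
            log, exp.rsid, "exclude",
            "palindromic: eaf uninformative or discordant "
            f"(exposure eaf={exp.eaf}, outcome eaf={aligned.eaf})",
        )
        return None

    if e_oa is None or o_oa is None:
        # alignment by effect allele only
        if o_ea == e_ea:
            _log(log, exp.rsid, "keep", "assumed same strand (other allele missing)")
            return out
        if e_oa is not None and o_ea == e_oa:
            _log(log, exp.rsid, "flip", "assumed same strand (other allele missing)")
            return flipped(out)
        _log(log, exp.rsid, "exclude", "effect alleles differ and other allele missing")
        return None

    if (o_ea, o_oa) == (e_ea, e_oa):
        return out
    if (o_ea, o_oa) == (e_oa, e_ea):
        _log(log, exp.rsid, "flip", "outcome coded on the other allele")
        return flipped(out)
    # try the opposite strand
    c_ea = _COMPLEMENT.get(o_ea)
    c_oa = _COMPLEMENT.get(o_oa)
    if (c_ea, c_oa) == (e_ea, e_oa):
        _log(log, exp.rsid, "strand_flip", "outcome alleles on the opposite strand")
        return replace(out, effect_allele=e_ea, other_allele=e_oa)
    if (c_ea, c_oa) == (e_oa, e_ea):
        _log(log, exp.rsid, "strand_flip+flip", "opposite strand, other allele")
        return flipped(out)
    _log(
        log, exp.rsid, "exclude",
        f"irreconcilable alleles: exposure {e_ea}/{e_oa} vs outcome {o_ea}/{o_oa}",
    )
    return None


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
) -> HarmonizedInstrument:
    """Pair exposure and outcome associations on a common allele orientation.

    For each rsid present in both tables the outcome effect is re-expressed
    on the exposure's effect allele (negating the log-OR when the coded
    alleles are swapped), then the whole pair is oriented so the exposure
    effect is positive. Palindromic variants are retained only when allele
    frequencies resolve the strand; irreconcilable variants are dropped with
    a logged reason. An empty result is a fatal error.
    """
    if not exposure or not outcome:
        raise SummaryStatsError("exposure and outcome tables must be non-empty")
    out_by_rsid = {r.rsid: r for r in outcome}
    log: list[dict] = []
    records: list[HarmonizedRecord] = []
    for exp in exposure:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            _log(log, exp.rsid, "exclude", "no matching outcome association")
            continue
        if exp.beta == 0:
            _log(log, exp.rsid, "exclude", "exposure beta is exactly 0 (cannot orient)")
            continue
        aligned = _align_outcome(exp, out, log)
        if aligned is None:
            continue
        exposure_beta, outcome_beta = exp.beta, aligned.beta
        if exposure_beta < 0:
            exposure_beta, outcome_beta = -exposure_beta, -outcome_beta
            _log(log, exp.rsid, "reorient", "negated both betas: exposure-increasing allele")
        records.append(
            HarmonizedRecord(
                rsid=exp.rsid,
                exposure_beta=exposure_beta,
                exposure_se=exp.resolved_se,
                outcome_beta=outcome_beta,
                outcome_se=aligned.resolved_se,
            )
        )
    matched_outcome_only = set(out_by_rsid) - {r.rsid for r in exposure}
    for rsid in sorted(matched_outcome_only):
        _log(log, rsid, "exclude", "no matching exposure association")
    if not records:
        raise SummaryStatsError("harmonization left zero usable variants")
    return HarmonizedInstrument(records=records, orientation_log=log)
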