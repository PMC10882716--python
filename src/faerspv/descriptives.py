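"""Descriptive characterization of a pharmacovigilance cohort.

Produces the standard case-series tables: per-regimen case counts and shares,
the target-SOC share of all adverse-event reports per regimen, and categorical
blocks (sex, age, reporting region/year, reporter occupation, indication
group, outcome codes), each with an explicit Unknown row so counts always sum
to the stratum size.

Percentages are computed against the stratum case count and rounded half-up
to two decimals.  Quantiles default to linear interpolation between order
statistics (configurable), which is what produces fractional IQR bounds such
as 145.4 days from integer day counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortReport, CohortResult

OVERALL = "overall"
UNKNOWN = "unknown"

#: ISO-like country string -> continent, covering common FAERS codes.
COUNTRY_TO_CONTINENT: dict[str, str] = {
    # North America
    "US": "North America", "USA": "North America", "CA": "North America",
    "MX": "North America", "PR": "North America",
    "UNITED STATES": "North America", "CANADA": "North America",
    # Europe
    "GB": "Europe", "UK": "Europe", "DE": "Europe", "FR": "Europe",
    "IT": "Europe", "ES": "Europe", "NL": "Europe", "BE": "Europe",
    "SE": "Europe", "DK": "Europe", "NO": "Europe", "FI": "Europe",
    "IE": "Europe", "PT": "Europe", "PL": "Europe", "CH": "Europe",
    "AT": "Europe", "GR": "Europe", "CZ": "Europe", "HU": "Europe",
    # Asia
    "JP": "Asia", "CN": "Asia", "KR": "Asia", "IN": "Asia", "IL": "Asia",
    "SA": "Asia", "TR": "Asia", "TH": "Asia", "PH": "Asia", "SG": "Asia",
    "TW": "Asia", "HK": "Asia", "MY": "Asia", "ID": "Asia", "VN": "Asia",
    # South America
    "BR": "South America", "AR": "South America", "CO": "South America",
    "CL": "South America", "PE": "South America", "VE": "South America",
    # Oceania
    "AU": "Oceania", "NZ": "Oceania",
    # Africa
    "ZA": "Africa", "NG": "Africa", "EG": "Africa", "KE": "Africa",
    "MA": "Africa", "TN": "Africa",
}

#: Keyword -> indication group, checked in order; no hit and non-empty -> "others".
INDICATION_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("DIABETES", "diabetes mellitus"),
    ("WEIGHT", "weight control"),
    ("OBESITY", "weight control"),
    ("BLOOD GLUCOSE", "blood glucose abnormal"),
)

OCCUPATION_LABELS = {
    "CN": "consumer", "MD": "physician", "PH": "pharmacist",
    "HP": "health professional", "OT": "other health professional",
    "LW": "lawyer",
}

OUTCOME_LABELS = {
    "DE": "death", "LT": "life threatening", "HO": "hospitalization",
    "DS": "disability", "CA": "congenital anomaly",
    "RI": "required intervention to prevent", "OT": "other medical event",
}

#: Conversion of FAERS age-unit codes to years.
AGE_UNIT_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52,
                  "DY": 1 / 365.25, "HR": 1 / (365.25 * 24)}


def pct(numerator: float, denominator: float, digits: int = 2) -> float:
    """Percentage rounded half-up to ``digits`` decimals; 0 on empty denominator."""
    if denominator == 0:
        return 0.0
    q = Decimal(numerator) / Decimal(denominator) * 100
    exp = Decimal(1).scaleb(-digits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def quantiles(values: Sequence[float], method: str = "linear") -> tuple[float, float, float] | None:
    """Median and IQR bounds ``(median, q25, q75)``; ``None`` on empty input.

    ``method`` is any numpy quantile interpolation rule; the default linear
    rule interpolates between order statistics.
    """
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return None
    q25, med, q75 = np.percentile(arr, [25, 50, 75], method=method)
    return float(med), float(q25), float(q75)


def age_in_years(age: float | None, age_cod: str) -> float | None:
    """Convert a FAERS age + unit code to years; unknown unit defaults to years."""
    if age is None:
        return None
    factor = AGE_UNIT_YEARS.get(age_cod.upper() or "YR", 1.0)
    return age * factor


def continent_of(country: str) -> str:
    return COUNTRY_TO_CONTINENT.get(country.strip().upper(), UNKNOWN) if country.strip() else UNKNOWN


def indication_group(indi_pt: str) -> str:
    s = indi_pt.strip().upper()
    if not s or "UNKNOWN INDICATION" in s:
        return UNKNOWN
    for key, group in INDICATION_KEYWORDS:
        if key in s:
            return group
    return "others"


@dataclass
class CharacteristicsTable:
    """Stratified categorical blocks plus age/onset quantile summaries.

    ``blocks[stratum][block]`` is a DataFrame with columns
    ``category, n, pct``; within each block the counts sum to the stratum's
    case count (an Unknown row is always present where data can be missing).
    """

    strata: list[str]
    n_cases: dict[str, int]
    blocks: dict[str, dict[str, pd.DataFrame]]
    age_summary: dict[str, tuple[float, float, float] | None]

    def block(self, stratum: str, name: str) -> pd.DataFrame:
        return self.blocks[stratum][name]

    def write(self, directory: str | Path) -> list[Path]:
        """One delimited file per stratum block."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for stratum, blocks in self.blocks.items():
            for name, df in blocks.items():
                p = directory / f"characteristics_{stratum}_{name}.tsv"
                df.to_csv(p, sep="\t", index=False)
                written.append(p)
        return written


def _categorical_block(labels: Iterable[str], n_total: int,
                       order: Sequence[str] | None = None) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    if order is None:
        order = sorted(counts, key=lambda k: (k == UNKNOWN, -counts[k], k))
    else:
        order = list(order) + sorted(set(counts) - set(order))
    rows = [{"category": lab, "n": counts.get(lab, 0),
             "pct": pct(counts.get(lab, 0), n_total)} for lab in order]
    return pd.DataFrame(rows, columns=["category", "n", "pct"])


def _sex_label(sex: str) -> str:
    return {"F": "women", "M": "men"}.get(sex, UNKNOWN)


def _occupation_label(code: str) -> str:
    return OCCUPATION_LABELS.get(code, UNKNOWN)


def _report_indication(report: CohortReport) -> str:
    """Best indication group over the INDI rows of the matched PS drugs."""
    groups = []
    for ind in report.bundle.indications:
        if report.matched_ps_seqs and ind.indi_drug_seq not in report.matched_ps_seqs:
            continue
        groups.append(indication_group(ind.indi_pt))
    for _, g in INDICATION_KEYWORDS:
        if g in groups:
            return g
    if "others" in groups:
        return "others"
    return UNKNOWN


def _outcome_labels(report: CohortReport) -> list[str]:
    # One outcome slot per report: the most serious listed code, by the
    # conventional severity order; reports with no OUTC row are unknown.
    severity = ["DE", "LT", "HO", "DS", "CA", "RI", "OT"]
    codes = {o.outc_cod for o in report.bundle.outcomes}
    for code in severity:
        if code in codes:
            return [OUTCOME_LABELS[code]]
    return [UNKNOWN]


def summarize_cohort(
    cohort: CohortResult | Sequence[CohortReport],
    target_only: bool = True,
    quantile_method: str = "linear",
) -> CharacteristicsTable:
    """Build the per-stratum characteristics table.

    Strata are ``overall`` plus one per regimen (a report naming two regimens
    as primary suspect appears once overall and once per regimen).  When
    ``target_only`` is set, only target-SOC cases are characterized — the
    usual case-series table.
    """
    reports = cohort.reports if isinstance(cohort, CohortResult) else list(cohort)
    if target_only:
        reports = [r for r in reports if r.is_target_soc]

    strata: dict[str, list[CohortReport]] = {OVERALL: reports}
    for r in reports:
        for reg in sorted(r.regimens):
            strata.setdefault(reg, []).append(r)

    blocks: dict[str, dict[str, pd.DataFrame]] = {}
    n_cases: dict[str, int] = {}
    age_summary: dict[str, tuple[float, float, float] | None] = {}
    for stratum, members in strata.items():
        n = len(members)
        n_cases[stratum] = n
        ages = [age_in_years(r.bundle.demo.age, r.bundle.demo.age_cod)
                for r in members]
        ages = [a for a in ages if a is not None]
        b: dict[str, pd.DataFrame] = {}
        b["sex"] = _categorical_block(
            (_sex_label(r.bundle.demo.sex) for r in members), n,
            order=["women", "men", UNKNOWN])
        b["age"] = _categorical_block(
            (("known" if age_in_years(r.bundle.demo.age, r.bundle.demo.age_cod)
              is not None else UNKNOWN) for r in members), n,
            order=["known", UNKNOWN])
        b["region"] = _categorical_block(
            (continent_of(r.bundle.demo.reporter_country) for r in members), n,
            order=["North America", "Europe", "Asia", "South America",
                   "Oceania", "Africa", UNKNOWN])
        b["year"] = _categorical_block(
            (str(r.bundle.demo.fda_dt.year) if r.bundle.demo.fda_dt.is_valid
             else UNKNOWN for r in members), n)
        b["occupation"] = _categorical_block(
            (_occupation_label(r.bundle.demo.occp_cod) for r in members), n,
            order=["consumer", "physician", "pharmacist", "health professional",
                   "other health professional", "lawyer", UNKNOWN])
        b["indication"] = _categorical_block(
            (_report_indication(r) for r in members), n,
            order=["diabetes mellitus", "weight control",
                   "blood glucose abnormal", "others", UNKNOWN])
        b["outcome"] = _categorical_block(
            (lab for r in members for lab in _outcome_labels(r)), n,
            order=[OUTCOME_LABELS[c] for c in
                   ["DE", "LT", "HO", "DS", "CA", "RI", "OT"]] + [UNKNOWN])
        blocks[stratum] = b
        age_summary[stratum] = quantiles(ages, method=quantile_method)

    ordered = [OVERALL] + sorted(s for s in strata if s != OVERALL)
    return CharacteristicsTable(strata=ordered, n_cases=n_cases, blocks=blocks,
                                age_summary=age_summary)


def soc_share_table(cohort: CohortResult) -> pd.DataFrame:
    """Target-SOC cases as a share of all cohort AE reports, per regimen.

    Columns: ``stratum, n_target, n_other, n_total, share_pct`` — the
    "target-SOC AEs / all AEs (%)" view of the cohort.
    """
    rows = []
    strata: dict[str, list[CohortReport]] = {OVERALL: list(cohort.reports)}
    for r in cohort.reports:
        for reg in sorted(r.regimens):
            strata.setdefault(reg, []).append(r)
    ordered = [OVERALL] + sorted(s for s in strata if s != OVERALL)
    for stratum in ordered:
        members = strata[stratum]
        n_total = len(members)
        n_target = sum(r.is_target_soc for r in members)
        rows.append({"stratum": stratum, "n_target": n_target,
                     "n_other": n_total - n_target, "n_total": n_total,
                     "share_pct": pct(n_target, n_total)})
    return pd.DataFrame(rows)


def case_share_table(counts_by_regimen: Mapping[str, int], n_overall: int) -> pd.DataFrame:
    """Per-regimen share of the overall case series (counts given as inputs)."""
    rows = [{"stratum": k, "n": v, "share_pct": pct(v, n_overall)}
            for k, v in counts_by_regimen.items()]
    return pd.DataFrame(rows)
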