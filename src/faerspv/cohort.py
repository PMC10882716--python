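"""Target-drug cohort extraction and system-organ-class tagging.

A report enters the cohort when at least one of its DRUG rows names a lexicon
drug (generic or brand) with role code PS (primary suspect).  Matching is
case-insensitive, on whitespace/punctuation-normalized tokens, by exact
equality or whole-word containment — ``"ozempic 0.5 mg pen"`` matches
semaglutide, ``"metformin"`` matches nothing.  Both ``drugname`` and
``prod_ai`` are matched by default (configurable).

Each reaction PT is then tagged with its system organ class through a
user-supplied PT→SOC table (single primary SOC per PT; the MedDRA dictionary
itself is licensed and not shipped), and the report is flagged a target-SOC
case when any of its PTs maps to the target SOC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import ReportBundle

# GLP-1 receptor agonist regimens: generic name -> FDA brand names.
GLP1_LEXICON: dict[str, tuple[str, ...]] = {
    "exenatide": ("BYETTA", "BYDUREON"),
    "liraglutide": ("VICTOZA", "SAXENDA"),
    "lixisenatide": ("ADLYXIN", "SOLIQUA"),
    "dulaglutide": ("TRULICITY",),
    "semaglutide": ("OZEMPIC", "RYBELSUS", "WEGOVY"),
    "tirzepatide": ("MOUNJARO",),
}

#: MedDRA code of the psychiatric disorders SOC, the default target.
PSYCHIATRIC_SOC = "psychiatric disorders"
PSYCHIATRIC_SOC_CODE = "10037175"

_TOKEN_RE = re.compile(r"[A-Z0-9]+")


def normalize_name(name: str) -> tuple[str, ...]:
    """Upper-case and split a drug-name string into alphanumeric tokens."""
    return tuple(_TOKEN_RE.findall(name.upper()))


@dataclass(frozen=True)
class DrugLexicon:
    """Regimen name -> set of normalized name token-sequences."""

    regimens: Mapping[str, frozenset[tuple[str, ...]]]

    @classmethod
    def from_names(cls, mapping: Mapping[str, Iterable[str]]) -> "DrugLexicon":
        reg: dict[str, frozenset[tuple[str, ...]]] = {}
        for regimen, names in mapping.items():
            toks = {normalize_name(regimen)} | {normalize_name(n) for n in names}
            toks = {t for t in toks if t}
            if not toks:
                raise ValueError(f"regimen {regimen!r} has no usable names")
            reg[regimen] = frozenset(toks)
        return cls(regimens=reg)

    @classmethod
    def glp1(cls) -> "DrugLexicon":
        """The six-regimen GLP-1 RA lexicon (generic + brand names)."""
        return cls.from_names(GLP1_LEXICON)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugLexicon":
        """Load a two-column delimited file: regimen <tab> name (one per row)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        grouped: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            grouped.setdefault(row["regimen"].strip(), []).append(row["name"])
        return cls.from_names(grouped)

    def match(self, text: str) -> frozenset[str]:
        """Regimens whose names equal or appear whole-word inside ``text``."""
        tokens = normalize_name(text)
        if not tokens:
            return frozenset()
        hits = set()
        for regimen, names in self.regimens.items():
            for name in names:
                if _contains(tokens, name):
                    hits.add(regimen)
                    break
        return frozenset(hits)


def _contains(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    if n == 0 or n > len(haystack):
        return False
    return any(haystack[i:i + n] == needle for i in range(len(haystack) - n + 1))


def match_drug(record, lexicon: DrugLexicon, fields: tuple[str, ...] = ("drugname", "prod_ai")) -> frozenset[str]:
    """Regimens matched by a DRUG row over the configured name fields."""
    hits: set[str] = set()
    for f in fields:
        hits |= lexicon.match(getattr(record, f, "") or "")
    return frozenset(hits)


@dataclass(frozen=True)
class PtSocMap:
    """Preferred Term -> (SOC name, SOC code); single primary SOC per PT."""

    mapping: Mapping[str, tuple[str, str]]  # upper-cased PT -> (soc, code)

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, tuple[str, str]]) -> "PtSocMap":
        return cls(mapping={pt.strip().upper(): (soc.strip().lower(), str(code).strip())
                            for pt, (soc, code) in pairs.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PtSocMap":
        """Load a delimited file with columns pt, soc, soc_code."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        return cls.from_pairs({row["pt"]: (row["soc"], row.get("soc_code", ""))
                               for _, row in df.iterrows()})

    def soc_of(self, pt: str) -> tuple[str, str] | None:
        return self.mapping.get(pt.strip().upper())


@dataclass
class CohortReport:
    """A retained report that matched the lexicon at PS role."""

    bundle: ReportBundle
    regimens: frozenset[str]                 # regimens matched at role PS
    matched_ps_seqs: frozenset[str]          # drug_seq of PS rows that matched
    pt_soc: dict[str, str | None] = field(default_factory=dict)  # PT -> soc or None
    is_target_soc: bool = False

    @property
    def primaryid(self) -> str:
        return self.bundle.primaryid

    @property
    def caseid(self) -> str:
        return self.bundle.caseid

    @property
    def target_pts(self) -> frozenset[str]:
        """PTs of this report mapped to the target SOC."""
        return frozenset(pt for pt, soc in self.pt_soc.items()
                         if soc is not None and self._target is not None and soc == self._target)

    _target: str | None = None


@dataclass
class CohortResult:
    reports: list[CohortReport]
    target_soc: str
    unmapped_pts: dict[str, int] = field(default_factory=dict)  # PT -> occurrence count

    @property
    def n(self) -> int:
        return len(self.reports)

    @property
    def n_target_soc(self) -> int:
        return sum(r.is_target_soc for r in self.reports)

    def counts_by_regimen(self, target_only: bool = False) -> dict[str, int]:
        """Per-regimen report counts; a two-regimen report counts once per regimen."""
        counts: dict[str, int] = {}
        for r in self.reports:
            if target_only and not r.is_target_soc:
                continue
            for reg in r.regimens:
                counts[reg] = counts.get(reg, 0) + 1
        return dict(sorted(counts.items()))


def build_cohort(
    bundles: Iterable[ReportBundle],
    lexicon: DrugLexicon,
    soc_map: PtSocMap,
    target_soc: str = PSYCHIATRIC_SOC,
    match_fields: tuple[str, ...] = ("drugname", "prod_ai"),
) -> CohortResult:
    """Extract lexicon-matched primary-suspect reports and tag SOC membership.

    PTs absent from ``soc_map`` are tagged unmapped and counted, never dropped.
    """
    target = target_soc.strip().lower()
    out: list[CohortReport] = []
    unmapped: dict[str, int] = {}
    for b in bundles:
        regimens: set[str] = set()
        seqs: set[str] = set()
        for d in b.drugs:
            if d.role_cod != "PS":
                continue
            hits = match_drug(d, lexicon, match_fields)
            if hits:
                regimens |= hits
                seqs.add(d.drug_seq)
        if not regimens:
            continue
        pt_soc: dict[str, str | None] = {}
        is_target = False
        for pt in sorted(b.pts):
            hit = soc_map.soc_of(pt)
            if hit is None:
                pt_soc[pt] = None
                unmapped[pt] = unmapped.get(pt, 0) + 1
            else:
                pt_soc[pt] = hit[0]
                if hit[0] == target:
                    is_target = True
        report = CohortReport(bundle=b, regimens=frozenset(regimens),
                              matched_ps_seqs=frozenset(seqs),
                              pt_soc=pt_soc, is_target_soc=is_target)
        report._target = target
        out.append(report)
    return CohortResult(reports=out, target_soc=target, unmapped_pts=unmapped)
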