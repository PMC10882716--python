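"""Reporting-odds-ratio disproportionality analysis.

For a drug set D and an event set E over a de-duplicated report universe, the
2x2 table counts *reports* (never PT occurrences):

    a = reports with a primary-suspect drug in D listing >=1 PT in E
    b = reports with a primary-suspect drug in D listing no PT in E
    c = comparator reports (no PS drug in D) listing >=1 PT in E
    d = comparator reports listing no PT in E

so a+b is the total number of target-drug reports and a+b+c+d the universe
size.  Then

    ROR = (a*d) / (b*c)
    95% CI = exp( ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96

A drug-event pair is a *signal* when the report count a is at least
``min_count`` (default 5, a false-positive guard) and the lower CI bound
(ROR05) exceeds 1.  Any zero cell makes the ROR not computable; there is no
continuity correction by default (a Haldane +0.5 option exists behind a flag).

The comparator is "all other drugs in the full database": every report whose
PS drugs include no member of the analyzed drug set — so when a single
regimen is analyzed, reports of sibling regimens fall in the comparator.  A
class-exclusive comparator (drop sibling-regimen reports entirely) is
available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .cohort import DrugLexicon, match_drug
from .io import ReportBundle

Z_95 = 1.96

REASON_POSITIVE = "positive"
REASON_BELOW_COUNT = "below_count_threshold"
REASON_CI_SPANS_ONE = "ci_spans_one"
REASON_NOT_COMPUTABLE = "not_computable"


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # target drug, target event
    b: int  # target drug, other events
    c: int  # comparator, target event
    d: int  # comparator, other events

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_drug + self.n_comparator


@dataclass(frozen=True)
class SignalResult:
    drug_label: str
    event_label: str
    table: ContingencyTable
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    is_signal: bool
    reason: str

    def as_row(self) -> dict:
        t = self.table
        return {"drug_set": self.drug_label, "event": self.event_label,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": self.ror, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "is_signal": self.is_signal, "reason": self.reason}


def compute_ror(table: ContingencyTable, z: float = Z_95,
                haldane: bool = False) -> tuple[float, float, float] | None:
    """(ROR, ci_low, ci_high) by the closed form, or ``None`` on a zero cell.

    With ``haldane`` set, 0.5 is added to every cell when any cell is zero
    (off by default; the count threshold already guards sparse tables).
    """
    a, b, c, d = (float(table.a), float(table.b), float(table.c), float(table.d))
    if min(a, b, c, d) == 0:
        if not haldane:
            return None
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    half_width = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, math.exp(math.log(ror) - half_width),
            math.exp(math.log(ror) + half_width))


# ---------------------------------------------------------------------------
# Report-level counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportFacts:
    """The per-report facts signal counting needs: PS regimens and PT set."""

    primaryid: str
    ps_regimens: frozenset[str]
    pts: frozenset[str]


def extract_facts(bundles: Iterable[ReportBundle],
                  lexicon: DrugLexicon,
                  match_fields: tuple[str, ...] = ("drugname", "prod_ai"),
                  ) -> list[ReportFacts]:
    """Reduce bundles to :class:`ReportFacts` for fast repeated counting."""
    facts = []
    for b in bundles:
        regs: set[str] = set()
        for drug in b.drugs:
            if drug.role_cod == "PS":
                regs |= match_drug(drug, lexicon, match_fields)
        facts.append(ReportFacts(primaryid=b.primaryid,
                                 ps_regimens=frozenset(regs), pts=b.pts))
    return facts


DrugPredicate = Callable[[ReportFacts], bool]


def drug_set_predicate(regimens: Iterable[str] | None) -> DrugPredicate:
    """Membership predicate: any PS regimen in ``regimens`` (None = any regimen)."""
    if regimens is None:
        return lambda r: bool(r.ps_regimens)
    wanted = frozenset(regimens)
    return lambda r: bool(r.ps_regimens & wanted)


def build_contingency(
    universe: Sequence[ReportFacts],
    drug_set: DrugPredicate | Iterable[str] | None,
    event_set: Iterable[str] | Callable[[frozenset[str]], bool],
    exclude: DrugPredicate | None = None,
) -> ContingencyTable:
    """Count the 2x2 table over the full de-duplicated universe.

    Each report lands in exactly one cell.  ``drug_set`` is a predicate over
    :class:`ReportFacts` or an iterable of regimen names; ``event_set`` is a
    PT collection (membership = report lists >=1 of them) or a predicate over
    the report's PT set.  ``exclude`` removes reports from the universe first
    (the class-exclusive comparator mode).
    """
    if not universe:
        raise ValueError("empty report universe")
    pred = drug_set if callable(drug_set) else drug_set_predicate(drug_set)
    if callable(event_set):
        event_pred = event_set
    else:
        wanted = frozenset(pt.strip().upper() for pt in event_set)
        event_pred = lambda pts: bool(pts & wanted)
    a = b = c = d = 0
    for r in universe:
        if exclude is not None and exclude(r) and not pred(r):
            continue
        in_drug = pred(r)
        in_event = event_pred(r.pts)
        if in_drug:
            if in_event:
                a += 1
            else:
                b += 1
        elif in_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _classify(drug_label: str, event_label: str, table: ContingencyTable,
              min_count: int, z: float, haldane: bool) -> SignalResult:
    est = compute_ror(table, z=z, haldane=haldane)
    if est is None:
        return SignalResult(drug_label, event_label, table, None, None, None,
                            False, REASON_NOT_COMPUTABLE)
    ror, lo, hi = est
    if table.a < min_count:
        return SignalResult(drug_label, event_label, table, ror, lo, hi,
                            False, REASON_BELOW_COUNT)
    if lo <= 1.0:
        return SignalResult(drug_label, event_label, table, ror, lo, hi,
                            False, REASON_CI_SPANS_ONE)
    return SignalResult(drug_label, event_label, table, ror, lo, hi,
                        True, REASON_POSITIVE)


def scan_signals(
    universe: Sequence[ReportFacts],
    drug_sets: Mapping[str, Iterable[str] | DrugPredicate | None],
    event_sets: Mapping[str, Iterable[str]],
    min_count: int = 5,
    z: float = Z_95,
    haldane: bool = False,
    class_exclusive: bool = False,
) -> list[SignalResult]:
    """One :class:`SignalResult` per (drug set, event set) with a >= 1.

    Results are ordered with signals first, by descending ROR, then the
    remainder by the same key.  ``class_exclusive`` switches the comparator to
    exclude reports of any regimen named across all analyzed drug sets.
    """
    exclude = None
    if class_exclusive:
        named: set[str] = set()
        for spec in drug_sets.values():
            if spec is not None and not callable(spec):
                named |= set(spec)
        exclude = drug_set_predicate(named or None)

    results: list[SignalResult] = []
    for dlabel, dspec in drug_sets.items():
        for elabel, pts in event_sets.items():
            table = build_contingency(universe, dspec, pts, exclude=exclude)
            if table.a < 1:
                continue
            results.append(_classify(dlabel, elabel, table, min_count, z, haldane))
    results.sort(key=lambda s: (not s.is_signal,
                                -(s.ror if s.ror is not None else -math.inf)))
    return results


def grouped_ror(
    universe: Sequence[ReportFacts],
    drug_set: Iterable[str] | DrugPredicate | None,
    pt_group: Iterable[str],
    label: str = "grouped",
    drug_label: str = "target",
    min_count: int = 5,
    z: float = Z_95,
    haldane: bool = False,
) -> SignalResult:
    """ROR treating a whole PT group as one event category (report-level)."""
    pts = list(pt_group)
    if not pts:
        raise ValueError("pt_group must be non-empty")
    table = build_contingency(universe, drug_set, pts)
    return _classify(drug_label, label, table, min_count, z, haldane)


def signals_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results],
                        columns=["drug_set", "event", "a", "b", "c", "d",
                                 "ror", "ci_low", "ci_high", "is_signal",
                                 "reason"])


def write_signal_table(results: Sequence[SignalResult], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    signals_to_frame(results).to_csv(path, sep="\t", index=False)
    return path
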