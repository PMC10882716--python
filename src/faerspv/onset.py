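"""Time-to-onset computation, summarization and between-regimen comparison.

Time to onset is the interval in days from initiation of the suspect drug
(the earliest day-precision therapy start date among THER rows linked to a
lexicon-matched primary-suspect drug) to the report's event date.  Only
strictly positive onsets are usable; a report is otherwise excluded with an
explicit reason:

* ``excluded_missing`` — either date absent or not day-precise;
* ``excluded_invalid_order`` — dosing date later than the event date;
* ``excluded_nonpositive`` — onset of exactly 0 days.

Summaries report the median/IQR (linear-interpolation quantiles by default),
counts over the conventional onset bins and the empirical cumulative
distribution.  Between-regimen comparison uses a global Kruskal–Wallis test
with pairwise two-sided Mann–Whitney tests (Holm-adjusted); a log-rank
variant over the cumulative curves is available since onsets are durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortReport
from .descriptives import pct, quantiles

INCLUDED = "included"
EXCLUDED_MISSING = "excluded_missing"
EXCLUDED_INVALID_ORDER = "excluded_invalid_order"
EXCLUDED_NONPOSITIVE = "excluded_nonpositive"
STATUSES = (INCLUDED, EXCLUDED_MISSING, EXCLUDED_INVALID_ORDER,
            EXCLUDED_NONPOSITIVE)

#: Conventional onset bins in days; edges are exclusive below, inclusive
#: above — with integer days and the >0 rule, "0-30" covers days 1..30.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0, 30, 60, 90, 120, 150, 180, 360,
                                        math.inf)

#: A regimen needs at least this many usable onsets to be summarized/compared.
MIN_INCLUDED = 5


@dataclass(frozen=True)
class OnsetRecord:
    primaryid: str
    regimen: str
    status: str
    onset_days: int | None = None  # present iff included; always >= 1

    def __post_init__(self):
        if (self.status == INCLUDED) != (self.onset_days is not None):
            raise ValueError("onset_days present iff status is included")
        if self.onset_days is not None and self.onset_days < 1:
            raise ValueError("included onset must be >= 1 day")


def bin_labels(edges: Sequence[float] = DEFAULT_BIN_EDGES) -> list[str]:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{int(lo)}+" if math.isinf(hi) else f"{int(lo)}-{int(hi)}")
    return labels


@dataclass
class OnsetSummary:
    regimen: str
    n_included: int
    median: float | None
    iqr: tuple[float, float] | None
    bin_counts: dict[str, int]
    curve: pd.DataFrame            # columns: days, cum_fraction
    insufficient: bool = False
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def first_bin_share_pct(self) -> float:
        first = next(iter(self.bin_counts))
        return pct(self.bin_counts[first], self.n_included)


def compute_onset(report: CohortReport, regimen: str | None = None) -> OnsetRecord:
    """Classify one cohort report and compute its onset when usable.

    The start date is the earliest day-precision ``start_dt`` among THER rows
    whose ``dsg_drug_seq`` links to a matched primary-suspect drug; the event
    date is the report's single DEMO ``event_dt``.  Both must be day-precise.
    """
    reg = regimen if regimen is not None else "+".join(sorted(report.regimens))
    event = report.bundle.demo.event_dt
    starts = [t.start_dt.to_date() for t in report.bundle.therapies
              if t.dsg_drug_seq in report.matched_ps_seqs and t.start_dt.is_day]
    if not starts or not event.is_day:
        return OnsetRecord(report.primaryid, reg, EXCLUDED_MISSING)
    start = min(starts)
    delta = (event.to_date() - start).days
    if delta < 0:
        return OnsetRecord(report.primaryid, reg, EXCLUDED_INVALID_ORDER)
    if delta == 0:
        return OnsetRecord(report.primaryid, reg, EXCLUDED_NONPOSITIVE)
    return OnsetRecord(report.primaryid, reg, INCLUDED, onset_days=delta)


def compute_onsets(reports: Iterable[CohortReport]) -> list[OnsetRecord]:
    """One OnsetRecord per (report, regimen) pair; every report classified."""
    out: list[OnsetRecord] = []
    for r in reports:
        for reg in sorted(r.regimens):
            out.append(compute_onset(r, regimen=reg))
    return out


def bin_counts(values: Sequence[int],
               edges: Sequence[float] = DEFAULT_BIN_EDGES) -> dict[str, int]:
    """Count integer onsets into (lo, hi] bins; conserves the total."""
    labels = bin_labels(edges)
    counts = dict.fromkeys(labels, 0)
    for v in values:
        for (lo, hi), lab in zip(zip(edges[:-1], edges[1:]), labels):
            if lo < v <= hi:
                counts[lab] += 1
                break
    return counts


def _ecdf(values: Sequence[int]) -> pd.DataFrame:
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        return pd.DataFrame({"days": [], "cum_fraction": []})
    days, idx = np.unique(arr, return_index=True)
    # cumulative fraction at each distinct onset value
    counts = np.diff(np.append(idx, arr.size))
    cum = np.cumsum(counts) / arr.size
    return pd.DataFrame({"days": days, "cum_fraction": cum})


def summarize_onset(
    records: Iterable[OnsetRecord],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    quantile_method: str = "linear",
    min_included: int = MIN_INCLUDED,
    include_overall: bool = True,
) -> dict[str, OnsetSummary]:
    """Per-regimen (plus overall) onset summaries.

    A regimen with fewer than ``min_included`` usable onsets is marked
    ``insufficient``: its counts are reported but no quantiles, and it is
    dropped from between-regimen comparison.
    """
    records = list(records)
    groups: dict[str, list[OnsetRecord]] = {}
    for rec in records:
        groups.setdefault(rec.regimen, []).append(rec)
    if include_overall:
        groups = {"overall": records, **dict(sorted(groups.items()))}

    out: dict[str, OnsetSummary] = {}
    for reg, recs in groups.items():
        values = [r.onset_days for r in recs if r.status == INCLUDED]
        exclusions = {s: sum(r.status == s for r in recs) for s in STATUSES}
        insufficient = len(values) < min_included
        q = None if insufficient else quantiles(values, method=quantile_method)
        out[reg] = OnsetSummary(
            regimen=reg, n_included=len(values),
            median=None if q is None else q[0],
            iqr=None if q is None else (q[1], q[2]),
            bin_counts=bin_counts(values, edges),
            curve=_ecdf(values),
            insufficient=insufficient,
            exclusions=exclusions,
        )
    return out


@dataclass
class OnsetComparison:
    groups: list[str]
    skipped: dict[str, str]                    # group -> reason
    kruskal_stat: float | None
    kruskal_p: float | None
    pairwise: pd.DataFrame                     # group_a, group_b, u_stat, p_raw, p_holm
    logrank: pd.DataFrame | None = None        # same layout, log-rank variant


def compare_onset(
    groups: Mapping[str, Sequence[int]],
    min_n: int = 2,
    include_logrank: bool = False,
) -> OnsetComparison:
    """Global Kruskal–Wallis + pairwise Mann–Whitney (Holm-adjusted).

    Degenerate groups (fewer than ``min_n`` values) are skipped with a reason;
    if the pooled values are all identical the tests are skipped as all-ties.
    """
    from statsmodels.stats.multitest import multipletests

    usable: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < min_n:
            skipped[name] = f"n={arr.size} < {min_n}"
        else:
            usable[name] = arr
    names = sorted(usable)
    if len(names) < 2:
        return OnsetComparison(groups=names, skipped=skipped, kruskal_stat=None,
                               kruskal_p=None,
                               pairwise=pd.DataFrame(columns=[
                                   "group_a", "group_b", "u_stat", "p_raw", "p_holm"]))
    pooled = np.concatenate([usable[n] for n in names])
    if np.all(pooled == pooled[0]):
        for n in names:
            skipped[n] = "all-ties"
        return OnsetComparison(groups=[], skipped=skipped, kruskal_stat=None,
                               kruskal_p=None,
                               pairwise=pd.DataFrame(columns=[
                                   "group_a", "group_b", "u_stat", "p_raw", "p_holm"]))

    kw_stat, kw_p = stats.kruskal(*[usable[n] for n in names])

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            u, p = stats.mannwhitneyu(usable[a], usable[b],
                                      alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "u_stat": float(u),
                         "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]

    logrank_df = None
    if include_logrank:
        from lifelines.statistics import logrank_test

        lr_rows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                res = logrank_test(usable[a], usable[b])
                lr_rows.append({"group_a": a, "group_b": b,
                                "u_stat": float(res.test_statistic),
                                "p_raw": float(res.p_value)})
        logrank_df = pd.DataFrame(lr_rows)
        logrank_df["p_holm"] = multipletests(logrank_df["p_raw"], method="holm")[1]

    return OnsetComparison(groups=names, skipped=skipped,
                           kruskal_stat=float(kw_stat), kruskal_p=float(kw_p),
                           pairwise=pairwise, logrank=logrank_df)


def write_onset_outputs(records: Sequence[OnsetRecord],
                        summaries: Mapping[str, OnsetSummary],
                        directory: str | Path) -> list[Path]:
    """Emit onset records, summaries and plot-ready cumulative curves."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    rec_df = pd.DataFrame([{"primaryid": r.primaryid, "regimen": r.regimen,
                            "status": r.status, "onset_days": r.onset_days}
                           for r in records])
    p = directory / "onset_records.tsv"
    rec_df.to_csv(p, sep="\t", index=False)
    written.append(p)

    rows = []
    for reg, s in summaries.items():
        row = {"regimen": reg, "n_included": s.n_included,
               "median": s.median,
               "q25": None if s.iqr is None else s.iqr[0],
               "q75": None if s.iqr is None else s.iqr[1],
               "insufficient": s.insufficient}
        row.update({f"bin_{k}": v for k, v in s.bin_counts.items()})
        rows.append(row)
    p = directory / "onset_summary.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    written.append(p)

    for reg, s in summaries.items():
        p = directory / f"onset_curve_{reg}.tsv"
        s.curve.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
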