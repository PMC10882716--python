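"""Reading and writing FAERS-style quarterly ASCII tables.

A FAERS quarterly extract is a set of dollar-delimited text tables sharing a
report-version key (``primaryid``): DEMO (demographics/administration), DRUG,
REAC (reactions as MedDRA Preferred Terms), OUTC (outcomes), THER (therapy
dates) and INDI (indications).  This module parses those tables into per-report
:class:`ReportBundle` objects and writes them back out, preserving row counts
and key fields (round-trip safe).

Dates in FAERS are ``YYYYMMDD`` strings that are frequently partial (``YYYYMM``
or ``YYYY``) or garbled.  :func:`parse_date` never raises: it returns a
:class:`FaersDate` carrying the parsed value *and* its precision, so each
downstream stage can apply its own usability rule (de-duplication tolerates
partial receipt dates; time-to-onset requires day precision on both sides).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: FAERS ASCII dialect: dollar-delimited, one header line.
DEFAULT_DELIMITER = "$"

#: Tables that must be present for a quarter to be readable.
MANDATORY_TABLES = ("demo", "drug", "reac")

#: All tables a quarter may carry, in canonical order.
ALL_TABLES = ("demo", "drug", "reac", "outc", "ther", "indi")

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


# ---------------------------------------------------------------------------
# Dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=False)
class FaersDate:
    """A possibly-partial FAERS date.

    ``precision`` is one of ``day``, ``month``, ``year`` or ``none`` (absent,
    empty or unparseable).  ``year``/``month``/``day`` components are ``None``
    beyond the known precision.
    """

    raw: str
    precision: str  # day | month | year | none
    year: int | None = None
    month: int | None = None
    day: int | None = None

    @property
    def is_valid(self) -> bool:
        return self.precision != "none"

    @property
    def is_day(self) -> bool:
        return self.precision == "day"

    def to_date(self) -> _dt.date | None:
        """Calendar date when day-precise, else ``None``."""
        if self.precision != "day":
            return None
        return _dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        """Ordering key for recency comparisons over partial dates.

        Compares by the known prefix; an unknown month/day sorts before any
        known one, so within the same month a day-precision date ranks as more
        recent than a month-precision one (more information = more recent
        knowledge).  Invalid dates sort first.
        """
        return (self.year or 0, self.month or 0, self.day or 0)


_INVALID = FaersDate(raw="", precision="none")


def parse_date(raw: object) -> FaersDate:
    """Parse a FAERS date string, tolerating partial and garbled input.

    ``"20230115"`` -> day precision; ``"202301"`` -> month; ``"2023"`` -> year;
    anything else (empty, ``00000000``, non-numeric, impossible calendar date)
    -> the invalid/absent flag.  Never raises.
    """
    if raw is None:
        return _INVALID
    s = str(raw).strip()
    if s.endswith(".0"):  # numeric column read back as float
        s = s[:-2]
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return replace(_INVALID, raw=s)
    year = int(s[:4])
    if not 1900 <= year <= 2199:
        return replace(_INVALID, raw=s)
    if len(s) == 4:
        return FaersDate(raw=s, precision="year", year=year)
    month = int(s[4:6])
    if not 1 <= month <= 12:
        return replace(_INVALID, raw=s)
    if len(s) == 6:
        return FaersDate(raw=s, precision="month", year=year, month=month)
    day = int(s[6:8])
    try:
        _dt.date(year, month, day)
    except ValueError:
        return replace(_INVALID, raw=s)
    return FaersDate(raw=s, precision="day", year=year, month=month, day=day)


def format_date(d: _dt.date, precision: str = "day") -> str:
    """Render a date back to the FAERS string dialect."""
    if precision == "day":
        return f"{d.year:04d}{d.month:02d}{d.day:02d}"
    if precision == "month":
        return f"{d.year:04d}{d.month:02d}"
    if precision == "year":
        return f"{d.year:04d}"
    return ""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: FaersDate
    event_dt: FaersDate
    sex: str = ""            # F / M / "" (unknown)
    age: float | None = None
    age_cod: str = ""        # YR / DEC / MON / WK / DY
    reporter_country: str = ""
    occp_cod: str = ""       # CN / MD / PH / HP / OT / LW / ""


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    drug_seq: str
    drugname: str
    prod_ai: str = ""
    role_cod: str = ""       # PS / SS / C / I, else flagged unknown

    @property
    def role_known(self) -> bool:
        return self.role_cod in ROLE_CODES


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    pt: str


@dataclass(frozen=True)
class TherRecord:
    primaryid: str
    dsg_drug_seq: str
    start_dt: FaersDate
    end_dt: FaersDate


@dataclass(frozen=True)
class OutcRecord:
    primaryid: str
    outc_cod: str

    @property
    def code_known(self) -> bool:
        return self.outc_cod in OUTCOME_CODES


@dataclass(frozen=True)
class IndiRecord:
    primaryid: str
    indi_drug_seq: str
    indi_pt: str


@dataclass
class ReportBundle:
    """One case-report version: a DEMO row plus its child rows.

    Reaction PTs are de-duplicated (case-insensitively) within the bundle,
    since downstream signal counting is at report level.
    """

    demo: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)
    therapies: list[TherRecord] = field(default_factory=list)
    outcomes: list[OutcRecord] = field(default_factory=list)
    indications: list[IndiRecord] = field(default_factory=list)

    @property
    def primaryid(self) -> str:
        return self.demo.primaryid

    @property
    def caseid(self) -> str:
        return self.demo.caseid

    @property
    def pts(self) -> frozenset[str]:
        """Normalized (upper-cased, stripped) reaction PT set."""
        return frozenset(r.pt.strip().upper() for r in self.reactions if r.pt.strip())


@dataclass
class ReadReport:
    """Bookkeeping from one :func:`read_quarter` call."""

    n_rows: dict[str, int] = field(default_factory=dict)
    quarantined: dict[str, list[int]] = field(default_factory=dict)  # table -> row numbers
    orphan_rows: dict[str, int] = field(default_factory=dict)        # child rows with no DEMO parent

    @property
    def n_quarantined(self) -> int:
        return sum(len(v) for v in self.quarantined.values())


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_table(path: Path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _get(row, col: str) -> str:
    v = row.get(col, "")
    return "" if v is None else str(v).strip()


def _parse_age(raw: str) -> float | None:
    try:
        return float(raw)
    except (TypeError, ValueError):
        return None


def read_quarter(
    paths: Mapping[str, str | Path],
    delimiter: str = DEFAULT_DELIMITER,
) -> tuple[list[ReportBundle], ReadReport]:
    """Read one quarterly table set into per-report bundles.

    ``paths`` maps lower-case table names (``demo``, ``drug``, ``reac``,
    ``outc``, ``ther``, ``indi``) to file locations.  DEMO, DRUG and REAC are
    mandatory; a missing mandatory file is a hard error.  Rows whose
    ``primaryid`` is empty/unparseable are quarantined (counted with their row
    number and logged), never silently dropped.  Child rows are attached to
    their DEMO parent by ``primaryid``; one bundle per DEMO row.
    """
    paths = {k.lower(): Path(v) for k, v in paths.items()}
    for table in MANDATORY_TABLES:
        if table not in paths:
            raise FileNotFoundError(f"mandatory table {table!r} not supplied")
        if not paths[table].exists():
            raise FileNotFoundError(f"mandatory table file missing: {paths[table]}")
    for table, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"table file missing: {p}")

    report = ReadReport()
    frames: dict[str, pd.DataFrame] = {}
    for table, p in paths.items():
        df = _read_table(p, delimiter)
        frames[table] = df
        report.n_rows[table] = len(df)

    def quarantine(table: str, idx: int) -> None:
        report.quarantined.setdefault(table, []).append(idx)
        logger.warning("%s row %d quarantined (bad primaryid)", table, idx)

    bundles: dict[str, ReportBundle] = {}
    for idx, row in enumerate(frames["demo"].to_dict("records")):
        pid = _get(row, "primaryid")
        cid = _get(row, "caseid")
        if not pid:
            quarantine("demo", idx)
            continue
        demo = DemoRecord(
            primaryid=pid,
            caseid=cid,
            fda_dt=parse_date(_get(row, "fda_dt")),
            event_dt=parse_date(_get(row, "event_dt")),
            sex=_get(row, "sex").upper(),
            age=_parse_age(_get(row, "age")),
            age_cod=_get(row, "age_cod").upper(),
            reporter_country=_get(row, "reporter_country").upper(),
            occp_cod=_get(row, "occp_cod").upper(),
        )
        bundles[pid] = ReportBundle(demo=demo)

    def attach(table: str, build) -> None:
        if table not in frames:
            return
        orphans = 0
        for idx, row in enumerate(frames[table].to_dict("records")):
            pid = _get(row, "primaryid")
            if not pid:
                quarantine(table, idx)
                continue
            bundle = bundles.get(pid)
            if bundle is None:
                orphans += 1
                continue
            build(bundle, pid, row)
        if orphans:
            report.orphan_rows[table] = orphans
            logger.info("%s: %d rows without a DEMO parent", table, orphans)

    attach("drug", lambda b, pid, r: b.drugs.append(DrugRecord(
        primaryid=pid, drug_seq=_get(r, "drug_seq"),
        drugname=_get(r, "drugname"), prod_ai=_get(r, "prod_ai"),
        role_cod=_get(r, "role_cod").upper())))
    attach("reac", lambda b, pid, r: b.reactions.append(ReacRecord(
        primaryid=pid, pt=_get(r, "pt"))))
    attach("ther", lambda b, pid, r: b.therapies.append(TherRecord(
        primaryid=pid, dsg_drug_seq=_get(r, "dsg_drug_seq"),
        start_dt=parse_date(_get(r, "start_dt")),
        end_dt=parse_date(_get(r, "end_dt")))))
    attach("outc", lambda b, pid, r: b.outcomes.append(OutcRecord(
        primaryid=pid, outc_cod=_get(r, "outc_cod").upper())))
    attach("indi", lambda b, pid, r: b.indications.append(IndiRecord(
        primaryid=pid, indi_drug_seq=_get(r, "indi_drug_seq"),
        indi_pt=_get(r, "indi_pt"))))

    out = list(bundles.values())
    for b in out:
        _dedup_reactions(b)
    return out, report


def _dedup_reactions(bundle: ReportBundle) -> None:
    seen: set[str] = set()
    kept: list[ReacRecord] = []
    for r in bundle.reactions:
        key = r.pt.strip().upper()
        if key and key not in seen:
            seen.add(key)
            kept.append(r)
    bundle.reactions = kept


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def bundles_to_frames(bundles: Iterable[ReportBundle]) -> dict[str, pd.DataFrame]:
    """Flatten bundles back into the six canonical tables."""
    demo, drug, reac, ther, outc, indi = [], [], [], [], [], []
    for b in bundles:
        d = b.demo
        demo.append({
            "primaryid": d.primaryid, "caseid": d.caseid,
            "fda_dt": d.fda_dt.raw, "event_dt": d.event_dt.raw,
            "sex": d.sex,
            "age": "" if d.age is None else (f"{d.age:g}"),
            "age_cod": d.age_cod,
            "reporter_country": d.reporter_country, "occp_cod": d.occp_cod,
        })
        for r in b.drugs:
            drug.append({"primaryid": r.primaryid, "drug_seq": r.drug_seq,
                         "drugname": r.drugname, "prod_ai": r.prod_ai,
                         "role_cod": r.role_cod})
        for r in b.reactions:
            reac.append({"primaryid": r.primaryid, "pt": r.pt})
        for r in b.therapies:
            ther.append({"primaryid": r.primaryid,
                         "dsg_drug_seq": r.dsg_drug_seq,
                         "start_dt": r.start_dt.raw, "end_dt": r.end_dt.raw})
        for r in b.outcomes:
            outc.append({"primaryid": r.primaryid, "outc_cod": r.outc_cod})
        for r in b.indications:
            indi.append({"primaryid": r.primaryid,
                         "indi_drug_seq": r.indi_drug_seq,
                         "indi_pt": r.indi_pt})
    cols = {
        "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
                 "age_cod", "reporter_country", "occp_cod"],
        "drug": ["primaryid", "drug_seq", "drugname", "prod_ai", "role_cod"],
        "reac": ["primaryid", "pt"],
        "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
        "outc": ["primaryid", "outc_cod"],
        "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
    }
    rows = {"demo": demo, "drug": drug, "reac": reac, "ther": ther,
            "outc": outc, "indi": indi}
    return {t: pd.DataFrame(rows[t], columns=cols[t]) for t in ALL_TABLES}


def write_quarter(
    bundles: Sequence[ReportBundle],
    directory: str | Path,
    delimiter: str = DEFAULT_DELIMITER,
    prefix: str = "",
) -> dict[str, Path]:
    """Write bundles as a quarterly table set; returns table -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = bundles_to_frames(bundles)
    paths: dict[str, Path] = {}
    for table, df in frames.items():
        p = directory / f"{prefix}{table}.txt"
        df.to_csv(p, sep=delimiter, index=False, lineterminator="\n")
        paths[table] = p
    return paths
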