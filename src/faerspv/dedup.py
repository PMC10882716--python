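"""Two-criterion de-duplication of spontaneous report versions.

FAERS publishes every version of a case; analysis uses one report per case.
The retained version is chosen by:

i.  among versions sharing a ``caseid``, the one with the most recent FDA
    receipt date (``fda_dt``) wins;
ii. on a receipt-date tie, the higher ``primaryid`` wins.

``primaryid`` is compared numerically when fully numeric, lexicographically as
a fallback (fixture data may carry non-numeric ids).  Partial receipt dates
compare by their known prefix; within the same month a day-precision date
outranks a month-precision one.  Bundles without a usable ``caseid`` are
quarantined and reported, never silently kept.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io import ReportBundle

RULE_SINGLETON = "singleton"
RULE_LATEST_FDA_DT = "latest_fda_dt"
RULE_MAX_PRIMARYID = "max_primaryid"


@dataclass(frozen=True)
class DedupDecision:
    caseid: str
    kept_primaryid: str
    dropped_primaryids: tuple[str, ...]
    rule_used: str  # singleton | latest_fda_dt | max_primaryid


@dataclass
class DedupResult:
    retained: list[ReportBundle]
    decisions: list[DedupDecision]
    quarantined: list[ReportBundle] = field(default_factory=list)

    def write_audit(self, path: str | Path) -> Path:
        """Write the decision log as a delimited audit file."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["caseid", "kept_primaryid", "dropped_primaryids", "rule_used"])
            for d in self.decisions:
                w.writerow([d.caseid, d.kept_primaryid,
                            ";".join(d.dropped_primaryids), d.rule_used])
        return path


def primaryid_key(pid: str) -> tuple[int, int, str]:
    """Ordering key: numeric ids compare numerically, others lexicographically.

    All numeric ids rank below all non-numeric ids so the comparison is total.
    """
    s = pid.strip()
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


def _version_key(b: ReportBundle) -> tuple:
    return (b.demo.fda_dt.sort_key(), primaryid_key(b.primaryid))


def deduplicate(bundles: Iterable[ReportBundle]) -> DedupResult:
    """Retain one report version per case.

    Returns retained bundles sorted by ``caseid`` (then ``primaryid``), one
    :class:`DedupDecision` per case, and any bundle quarantined for a missing
    ``caseid``.  Deterministic and independent of input order; idempotent.
    """
    by_case: dict[str, list[ReportBundle]] = {}
    quarantined: list[ReportBundle] = []
    for b in bundles:
        cid = b.caseid.strip()
        if not cid:
            quarantined.append(b)
            continue
        by_case.setdefault(cid, []).append(b)

    retained: list[ReportBundle] = []
    decisions: list[DedupDecision] = []
    for cid in sorted(by_case, key=primaryid_key):
        versions = sorted(by_case[cid], key=_version_key)
        winner = versions[-1]
        if len(versions) == 1:
            rule = RULE_SINGLETON
        else:
            runner_up = versions[-2]
            tie = runner_up.demo.fda_dt.sort_key() == winner.demo.fda_dt.sort_key()
            rule = RULE_MAX_PRIMARYID if tie else RULE_LATEST_FDA_DT
        dropped = tuple(sorted((v.primaryid for v in versions[:-1]),
                               key=primaryid_key))
        retained.append(winner)
        decisions.append(DedupDecision(caseid=cid, kept_primaryid=winner.primaryid,
                                       dropped_primaryids=dropped, rule_used=rule))
    return DedupResult(retained=retained, decisions=decisions,
                       quarantined=quarantined)
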