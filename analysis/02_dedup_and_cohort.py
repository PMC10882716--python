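#!/usr/bin/env python
"""De-duplicate the universe and extract the primary-suspect drug cohort.

Reports the attrition flow (raw versions -> one report per case -> cohort ->
target-SOC cases) and writes the de-duplication audit plus attrition table.
"""

import argparse
import json
from pathlib import Path

from faerspv.cohort import DrugLexicon, build_cohort
from faerspv.dedup import deduplicate
from faerspv.io import ALL_TABLES, read_quarter
from faerspv.synth import SynthConfig


def load_universe(data_dir: Path):
    paths = {t: data_dir / f"{t}.txt" for t in ALL_TABLES
             if (data_dir / f"{t}.txt").exists()}
    return read_quarter(paths)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/universe"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundles, report = load_universe(args.data_dir)
    print(f"read {len(bundles)} report versions "
          f"({report.n_quarantined} rows quarantined)")

    res = deduplicate(bundles)
    audit = res.write_audit(args.results / "dedup_audit.tsv")
    rules = {}
    for d in res.decisions:
        rules[d.rule_used] = rules.get(d.rule_used, 0) + 1
    print(f"retained {len(res.retained)} unique cases "
          f"(rules used: {rules}); audit -> {audit}")

    cohort = build_cohort(res.retained, DrugLexicon.glp1(),
                          SynthConfig().soc_map())
    attrition = {
        "raw_report_versions": len(bundles),
        "deduplicated_reports": len(res.retained),
        "cohort_reports": cohort.n,
        "target_soc_cases": cohort.n_target_soc,
    }
    print("attrition flow:", " -> ".join(f"{k}={v}"
                                         for k, v in attrition.items()))
    args.results.mkdir(parents=True, exist_ok=True)
    with open(args.results / "attrition.json", "w") as fh:
        json.dump(attrition, fh, indent=2)
        fh.write("\n")
    print("per-regimen cohort counts:", cohort.counts_by_regimen())


if __name__ == "__main__":
    main()
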