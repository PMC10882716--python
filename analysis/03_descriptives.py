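#!/usr/bin/env python
"""Characterize the target-SOC case series: demographics, reporting, outcomes.

Writes one delimited block per stratum under results/descriptives/ plus the
target-SOC share of all cohort reports per regimen (the "pAEs / all AEs"
view), and prints the headline numbers.
"""

import argparse
from pathlib import Path

from faerspv.cohort import DrugLexicon, build_cohort
from faerspv.dedup import deduplicate
from faerspv.descriptives import soc_share_table, summarize_cohort
from faerspv.synth import SynthConfig

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "stage02", Path(__file__).with_name("02_dedup_and_cohort.py"))
_stage02 = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_stage02)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/universe"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundles, _ = _stage02.load_universe(args.data_dir)
    retained = deduplicate(bundles).retained
    cohort = build_cohort(retained, DrugLexicon.glp1(), SynthConfig().soc_map())

    share = soc_share_table(cohort)
    out = args.results / "soc_share.tsv"
    share.to_csv(out, sep="\t", index=False)
    overall = share[share.stratum == "overall"].iloc[0]
    print(f"target-SOC events account for {overall.share_pct}% "
          f"({overall.n_target}/{overall.n_total}) of cohort reports")
    print(f"per-regimen shares -> {out}")

    table = summarize_cohort(cohort, target_only=True)
    written = table.write(args.results / "descriptives")
    print(f"{len(written)} characteristic blocks -> "
          f"{args.results / 'descriptives'}")
    sex = table.block("overall", "sex").set_index("category")
    n = table.n_cases["overall"]
    print(f"case series n={n}: women {sex.loc['women', 'pct']}%, "
          f"men {sex.loc['men', 'pct']}%, unknown {sex.loc['unknown', 'pct']}%")
    age = table.age_summary["overall"]
    if age:
        print(f"age known for {table.block('overall', 'age').set_index('category').loc['known', 'n']} "
              f"cases; median {age[0]:.0f} y (IQR {age[1]:.0f}-{age[2]:.0f})")


if __name__ == "__main__":
    main()
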