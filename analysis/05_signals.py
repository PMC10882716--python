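#!/usr/bin/env python
"""Scan for drug-event signals by reporting odds ratio.

One ROR per (drug set, target-SOC PT) over the full de-duplicated universe,
positivity by report count >= 5 and ROR05 > 1, plus the grouped-category ROR
treating all positive PTs as one event class.  Writes results/signals.tsv and
results/signals_grouped.tsv.
"""

import argparse
from pathlib import Path

from faerspv.cohort import DrugLexicon, build_cohort
from faerspv.dedup import deduplicate
from faerspv.disproportionality import (extract_facts, grouped_ror,
                                        scan_signals, write_signal_table)
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
    ap.add_argument("--min-count", type=int, default=5)
    args = ap.parse_args()

    bundles, _ = _stage02.load_universe(args.data_dir)
    retained = deduplicate(bundles).retained
    lexicon = DrugLexicon.glp1()
    cohort = build_cohort(retained, lexicon, SynthConfig().soc_map())
    cases = [r for r in cohort.reports if r.is_target_soc]

    facts = extract_facts(retained, lexicon)
    regimens = sorted({reg for f in facts for reg in f.ps_regimens})
    drug_sets = {"overall": None, **{r: [r] for r in regimens}}
    target_pts = sorted({pt for r in cases for pt in r.target_pts})
    results = scan_signals(facts, drug_sets, {pt: [pt] for pt in target_pts},
                           min_count=args.min_count)
    out = write_signal_table(results, args.results / "signals.tsv")
    signals = [r for r in results if r.is_signal]
    print(f"{len(results)} (drug set, PT) pairs scanned over "
          f"{len(target_pts)} target-SOC PTs -> {out}")
    print(f"{len(signals)} positive signals (count >= {args.min_count} "
          f"and ROR05 > 1):")
    for r in signals:
        print(f"  {r.drug_label} / {r.event_label}: a={r.table.a}, "
              f"ROR={r.ror:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")

    positive = [r.event_label for r in signals if r.drug_label == "overall"]
    if positive:
        grouped = [grouped_ror(facts, None, positive, drug_label="overall",
                               label="grouped_positive_pts",
                               min_count=args.min_count)]
        grouped += [grouped_ror(facts, [reg], positive, drug_label=reg,
                                label="grouped_positive_pts",
                                min_count=args.min_count)
                    for reg in regimens]
        out = write_signal_table(grouped, args.results / "signals_grouped.tsv")
        g = grouped[0]
        print(f"grouped category ({len(positive)} PTs as one event): "
              f"ROR={g.ror:.2f} (95% CI {g.ci_low:.2f}-{g.ci_high:.2f}) -> {out}")


if __name__ == "__main__":
    main()
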