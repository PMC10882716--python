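#!/usr/bin/env python
"""Time-to-onset of target-SOC events: per-regimen medians, bins, comparison.

Writes onset records, summaries and cumulative curves under results/onset/
and prints the Kruskal-Wallis / pairwise Mann-Whitney comparison.
"""

import argparse
from pathlib import Path

from faerspv.cohort import DrugLexicon, build_cohort
from faerspv.dedup import deduplicate
from faerspv.onset import (INCLUDED, MIN_INCLUDED, compare_onset,
                           compute_onsets, summarize_onset,
                           write_onset_outputs)
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
    cases = [r for r in cohort.reports if r.is_target_soc]

    records = compute_onsets(cases)
    summaries = summarize_onset(records)
    write_onset_outputs(records, summaries, args.results / "onset")
    overall = summaries["overall"]
    print(f"{overall.n_included} of {len(records)} target-SOC cases have a "
          f"usable onset (exclusions: {overall.exclusions})")
    if overall.median is not None:
        print(f"overall median onset {overall.median:.0f} d "
              f"(IQR {overall.iqr[0]:.1f}-{overall.iqr[1]:.1f}); "
              f"first 30 days: {overall.first_bin_share_pct}%")
    for reg, s in summaries.items():
        if reg == "overall":
            continue
        if s.insufficient:
            print(f"  {reg}: insufficient usable onsets (n={s.n_included})")
        else:
            print(f"  {reg}: median {s.median:.0f} d "
                  f"(IQR {s.iqr[0]:.1f}-{s.iqr[1]:.1f}), n={s.n_included}")

    groups = {reg: [r.onset_days for r in records
                    if r.regimen == reg and r.status == INCLUDED]
              for reg in {r.regimen for r in records}}
    groups = {k: v for k, v in groups.items() if len(v) >= MIN_INCLUDED}
    cmp = compare_onset(groups)
    if cmp.kruskal_p is not None:
        print(f"Kruskal-Wallis over {len(cmp.groups)} regimens: "
              f"H={cmp.kruskal_stat:.2f}, p={cmp.kruskal_p:.3g}")
        out = args.results / "onset" / "onset_comparison.tsv"
        cmp.pairwise.to_csv(out, sep="\t", index=False)
        print(f"pairwise Mann-Whitney (Holm-adjusted) -> {out}")
    if cmp.skipped:
        print("skipped groups:", cmp.skipped)


if __name__ == "__main__":
    main()
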