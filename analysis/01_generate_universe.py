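#!/usr/bin/env python
"""Generate the synthetic FAERS-like report universe used by stages 02-05.

Writes the six quarterly tables under a data directory (large, scratch by
default) and a small ground-truth summary under results/, so later stages can
be audited against what was planted.
"""

import argparse
import json
from pathlib import Path

from faerspv.disproportionality import compute_ror
from faerspv.synth import SynthConfig, generate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cases", type=int, default=20_000)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/universe"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SynthConfig(seed=args.seed, n_cases=args.n_cases)
    paths, truth = generate(cfg, args.data_dir)
    print(f"wrote {len(paths)} tables under {args.data_dir}")
    print(f"cases: {cfg.n_cases}  report versions incl. duplicates: "
          f"{sum(1 for _ in open(paths['demo'])) - 1}")
    print(f"planted cohort: {len(truth.cohort_caseids)} cases "
          f"({len(truth.target_soc_caseids)} with a target-SOC event)")

    rows = {}
    for pt, table in truth.planted_tables.items():
        est = compute_ror(table)
        rows[pt] = {"a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "constructed_ror": None if est is None else round(est[0], 3),
                    "constructed_ror05": None if est is None else round(est[1], 3)}
    args.results.mkdir(parents=True, exist_ok=True)
    out = args.results / "ground_truth_summary.json"
    with open(out, "w") as fh:
        json.dump({"seed": cfg.seed, "n_cases": cfg.n_cases,
                   "survivor_count": len(truth.survivors),
                   "planted_tables": rows}, fh, indent=2)
        fh.write("\n")
    print(f"planted-association ground truth -> {out}")
    expected = truth.planted_expected_signals()
    print(f"planted PTs meeting both positivity criteria by construction: "
          f"{len(expected)}: {sorted(expected)}")


if __name__ == "__main__":
    main()
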