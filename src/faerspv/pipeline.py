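"""End-to-end pipeline: read -> dedup -> cohort -> descriptives | onset | signals.

The pipeline is driven by a :class:`PipelineConfig` (loadable from YAML) and
writes every artifact under one output directory together with a manifest
recording row counts, the attrition flow (raw -> deduplicated -> cohort ->
target-SOC cases) and a hash of the configuration, so any artifact can be
re-derived from manifest + config.

Input is either a FAERS-style quarter directory or a synthetic universe
generated on the fly from embedded generator settings (the usual test and
demo route).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import dedup as _dedup
from . import descriptives as _desc
from . import disproportionality as _dispro
from . import onset as _onset
from . import synth as _synth
from .cohort import DrugLexicon, PSYCHIATRIC_SOC, PtSocMap, build_cohort
from .io import ALL_TABLES, read_quarter

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str = "out"
    seed: int = 0
    quarter_dir: str | None = None        # existing FAERS-style tables, or...
    synth: dict | None = None             # ...generator overrides (synthetic run)
    lexicon_path: str | None = None       # TSV; None = built-in GLP-1 RA lexicon
    soc_map_path: str | None = None       # TSV; None = synthetic catalog map
    target_soc: str = PSYCHIATRIC_SOC
    min_count: int = 5
    z: float = 1.96
    quantile_method: str = "linear"
    comparator: str = "full"              # full | class_exclusive
    delimiter: str = "$"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.quarter_dir is None and self.synth is None:
            raise ValueError("config needs either quarter_dir or synth settings")
        if self.quarter_dir is not None and not Path(self.quarter_dir).is_dir():
            raise ValueError(f"quarter_dir does not exist: {self.quarter_dir}")
        for attr in ("lexicon_path", "soc_map_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).is_file():
                raise ValueError(f"{attr} does not exist: {p}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.comparator not in ("full", "class_exclusive"):
            raise ValueError("comparator must be 'full' or 'class_exclusive'")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Manifest:
    config_hash: str
    attrition: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, dict] = field(default_factory=dict)  # name -> {path, rows}

    def add(self, name: str, path: Path, rows: int) -> None:
        self.outputs[name] = {"path": str(path), "rows": int(rows)}

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash,
                       "attrition": self.attrition,
                       "outputs": self.outputs}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _synth_config(cfg: PipelineConfig) -> _synth.SynthConfig:
    overrides: Mapping[str, Any] = cfg.synth or {}
    base = _synth.SynthConfig(seed=cfg.seed)
    return dataclasses.replace(base, **overrides)


def run_pipeline(cfg: PipelineConfig) -> Manifest:
    """Run every stage in order; returns the output manifest.

    Raises on validation failure before any computation; stage failures
    propagate (the CLI maps them to a non-zero exit status).
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config_hash=cfg.config_hash())

    # --- acquire ---
    if cfg.quarter_dir is not None:
        paths = {t: Path(cfg.quarter_dir) / f"{t}.txt" for t in ALL_TABLES
                 if (Path(cfg.quarter_dir) / f"{t}.txt").exists()}
    else:
        synth_cfg = _synth_config(cfg)
        paths, _truth = _synth.generate(synth_cfg, out / "universe",
                                        delimiter=cfg.delimiter)
        logger.info("synthetic universe generated under %s", out / "universe")
    bundles, read_report = read_quarter(paths, delimiter=cfg.delimiter)
    manifest.attrition["raw_reports"] = len(bundles)
    logger.info("read %d report versions (%d rows quarantined)",
                len(bundles), read_report.n_quarantined)

    # --- dedup ---
    dres = _dedup.deduplicate(bundles)
    audit = dres.write_audit(out / "dedup_audit.tsv")
    manifest.add("dedup_audit", audit, len(dres.decisions))
    manifest.attrition["deduplicated_reports"] = len(dres.retained)

    # --- cohort ---
    lexicon = (DrugLexicon.from_tsv(cfg.lexicon_path)
               if cfg.lexicon_path else DrugLexicon.glp1())
    if cfg.soc_map_path:
        soc_map = PtSocMap.from_tsv(cfg.soc_map_path)
    elif cfg.synth is not None or cfg.quarter_dir is None:
        soc_map = _synth_config(cfg).soc_map()
    else:
        raise ValueError("soc_map_path is required when reading real quarters")
    cohort = build_cohort(dres.retained, lexicon, soc_map,
                          target_soc=cfg.target_soc)
    manifest.attrition["cohort_reports"] = cohort.n
    manifest.attrition["target_soc_cases"] = cohort.n_target_soc
    logger.info("attrition: %s", manifest.attrition)

    # --- descriptives ---
    table = _desc.summarize_cohort(cohort, target_only=True,
                                   quantile_method=cfg.quantile_method)
    for p in table.write(out / "characteristics"):
        manifest.add(p.stem, p, sum(1 for _ in open(p)) - 1)
    share = _desc.soc_share_table(cohort)
    p = out / "soc_share.tsv"
    share.to_csv(p, sep="\t", index=False)
    manifest.add("soc_share", p, len(share))

    # --- onset ---
    cases = [r for r in cohort.reports if r.is_target_soc]
    records = _onset.compute_onsets(cases)
    summaries = _onset.summarize_onset(records,
                                       quantile_method=cfg.quantile_method)
    for p in _onset.write_onset_outputs(records, summaries, out / "onset"):
        manifest.add(p.stem, p, sum(1 for _ in open(p)) - 1)
    groups = {reg: [r.onset_days for r in records
                    if r.regimen == reg and r.status == _onset.INCLUDED]
              for reg in {r.regimen for r in records}}
    groups = {k: v for k, v in groups.items()
              if len(v) >= _onset.MIN_INCLUDED}
    comparison = _onset.compare_onset(groups)
    p = out / "onset" / "onset_comparison.tsv"
    comparison.pairwise.to_csv(p, sep="\t", index=False)
    manifest.add("onset_comparison", p, len(comparison.pairwise))

    # --- signals ---
    facts = _dispro.extract_facts(dres.retained, lexicon)
    regimens = sorted({reg for f in facts for reg in f.ps_regimens})
    drug_sets: dict[str, Any] = {"overall": None}
    drug_sets.update({reg: [reg] for reg in regimens})
    target_pts = sorted({pt for r in cases for pt in r.target_pts})
    event_sets = {pt: [pt] for pt in target_pts}
    results = _dispro.scan_signals(
        facts, drug_sets, event_sets, min_count=cfg.min_count, z=cfg.z,
        class_exclusive=(cfg.comparator == "class_exclusive"))
    p = _dispro.write_signal_table(results, out / "signals.tsv")
    manifest.add("signals", p, len(results))

    # grouped category: the overall drug set's positive PTs as one event
    positive_pts = [r.event_label for r in results
                    if r.drug_label == "overall" and r.is_signal]
    if positive_pts:
        grouped = [_dispro.grouped_ror(facts, None, positive_pts,
                                       label="grouped_positive_pts",
                                       drug_label="overall",
                                       min_count=cfg.min_count, z=cfg.z)]
        grouped += [_dispro.grouped_ror(facts, [reg], positive_pts,
                                        label="grouped_positive_pts",
                                        drug_label=reg,
                                        min_count=cfg.min_count, z=cfg.z)
                    for reg in regimens]
        p = _dispro.write_signal_table(grouped, out / "signals_grouped.tsv")
        manifest.add("signals_grouped", p, len(grouped))

    mpath = manifest.write(out / "manifest.json")
    logger.info("manifest written to %s", mpath)
    return manifest
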