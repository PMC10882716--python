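"""Synthetic FAERS-like report universe with known ground truth.

The generator emits a quarterly file bundle (DEMO/DRUG/REAC/OUTC/THER/INDI)
that parses with :mod:`faerspv.io`, together with a :class:`GroundTruth`
object recording exactly what was planted: which report version must survive
de-duplication, which cases belong to the target-drug cohort, the exact 2x2
contingency cells behind every planted drug-event association, and every
case's true time-to-onset before date corruption.  Identical configs produce
byte-identical files.

The defaults emulate the GLP-1 receptor agonist psychiatric-AE case series:
the six-regimen mix follows the published per-regimen report shares, sex /
region / occupation / indication / outcome margins follow the published case
series, and per-regimen onset distributions are log-normal with the published
medians and IQR-derived scales.  The universe itself is scaled to desk size
(tens of thousands of reports rather than sixteen million), and planted
signal-event background rates are raised accordingly so that planted
associations remain detectable at that scale; both choices are documented in
the methods note.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import GLP1_LEXICON, PSYCHIATRIC_SOC, PSYCHIATRIC_SOC_CODE, PtSocMap
from .disproportionality import ContingencyTable
from .io import (DemoRecord, DrugRecord, IndiRecord, OutcRecord, ReacRecord,
                 ReportBundle, TherRecord, parse_date, write_quarter)

# normal quartile deviate: q75/q25 of a log-normal = exp(2 * z25 * sigma)
_Z25 = 0.6744897501960817

# ---------------------------------------------------------------------------
# Default catalogs (the study conditions)
# ---------------------------------------------------------------------------

#: The eight planted signal PTs with their published reporting odds ratios.
PLANTED_ROR: dict[str, float] = {
    "NERVOUSNESS": 1.97,
    "STRESS": 1.28,
    "EATING DISORDER": 1.57,
    "FEAR OF INJECTION": 1.96,
    "SLEEP DISORDER DUE TO GENERAL MEDICAL CONDITION-INSOMNIA TYPE": 2.01,
    "BINGE EATING": 2.70,
    "FEAR OF EATING": 3.35,
    "SELF-INDUCED VOMITING": 3.77,
}

_PSY = (PSYCHIATRIC_SOC, PSYCHIATRIC_SOC_CODE)
_GI = ("gastrointestinal disorders", "10017947")
_NERV = ("nervous system disorders", "10029205")
_GEN = ("general disorders and administration site conditions", "10018065")
_META = ("metabolism and nutrition disorders", "10027433")
_SKIN = ("skin and subcutaneous tissue disorders", "10040785")
_MUSC = ("musculoskeletal and connective tissue disorders", "10028395")
_INV = ("investigations", "10022891")
_RESP = ("respiratory, thoracic and mediastinal disorders", "10038738")

#: PT -> (SOC name, SOC code, comparator-arm report rate).  Planted PTs carry
#: elevated target-arm odds; every other PT is a null (identical rates in
#: both arms).  >=40 null PTs so scans have realistic breadth.
DEFAULT_PT_CATALOG: dict[str, tuple[str, str, float]] = {
    # planted psychiatric signal PTs
    "NERVOUSNESS": (*_PSY, 0.0040),
    "STRESS": (*_PSY, 0.0050),
    "EATING DISORDER": (*_PSY, 0.0030),
    "FEAR OF INJECTION": (*_PSY, 0.0020),
    "SLEEP DISORDER DUE TO GENERAL MEDICAL CONDITION-INSOMNIA TYPE": (*_PSY, 0.0018),
    "BINGE EATING": (*_PSY, 0.0015),
    "FEAR OF EATING": (*_PSY, 0.0012),
    "SELF-INDUCED VOMITING": (*_PSY, 0.0010),
    # frequent null psychiatric PTs
    "INSOMNIA": (*_PSY, 0.0060),
    "ANXIETY": (*_PSY, 0.0050),
    "DEPRESSION": (*_PSY, 0.0040),
    "CONFUSIONAL STATE": (*_PSY, 0.0030),
    # null psychiatric background
    "IRRITABILITY": (*_PSY, 0.0012), "AGITATION": (*_PSY, 0.0012),
    "PANIC ATTACK": (*_PSY, 0.0010), "HALLUCINATION": (*_PSY, 0.0010),
    "SUICIDAL IDEATION": (*_PSY, 0.0010), "MOOD SWINGS": (*_PSY, 0.0010),
    "RESTLESSNESS": (*_PSY, 0.0010), "APATHY": (*_PSY, 0.0008),
    "BRUXISM": (*_PSY, 0.0008), "NIGHTMARE": (*_PSY, 0.0008),
    "ABNORMAL DREAMS": (*_PSY, 0.0008), "EMOTIONAL DISTRESS": (*_PSY, 0.0008),
    "DEPRESSED MOOD": (*_PSY, 0.0010), "ANGER": (*_PSY, 0.0008),
    "DELIRIUM": (*_PSY, 0.0008), "PSYCHOTIC DISORDER": (*_PSY, 0.0006),
    "LIBIDO DECREASED": (*_PSY, 0.0006), "TEARFULNESS": (*_PSY, 0.0006),
    "DISORIENTATION": (*_PSY, 0.0008), "LISTLESS": (*_PSY, 0.0005),
    # null non-psychiatric background
    "NAUSEA": (*_GI, 0.0300), "VOMITING": (*_GI, 0.0200),
    "DIARRHOEA": (*_GI, 0.0180), "ABDOMINAL PAIN": (*_GI, 0.0100),
    "CONSTIPATION": (*_GI, 0.0080), "DYSPEPSIA": (*_GI, 0.0060),
    "PANCREATITIS": (*_GI, 0.0030),
    "HEADACHE": (*_NERV, 0.0150), "DIZZINESS": (*_NERV, 0.0120),
    "DYSGEUSIA": (*_NERV, 0.0030), "TREMOR": (*_NERV, 0.0040),
    "FATIGUE": (*_GEN, 0.0150), "INJECTION SITE PAIN": (*_GEN, 0.0080),
    "PYREXIA": (*_GEN, 0.0060), "MALAISE": (*_GEN, 0.0070),
    "HYPOGLYCAEMIA": (*_META, 0.0080), "DECREASED APPETITE": (*_META, 0.0100),
    "DEHYDRATION": (*_META, 0.0040),
    "RASH": (*_SKIN, 0.0080), "PRURITUS": (*_SKIN, 0.0060),
    "ALOPECIA": (*_SKIN, 0.0040),
    "ARTHRALGIA": (*_MUSC, 0.0070), "MYALGIA": (*_MUSC, 0.0050),
    "WEIGHT DECREASED": (*_INV, 0.0120), "BLOOD GLUCOSE INCREASED": (*_INV, 0.0060),
    "COUGH": (*_RESP, 0.0050), "DYSPNOEA": (*_RESP, 0.0060),
}

#: Per-regimen share of all target-drug reports (published all-AE mix).
DEFAULT_REGIMEN_MIX: dict[str, float] = {
    "exenatide": 0.399, "liraglutide": 0.160, "lixisenatide": 0.002,
    "dulaglutide": 0.288, "semaglutide": 0.098, "tirzepatide": 0.053,
}

#: Per-regimen log-normal onset model (median days, log-scale sigma).  The
#: medians are the published per-regimen medians; sigma is derived from the
#: published IQRs via q75/q25 = exp(2 * 0.6745 * sigma).
DEFAULT_ONSET_PARAMS: dict[str, tuple[float, float]] = {
    "exenatide": (45.0, math.log(212.5 / 11.0) / (2 * _Z25)),
    "liraglutide": (16.0, math.log(61.0 / 5.5) / (2 * _Z25)),
    "lixisenatide": (31.0, math.log(145.4 / 7.0) / (2 * _Z25)),
    "dulaglutide": (7.0, math.log(9.0 / 2.0) / (2 * _Z25)),
    "semaglutide": (12.0, math.log(45.5 / 4.0) / (2 * _Z25)),
    "tirzepatide": (10.0, math.log(35.5 / 2.0) / (2 * _Z25)),
}

BACKGROUND_DRUGS = (
    "METFORMIN", "ASPIRIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE",
    "AMLODIPINE", "LEVOTHYROXINE", "GABAPENTIN", "SERTRALINE", "IBUPROFEN",
    "INSULIN GLARGINE", "WARFARIN", "PREDNISONE", "ADALIMUMAB", "RIVAROXABAN",
    "HYDROCHLOROTHIAZIDE", "LOSARTAN", "SIMVASTATIN", "PANTOPRAZOLE",
    "METOPROLOL",
)

INDICATION_PTS = {
    "diabetes": "TYPE 2 DIABETES MELLITUS",
    "weight": "WEIGHT CONTROL",
    "glucose": "BLOOD GLUCOSE ABNORMAL",
    "others": "HYPERTENSION",
    "unknown": "PRODUCT USED FOR UNKNOWN INDICATION",
}

_EPOCH = _dt.date(2004, 1, 1)
_LAST = _dt.date(2023, 3, 31)


# ---------------------------------------------------------------------------
# Config / ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for one synthetic universe.

    Distributions default to the published case-series margins (sex, region,
    occupation, indication, outcome, onset-status attrition); sizes and
    planted-event rates are desk-scale choices.
    """

    seed: int = 0
    n_cases: int = 20_000
    # duplicate versioning
    duplicate_rate: float = 0.15
    duplicate_tie_rate: float = 0.30     # duplicate keeps the same fda_dt
    duplicate_extra_rate: float = 0.20   # a duplicated case gets a 3rd version
    # target drug assignment
    target_drug_prob: float = 0.08
    ps_role_prob: float = 0.90           # target drug reported as primary suspect
    brand_name_prob: float = 0.40
    regimen_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGIMEN_MIX))
    # events
    pt_catalog: Mapping[str, tuple[str, str, float]] = field(
        default_factory=lambda: dict(DEFAULT_PT_CATALOG))
    planted_log_ror: Mapping[str, float] = field(
        default_factory=lambda: {pt: math.log(r) for pt, r in PLANTED_ROR.items()})
    # onset model and date corruption
    onset_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ONSET_PARAMS))
    onset_status_probs: Mapping[str, float] = field(default_factory=lambda: {
        "included": 0.183,               # published usable-onset attrition
        "excluded_missing": 0.777,
        "excluded_invalid_order": 0.020,
        "excluded_nonpositive": 0.020,
    })
    partial_date_share: float = 0.15     # of missing-date cases: partial, not absent
    # demographics (published case-series margins)
    sex_dist: Mapping[str, float] = field(default_factory=lambda: {
        "F": 0.659, "M": 0.310, "": 0.031})
    age_known_rate: float = 0.0347
    age_mean: float = 57.0
    age_sd: float = 14.0
    country_dist: Mapping[str, float] = field(default_factory=lambda: {
        "US": 0.915, "CA": 0.016, "GB": 0.009, "DE": 0.008, "FR": 0.008,
        "JP": 0.008, "CN": 0.008, "BR": 0.008, "AU": 0.006, "ZA": 0.001,
        "": 0.013})
    occp_dist: Mapping[str, float] = field(default_factory=lambda: {
        "CN": 0.798, "MD": 0.084, "PH": 0.017, "HP": 0.020, "OT": 0.025,
        "LW": 0.002, "": 0.054})
    outcome_dist: Mapping[str, float] = field(default_factory=lambda: {
        "HO": 0.107, "OT": 0.129, "DE": 0.010, "LT": 0.005, "DS": 0.013,
        "CA": 0.0005, "RI": 0.002, "": 0.7335})
    indication_dist: Mapping[str, float] = field(default_factory=lambda: {
        "diabetes": 0.641, "weight": 0.040, "glucose": 0.010, "others": 0.032,
        "unknown": 0.277})
    concomitant_prob: float = 0.40

    def soc_map(self) -> PtSocMap:
        """The PT->SOC fixture map implied by the catalog."""
        return PtSocMap.from_pairs(
            {pt: (soc, code) for pt, (soc, code, _) in self.pt_catalog.items()})

    def psychiatric_pts(self) -> frozenset[str]:
        return frozenset(pt for pt, (soc, _, _) in self.pt_catalog.items()
                         if soc == PSYCHIATRIC_SOC)


@dataclass
class OnsetTruth:
    caseid: str
    regimen: str
    status: str          # the emitted status, realized by date construction
    true_days: int       # pre-censoring onset draw (always >= 1)
    is_target_soc: bool


@dataclass
class GroundTruth:
    """Exact bookkeeping of what was planted, keyed to surviving versions."""

    survivors: dict[str, str]                       # caseid -> kept primaryid
    cohort_caseids: frozenset[str]                  # PS-matched target cases
    target_soc_caseids: frozenset[str]              # cohort cases with a target-SOC PT
    planted_tables: dict[str, ContingencyTable]     # planted PT -> exact 2x2
    grouped_table: ContingencyTable | None          # all planted PTs as one category
    onsets: list[OnsetTruth]
    regimen_counts: dict[str, int]                  # cohort cases per regimen

    def planted_expected_signals(self, min_count: int = 5) -> list[str]:
        """Planted PTs whose *constructed* cells meet both positivity criteria."""
        from .disproportionality import compute_ror
        out = []
        for pt, table in self.planted_tables.items():
            est = compute_ror(table)
            if est is not None and table.a >= min_count and est[1] > 1.0:
                out.append(pt)
        return out


def validate(config: SynthConfig) -> None:
    """Reject infeasible configs before anything is generated."""
    if config.n_cases <= 0:
        raise ValueError("n_cases must be positive")
    for name in ("duplicate_rate", "duplicate_tie_rate", "duplicate_extra_rate",
                 "target_drug_prob", "ps_role_prob", "brand_name_prob",
                 "age_known_rate", "partial_date_share", "concomitant_prob"):
        v = getattr(config, name)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    for name in ("regimen_mix", "sex_dist", "country_dist", "occp_dist",
                 "outcome_dist", "indication_dist", "onset_status_probs"):
        dist = getattr(config, name)
        if any(p < 0 for p in dist.values()):
            raise ValueError(f"{name} has a negative probability")
        if abs(sum(dist.values()) - 1.0) > 1e-6:
            raise ValueError(f"{name} weights must sum to 1")
    for reg in config.regimen_mix:
        if reg not in config.onset_params:
            raise ValueError(f"no onset parameters for regimen {reg!r}")
    for pt, logror in config.planted_log_ror.items():
        if pt not in config.pt_catalog:
            raise ValueError(f"planted PT {pt!r} not in catalog")
        if not math.isfinite(logror):
            raise ValueError(f"planted log-ROR for {pt!r} must be finite")
        rate = config.pt_catalog[pt][2]
        odds = rate / (1 - rate) * math.exp(logror)
        if odds / (1 + odds) > 0.95:
            # a planted event carried by essentially every target report is
            # outside the spontaneous-reporting regime the generator emulates
            raise ValueError(f"planted rate for {pt!r} is infeasible")
    for pt, (_, _, rate) in config.pt_catalog.items():
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"background rate for {pt!r} out of range")


# ---------------------------------------------------------------------------
# Duplicate planting
# ---------------------------------------------------------------------------

def _reversion(bundle: ReportBundle, new_pid: str, new_fda_raw: str,
               drop_last_reaction: bool) -> ReportBundle:
    """A version of ``bundle`` under a different primaryid / receipt date."""
    demo = dataclasses.replace(bundle.demo, primaryid=new_pid,
                               fda_dt=parse_date(new_fda_raw))
    reactions = bundle.reactions[:-1] if (drop_last_reaction and
                                          len(bundle.reactions) > 1) else bundle.reactions
    repid = lambda r: dataclasses.replace(r, primaryid=new_pid)
    return ReportBundle(
        demo=demo,
        drugs=[repid(r) for r in bundle.drugs],
        reactions=[repid(r) for r in reactions],
        therapies=[repid(r) for r in bundle.therapies],
        outcomes=[repid(r) for r in bundle.outcomes],
        indications=[repid(r) for r in bundle.indications],
    )


def plant_duplicates(
    bundles: Sequence[ReportBundle],
    rate: float,
    rng: np.random.Generator | int,
    tie_rate: float = 0.30,
    extra_rate: float = 0.20,
) -> tuple[list[ReportBundle], dict[str, str]]:
    """Version a fraction of cases; return all versions plus survivors.

    Each duplicated case gains one (or, with ``extra_rate``, two) later
    versions carrying a later-or-equal ``fda_dt`` and a strictly larger
    ``primaryid`` (digits appended, so numeric order is preserved).  Earlier
    versions may drop their last reaction, mimicking resubmission corrections.
    The returned mapping records the version de-duplication must keep; the
    full content always lives on that surviving version.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out: list[ReportBundle] = []
    survivors: dict[str, str] = {}
    for b in bundles:
        if rng.random() >= rate:
            out.append(b)
            survivors[b.caseid] = b.primaryid
            continue
        n_extra = 2 if rng.random() < extra_rate else 1
        fda = b.demo.fda_dt.to_date() or _EPOCH
        versions = [b]
        pid = b.primaryid
        for k in range(n_extra):
            pid = pid + str(k + 2)
            if rng.random() >= tie_rate:
                fda = fda + _dt.timedelta(days=int(rng.integers(1, 121)))
            versions.append(_reversion(b, pid, fda.strftime("%Y%m%d"),
                                       drop_last_reaction=False))
        # survivor is the last version; earlier ones may be truncated
        for v in versions[:-1]:
            if rng.random() < 0.5:
                v = _reversion(v, v.primaryid, v.demo.fda_dt.raw,
                               drop_last_reaction=True)
            out.append(v)
        out.append(versions[-1])
        survivors[b.caseid] = versions[-1].primaryid
    return out, survivors


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(dist)
    p = np.asarray([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(keys, dtype=object), size=n, p=p)


def _date_str(d: _dt.date) -> str:
    return d.strftime("%Y%m%d")


def sample_onset_days(rng: np.random.Generator, median: float, sigma: float,
                      n: int) -> np.ndarray:
    """Integer onset days >= 1 from a log-normal with the given median."""
    draws = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.maximum(1, np.rint(draws)).astype(int)


def generate_bundles(config: SynthConfig) -> tuple[list[ReportBundle], GroundTruth]:
    """Build every report version (pre-dedup) plus exact ground truth."""
    validate(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    regimens = list(config.regimen_mix)
    pts = list(config.pt_catalog)
    psych = config.psychiatric_pts()
    base_rates = np.asarray([config.pt_catalog[pt][2] for pt in pts])
    target_rates = base_rates.copy()
    for i, pt in enumerate(pts):
        logror = config.planted_log_ror.get(pt)
        if logror is not None:
            odds = base_rates[i] / (1 - base_rates[i]) * math.exp(logror)
            target_rates[i] = odds / (1 + odds)

    # --- per-case draws (fixed order => determinism) ---
    is_target = rng.random(n) < config.target_drug_prob
    regimen_idx = rng.choice(len(regimens), size=n,
                             p=np.asarray(list(config.regimen_mix.values()))
                             / sum(config.regimen_mix.values()))
    is_ps = rng.random(n) < config.ps_role_prob
    use_brand = rng.random(n) < config.brand_name_prob
    sex = _choice(rng, config.sex_dist, n)
    age_known = rng.random(n) < config.age_known_rate
    ages = np.clip(np.rint(rng.normal(config.age_mean, config.age_sd, n)), 18, 95)
    country = _choice(rng, config.country_dist, n)
    occp = _choice(rng, config.occp_dist, n)
    outcome = _choice(rng, config.outcome_dist, n)
    indication = _choice(rng, config.indication_dist, n)
    fda_offset = rng.integers(365, (_LAST - _EPOCH).days + 1, size=n)
    onset_status = _choice(rng, config.onset_status_probs, n)
    med = np.asarray([config.onset_params[r][0] for r in regimens])
    sig = np.asarray([config.onset_params[r][1] for r in regimens])
    # clip the heavy log-normal tail at ~16 years so therapy start dates stay
    # on the calendar; the 360+ bin is unaffected
    true_onsets = np.clip(np.rint(rng.lognormal(
        mean=np.log(med)[regimen_idx], sigma=sig[regimen_idx])),
        1, 6_000).astype(int)
    start_lag = rng.integers(0, 91, size=n)

    # event membership per case (row = case, col = PT)
    u = rng.random((n, len(pts)))
    in_drug_arm = is_target & is_ps
    rates = np.where(in_drug_arm[:, None], target_rates[None, :],
                     base_rates[None, :])
    has_pt = u < rates
    # Reports that drew no PT get one baseline event.  The fallback pool is
    # restricted to non-target-SOC null PTs so that planted (and null)
    # target-SOC PT memberships stay exactly Bernoulli with the planted odds
    # in each arm — the fallback never touches an analyzed event rate.
    none_rows = np.flatnonzero(~has_pt.any(axis=1))
    pool = np.asarray([j for j, pt in enumerate(pts)
                       if config.pt_catalog[pt][0] != PSYCHIATRIC_SOC])
    if pool.size == 0:
        pool = np.arange(len(pts))
    pool_w = base_rates[pool] / base_rates[pool].sum()
    fallback = pool[rng.choice(pool.size, size=none_rows.size, p=pool_w)]
    has_pt[none_rows, fallback] = True

    # auxiliary draws for non-target date fields and concomitants
    aux_event = rng.random(n)
    aux_start = rng.random(n)
    missing_side = rng.random(n)          # which side goes missing
    partial_draw = rng.random(n)
    invalid_gap = rng.integers(1, 61, size=n)
    concomitant = rng.random(n) < config.concomitant_prob
    bg_drug_idx = rng.integers(0, len(BACKGROUND_DRUGS), size=n)
    bg_drug2_idx = rng.integers(0, len(BACKGROUND_DRUGS), size=n)
    brand_pick = rng.random(n)
    indi_emit = rng.random(n)

    bundles: list[ReportBundle] = []
    onset_truth: list[OnsetTruth] = []
    cohort_cases: list[str] = []
    target_soc_cases: list[str] = []
    regimen_counts: dict[str, int] = {r: 0 for r in regimens}
    # survivor-level facts for exact contingency bookkeeping
    fact_in_drug: list[bool] = []
    fact_pts: list[frozenset[str]] = []

    for i in range(n):
        caseid = str(100_000_001 + i)
        pid = caseid + "1"
        fda_date = _EPOCH + _dt.timedelta(days=int(fda_offset[i]))
        case_pts = frozenset(pts[j] for j in np.flatnonzero(has_pt[i]))
        target = bool(is_target[i])
        ps = bool(is_ps[i])
        regimen = regimens[regimen_idx[i]]

        event_raw = ""
        drugs: list[DrugRecord] = []
        thers: list[TherRecord] = []
        indis: list[IndiRecord] = []

        if target:
            generic = regimen
            brands = GLP1_LEXICON[generic]
            if use_brand[i] and brands:
                name = brands[int(brand_pick[i] * len(brands)) % len(brands)]
            else:
                name = generic.upper()
            role = "PS" if ps else ("C" if brand_pick[i] < 0.5 else "SS")
            drugs.append(DrugRecord(primaryid=pid, drug_seq="1", drugname=name,
                                    prod_ai=generic.upper(), role_cod=role))
            # therapy/event dates realizing the drawn onset status
            status = str(onset_status[i])
            onset = int(true_onsets[i])
            start = fda_date - _dt.timedelta(days=onset + int(start_lag[i]))
            event = start + _dt.timedelta(days=onset)
            start_raw = _date_str(start)
            event_raw = _date_str(event)
            if not ps:
                status = "excluded_missing"  # never enters onset analysis
            elif status == "excluded_missing":
                if missing_side[i] < 0.45:
                    event_raw = (event.strftime("%Y%m")
                                 if partial_draw[i] < config.partial_date_share
                                 else "")
                elif missing_side[i] < 0.85:
                    start_raw = (start.strftime("%Y%m")
                                 if partial_draw[i] < config.partial_date_share
                                 else "")
                else:
                    start_raw = ""
                    event_raw = ""
            elif status == "excluded_invalid_order":
                event = start - _dt.timedelta(days=int(invalid_gap[i]))
                event_raw = _date_str(event)
            elif status == "excluded_nonpositive":
                event = start
                event_raw = _date_str(event)
            if start_raw:
                thers.append(TherRecord(primaryid=pid, dsg_drug_seq="1",
                                        start_dt=parse_date(start_raw),
                                        end_dt=parse_date("")))
            if concomitant[i]:
                drugs.append(DrugRecord(
                    primaryid=pid, drug_seq="2",
                    drugname=BACKGROUND_DRUGS[bg_drug_idx[i]], prod_ai="",
                    role_cod="C"))
            if ps:
                onset_truth.append(OnsetTruth(
                    caseid=caseid, regimen=regimen,
                    status=str(onset_status[i]), true_days=onset,
                    is_target_soc=bool(case_pts & psych)))
                cohort_cases.append(caseid)
                regimen_counts[regimen] += 1
                if case_pts & psych:
                    target_soc_cases.append(caseid)
            ind_key = str(indication[i])
            if ps and (ind_key != "unknown" or indi_emit[i] < 0.5):
                indis.append(IndiRecord(primaryid=pid, indi_drug_seq="1",
                                        indi_pt=INDICATION_PTS[ind_key]))
        else:
            drugs.append(DrugRecord(
                primaryid=pid, drug_seq="1",
                drugname=BACKGROUND_DRUGS[bg_drug_idx[i]], prod_ai="",
                role_cod="PS" if brand_pick[i] < 0.95 else "SS"))
            if concomitant[i]:
                drugs.append(DrugRecord(
                    primaryid=pid, drug_seq="2",
                    drugname=BACKGROUND_DRUGS[bg_drug2_idx[i]], prod_ai="",
                    role_cod="C"))
            if aux_event[i] < 0.40:
                event_raw = _date_str(fda_date - _dt.timedelta(
                    days=int(start_lag[i]) + 1))
            if aux_start[i] < 0.50:
                start = fda_date - _dt.timedelta(
                    days=int(start_lag[i]) + int(true_onsets[i]))
                thers.append(TherRecord(primaryid=pid, dsg_drug_seq="1",
                                        start_dt=parse_date(_date_str(start)),
                                        end_dt=parse_date("")))
            if indi_emit[i] < 0.6:
                indis.append(IndiRecord(primaryid=pid, indi_drug_seq="1",
                                        indi_pt="HYPERTENSION"))

        demo = DemoRecord(
            primaryid=pid, caseid=caseid,
            fda_dt=parse_date(_date_str(fda_date)),
            event_dt=parse_date(event_raw),
            sex=str(sex[i]),
            age=float(ages[i]) if age_known[i] else None,
            age_cod="YR" if age_known[i] else "",
            reporter_country=str(country[i]),
            occp_cod=str(occp[i]),
        )
        reactions = [ReacRecord(primaryid=pid, pt=pt.title())
                     for pt in sorted(case_pts)]
        outcomes = ([OutcRecord(primaryid=pid, outc_cod=str(outcome[i]))]
                    if outcome[i] else [])
        bundles.append(ReportBundle(demo=demo, drugs=drugs, reactions=reactions,
                                    therapies=thers, outcomes=outcomes,
                                    indications=indis))
        fact_in_drug.append(target and ps)
        fact_pts.append(case_pts)

    # exact planted contingency tables over the surviving (case-level) universe
    in_drug = np.asarray(fact_in_drug)
    planted_tables: dict[str, ContingencyTable] = {}
    for pt in config.planted_log_ror:
        has = np.asarray([pt in s for s in fact_pts])
        planted_tables[pt] = ContingencyTable(
            a=int((in_drug & has).sum()), b=int((in_drug & ~has).sum()),
            c=int((~in_drug & has).sum()), d=int((~in_drug & ~has).sum()))
    grouped = None
    if config.planted_log_ror:
        group = frozenset(config.planted_log_ror)
        has = np.asarray([bool(s & group) for s in fact_pts])
        grouped = ContingencyTable(
            a=int((in_drug & has).sum()), b=int((in_drug & ~has).sum()),
            c=int((~in_drug & has).sum()), d=int((~in_drug & ~has).sum()))

    versioned, survivors = plant_duplicates(
        bundles, config.duplicate_rate, rng,
        tie_rate=config.duplicate_tie_rate,
        extra_rate=config.duplicate_extra_rate)

    truth = GroundTruth(
        survivors=survivors,
        cohort_caseids=frozenset(cohort_cases),
        target_soc_caseids=frozenset(target_soc_cases),
        planted_tables=planted_tables,
        grouped_table=grouped,
        onsets=onset_truth,
        regimen_counts=regimen_counts,
    )
    return versioned, truth


def generate(config: SynthConfig, directory: str | Path,
             delimiter: str = "$") -> tuple[dict[str, Path], GroundTruth]:
    """Generate a quarterly file bundle on disk; returns paths + ground truth.

    Same config => byte-identical files.
    """
    versioned, truth = generate_bundles(config)
    paths = write_quarter(versioned, directory, delimiter=delimiter)
    return paths, truth


def write_soc_map(config: SynthConfig, path: str | Path) -> Path:
    """Write the catalog's PT->SOC fixture map as a TSV config file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("pt\tsoc\tsoc_code\n")
        for pt, (soc, code, _) in config.pt_catalog.items():
            fh.write(f"{pt}\t{soc}\t{code}\n")
    return path


def write_lexicon(path: str | Path,
                  mapping: Mapping[str, Iterable[str]] | None = None) -> Path:
    """Write a regimen/name lexicon TSV (defaults to the GLP-1 RA lexicon)."""
    mapping = mapping if mapping is not None else GLP1_LEXICON
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("regimen\tname\n")
        for regimen, names in mapping.items():
            fh.write(f"{regimen}\t{regimen.upper()}\n")
            for name in names:
                fh.write(f"{regimen}\t{name}\n")
    return path
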