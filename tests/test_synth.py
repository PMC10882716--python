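import dataclasses
import math

import numpy as np
import pytest

from faerspv.dedup import RULE_MAX_PRIMARYID, deduplicate
from faerspv.io import read_quarter
from faerspv.synth import (SynthConfig, generate, generate_bundles,
                           plant_duplicates, validate)

from conftest import make_bundle


def test_same_config_means_identical_bytes(tmp_path):
    cfg = SynthConfig(seed=99, n_cases=300)
    paths1, truth1 = generate(cfg, tmp_path / "one")
    paths2, truth2 = generate(cfg, tmp_path / "two")
    for table in paths1:
        assert paths1[table].read_bytes() == paths2[table].read_bytes(), table
    assert truth1.survivors == truth2.survivors


def test_generated_quarter_parses_and_counts_match(tmp_path):
    cfg = SynthConfig(seed=4, n_cases=400)
    paths, truth = generate(cfg, tmp_path)
    bundles, report = read_quarter(paths)
    assert report.n_quarantined == 0
    assert len(bundles) == report.n_rows["demo"]
    assert len({b.caseid for b in bundles}) == cfg.n_cases
    assert set(truth.survivors) == {b.caseid for b in bundles}


def test_zero_duplicate_rate_makes_dedup_identity():
    cfg = SynthConfig(seed=1, n_cases=300, duplicate_rate=0.0)
    bundles, truth = generate_bundles(cfg)
    assert len(bundles) == cfg.n_cases
    res = deduplicate(bundles)
    assert [b.primaryid for b in res.retained] == \
        sorted((b.primaryid for b in bundles), key=int)
    assert all(d.rule_used == "singleton" for d in res.decisions)


def test_forced_ties_exercise_the_primaryid_criterion():
    base = [make_bundle(pid=f"{100+i}1", caseid=str(100 + i), fda="20210401")
            for i in range(50)]
    versions, survivors = plant_duplicates(base, rate=1.0, rng=0, tie_rate=1.0)
    assert len(versions) > len(base)
    res = deduplicate(versions)
    assert {b.caseid: b.primaryid for b in res.retained} == survivors
    assert all(d.rule_used == RULE_MAX_PRIMARYID for d in res.decisions)


def test_duplicate_conservation_at_half_rate():
    base = [make_bundle(pid=f"{1000+i}1", caseid=str(1000 + i))
            for i in range(1000)]
    versions, survivors = plant_duplicates(base, rate=0.5, rng=3)
    assert len(survivors) == 1000
    assert len(deduplicate(versions).retained) == 1000


@pytest.mark.parametrize("seed", range(10))
def test_dedup_matches_ground_truth_over_random_rates(seed):
    rng = np.random.default_rng(seed)
    rate = float(rng.random())
    tie = float(rng.random())
    base = [make_bundle(pid=f"{5000+i}1", caseid=str(5000 + i),
                        fda=f"202{seed % 3}0{1 + i % 9}15")
            for i in range(100)]
    versions, survivors = plant_duplicates(base, rate=rate, rng=rng,
                                           tie_rate=tie)
    res = deduplicate(versions)
    assert {b.caseid: b.primaryid for b in res.retained} == survivors


@pytest.mark.parametrize("overrides", [
    {"n_cases": 0},
    {"duplicate_rate": 1.5},
    {"sex_dist": {"F": 0.5, "M": 0.4, "": 0.2}},          # weights not 1
    {"planted_log_ror": {"NOT A PT": 0.5}},
    {"planted_log_ror": {"NERVOUSNESS": math.inf}},
])
def test_invalid_configs_rejected_before_generation(overrides):
    cfg = dataclasses.replace(SynthConfig(), **overrides)
    with pytest.raises(ValueError):
        validate(cfg)


def test_regimen_subset_with_onset_params_is_valid():
    validate(dataclasses.replace(SynthConfig(),
                                 regimen_mix={"semaglutide": 1.0}))


def test_infeasible_planted_rate_rejected():
    cfg = SynthConfig()
    catalog = dict(cfg.pt_catalog)
    catalog["NERVOUSNESS"] = (*catalog["NERVOUSNESS"][:2], 0.9)
    cfg = dataclasses.replace(cfg, pt_catalog=catalog,
                              planted_log_ror={"NERVOUSNESS": math.log(50)})
    with pytest.raises(ValueError, match="infeasible"):
        validate(cfg)


def test_ground_truth_tables_are_internally_consistent(small_universe,
                                                       small_config):
    _, truth = small_universe
    n = small_config.n_cases
    for pt, t in truth.planted_tables.items():
        assert t.total == n, pt
    assert truth.grouped_table.total == n
    # grouped cell a can never exceed the per-PT sum and never undercuts
    # the largest single-PT cell
    a_values = [t.a for t in truth.planted_tables.values()]
    assert max(a_values) <= truth.grouped_table.a <= sum(a_values)
    # cohort bookkeeping: target-SOC cases are cohort cases
    assert truth.target_soc_caseids <= truth.cohort_caseids
    assert sum(truth.regimen_counts.values()) == len(truth.cohort_caseids)


def test_null_planted_association_has_nominal_ci_coverage():
    # plant a true ROR of 1 on a frequent PT: the estimated ROR's 95% CI
    # must contain 1 at close to the nominal rate across seeded replicates
    from faerspv.disproportionality import compute_ror

    base = SynthConfig()
    catalog = dict(base.pt_catalog)
    catalog["INSOMNIA"] = (*catalog["INSOMNIA"][:2], 0.02)
    covered = computable = 0
    for seed in range(100):
        cfg = dataclasses.replace(
            base, seed=seed, n_cases=2_000, target_drug_prob=0.5,
            duplicate_rate=0.0, pt_catalog=catalog,
            planted_log_ror={"INSOMNIA": 0.0})
        _, truth = generate_bundles(cfg)
        est = compute_ror(truth.planted_tables["INSOMNIA"])
        if est is not None:
            computable += 1
            covered += est[1] <= 1.0 <= est[2]
    assert computable >= 95
    assert covered / computable >= 0.89


def test_planted_onset_median_recovered():
    # a single-regimen universe with median-31-day onsets: the generator's
    # pre-censoring draws must center on the planted median
    cfg = SynthConfig(
        seed=17, n_cases=2200, target_drug_prob=1.0, ps_role_prob=1.0,
        duplicate_rate=0.0, regimen_mix={"lixisenatide": 1.0},
        onset_status_probs={"included": 1.0, "excluded_missing": 0.0,
                            "excluded_invalid_order": 0.0,
                            "excluded_nonpositive": 0.0})
    _, truth = generate_bundles(cfg)
    values = np.sort([t.true_days for t in truth.onsets])
    assert values.size == 2200
    # order-statistic 99% interval for the median of a continuous sample
    from scipy import stats
    lo_k = int(stats.binom.ppf(0.005, values.size, 0.5))
    hi_k = min(int(stats.binom.ppf(0.995, values.size, 0.5)), values.size - 1)
    assert values[lo_k] <= 31 <= values[hi_k]
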