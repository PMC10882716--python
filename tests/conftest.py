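import pytest

from faerspv.dedup import deduplicate
from faerspv.io import (DemoRecord, DrugRecord, IndiRecord, OutcRecord,
                        ReacRecord, ReportBundle, TherRecord, parse_date)
from faerspv.synth import SynthConfig, generate_bundles


def make_bundle(pid="1001", caseid=None, fda="20200101", event="", sex="F",
                age=None, age_cod="", country="US", occp="CN",
                drugs=(("1", "OZEMPIC", "PS"),), pts=("NAUSEA",),
                thers=(), outcomes=(), indis=()):
    """Hand-built report bundle for unit tests.

    ``drugs`` are (seq, name, role) triples, ``thers`` are (seq, start_dt)
    pairs, ``indis`` are (seq, indication PT) pairs.
    """
    caseid = caseid if caseid is not None else pid
    demo = DemoRecord(primaryid=pid, caseid=caseid, fda_dt=parse_date(fda),
                      event_dt=parse_date(event), sex=sex, age=age,
                      age_cod=age_cod, reporter_country=country, occp_cod=occp)
    return ReportBundle(
        demo=demo,
        drugs=[DrugRecord(primaryid=pid, drug_seq=s, drugname=n, role_cod=r)
               for s, n, r in drugs],
        reactions=[ReacRecord(primaryid=pid, pt=p) for p in pts],
        therapies=[TherRecord(primaryid=pid, dsg_drug_seq=s,
                              start_dt=parse_date(d), end_dt=parse_date(""))
                   for s, d in thers],
        outcomes=[OutcRecord(primaryid=pid, outc_cod=c) for c in outcomes],
        indications=[IndiRecord(primaryid=pid, indi_drug_seq=s, indi_pt=p)
                     for s, p in indis],
    )


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(seed=11, n_cases=4000)


@pytest.fixture(scope="session")
def small_universe(small_config):
    """(all report versions, ground truth) for a 4,000-case universe."""
    return generate_bundles(small_config)


@pytest.fixture(scope="session")
def small_retained(small_universe):
    bundles, _ = small_universe
    return deduplicate(bundles).retained
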