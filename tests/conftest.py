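import logging

import pytest

from retrokit import retrocopy_caller as rc
from retrokit import synthetic_data as sd

logging.getLogger("retrokit").setLevel(logging.WARNING)


SMALL_CONFIG = dict(
    n_contigs=2, contig_length=70_000, n_genes=12, n_retro_events=8,
    n_dna_duplications=2, substitution_probability=0.0,
    frameshift_probability=0.12, premature_stop_probability=0.12,
    chimeric_probability=0.3, retrogene_probability=0.25,
)


@pytest.fixture(scope="session")
def noiseless_bundle() -> sd.FixtureBundle:
    """Small noiseless genome with planted events, shared across tests."""
    cfg = sd.SimulationConfig(seed=3, **SMALL_CONFIG)
    return sd.generate_bundle(cfg)


@pytest.fixture(scope="session")
def noiseless_records(noiseless_bundle):
    return rc.call_retrocopies(noiseless_bundle.genome, noiseless_bundle.genes)


def match_truth(record, truth):
    """Planted event recovered by a record: >50% overlap of the truth span."""
    for t in truth:
        if t.kind != "retro":
            continue
        if (t.contig_id == record.contig_id
                and min(t.end, record.end) - max(t.start, record.start)
                > 0.5 * (t.end - t.start)):
            return t
    return None
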