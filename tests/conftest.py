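import numpy as np
import pytest

from ervkit import synth
from ervkit.cli import default_transcript_program


@pytest.fixture(scope="session")
def ancestor():
    return synth.build_ancestor(synth.SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """Small planted simulation shared across read-only tests."""
    config = synth.SimConfig(
        seed=11,
        genome_len=300_000,
        n_proviruses=5,
        n_solo_ltrs=6,
        gene_program={
            "prov3": "intronic_same",
            "prov4": "intronic_opposite",
            "solo1": "exonic_opposite",
        },
        transcript_program=default_transcript_program(),
    )
    sim = synth.plant_loci(config)
    synth.transcribe(sim.truth, config.transcript_program)
    return sim


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
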