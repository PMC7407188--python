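import numpy as np
import pytest

from ddiscreen import (
    ProteinRecord,
    SimulationConfig,
    TaxonProfile,
    load_s100b_interaction_map,
    simulate,
)


@pytest.fixture(scope="session")
def s100b_map():
    return load_s100b_interaction_map()


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One small synthetic bundle shared by pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(seed=11, proteins_per_genus=40)
    return config, simulate(config, outdir)


def make_records(rng: np.random.Generator, n: int, genera, domains,
                 p: float = 0.3) -> list[ProteinRecord]:
    """Random protein records: each domain present independently with prob p."""
    records = []
    for i in range(n):
        present = tuple(d for d in domains if rng.random() < p)
        records.append(
            ProteinRecord(
                accession=f"P{i:05d}",
                genus=str(rng.choice(genera)),
                domains=present,
            )
        )
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile_factory():
    def make(group, genera, abundances=None):
        return TaxonProfile(group=group, genera=frozenset(genera),
                            abundances=abundances)
    return make
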