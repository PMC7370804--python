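import pytest
from hypothesis import settings

from strainvade.demux import MarkerDB

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_db() -> MarkerDB:
    return MarkerDB(records={"A": ["ACGTTGCA"], "B": ["GGGGCCAA"]})


@pytest.fixture
def grouped_db() -> MarkerDB:
    return MarkerDB(
        records={
            "MEL07": ["ACGTACGTAC"],
            "Peter07_149": ["TTGGCCAATT"],
            "ZIE05": ["AACCGGTTAA"],
            "ZIE11": ["GGAATTCCGG"],
            "27F11": ["CATGCATGCA"],
        },
        groups=[
            frozenset({"MEL07", "Peter07_149"}),
            frozenset({"ZIE05", "ZIE11"}),
        ],
    )


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """One small synthetic experiment on disk, shared across tests."""
    from strainvade.synthetic import SimulationConfig, generate_experiment

    out = tmp_path_factory.mktemp("experiment")
    config = SimulationConfig(
        diversity_levels=(1, 3), replicates_per_level=(1, 4),
        n_strains=5, n_resident_species=6, read_depth=2000,
        duration_days=30, seed=11,
    )
    bundle = generate_experiment(config, out)
    return config, bundle, out
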