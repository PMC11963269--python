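import numpy as np
import pytest

from prare.io import package_data_path
from prare.panels import build_profile_consensi
from prare.profiles import load_profiles
from prare.rtsearch import load_queries
from prare.synthetic import ScenarioConfig, default_scenario_config, generate_scenario


@pytest.fixture(scope="session")
def queries():
    return load_queries(package_data_path("retand_rt_queries.synthetic.faa"))


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def consensi():
    return build_profile_consensi()


@pytest.fixture(scope="session")
def small_scenario():
    """A 1.5-Mb scenario shared by the element/cluster/pipeline tests.

    Same family structure as the default 5-Mb stated world, scaled down so the
    unit-test suite stays fast; the full-size scenario runs in the acceptance
    tests.
    """
    cfg = default_scenario_config()
    cfg = ScenarioConfig(genome_length=1_500_000, n_contigs=3, families=cfg.families)
    genomes, truths = generate_scenario(cfg, 7)
    return cfg, genomes, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
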