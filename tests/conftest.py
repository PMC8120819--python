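import pytest
from hypothesis import HealthCheck, settings

from curculigo.neoculin import ReferencePanel, derive_regions
from curculigo.seq import ScoringScheme
from curculigo.simulate import SyntheticConfig, generate_two_species_dataset
from curculigo.synthetic_panel import reference_panel

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel_records():
    return reference_panel()


@pytest.fixture(scope="session")
def panel(panel_records):
    return ReferencePanel.from_records(panel_records)


@pytest.fixture(scope="session")
def partition(panel):
    return derive_regions(panel.nbs)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """Default-condition two-species bundle: 12 members/side at 10% pair
    divergence plus 12 shuffled decoys per side, anti-correlated TPMs."""
    config = SyntheticConfig(seed=11)
    outdir = tmp_path_factory.mktemp("bundle")
    bundle, truth = generate_two_species_dataset(config, outdir)
    return bundle, truth
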