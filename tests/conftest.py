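import numpy as np
import pytest
from hypothesis import settings

import cofnet as cf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world() -> cf.World:
    """Desk-scale planted-module world shared by read-only tests."""
    cfg = cf.SynthConfig(
        n_genes=300,
        n_modules=6,
        module_size=10,
        background_pairs_per_source=3000,
        n_samples=30,
        n_features=120,
        seed=11,
    )
    return cf.generate_world(cfg)


@pytest.fixture(scope="session")
def small_build(small_world: cf.World) -> cf.BuildResult:
    """Network built from the small world (admission floor scaled to size)."""
    return cf.build_network(
        small_world.evidence_tables, small_world.gold_standard, min_links=100
    )


@pytest.fixture()
def toy_network() -> cf.WeightedNetwork:
    return cf.WeightedNetwork(
        {
            ("a", "b"): 3.5,
            ("a", "c"): 2.0,
            ("b", "c"): 1.0,
            ("c", "d"): 0.5,
            ("d", "e"): 2.9,
        }
    )
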