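import numpy as np
import pytest

from cohet.pipeline import analyze_panel
from cohet.synthetic_data import (
    BreedSpec,
    SimulationConfig,
    SkewedSet,
    simulate,
)


def three_lineage_config(seed: int = 42, **overrides) -> SimulationConfig:
    """A small BI/BT/BTI panel with one skewed set per component."""
    params = dict(
        n_snp=520,
        n_genes=60,
        n_chromosomes=2,
        fst=0.2,
        ancestry_sd=0.15,
        breeds=[
            BreedSpec("BI1", "BI", 1.0, 60),
            BreedSpec("BT1", "BT", 0.0, 60),
            BreedSpec("XB1", "BTI", 0.5, 60),
        ],
        skewed_sets=[
            SkewedSet("tauset", 10, "taurine"),
            SkewedSet("indset", 10, "indicine"),
        ],
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate(three_lineage_config())


@pytest.fixture(scope="session")
def tiny_analysis(tiny_sim):
    return analyze_panel(tiny_sim)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
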