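import numpy as np
import pytest

from rhythmage import (
    SimulationConfig,
    generate_reference_profiles,
    generate_toy_clock,
    simulate_study,
)

TOY_TARGETS = {
    "Neu": 50.0,
    "NK": 56.0,
    "B": 44.0,
    "CD4T": 46.0,
    "CD8T": 50.0,
    "Mono": 50.0,
}

WBC_NEU_TIMES = np.arange(0.0, 72.0, 3.0)  # 24 samples, every 3 h for 72 h


@pytest.fixture(scope="session")
def panel6():
    """Six-cell-type reference panel with 10 planted markers per type."""
    return generate_reference_profiles(400, 6, seed=11, n_discriminating=10)


@pytest.fixture(scope="session")
def toy_linear_clock(panel6):
    return generate_toy_clock(panel6, TOY_TARGETS, "linear")


@pytest.fixture(scope="session")
def noiseless_study():
    """Exact convex mixtures: no oscillators, no age trend, no noise."""
    cfg = SimulationConfig(
        n_cpgs=400,
        frac_oscillating=0.0,
        frac_age_trend=0.0,
        noise_sd=0.0,
        seed=11,
    )
    return simulate_study(cfg)
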