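import numpy as np
import pandas as pd
import pytest

from hibernage import (
    DesignConfig,
    SampleTable,
    SiteConfig,
    TraitConfig,
    generate_design,
    simulate_beta_matrix,
    simulate_trait,
)


@pytest.fixture(scope="session")
def design_default() -> SampleTable:
    """The study-scale sampling design: 73 females, 149 samples."""
    return generate_design(DesignConfig(seed=0))


@pytest.fixture(scope="session")
def design_small() -> SampleTable:
    """A reduced design for fast GAMM fits."""
    cfg = DesignConfig(
        n_individuals=22,
        samples_min=1,
        samples_max=5,
        n_samples_total=52,
        n_consecutive_pairs=4,
        seed=11,
    )
    return generate_design(cfg)


@pytest.fixture(scope="session")
def null_sim_500(design_default):
    """Shared 500-replicate null simulation (type-I calibration)."""
    from hibernage import run_null_simulation

    return run_null_simulation(design_default, None, n_reps=500, seed=0)


@pytest.fixture(scope="session")
def seasonal_states(design_default) -> np.ndarray:
    """Season-stalled latent states on the default design."""
    return simulate_trait(design_default, TraitConfig(seed=42), seasonal=True)


@pytest.fixture(scope="session")
def small_beta(design_small):
    """Beta matrix + ground truth on the small design (low noise)."""
    states = simulate_trait(design_small, TraitConfig(seed=7), seasonal=False)
    matrix, params = simulate_beta_matrix(
        design_small,
        states,
        SiteConfig(n_sites=120, n_age_sites=60, n_chron_sites=20, noise_sd=0.01, seed=3),
        return_params=True,
    )
    return matrix, params, states


def tiny_table(rows: list[dict]) -> SampleTable:
    return SampleTable(pd.DataFrame(rows))
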