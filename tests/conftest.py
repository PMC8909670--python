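import numpy as np
import pytest

from methyltraj import MethylationDataset, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """5 samples x 4 sites with one perfectly age-linear site."""
    ages = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
    betas = np.vstack([
        ages / 100.0,                              # perfect positive
        np.array([0.9, 0.7, 0.6, 0.4, 0.2]),       # strongly negative
        np.full(5, 0.5),                           # constant
        np.array([0.31, 0.28, 0.33, 0.30, 0.29]),  # weak
    ])
    return MethylationDataset(
        betas=betas,
        sample_ids=[f"s{i}" for i in range(5)],
        ages=ages,
        probe_ids=[f"cg{i}" for i in range(4)],
        probe_types=np.array(["I", "II", "I", "II"], dtype=object),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A blood-like cohort small enough for per-module tests."""
    config = SimulationConfig(n_samples=300, n_sites=300, seed=42)
    train, validation, test, truth = simulate_cohort(config)
    return {"config": config, "train": train, "validation": validation,
            "test": test, "truth": truth}


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: betas are an exact linear function of the state."""
    config = SimulationConfig(n_samples=120, n_sites=150, noise_sd=0.0, seed=9)
    train, validation, test, truth = simulate_cohort(config)
    return {"config": config, "train": train, "validation": validation,
            "test": test, "truth": truth}
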