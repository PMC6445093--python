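import pytest

from tgfbsig.simulate import SimulationConfig, simulate_study


def small_config(**overrides) -> SimulationConfig:
    """Scaled-down study (200 proteins, 60 patients) for fast unit tests."""
    kwargs = dict(
        n_proteins=200, n_up=15, n_down=15, n_mouse_fast_extra=8,
        n_patients=60, n_null_genes=5, n_secretome_up=20, n_secretome_down=15,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(), seed=11)


@pytest.fixture(scope="session")
def zero_noise_study():
    return simulate_study(small_config(noise_cv=0.0, mouse_noise_cv=0.0), seed=7)
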