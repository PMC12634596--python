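import pytest

from syncoh import SimulationConfig, fibonacci_sphere, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two synthetic participants, 8 muscles / 4 synergies, 16 trials each."""
    cfg = SimulationConfig(
        n_participants=2, n_muscles=8, n_synergies=4,
        directions=fibonacci_sphere(8), n_repetitions=2,
        drive_gain=0.6, noise_gain=1.0, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_trial(small_dataset):
    return small_dataset.participants[0].trials[0]
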