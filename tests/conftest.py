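import numpy as np
import pytest

from actirhythm import DiurnalProfile, NoiseSpec, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def small_config(**overrides) -> SyntheticConfig:
    """A fast 10-min-epoch cohort config (l=144) for end-to-end tests."""
    base = dict(
        n_control=3,
        n_insomnia=3,
        days_range=(2, 3),
        epoch_minutes=10,
        day_length=144,
        control_profile=DiurnalProfile(
            wake_minute=42, sleep_minute=137, day_level=300.0,
            night_level=15.0, transition_width_minutes=1,
        ),
        insomnia_profile=DiurnalProfile(
            wake_minute=42, sleep_minute=137, day_level=300.0,
            night_level=15.0, transition_width_minutes=12,
        ),
        offset_delay_minutes=90.0,
        ultradian_components=[(17, 0.05, 0.6)],
        noise=NoiseSpec(family="poisson"),
        seed=7,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def shift_only_config(delta_minutes: float = 90.0, **overrides) -> SyntheticConfig:
    """Noiseless shift-only config: insomnia = control delayed by delta."""
    base = dict(
        shift_only=True,
        offset_delay_minutes=delta_minutes,
        noise=NoiseSpec(family="point"),
    )
    base.update(overrides)
    return small_config(**base)


@pytest.fixture
def toy_cohort():
    """Six recordings from the small Poisson config."""
    from actirhythm import simulate_cohort

    return simulate_cohort(small_config())
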