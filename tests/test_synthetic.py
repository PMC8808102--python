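"""Synthetic cohort generator: intensity construction, noise, seeding."""

import dataclasses

import numpy as np
import pytest

from actirhythm import (
    DiurnalProfile,
    NoiseSpec,
    SyntheticConfig,
    build_intensity,
    group_intensity,
    simulate_cohort,
    simulate_subject,
)
from actirhythm.io import cohort_day_matrices
from actirhythm.spectral import build_ensembles
from actirhythm.synthetic import (
    config_from_yaml,
    config_to_yaml,
    _draw_counts,
)

from conftest import shift_only_config, small_config


class TestBuildIntensity:
    def test_all_awake_degenerate_profile_is_constant(self):
        profile = DiurnalProfile(wake_minute=0, sleep_minute=16,
                                 day_level=50.0, night_level=0.0)
        intensity = build_intensity(profile, [], 16)
        np.testing.assert_array_equal(intensity, np.full(16, 50.0))

    def test_step_function_epoch_counting(self):
        profile = DiurnalProfile(wake_minute=3, sleep_minute=11,
                                 day_level=100.0, night_level=5.0,
                                 transition_width_minutes=0)
        intensity = build_intensity(profile, [], 16)
        assert np.sum(intensity == 100.0) == 8  # (sleep - wake) mod l
        assert np.sum(intensity == 5.0) == 8

    def test_wrap_around_awake_interval(self):
        profile = DiurnalProfile(wake_minute=12, sleep_minute=4,
                                 day_level=10.0, night_level=1.0)
        intensity = build_intensity(profile, [], 16)
        assert np.sum(intensity == 10.0) == 8
        assert intensity[12] == 10.0 and intensity[4] == 1.0

    def test_ultradian_reconstruction_oracle(self):
        """Intensity minus the bare step equals the injected cosine exactly."""
        profile = DiurnalProfile(wake_minute=3, sleep_minute=11,
                                 day_level=100.0, night_level=5.0)
        l, k, a, phi = 16, 2, 0.04, 0.7
        base = build_intensity(profile, [], l)
        with_wave = build_intensity(profile, [(k, a, phi)], l)
        t = np.arange(l)
        expected = a * profile.day_level * np.cos(2 * np.pi * k * t / l + phi)
        np.testing.assert_allclose(with_wave - base, expected, atol=1e-12)

    def test_negative_intensity_rejected(self):
        profile = DiurnalProfile(wake_minute=3, sleep_minute=11,
                                 day_level=100.0, night_level=0.0)
        with pytest.raises(ValueError, match="negative"):
            build_intensity(profile, [(2, 1.0, 0.0)], 16)

    def test_day_level_must_exceed_night(self):
        with pytest.raises(ValueError, match="exceed"):
            DiurnalProfile(0, 8, day_level=5.0, night_level=5.0).validate(16)


class TestConfigValidation:
    def test_day_length_epoch_product(self):
        with pytest.raises(ValueError, match="1440"):
            small_config(day_length=100).validate()

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            small_config(n_control=0).validate()

    def test_offset_must_be_whole_epochs(self):
        with pytest.raises(ValueError, match="whole number"):
            small_config(offset_delay_minutes=95.0).validate()

    def test_ultradian_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="≥ 2"):
            small_config(ultradian_components=[(1, 0.1, 0.0)]).validate()

    def test_yaml_round_trip(self, tmp_path):
        config = small_config(seed=42)
        path = tmp_path / "config.yaml"
        config_to_yaml(config, path)
        assert config_from_yaml(path) == config


class TestSimulation:
    def test_shift_only_noiseless_days_are_shifted_control(self):
        config = shift_only_config(delta_minutes=90.0)
        control_intensity = group_intensity(config, "control")
        rec = simulate_subject(config, "insomnia", 0)
        matrix = cohort_day_matrices([rec])[0]
        expected = np.roll(control_intensity, config.offset_epochs)
        for row in matrix.days:
            np.testing.assert_array_equal(row, expected)

    def test_seeded_determinism(self):
        config = small_config(seed=11)
        a, b = simulate_cohort(config), simulate_cohort(config)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.counts, rb.counts)

    def test_different_seeds_differ(self):
        a = simulate_cohort(small_config(seed=1))
        b = simulate_cohort(small_config(seed=2))
        assert any(
            ra.counts.shape != rb.counts.shape or not np.array_equal(ra.counts, rb.counts)
            for ra, rb in zip(a, b)
        )

    def test_study_scale_cohort_labels(self):
        config = small_config(n_control=21, n_insomnia=18, days_range=(1, 1))
        cohort = simulate_cohort(config)
        assert len(cohort) == 39
        assert sum(r.group == "control" for r in cohort) == 21
        assert sum(r.group == "insomnia" for r in cohort) == 18
        assert len({r.subject_id for r in cohort}) == 39

    def test_minimal_cohort_two_day_segments(self):
        config = small_config(n_control=1, n_insomnia=1, days_range=(1, 1))
        matrices = cohort_day_matrices(simulate_cohort(config))
        assert sum(m.n_days for m in matrices) == 2

    def test_adding_subjects_preserves_existing_streams(self):
        small = simulate_cohort(small_config(n_control=2, n_insomnia=2))
        large = simulate_cohort(small_config(n_control=3, n_insomnia=3))
        np.testing.assert_array_equal(small[0].counts, large[0].counts)
        np.testing.assert_array_equal(small[2].counts, large[3].counts)  # I01

    def test_counts_are_nonnegative_integers(self):
        for rec in simulate_cohort(small_config(noise=NoiseSpec("nbinom", 5.0))):
            assert np.all(rec.counts >= 0)
            assert np.all(rec.counts == np.round(rec.counts))

    def test_days_drawn_within_range(self):
        config = small_config(days_range=(2, 4), n_control=8, n_insomnia=8)
        for m in cohort_day_matrices(simulate_cohort(config)):
            assert 2 <= m.n_days <= 4


class TestNoiseFamilies:
    def test_poisson_law_of_large_numbers(self):
        """Sample mean over 10^4 days within 3 standard errors of μ."""
        rng = np.random.default_rng(123)
        mu = np.array([5.0, 50.0, 300.0, 0.0])
        n = 10_000
        draws = np.vstack([
            _draw_counts(rng, mu, NoiseSpec("poisson")) for _ in range(n)
        ])
        se = np.sqrt(np.maximum(mu, 1e-12) / n)
        assert np.all(np.abs(draws.mean(axis=0) - mu) <= 3 * se + 1e-9)

    def test_nbinom_overdispersed_relative_to_poisson(self):
        rng = np.random.default_rng(7)
        mu = np.full(20_000, 100.0)
        pois = _draw_counts(rng, mu, NoiseSpec("poisson"))
        nb = _draw_counts(rng, mu, NoiseSpec("nbinom", dispersion=5.0))
        # nbinom variance ≈ μ + μ²/r = 2100 ≫ 100
        assert nb.var() > 3 * pois.var()

    def test_point_mass_returns_intensity(self):
        mu = np.array([1.5, 0.0, 7.25])
        out = _draw_counts(np.random.default_rng(0), mu, NoiseSpec("point"))
        np.testing.assert_array_equal(out, mu)


class TestSpectralInjection:
    def test_injected_amplitude_monotone_in_a(self):
        """Group-mean amplitude at the injected component grows with a.

        A flat (always-awake) base profile carries no spectral content of
        its own at k0, so the component amplitude reflects the injection
        alone plus noise."""
        flat = DiurnalProfile(wake_minute=0, sleep_minute=144,
                              day_level=200.0, night_level=0.0)
        k0 = 12
        means = []
        for a in [0.0, 0.05, 0.1, 0.2]:
            config = small_config(
                control_profile=flat, insomnia_profile=flat,
                ultradian_components=[(k0, a, 0.3)] if a > 0 else [],
                noise=NoiseSpec("poisson"), seed=5,
            )
            matrices = cohort_day_matrices(simulate_cohort(config))
            ens = build_ensembles(matrices, K=k0)
            pooled = np.concatenate([
                ens["control"].amplitude_sample(k0),
                ens["insomnia"].amplitude_sample(k0),
            ])
            means.append(pooled.mean())
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))
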