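"""Fourier decomposition, phase conventions, and ensemble construction."""

import numpy as np
import pytest

from actirhythm import (
    Spectrum,
    build_ensembles,
    circular_mean,
    component_period_minutes,
    dft,
    phase_difference_minutes,
    wrap_angle,
)
from actirhythm.io import DayMatrix, cohort_day_matrices
from actirhythm.spectral import ensemble_summary, inverse_check
from actirhythm.synthetic import simulate_cohort

from conftest import shift_only_config


def naive_dft(x):
    # independent O(l^2) double-sum oracle, negative-exponent convention
    l = len(x)
    out = np.empty(l, dtype=complex)
    for k in range(l):
        out[k] = sum(x[t] * np.exp(-2j * np.pi * t * k / l) for t in range(l))
    return out


class TestDft:
    def test_matches_double_sum_oracle(self, rng):
        x = rng.random(8) * 100
        spec = dft(x)
        np.testing.assert_allclose(spec.coefficients, naive_dft(x), atol=1e-10)

    def test_constant_has_zero_ac_amplitudes(self):
        spec = dft(np.full(16, 3.7))
        assert np.all(spec.amplitudes[1:] <= 1e-10)
        assert np.all(np.isnan(spec.phases[1:]))  # undefined, not 0

    def test_pure_cosine_amplitude_and_phase(self):
        l = 64
        x = np.cos(2 * np.pi * np.arange(l) / l)
        spec = dft(x)
        assert spec.amplitude(1) == pytest.approx(l / 2, rel=1e-12)
        assert spec.phase(1) == pytest.approx(0.0, abs=1e-12)

    def test_parseval(self, rng):
        x = rng.random(32) * 50
        spec = dft(x)
        lhs = np.sum(x**2)
        rhs = np.sum(np.abs(spec.coefficients) ** 2) / len(x)
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_inverse_reconstruction(self, rng):
        x = rng.random(48) * 300
        assert inverse_check(dft(x), x)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            dft(np.array([1.0, np.inf, 0.0, 0.0]))

    @pytest.mark.parametrize("s", range(8))
    def test_shift_theorem(self, s, rng):
        """Rotating x by s leaves amplitudes alone and shifts phase k by -2πks/l."""
        l = 8
        x = rng.random(l) * 100 + 10
        base = dft(x)
        shifted = dft(np.roll(x, -s))  # x advanced by s: x'(t) = x(t+s)
        np.testing.assert_allclose(shifted.amplitudes, base.amplitudes, atol=1e-9)
        for k in range(1, l // 2 + 1):
            if np.isnan(base.phases[k]):
                continue
            expected = wrap_angle(base.phase(k) + 2 * np.pi * k * s / l)
            assert wrap_angle(shifted.phase(k) - expected) == pytest.approx(0.0, abs=1e-9)


class TestPhaseConventions:
    def test_quadrant_aware_angles(self):
        spec = Spectrum(np.array([1.0, 1j, -1.0, -1j], dtype=complex))
        assert spec.phase(1) == pytest.approx(np.pi / 2)  # (0, +b)
        assert spec.phase(2) == pytest.approx(np.pi)  # (-a, 0): π, not 0

    def test_k_out_of_range(self):
        spec = dft(np.arange(8.0))
        with pytest.raises(ValueError, match="outside"):
            spec.phase(5)

    def test_wrap_angle_branch(self):
        assert wrap_angle(np.pi) == pytest.approx(np.pi)
        assert wrap_angle(-np.pi) == pytest.approx(np.pi)  # branch is (−π, π]
        assert wrap_angle(3 * np.pi / 2) == pytest.approx(-np.pi / 2)


class TestCircularMean:
    def test_constant_sample(self):
        angle, r = circular_mean(np.full(10, 1.3))
        assert angle == pytest.approx(1.3)
        assert r == pytest.approx(1.0)

    def test_antipodal_undefined(self):
        angle, r = circular_mean(np.array([np.pi / 2, -np.pi / 2]))
        assert np.isnan(angle)
        assert r == 0.0

    def test_two_phasor_mean(self):
        angle, r = circular_mean(np.array([0.0, np.pi / 2]))
        assert angle == pytest.approx(np.pi / 4)
        assert r == pytest.approx(np.sqrt(2) / 2)

    def test_nan_markers_excluded(self):
        angle, _ = circular_mean(np.array([0.5, np.nan, 0.5]))
        assert angle == pytest.approx(0.5)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="empty"):
            circular_mean(np.array([np.nan]))


class TestUnitConversions:
    @pytest.mark.parametrize(
        "deg,expected_min",
        [(20.0, 80.0), (0.0, 0.0), (350.0, -40.0)],  # 350° wraps to −10°
    )
    def test_phase_difference_minutes_k1(self, deg, expected_min):
        result = phase_difference_minutes(np.deg2rad(deg), 0.0, k=1, l=1440)
        assert result == pytest.approx(expected_min)

    def test_scaling_with_k_and_epoch(self):
        # same angular difference spans fewer minutes on faster components
        assert phase_difference_minutes(np.pi, 0, k=2, l=1440) == pytest.approx(360.0)
        assert phase_difference_minutes(np.pi, 0, k=1, l=144, epoch_minutes=10) == (
            pytest.approx(720.0)
        )

    @pytest.mark.parametrize(
        "k,period", [(1, 1440.0), (20, 72.0), (17, 1440 / 17), (19, 1440 / 19)]
    )
    def test_component_periods(self, k, period):
        assert component_period_minutes(k, 1440) == pytest.approx(period)

    def test_dc_component_rejected(self):
        with pytest.raises(ValueError):
            component_period_minutes(0, 1440)
        with pytest.raises(ValueError):
            phase_difference_minutes(0.1, 0.0, k=0, l=1440)


class TestEnsembles:
    def test_sample_counting(self, rng):
        matrices = [
            DayMatrix(f"C{i}", "control", rng.random((3, 16)) + 0.1, 90)
            for i in range(4)
        ] + [DayMatrix("I1", "insomnia", rng.random((2, 16)) + 0.1, 90)]
        ens = build_ensembles(matrices, K=5)
        assert ens["control"].amplitudes.shape == (12, 5)
        assert ens["insomnia"].amplitudes.shape == (2, 5)
        assert ens["control"].amplitude_sample(3).size == 12

    def test_degenerate_days_excluded(self, rng):
        days = np.vstack([rng.random(16) + 0.1, np.zeros(16)])
        ens = build_ensembles(
            [
                DayMatrix("A", "control", days, 90),
                DayMatrix("B", "insomnia", days[:1], 90),
            ],
            K=4,
        )
        assert ens["control"].n_segments == 1

    def test_shift_only_cohort_amplitudes_identical_phases_lagged(self):
        """Shift theorem at cohort level: amplitudes shift-invariant, phases
        offset by exactly 2πkΔ/l between groups."""
        config = shift_only_config(delta_minutes=90.0, days_range=(2, 2))
        matrices = cohort_day_matrices(simulate_cohort(config))
        ens = build_ensembles(matrices, K=10)
        ctrl, ins = ens["control"], ens["insomnia"]
        delta = config.offset_epochs
        l = config.day_length
        for k in range(1, 11):
            a, b = np.sort(ctrl.amplitude_sample(k)), np.sort(ins.amplitude_sample(k))
            np.testing.assert_allclose(a, b, rtol=1e-9)
            # insomnia delayed by Δ → phase lowered by 2πkΔ/l
            expected = wrap_angle(ctrl.phase_sample(k) - 2 * np.pi * k * delta / l)
            diff = wrap_angle(ins.phase_sample(k) - expected)
            np.testing.assert_allclose(diff, 0.0, atol=1e-8)

    def test_summary_table_shape(self, toy_cohort):
        matrices = cohort_day_matrices(toy_cohort)
        summary = ensemble_summary(build_ensembles(matrices, K=6))
        assert set(summary["group"]) == {"control", "insomnia"}
        assert summary.shape[0] == 12
        assert (summary["n_segments"] > 0).all()
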