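"""Fourier decomposition of 24 h day-segments: amplitudes, phases, ensembles.

The transform convention is the plain forward DFT with negative exponent
and no normalization,

    ŷ(ω_k) = Σ_{t=0}^{l−1} x(t) · exp(−i 2π t k / l),

which is exactly ``numpy.fft.fft``.  For real-valued day vectors only the
components k = 1 … l/2 carry physical information: k = 1 is the circadian
(24 h) mode, and component k has period l·P/k minutes (P the epoch length),
so k = 17, 19, 20 sit in the ≈85/75/72 min ultradian (BRAC) band.

Phases are quadrant-aware angles of the complex coefficients on the fixed
branch (−π, π].  A zero-amplitude coefficient has no defined phase; such
phases are recorded as NaN markers and excluded from ensembles with a
logged count, never silently set to 0.  The DC component k = 0 never
enters ensembles, and the Nyquist coefficient (real by symmetry, phase in
{0, π}) is handled like any other component.

Phase summaries across day-segments are circular: the mean angle is the
argument of the average unit phasor and the resultant length R ∈ [0, 1]
measures concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DayMatrix

logger = logging.getLogger(__name__)

DEFAULT_K = 30  # reporting cutoff; full l/2 spectrum available on demand

# relative floor below which a coefficient is treated as numerically zero
# and its phase undefined (fft of a constant leaves ~1e-13 relative residue)
_ZERO_AMP_RTOL = 1e-12


def wrap_angle(phi: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) onto the fixed branch (−π, π]."""
    wrapped = np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), 2 * np.pi)
    if np.ndim(phi) == 0:
        return float(wrapped)
    return wrapped


@dataclass
class Spectrum:
    """DFT of one day vector with derived amplitudes and phases.

    ``amplitudes[k]`` and ``phases[k]`` index components k = 0 … l/2;
    ``phases`` holds NaN where the amplitude is (numerically) zero.
    """

    coefficients: np.ndarray
    amplitudes: np.ndarray = field(init=False)
    phases: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        l = self.coefficients.size
        half = l // 2
        coeffs = self.coefficients[: half + 1]
        self.amplitudes = np.abs(coeffs)
        phases = wrap_angle(np.angle(coeffs))
        scale = max(np.max(self.amplitudes), 1.0)
        undefined = self.amplitudes <= _ZERO_AMP_RTOL * scale
        self.phases = np.where(undefined, np.nan, phases)

    @property
    def l(self) -> int:
        return self.coefficients.size

    def amplitude(self, k: int) -> float:
        """A_k = |ŷ(ω_k)| for k in 0 … l/2."""
        self._check_k(k)
        return float(self.amplitudes[k])

    def phase(self, k: int) -> float:
        """Quadrant-aware phase φ_k ∈ (−π, π]; NaN when A_k = 0."""
        self._check_k(k)
        return float(self.phases[k])

    def _check_k(self, k: int) -> None:
        if not 0 <= k <= self.l // 2:
            raise ValueError(f"component k={k} outside 0…l/2 (l={self.l})")


def dft(x: np.ndarray) -> Spectrum:
    """Forward DFT of a day vector (negative-exponent, unnormalized)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return Spectrum(coefficients=np.fft.fft(x))


def inverse_check(spec: Spectrum, x: np.ndarray, rtol: float = 1e-8) -> bool:
    """True when the inverse transform reconstructs x within rtol."""
    recon = np.fft.ifft(spec.coefficients).real
    scale = max(float(np.max(np.abs(x))), 1.0)
    return bool(np.max(np.abs(recon - np.asarray(x, dtype=float))) <= rtol * scale)


def circular_mean(phases: np.ndarray) -> tuple[float, float]:
    """Mean angle and resultant length of a sample of phases.

    Returns (mean_angle, R) where R ∈ [0, 1] is the modulus of the average
    unit phasor.  NaN entries (undefined phases) are excluded.  When the
    resultant vanishes (e.g. antipodal phases) the mean angle is undefined
    and returned as NaN with R = 0.
    """
    phases = np.asarray(phases, dtype=float)
    phases = phases[~np.isnan(phases)]
    if phases.size == 0:
        raise ValueError("empty phase sample")
    phasor = np.exp(1j * phases).mean()
    r = float(np.abs(phasor))
    if r < 1e-12:
        return float("nan"), 0.0
    return wrap_angle(float(np.angle(phasor))), r


def phase_difference_minutes(
    phi_a: float, phi_b: float, k: int, l: int, epoch_minutes: int = 1
) -> float:
    """Signed phase difference φ_a − φ_b expressed in minutes of component k.

    The difference is first wrapped onto (−π, π] — a 350° difference reads
    as −10°, not +350° — then scaled by the component period l·P/(2π·k).
    At k = 1, l = 1440, P = 1 min, a 20° difference converts to 80 min.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1 (DC component has no phase)")
    dphi = wrap_angle(phi_a - phi_b)
    return dphi * (l * epoch_minutes) / (2 * np.pi * k)


def component_period_minutes(k: int, l: int, epoch_minutes: int = 1) -> float:
    """Period of spectral component k in minutes: l·P/k (k=1 → 1440)."""
    if k < 1:
        raise ValueError("k must be ≥ 1 (DC component has no period)")
    return l * epoch_minutes / k


@dataclass
class SpectralEnsemble:
    """Per-group samples of amplitudes and phases across all day-segments.

    ``amplitudes`` and ``phases`` have shape (n_segments, K); column j
    holds component k = j + 1 (the DC component is excluded).  ``phases``
    contains NaN markers for undefined phases.  ``subjects`` and
    ``day_index`` identify each row's origin.
    """

    group: str
    l: int
    amplitudes: np.ndarray
    phases: np.ndarray
    subjects: list[str]
    day_index: np.ndarray
    epoch_minutes: int = 1

    @property
    def K(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def n_segments(self) -> int:
        return self.amplitudes.shape[0]

    def amplitude_sample(self, k: int) -> np.ndarray:
        """All day-segment amplitudes at component k (1-based)."""
        self._check_k(k)
        return self.amplitudes[:, k - 1]

    def phase_sample(self, k: int) -> np.ndarray:
        """Defined day-segment phases at component k; NaNs dropped."""
        self._check_k(k)
        col = self.phases[:, k - 1]
        return col[~np.isnan(col)]

    def _check_k(self, k: int) -> None:
        if not 1 <= k <= self.K:
            raise ValueError(f"component k={k} outside 1…K (K={self.K})")


def build_ensembles(
    matrices: Sequence[DayMatrix], K: int | None = None
) -> dict[str, SpectralEnsemble]:
    """Pool per-day amplitudes and phases over every subject of each group.

    Degenerate (all-zero) days are excluded, consistently with the PDF
    pipeline.  ``K`` defaults to 30 and is capped at l/2.
    """
    if not matrices:
        raise ValueError("no day matrices supplied")
    l = matrices[0].day_length
    epoch_minutes = matrices[0].epoch_minutes
    if any(m.day_length != l for m in matrices):
        raise ValueError("mixed day lengths across subjects")
    K = min(K if K is not None else DEFAULT_K, l // 2)

    acc: dict[str, dict[str, list]] = {}
    n_undefined = 0
    for m in matrices:
        slot = acc.setdefault(
            m.group, {"amp": [], "phase": [], "subject": [], "day": []}
        )
        for day_idx, row in enumerate(m.days):
            if not row.any():
                logger.warning(
                    "subject %s day %d: degenerate day excluded from spectra",
                    m.subject_id, day_idx,
                )
                continue
            spec = dft(row)
            slot["amp"].append(spec.amplitudes[1 : K + 1])
            phases = spec.phases[1 : K + 1]
            n_undefined += int(np.isnan(phases).sum())
            slot["phase"].append(phases)
            slot["subject"].append(m.subject_id)
            slot["day"].append(day_idx)
    if n_undefined:
        logger.info("excluded %d undefined (zero-amplitude) phase value(s)", n_undefined)

    ensembles = {}
    for group, slot in sorted(acc.items()):
        if not slot["amp"]:
            raise ValueError(f"group {group!r} has no non-degenerate days")
        ensembles[group] = SpectralEnsemble(
            group=group,
            l=l,
            amplitudes=np.vstack(slot["amp"]),
            phases=np.vstack(slot["phase"]),
            subjects=slot["subject"],
            day_index=np.array(slot["day"]),
            epoch_minutes=epoch_minutes,
        )
    return ensembles


def ensemble_table(ensembles: dict[str, SpectralEnsemble]) -> pd.DataFrame:
    """Long-format table (group, subject, day, k, amplitude, phase_radians)."""
    frames = []
    for group, ens in sorted(ensembles.items()):
        n, K = ens.amplitudes.shape
        frames.append(
            pd.DataFrame(
                {
                    "group": np.repeat(group, n * K),
                    "subject": np.repeat(ens.subjects, K),
                    "day": np.repeat(ens.day_index, K),
                    "k": np.tile(np.arange(1, K + 1), n),
                    "amplitude": ens.amplitudes.ravel(),
                    "phase_radians": ens.phases.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_ensembles(ensembles: dict[str, SpectralEnsemble], path: str | Path) -> None:
    ensemble_table(ensembles).to_csv(path, sep="\t", index=False)


def ensemble_summary(
    ensembles: dict[str, SpectralEnsemble], circular: bool = True
) -> pd.DataFrame:
    """Per-group, per-component mean amplitude and mean phase.

    Phase means are circular by default (argument of the mean unit
    phasor, with the resultant length reported); an arithmetic mean on
    the (−π, π] branch is available for comparison.
    """
    rows = []
    for group, ens in sorted(ensembles.items()):
        for k in range(1, ens.K + 1):
            amp = ens.amplitude_sample(k)
            ph = ens.phase_sample(k)
            if ph.size == 0:
                mean_phase, r = float("nan"), float("nan")
            elif circular:
                mean_phase, r = circular_mean(ph)
            else:
                mean_phase, r = float(np.mean(ph)), float("nan")
            rows.append(
                {
                    "group": group,
                    "k": k,
                    "period_minutes": component_period_minutes(
                        k, ens.l, ens.epoch_minutes
                    ),
                    "mean_amplitude": float(np.mean(amp)),
                    "mean_phase_radians": mean_phase,
                    "resultant_length": r,
                    "n_segments": int(amp.size),
                    "n_phases": int(ph.size),
                }
            )
    return pd.DataFrame(rows)
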