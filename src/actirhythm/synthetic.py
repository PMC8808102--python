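"""Seeded synthetic actigraphy cohorts with the structure the analysis assumes.

The generator emulates the kind of wrist-actigraphy study the pipeline is
built for: two groups (controls and insomniacs), each subject wearing the
device for 7–14 whole days at 1-minute epochs with recordings aligned to
midnight.  Each group has a stable diurnal mean-intensity profile — a
two-level day/night step with configurable ramp widths at activity onset
and offset (narrow ramps give the controls' abrupt transitions, a wide
ramp gives the insomniacs' slow evening decay) — plus weaker ultradian
cosine components superposed on it.  The insomnia-group intensity is
circularly delayed by a configurable offset Δ (study value ≈90 min), which
is the ground-truth temporal shift downstream estimators should recover.

Counts are independent non-negative integers drawn around the intensity.
Three noise families are exposed, because the analysis itself makes no
noise assumption and tests need all three regimes:

``point``
    no noise; counts equal the intensity exactly (reals allowed).
``poisson``
    Poisson counts with the intensity as mean.
``nbinom``
    gamma-mixed Poisson (negative-binomial-like): mean μ, variance
    μ + μ²/dispersion.  The default, with dispersion 10 — real count data
    are overdispersed, but no device noise characterization exists, so
    the dispersion value is a free modelling choice.

Seeding: one master seed; each subject draws from an independent substream
derived via ``np.random.SeedSequence(seed, spawn_key=(group, index))`` so
that adding a subject never changes earlier subjects' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import ActigraphyRecording, MINUTES_PER_DAY

NOISE_FAMILIES = ("point", "poisson", "nbinom")

_GROUP_CODE = {"control": 0, "insomnia": 1}


@dataclass
class DiurnalProfile:
    """Two-level day/night mean-intensity profile on the epoch grid.

    ``wake_minute`` and ``sleep_minute`` are epoch-grid indices within the
    day (equal to clock minutes at the default 1-min epoch).  The subject
    is awake on the circular interval [wake, sleep) at ``day_level`` mean
    counts/epoch and asleep at ``night_level``.  ``transition_width_minutes``
    is the length of the linear ramp at activity onset (rising into the
    awake interval) and offset (decaying after sleep onset): small for
    abrupt control-like transitions, large for a slow insomniac-like
    evening decay.  ``sleep_minute == day_length`` with ``wake_minute == 0``
    expresses the degenerate always-awake profile.
    """

    wake_minute: int
    sleep_minute: int
    day_level: float
    night_level: float
    transition_width_minutes: int = 0

    def validate(self, day_length: int) -> None:
        if not 0 <= self.wake_minute < day_length:
            raise ValueError(f"wake_minute {self.wake_minute} outside [0, {day_length})")
        if not 0 <= self.sleep_minute <= day_length:
            raise ValueError(
                f"sleep_minute {self.sleep_minute} outside [0, {day_length}]"
            )
        if self.sleep_minute == self.wake_minute:
            raise ValueError("wake_minute == sleep_minute is ambiguous")
        if self.day_level <= self.night_level:
            raise ValueError("day_level must exceed night_level")
        if self.night_level < 0:
            raise ValueError("night_level must be non-negative")
        if self.transition_width_minutes < 0:
            raise ValueError("transition_width_minutes must be non-negative")


@dataclass
class NoiseSpec:
    """Count-noise family around the per-epoch mean intensity."""

    family: str = "nbinom"
    dispersion: float = 10.0

    def validate(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family == "nbinom" and self.dispersion <= 0:
            raise ValueError("nbinom dispersion must be positive")


@dataclass
class SyntheticConfig:
    """Full description of one synthetic cohort.

    ``ultradian_components`` is a list of (k, relative_amplitude, phase)
    triples: component k ≥ 2 with amplitude ``relative_amplitude ×
    day_level`` and the given phase in radians, defined against the
    midnight-anchored epoch grid with the same cosine convention the
    spectral module's DFT uses (so an injected phase φ is what the k-th
    Fourier phase reads back on a flat base profile).

    ``shift_only`` makes the insomnia-group intensity an exact circular
    delay of the control intensity by ``offset_delay_minutes``, ignoring
    ``insomnia_profile``; otherwise the insomnia profile is built from its
    own shape and then delayed by the same offset, so Δ stays the
    controlled ground-truth shift in both modes.
    """

    n_control: int = 21
    n_insomnia: int = 18
    days_range: tuple[int, int] = (7, 14)
    epoch_minutes: int = 1
    day_length: int = 1440
    control_profile: DiurnalProfile = field(
        default_factory=lambda: DiurnalProfile(
            wake_minute=420, sleep_minute=1380,
            day_level=300.0, night_level=20.0,
            transition_width_minutes=10,
        )
    )
    insomnia_profile: DiurnalProfile = field(
        default_factory=lambda: DiurnalProfile(
            wake_minute=420, sleep_minute=1380,
            day_level=300.0, night_level=20.0,
            transition_width_minutes=120,
        )
    )
    offset_delay_minutes: float = 90.0
    shift_only: bool = False
    # weak ultradian (BRAC-band) components; summed amplitude 0.06×day_level
    # stays below night_level so the mean intensity is positive everywhere
    ultradian_components: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(17, 0.03, 0.6), (19, 0.02, 1.1), (20, 0.01, -0.8)]
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 1 or self.n_insomnia < 1:
            raise ValueError("both groups need at least one subject")
        lo, hi = self.days_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid days_range {self.days_range}")
        if self.epoch_minutes < 1 or MINUTES_PER_DAY % self.epoch_minutes != 0:
            raise ValueError("epoch_minutes must divide 1440")
        if self.day_length * self.epoch_minutes != MINUTES_PER_DAY:
            raise ValueError(
                f"day_length × epoch_minutes must equal 1440, got "
                f"{self.day_length} × {self.epoch_minutes}"
            )
        if self.offset_delay_minutes < 0:
            raise ValueError("offset_delay_minutes must be non-negative")
        if self.offset_delay_minutes % self.epoch_minutes != 0:
            raise ValueError(
                "offset_delay_minutes must be a whole number of epochs"
            )
        self.control_profile.validate(self.day_length)
        if not self.shift_only:
            self.insomnia_profile.validate(self.day_length)
        for k, a, _phi in self.ultradian_components:
            if k < 2:
                raise ValueError(f"ultradian component k={k} must be ≥ 2")
            if not 0 <= a <= 1:
                raise ValueError(f"relative_amplitude {a} outside [0, 1]")
        self.noise.validate()

    @property
    def offset_epochs(self) -> int:
        return int(self.offset_delay_minutes) // self.epoch_minutes


def build_intensity(
    profile: DiurnalProfile,
    ultradian: Sequence[tuple[int, float, float]],
    day_length: int,
) -> np.ndarray:
    """Deterministic per-epoch mean intensity: diurnal profile + ultradian cosines.

    The diurnal part is the two-level step with linear ramps of
    ``transition_width_minutes`` epochs starting at wake (rising) and at
    sleep onset (decaying).  Each ultradian triple (k, a, φ) adds
    a·day_level·cos(2π k t / day_length + φ).  Configurations whose summed
    intensity dips below zero anywhere are rejected.
    """
    profile.validate(day_length)
    t = np.arange(day_length)
    day, night = profile.day_level, profile.night_level
    w = profile.transition_width_minutes

    awake_dur = (profile.sleep_minute - profile.wake_minute) % day_length
    if awake_dur == 0:  # sleep_minute == day_length with wake 0: always awake
        awake_dur = day_length
    u = (t - profile.wake_minute) % day_length  # epochs since wake
    v = (t - profile.sleep_minute) % day_length  # epochs since sleep onset

    base = np.full(day_length, night, dtype=float)
    awake = u < awake_dur
    if w == 0:
        base[awake] = day
    else:
        rise = np.minimum((u + 1) / (w + 1), 1.0)
        decay = 1.0 - np.minimum((v + 1) / (w + 1), 1.0)
        base[awake] = night + (day - night) * rise[awake]
        asleep = ~awake
        base[asleep] = night + (day - night) * decay[asleep]

    intensity = base.copy()
    for k, a, phi in ultradian:
        intensity += a * day * np.cos(2 * np.pi * k * t / day_length + phi)
    if np.any(intensity < 0):
        raise ValueError(
            "ultradian superposition drives the mean intensity negative; "
            "reduce relative amplitudes"
        )
    return intensity


def group_intensity(config: SyntheticConfig, group: str) -> np.ndarray:
    """Mean intensity for a group, including the built-in offset delay Δ."""
    config.validate()
    control = build_intensity(
        config.control_profile, config.ultradian_components, config.day_length
    )
    if group == "control":
        return control
    if config.shift_only:
        return np.roll(control, config.offset_epochs)
    insomnia = build_intensity(
        config.insomnia_profile, config.ultradian_components, config.day_length
    )
    return np.roll(insomnia, config.offset_epochs)


def _draw_counts(
    rng: np.random.Generator, mu: np.ndarray, noise: NoiseSpec
) -> np.ndarray:
    if noise.family == "point":
        return mu.copy()
    if noise.family == "poisson":
        return rng.poisson(mu).astype(float)
    # gamma-mixed Poisson: mean mu, variance mu + mu^2 / r
    r = noise.dispersion
    lam = np.where(mu > 0, rng.gamma(shape=r, scale=np.maximum(mu, 1e-300) / r), 0.0)
    return rng.poisson(lam).astype(float)


def _subject_rng(config: SyntheticConfig, group: str, index: int) -> np.random.Generator:
    seq = np.random.SeedSequence(config.seed, spawn_key=(_GROUP_CODE[group], index))
    return np.random.default_rng(seq)


def simulate_subject(
    config: SyntheticConfig, group: str, subject_index: int
) -> ActigraphyRecording:
    """Simulate one subject: D_s whole days of counts around the group intensity."""
    config.validate()
    if group not in _GROUP_CODE:
        raise ValueError(f"unknown group {group!r}")
    rng = _subject_rng(config, group, subject_index)
    lo, hi = config.days_range
    n_days = int(rng.integers(lo, hi + 1))
    mu = np.tile(group_intensity(config, group), n_days)
    counts = _draw_counts(rng, mu, config.noise)
    prefix = "C" if group == "control" else "I"
    return ActigraphyRecording(
        subject_id=f"{prefix}{subject_index + 1:02d}",
        group=group,
        counts=counts,
        epoch_minutes=config.epoch_minutes,
        start_offset_minutes=0,
    )


def simulate_cohort(config: SyntheticConfig) -> list[ActigraphyRecording]:
    """Simulate the full two-group cohort (controls first, then insomniacs)."""
    config.validate()
    cohort = [
        simulate_subject(config, "control", i) for i in range(config.n_control)
    ]
    cohort += [
        simulate_subject(config, "insomnia", i) for i in range(config.n_insomnia)
    ]
    return cohort


def config_to_yaml(config: SyntheticConfig, path: str | Path) -> None:
    """Serialize a config as a YAML document (schema mirrors the dataclasses)."""
    doc = asdict(config)
    doc["days_range"] = list(config.days_range)
    doc["ultradian_components"] = [list(c) for c in config.ultradian_components]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    """Load a config written by :func:`config_to_yaml` (or hand-authored)."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> SyntheticConfig:
    doc = dict(doc)
    for key in ("control_profile", "insomnia_profile"):
        if key in doc and isinstance(doc[key], dict):
            doc[key] = DiurnalProfile(**doc[key])
    if "noise" in doc and isinstance(doc["noise"], dict):
        doc["noise"] = NoiseSpec(**doc["noise"])
    if "days_range" in doc:
        doc["days_range"] = tuple(doc["days_range"])
    if "ultradian_components" in doc:
        doc["ultradian_components"] = [
            (int(k), float(a), float(phi)) for k, a, phi in doc["ultradian_components"]
        ]
    config = SyntheticConfig(**doc)
    config.validate()
    return config
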