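"""Epoch-level actigraphy tables: reading, writing, midnight alignment, day segmentation.

The on-disk format is delimiter-separated UTF-8 text with a header row and
fixed column order::

    subject_id,group,epoch_index,count[,start_offset_minutes[,epoch_minutes]]

One row per epoch, epochs contiguous and 0-based within each subject.
``group`` is ``control`` or ``insomnia``.  ``start_offset_minutes`` (optional,
constant per subject, default 0) records how many minutes after midnight the
first epoch was taken; :func:`align_to_midnight` consumes it.
``epoch_minutes`` (optional, default 1) is the device summation window P.

No operation in this module ever modifies a count value — only trimming and
reshaping are performed, and every discarded epoch is logged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

GROUP_LABELS = ("control", "insomnia")

COLUMNS = ("subject_id", "group", "epoch_index", "count")
OFFSET_COLUMN = "start_offset_minutes"
EPOCH_COLUMN = "epoch_minutes"


class CohortFormatError(ValueError):
    """A cohort table violates the documented format; message names the line."""


@dataclass
class ActigraphyRecording:
    """One subject's epoch-level activity-count series.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        ``"control"`` or ``"insomnia"``.
    counts : ndarray
        Finite, non-negative activity counts, one per epoch, in temporal
        order (integers for real devices; reals allowed for noiseless
        synthetic data).
    epoch_minutes : int
        Epoch summation window P in minutes; must divide 1440.
    start_offset_minutes : int
        Minutes after midnight of the first epoch (0 once aligned).
    """

    subject_id: str
    group: str
    counts: np.ndarray
    epoch_minutes: int = 1
    start_offset_minutes: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group!r}")
        if self.epoch_minutes <= 0 or MINUTES_PER_DAY % self.epoch_minutes != 0:
            raise ValueError(
                f"epoch_minutes={self.epoch_minutes} must be positive and divide 1440"
            )
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def day_length(self) -> int:
        """Epochs per 24 h day, l = 1440 / epoch_minutes."""
        return MINUTES_PER_DAY // self.epoch_minutes

    def __len__(self) -> int:
        return self.counts.size


@dataclass
class DayMatrix:
    """A subject's recording reshaped into whole 24 h day rows.

    ``days`` has shape (D_s, l): one row y_{s,k}(t) per observed day.
    """

    subject_id: str
    group: str
    days: np.ndarray
    epoch_minutes: int = 1

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        if self.days.ndim != 2 or self.days.shape[0] < 1:
            raise ValueError("days must be a 2-D array with at least one row")

    @property
    def n_days(self) -> int:
        return self.days.shape[0]

    @property
    def day_length(self) -> int:
        return self.days.shape[1]


def read_cohort(path: str | Path, *, fill_gaps: bool = False) -> list[ActigraphyRecording]:
    """Read a cohort table into one recording per subject.

    Malformed rows raise :class:`CohortFormatError` naming the offending
    line number (1-based, header on line 1).  Missing epoch indices are a
    hard error unless ``fill_gaps`` is set, in which case they are
    zero-filled and logged.
    """
    path = Path(path)
    # per-subject accumulation: epoch_index -> count
    data: dict[str, dict[int, float]] = {}
    meta: dict[str, tuple[str, int]] = {}
    order: list[str] = []

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if tuple(header[:4]) != COLUMNS:
            raise CohortFormatError(
                f"{path}: line 1: expected header {','.join(COLUMNS)}"
                f"[,{OFFSET_COLUMN}[,{EPOCH_COLUMN}]], got {','.join(header)}"
            )
        extras = {name: 4 + i for i, name in enumerate(header[4:])}
        unknown = set(extras) - {OFFSET_COLUMN, EPOCH_COLUMN}
        if unknown:
            raise CohortFormatError(
                f"{path}: line 1: unknown column(s) {sorted(unknown)}"
            )

        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 4:
                raise CohortFormatError(f"{path}: line {lineno}: expected ≥4 columns")
            sid, group = row[0].strip(), row[1].strip()
            if group not in GROUP_LABELS:
                raise CohortFormatError(
                    f"{path}: line {lineno}: unknown group label {group!r}"
                )
            try:
                idx = int(row[2])
            except ValueError:
                raise CohortFormatError(
                    f"{path}: line {lineno}: non-integer epoch_index {row[2]!r}"
                ) from None
            try:
                count = float(row[3])
            except ValueError:
                raise CohortFormatError(
                    f"{path}: line {lineno}: non-numeric count {row[3]!r}"
                ) from None
            if not np.isfinite(count) or count < 0:
                raise CohortFormatError(
                    f"{path}: line {lineno}: count must be finite and non-negative, "
                    f"got {row[3]!r}"
                )
            offset, epoch = 0, 1
            for name, default in ((OFFSET_COLUMN, 0), (EPOCH_COLUMN, 1)):
                col = extras.get(name)
                if col is not None and len(row) > col and row[col].strip():
                    try:
                        value = int(row[col])
                    except ValueError:
                        raise CohortFormatError(
                            f"{path}: line {lineno}: non-integer {name} "
                            f"{row[col]!r}"
                        ) from None
                    if name == OFFSET_COLUMN:
                        offset = value
                    else:
                        epoch = value

            if sid not in data:
                data[sid] = {}
                meta[sid] = (group, offset, epoch)
                order.append(sid)
            elif meta[sid][0] != group:
                raise CohortFormatError(
                    f"{path}: line {lineno}: subject {sid!r} has conflicting group labels"
                )
            if idx in data[sid]:
                raise CohortFormatError(
                    f"{path}: line {lineno}: duplicate epoch {idx} for subject {sid!r}"
                )
            data[sid][idx] = count

    recordings = []
    for sid in order:
        group, offset, epoch = meta[sid]
        epochs = data[sid]
        n = max(epochs) + 1
        missing = n - len(epochs)
        if missing:
            if not fill_gaps:
                gaps = sorted(set(range(n)) - set(epochs))
                raise CohortFormatError(
                    f"{path}: subject {sid!r} is missing {missing} epoch(s) "
                    f"(first gap at index {gaps[0]}); pass fill_gaps=True to zero-fill"
                )
            logger.warning("subject %s: zero-filled %d missing epoch(s)", sid, missing)
        counts = np.zeros(n)
        for idx, c in epochs.items():
            counts[idx] = c
        recordings.append(
            ActigraphyRecording(
                subject_id=sid, group=group, counts=counts,
                epoch_minutes=epoch, start_offset_minutes=offset,
            )
        )
    return recordings


def write_cohort(recordings: Iterable[ActigraphyRecording], path: str | Path) -> None:
    """Write recordings as a cohort table (inverse of :func:`read_cohort`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(COLUMNS) + [OFFSET_COLUMN, EPOCH_COLUMN])
        for rec in recordings:
            for idx, c in enumerate(rec.counts):
                # store integers without a trailing .0 so device data round-trips
                val = int(c) if float(c).is_integer() else repr(float(c))
                writer.writerow(
                    [rec.subject_id, rec.group, idx, val,
                     rec.start_offset_minutes, rec.epoch_minutes]
                )


def align_to_midnight(recording: ActigraphyRecording) -> ActigraphyRecording:
    """Trim leading epochs so the recording starts at the first midnight.

    Recordings whose start offset is already 0 are returned unchanged.
    Raises ``ValueError`` ("no whole day available") when the recording
    ends before its first midnight; a recording shorter than one whole
    day after trimming is left for :func:`segment_days` to reject.
    """
    offset = recording.start_offset_minutes
    if offset % recording.epoch_minutes != 0:
        raise ValueError(
            f"start offset {offset} min is not a multiple of the "
            f"{recording.epoch_minutes} min epoch"
        )
    if offset == 0:
        return recording
    drop = (MINUTES_PER_DAY - offset % MINUTES_PER_DAY) % MINUTES_PER_DAY
    drop //= recording.epoch_minutes
    remaining = len(recording) - drop
    if remaining <= 0:
        raise ValueError(
            f"subject {recording.subject_id}: no whole day available — the "
            "recording ends before its first midnight"
        )
    logger.info(
        "subject %s: dropped %d leading epoch(s) (sum %.0f) aligning to midnight",
        recording.subject_id, drop, recording.counts[:drop].sum(),
    )
    return replace(
        recording, counts=recording.counts[drop:], start_offset_minutes=0
    )


def segment_days(recording: ActigraphyRecording) -> DayMatrix:
    """Partition a midnight-aligned recording into whole 24 h day rows.

    The trailing partial day, if any, is discarded and logged.
    """
    if recording.start_offset_minutes != 0:
        raise ValueError(
            f"subject {recording.subject_id}: recording must be midnight-aligned "
            "before segmentation (call align_to_midnight)"
        )
    l = recording.day_length
    n_days = len(recording) // l
    if n_days < 1:
        raise ValueError(
            f"subject {recording.subject_id}: fewer than one whole day "
            f"({len(recording)} epochs < l={l})"
        )
    trailing = len(recording) - n_days * l
    if trailing:
        logger.info(
            "subject %s: discarded trailing partial day of %d epoch(s) (sum %.0f)",
            recording.subject_id, trailing, recording.counts[n_days * l:].sum(),
        )
    return DayMatrix(
        subject_id=recording.subject_id,
        group=recording.group,
        days=recording.counts[: n_days * l].reshape(n_days, l),
        epoch_minutes=recording.epoch_minutes,
    )


def cohort_day_matrices(
    recordings: Sequence[ActigraphyRecording],
) -> list[DayMatrix]:
    """Align and segment every recording of a cohort."""
    return [segment_days(align_to_midnight(rec)) for rec in recordings]
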