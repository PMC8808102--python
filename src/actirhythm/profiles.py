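"""Motion probability density functions at day, subject and group level.

Each whole-day count vector y_{s,k}(t) is normalized by its total count
C_{s,k} = Σ_t y_{s,k}(t) to give a motion PDF P_{s,k}(t) — the probability
that a movement count occurs at minute t of that day.  Subject-level PDFs
average a subject's day PDFs (each day weighted 1/D_s), and group-level
PDFs average subject PDFs with equal weight per subject regardless of how
many days each contributed — so a subject observed 14 days counts the same
as one observed 7.

All-zero days carry no timing information and cannot be normalized; they
are flagged degenerate and excluded from averages with a logged warning,
never silently replaced by a uniform density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import DayMatrix

logger = logging.getLogger(__name__)

SUM_TOL = 1e-9  # double precision headroom at l = 1440

PROVENANCE_LEVELS = ("day", "subject_mean", "group_mean")


class DegenerateDayError(ValueError):
    """An all-zero day vector cannot be normalized into a PDF."""


@dataclass
class MotionPDF:
    """A length-l non-negative vector summing to 1 (within 1e-9).

    ``provenance`` records the averaging level (``day``, ``subject_mean``
    or ``group_mean``); ``label`` carries the identifier (subject id or
    group name) for reporting.
    """

    values: np.ndarray
    provenance: str = "day"
    label: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCE_LEVELS:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("PDF values must be one-dimensional")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("PDF values must be finite and non-negative")
        total = self.values.sum()
        if abs(total - 1.0) > SUM_TOL:
            raise ValueError(f"PDF must sum to 1 within {SUM_TOL}, got {total!r}")

    @property
    def l(self) -> int:
        return self.values.size


def normalize_day(y: np.ndarray, *, label: str = "") -> MotionPDF:
    """Normalize one day's counts into a motion PDF: P(t) = y(t) / Σ y.

    Raises :class:`DegenerateDayError` when the day total is zero.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("day vector must be finite and non-negative")
    total = y.sum()
    if total == 0:
        raise DegenerateDayError("all-zero day: no PDF defined")
    return MotionPDF(values=y / total, provenance="day", label=label)


def day_pdfs(matrix: DayMatrix) -> list[MotionPDF]:
    """Per-day PDFs for one subject, excluding degenerate days (logged)."""
    pdfs = []
    n_degenerate = 0
    for k, row in enumerate(matrix.days):
        try:
            pdfs.append(normalize_day(row, label=f"{matrix.subject_id}/day{k}"))
        except DegenerateDayError:
            n_degenerate += 1
    if n_degenerate:
        logger.warning(
            "subject %s: excluded %d degenerate (all-zero) day(s) from PDFs",
            matrix.subject_id, n_degenerate,
        )
    return pdfs


def _mean_pdf(pdfs: Sequence[MotionPDF], provenance: str, label: str) -> MotionPDF:
    if not pdfs:
        raise ValueError("cannot average an empty list of PDFs")
    lengths = {p.l for p in pdfs}
    if len(lengths) > 1:
        raise ValueError(f"PDFs have mixed lengths {sorted(lengths)}")
    mean = np.mean([p.values for p in pdfs], axis=0)
    return MotionPDF(values=mean, provenance=provenance, label=label)


def subject_mean_pdf(pdfs: Sequence[MotionPDF], *, label: str = "") -> MotionPDF:
    """Average one subject's day PDFs: Σ_k P_{s,k}(t) / D_s."""
    return _mean_pdf(pdfs, "subject_mean", label)


def group_mean_pdf(subject_pdfs: Sequence[MotionPDF], *, label: str = "") -> MotionPDF:
    """Unweighted mean over subjects of their subject-mean PDFs.

    Each subject counts once regardless of days observed (divide by D_s
    inside the subject mean, by the number of subjects outside).
    """
    return _mean_pdf(subject_pdfs, "group_mean", label)


def group_profiles(matrices: Sequence[DayMatrix]) -> dict[str, MotionPDF]:
    """Group-mean motion PDFs, one per group label present in the cohort."""
    by_group: dict[str, list[MotionPDF]] = {}
    for m in matrices:
        pdfs = day_pdfs(m)
        if not pdfs:
            logger.warning(
                "subject %s: every day degenerate; subject excluded", m.subject_id
            )
            continue
        by_group.setdefault(m.group, []).append(
            subject_mean_pdf(pdfs, label=m.subject_id)
        )
    return {
        g: group_mean_pdf(subs, label=g) for g, subs in sorted(by_group.items())
    }


def write_pdf(pdf: MotionPDF, path: str | Path) -> None:
    """Write a PDF as tabular text (t, value) with a provenance header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# provenance={pdf.provenance} label={pdf.label} l={pdf.l}\n")
        fh.write("t\tvalue\n")
        for t, v in enumerate(pdf.values):
            fh.write(f"{t}\t{float(v)!r}\n")


def read_pdf(path: str | Path) -> MotionPDF:
    """Read a PDF written by :func:`write_pdf`."""
    path = Path(path)
    provenance, label = "day", ""
    values = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, val = token.partition("=")
                    if key == "provenance":
                        provenance = val
                    elif key == "label":
                        label = val
                continue
            if line.startswith("t\t"):
                continue
            _, _, v = line.partition("\t")
            values.append(float(v))
    return MotionPDF(values=np.array(values), provenance=provenance, label=label)
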