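"""Jaccard distance between motion PDFs and the delayed Jaccard curve.

For two PDFs P, Q on the same circular day grid,

    J(P, Q) = 1 − Σ_t min(P(t), Q(t)) / Σ_t max(P(t), Q(t))

is a proper distance in [0, 1]: 0 for identical densities, 1 for densities
with disjoint support.  Imposing periodic boundary conditions gives the
delayed Jaccard curve

    J(τ) = J(P, Q(· + τ)),   τ = 0, …, l−1,

whose minimizer τ_min estimates the temporal shift between the two
activity profiles: τ_min is the amount by which Q must be *advanced*
(rotated toward earlier clock time) to best overlap P.  With P the control
group profile and Q the insomnia profile, τ_min > 0 reads "insomnia lags
control by τ_min minutes".

Worked toy example (l = 8): if Q(t) = P(t − 3), i.e. Q is P delayed by 3
epochs, then Q(t + 3) = P(t), the curve attains exactly 0 at τ = 3 and
τ_min = 3.

The plateau is the maximal circular run of consecutive shifts whose J
value lies within ``plateau_tol`` of the minimum and which contains
τ_min; its width quantifies how sharply the shift is determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import MotionPDF

DEFAULT_PLATEAU_TOL = 1e-3  # absolute, in J units


def _values(p: MotionPDF | np.ndarray) -> np.ndarray:
    return p.values if isinstance(p, MotionPDF) else np.asarray(p, dtype=float)


@dataclass
class DelayedJaccardCurve:
    """J(τ) over all circular shifts, with its minimizer and plateau.

    ``plateau`` is a circular interval (lo, hi) of epoch shifts; widths
    wrap through l, so lo may exceed hi.
    """

    values: np.ndarray
    tau_min: int
    plateau: tuple[int, int]
    plateau_tol: float
    epoch_minutes: int = 1

    @property
    def l(self) -> int:
        return self.values.size

    @property
    def taus(self) -> np.ndarray:
        return np.arange(self.l)

    @property
    def tau_min_minutes(self) -> float:
        return self.tau_min * self.epoch_minutes

    @property
    def plateau_width_epochs(self) -> int:
        lo, hi = self.plateau
        return (hi - lo) % self.l + 1

    @property
    def plateau_width_minutes(self) -> float:
        return self.plateau_width_epochs * self.epoch_minutes

    @property
    def min_value(self) -> float:
        return float(self.values[self.tau_min])


def jaccard_distance(p: MotionPDF | np.ndarray, q: MotionPDF | np.ndarray) -> float:
    """Jaccard distance between two PDFs on the same grid."""
    pv, qv = _values(p), _values(q)
    if pv.size != qv.size:
        raise ValueError(f"length mismatch: {pv.size} vs {qv.size}")
    denom = np.maximum(pv, qv).sum()
    if denom == 0:
        raise ValueError("both PDFs are identically zero")
    return float(1.0 - np.minimum(pv, qv).sum() / denom)


def delayed_jaccard(
    p: MotionPDF | np.ndarray,
    q: MotionPDF | np.ndarray,
    *,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
    epoch_minutes: int = 1,
) -> DelayedJaccardCurve:
    """Delayed Jaccard curve J(τ) = J(P, Q(·+τ)) for τ = 0 … l−1.

    Shifts are evaluated at epoch resolution only; Q(·+τ) means the values
    of Q rotated so that epoch t reads Q((t+τ) mod l).
    """
    pv, qv = _values(p), _values(q)
    if pv.size != qv.size:
        raise ValueError(f"length mismatch: {pv.size} vs {qv.size}")
    l = pv.size
    # all rotations at once: rot[tau, t] = q[(t + tau) % l]
    idx = (np.arange(l)[:, None] + np.arange(l)[None, :]) % l
    rot = qv[idx]
    mins = np.minimum(pv[None, :], rot).sum(axis=1)
    maxs = np.maximum(pv[None, :], rot).sum(axis=1)
    values = 1.0 - mins / maxs
    tau_min, plateau = find_plateau(values, plateau_tol)
    return DelayedJaccardCurve(
        values=values,
        tau_min=tau_min,
        plateau=plateau,
        plateau_tol=plateau_tol,
        epoch_minutes=epoch_minutes,
    )


def find_plateau(
    values: np.ndarray, plateau_tol: float = DEFAULT_PLATEAU_TOL
) -> tuple[int, tuple[int, int]]:
    """Locate the global minimizer and its surrounding plateau.

    Ties in the global minimum are broken toward the shift circularly
    closest to 0 (so a shift of l−30 beats one of 40), then toward the
    smaller shift index, making the output deterministic.  The plateau is
    the maximal circular run of consecutive shifts with value ≤ min +
    ``plateau_tol`` that contains the minimizer.
    """
    values = np.asarray(values, dtype=float)
    l = values.size
    vmin = values.min()
    candidates = np.flatnonzero(values == vmin)
    tau_min = int(min(candidates, key=lambda t: (min(t, l - t), t)))

    ok = values <= vmin + plateau_tol
    if ok.all():
        return tau_min, (0, l - 1)
    lo = tau_min
    while ok[(lo - 1) % l]:
        lo -= 1
    hi = tau_min
    while ok[(hi + 1) % l]:
        hi += 1
    return tau_min, (lo % l, hi % l)


def write_curve(curve: DelayedJaccardCurve, path) -> None:
    """Write the (τ, J) table plus a summary header line as tabular text."""
    from pathlib import Path

    path = Path(path)
    lo, hi = curve.plateau
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            f"# tau_min={curve.tau_min} tau_min_minutes={curve.tau_min_minutes} "
            f"J_min={curve.min_value!r} plateau_lo={lo} plateau_hi={hi} "
            f"plateau_width_minutes={curve.plateau_width_minutes} "
            f"plateau_tol={curve.plateau_tol} epoch_minutes={curve.epoch_minutes}\n"
        )
        fh.write("tau\tJ\n")
        for tau, v in enumerate(curve.values):
            fh.write(f"{tau}\t{float(v)!r}\n")
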