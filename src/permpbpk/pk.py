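"""Non-compartmental PK metrics for toxicokinetic series.

24-h area under the concentration-time curve (linear trapezoid, no
extrapolation), time of maximal concentration, terminal half-life from a
log-linear fit of the points strictly after Tmax, named AUC ratios
(tissue/blood, accumulation, feto-maternal, cis/trans), and the
limit-of-quantification substitution rule used throughout the study
(detected-but-below-LOQ values enter as LOQ/2; non-detected values are
excluded).

Group-sacrifice (destructive-sampling) designs yield one composite curve
per matrix: :func:`composite_curve` averages the replicate concentrations at
each sampling time, which is how the observed AUCs are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NCAResult",
    "auc_trapezoid",
    "tmax",
    "half_life",
    "nca",
    "ratios",
    "loq_substitute",
    "composite_curve",
]


@dataclass(frozen=True)
class NCAResult:
    """Summary metrics of one concentration-time curve."""

    auc_0_24: float  # ug.h/ml (blood) or ug.h/g (tissue)
    tmax: float  # h
    t_half: float | None  # h; None when the terminal phase is not estimable
    n_points_used: int

    def __post_init__(self) -> None:
        if self.auc_0_24 < 0:
            raise ValueError("AUC must be non-negative")
        if self.t_half is not None and self.t_half <= 0:
            raise ValueError("defined half-life must be positive")


def _validate(times, concs, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concentrations must be 1-d and equal length")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(t < 0) or np.any(c < 0) or not np.all(np.isfinite(t) & np.isfinite(c)):
        raise ValueError("times and concentrations must be finite and non-negative")
    return t, c


def auc_trapezoid(times: Sequence[float], concs: Sequence[float]) -> float:
    """Linear-trapezoid AUC over the provided points (no extrapolation)."""
    t, c = _validate(times, concs, 2)
    return float(np.trapezoid(c, t))


def tmax(times: Sequence[float], concs: Sequence[float]) -> float:
    """Sampling time of the maximal concentration; ties break earliest."""
    t, c = _validate(times, concs, 1)
    return float(t[int(np.argmax(c))])


def half_life(times: Sequence[float], concs: Sequence[float]) -> float | None:
    """Terminal half-life ln2/lambda from the points at and after Tmax.

    lambda is the negated least-squares slope of ln(concentration) on time
    over all positive-concentration points from the peak onward (the peak
    itself included: with 7-point sacrifice designs and a 6-h Tmax only two
    later samples exist, yet the study reports a defined half-life there).
    Returns ``None`` (the study's "-" entries) with fewer than 3 usable
    terminal points or a non-positive elimination slope.
    """
    t, c = _validate(times, concs, 1)
    t_max = tmax(t, c)
    sel = (t >= t_max) & (c > 0)
    if sel.sum() < 3:
        return None
    fit = stats.linregress(t[sel], np.log(c[sel]))
    lam = -fit.slope
    if lam <= 0:
        return None
    return float(math.log(2.0) / lam)


def nca(times: Sequence[float], concs: Sequence[float]) -> NCAResult:
    """AUC(0-24), Tmax and terminal half-life of one curve."""
    t, c = _validate(times, concs, 2)
    return NCAResult(
        auc_0_24=auc_trapezoid(t, c),
        tmax=tmax(t, c),
        t_half=half_life(t, c),
        n_points_used=int(t.size),
    )


def composite_curve(
    times: Sequence[float], concs: Sequence[float], anchor_zero: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Composite mean curve from destructive-sampling data.

    Averages replicate concentrations at each distinct sampling time (each
    animal contributes a single time point).  ``anchor_zero`` prepends a
    (0, 0) point, the pre-dose anchor used for observed 1-24 h designs.
    NaN concentrations (non-detected records) are dropped.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    keep = np.isfinite(c)
    t, c = t[keep], c[keep]
    if t.size == 0:
        raise ValueError("no quantifiable points in the series")
    uniq = np.unique(t)
    means = np.array([c[t == u].mean() for u in uniq])
    if anchor_zero and uniq[0] > 0:
        uniq = np.insert(uniq, 0, 0.0)
        means = np.insert(means, 0, 0.0)
    return uniq, means


def ratios(
    auc_map: Mapping[str, float], pairs: Mapping[str, tuple[str, str]]
) -> dict[str, float]:
    """Named AUC quotients (tissue/blood, GDx/GD1 accumulation, feto/maternal, ...).

    ``pairs`` maps a ratio name to the (numerator, denominator) keys of
    ``auc_map``.  A missing key raises ``KeyError`` naming it.
    """
    out: dict[str, float] = {}
    for name, (num, den) in pairs.items():
        for key in (num, den):
            if key not in auc_map:
                raise KeyError(f"ratio {name!r} needs AUC entry {key!r}, not provided")
        out[name] = auc_map[num] / auc_map[den]
    return out


def loq_substitute(value: float, loq: float, detected: bool = True) -> float:
    """Apply the study's LOQ rule to one measured concentration.

    Quantified values (>= LOQ) pass through; detected-but-below-LOQ values
    are set to LOQ/2; non-detected values become NaN (excluded marker).
    """
    if loq <= 0:
        raise ValueError("LOQ must be positive")
    if not detected:
        return float("nan")
    if value >= loq:
        return float(value)
    return loq / 2.0
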