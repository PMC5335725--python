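"""Detection of the dithionite-addition time point in fluorescence traces.

Adding the membrane-impermeable reductant produces the one sustained,
steep drop in an otherwise flat-then-decaying trace. The detector locates
it as the maximal ridge-supported peak of the continuous wavelet transform
(Ricker / Mexican-hat wavelet, dyadic scale ladder covering 2-64 samples)
of the negated first difference of the intensity series:

* a peak must be supported by a ridge across at least three adjacent
  scales (noise spikes are not),
* its best coefficient must exceed five times the median absolute wavelet
  coefficient at the scale where that coefficient was attained (the noise
  floor of its own scale),
* among accepted peaks the largest coefficient wins; ties go to the
  earliest time.

The wavelet ridge locates the drop region and gates it against noise, but
the Ricker wavelet is symmetric while the negated-difference pulse of a
reduction trace is one-sided (sharp onset, exponential tail), so the raw
ridge position sits a few samples late of the true onset. The final index
is therefore refined by a local least-squares changepoint fit of the
piecewise model (flat plateau, then offset exponential decay) to the raw
intensities inside the ridge window; the exponential rate is profiled
over a coarse geometric grid, the segment amplitudes are linear and
solved exactly. Ties prefer the earliest candidate.

The returned index is the sample immediately preceding the steepest
sustained drop. A manual per-record addition time may bypass detection
entirely (``method="manual"``), which matters when algorithmic and visual
calls diverge on unusual traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.optimize import minimize_scalar

from .errors import DetectionError
from .io import Trace

__all__ = ["AdditionCall", "detect_addition_time", "manual_addition_call", "align_traces"]

#: Dyadic CWT scale ladder, in samples.
SCALES = (2, 4, 8, 16, 32, 64)
#: Minimum number of adjacent scales a ridge must span.
RIDGE_MIN_LENGTH = 3
#: Peak coefficient must exceed this multiple of the smallest-scale
#: median absolute coefficient.
NOISE_FLOOR_FACTOR = 5.0
#: Minimum number of samples required on each side of the addition point
#: (the ten-point median windows plus margin).
EDGE_MARGIN = 10


@dataclass(frozen=True)
class AdditionCall:
    """The detected (or manually supplied) dithionite-addition point."""

    index: int  # last pre-addition sample
    time_s: float
    confidence: float  # CWT coefficient of the winning peak (0 for manual)
    method: str  # "cwt" or "manual"


def _local_maxima(row: np.ndarray) -> np.ndarray:
    """Indices of strictly positive interior local maxima."""
    if row.size < 3:
        return np.empty(0, dtype=int)
    interior = (row[1:-1] >= row[:-2]) & (row[1:-1] > row[2:]) & (row[1:-1] > 0)
    return np.flatnonzero(interior) + 1


def _check_index(index: int, n: int, where: str) -> None:
    if index < EDGE_MARGIN or index > n - EDGE_MARGIN:
        raise DetectionError(
            f"{where}: addition point at sample {index} is too close to the "
            f"trace edge (need {EDGE_MARGIN} samples on both sides); supply a "
            "manual addition time or acquire a longer baseline"
        )


#: Half-width (samples) of the candidate window for changepoint refinement.
REFINE_HALFWIDTH = 12
#: Samples of baseline/decay context used by the refinement fit.
REFINE_LEFT, REFINE_RIGHT = 45, 150


def _refine_changepoint(time_s: np.ndarray, intensity: np.ndarray, p: int) -> int:
    """Refine the ridge position ``p`` to the last pre-addition sample.

    Scans candidate changepoints around ``p``; for each, the left segment
    is fit as a constant and the right segment as ``B + A*exp(-k*tau)``
    with ``k`` profiled over a geometric grid (amplitudes solved by linear
    least squares). Returns the earliest candidate attaining the minimal
    total residual sum of squares.
    """
    n = intensity.size
    c_lo = max(2, p - REFINE_HALFWIDTH)
    c_hi = min(n - 11, p + REFINE_HALFWIDTH)
    if c_hi <= c_lo:
        return p
    lo = max(0, c_lo - REFINE_LEFT)
    hi = min(n - 1, c_hi + REFINE_RIGHT)
    dt = float(np.median(np.diff(time_s)))
    k_grid = np.geomspace(0.005, 0.5, 12) / dt

    def rss_decay(k: float, right: np.ndarray, tau: np.ndarray) -> float:
        basis = np.column_stack([np.ones_like(tau), np.exp(-k * tau)])
        coef, res, *_ = np.linalg.lstsq(basis, right, rcond=None)
        if coef[1] < 0:  # decay amplitude must be non-negative
            return float(np.sum((right - right.mean()) ** 2))
        if res.size:
            return float(res[0])
        return float(np.sum((right - basis @ coef) ** 2))

    candidates = np.arange(c_lo, c_hi + 1)
    rss = np.full(candidates.size, np.inf)
    for i, c in enumerate(candidates):
        left = intensity[lo : c + 1]
        rss_left = float(np.sum((left - left.mean()) ** 2))
        right = intensity[c + 1 : hi + 1]
        tau = time_s[c + 1 : hi + 1] - time_s[c + 1]
        grid_vals = [rss_decay(k, right, tau) for k in k_grid]
        j = int(np.argmin(grid_vals))
        best_right = grid_vals[j]
        # continuous refinement of the rate around the best grid point
        bounds = (
            np.log(k_grid[max(0, j - 1)]),
            np.log(k_grid[min(k_grid.size - 1, j + 1)]),
        )
        if bounds[1] > bounds[0]:
            opt = minimize_scalar(
                lambda lnk: rss_decay(np.exp(lnk), right, tau),
                bounds=bounds,
                method="bounded",
                options={"xatol": 1e-3},
            )
            best_right = min(best_right, float(opt.fun))
        rss[i] = rss_left + best_right
    if not np.any(np.isfinite(rss)):
        return p
    tol = np.min(rss) * (1.0 + 1e-9) + 1e-12
    return int(candidates[np.flatnonzero(rss <= tol)[0]])


def detect_addition_time(trace: Trace) -> AdditionCall:
    """Locate the dithionite-addition point of a single trace.

    Returns the index of the last pre-addition sample. Raises
    :class:`DetectionError` when no peak rises above the noise floor
    (e.g. a constant trace), instructing a manual override.
    """
    d = -np.diff(trace.intensity)
    coeffs, _ = pywt.cwt(d, np.asarray(SCALES, dtype=float), "mexh")
    maxima = [_local_maxima(coeffs[j]) for j in range(len(SCALES))]
    floors = NOISE_FLOOR_FACTOR * np.median(np.abs(coeffs), axis=1)

    # Seed ridges at the coarsest scale and walk them down to the finest
    # reachable scale; the finest position localizes the peak.
    candidates: list[tuple[float, int]] = []  # (ridge max coefficient, index)
    for seed in maxima[-1]:
        pos = int(seed)
        rows = [len(SCALES) - 1]
        positions = [pos]
        for j in range(len(SCALES) - 2, -1, -1):
            cand = maxima[j]
            if cand.size == 0:
                break
            k = int(cand[np.argmin(np.abs(cand - pos))])
            if abs(k - pos) > SCALES[j + 1]:
                break
            pos = k
            rows.append(j)
            positions.append(k)
        if len(positions) < RIDGE_MIN_LENGTH:
            continue
        ridge_coefs = [float(coeffs[r][p]) for r, p in zip(rows, positions)]
        i_best = int(np.argmax(ridge_coefs))
        coef = ridge_coefs[i_best]
        if coef > floors[rows[i_best]] and coef > 0.0:
            candidates.append((coef, pos))

    if not candidates:
        raise DetectionError(
            f"{trace.source_path}: no dithionite-addition step detected above "
            "the noise floor; supply a manual addition time for this spectrum"
        )
    best_coef, ridge_idx = max(candidates, key=lambda cp: (cp[0], -cp[1]))
    best_idx = _refine_changepoint(trace.time_s, trace.intensity, ridge_idx)
    _check_index(best_idx, len(trace), trace.source_path)
    return AdditionCall(
        index=best_idx,
        time_s=float(trace.time_s[best_idx]),
        confidence=best_coef,
        method="cwt",
    )


def manual_addition_call(trace: Trace, time_s: float) -> AdditionCall:
    """Build an :class:`AdditionCall` from a user-supplied addition time."""
    index = int(np.searchsorted(trace.time_s, time_s, side="left")) - 1
    if index < 0:
        raise DetectionError(
            f"{trace.source_path}: manual addition time {time_s} s precedes "
            "the first sample"
        )
    _check_index(index, len(trace), trace.source_path)
    return AdditionCall(
        index=index, time_s=float(trace.time_s[index]), confidence=0.0, method="manual"
    )


def align_traces(
    traces: list[tuple[Trace, AdditionCall]], adjust: bool = True
) -> list[Trace]:
    """Shift each trace so its addition call sits at t = 0.

    With ``adjust=False`` the traces pass through untouched (the trace-plot
    ``adjust`` flag). Intensities are never modified.
    """
    if not adjust:
        return [trace for trace, _ in traces]
    return [
        replace(trace, time_s=trace.time_s - call.time_s) for trace, call in traces
    ]
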