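"""Gaussian-kernel spike density functions and activity half-duration.

A spike density function (SDF) is built by placing a Gaussian kernel
(default sigma = 100 ms) on every spike and averaging over trials. The SDF
is peak-normalized to [0, 1] and the activity half-duration is the time
from the peak (1) to the half-maximum crossing (0.5); when both sides of
the peak cross, the longer side is reported. Half-duration measures how
phasic a unit's delay-period firing is: a brief bump gives a short
half-duration, persistent elevation never crosses and is censored at the
window edge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import AnalysisWindow, UnitSpikeSet, window_spikes

__all__ = [
    "SpikeDensityFunction",
    "HalfDuration",
    "FlatSDFError",
    "spike_density",
    "sdf_for_unit",
    "normalize_sdf",
    "half_duration",
    "peak_order",
]

DEFAULT_SIGMA_S = 0.1
DEFAULT_DT_S = 0.01
EDGE_MARGIN_SIGMAS = 4.0  # spikes this far outside the window still contribute


class FlatSDFError(ValueError):
    """SDF is constant (max == min); normalization undefined."""


@dataclass
class SpikeDensityFunction:
    time_grid: np.ndarray  # seconds, uniform step dt
    rate: np.ndarray       # Hz per grid point (or unitless if normalized)
    sigma: float
    n_trials: int
    normalized: bool = False

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    def peak_time(self) -> float:
        """Time of the global maximum; earliest grid point on ties."""
        return float(self.time_grid[int(np.argmax(self.rate))])


def spike_density(
    trains: Sequence[np.ndarray],
    window: AnalysisWindow,
    sigma: float = DEFAULT_SIGMA_S,
    dt: float = DEFAULT_DT_S,
) -> SpikeDensityFunction:
    """Trial-averaged Gaussian-kernel SDF on a uniform grid over the window.

    ``trains`` are aligned spike times per trial and may include flanking
    spikes outside [start, end); all supplied spikes contribute, which
    keeps the estimate edge-correct when the caller extracts spikes with a
    margin of a few sigma (see :func:`sdf_for_unit`).
    """
    if len(trains) == 0:
        raise ValueError("spike_density requires at least one trial")
    grid = np.arange(window.start, window.end + dt / 2, dt)
    total = np.zeros_like(grid)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for spikes in trains:
        spikes = np.asarray(spikes, float)
        if spikes.size:
            z = (grid[None, :] - spikes[:, None]) / sigma
            total += norm * np.exp(-0.5 * z**2).sum(axis=0)
    return SpikeDensityFunction(
        time_grid=grid, rate=total / len(trains), sigma=sigma, n_trials=len(trains)
    )


def sdf_for_unit(
    unit: UnitSpikeSet,
    trials: pd.DataFrame,
    window: AnalysisWindow,
    sigma: float = DEFAULT_SIGMA_S,
    dt: float = DEFAULT_DT_S,
) -> SpikeDensityFunction:
    """Condition-averaged SDF of one unit over the given trials.

    Spikes are extracted with a margin of a few kernel widths on both sides
    of the window so mass leaking across the edges is represented.
    """
    margin = EDGE_MARGIN_SIGMAS * sigma
    wide = AnalysisWindow(window.alignment, window.start - margin, window.end + margin)
    trains = [
        window_spikes(unit, trial, wide).times for trial in trials.to_dict("records")
    ]
    out = spike_density(trains, window, sigma=sigma, dt=dt)
    return out


def normalize_sdf(sdf: SpikeDensityFunction) -> SpikeDensityFunction:
    """Min-max normalize to [0, 1]. Raises FlatSDFError on a constant SDF."""
    lo, hi = float(sdf.rate.min()), float(sdf.rate.max())
    if not hi > lo:
        raise FlatSDFError("flat SDF: max equals min, normalization undefined")
    return replace(sdf, rate=(sdf.rate - lo) / (hi - lo), normalized=True)


@dataclass(frozen=True)
class HalfDuration:
    """Peak-to-half-maximum duration of a normalized SDF, seconds."""

    value: float
    peak_time: float
    censored: bool      # True when the reported side never crossed 0.5
    side: str           # "left" | "right"


def _side_half_duration(
    grid: np.ndarray, rate: np.ndarray, peak_idx: int, direction: int
) -> tuple[float, bool]:
    """Distance from the peak to the first 0.5-crossing in one direction.

    Linear interpolation between the grid points bracketing the crossing;
    censored at the window edge when the SDF never drops below 0.5.
    """
    t_peak = grid[peak_idx]
    idx = peak_idx
    while 0 <= idx + direction < len(grid):
        nxt = idx + direction
        if rate[nxt] < 0.5:
            # interpolate between grid[idx] (>= 0.5) and grid[nxt] (< 0.5)
            frac = (rate[idx] - 0.5) / (rate[idx] - rate[nxt])
            t_cross = grid[idx] + frac * (grid[nxt] - grid[idx])
            return abs(t_cross - t_peak), False
        idx = nxt
    return abs(grid[idx] - t_peak), True


def half_duration(sdf: SpikeDensityFunction) -> HalfDuration:
    """Longer of the two peak-to-half-maximum durations.

    The peak is the first grid point attaining the maximum (1). Each side
    is scanned outward for the first crossing below 0.5, interpolated
    linearly. If only one side crosses, that side is reported; if neither
    does, the longer edge distance is reported and flagged censored.
    """
    if not sdf.normalized:
        raise ValueError("half_duration expects a normalized SDF")
    grid, rate = sdf.time_grid, sdf.rate
    peak_idx = int(np.argmax(rate))
    left, left_cens = _side_half_duration(grid, rate, peak_idx, -1)
    right, right_cens = _side_half_duration(grid, rate, peak_idx, +1)
    t_peak = float(grid[peak_idx])
    candidates = []
    if not left_cens:
        candidates.append((left, False, "left"))
    if not right_cens:
        candidates.append((right, False, "right"))
    if candidates:
        value, cens, side = max(candidates, key=lambda c: c[0])
    else:
        value, cens, side = max(
            [(left, True, "left"), (right, True, "right")], key=lambda c: c[0]
        )
    return HalfDuration(value=float(value), peak_time=t_peak, censored=cens, side=side)


def peak_order(norm_sdfs: Mapping[str, SpikeDensityFunction]) -> List[str]:
    """Unit ids sorted by ascending peak time; ties broken by unit_id."""
    return sorted(norm_sdfs, key=lambda uid: (norm_sdfs[uid].peak_time(), uid))
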