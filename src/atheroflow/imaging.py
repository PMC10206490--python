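"""Longitudinal imaging readouts: lumen geometry, stenosis, peak velocity.

Per-slice lumen masks yield cross-sectional area and Feret diameters (the
lumen diameter is the mean of the min and max Feret). The instrumented
artery's patency over time is summarized as the lumen area at the point of
maximum stenosis relative to the pre-cuff baseline, matching slices by
anatomical index from the carotid bifurcation. Doppler traces yield the peak
systolic velocity averaged over three cardiac cycles, likewise reported as a
percentage of baseline.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull

from .types import LumenMeasurement

#: Angular resolution of the rotating-calipers Feret sweep, degrees.
FERET_STEP_DEG = 1.0


def _feret_diameters(points: np.ndarray, step_deg: float = FERET_STEP_DEG) -> tuple[float, float]:
    """Min/max caliper width of a set of unit-square pixels centred on ``points``.

    Projects the convex hull onto directions at ``step_deg`` resolution and
    adds the pixel footprint's support (|cos| + |sin|) so a rasterized shape
    measures its continuous extent, not the centre-to-centre span.
    """
    if len(points) >= 3:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (collinear) masks: sweep all points
            pass
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = points @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0) + np.abs(dirs).sum(axis=1)
    return float(widths.min()), float(widths.max())


def lumen_measurement(mask: np.ndarray, pixel_size: float,
                      slice_index: int = 0) -> LumenMeasurement:
    """Area and Feret diameters of one binary lumen mask.

    ``pixel_size`` in mm/px; area in mm², diameters in mm.
    """
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty lumen mask")
    ys, xs = np.nonzero(mask)
    fmin, fmax = _feret_diameters(np.column_stack([xs, ys]).astype(float))
    return LumenMeasurement(
        slice_index=slice_index,
        area=n * pixel_size**2,
        feret_min=fmin * pixel_size,
        feret_max=fmax * pixel_size,
    )


def max_stenosis_percent(
    followup_areas: Sequence[float], baseline_areas: Sequence[float]
) -> float:
    """Lumen area at the point of maximum stenosis, % of the matched baseline.

    Slices are matched by index from the carotid bifurcation; the reported
    value is 100 x min over slices of (follow-up area / baseline area).
    """
    follow = np.asarray(followup_areas, dtype=float)
    base = np.asarray(baseline_areas, dtype=float)
    if follow.shape != base.shape or follow.ndim != 1 or len(follow) == 0:
        raise ValueError("follow-up and baseline areas must be matching 1-D sequences")
    if np.any(~np.isfinite(base)) or np.any(base <= 0):
        raise ValueError("baseline areas missing or non-positive")
    if np.any(~np.isfinite(follow)) or np.any(follow < 0):
        raise ValueError("follow-up areas missing or negative")
    return float(100.0 * np.min(follow / base))


def peak_systolic_velocity(
    times: np.ndarray,
    velocities: np.ndarray,
    period: float | None = None,
    cycle_bounds: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Mean of the per-cycle velocity maxima over three cardiac cycles.

    Cycle boundaries come from ``cycle_bounds`` when given, otherwise from
    ``period`` (consecutive windows from the trace start), otherwise from
    systolic peak detection. At least three complete cycles are required; the
    last three are averaged. A constant trace returns its value.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and velocities must be matching 1-D arrays")

    if cycle_bounds is None:
        if period is not None:
            # span is inclusive of the final sample's dt
            dt_med = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
            n_cycles = int(np.floor((t[-1] - t[0] + dt_med) / period + 1e-9))
            cycle_bounds = [(t[0] + k * period, t[0] + (k + 1) * period)
                            for k in range(n_cycles)]
        elif np.ptp(v) == 0:
            warnings.warn("constant trace: peak systolic velocity equals the trace value",
                          stacklevel=2)
            return float(v[0])
        else:
            peaks, _ = find_peaks(v, prominence=0.25 * np.ptp(v))
            if len(peaks) < 3:
                raise ValueError("fewer than 3 systolic peaks detected")
            mids = (t[peaks][:-1] + t[peaks][1:]) / 2
            edges = np.concatenate([[t[0]], mids, [t[-1]]])
            cycle_bounds = list(zip(edges[:-1], edges[1:]))

    maxima = []
    for lo, hi in cycle_bounds:
        sel = (t >= lo) & (t < hi)
        if sel.any():
            maxima.append(v[sel].max())
    if len(maxima) < 3:
        raise ValueError("need at least 3 complete cardiac cycles")
    return float(np.mean(maxima[-3:]))


def percent_of_baseline(value: float, baseline_value: float) -> float:
    """100 x value / baseline (baseline must be positive)."""
    if baseline_value <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * value / baseline_value


# group comparisons live in the statistics module; re-exported here because
# the imaging readouts are what feeds them
from .stats import compare_groups, holm_bonferroni  # noqa: E402,F401
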