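"""Synthetic study inputs with known ground truth.

Emulates the four data streams of a carotid-cuff flow-restoration study so
every downstream stage is testable without animal data: stenotic straightened
vessel profiles sampled like an MRI slice stack, pulsatile inlet waveforms
with an optional early-diastolic reversal lobe, annular plaque sections with
exactly constructed stain fractions, and per-mouse cohort tables with known
group effects. Every generator is a pure function of its parameters and seed.

Default physiology (mouse carotid): baseline radius 0.25 mm, cardiac period
0.12 s (500 bpm), peak systolic velocity 0.25 m/s, cycle-mean 0.10 m/s. With
blood viscosity 3.5 mPa·s these give a baseline Poiseuille wall shear
4 mu V/R of 14 Pa at peak systole — the physiological range for this vessel.
The default cuff narrows the lumen to 14% of the baseline cross-sectional
area, the degree of stenosis such a constrictive cuff produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .histomorphometry import rasterize_polygon
from .types import HistoSection, VelocityWaveform, VesselProfile


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic vessel + inlet waveform.

    Lengths in mm, times in s, velocities in m/s. ``stenosis_area_fraction``
    is the minimum lumen area under the cuff relative to baseline; 1 means no
    cuff. ``reversal_depth`` is the magnitude of early-diastolic reverse flow
    as a fraction of the systolic peak (0 = non-reversing waveform).
    """

    baseline_radius: float = 0.25
    stenosis_area_fraction: float = 0.14
    cuff_center: float = 3.0
    cuff_length: float = 1.5
    n_slices: int = 14
    slice_thickness: float = 0.5
    period: float = 0.12
    peak_velocity: float = 0.25
    mean_velocity: float = 0.10
    reversal_depth: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_radius <= 0:
            raise ValueError("baseline radius must be positive")
        if not (0 < self.stenosis_area_fraction <= 1):
            raise ValueError("stenosis_area_fraction must lie in (0, 1]")
        if self.n_slices < 3:
            raise ValueError("need at least 3 slices")
        if self.slice_thickness <= 0 or self.period <= 0 or self.cuff_length <= 0:
            raise ValueError("lengths and period must be positive")
        if not (self.peak_velocity >= self.mean_velocity > 0):
            raise ValueError("require peak_velocity >= mean_velocity > 0")
        if self.reversal_depth < 0:
            raise ValueError("reversal_depth must be >= 0")
        if self.stenosis_area_fraction < 1:
            lo = self.cuff_center - 0.5 * self.cuff_length
            hi = self.cuff_center + 0.5 * self.cuff_length
            if lo < 0 or hi > self.domain_length:
                raise ValueError("cuff interval must lie within the imaged domain")

    @property
    def domain_length(self) -> float:
        """Axial extent covered by the slice stack, mm."""
        return (self.n_slices - 1) * self.slice_thickness


def make_vessel_profile(spec: SyntheticSpec) -> VesselProfile:
    """Straightened stenotic radius profile sampled at the slice stations.

    Outside the cuff the radius is the baseline value; inside, a raised-cosine
    dip whose minimum radius is baseline x sqrt(stenosis_area_fraction), so
    the minimum cross-sectional area is the requested fraction of baseline
    (area scales with radius squared).
    """
    z = np.arange(spec.n_slices) * spec.slice_thickness
    r = np.full(spec.n_slices, spec.baseline_radius)
    if spec.stenosis_area_fraction >= 1.0:
        return VesselProfile(z=z, r=r, cuff_interval=None)
    r_min = spec.baseline_radius * math.sqrt(spec.stenosis_area_fraction)
    half = 0.5 * spec.cuff_length
    inside = np.abs(z - spec.cuff_center) <= half
    bump = 0.5 * (1 + np.cos(np.pi * (z[inside] - spec.cuff_center) / half))
    r[inside] = spec.baseline_radius - (spec.baseline_radius - r_min) * bump
    cuff = (spec.cuff_center - half, spec.cuff_center + half)
    return VesselProfile(z=z, r=r, cuff_interval=cuff)


def make_waveform(spec: SyntheticSpec, n_samples: int = 128) -> VelocityWaveform:
    """One-period pulsatile inlet waveform with exact peak, mean, and minimum.

    Shape: a baseline (diastolic) level plus a raised-cosine systolic pulse
    whose maximum equals ``peak_velocity``, and — when ``reversal_depth`` > 0 —
    a raised-cosine early-diastolic reverse lobe reaching exactly
    −reversal_depth x peak_velocity. The baseline level is solved so the
    discrete time-mean of the samples equals ``mean_velocity`` exactly.
    """
    if n_samples < 64:
        raise ValueError("waveform needs at least 64 samples")
    phases = np.arange(n_samples) / n_samples
    # centre the lobes on sample points so the extrema are attained exactly
    sys_center = round(0.2 * n_samples) / n_samples
    rev_center = round(0.5 * n_samples) / n_samples
    g = _raised_cosine(phases, sys_center, width=0.35)
    h = _raised_cosine(phases, rev_center, width=0.15)

    peak, mean = spec.peak_velocity, spec.mean_velocity
    v_min = -spec.reversal_depth * peak
    g_bar = float(g.mean())
    h_bar = float(h.mean()) if spec.reversal_depth > 0 else 0.0
    if spec.reversal_depth == 0:
        h = np.zeros_like(h)
    base = (mean - peak * g_bar - v_min * h_bar) / (1 - g_bar - h_bar)
    if base > peak + 1e-12:
        raise ValueError("mean_velocity too close to peak for a pulsatile shape")
    if spec.reversal_depth > 0 and base < v_min:
        raise ValueError("mean_velocity unattainable given the reversal depth")
    if spec.reversal_depth == 0 and base < 0:
        raise ValueError("mean_velocity too low for a non-reversing waveform")
    v = base + (peak - base) * g + (v_min - base) * h
    return VelocityWaveform(period=spec.period, phases=phases, velocities=v)


def _raised_cosine(phases: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height raised-cosine lobe of the given support width (cycle fraction)."""
    d = phases - center
    d -= np.round(d)  # periodic distance in [-0.5, 0.5)
    out = np.zeros_like(phases)
    inside = np.abs(d) <= width / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * d[inside] / width))
    return out


def _circle(cx: float, cy: float, radius: float, n: int = 256) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + radius * np.cos(th), cy + radius * np.sin(th)])


def make_histology_section(
    intima_fraction: float,
    stain_fraction: float,
    greyscale: bool = False,
    seed: int = 0,
    offset: float = 0.0,
    image_size: int = 200,
    pixel_size: float = 2.0,
) -> tuple[HistoSection, dict]:
    """Annular plaque section with an exactly constructed stain content.

    Concentric (or, with ``offset`` > 0, eccentric-crescent) lumen/IEL/EEL
    circles are sized so that (IEL area − lumen area)/EEL area equals
    ``intima_fraction``. The stain image holds exactly
    floor(stain_fraction x N_intima) positive pixels inside the intima
    (binary mode), or random greyscale values rescaled so that
    sum / (N_intima x 30) equals ``stain_fraction`` (greyscale mode), using
    the same pixel-centre rasterization the quantification stage uses.
    Returns the section plus a ground-truth record.

    ``offset`` in [0, 1) shifts the lumen centre by that fraction of the
    IEL-lumen radial gap, producing a crescent-shaped intima.
    """
    if not (0 <= intima_fraction < 1):
        raise ValueError("intima_fraction must lie in [0, 1)")
    if stain_fraction < 0 or stain_fraction > 1:
        raise ValueError("stain_fraction must lie in [0, 1]")
    if not (0 <= offset < 1):
        raise ValueError("offset must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    c = image_size / 2.0
    r_eel = 0.42 * image_size
    # keep the lumen open: IEL area fraction exceeds the intima fraction
    r_iel = r_eel * math.sqrt(min(0.96, intima_fraction + 0.36))
    r_lum = math.sqrt(r_iel**2 - intima_fraction * r_eel**2)
    dx = offset * (r_iel - r_lum)

    eel = _circle(c, c, r_eel)
    iel = _circle(c, c, r_iel)
    lumen = iel.copy() if intima_fraction == 0 else _circle(c + dx, c, r_lum)

    shape = (image_size, image_size)
    intima = rasterize_polygon(iel, shape) & ~rasterize_polygon(lumen, shape)
    n_intima = int(intima.sum())
    idx = np.flatnonzero(intima.ravel())

    if greyscale:
        img = np.zeros(shape, dtype=float)
        if n_intima and stain_fraction > 0:
            raw = rng.uniform(0.5, 1.5, size=n_intima)
            vals = raw * (stain_fraction * n_intima * 30.0 / raw.sum())
            img.ravel()[idx] = vals
        kind = "cd68"
    else:
        img = np.zeros(shape, dtype=np.uint8)
        n_pos = int(math.floor(stain_fraction * n_intima))
        chosen = rng.choice(idx, size=n_pos, replace=False) if n_pos else []
        img.ravel()[chosen] = 1
        kind = "oil-red-o"

    section = HistoSection(lumen=lumen, iel=iel, eel=eel, stain_image=img,
                           pixel_size=pixel_size, stain_kind=kind)
    if greyscale or n_intima == 0:
        frac = stain_fraction
        # same operation order as the greyscale quantifier, so the recorded
        # percentage is bit-identical to a perfect recovery
        pct = (100.0 * float(img[intima].sum()) / (n_intima * 30.0)
               if n_intima else math.nan)
    else:
        n_pos = int(math.floor(stain_fraction * n_intima))
        frac = n_pos / n_intima
        pct = 100.0 * n_pos / n_intima
    truth = {
        "intima_fraction": intima_fraction,
        "stain_fraction": frac,
        "stain_fraction_pct": pct,
        "n_intima_px": n_intima,
        "plaque_burden_pct": 100.0 * (r_iel**2 - r_lum**2) / r_eel**2,
        "greyscale": greyscale,
    }
    return section, truth


def make_cohort(
    group_means: dict[str, float],
    sd: float,
    n_per_group: int,
    seed: int = 0,
    region: str = "upstream",
    measurement: str = "value",
    week: int = 9,
) -> pd.DataFrame:
    """Tidy per-mouse cohort table with normally distributed group values."""
    if n_per_group < 3:
        raise ValueError("need at least 3 mice per group")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mu in group_means.items():
        draws = mu + sd * rng.standard_normal(n_per_group)
        for i, val in enumerate(draws):
            rows.append({
                "mouse": f"{group}-{i:02d}", "group": group, "region": region,
                "week": week, "measurement": measurement, "value": float(val),
            })
    return pd.DataFrame(rows)


def default_cuffed_spec(seed: int = 0) -> SyntheticSpec:
    """The default stenotic study condition (14% residual lumen area)."""
    return SyntheticSpec(seed=seed)


def default_uncuffed_spec(seed: int = 0) -> SyntheticSpec:
    """The default baseline/decuffed condition (uniform vessel)."""
    return SyntheticSpec(stenosis_area_fraction=1.0, seed=seed)
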