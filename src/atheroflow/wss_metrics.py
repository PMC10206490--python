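"""Wall-shear-stress readouts: pWSS, TAWSS, OSI over analysis regions.

pWSS is the region-mean WSS magnitude at the instant of peak systolic inlet
velocity; TAWSS the region-mean of the per-station time-averaged |τ|; OSI the
oscillatory shear index 0.5 (1 − |∫τ dt| / ∫|τ| dt), 0 for unidirectional and
0.5 for purely oscillatory shear. In the axisymmetric model the WSS vector is
purely axial, so oscillation means sign reversal of τ.

Region OSI follows the recirculation-zone averaging convention: the mean is
taken over stations with OSI >= 0.01 (OSI localizes to parts of the
recirculation zone); if no station reaches 0.01 the mean is over the entire
segment and a fallback flag is set. OSI is reported rounded to two decimals.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import AnalysisRegions, VelocityWaveform, WallShearSeries, WSSMetrics

#: OSI station-inclusion threshold.
OSI_THRESHOLD = 0.01


def peak_systole_time(waveform: VelocityWaveform) -> float:
    """Cycle phase in [0, 1) of the global velocity maximum (earliest on ties)."""
    v = waveform.velocities
    if np.allclose(v, v[0]):
        warnings.warn("constant waveform: peak systole defaulting to phase 0",
                      stacklevel=2)
        return 0.0
    return float(waveform.phases[int(np.argmax(v))])


def _station_slice(series: WallShearSeries, region: tuple[float, float]) -> np.ndarray:
    lo, hi = region
    mask = (series.z >= lo - 1e-9) & (series.z <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"no wall stations inside region {region}")
    return mask


def _periodic_time_integral(series: WallShearSeries, values: np.ndarray) -> np.ndarray:
    """∫ f dt over one period, trapezoid with periodic wrap; values (nt, ns)."""
    t = np.concatenate([series.t, [series.t[0] + series.period]])
    f = np.vstack([values, values[:1]])
    return np.trapezoid(f, t, axis=0)


def compute_pwss(
    series: WallShearSeries, region: tuple[float, float], t_peak: float
) -> float:
    """Region-mean |τ| at the peak-systole phase (linear interpolation in time).

    ``t_peak`` is a cycle phase in [0, 1).
    """
    mask = _station_slice(series, region)
    phase = np.mod((series.t - series.t[0]) / series.period, 1.0)
    order = np.argsort(phase)
    xp = np.concatenate([phase[order], [phase[order][0] + 1.0]])
    fp = np.vstack([series.tau[order][:, mask], series.tau[order][:1, mask]])
    target = np.mod(t_peak, 1.0)
    i = np.searchsorted(xp, target, side="right") - 1
    i = np.clip(i, 0, len(xp) - 2)
    w = (target - xp[i]) / (xp[i + 1] - xp[i])
    tau_peak = (1 - w) * fp[i] + w * fp[i + 1]
    return float(np.mean(np.abs(tau_peak)))


def compute_tawss(series: WallShearSeries, region: tuple[float, float]) -> float:
    """Region-mean of the per-station time-averaged |τ| over the cycle."""
    mask = _station_slice(series, region)
    per_station = _periodic_time_integral(series, np.abs(series.tau[:, mask]))
    return float(np.mean(per_station) / series.period)


def station_osi(series: WallShearSeries) -> np.ndarray:
    """Per-station OSI = 0.5 (1 − |∫τ dt| / ∫|τ| dt); 0 where shear vanishes."""
    num = np.abs(_periodic_time_integral(series, series.tau))
    den = _periodic_time_integral(series, np.abs(series.tau))
    osi = np.zeros_like(den)
    nz = den > 0
    osi[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    return np.clip(osi, 0.0, 0.5)


def compute_osi(
    series: WallShearSeries,
    region: tuple[float, float],
    threshold: float = OSI_THRESHOLD,
) -> tuple[float, bool]:
    """Region OSI with the >= threshold inclusion rule.

    Mean over stations whose (unrounded) OSI is at least ``threshold``; when
    no station qualifies, the mean over the whole segment with the fallback
    flag set.
    """
    mask = _station_slice(series, region)
    osi = station_osi(series)[mask]
    eligible = osi >= threshold
    if eligible.any():
        return float(osi[eligible].mean()), False
    return float(osi.mean()), True


def compute_metrics(
    series: WallShearSeries,
    regions: AnalysisRegions,
    waveform: VelocityWaveform,
    osi_threshold: float = OSI_THRESHOLD,
) -> list[WSSMetrics]:
    """pWSS/TAWSS/OSI for the upstream and downstream analysis regions."""
    t_peak = peak_systole_time(waveform)
    out = []
    for name, span in (("upstream", regions.upstream), ("downstream", regions.downstream)):
        osi, fallback = compute_osi(series, span, osi_threshold)
        out.append(WSSMetrics(
            region=name,
            pwss=compute_pwss(series, span, t_peak),
            tawss=compute_tawss(series, span),
            osi=osi,
            osi_fallback_used=fallback,
        ))
    return out


def round_osi(value: float) -> float:
    """OSI as reported: rounded to two decimals."""
    return float(np.round(value, 2))
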