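"""Vessel reconstruction and gridding.

Builds the straightened axisymmetric vessel from per-slice lumen measurements
(the imaging analogue of placing best-fit lumen diameters on a straightened
centreline), adds inlet/outlet flow extensions, defines the 2-mm
upstream/downstream analysis regions, and constructs the body-fitted
simulation grid with zoned axial density.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .types import AnalysisRegions, SimulationGrid, VesselProfile

#: Region length flanking the cuff over which metrics are reported, mm.
REGION_LENGTH_MM = 2.0

#: Flow-extension lengths as multiples of the local diameter.
INLET_EXTENSION_DIAMETERS = 1.5
OUTLET_EXTENSION_DIAMETERS = 7.0

#: Default zoned maximum element side lengths, mm (fine near the cuff,
#: medium 2-3 mm away, coarse elsewhere).
FINE_SPACING_MM = 0.013
MEDIUM_SPACING_MM = 0.025
COARSE_SPACING_MM = 0.05


def _radius_from_record(rec: Mapping[str, float]) -> tuple[float | None, float | None]:
    """Return (feret_radius, area_radius) available in one slice record."""
    fr = None
    if rec.get("feret_min") is not None and rec.get("feret_max") is not None:
        fmin, fmax = float(rec["feret_min"]), float(rec["feret_max"])
        if fmin <= 0 or fmax <= 0:
            raise ValueError("Feret diameters must be positive")
        if fmin > fmax:
            raise ValueError("min Feret cannot exceed max Feret")
        # lumen diameter = mean of min/max Feret; radius is half of that
        fr = 0.25 * (fmin + fmax)
    ar = None
    if rec.get("area") is not None:
        area = float(rec["area"])
        if area <= 0:
            raise ValueError("slice areas must be positive")
        ar = math.sqrt(area / math.pi)
    return fr, ar


def reconstruct_profile(
    slice_measurements: Sequence[Mapping[str, float]] | pd.DataFrame,
    slice_thickness: float,
    cuff_interval: tuple[float, float] | None = None,
) -> VesselProfile:
    """Build a straightened radius profile from per-slice lumen measurements.

    Each record may carry ``area`` (mm²) and/or the pair ``feret_min`` /
    ``feret_max`` (mm). When Feret diameters are available for every slice the
    radius is half the mean Feret diameter; otherwise every slice must supply
    an area and the equivalent-circle radius sqrt(A/pi) is used. Mixing the
    two conventions across slices is rejected.
    """
    if isinstance(slice_measurements, pd.DataFrame):
        records: list[Mapping[str, float]] = [
            {k: (None if pd.isna(v) else v) for k, v in row.items()}
            for row in slice_measurements.to_dict("records")
        ]
    else:
        records = list(slice_measurements)
    if len(records) < 3:
        raise ValueError("need at least 3 slices to reconstruct a profile")
    if slice_thickness <= 0:
        raise ValueError("slice thickness must be positive")

    pairs = [_radius_from_record(rec) for rec in records]
    have_feret = [fr is not None for fr, _ in pairs]
    have_area = [ar is not None for _, ar in pairs]
    if all(have_feret):
        radii = np.array([fr for fr, _ in pairs])
    elif all(have_area):
        if any(have_feret):
            raise ValueError(
                "mixed measurement conventions: provide Feret diameters for all "
                "slices or areas for all slices"
            )
        radii = np.array([ar for _, ar in pairs])
    else:
        raise ValueError("every slice needs either both Feret diameters or an area")

    z = np.arange(len(records)) * float(slice_thickness)
    return VesselProfile(z=z, r=radii, cuff_interval=cuff_interval)


def add_flow_extensions(profile: VesselProfile) -> VesselProfile:
    """Prepend/append constant-radius flow extensions of 1.5x / 7x the local diameter.

    Coordinates of the original vessel are preserved (the inlet extension runs
    to negative z), so analysis regions defined on the core domain are
    unaffected. Calling this twice is an error.
    """
    if profile.has_extensions:
        raise ValueError("profile already has flow extensions")
    d_in = 2.0 * profile.r[0]
    d_out = 2.0 * profile.r[-1]
    len_in = INLET_EXTENSION_DIAMETERS * d_in
    len_out = OUTLET_EXTENSION_DIAMETERS * d_out
    dz = float(np.median(np.diff(profile.z)))

    n_in = max(2, math.ceil(len_in / dz))
    z_in = np.linspace(profile.z[0] - len_in, profile.z[0], n_in + 1)[:-1]
    n_out = max(2, math.ceil(len_out / dz))
    z_out = np.linspace(profile.z[-1], profile.z[-1] + len_out, n_out + 1)[1:]

    z = np.concatenate([z_in, profile.z, z_out])
    r = np.concatenate([np.full(n_in, profile.r[0]), profile.r, np.full(n_out, profile.r[-1])])
    return VesselProfile(z=z, r=r, cuff_interval=profile.cuff_interval,
                         extensions=(len_in, len_out))


def _clip_interval(
    lo: float, hi: float, domain: tuple[float, float], label: str
) -> tuple[tuple[float, float], bool]:
    clo, chi = max(lo, domain[0]), min(hi, domain[1])
    clipped = (clo > lo + 1e-12) or (chi < hi - 1e-12)
    if chi <= clo:
        raise ValueError(f"{label} analysis region collapses after clipping")
    if clipped:
        warnings.warn(
            f"{label} analysis region clipped to {chi - clo:.3g} mm "
            f"(vessel shorter than the nominal {REGION_LENGTH_MM} mm)",
            stacklevel=3,
        )
    return (clo, chi), clipped


def analysis_regions(profile: VesselProfile) -> AnalysisRegions:
    """2-mm segments immediately upstream/downstream of the cuff.

    Without a cuff (baseline or decuffed vessels where the cuff site cannot be
    located) the central portion is used: two 2-mm intervals abutting the
    midpoint of the un-extended domain. Regions are clipped (with a warning)
    when the vessel is too short.
    """
    core = profile.core_interval
    if profile.cuff_interval is not None:
        c0, c1 = profile.cuff_interval
        up, up_clip = _clip_interval(c0 - REGION_LENGTH_MM, c0, core, "upstream")
        down, down_clip = _clip_interval(c1, c1 + REGION_LENGTH_MM, core, "downstream")
    else:
        mid = 0.5 * (core[0] + core[1])
        up, up_clip = _clip_interval(mid - REGION_LENGTH_MM, mid, core, "upstream")
        down, down_clip = _clip_interval(mid, mid + REGION_LENGTH_MM, core, "downstream")
    return AnalysisRegions(upstream=up, downstream=down,
                           upstream_clipped=up_clip, downstream_clipped=down_clip)


def _zone_breaks(profile: VesselProfile) -> list[tuple[float, float, str]]:
    """Partition the axial domain into (start, end, zone) pieces."""
    z0, z1 = float(profile.z[0]), float(profile.z[-1])
    if profile.cuff_interval is None:
        return [(z0, z1, "coarse")]
    c0, c1 = profile.cuff_interval
    pts = sorted(
        {z0, z1}
        | {np.clip(p, z0, z1) for p in (c0 - 3, c0 - 2, c1 + 2, c1 + 3)}
    )
    pieces = []
    for a, b in zip(pts[:-1], pts[1:]):
        if b - a <= 1e-12:
            continue
        mid = 0.5 * (a + b)
        if c0 - 2 <= mid <= c1 + 2:
            zone = "fine"
        elif c0 - 3 <= mid <= c1 + 3:
            zone = "medium"
        else:
            zone = "coarse"
        pieces.append((a, b, zone))
    return pieces


def build_grid(
    profile: VesselProfile,
    fine_spacing: float = FINE_SPACING_MM,
    medium_spacing: float = MEDIUM_SPACING_MM,
    coarse_spacing: float = COARSE_SPACING_MM,
) -> SimulationGrid:
    """Body-fitted grid with zoned axial density and uniform radial fractions.

    Axial spacing within each zone is at most the zone's maximum element side
    length (fine inside and within 2 mm of the cuff, medium 2-3 mm away,
    coarse elsewhere). The radial fraction axis is uniform with enough
    intervals that the wall-adjacent spacing is <= ``fine_spacing`` at the
    largest radius, so fine zones are always radially resolved. The lumen
    radius between profile stations is interpolated with a monotone cubic
    (PCHIP) to avoid overshoot at the stenosis shoulders.
    """
    if not (0 < fine_spacing <= medium_spacing <= coarse_spacing):
        raise ValueError("need 0 < fine <= medium <= coarse spacing")
    spacing = {"fine": fine_spacing, "medium": medium_spacing, "coarse": coarse_spacing}

    interp = PchipInterpolator(profile.z, profile.r)
    z_parts: list[np.ndarray] = []
    zone_parts: list[np.ndarray] = []
    for a, b, zone in _zone_breaks(profile):
        n = max(1, math.ceil((b - a) / spacing[zone]))
        pts = np.linspace(a, b, n + 1)
        z_parts.append(pts[:-1])
        zone_parts.append(np.full(n, zone, dtype=object))
    z = np.append(np.concatenate(z_parts), profile.z[-1])
    zones = np.append(np.concatenate(zone_parts), zone_parts[-1][-1])

    R = interp(z)
    if np.any(R < 2 * fine_spacing):
        raise ValueError(
            "stenosis unresolvable: lumen radius falls below twice the fine spacing"
        )
    dRdz = interp.derivative()(z)

    n_eta = max(4, math.ceil(float(R.max()) / fine_spacing))
    eta = np.linspace(0.0, 1.0, n_eta + 1)
    return SimulationGrid(z=z, eta=eta, R=np.asarray(R), dRdz=np.asarray(dRdz),
                          zones=np.asarray(zones), profile=profile)
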