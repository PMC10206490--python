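"""Core data containers shared across the pipeline.

Unit conventions: lengths and axial coordinates in millimetres, velocities in
m/s, times in seconds, wall shear stress in pascal. Containers validate their
own invariants on construction; operations live in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood analogue: dynamic viscosity (Pa·s) and density (kg/m³)."""

    viscosity: float = 3.5e-3
    density: float = 1050.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        """ν = μ/ρ in m²/s."""
        return self.viscosity / self.density


@dataclass
class VelocityWaveform:
    """Periodic cross-section-mean (plug) inlet velocity over one cardiac cycle.

    ``phases`` are cycle fractions in [0, 1), strictly increasing; ``velocities``
    are the matching plug velocities in m/s. The waveform is interpreted
    periodically: the sample after the last phase wraps to the first.
    """

    period: float
    phases: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.phases.ndim != 1 or self.phases.shape != self.velocities.shape:
            raise ValueError("phases and velocities must be matching 1-D arrays")
        if len(self.phases) < 16:
            raise ValueError("waveform needs at least 16 samples")
        if np.any(np.diff(self.phases) <= 0) or self.phases[0] < 0 or self.phases[-1] >= 1:
            raise ValueError("phases must be strictly increasing within [0, 1)")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        """Velocity at time(s) ``t`` (s) by periodic linear interpolation."""
        phase = np.mod(np.asarray(t, dtype=float) / self.period, 1.0)
        xp = np.concatenate([self.phases, [self.phases[0] + 1.0]])
        fp = np.concatenate([self.velocities, [self.velocities[0]]])
        return np.interp(phase, xp, fp)

    @property
    def mean(self) -> float:
        """Time-mean velocity (trapezoid over the periodic cycle)."""
        xp = np.concatenate([self.phases, [self.phases[0] + 1.0]])
        fp = np.concatenate([self.velocities, [self.velocities[0]]])
        return float(np.trapezoid(fp, xp))

    @property
    def peak(self) -> float:
        return float(np.max(self.velocities))


@dataclass
class VesselProfile:
    """Straightened axisymmetric lumen: radius r(z) on strictly increasing z.

    ``cuff_interval`` marks the axial extent of the constrictive cuff in the
    un-extended (core) domain. ``extensions`` records prepended/appended
    constant-radius flow-extension lengths; metrics never use the extensions.
    """

    z: np.ndarray
    r: np.ndarray
    cuff_interval: tuple[float, float] | None = None
    extensions: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.r.shape or len(self.z) < 3:
            raise ValueError("need matching 1-D z and r with at least 3 stations")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(self.r <= 0):
            raise ValueError("all radii must be positive")
        if self.cuff_interval is not None:
            lo, hi = self.core_interval
            c0, c1 = self.cuff_interval
            if not (lo <= c0 < c1 <= hi):
                raise ValueError("cuff_interval must lie within the un-extended domain")

    @property
    def core_interval(self) -> tuple[float, float]:
        """(z_start, z_end) of the un-extended vessel."""
        return float(self.z[0] + self.extensions[0]), float(self.z[-1] - self.extensions[1])

    @property
    def has_extensions(self) -> bool:
        return self.extensions[0] > 0 or self.extensions[1] > 0


@dataclass
class AnalysisRegions:
    """2-mm upstream/downstream analysis segments flanking the cuff."""

    upstream: tuple[float, float]
    downstream: tuple[float, float]
    upstream_clipped: bool = False
    downstream_clipped: bool = False


ZoneLabel = Literal["fine", "medium", "coarse"]


@dataclass
class SimulationGrid:
    """Body-fitted axisymmetric grid: axial stations ``z`` and radial fractions
    ``eta`` ∈ [0, 1] mapped to the local radius ``R(z)``.

    Node (i, j) sits at (z[i], eta[j] * R[i]); eta = 1 is the wall, eta = 0 the
    centreline. ``zones`` labels each axial station fine/medium/coarse.
    """

    z: np.ndarray
    eta: np.ndarray
    R: np.ndarray
    dRdz: np.ndarray
    zones: np.ndarray
    profile: VesselProfile

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.z), len(self.eta)

    @property
    def r_nodes(self) -> np.ndarray:
        """Physical radius of every node, shape (nz, neta), mm."""
        return self.R[:, None] * self.eta[None, :]


@dataclass
class WallShearSeries:
    """Signed axial wall shear stress τ(z, t) over one cardiac cycle.

    ``z`` are wall stations (mm) inside the un-extended domain; ``t`` spans the
    final (converged) simulated cycle; ``tau`` has shape (len(t), len(z)), Pa,
    positive streamwise.
    """

    z: np.ndarray
    t: np.ndarray
    tau: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.shape != (len(self.t), len(self.z)):
            raise ValueError("tau must have shape (len(t), len(z))")
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("wall shear must be finite everywhere")


@dataclass
class FlowField:
    """Velocity/streamfunction/vorticity snapshots on the simulation grid.

    The solver works in streamfunction–vorticity variables, so pressure is not
    part of the state; mass conservation is exact by construction.
    """

    grid: SimulationGrid
    times: np.ndarray
    u: np.ndarray  # axial velocity, (nt, nz, neta), m/s
    v: np.ndarray  # radial velocity, (nt, nz, neta), m/s
    psi: np.ndarray  # Stokes streamfunction, (nt, nz, neta), m³/s per rad
    omega: np.ndarray  # azimuthal vorticity, (nt, nz, neta), 1/s


@dataclass
class WSSMetrics:
    """Per-region wall-shear readouts: peak-systolic WSS, TAWSS, OSI."""

    region: str
    pwss: float
    tawss: float
    osi: float
    osi_fallback_used: bool

    def __post_init__(self) -> None:
        if self.pwss < 0 or self.tawss < 0:
            raise ValueError("pWSS and TAWSS are magnitudes and must be >= 0")
        if not (0.0 <= self.osi <= 0.5 + 1e-12):
            raise ValueError("OSI must lie in [0, 0.5]")


@dataclass
class HistoSection:
    """One histology section: lumen/IEL/EEL contours plus a stain image.

    Contours are (N, 2) arrays of (x, y) pixel coordinates (0-based pixel
    centres); containment lumen ⊆ IEL ⊆ EEL is required by area. The stain
    image is binary {0,1} or greyscale in [0, 105].
    """

    lumen: np.ndarray
    iel: np.ndarray
    eel: np.ndarray
    stain_image: np.ndarray
    pixel_size: float = 1.0  # μm per pixel
    stain_kind: Literal["oil-red-o", "picrosirius", "cd68"] = "oil-red-o"

    def __post_init__(self) -> None:
        for name in ("lumen", "iel", "eel"):
            poly = np.asarray(getattr(self, name), dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise ValueError(f"{name} contour must be an (N>=3, 2) array")
            setattr(self, name, poly)
        img = np.asarray(self.stain_image)
        if img.ndim != 2:
            raise ValueError("stain_image must be 2-D")
        if img.min() < 0 or img.max() > 105:
            raise ValueError("stain values must lie within [0, 105]")
        self.stain_image = img


@dataclass
class StainQuant:
    """Per-section quantification: intima area, stain fraction, plaque burden."""

    intima_area_px: float
    intima_area_um2: float
    stain_fraction_pct: float
    plaque_burden_pct: float
    over_100_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.plaque_burden_pct <= 100.0 + 1e-9):
            raise ValueError("plaque burden must lie in [0, 100] %")
        if self.stain_fraction_pct < 0 or self.intima_area_px < 0:
            raise ValueError("areas and stain fractions must be >= 0")


@dataclass
class LumenMeasurement:
    """Per-slice lumen geometry from a binary mask."""

    slice_index: int
    area: float  # mm²
    feret_min: float  # mm
    feret_max: float  # mm

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("lumen area must be positive")
        if self.feret_min > self.feret_max:
            raise ValueError("min Feret cannot exceed max Feret")

    @property
    def lumen_diameter(self) -> float:
        """Mean of the min and max Feret diameters, mm."""
        return 0.5 * (self.feret_min + self.feret_max)


@dataclass
class ComparisonResult:
    """One pairwise/group contrast with raw and Holm-adjusted p values."""

    contrast: str
    test: str
    tails: Literal["one", "two"]
    p_raw: float
    p_adjusted: float
    significant: bool
    family: str = "default"


GROUPS: tuple[str, ...] = ("5U", "9U", "9A", "9D", "9AD")
REGIONS: tuple[str, ...] = ("upstream", "downstream")
WEEKS: tuple[int, ...] = (-1, 1, 4, 7, 9)
COHORT_COLUMNS: tuple[str, ...] = ("mouse", "group", "region", "week", "measurement", "value")


def validate_cohort(table, allow_repeated_groups: bool = False) -> None:
    """Check a cohort DataFrame for the expected tidy columns and consistency.

    In paired designs the "group" column holds within-mouse conditions, so a
    mouse may legitimately appear under several groups
    (``allow_repeated_groups``).
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if not allow_repeated_groups:
        per_mouse = table.groupby("mouse")["group"].nunique()
        if (per_mouse > 1).any():
            raise ValueError("each mouse must belong to exactly one group")
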