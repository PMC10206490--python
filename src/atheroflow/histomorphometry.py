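"""Plaque histomorphometry from segmented contours and stain images.

Given manually segmented lumen / internal elastic lamina (IEL) / external
elastic lamina (EEL) contours for a section, the intima (plaque) is the
region between the lumen and the IEL. Stains are quantified as stain area to
intima area: binary stains (oil red O, picrosirius red) as the fraction of
positive intimal pixels, the greyscale macrophage stain (CD68, 0-105 scale)
as the intimal pixel sum normalized by count x 30 so that intensity per area
approximates area fraction. Plaque burden is plaque (intima) area as a
percentage of the EEL-enclosed area.

Rasterization convention: a pixel belongs to a contour's interior when its
0-based centre lies inside the polygon (even-odd rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib.path import Path
from shapely.geometry import Polygon

from .types import HistoSection, StainQuant

logger = logging.getLogger(__name__)

#: Greyscale normalization constant for the CD68 stain (mean manual threshold).
CD68_NORM = 30.0

#: Tolerated fraction of lumen area protruding beyond the IEL before erroring.
CONTAINMENT_TOL = 0.01


def _as_polygon(contour: np.ndarray, name: str = "contour") -> Polygon:
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid:
        raise ValueError(f"{name} is not a simple polygon (self-intersection?)")
    return poly


def polygon_area(contour: np.ndarray) -> float:
    """Area enclosed by a simple polygon, independent of vertex orientation."""
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
        raise ValueError("contour must be an (N>=3, 2) array")
    return _as_polygon(contour).area


def rasterize_polygon(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon.

    ``shape`` is (rows, cols); contour coordinates are (x, y) = (col, row).
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = Path(np.asarray(contour, dtype=float)).contains_points(pts)
    return inside.reshape(rows, cols)


def intima_mask(
    lumen: np.ndarray,
    iel: np.ndarray,
    image_shape: tuple[int, int],
    pixel_size: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Pixels inside the IEL but outside the lumen; returns (mask, area in μm²).

    A lumen contour protruding beyond the IEL by more than a small tolerance
    (segmentation error) is rejected; sub-tolerance protrusion is clipped.
    """
    lum_poly = _as_polygon(lumen, "lumen")
    iel_poly = _as_polygon(iel, "IEL")
    outside = lum_poly.difference(iel_poly).area
    if lum_poly.area > 0 and outside / lum_poly.area > CONTAINMENT_TOL:
        raise ValueError("lumen contour extends outside the IEL beyond tolerance")
    mask = rasterize_polygon(iel, image_shape) & ~rasterize_polygon(lumen, image_shape)
    return mask, float(mask.sum()) * pixel_size**2


def plaque_burden(lumen: np.ndarray, iel: np.ndarray, eel: np.ndarray) -> float:
    """Plaque (intima) area as a percentage of the EEL-enclosed area.

    Areas come from the polygon contours themselves (shoelace), not from
    rasterization, matching how contour-based morphometry is reported.
    """
    a_lum = polygon_area(lumen)
    a_iel = polygon_area(iel)
    a_eel = polygon_area(eel)
    if a_eel <= 0:
        raise ValueError("EEL area must be positive")
    plaque = max(0.0, a_iel - a_lum)
    return 100.0 * plaque / a_eel


def binary_stain_fraction(stain_mask: np.ndarray, intima: np.ndarray) -> float:
    """Percentage of intimal pixels that are stain-positive."""
    stain_mask = np.asarray(stain_mask).astype(bool)
    intima = np.asarray(intima).astype(bool)
    if stain_mask.shape != intima.shape:
        raise ValueError("stain mask and intima mask must share a shape")
    n_intima = int(intima.sum())
    if n_intima == 0:
        raise ValueError("empty intima: stain fraction undefined")
    return 100.0 * int((stain_mask & intima).sum()) / n_intima


def greyscale_stain_fraction(
    stain_image: np.ndarray, intima: np.ndarray, norm: float = CD68_NORM
) -> tuple[float, bool]:
    """Greyscale stain content: intimal pixel sum / (pixel count x norm), as %.

    Values are deliberately not clipped at 100% — mean intimal intensity above
    the normalization constant yields >100%, which is flagged.
    """
    stain_image = np.asarray(stain_image, dtype=float)
    intima = np.asarray(intima).astype(bool)
    if stain_image.shape != intima.shape:
        raise ValueError("stain image and intima mask must share a shape")
    if stain_image.min() < 0 or stain_image.max() > 105:
        raise ValueError("greyscale stain values must lie within [0, 105]")
    n_intima = int(intima.sum())
    if n_intima == 0:
        raise ValueError("empty intima: stain fraction undefined")
    pct = 100.0 * float(stain_image[intima].sum()) / (n_intima * norm)
    return pct, pct > 100.0


@dataclass(frozen=True)
class ChannelBounds:
    """Per-channel inclusive intensity bounds for one colour threshold."""

    r: tuple[float, float] = (0.0, 255.0)
    g: tuple[float, float] = (0.0, 255.0)
    b: tuple[float, float] = (0.0, 255.0)

    def apply(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("colour image must be (rows, cols, 3)")
        mask = np.ones(img.shape[:2], dtype=bool)
        for ch, (lo, hi) in enumerate((self.r, self.g, self.b)):
            mask &= (img[..., ch] >= lo) & (img[..., ch] <= hi)
        return mask


def dual_threshold_picrosirius(
    color_image: np.ndarray, threshold_a: ChannelBounds, threshold_b: ChannelBounds
) -> np.ndarray:
    """Binary collagen mask: union of two colour thresholds.

    Polarized-light picrosirius red shows collagen as red/yellow and
    green/blue birefringence, so two thresholds are applied and combined.
    Overlapping pixels count once (logical union).
    """
    return threshold_a.apply(color_image) | threshold_b.apply(color_image)


def quantify_section(section: HistoSection) -> StainQuant:
    """Full per-section quantification from contours + stain image."""
    shape = section.stain_image.shape
    mask, area_um2 = intima_mask(section.lumen, section.iel, shape, section.pixel_size)
    burden = plaque_burden(section.lumen, section.iel, section.eel)
    over = False
    if section.stain_kind == "cd68":
        frac, over = greyscale_stain_fraction(section.stain_image, mask)
    else:
        frac = binary_stain_fraction(section.stain_image > 0, mask)
    return StainQuant(
        intima_area_px=float(mask.sum()),
        intima_area_um2=area_um2,
        stain_fraction_pct=frac,
        plaque_burden_pct=burden,
        over_100_flag=over,
    )


def aggregate_sections(
    values: Sequence[float], viable: Sequence[bool] | None = None,
    reasons: Sequence[str] | None = None,
) -> float:
    """Per-mouse/region value: unweighted mean over viable sections.

    Sections flagged non-viable (missing, damaged, plaque-end taper) are
    excluded and logged. With no viable section the value is missing (NaN),
    never zero.
    """
    values = list(values)
    if viable is None:
        viable = [True] * len(values)
    if len(viable) != len(values):
        raise ValueError("viability flags must match the section values")
    kept = [v for v, ok in zip(values, viable) if ok]
    for idx, ok in enumerate(viable):
        if not ok:
            why = reasons[idx] if reasons is not None else "flagged non-viable"
            logger.info("excluding section %d: %s", idx, why)
    if not kept:
        logger.warning("no viable sections: value reported as missing")
        return math.nan
    return float(np.mean(kept))
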