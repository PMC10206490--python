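"""Readers and writers for the pipeline's on-disk formats.

Profiles, waveforms, wall shear series and cohorts travel as CSV; histology
contours as CSV polygon tables and stain images as TIFF; ground truth and
comparison reports as JSON; grids and flow snapshots as legacy-ASCII VTK
structured grids (readable by ParaView). Scalar metadata (period, cuff
interval, extensions) rides in ``# key: value`` comment headers of the CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    HistoSection,
    SimulationGrid,
    VelocityWaveform,
    VesselProfile,
    WallShearSeries,
    WSSMetrics,
)


def _write_csv_with_meta(path, frame: pd.DataFrame, meta: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        frame.to_csv(fh, index=False)


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# ") and ":" in line:
                key, _, val = line[2:].partition(":")
                meta[key.strip()] = json.loads(val)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        frame = pd.read_csv(fh)
    return frame, meta


def write_profile_csv(profile: VesselProfile, path) -> None:
    meta = {"cuff_interval": profile.cuff_interval, "extensions": profile.extensions}
    _write_csv_with_meta(path, pd.DataFrame({"z_mm": profile.z, "r_mm": profile.r}), meta)


def read_profile_csv(path) -> VesselProfile:
    frame, meta = _read_csv_with_meta(path)
    cuff = meta.get("cuff_interval")
    ext = meta.get("extensions") or (0.0, 0.0)
    return VesselProfile(z=frame["z_mm"].to_numpy(), r=frame["r_mm"].to_numpy(),
                         cuff_interval=tuple(cuff) if cuff else None,
                         extensions=tuple(ext))


def write_waveform_csv(waveform: VelocityWaveform, path) -> None:
    frame = pd.DataFrame({
        "time_s": waveform.phases * waveform.period,
        "velocity_m_per_s": waveform.velocities,
    })
    _write_csv_with_meta(path, frame, {"period_s": waveform.period})


def read_waveform_csv(path) -> VelocityWaveform:
    frame, meta = _read_csv_with_meta(path)
    period = float(meta["period_s"])
    return VelocityWaveform(period=period,
                            phases=frame["time_s"].to_numpy() / period,
                            velocities=frame["velocity_m_per_s"].to_numpy())


def write_wall_shear_csv(series: WallShearSeries, path) -> None:
    tt, zz = np.meshgrid(series.t, series.z, indexing="ij")
    frame = pd.DataFrame({"z_mm": zz.ravel(), "time_s": tt.ravel(),
                          "tau_pa": series.tau.ravel()})
    _write_csv_with_meta(path, frame, {"period_s": series.period})


def read_wall_shear_csv(path) -> WallShearSeries:
    frame, meta = _read_csv_with_meta(path)
    z = np.unique(frame["z_mm"].to_numpy())
    t = np.unique(frame["time_s"].to_numpy())
    tau = (frame.pivot(index="time_s", columns="z_mm", values="tau_pa")
           .to_numpy())
    return WallShearSeries(z=z, t=t, tau=tau, period=float(meta["period_s"]))


def write_metrics(metrics: Sequence[WSSMetrics], path) -> None:
    """Per-region metrics table; CSV or JSON chosen by the file suffix."""
    frame = pd.DataFrame([vars(m) for m in metrics])
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(frame.to_json(orient="records", indent=2))
    else:
        frame.to_csv(path, index=False)


def write_histo_section(section: HistoSection, stem) -> None:
    """Contours to <stem>_contours.csv, stain image to <stem>_stain.tif."""
    stem = Path(stem)
    rows = []
    for layer in ("lumen", "iel", "eel"):
        for x, y in getattr(section, layer):
            rows.append({"layer": layer, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(stem.with_name(stem.name + "_contours.csv"), index=False)
    img = section.stain_image
    data = (img.astype(np.uint16) if img.dtype.kind in "ui"
            else np.round(img * 100).astype(np.uint16))  # 0.01 greyscale units
    tifffile.imwrite(stem.with_name(stem.name + "_stain.tif"), data)


def read_histo_section(stem, pixel_size: float = 1.0,
                       stain_kind: str = "oil-red-o") -> HistoSection:
    stem = Path(stem)
    frame = pd.read_csv(stem.with_name(stem.name + "_contours.csv"))
    polys = {layer: grp[["x", "y"]].to_numpy()
             for layer, grp in frame.groupby("layer")}
    img = tifffile.imread(stem.with_name(stem.name + "_stain.tif"))
    if stain_kind == "cd68":
        img = img.astype(float) / 100.0
    return HistoSection(lumen=polys["lumen"], iel=polys["iel"], eel=polys["eel"],
                        stain_image=img, pixel_size=pixel_size, stain_kind=stain_kind)


def write_vtk_structured_grid(grid: SimulationGrid, path,
                              fields: Mapping[str, np.ndarray] | None = None) -> None:
    """Legacy-ASCII VTK structured grid of the body-fitted mesh.

    ``fields`` maps names to (nz, neta) nodal arrays written as point data.
    Hand-rolled writer: the legacy format is a short plain-text header plus
    coordinate and scalar blocks.
    """
    nz, ne = grid.shape
    r = grid.r_nodes
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\naxisymmetric vessel grid\nASCII\n")
        fh.write(f"DATASET STRUCTURED_GRID\nDIMENSIONS {ne} {nz} 1\n")
        fh.write(f"POINTS {nz * ne} float\n")
        for i in range(nz):
            for j in range(ne):
                fh.write(f"{grid.z[i]:.6g} {r[i, j]:.6g} 0\n")
        if fields:
            fh.write(f"POINT_DATA {nz * ne}\n")
            for name, arr in fields.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for i in range(nz):
                    for j in range(ne):
                        fh.write(f"{arr[i, j]:.6g}\n")


def write_ground_truth(truth: Mapping[str, object], path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float))


def load_config(path) -> dict:
    """YAML run configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
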