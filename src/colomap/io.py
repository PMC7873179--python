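"""Readers and writers for the pipeline's file formats.

Images travel as NIfTI (primary; MRI-native, carries pixel spacing and frame
interval in the header) or multi-page TIFF (metadata in the shaped-JSON
description). Pressure traces are CSV (``time_s, ch1..chN``) with a YAML
sidecar for sensor geometry and units. Matrices (diameter series, residual
maps) are CSV with times in the first row and positions in the first
column; invalid cells are empty. Events and summaries are JSON.

All round-trips are lossless for the quantities the pipeline consumes;
missing physical metadata (pixel spacing, frame interval, sensor positions)
is a hard error, never defaulted, because every downstream quantity is in mm
and seconds.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from colomap._types import ImageSeries
from colomap.manometry import ContractionEvent, HAPCEvent, PressureRecording
from colomap.motility_map import DiameterProfileSeries, MidlineCurve, ResidualMap, WallCorridor
from colomap.phantom import PhantomGroundTruth


# --------------------------------------------------------------------------
# image series


def write_image_series(series: ImageSeries, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            np.moveaxis(series.data, 2, 0),  # pages = time
            photometric="minisblack",
            metadata={
                "pixel_spacing_mm": float(series.pixel_spacing_mm),
                "frame_interval_s": float(series.frame_interval_s),
            },
        )
        return
    if "".join(path.suffixes) in (".nii", ".nii.gz") or path.suffix == ".nii":
        img = nib.Nifti1Image(np.asarray(series.data), affine=None)
        img.header.set_zooms(
            (series.pixel_spacing_mm, series.pixel_spacing_mm, series.frame_interval_s)
        )
        img.header.set_xyzt_units(xyz="mm", t="sec")
        nib.save(img, path)
        return
    raise ValueError(f"unsupported image format: {path.name}")


def read_image_series(path: str | Path) -> ImageSeries:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        for key in ("pixel_spacing_mm", "frame_interval_s"):
            if key not in meta:
                raise ValueError(f"TIFF {path.name} is missing required metadata field {key!r}")
        return ImageSeries(
            data=np.moveaxis(data, 0, 2),
            pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
            frame_interval_s=float(meta["frame_interval_s"]),
        )
    img = nib.load(path)
    zooms = img.header.get_zooms()
    if len(zooms) < 3 or zooms[0] <= 0 or zooms[2] <= 0:
        raise ValueError(f"NIfTI {path.name} is missing pixel spacing / frame interval zooms")
    if not np.isclose(zooms[0], zooms[1]):
        raise ValueError("anisotropic in-plane pixel spacing is not supported")
    return ImageSeries(
        data=np.asarray(img.dataobj),
        pixel_spacing_mm=float(zooms[0]),
        frame_interval_s=float(zooms[2]),
    )


# --------------------------------------------------------------------------
# pressure traces


def write_pressure_csv(rec: PressureRecording, csv_path: str | Path, sidecar_path: str | Path) -> None:
    df = pd.DataFrame({"time_s": rec.times_s})
    for label, trace in zip(rec.channel_labels, rec.pressures_mmhg):
        df[label] = trace
    df.to_csv(csv_path, index=False)
    sidecar = {
        "units": "mmHg",
        "sampling_rate_hz": float(rec.sampling_rate_hz),
        "channel_positions_mm": [float(p) for p in rec.channel_positions_mm],
        "channel_labels": list(rec.channel_labels),
        "distal_direction": "increasing",
    }
    Path(sidecar_path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_pressure_csv(csv_path: str | Path, sidecar_path: str | Path) -> PressureRecording:
    df = pd.read_csv(csv_path)
    if "time_s" not in df.columns:
        raise ValueError("pressure CSV must have a leading 'time_s' column")
    if df.isna().any().any():
        raise ValueError("pressure CSV contains missing values (ragged rows?)")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time_s column must be strictly increasing")
    meta = yaml.safe_load(Path(sidecar_path).read_text())
    positions = np.asarray(meta["channel_positions_mm"], dtype=float)
    channels = [c for c in df.columns if c != "time_s"]
    if positions.size != len(channels):
        raise ValueError(
            f"sidecar lists {positions.size} channel positions but CSV has "
            f"{len(channels)} channels"
        )
    if meta.get("distal_direction", "increasing") != "increasing":
        raise ValueError("channels must be ordered proximal->distal (distal_direction: increasing)")
    if t.size > 1:
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        rate = float(meta.get("sampling_rate_hz", 1.0))
    return PressureRecording(
        pressures_mmhg=df[channels].to_numpy(dtype=float).T,
        sampling_rate_hz=rate,
        channel_positions_mm=positions,
        channel_labels=channels,
    )


# --------------------------------------------------------------------------
# matrices (first row = times s, first column = positions mm)


def write_matrix_csv(
    values: np.ndarray, positions_mm: np.ndarray, times_s: np.ndarray, path: str | Path
) -> None:
    df = pd.DataFrame(values, index=positions_mm, columns=times_s)
    df.index.name = "position_mm"
    df.to_csv(path, na_rep="")


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    positions = df.index.to_numpy(dtype=float)
    times = df.columns.to_numpy(dtype=float)
    return values, positions, times


def write_diameters_csv(diams: DiameterProfileSeries, path: str | Path) -> None:
    vals = np.where(diams.valid, diams.diameters_mm, np.nan)
    write_matrix_csv(vals, diams.positions_mm, diams.times_s, path)


def read_diameters_csv(path: str | Path) -> DiameterProfileSeries:
    vals, pos, t = read_matrix_csv(path)
    return DiameterProfileSeries(
        diameters_mm=vals, valid=np.isfinite(vals), positions_mm=pos, times_s=t
    )


def write_residual_csv(rmap: ResidualMap, path: str | Path) -> None:
    vals = np.where(rmap.valid, rmap.residuals_mm, np.nan)
    write_matrix_csv(vals, rmap.positions_mm, rmap.times_s, path)


def read_residual_csv(path: str | Path) -> ResidualMap:
    vals, pos, t = read_matrix_csv(path)
    valid = np.isfinite(vals)
    n = pos.size
    return ResidualMap(
        residuals_mm=vals,
        valid=valid,
        positions_mm=pos,
        times_s=t,
        intercepts_mm=np.full(n, np.nan),
        slopes_mm_per_s=np.full(n, np.nan),
    )


# --------------------------------------------------------------------------
# polylines


def write_polyline_csv(points_mm: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(points_mm, dtype=float), columns=["x_mm", "y_mm"]).to_csv(
        path, index=False
    )


def read_polyline_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("x_mm", "y_mm"):
        if col not in df.columns:
            raise ValueError(f"polyline CSV {Path(path).name} must have columns x_mm,y_mm")
    return df[["x_mm", "y_mm"]].to_numpy(dtype=float)


def read_midline_csv(path: str | Path) -> MidlineCurve:
    return MidlineCurve(points_mm=read_polyline_csv(path))


def read_corridor_csvs(path_a: str | Path, path_b: str | Path, margin_mm: float = 10.0) -> WallCorridor:
    return WallCorridor(
        side_a_mm=read_polyline_csv(path_a),
        side_b_mm=read_polyline_csv(path_b),
        margin_mm=margin_mm,
    )


# --------------------------------------------------------------------------
# events / ground truth JSON


def _event_dict(ev: ContractionEvent) -> dict:
    return dataclasses.asdict(ev)


def write_events_json(events: list[ContractionEvent], path: str | Path) -> None:
    Path(path).write_text(json.dumps([_event_dict(e) for e in events], indent=1))


def read_events_json(path: str | Path) -> list[ContractionEvent]:
    return [ContractionEvent(**d) for d in json.loads(Path(path).read_text())]


def write_hapcs_json(hapcs: list[HAPCEvent], path: str | Path) -> None:
    payload = []
    for h in hapcs:
        d = dataclasses.asdict(h)
        d["window_s"] = list(h.window_s)
        if not h.velocity_defined:
            d["velocity_mm_s"] = None
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_hapcs_json(path: str | Path) -> list[HAPCEvent]:
    out = []
    for d in json.loads(Path(path).read_text()):
        vel = d["velocity_mm_s"]
        out.append(
            HAPCEvent(
                channels=list(d["channels"]),
                onsets_s=list(d["onsets_s"]),
                amplitudes_mmhg=list(d["amplitudes_mmhg"]),
                min_amplitude_mmhg=float(d["min_amplitude_mmhg"]),
                velocity_mm_s=math.nan if vel is None else float(vel),
                velocity_defined=bool(d["velocity_defined"]),
                window_s=(float(d["window_s"][0]), float(d["window_s"][1])),
            )
        )
    return out


def write_ground_truth_json(truth: PhantomGroundTruth, path: str | Path) -> None:
    payload = {
        "sensor_positions_mm": [float(p) for p in truth.sensor_positions_mm],
        "event_windows": [
            {
                "wave": dataclasses.asdict(w.wave),
                "enters_segment": w.enters_segment,
                "t_enter_s": w.t_enter_s,
                "t_exit_s": w.t_exit_s,
                "sensor_arrival_s": w.sensor_arrival_s,
            }
            for w in truth.event_windows
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
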