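"""File formats for phantom data and reconstruction results.

Everything is plain text or TIFF: marker tracks and flow/volume curves as
CSV, slice stacks as one multi-page TIFF per slice with a JSON sidecar,
meshes as PLY/STL via trimesh, PIV vector fields as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .slices import SliceStack
from .waveform import FlowSeries, VolumeSeries

__all__ = [
    "write_tracks_csv",
    "read_tracks_csv",
    "write_flows_csv",
    "read_flows_csv",
    "write_volumes_csv",
    "read_volumes_csv",
    "write_slice_stack",
    "read_slice_stack",
    "write_mesh",
    "write_vector_field_csv",
]

TRACK_COLUMNS = ["cycle", "frame", "marker_id", "cam", "x_px", "y_px"]


def write_tracks_csv(tracks: pd.DataFrame, path) -> Path:
    path = Path(path)
    tracks[TRACK_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    return path


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tracks file lacks columns: {sorted(missing)}")
    return df


def write_flows_csv(flows: FlowSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": flows.times, "q_mv_lpm": flows.q_mv, "q_av_lpm": flows.q_av}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_flows_csv(path, period: float | None = None) -> FlowSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t_s"].to_numpy()
    if period is None:
        period = float(t[-1] - t[0] + (t[1] - t[0]))
    return FlowSeries(
        times=t, q_mv=df["q_mv_lpm"].to_numpy(), q_av=df["q_av_lpm"].to_numpy(), period=period
    )


def write_volumes_csv(v: VolumeSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": v.times, "v_ml": v.volumes}).to_csv(path, index=False, float_format="%.17g")
    return path


def read_volumes_csv(path, period: float | None = None) -> VolumeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t_s"].to_numpy()
    if period is None:
        period = float(t[-1] - t[0] + (t[1] - t[0]))
    return VolumeSeries(times=t, volumes=df["v_ml"].to_numpy(), period=period)


def write_slice_stack(stack: SliceStack, directory) -> Path:
    """One multi-page TIFF per slice (pages = phases) + a JSON sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in range(stack.n_slices):
        tifffile.imwrite(
            directory / f"slice_{s:02d}.tif",
            (stack.images[s] * 65535).astype(np.uint16),
            photometric="minisblack",
        )
    meta = {
        "n_slices": stack.n_slices,
        "n_phases": stack.n_phases,
        "slice_z_mm": stack.slice_z.tolist(),
        "slice_thickness_mm": stack.slice_thickness,
        "pixel_size_mm": stack.pixel_size,
        "phase_times_s": stack.phase_times.tolist(),
        "period_s": stack.period,
        "blur_flags": stack.blur_flags.astype(int).tolist(),
        "wall_speed_mm_s": stack.wall_speed.tolist(),
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_slice_stack(directory) -> SliceStack:
    import tifffile

    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    images = np.stack(
        [
            tifffile.imread(directory / f"slice_{s:02d}.tif").astype(np.float32) / 65535.0
            for s in range(meta["n_slices"])
        ]
    )
    return SliceStack(
        images=images,
        slice_z=np.array(meta["slice_z_mm"]),
        slice_thickness=meta["slice_thickness_mm"],
        pixel_size=meta["pixel_size_mm"],
        phase_times=np.array(meta["phase_times_s"]),
        period=meta["period_s"],
        blur_flags=np.array(meta["blur_flags"], dtype=bool),
        wall_speed=np.array(meta["wall_speed_mm_s"]),
    )


def write_mesh(mesh, path) -> Path:
    path = Path(path)
    mesh.export(path)
    return path


def write_vector_field_csv(field, path) -> Path:
    """Vector field as `x_px,y_px,u_ms,v_ms,q,valid` rows."""
    path = Path(path)
    gy, gx = np.meshgrid(field.y, field.x, indexing="ij")
    u_ms = field.u_ms if field.u_ms is not None else np.full_like(field.u, np.nan)
    v_ms = field.v_ms if field.v_ms is not None else np.full_like(field.v, np.nan)
    pd.DataFrame(
        {
            "x_px": gx.ravel(),
            "y_px": gy.ravel(),
            "u_ms": u_ms.ravel(),
            "v_ms": v_ms.ravel(),
            "q": field.q.ravel(),
            "valid": field.valid.ravel().astype(int),
        }
    ).to_csv(path, index=False, float_format="%.17g")
    return path
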