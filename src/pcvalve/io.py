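"""File formats: NIfTI-1 velocity series with JSON sidecar, CSV traces, YAML config."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .pc_synth import AcquisitionParams, CWTrace, PCSeries

__all__ = [
    "save_pc_series",
    "load_pc_series",
    "save_cw_trace",
    "load_cw_trace",
    "load_config",
    "sidecar_path",
]


def sidecar_path(nii_path) -> Path:
    p = Path(nii_path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def save_pc_series(series: PCSeries, nii_path, sidecar: Path | None = None) -> Path:
    """Write a PC series as 4-D NIfTI (rows, cols, 1, frames) plus JSON sidecar.

    Velocities are stored in cm/s; voxel dimensions carry the in-plane pixel
    spacing (mm) and slice thickness, and the repetition time carries the
    frame interval (s).  Acquisition parameters and the mid-frame times go to
    the sidecar.
    """
    nii_path = Path(nii_path)
    data = np.moveaxis(series.velocity_cm_s, 0, -1)[:, :, np.newaxis, :]
    p = series.params
    affine = np.diag([p.pixel_spacing_mm[0], p.pixel_spacing_mm[1],
                      p.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((p.pixel_spacing_mm[0], p.pixel_spacing_mm[1],
                          p.slice_thickness_mm, p.frame_interval_ms / 1000.0))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(nii_path))

    side = sidecar or sidecar_path(nii_path)
    payload = {
        "units": "cm/s",
        "acquisition": p.to_dict(),
        "frame_times_s": [float(t) for t in series.frame_times_s],
    }
    side.write_text(json.dumps(payload, indent=2))
    return nii_path


def load_pc_series(nii_path, sidecar: Path | None = None) -> PCSeries:
    """Read a PC series written by :func:`save_pc_series`."""
    nii_path = Path(nii_path)
    side = Path(sidecar) if sidecar else sidecar_path(nii_path)
    if not side.exists():
        raise InvalidParameterError(f"missing JSON sidecar: {side}")
    payload = json.loads(side.read_text())
    params = AcquisitionParams.from_dict(payload["acquisition"])
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[2] != 1:
        raise InvalidParameterError(
            f"expected a (rows, cols, 1, frames) volume, got shape {data.shape}"
        )
    vel = np.moveaxis(data[:, :, 0, :], -1, 0)
    frame_times = np.asarray(payload["frame_times_s"], dtype=float)
    return PCSeries(vel, frame_times, params)


def save_cw_trace(trace: CWTrace, path) -> Path:
    """Write a CW envelope as two-column CSV (time_s, velocity_cm_s)."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s,
                  "velocity_cm_s": trace.envelope_cm_s}).to_csv(path, index=False)
    return path


def load_cw_trace(path, cycle_s: float | None = None,
                  n_beats: int | None = None) -> CWTrace:
    """Read a CW envelope CSV; infer the cycle length if not given.

    If ``cycle_s`` is omitted the trace is assumed to span exactly
    ``n_beats`` (default 1) full cycles.
    """
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    v = df["velocity_cm_s"].to_numpy(float)
    if cycle_s is None:
        beats = n_beats or 1
        dt = t[1] - t[0]
        cycle_s = (t[-1] - t[0] + dt) / beats
    return CWTrace(t, v, float(cycle_s))


def load_config(path) -> dict:
    """Load a YAML (or JSON) experiment/valve configuration into a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InvalidParameterError("configuration file must contain a mapping")
    return cfg
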