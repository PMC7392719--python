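"""Synthetic phase-contrast velocity maps and continuous-wave Doppler envelopes.

This module is the in-silico stand-in for the scanner and the ultrasound probe.
From the ground-truth flow model it produces:

* ``PCSeries`` — a cine stack of through-plane velocity maps (frames x rows x
  cols, cm/s) with finite temporal resolution, per-frame temporal averaging,
  Gaussian velocity noise, optional VENC aliasing and optional in-plane
  smoothing (partial voluming);
* ``CWTrace`` — a high-temporal-resolution maximal-velocity envelope, i.e.
  what continuous-wave Doppler records along a beam through the jet.

Jet spatial model
-----------------
The imaging plane sits at the valve tips, perpendicular to the inflow jet.
The through-plane velocity pattern is a circular jet core of the *effective*
(vena contracta) area ``Cc * AOA`` with a tanh edge, surrounded by a slow
annular "skirt" (default 0.2x the core velocity) extending to the *anatomic*
radius — the broad jet base and partial-volume signal that a plane at the
leaflet tips sees.  The per-frame amplitude is normalized so that the discrete
pixel-sum flux equals the (window-averaged) pump flow exactly: flow is
conserved by construction, which makes the core plateau velocity
``Q / (A_eff + skirt area)`` — slightly below the ideal vena-contracta
velocity, as finite-resolution PC measurement is in practice.  With the skirt
disabled the jet is a uniform top-hat of area ``Cc * AOA`` and the continuity
identity ``FFV / TVI = Cc * AOA`` holds analytically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidParameterError
from .flow_model import FlowWaveform, ValveModel, true_velocity_trace

__all__ = [
    "AcquisitionParams",
    "PCSeries",
    "CWTrace",
    "jet_profile",
    "synthesize_pc_series",
    "synthesize_cw_trace",
]


@dataclass
class AcquisitionParams:
    """Phase-contrast acquisition parameters.

    Defaults follow a clinical mitral PC protocol: 1.2 x 0.9 mm in-plane,
    4 mm slice, 48.9 ms temporal resolution with one-frame temporal averaging,
    VENC 400 cm/s.  ``temporal_window_ms`` may exceed ``frame_interval_ms`` to
    model view-shared reconstructions.
    """

    pixel_spacing_mm: tuple[float, float] = (1.2, 0.9)  # (row, col)
    slice_thickness_mm: float = 4.0
    frame_interval_ms: float = 48.9
    venc_cm_s: float = 400.0
    noise_sd_cm_s: float = 3.0
    temporal_window_ms: float = 48.9
    grid_size: tuple[int, int] = (64, 72)  # (rows, cols)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise InvalidParameterError("pixel spacing must be positive")
        for name in ("slice_thickness_mm", "frame_interval_ms", "venc_cm_s",
                     "temporal_window_ms"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.noise_sd_cm_s < 0:
            raise InvalidParameterError("noise_sd_cm_s must be non-negative")
        if any(int(n) < 8 for n in self.grid_size):
            raise InvalidParameterError("grid_size must be at least 8x8")

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1] / 100.0

    def covers(self, diameter_mm: float, factor: float = 3.0) -> bool:
        """Whether the field of view spans ``factor`` times the given diameter."""
        rows, cols = self.grid_size
        extent = (rows * self.pixel_spacing_mm[0], cols * self.pixel_spacing_mm[1])
        return min(extent) >= factor * diameter_mm

    def replace(self, **kwargs) -> "AcquisitionParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pixel_spacing_mm"] = list(self.pixel_spacing_mm)
        d["grid_size"] = list(self.grid_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        d["pixel_spacing_mm"] = tuple(d["pixel_spacing_mm"])
        d["grid_size"] = tuple(d["grid_size"])
        return cls(**d)


@dataclass
class PCSeries:
    """A cine phase-contrast velocity-map series.

    ``velocity_cm_s`` has shape (frames, rows, cols); ``frame_times_s`` are the
    mid-frame trigger times, strictly increasing over one cardiac cycle.
    """

    velocity_cm_s: np.ndarray
    frame_times_s: np.ndarray
    params: AcquisitionParams

    @property
    def n_frames(self) -> int:
        return self.velocity_cm_s.shape[0]

    @property
    def pixel_area_cm2(self) -> float:
        return self.params.pixel_area_cm2


@dataclass
class CWTrace:
    """Continuous-wave Doppler maximal-velocity envelope.

    ``cycle_s`` is the cardiac cycle length; the trace may span several
    consecutive beats (``time_s`` keeps running across beats).
    """

    time_s: np.ndarray
    envelope_cm_s: np.ndarray
    cycle_s: float

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def n_beats(self) -> int:
        total = self.time_s[-1] - self.time_s[0] + self.dt_s
        return int(round(total / self.cycle_s))


def _disc_coverage(radius_mm: float, spacing_mm: tuple[float, float],
                   row_mm: np.ndarray, col_mm: np.ndarray) -> np.ndarray:
    """Pixel coverage fraction of a centered disc, 8x8 supersampled."""
    n = 8
    dr, dc = spacing_mm
    off = (np.arange(n) + 0.5) / n - 0.5
    rows = row_mm[:, None] + off[None, :] * dr  # (R, n)
    cols = col_mm[:, None] + off[None, :] * dc  # (C, n)
    r2 = rows[:, None, :, None] ** 2 + cols[None, :, None, :] ** 2
    return (r2 <= radius_mm ** 2).mean(axis=(2, 3))


def jet_profile(valve: ValveModel, params: AcquisitionParams,
                edge_mm: float = 0.45, skirt: float = 0.2) -> np.ndarray:
    """Static, dimensionless spatial profile of the jet (1.0 at the core).

    ``edge_mm`` is the tanh length scale of the jet boundary (the 10-90%
    transition spans about 2.2x this; the default ~0.45 mm gives a one-pixel
    boundary).  ``edge_mm = 0`` produces an anti-aliased top-hat (pixel
    coverage fractions).  ``skirt`` is the relative velocity of the annular
    jet base between the effective and anatomic radii; 0 disables it.
    """
    rows, cols = params.grid_size
    dr, dc = params.pixel_spacing_mm
    row_mm = (np.arange(rows) - (rows - 1) / 2.0) * dr
    col_mm = (np.arange(cols) - (cols - 1) / 2.0) * dc
    r_eff = valve.effective_radius_mm
    r_aoa = valve.anatomic_radius_mm

    half_fov = (min(rows * dr, cols * dc)) / 2.0
    if r_aoa + 2.0 * edge_mm >= half_fov:
        raise GeometryError(
            f"jet (anatomic radius {r_aoa:.1f} mm + edge) does not fit the "
            f"{rows}x{cols} grid (half-FOV {half_fov:.1f} mm)"
        )

    if edge_mm > 0:
        r = np.sqrt(row_mm[:, None] ** 2 + col_mm[None, :] ** 2)
        core = 0.5 * (1.0 - np.tanh((r - r_eff) / edge_mm))
        outer = 0.5 * (1.0 - np.tanh((r - r_aoa) / edge_mm))
    else:
        core = _disc_coverage(r_eff, (dr, dc), row_mm, col_mm)
        outer = _disc_coverage(r_aoa, (dr, dc), row_mm, col_mm)
    if skirt > 0:
        return core + skirt * np.clip(outer - core, 0.0, None)
    return core


def _window_averaged_flow(waveform: FlowWaveform, t_centers: np.ndarray,
                          window_s: float) -> np.ndarray:
    """Boxcar average of the (periodic) flow rate around each frame time."""
    interp = waveform.interpolator()
    if window_s <= 0:
        return interp(t_centers)
    # fine periodic sampling; 97 sub-samples keep the boxcar quadrature smooth
    n_sub = 97
    offs = np.linspace(-window_s / 2.0, window_s / 2.0, n_sub)
    return interp(t_centers[:, None] + offs[None, :]).mean(axis=1)


def synthesize_pc_series(
    waveform: FlowWaveform,
    valve: ValveModel,
    params: AcquisitionParams,
    *,
    edge_mm: float = 0.45,
    skirt: float = 0.2,
    smooth: bool = False,
    alias: bool = True,
) -> PCSeries:
    """Simulate a cine through-plane PC acquisition of the transvalvular jet.

    Each frame is the jet profile scaled so the pixel-sum flux equals the
    pump flow averaged over ``temporal_window_ms`` centred on the mid-frame
    time, plus i.i.d. Gaussian velocity noise per pixel (seeded).  If
    ``smooth`` is set, a 3x3 boxcar models in-plane partial voluming (applied
    to the signal, before noise).  If ``alias`` is set, velocities beyond the
    VENC wrap modulo ``2 * VENC``.
    """
    profile = jet_profile(valve, params, edge_mm=edge_mm, skirt=skirt)
    if smooth:
        from scipy.ndimage import uniform_filter

        profile = uniform_filter(profile, size=3, mode="constant")
    flux_area_cm2 = float(profile.sum() * params.pixel_area_cm2)

    period = waveform.period_s
    dt = params.frame_interval_ms / 1000.0
    n_frames = int(np.floor(period / dt))
    if n_frames < 2:
        raise InvalidParameterError("frame interval too long: fewer than 2 frames per cycle")
    frame_times = (np.arange(n_frames) + 0.5) * dt

    q_bar = _window_averaged_flow(waveform, frame_times, params.temporal_window_ms / 1000.0)
    amplitude = q_bar / flux_area_cm2  # cm/s plateau per frame

    vel = amplitude[:, None, None] * profile[None, :, :]
    if params.noise_sd_cm_s > 0:
        rng = np.random.default_rng(params.seed)
        vel = vel + rng.normal(0.0, params.noise_sd_cm_s, size=vel.shape)
    if alias:
        venc = params.venc_cm_s
        vel = np.mod(vel + venc, 2.0 * venc) - venc
    return PCSeries(vel, frame_times, params)


def synthesize_cw_trace(
    waveform: FlowWaveform,
    valve: ValveModel,
    noise_sd_cm_s: float = 3.0,
    dt_ms: float = 2.0,
    seed: int = 0,
    n_beats: int = 1,
) -> CWTrace:
    """Simulate a CW Doppler envelope of the transmitral jet.

    The envelope is the ideal vena-contracta velocity ``Q(t)/A_eff`` sampled
    at ``dt_ms`` (<= 5 ms, far finer than the PC frame interval) plus Gaussian
    noise, clipped at zero.  ``n_beats`` consecutive beats are concatenated
    (the pump is perfectly periodic; only the noise differs between beats).
    """
    if dt_ms > 5.0 or dt_ms <= 0:
        raise InvalidParameterError("dt_ms must be in (0, 5] ms")
    if n_beats < 1:
        raise InvalidParameterError("n_beats must be >= 1")
    if noise_sd_cm_s < 0:
        raise InvalidParameterError("noise_sd_cm_s must be non-negative")

    ideal = true_velocity_trace(waveform, valve)
    period = waveform.period_s
    # snap the step to divide the cycle exactly so beats are sample-periodic
    n_per_beat = int(round(period / (dt_ms / 1000.0)))
    dt = period / n_per_beat
    t = np.arange(n_per_beat * n_beats) * dt
    v = np.interp(t % period, ideal.time_s, ideal.v_cm_s, left=0.0, right=0.0)
    if noise_sd_cm_s > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd_cm_s, size=v.shape)
    return CWTrace(t, np.clip(v, 0.0, None), period)
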