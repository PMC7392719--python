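"""Ground truth for the pulsatile flow loop: diastolic waveform and valve geometry.

The physical system being emulated is a pulsatile pump driving flow through a
bioprosthetic mitral valve (BMV) in an imaging chamber.  The pump produces a
single diastolic filling phase per cycle (no atrial kick, no regurgitation);
the valve converts the volumetric flow rate Q(t) into a transvalvular jet whose
effective cross-section is the anatomic orifice area (AOA) scaled by a flow
contraction coefficient Cc in [0.6, 1.0], so the ideal vena-contracta velocity
is v(t) = Q(t) / (Cc * AOA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "WAVEFORM_SHAPES",
    "AOA_TABLE_CM2",
    "OCCLUDER_AREA_FACTOR",
    "CC_NORMAL",
    "CC_STENOTIC",
    "FlowWaveform",
    "VelocityTrace",
    "ValveModel",
    "generate_diastolic_waveform",
    "true_velocity_trace",
]

WAVEFORM_SHAPES = ("half_sine", "e_wave")

#: Nominal anatomic orifice areas (cm^2) for normal valves by labelled size (mm).
#: Group mean 2.9 cm^2 over the four sizes.
AOA_TABLE_CM2 = {27: 2.4, 29: 2.7, 31: 3.1, 33: 3.4}

#: Multiplicative AOA reduction per number of occluders (stenosis model).
#: One occluder = mild, two = severe obstruction; the stenotic group mean over
#: {27, 29} x {1, 2} occluders is ~1.2 cm^2.
OCCLUDER_AREA_FACTOR = {0: 1.0, 1: 0.55, 2: 0.40}

#: Default contraction coefficients.  Stenotic orifices run at higher
#: transvalvular gradient, forcing flow to occupy more of the anatomic area,
#: hence a Cc closer to 1.
CC_NORMAL = 0.62
CC_STENOTIC = 0.85


@dataclass
class FlowWaveform:
    """Volumetric flow rate over one cardiac cycle.

    Attributes
    ----------
    time_s : ndarray
        Uniform time grid spanning one cycle, starting at 0 (s).
    flow_ml_s : ndarray
        Volumetric flow rate (mL/s), non-negative everywhere.
    heart_rate_bpm : float
        Pump rate (beats/min); the cycle length is ``60 / heart_rate_bpm``.
    stroke_volume_ml : float
        Per-beat forward volume; equals the trapezoidal integral of the flow.
    """

    time_s: np.ndarray
    flow_ml_s: np.ndarray
    heart_rate_bpm: float
    stroke_volume_ml: float

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def interpolator(self):
        """Periodic linear interpolant of the flow rate (mL/s)."""
        t, q, T = self.time_s, self.flow_ml_s, self.period_s

        def _interp(times):
            return np.interp(np.asarray(times, dtype=float) % T, t, q, left=0.0, right=0.0)

        return _interp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "flow_ml_s": self.flow_ml_s})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, heart_rate_bpm: float | None = None) -> "FlowWaveform":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        q = df["flow_ml_s"].to_numpy(float)
        sv = float(np.trapezoid(q, t))
        if heart_rate_bpm is None:
            # grid spans one full cycle
            heart_rate_bpm = 60.0 / (t[-1] - t[0] + (t[1] - t[0]))
        return cls(t, q, float(heart_rate_bpm), sv)


@dataclass
class VelocityTrace:
    """A velocity-versus-time trace (cm/s) on an arbitrary time grid."""

    time_s: np.ndarray
    v_cm_s: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "velocity_cm_s": self.v_cm_s})


@dataclass
class ValveModel:
    """Orifice geometry and contraction behaviour of one valve configuration.

    ``effective_area_cm2 = contraction_coefficient * aoa_cm2`` is the area of
    the vena contracta, i.e. the physiologic flow area that the continuity
    equation (EOA = FFV / TVI) measures.
    """

    size_label_mm: int
    aoa_cm2: float
    occluder_count: int = 0
    contraction_coefficient: float = CC_NORMAL

    def __post_init__(self) -> None:
        if self.size_label_mm not in AOA_TABLE_CM2:
            raise InvalidParameterError(
                f"size_label_mm must be one of {sorted(AOA_TABLE_CM2)}, got {self.size_label_mm}"
            )
        if not self.aoa_cm2 > 0:
            raise InvalidParameterError("aoa_cm2 must be positive")
        if self.occluder_count not in (0, 1, 2):
            raise InvalidParameterError("occluder_count must be 0, 1 or 2")
        if not 0.6 <= self.contraction_coefficient <= 1.0:
            raise InvalidParameterError("contraction_coefficient must lie in [0.6, 1.0]")

    @property
    def effective_area_cm2(self) -> float:
        return self.contraction_coefficient * self.aoa_cm2

    @property
    def is_stenotic(self) -> bool:
        return self.occluder_count > 0

    @property
    def anatomic_radius_mm(self) -> float:
        return 10.0 * float(np.sqrt(self.aoa_cm2 / np.pi))

    @property
    def effective_radius_mm(self) -> float:
        return 10.0 * float(np.sqrt(self.effective_area_cm2 / np.pi))

    @classmethod
    def from_size(cls, size_mm: int, occluders: int = 0,
                  contraction_coefficient: float | None = None) -> "ValveModel":
        """Build a valve from the default AOA table and stenosis factors."""
        if size_mm not in AOA_TABLE_CM2:
            raise InvalidParameterError(
                f"size_mm must be one of {sorted(AOA_TABLE_CM2)}, got {size_mm}"
            )
        if occluders not in OCCLUDER_AREA_FACTOR:
            raise InvalidParameterError("occluders must be 0, 1 or 2")
        aoa = AOA_TABLE_CM2[size_mm] * OCCLUDER_AREA_FACTOR[occluders]
        if contraction_coefficient is None:
            contraction_coefficient = CC_STENOTIC if occluders else CC_NORMAL
        return cls(size_mm, aoa, occluders, contraction_coefficient)


def _shape_profile(phase: np.ndarray, shape: str) -> np.ndarray:
    """Unnormalized filling profile on phase in [0, 1] (the filling window)."""
    q = np.zeros_like(phase)
    inside = (phase >= 0.0) & (phase <= 1.0)
    if shape == "half_sine":
        q[inside] = np.sin(np.pi * phase[inside])
    elif shape == "e_wave":
        # Early raised-cosine hump over the first 60% of the window plus a
        # lower (0.35 relative amplitude) mid-diastolic hump over the last
        # 55%; the overlap produces a dominant E wave with a plateau-like
        # mid-diastolic tail.
        e_sup = inside & (phase <= 0.6)
        q[e_sup] += 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[e_sup] / 0.6))
        m_sup = inside & (phase >= 0.45)
        q[m_sup] += 0.35 * 0.5 * (1.0 - np.cos(2.0 * np.pi * (phase[m_sup] - 0.45) / 0.55))
    else:
        raise InvalidParameterError(f"shape must be one of {WAVEFORM_SHAPES}, got {shape!r}")
    return q


def generate_diastolic_waveform(
    stroke_volume_ml: float,
    heart_rate_bpm: float,
    filling_fraction: float = 0.65,
    shape: str = "half_sine",
    n_samples: int = 1024,
) -> FlowWaveform:
    """Build a single-phase diastolic filling waveform.

    The flow is nonzero only within the filling window, which occupies the
    first ``filling_fraction`` of the cycle (the remainder is "systole", with
    the mitral valve closed).  The profile is renormalized so the trapezoidal
    integral over the cycle equals ``stroke_volume_ml`` to machine precision.

    Parameters
    ----------
    stroke_volume_ml : float
        Target per-beat forward volume (mL); must be positive.
    heart_rate_bpm : float
        Pump rate (beats/min); must be positive.
    filling_fraction : float
        Fraction of the cycle occupied by diastolic filling, in (0, 1).
    shape : {"half_sine", "e_wave"}
        ``half_sine`` is a single half-sinusoid; ``e_wave`` adds a lower
        mid-diastolic hump to the early filling wave.
    n_samples : int
        Number of grid points over the cycle (>= 64).
    """
    if not stroke_volume_ml > 0:
        raise InvalidParameterError("stroke_volume_ml must be positive")
    if not heart_rate_bpm > 0:
        raise InvalidParameterError("heart_rate_bpm must be positive")
    if not 0.0 < filling_fraction < 1.0:
        raise InvalidParameterError("filling_fraction must lie in (0, 1)")
    if n_samples < 64:
        raise InvalidParameterError("n_samples must be at least 64")

    period = 60.0 / heart_rate_bpm
    t = np.linspace(0.0, period, int(n_samples))
    t_fill = filling_fraction * period
    q = _shape_profile(t / t_fill, shape)
    area = float(np.trapezoid(q, t))
    q *= stroke_volume_ml / area
    return FlowWaveform(t, q, float(heart_rate_bpm), float(stroke_volume_ml))


def true_velocity_trace(waveform: FlowWaveform, valve: ValveModel) -> VelocityTrace:
    """Ideal vena-contracta jet velocity implied by conservation of flow.

    v(t) = Q(t) / A_eff, with Q in mL/s and A_eff in cm^2 giving v in cm/s.
    """
    a_eff = valve.effective_area_cm2
    if not a_eff > 0:
        raise InvalidParameterError("effective area must be positive")
    return VelocityTrace(waveform.time_s.copy(), waveform.flow_ml_s / a_eff)
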