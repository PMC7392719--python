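"""Doppler-analog pipeline: envelope indices, gradients and Doppler EOA.

Continuous-wave Doppler records the maximal jet velocity at millisecond
temporal resolution; its indices (peak velocity, TVI, Bernoulli gradients)
are computed per beat with the same integrators as the PC pipeline and then
averaged over consecutive beats (default five).  The Doppler EOA uses the
continuity equation with the flow-meter reference FFV:
``EOA = FFV_reference / Doppler TVI``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError
from .flow_model import VelocityTrace
from .pc_analysis import (FILLING_FLOOR, ValveSummary, bernoulli_gradients,
                          time_velocity_integral)
from .pc_synth import CWTrace

__all__ = ["DopplerIndices", "doppler_indices", "doppler_eoa", "analyze_cw_trace"]


@dataclass
class DopplerIndices:
    """Beat-averaged CW Doppler measurements."""

    peak_velocity_cm_s: float
    tvi_cm: float
    peak_gradient_mmhg: float
    mean_gradient_mmhg: float
    n_beats: int


def doppler_indices(trace: CWTrace, n_beats: int = 5,
                    floor_fraction: float = FILLING_FLOOR) -> DopplerIndices:
    """Per-beat envelope indices, arithmetic-meaned over ``n_beats`` beats."""
    if n_beats < 1:
        raise InvalidParameterError("n_beats must be >= 1")
    dt = trace.dt_s
    per_beat = int(round(trace.cycle_s / dt))
    if len(trace.time_s) < n_beats * per_beat:
        raise InsufficientDataError(
            f"trace covers {len(trace.time_s) * dt:.3f} s; "
            f"{n_beats} beats of {trace.cycle_s:.3f} s required"
        )
    peaks, tvis, pgrads, mgrads = [], [], [], []
    for b in range(n_beats):
        sl = slice(b * per_beat, (b + 1) * per_beat)
        beat = VelocityTrace(trace.time_s[sl], trace.envelope_cm_s[sl])
        peaks.append(float(np.max(beat.v_cm_s)))
        tvis.append(time_velocity_integral(beat, floor_fraction))
        pg, mg = bernoulli_gradients(beat, floor_fraction)
        pgrads.append(pg)
        mgrads.append(mg)
    return DopplerIndices(
        peak_velocity_cm_s=float(np.mean(peaks)),
        tvi_cm=float(np.mean(tvis)),
        peak_gradient_mmhg=float(np.mean(pgrads)),
        mean_gradient_mmhg=float(np.mean(mgrads)),
        n_beats=n_beats,
    )


def doppler_eoa(reference_ffv_ml: float, doppler_tvi_cm: float) -> float:
    """Continuity-equation EOA from the flow-meter FFV and Doppler TVI."""
    if doppler_tvi_cm <= 0:
        raise InvalidParameterError("doppler_tvi_cm must be positive")
    if reference_ffv_ml < 0:
        raise InvalidParameterError("reference_ffv_ml must be non-negative")
    return reference_ffv_ml / doppler_tvi_cm


def analyze_cw_trace(trace: CWTrace, reference_ffv_ml: float,
                     n_beats: int = 5) -> ValveSummary:
    """Full Doppler pipeline on one CW trace, yielding a :class:`ValveSummary`."""
    idx = doppler_indices(trace, n_beats)
    return ValveSummary(
        method="Doppler",
        peak_velocity_cm_s=idx.peak_velocity_cm_s,
        tvi_cm=idx.tvi_cm,
        ffv_ml=reference_ffv_ml,
        eoa_cm2=doppler_eoa(reference_ffv_ml, idx.tvi_cm),
        aoa_cm2=None,
        peak_gradient_mmhg=idx.peak_gradient_mmhg,
        mean_gradient_mmhg=idx.mean_gradient_mmhg,
    )
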