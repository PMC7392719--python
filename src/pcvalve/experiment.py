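"""The 24-condition validation grid: 8 valve configurations x 3 stroke volumes.

Mirrors the in vitro protocol: four normal valve sizes (27/29/31/33 mm) and
four stenotic constructs (27/29 mm with one or two occluders) are each run at
stroke volumes of 70, 90 and 110 mL/beat at 70 bpm.  Every condition is
simulated, measured by the PC and Doppler pipelines, and compared against the
ground truth; the grid emits a long-format per-condition table, normal- and
stenotic-group summaries (mean +/- SD over the 12 conditions per group), and
pairwise agreement reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import AgreementReport, compare_methods
from .doppler_analysis import analyze_cw_trace
from .errors import InvalidParameterError
from .flow_model import (FlowWaveform, ValveModel, generate_diastolic_waveform,
                         true_velocity_trace)
from .pc_analysis import (ValveSummary, analyze_pc_series,
                          time_velocity_integral)
from .pc_synth import AcquisitionParams, synthesize_cw_trace, synthesize_pc_series

__all__ = [
    "DEFAULT_VALVES",
    "ExperimentConfig",
    "GridResult",
    "run_grid",
    "relative_area_difference",
]

logger = logging.getLogger(__name__)

#: (size_mm, occluders) for the 8 default valve configurations.
DEFAULT_VALVES = (
    (27, 0), (29, 0), (31, 0), (33, 0),
    (27, 1), (29, 1), (27, 2), (29, 2),
)

#: Number of signal averages of the PC acquisition; noise scales as 1/sqrt(N).
PC_AVERAGES = 8

METRICS = ("peak_velocity_cm_s", "tvi_cm", "ffv_ml", "eoa_cm2", "aoa_cm2",
           "peak_gradient_mmhg", "mean_gradient_mmhg")


@dataclass
class ExperimentConfig:
    """Full description of a grid run (pump, valves, acquisition, Doppler)."""

    stroke_volumes_ml: tuple[float, ...] = (70.0, 90.0, 110.0)
    heart_rate_bpm: float = 70.0
    filling_fraction: float = 0.65
    shape: str = "half_sine"
    n_waveform_samples: int = 2048
    valves: tuple[tuple[int, int], ...] = DEFAULT_VALVES
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    pc_averages: int = PC_AVERAGES
    jet_edge_mm: float = 0.45
    jet_skirt: float = 0.2
    doppler_n_beats: int = 5
    doppler_noise_sd_cm_s: float = 3.0
    doppler_dt_ms: float = 2.0
    flow_threshold: float = 0.05
    aoa_threshold: float = 0.1
    percentile: float = 100.0

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExperimentConfig":
        """Build from a nested config mapping (``pump``/``valves``/``acquisition``/``doppler``)."""
        kwargs: dict = {}
        pump = cfg.get("pump", {})
        for src, dst in (("stroke_volumes_ml", "stroke_volumes_ml"),
                         ("heart_rate_bpm", "heart_rate_bpm"),
                         ("filling_fraction", "filling_fraction"),
                         ("shape", "shape")):
            if src in pump:
                kwargs[dst] = tuple(pump[src]) if dst == "stroke_volumes_ml" else pump[src]
        if "valves" in cfg:
            kwargs["valves"] = tuple(
                (int(v["size_mm"]), int(v.get("occluders", 0))) for v in cfg["valves"]
            )
        if "acquisition" in cfg:
            base = AcquisitionParams().to_dict()
            base.update(cfg["acquisition"])
            kwargs["acquisition"] = AcquisitionParams.from_dict(base)
        dop = cfg.get("doppler", {})
        if "n_beats" in dop:
            kwargs["doppler_n_beats"] = int(dop["n_beats"])
        if "noise_sd" in dop:
            kwargs["doppler_noise_sd_cm_s"] = float(dop["noise_sd"])
        jet = cfg.get("jet", {})
        if "edge_mm" in jet:
            kwargs["jet_edge_mm"] = float(jet["edge_mm"])
        if "skirt" in jet:
            kwargs["jet_skirt"] = float(jet["skirt"])
        return cls(**kwargs)


@dataclass
class GridResult:
    """Outputs of one grid run."""

    conditions: pd.DataFrame      # long format: one row per condition x method
    group_summary: pd.DataFrame   # mean +/- SD per group x method x metric
    agreement: pd.DataFrame       # one row per cross-method comparison
    reports: dict[str, AgreementReport]

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.conditions.to_csv(outdir / "conditions.csv", index=False)
        self.group_summary.to_csv(outdir / "group_summary.csv", index=False)
        self.agreement.to_csv(outdir / "agreement.csv", index=False)


def relative_area_difference(aoa_cm2: float, eoa_cm2: float) -> int:
    """Relative AOA-EOA difference, 100 (AOA - EOA) / AOA, as integer percent."""
    if aoa_cm2 <= 0:
        raise InvalidParameterError("aoa_cm2 must be positive")
    return int(round(100.0 * (aoa_cm2 - eoa_cm2) / aoa_cm2))


def _reference_summary(waveform: FlowWaveform, valve: ValveModel) -> ValveSummary:
    """Ground-truth indices: exact waveform integral and vena-contracta velocity."""
    from .pc_analysis import bernoulli_gradients

    ideal = true_velocity_trace(waveform, valve)
    tvi = time_velocity_integral(ideal)
    pg, mg = bernoulli_gradients(ideal)
    return ValveSummary(
        method="reference",
        peak_velocity_cm_s=float(ideal.v_cm_s.max()),
        tvi_cm=tvi,
        ffv_ml=waveform.stroke_volume_ml,
        eoa_cm2=valve.effective_area_cm2,
        aoa_cm2=valve.aoa_cm2,
        peak_gradient_mmhg=pg,
        mean_gradient_mmhg=mg,
    )


def run_grid(config: ExperimentConfig | None = None, seed: int = 0) -> GridResult:
    """Run the full validation grid, fully reproducible under a fixed seed."""
    cfg = config or ExperimentConfig()
    if not cfg.valves or not cfg.stroke_volumes_ml:
        raise InvalidParameterError("configuration must list valves and flow conditions")

    n_cond = len(cfg.valves) * len(cfg.stroke_volumes_ml)
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_cond) % (2 ** 31)
    logger.info("running grid: %d valves x %d flows = %d conditions (seed=%d)",
                len(cfg.valves), len(cfg.stroke_volumes_ml), n_cond, seed)

    pc_noise = cfg.acquisition.noise_sd_cm_s / np.sqrt(cfg.pc_averages)
    rows: list[dict] = []
    cond_id = 0
    for size_mm, occluders in cfg.valves:
        valve = ValveModel.from_size(size_mm, occluders)
        for sv in cfg.stroke_volumes_ml:
            waveform = generate_diastolic_waveform(
                sv, cfg.heart_rate_bpm, cfg.filling_fraction, cfg.shape,
                cfg.n_waveform_samples,
            )
            acq = cfg.acquisition.replace(noise_sd_cm_s=pc_noise,
                                          seed=int(seeds[2 * cond_id]))
            series = synthesize_pc_series(waveform, valve, acq,
                                          edge_mm=cfg.jet_edge_mm,
                                          skirt=cfg.jet_skirt)
            pc = analyze_pc_series(series,
                                   flow_threshold=cfg.flow_threshold,
                                   aoa_threshold=cfg.aoa_threshold,
                                   percentile=cfg.percentile)
            cw = synthesize_cw_trace(waveform, valve,
                                     noise_sd_cm_s=cfg.doppler_noise_sd_cm_s,
                                     dt_ms=cfg.doppler_dt_ms,
                                     seed=int(seeds[2 * cond_id + 1]),
                                     n_beats=cfg.doppler_n_beats)
            doppler = analyze_cw_trace(cw, waveform.stroke_volume_ml,
                                       cfg.doppler_n_beats)
            reference = _reference_summary(waveform, valve)

            base = {
                "condition_id": cond_id,
                "size_mm": size_mm,
                "occluders": occluders,
                "group": "stenotic" if occluders else "normal",
                "stroke_volume_ml": sv,
            }
            for summary in (reference, pc, doppler):
                rows.append(base | summary.to_dict())
                logger.info(
                    "condition %02d %dmm occ=%d sv=%.0f %s: peak=%.1f cm/s "
                    "tvi=%.1f cm ffv=%.1f mL eoa=%.2f cm2",
                    cond_id, size_mm, occluders, sv, summary.method,
                    summary.peak_velocity_cm_s, summary.tvi_cm,
                    summary.ffv_ml, summary.eoa_cm2,
                )
            cond_id += 1

    conditions = pd.DataFrame(rows)
    group_summary = _group_summary(conditions)
    reports = _agreement_reports(conditions)
    agreement = pd.DataFrame(
        [{"comparison": name} | rep.to_dict() for name, rep in reports.items()]
    )
    return GridResult(conditions, group_summary, agreement, reports)


def _group_summary(conditions: pd.DataFrame) -> pd.DataFrame:
    out = []
    for (group, method), sub in conditions.groupby(["group", "method"]):
        for metric in METRICS:
            vals = sub[metric].dropna()
            if vals.empty:
                continue
            out.append({
                "group": group,
                "method": method,
                "metric": metric,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "n": int(len(vals)),
            })
    return pd.DataFrame(out)


#: (name, metric, first/comparator method, second method) — differences are
#: oriented second minus first, matching the reported bias direction.
COMPARISONS = (
    ("ffv_pc_vs_reference", "ffv_ml", "reference", "PC"),
    ("peak_velocity_pc_vs_doppler", "peak_velocity_cm_s", "Doppler", "PC"),
    ("tvi_pc_vs_doppler", "tvi_cm", "Doppler", "PC"),
    ("eoa_pc_vs_doppler", "eoa_cm2", "Doppler", "PC"),
    ("eoa_pc_vs_reference", "eoa_cm2", "reference", "PC"),
)


def _agreement_reports(conditions: pd.DataFrame) -> dict[str, AgreementReport]:
    wide = conditions.pivot(index="condition_id", columns="method")
    reports = {}
    for name, metric, first, second in COMPARISONS:
        x = wide[(metric, first)].to_numpy(float)
        y = wide[(metric, second)].to_numpy(float)
        reports[name] = compare_methods(x, y)
    return reports
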