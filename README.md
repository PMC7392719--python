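# pcvalve

Phase-contrast (PC) cardiovascular MR quantification of **bioprosthetic mitral
valve (BMV)** function, with a built-in pulsatile flow-loop simulator and the
method-agreement statistics needed to validate PC against Doppler
echocardiography.

## The problem

After mitral valve replacement, valve function is followed with Doppler
echocardiography: the continuous-wave (CW) envelope gives the peak
transvalvular velocity, the time–velocity integral (TVI), simplified-Bernoulli
pressure gradients, and — via the continuity equation — the **effective
orifice area**

```
EOA = FFV / TVI        [cm³ / cm = cm²]
```

where FFV is the forward flow volume per beat. PC-CMR measures the same
physiology differently: through-plane velocity maps at the valve tips give the
instantaneous flow (sum of in-ROI pixel velocities × pixel area), whose time
integral is the PC-FFV, and a per-frame peak-velocity trace whose integral is
the PC-TVI, so **PC-EOA = PC-FFV / PC-TVI**. Planimetry of the jet base
yields the **anatomic orifice area (AOA)**, which exceeds the EOA by the flow
contraction coefficient Cc ∈ [0.6, 1.0] (A_eff = Cc · AOA): flow contracts to
a vena contracta, and the contraction weakens (Cc → 1) as the transvalvular
gradient rises.

`pcvalve` is for people developing or validating such pipelines: it generates
fully controlled synthetic acquisitions (known waveform, known orifice, known
noise), measures them with the PC and Doppler pipelines, and quantifies
cross-method agreement with Pearson r, Bland–Altman bias / limits of
agreement, and Shrout–Fleiss single-measure ICCs.

## What is simulated

* **Pump**: single-phase diastolic filling (half-sine or E-wave shaped),
  stroke volumes 70/90/110 mL at 70 bpm; flow is conserved to machine
  precision.
* **Valves**: normal 27/29/31/33 mm (AOA 2.4–3.4 cm², Cc 0.62) and stenotic
  constructs (27/29 mm with one or two occluders shrinking the AOA, Cc 0.85).
* **PC acquisition**: 1.2 × 0.9 mm in-plane, 4 mm slice, 48.9 ms frames with
  per-frame temporal averaging, VENC 400 cm/s with aliasing wrap, Gaussian
  velocity noise (8-average protocol ⇒ SD/√8), optional 3×3 partial-volume
  smoothing. The jet is a flux-conserving core (vena contracta) plus a slow
  annular skirt out to the anatomic radius.
* **CW Doppler**: the ideal vena-contracta velocity sampled at 2 ms plus
  noise, clipped at zero; indices averaged over 5 consecutive beats.

## Worked example

A severely stenotic 27 mm construct (two occluders: AOA 0.96 cm²,
A_eff = 0.85 × 0.96 = 0.816 cm²) at 90 mL/beat:

```python
from pcvalve import (ValveModel, generate_diastolic_waveform, AcquisitionParams,
                     synthesize_pc_series, synthesize_cw_trace,
                     analyze_pc_series, analyze_cw_trace)

valve = ValveModel.from_size(27, occluders=2)
wf = generate_diastolic_waveform(90, 70)                   # 90 mL at 70 bpm
params = AcquisitionParams(noise_sd_cm_s=3.0 / 8**0.5, seed=7)
pc = analyze_pc_series(synthesize_pc_series(wf, valve, params))
cw = synthesize_cw_trace(wf, valve, noise_sd_cm_s=3.0, seed=8, n_beats=5)
doppler = analyze_cw_trace(cw, reference_ffv_ml=90.0, n_beats=5)
```

which prints (peak velocity cm/s, TVI cm, FFV mL, EOA cm², AOA cm²,
peak/mean gradient mmHg):

```
PC       peak 300.1  tvi 107.0  ffv 89.0  eoa 0.832  aoa 0.994  grad 36.0/20.5
Doppler  peak 314.9  tvi 110.1  ffv 90.0  eoa 0.817  aoa   -    grad 39.7/20.0
```

Both pipelines recover the true effective area (0.816 cm²) to within a few
percent and the planimetric AOA ≈ 0.96 cm²; the PC peak velocity and TVI sit
slightly *below* Doppler (finite spatial/temporal resolution), so PC-EOA
comes out slightly *above* Doppler EOA — the characteristic asymmetry of the
two methods. The gradients (≈20 mmHg mean) are in the severe-stenosis range.

The same is available from the shell:

```bash
pcvalve simulate --size-mm 27 --occluders 2 --outdir demo
pcvalve analyze-pc demo/valve27_occ2_sv90_pc.nii.gz
pcvalve analyze-cw demo/valve27_occ2_sv90_cw.csv --ffv-ml 90
pcvalve run-grid --outdir grid --seed 1       # full 24-condition validation
pcvalve compare pairs.csv --out report.json   # Bland-Altman / r / ICC
```

`run-grid` writes `conditions.csv` (24 conditions × 3 methods),
`group_summary.csv` (normal/stenotic means ± SD) and `agreement.csv`
(pairwise Pearson/Bland–Altman/ICC reports).

## Configuration

`run-grid --config grid.yaml` accepts:

```yaml
pump:        {stroke_volumes_ml: [70, 90, 110], heart_rate_bpm: 70,
              filling_fraction: 0.65, shape: half_sine}
valves:      [{size_mm: 27}, {size_mm: 29, occluders: 2}]
acquisition: {frame_interval_ms: 48.9, pixel_spacing_mm: [1.2, 0.9],
              noise_sd_cm_s: 3.0, venc_cm_s: 400.0, grid_size: [64, 72]}
doppler:     {n_beats: 5, noise_sd: 3.0}
jet:         {edge_mm: 0.45, skirt: 0.2}
```

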