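# Methods

## Physical model

The package emulates a pulsatile flow loop driving a bioprosthetic mitral
valve inside an imaging chamber. One cardiac cycle of length `60 / HR`
contains a single diastolic filling phase and a zero-flow "systole" — there
is no atrial kick, no regurgitation and no valve motion, which is what an in
vitro pump rig provides and what makes the ground truth exactly known.

**Waveform.** `generate_diastolic_waveform` places all flow in the first
`filling_fraction` of the cycle (default 0.65, the diastolic fraction at
70 bpm) and renormalizes the profile so its trapezoidal integral equals the
stroke volume exactly. Two shapes are provided: a half-sinusoid, and an
"e_wave" built from a dominant raised-cosine early wave (first 60 % of the
window) plus a 0.35-amplitude mid-diastolic hump (last 55 %, overlapping).
The grid default is the half-sine: the pump produced one smooth filling
phase, and the e_wave's higher peak-to-mean ratio (~2.5 vs π/2) would push
the severest stenotic condition past both the 400 cm/s VENC and the peak
velocities observed clinically for stenotic bioprostheses (151–418 cm/s).

**Valves.** Normal AOAs by labelled size: 27→2.4, 29→2.7, 31→3.1,
33→3.4 cm² (group mean 2.9 cm²). Occluders multiply the AOA by 0.55 (one,
mild) or 0.40 (two, severe); the stenotic group 27/29 × {1,2} then averages
1.21 cm². The contraction coefficient defaults to 0.62 for normal valves and
0.85 for stenotic ones — both inside the physical 0.6–1.0 range, stenotic
higher because a larger transvalvular gradient forces flow to occupy more of
the anatomic opening. The effective (vena-contracta) area is
`A_eff = Cc · AOA`, and the ideal jet velocity is `v(t) = Q(t) / A_eff`.

## Synthetic phase-contrast acquisition

Defaults mirror a clinical mitral PC protocol: 1.2 × 0.9 mm pixels, 4 mm
slice, 48.9 ms frame interval, VENC 400 cm/s, velocity noise SD 3 cm/s
(divided by √8 in the grid, modelling an 8-average acquisition). The grid is
64 × 72 pixels so the FOV covers at least three anatomic diameters for every
default valve.

**Jet cross-section.** The through-plane velocity pattern is separable:
`v(t, x, y) = u(t) · P(x, y)`.  `P` is a circular core of the effective
radius with a tanh edge (length scale 0.45 mm ≈ a one-pixel 10–90 %
transition; `edge_mm=0` gives an anti-aliased top-hat), surrounded by an
annular "skirt" at 0.2 × the core velocity extending to the anatomic radius
— the slow flow at the margin of the jet base that a plane at the leaflet
tips sees. The amplitude `u(t)` is normalized so that the *discrete*
pixel-sum flux equals the pump flow at every frame: flow is conserved by
construction. Two consequences deliberately mirror real PC measurement:

* the core plateau velocity is `Q / (A_eff + 0.2 · A_annulus)`, slightly
  below the ideal vena-contracta velocity that CW Doppler reads, so PC peak
  velocity and PC-TVI come out below their Doppler counterparts and PC-EOA
  slightly above Doppler EOA;
* with the skirt off ("uniform jet") the flux area is exactly `Cc × AOA`,
  giving the analytic continuity identity used as the pipeline's oracle.

**Degradations.** Each frame is the boxcar average of the flow over
`temporal_window_ms` (default = one frame interval, as in retrospectively
gated cine; wider windows model view sharing) centred on the mid-frame time;
i.i.d. Gaussian noise is added per pixel (seeded `default_rng`); velocities
beyond the VENC wrap modulo 2·VENC when aliasing is enabled; an optional 3×3
boxcar models in-plane partial voluming. Not modelled: k-space effects,
eddy-current phase offsets, slice-profile integration, valve motion.

**CW Doppler.** The envelope is the ideal vena-contracta velocity sampled at
~2 ms (the step is snapped to divide the cycle exactly so consecutive beats
are sample-periodic) plus clipped Gaussian noise. Beat-to-beat variability
is therefore pure measurement noise, and the 5-beat averaging of the Doppler
indices is a √5 noise-reduction device, as in practice.

## Measurement pipelines

**Segmentation.** The reference frame is the frame with the greatest
spatial-sum velocity; the threshold is a fraction of its maximum pixel
velocity; each frame keeps the largest 4-connected super-threshold
component, and frames with none (systole) inherit the reference mask.
`segment_jet_roi`'s own default fraction is 0.5 (jet-core identification),
but the full PC pipeline contours *flow* at 0.05 — a generous contour that
encloses the entire jet base, as clinical contouring does, while still
sitting ≳5σ above the default 8-average noise floor. The planimetric AOA
uses 0.1 at the peak-flow frame: with the 0.2-amplitude skirt, the
0.1-of-maximum contour falls exactly at the anatomic radius.

**Integration.** FFV and TVI integrate over the contiguous "filling window"
around the peak where the trace stays above 5 % of its maximum (this floor
excludes noise-only systolic frames; negative flows are clipped). The
quadrature is the rectangle rule — frame sum × frame interval — because
gated cine samples *are* temporal means over their interval, making the
rectangle rule the exact quadrature for them; on dense grids it coincides
with the trapezoid. The Bernoulli *mean* gradient, being a time average
rather than an accumulation, uses the trapezoidal rule over the window.

**Peak velocity** is the in-ROI maximum per frame (an upper-percentile
variant is exposed because noise inflates maxima). Gradients use the
simplified Bernoulli relation ΔP = 4 v² (v in m/s). PC-EOA = FFV/TVI;
Doppler EOA divides the *flow-meter* (ground-truth) FFV by the Doppler TVI,
mirroring the reference transducer's role in a rig.

## Agreement statistics

Differences are oriented `second method − first method`. Bland–Altman uses
the classical fixed 1.96 multiplier on the SD (n−1) of differences — the
limits of agreement, not a confidence interval of the bias. ICCs are the
Shrout–Fleiss single-measure forms, ICC(1,1) and ICC(2,1), computed from the
one- and two-way ANOVA mean squares; negative estimates are reported
unclipped. Pearson r delegates to `scipy.stats.pearsonr`; zero-variance
input raises rather than returning NaN at the function level, while the
bundled `compare_methods` report records NaN for undefined r/ICC so
degenerate grids still yield their bias and limits.

## The validation grid

`run_grid` crosses 8 valve configurations with 3 stroke volumes (n = 24),
simulates each condition (PC series, 5-beat CW trace), measures it with both
pipelines, and tabulates per-condition indices, normal/stenotic group means
± SD (12 conditions per group), and agreement reports for FFV (PC vs
truth), peak velocity / TVI / EOA (PC vs Doppler) and EOA (PC vs truth).
All randomness derives from one seed via `SeedSequence`; a fixed seed
reproduces every CSV bit-for-bit.

## What the synthetic world does and does not show

Passing tests demonstrate that the *pipelines* are correct and that the
acquisition degradations produce the expected direction and rough size of
cross-method differences (PC-TVI below Doppler TVI, PC-EOA above Doppler
EOA, near-zero FFV bias). They do not validate against real scanners: the
simulator has no phase-offset errors, no intra-voxel dephasing, no operator
variability in contouring or beam alignment, and a perfectly periodic pump.
Group means land near clinically reported values for normal and stenotic
bioprostheses by construction of the default valve table, not as an
independent finding.

## Numerical choices and degenerate inputs

* Frame times are mid-frame, `(k + ½) · Δt`, spanning one cycle.
* The window-averaged flow uses 97 sub-samples per boxcar with periodic
  extension of the waveform.
* Disc coverage fractions (sharp-edged jets) are 8×8 supersampled.
* The continuity-identity check runs at 0.6 × 0.45 mm / 10 ms, noise-free
  with the skirt off, where pixel quantization is far below the 0.5 %
  assertion level; problem sizes throughout (64×72 grid, ≤2048 waveform
  samples, 5 beats) keep a full grid run under a second.
* All-zero series raise a no-jet error; single-frame traces raise
  insufficient-data errors; TVI of an all-zero trace is 0 (valid);
  `pc_eoa`/`doppler_eoa` reject non-positive TVI.

## Known limitations

Circular jets only; a single imaging plane (no multi-slice or 4D flow); no
pressure-half-time EOA; no A-wave (biphasic) filling; the skirt amplitude
(0.2) is a stylized stand-in for the continuum of slow flow around a real
jet base, chosen jointly with the 0.1 planimetry threshold so planimetry
reads the anatomic area.
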