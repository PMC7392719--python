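"""PC pipeline: segmentation, flow, FFV, TVI, EOA, planimetry, gradients."""

import numpy as np
import pytest

from pcvalve import (AcquisitionParams, InsufficientDataError,
                     InvalidParameterError, NoJetError, PCSeries, ValveModel,
                     analyze_pc_series, bernoulli_gradients,
                     forward_flow_volume, generate_diastolic_waveform,
                     instantaneous_flow, pc_eoa, peak_velocity_trace,
                     planimeter_aoa, segment_jet_roi, synthesize_pc_series,
                     time_velocity_integral)
from pcvalve.flow_model import VelocityTrace
from pcvalve.pc_analysis import FlowTrace


def make_series(frames, params=None, frame_interval_s=0.05):
    """Wrap a (frames, rows, cols) array into a PCSeries."""
    frames = np.asarray(frames, dtype=float)
    params = params or AcquisitionParams()
    times = (np.arange(frames.shape[0]) + 0.5) * frame_interval_s
    return PCSeries(frames, times, params)


def disc_frame(shape, radius_px, value=100.0):
    rows, cols = shape
    rr = np.arange(rows)[:, None] - (rows - 1) / 2.0
    cc = np.arange(cols)[None, :] - (cols - 1) / 2.0
    return np.where(rr ** 2 + cc ** 2 <= radius_px ** 2, value, 0.0)


class TestSegmentation:
    def test_recovers_jet_area_within_edge_tolerance(self):
        # ~80-pixel disc, threshold 0.5 -> mask within +/- 8 pixels
        frame = disc_frame((64, 64), np.sqrt(80 / np.pi))
        n_pix = int((frame > 0).sum())
        roi = segment_jet_roi(make_series([frame, frame]), 0.5)
        assert abs(int(roi.mask[0].sum()) - n_pix) <= 8

    def test_all_zero_series_raises(self):
        with pytest.raises(NoJetError):
            segment_jet_roi(make_series(np.zeros((3, 32, 32))))

    def test_largest_component_wins(self):
        frame = np.zeros((64, 64))
        frame[10:14, 10:14] = 100.0   # 16-pixel blob
        frame[30:42, 30:42] = 100.0   # 144-pixel jet
        roi = segment_jet_roi(make_series([frame]), 0.5)
        assert roi.mask[0, 35, 35] and not roi.mask[0, 11, 11]
        assert int(roi.mask[0].sum()) == 144

    def test_empty_frames_inherit_reference_mask(self):
        jet = disc_frame((32, 32), 5.0)
        roi = segment_jet_roi(make_series([jet, np.zeros((32, 32))]), 0.5)
        assert np.array_equal(roi.mask[1], roi.mask[0])


class TestFlowAndFFV:
    def test_single_pixel_flow_arithmetic(self):
        frame = np.zeros((16, 16))
        frame[8, 8] = 100.0  # cm/s; 1.2 x 0.9 mm pixel = 0.0108 cm^2
        series = make_series([frame, frame])
        roi = segment_jet_roi(series, 0.5)
        flow = instantaneous_flow(series, roi)
        assert flow.flow_ml_s[0] == pytest.approx(1.08, rel=1e-12)

    def test_constant_flow_closed_form(self):
        # 100 mL/s held over 0.3 s -> 30 mL
        t = np.arange(6) * 0.05 + 0.025
        ffv = forward_flow_volume(FlowTrace(t, np.full(6, 100.0)))
        assert ffv == pytest.approx(30.0, rel=1e-12)

    def test_single_frame_raises(self):
        with pytest.raises(InsufficientDataError):
            forward_flow_volume(FlowTrace(np.array([0.0]), np.array([1.0])))

    def test_simulated_ffv_recovers_stroke_volume(self, clean_series):
        roi = segment_jet_roi(clean_series, 0.05)
        ffv = forward_flow_volume(instantaneous_flow(clean_series, roi))
        assert ffv == pytest.approx(90.0, rel=0.03)

    def test_negative_flow_clipped(self):
        t = np.arange(4) * 0.05
        trace = FlowTrace(t, np.array([100.0, 100.0, -50.0, 100.0]))
        assert forward_flow_volume(trace) >= 0.0


class TestPeakVelocityAndTVI:
    def test_plateau_jet_yields_plateau_trace(self):
        frame = disc_frame((32, 32), 6.0, value=120.0)
        series = make_series([frame, 0.5 * frame])
        roi = segment_jet_roi(series, 0.3)
        trace = peak_velocity_trace(series, roi)
        assert trace.v_cm_s == pytest.approx([120.0, 60.0])

    def test_noise_inflates_the_maximum_on_average(self):
        rng = np.random.default_rng(5)
        frame = disc_frame((32, 32), 6.0, value=120.0)
        diffs = []
        for _ in range(30):
            noisy = frame + rng.normal(0.0, 3.0, frame.shape)
            series = make_series([noisy, noisy])
            roi = segment_jet_roi(series, 0.3)
            diffs.append(peak_velocity_trace(series, roi).v_cm_s[0] - 120.0)
        assert np.mean(diffs) > 0.0

    def test_percentile_option_is_less_than_max(self):
        rng = np.random.default_rng(6)
        frame = disc_frame((32, 32), 6.0, value=120.0) + rng.normal(0, 3, (32, 32))
        series = make_series([frame, frame])
        roi = segment_jet_roi(series, 0.3)
        vmax = peak_velocity_trace(series, roi, 100.0).v_cm_s[0]
        v95 = peak_velocity_trace(series, roi, 95.0).v_cm_s[0]
        assert v95 < vmax

    def test_constant_trace_closed_form(self):
        t = np.arange(10) * 0.05 + 0.025
        tvi = time_velocity_integral(VelocityTrace(t, np.full(10, 100.0)))
        assert tvi == pytest.approx(50.0, rel=1e-12)

    def test_half_sine_tvi_closed_form(self):
        # peak 150 cm/s over 0.4 s -> (2/pi) * 150 * 0.4 ~ 38.20 cm
        t = np.linspace(0.0, 0.4, 4000)
        v = 150.0 * np.sin(np.pi * t / 0.4)
        tvi = time_velocity_integral(VelocityTrace(t, v))
        assert tvi == pytest.approx(2.0 / np.pi * 150.0 * 0.4, rel=0.01)

    def test_all_zero_trace_gives_zero(self):
        t = np.arange(5) * 0.05
        assert time_velocity_integral(VelocityTrace(t, np.zeros(5))) == 0.0

    def test_coarse_sampling_does_not_inflate_tvi(self):
        # 48.9 ms sampling of a smooth hump stays below dense TVI + 2%
        t_dense = np.linspace(0.0, 0.557, 2000)
        v = 180.0 * np.sin(np.pi * t_dense / 0.557)
        dense = time_velocity_integral(VelocityTrace(t_dense, v))
        t_coarse = np.arange(0.0245, 0.557, 0.0489)
        v_coarse = 180.0 * np.sin(np.pi * t_coarse / 0.557)
        coarse = time_velocity_integral(VelocityTrace(t_coarse, v_coarse))
        assert coarse <= dense * 1.02


class TestEOA:
    def test_arithmetic(self):
        assert pc_eoa(90.0, 60.0) == pytest.approx(1.5)
        assert pc_eoa(0.0, 50.0) == 0.0

    def test_invalid_tvi_raises(self):
        with pytest.raises(InvalidParameterError):
            pc_eoa(90.0, 0.0)
        with pytest.raises(InvalidParameterError):
            pc_eoa(90.0, -2.0)

    @pytest.mark.parametrize("size,occ", [(27, 0), (33, 0), (27, 2), (29, 1)])
    @pytest.mark.parametrize("shape", ["half_sine", "e_wave"])
    def test_continuity_identity_uniform_jet(self, uniform_series_factory,
                                             size, occ, shape):
        # noise-free uniform jet at dense sampling: EOA = Cc x AOA (< 0.5%)
        valve = ValveModel.from_size(size, occ)
        wf = generate_diastolic_waveform(90.0, 70.0, 0.65, shape, 2048)
        series = uniform_series_factory(valve, wf)
        summary = analyze_pc_series(series)
        assert summary.eoa_cm2 == pytest.approx(valve.effective_area_cm2, rel=0.005)

    def test_linearity_in_velocity_scaling(self, clean_series):
        doubled = PCSeries(2.0 * clean_series.velocity_cm_s,
                           clean_series.frame_times_s, clean_series.params)
        base = analyze_pc_series(clean_series)
        scaled = analyze_pc_series(doubled)
        assert scaled.ffv_ml == pytest.approx(2.0 * base.ffv_ml, rel=1e-9)
        assert scaled.tvi_cm == pytest.approx(2.0 * base.tvi_cm, rel=1e-9)


class TestPlanimetry:
    def test_synthetic_disc_area(self):
        # 200-pixel disc at 0.0108 cm^2/pixel -> ~2.16 cm^2 within 5%
        frame = disc_frame((64, 64), np.sqrt(200 / np.pi))
        aoa = planimeter_aoa(make_series([frame, frame]), 0.1)
        assert aoa == pytest.approx(2.16, rel=0.05)

    def test_exact_pixel_count(self):
        params = AcquisitionParams(pixel_spacing_mm=(1.0, 1.0))
        frame = np.zeros((32, 32))
        frame[10:20, 10:20] = 50.0  # 100 pixels of 0.01 cm^2
        aoa = planimeter_aoa(make_series([frame], params), 0.1)
        assert aoa == pytest.approx(1.0, rel=1e-12)

    def test_no_jet_raises(self):
        with pytest.raises(NoJetError):
            planimeter_aoa(make_series(np.zeros((2, 16, 16))))

    def test_normal_group_mean_aoa_in_rig_range(self, clean_params):
        wf = generate_diastolic_waveform(90.0, 70.0)
        aoas = []
        for size in (27, 29, 31, 33):
            valve = ValveModel.from_size(size, 0)
            series = synthesize_pc_series(wf, valve, clean_params)
            aoas.append(planimeter_aoa(series, 0.1))
        assert 2.4 <= np.mean(aoas) <= 3.4

    def test_aoa_exceeds_eoa_on_defaults(self, clean_series):
        summary = analyze_pc_series(clean_series)
        assert summary.aoa_cm2 > summary.eoa_cm2


class TestBernoulli:
    def test_closed_forms(self):
        t = np.linspace(0.0, 0.4, 201)  # includes the exact mid-filling peak
        v = 282.0 * np.sin(np.pi * t / 0.4)
        peak, mean = bernoulli_gradients(VelocityTrace(t, v))
        assert peak == pytest.approx(4.0 * 2.82 ** 2, rel=1e-6)  # 31.8 mmHg
        assert mean < peak

    def test_simple_values(self):
        t = np.arange(5) * 0.1
        peak, _ = bernoulli_gradients(VelocityTrace(t, np.full(5, 100.0)))
        assert peak == pytest.approx(4.0)
        peak, mean = bernoulli_gradients(VelocityTrace(t, np.full(5, 200.0)))
        assert peak == pytest.approx(16.0)
        assert mean == pytest.approx(16.0)


class TestCcMonotonicity:
    def test_area_gap_shrinks_as_cc_rises(self, waveform90, clean_params):
        gaps = []
        for cc in (0.62, 0.75, 0.9, 1.0):
            valve = ValveModel(29, 2.7, 0, cc)
            series = synthesize_pc_series(waveform90, valve, clean_params)
            s = analyze_pc_series(series)
            gaps.append((s.aoa_cm2 - s.eoa_cm2) / s.aoa_cm2)
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
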