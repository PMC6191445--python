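"""Trace extraction, ratio computation, normalization, SNR, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thrombofret import ratiometrics as rm
from thrombofret import segment as seg
from thrombofret.io import CFP, FURA_340, FURA_380, YFP, TimeLapseStack


def toy_stack(cfp_frames, yfp_frames):
    data = np.stack([np.stack([c, y]) for c, y in zip(cfp_frames, yfp_frames)])
    return TimeLapseStack(data=data.astype(float), channel_names=[CFP, YFP])


class TestBackground:
    def test_constant_background_recovered_exactly(self):
        img = np.full((16, 16), 40.0)
        img[4:12, 4:12] = 500.0
        stack = toy_stack([img], [img])
        whole = seg.MaskSeries(whole=np.stack([img > 100]))
        bg = rm.estimate_background(stack, whole_masks=whole, dilate_px=1)
        assert bg["F480"].iloc[0] == pytest.approx(40.0)

    def test_roi_inside_thrombus_rejected(self):
        img = np.full((16, 16), 40.0)
        img[4:12, 4:12] = 500.0
        stack = toy_stack([img], [img])
        whole = seg.MaskSeries(whole=np.stack([img > 100]))
        with pytest.raises(ValueError, match="intersects"):
            rm.estimate_background(stack, whole_masks=whole, bg_roi=(5, 8, 5, 8))

    def test_roi_mean_used_when_given(self):
        img = np.full((16, 16), 40.0)
        img[0:4, 0:4] = 10.0
        stack = toy_stack([img], [img])
        whole = seg.MaskSeries(whole=np.zeros((1, 16, 16), bool))
        bg = rm.estimate_background(stack, whole_masks=whole, bg_roi=(0, 4, 0, 4))
        assert bg["F535"].iloc[0] == pytest.approx(10.0)

    def test_poisson_background_within_three_se(self, pipeline_bundle):
        noise_level = 150.0  # generator default
        bg = pipeline_bundle["background"]
        # median estimator over >2e4 pixels/frame: stays within a count
        assert abs(bg["F480"].mean() - noise_level) < 1.0
        assert abs(bg["F535"].mean() - noise_level) < 1.0


class TestExtractTraces:
    def test_hand_computed_mean(self):
        cfp = np.arange(9, dtype=float).reshape(3, 3) + 10
        yfp = np.full((3, 3), 5.0)
        stack = toy_stack([cfp], [yfp])
        mask = np.zeros((1, 3, 3), bool)
        mask[0, 0, 0] = mask[0, 0, 1] = mask[0, 1, 0] = mask[0, 1, 1] = True
        masks = seg.MaskSeries(whole=mask)
        bg = pd.DataFrame({"F480": [2.0], "F535": [1.0]})
        traces = rm.extract_traces(stack, masks, bg)
        # pixels 10, 11, 13, 14 -> mean 12, minus background 2 -> 10
        assert traces.region("whole")["F480"].iloc[0] == pytest.approx(10.0)
        assert traces.region("whole")["F535"].iloc[0] == pytest.approx(4.0)

    def test_constant_field_constant_trace(self):
        frames = [np.full((8, 8), 100.0)] * 4
        stack = toy_stack(frames, frames)
        masks = seg.MaskSeries(whole=np.ones((4, 8, 8), bool))
        bg = pd.DataFrame({"F480": np.zeros(4), "F535": np.zeros(4)})
        traces = rm.extract_traces(stack, masks, bg)
        assert np.allclose(traces.region("whole")["F480"], 100.0)

    def test_empty_frame_flagged_not_dropped(self):
        frames = [np.full((8, 8), 100.0)] * 3
        stack = toy_stack(frames, frames)
        whole = np.ones((3, 8, 8), bool)
        whole[1] = False
        masks = seg.MaskSeries(whole=whole)
        bg = pd.DataFrame({"F480": np.zeros(3), "F535": np.zeros(3)})
        traces = rm.extract_traces(stack, masks, bg)
        sub = traces.region("whole")
        assert sub["empty"].tolist() == [False, True, False]
        assert np.isnan(sub["F480"].iloc[1])

    def test_all_empty_region_rejected(self):
        frames = [np.full((8, 8), 100.0)] * 3
        stack = toy_stack(frames, frames)
        masks = seg.MaskSeries(whole=np.zeros((3, 8, 8), bool))
        bg = pd.DataFrame({"F480": np.zeros(3), "F535": np.zeros(3)})
        with pytest.raises(ValueError, match="empty in every frame"):
            rm.extract_traces(stack, masks, bg)


def make_region_traces(f480, f535):
    n = len(f480)
    df = pd.DataFrame({
        "t_s": np.arange(n, dtype=float), "region": "whole",
        "F480": f480, "F535": f535, "empty": [False] * n,
    })
    return rm.RegionTraces(df=df, channels=["F480", "F535"], dt=1.0)


class TestRatioAndNormalize:
    def test_simple_ratio(self):
        traces = make_region_traces([100.0] * 4, [200.0] * 4)
        ratio = rm.compute_ratio(traces)["whole"]
        assert np.allclose(ratio.r, 0.5)

    def test_opposite_channel_steps_compound(self):
        # CFP +10% and YFP -10% move R by 1.1/0.9
        traces = make_region_traces([100, 100, 110, 110], [100, 100, 90, 90])
        ratio = rm.compute_ratio(traces)["whole"]
        assert ratio.r[2] / ratio.r[0] == pytest.approx(1.1 / 0.9)

    def test_gain_invariance(self):
        f480 = np.array([100, 105, 120, 100.0])
        f535 = np.array([200, 195, 180, 200.0])
        r1 = rm.compute_ratio(make_region_traces(f480, f535))["whole"].r
        r2 = rm.compute_ratio(make_region_traces(3.7 * f480, 3.7 * f535))["whole"].r
        assert np.allclose(r1, r2)

    def test_nonpositive_f535_flagged(self):
        traces = make_region_traces([100.0] * 5, [200, 200, 0, 200, 200.0])
        ratio = rm.compute_ratio(traces)["whole"]
        assert not ratio.valid[2]
        assert np.isnan(ratio.r[2])

    def test_mostly_invalid_trace_rejected(self):
        traces = make_region_traces([100.0] * 4, [0.0, 0.0, 0.0, 200.0])
        with pytest.raises(ValueError, match="50%"):
            rm.compute_ratio(traces)

    def test_normalize_fractional_change(self):
        t = np.arange(10.0)
        x = np.array([0.5] * 5 + [0.6] * 5)
        dx, base = rm.normalize_trace(t, x, (0.0, 5.0))
        assert base == pytest.approx(0.5)
        assert dx[-1] == pytest.approx(0.2)

    def test_all_baseline_trace_normalizes_to_zero(self):
        t = np.arange(6.0)
        dx, _ = rm.normalize_trace(t, np.full(6, 0.8), (0.0, 6.0))
        assert np.allclose(dx, 0.0)

    @given(k=st.floats(min_value=1e-3, max_value=1e3,
                       allow_nan=False, allow_infinity=False))
    def test_scale_invariance(self, k):
        t = np.arange(12.0)
        x = np.linspace(1.0, 2.0, 12)
        dx1, _ = rm.normalize_trace(t, x, (0.0, 4.0))
        dx2, _ = rm.normalize_trace(t, k * x, (0.0, 4.0))
        assert np.allclose(dx1, dx2, rtol=1e-9)

    def test_sparse_baseline_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError, match="baseline"):
            rm.normalize_trace(t, np.ones(10), (0.0, 2.0))


class TestSnrFilter:
    def build_trace(self, peak_dev):
        rng_free = np.array([-1, 1, -1, 1, -1, 1, -1, 1, -1, 1], float)
        baseline = 1.0 + 0.01 * np.sqrt(9 / 10) * rng_free  # SD (ddof=1) = 0.01
        response = np.full(10, 1.0)
        response[5] = baseline.mean() + peak_dev
        r = np.concatenate([baseline, response])
        t = np.arange(20.0)
        return rm.RatioTrace(region="whole", t=t, r=r, valid=np.ones(20, bool))

    def test_snr_below_threshold_excluded(self):
        trace = self.build_trace(peak_dev=0.024)
        kept, dropped, log = rm.snr_filter([trace], (0, 10), (10, 20))
        assert dropped and not kept
        assert log["snr"].iloc[0] == pytest.approx(2.4, rel=1e-6)

    def test_snr_above_threshold_retained(self):
        trace = self.build_trace(peak_dev=0.026)
        kept, dropped, _ = rm.snr_filter([trace], (0, 10), (10, 20))
        assert kept and not dropped
        assert kept[0].snr == pytest.approx(2.6, rel=1e-6)

    def test_zero_variance_baseline_retained_with_warning(self):
        t = np.arange(20.0)
        r = np.ones(20)
        r[15] = 1.5
        trace = rm.RatioTrace(region="whole", t=t, r=r, valid=np.ones(20, bool))
        with pytest.warns(UserWarning, match="zero baseline variance"):
            kept, dropped, _ = rm.snr_filter([trace], (0, 10), (10, 20))
        assert kept and kept[0].snr == np.inf

    def test_decisions_reproducible(self):
        trace = self.build_trace(peak_dev=0.024)
        logs = [rm.snr_filter([self.build_trace(0.024)], (0, 10), (10, 20))[2]
                for _ in range(2)]
        pd.testing.assert_frame_equal(logs[0], logs[1])


class TestSensorModel:
    def test_forward_anchors(self):
        m = rm.SensorModel()
        assert rm.sensor_forward(0.0, m) == pytest.approx(m.r_min)
        assert rm.sensor_forward(m.ec50, m) == pytest.approx((m.r_min + m.r_max) / 2)
        assert rm.sensor_forward(100 * m.ec50, m) == pytest.approx(m.r_max, rel=0.01)

    def test_forward_strictly_increasing(self):
        m = rm.SensorModel(hill_n=1.7)
        c = np.linspace(0, 5, 200)
        assert (np.diff(rm.sensor_forward(c, m)) > 0).all()

    def test_inverse_half_occupancy(self):
        m = rm.SensorModel()
        c, sat = rm.sensor_inverse((m.r_min + m.r_max) / 2, m)
        assert c == pytest.approx(m.ec50)
        assert not sat

    @pytest.mark.parametrize("hill_n", [1.0, 2.0])
    def test_round_trip_below_saturation(self, hill_n):
        m = rm.SensorModel(hill_n=hill_n)
        c = np.linspace(0.01, 2.9, 50)
        back, sat = rm.sensor_inverse(rm.sensor_forward(c, m), m)
        assert np.allclose(back, c, atol=1e-9)
        assert not sat.any()

    def test_saturated_ratio_reports_lower_bound(self):
        m = rm.SensorModel()
        r_at_4um = rm.sensor_forward(4.0, m)
        c, sat = rm.sensor_inverse(r_at_4um, m)
        assert sat
        assert c == pytest.approx(m.c_sat)

    def test_out_of_range_ratio_clipped_with_warning(self):
        m = rm.SensorModel()
        with pytest.warns(UserWarning, match="clipped"):
            c, sat = rm.sensor_inverse(m.r_max + 0.5, m)
        assert sat and c == m.c_sat
        with pytest.warns(UserWarning, match="clipped"):
            c, _ = rm.sensor_inverse(m.r_min - 0.5, m)
        assert c == 0.0

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            rm.SensorModel(r_min=2.0, r_max=1.0)
        with pytest.raises(ValueError):
            rm.SensorModel(c_sat=0.1)

    def test_region_mean_concentration_recovered_within_15_percent(self):
        # noisy movie with sub-saturation levels in both regions
        from thrombofret import synth

        kin = synth.CgmpKinetics(c_on_core=0.4, c_on_periphery=2.0)
        stack, gt, sched = synth.default_flow_movie(
            seed=11, duration=120.0, on_windows=((30.0, 120.0),), kinetics=kin
        )
        thr = synth.consistent_threshold()
        masks = seg.segment_stack(stack, seg.SegmentationParams(threshold=thr))
        bg = rm.estimate_background(stack, whole_masks=masks)
        ratios = rm.compute_ratio(rm.extract_traces(stack, masks, bg))
        m = rm.SensorModel()
        plateau = slice(90, 120)
        for region, true_c in (("core", 0.4), ("periphery", 2.0)):
            r_pl = np.nanmean(ratios[region].r[plateau])
            c, sat = rm.sensor_inverse(r_pl, m)
            assert not sat
            assert c == pytest.approx(true_c, rel=0.15)


class TestFura:
    def make_fura_traces(self, f340, f380):
        n = len(f340)
        df = pd.DataFrame({
            "t_s": np.arange(n, dtype=float), "region": "whole",
            "F340": f340, "F380": f380, "empty": [False] * n,
        })
        return rm.RegionTraces(df=df, channels=["F340", "F380"], dt=1.0)

    def test_equal_channels_give_unity(self):
        tr = self.make_fura_traces([50.0] * 3, [50.0] * 3)
        assert np.allclose(rm.fura_signal(tr)["whole"].r, 1.0)

    def test_calcium_step_sign_convention(self):
        tr = self.make_fura_traces([50, 60.0], [50, 40.0])
        ratio = rm.fura_signal(tr)["whole"].r
        assert ratio[1] > ratio[0]

    def test_missing_channel_rejected(self):
        tr = make_region_traces([1.0] * 3, [1.0] * 3)
        with pytest.raises(ValueError, match="F340"):
            rm.fura_signal(tr)

    def test_synthetic_ca_anticorrelated_with_cgmp(self, ca_bundle):
        cg = ca_bundle["ratios"]["whole"]
        ca = ca_bundle["fura"]["whole"]
        r = np.corrcoef(cg.dr_over_r, ca.r)[0, 1]
        assert r < -0.8
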