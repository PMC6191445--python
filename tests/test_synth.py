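"""Synthetic movie generator: schedules, kinetics, rendering, ground truth."""

import numpy as np
import pandas as pd
import pytest

from thrombofret import synth
from thrombofret.ratiometrics import SensorModel


class TestFlowSchedule:
    def test_all_off_indicator(self):
        sched = synth.make_flow_schedule([], duration=300.0)
        assert not sched.flow_on().any()

    def test_half_open_window_convention(self):
        sched = synth.make_flow_schedule([(60, 120)], duration=300.0, dt=1.0)
        on = sched.flow_on()
        assert on[60] and on[119]
        assert not on[59] and not on[120]
        assert on.sum() == 60

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth.make_flow_schedule([(10, 50), (40, 80)], duration=300.0)

    def test_out_of_range_window_rejected(self):
        with pytest.raises(ValueError):
            synth.make_flow_schedule([(250, 310)], duration=300.0)

    def test_shear_rate_follows_indicator(self):
        sched = synth.make_flow_schedule([(10, 20)], duration=30.0,
                                         shear_rate_on=500.0)
        rates = sched.shear_rate()
        assert rates[15] == 500.0 and rates[5] == 0.0


class TestCgmpKinetics:
    def test_all_off_stays_at_base(self):
        sched = synth.make_flow_schedule([], duration=100.0)
        traces = synth.simulate_region_cgmp(sched, synth.CgmpKinetics())
        assert np.allclose(traces["core"], 0.1)
        assert np.allclose(traces["periphery"], 0.1)

    def test_exponential_rise_one_tau(self):
        # one on-time-constant after flow onset the excursion is 1 - 1/e
        kin = synth.CgmpKinetics()
        sched = synth.make_flow_schedule([(60, 120)], duration=240.0)
        traces = synth.simulate_region_cgmp(sched, kin)
        for region, c_on in (("core", kin.c_on_core),
                             ("periphery", kin.c_on_periphery)):
            step = c_on - kin.c_base
            got = traces[region][60 + int(kin.tau_on)] - kin.c_base
            assert got == pytest.approx((1 - np.exp(-1)) * step, rel=1e-9)

    def test_off_decay_reenters_baseline_band_within_three_tau(self):
        # tau_off = 5 s: back inside +-5% of the step within 15 s <= ~20 s
        kin = synth.CgmpKinetics(tau_off=5.0)
        sched = synth.make_flow_schedule([(60, 120)], duration=240.0)
        traces = synth.simulate_region_cgmp(sched, kin)
        for region, c_on in (("core", kin.c_on_core),
                             ("periphery", kin.c_on_periphery)):
            step = c_on - kin.c_base
            tail = traces[region][traces["t"] >= 120 + 3 * kin.tau_off]
            assert (np.abs(tail - kin.c_base) <= 0.05 * step).all()

    def test_traces_bounded_and_gradient_preserved(self):
        kin = synth.CgmpKinetics()
        sched = synth.make_flow_schedule([(30, 60), (90, 150)], duration=200.0)
        traces = synth.simulate_region_cgmp(sched, kin)
        assert (traces["periphery"] >= traces["core"] - 1e-12).all()
        assert traces["periphery"].between(kin.c_base, kin.c_on_periphery).all()

    def test_coarse_dt_warns(self):
        sched = synth.make_flow_schedule([], duration=50.0, dt=5.0)
        with pytest.warns(UserWarning, match="coarse"):
            synth.simulate_region_cgmp(sched, synth.CgmpKinetics(tau_on=4.0))

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            synth.CgmpKinetics(c_on_core=5.0, c_on_periphery=1.0)


class TestAreaProfile:
    def test_triangular_knots(self):
        prof = synth.make_area_profile(0.0, 100.0, 0.0, 60.0, 40.0, 300.0,
                                       shape="linear")
        a = dict(zip(prof.t, prof.area))
        assert a[60.0] == pytest.approx(100.0)
        assert a[300.0] == pytest.approx(40.0)

    def test_plateau_when_end_equals_max(self):
        prof = synth.make_area_profile(0.0, 100.0, 0.0, 60.0, 100.0, 300.0)
        assert np.allclose(prof.area[prof.t >= 60.0], 100.0)

    def test_logistic_hits_knots_within_one_percent(self):
        prof = synth.make_area_profile(0.0, 100.0, 0.0, 60.0, 40.0, 300.0,
                                       shape="logistic")
        a = dict(zip(prof.t, prof.area))
        assert abs(a[60.0] - 100.0) < 1.0
        assert abs(a[300.0] - 40.0) < 1.0
        assert abs(a[0.0] - 0.0) < 1.0

    def test_inconsistent_ordering_rejected(self):
        with pytest.raises(ValueError):
            synth.make_area_profile(0.0, 100.0, 60.0, 30.0, 40.0, 300.0)
        with pytest.raises(ValueError):
            synth.make_area_profile(0.0, 100.0, 0.0, 60.0, 120.0, 300.0)


class TestRendering:
    def test_noise_free_pixel_ratio_equals_calibration(self):
        kin = synth.CgmpKinetics()
        sched = synth.make_flow_schedule([(20, 60)], duration=80.0)
        cgmp = synth.simulate_region_cgmp(sched, kin)
        area = synth.constant_area_profile(2000.0, 80.0)
        geo = synth.Geometry(shape=(96, 96))
        stack, gt = synth.render_movie(area, cgmp, geometry=geo, noise=None)
        sensor = SensorModel()
        for frame in (10, 50):
            for region in ("core", "periphery"):
                mask = gt.masks.region(region)[frame]
                ratio = stack.channel("EM480")[frame][mask] / \
                    stack.channel("EM535")[frame][mask]
                expected = sensor.forward(cgmp[region][frame])
                assert np.allclose(ratio, expected, rtol=1e-12)

    def test_channels_anticorrelated_on_cgmp_step(self):
        kin = synth.CgmpKinetics()
        sched = synth.make_flow_schedule([(20, 60)], duration=80.0)
        cgmp = synth.simulate_region_cgmp(sched, kin)
        area = synth.constant_area_profile(2000.0, 80.0)
        stack, gt = synth.render_movie(
            area, cgmp, geometry=synth.Geometry(shape=(96, 96)), noise=None
        )
        core = gt.masks.core[0]
        cfp = stack.channel("EM480")
        yfp = stack.channel("EM535")
        d_cfp = cfp[40][core].mean() - cfp[10][core].mean()
        d_yfp = yfp[40][core].mean() - yfp[10][core].mean()
        assert d_cfp > 0 > d_yfp

    def test_seed_determinism(self):
        a1 = synth.default_flow_movie(seed=7, duration=30.0, on_windows=((5.0, 15.0),))[0]
        a2 = synth.default_flow_movie(seed=7, duration=30.0, on_windows=((5.0, 15.0),))[0]
        b = synth.default_flow_movie(seed=8, duration=30.0, on_windows=((5.0, 15.0),))[0]
        assert np.array_equal(a1.data, a2.data)
        assert not np.array_equal(a1.data, b.data)

    def test_background_mean_matches_noise_law(self):
        stack, gt, _ = synth.default_flow_movie(seed=5, duration=20.0, on_windows=())
        noise = synth.NoiseModel(seed=5)
        outside = ~gt.masks.whole[0]
        pixels = stack.channel("EM535")[0][outside].astype(float)
        assert pixels.size >= 10_000
        se = np.sqrt((noise.background_level + noise.read_noise_sd**2) / pixels.size)
        assert abs(pixels.mean() - noise.background_level) < 3 * se

    def test_mask_area_conservation(self):
        _, gt, _ = synth.default_flow_movie(seed=0, duration=10.0, on_windows=())
        area_px = gt.params["pixel_area_um2"]
        for frame in range(gt.masks.n_frames):
            count = gt.masks.whole[frame].sum()
            target = 5000.0 / area_px
            r_px = np.sqrt(target / np.pi)
            # rasterization error bounded by one pixel row around the rim
            assert abs(count - target) <= 2 * np.pi * r_px

    def test_ground_truth_partition_identity(self):
        _, gt, _ = synth.default_flow_movie(seed=0, duration=10.0, on_windows=())
        assert gt.masks.partition_ok()

    def test_oversized_thrombus_rejected(self):
        area = synth.constant_area_profile(50_000.0, 10.0)
        cgmp = pd.DataFrame(
            {"t": area.t, "core": np.full(10, 0.1), "periphery": np.full(10, 0.1)}
        )
        with pytest.raises(ValueError, match="fit"):
            synth.render_movie(area, cgmp, geometry=synth.Geometry(shape=(96, 96)))


class TestCaCoupling:
    def test_anticorrelated_lagged_drive(self):
        kin = synth.CgmpKinetics()
        sched = synth.make_flow_schedule([(60, 120)], duration=240.0)
        cgmp = synth.simulate_region_cgmp(sched, kin)
        ca = synth.simulate_region_ca(cgmp, synth.CaModel(lag=2.0), kin)
        # rest level is ca_high; flow-on drives Ca down, two frames later
        assert ca["periphery"][0] == pytest.approx(1.0)
        drive = (cgmp["periphery"].to_numpy() - kin.c_base) / (
            kin.c_on_periphery - kin.c_base)
        expected = 1.0 - 0.9 * drive
        assert np.allclose(ca["periphery"].to_numpy()[2:], expected[:-2])

    def test_positive_coupling_moves_with_cgmp(self):
        kin = synth.CgmpKinetics()
        sched = synth.make_flow_schedule([(10, 40)], duration=60.0)
        cgmp = synth.simulate_region_cgmp(sched, kin)
        ca = synth.simulate_region_ca(cgmp, synth.CaModel(lag=0.0, coupling=+1), kin)
        corr = np.corrcoef(cgmp["periphery"], ca["periphery"])[0, 1]
        assert corr > 0.99
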