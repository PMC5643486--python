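"""Synthetic dye-transit simulator: curve model, rendering, ground truth."""

import dataclasses

import numpy as np
import pytest

from fadyn.errors import ConfigError, ParameterError
from fadyn.synthetic import (
    CurveParams,
    SceneConfig,
    analytic_curve_features,
    make_disruption_scenario,
    render_video,
    simulate_pixel_curve,
)


class TestPixelCurve:
    def test_baseline_before_arrival(self):
        p = CurveParams(t0=4.0, alpha=3.0, beta=1.5, amplitude=100.0)
        t = np.linspace(0.0, 3.99, 200)
        assert np.all(simulate_pixel_curve(p, t) == 0.0)

    def test_leakage_plateau_level(self):
        # once the first pass has washed out, the curve sits at leak_frac x peak
        p = CurveParams(t0=4.0, alpha=3.0, beta=1.5, amplitude=100.0, leak_frac=0.2,
                        tau_leak=1.0)
        t = np.array([p.t0 + 50.0 * p.tau_leak])
        val = simulate_pixel_curve(p, t)[0]
        assert val == pytest.approx(0.2 * 100.0, rel=0.01)

    def test_peak_time_matches_closed_form_and_fine_grid(self):
        # pure gamma-variate peaks at t0 + alpha*beta; check against a 1 ms grid
        p = CurveParams(t0=4.0, alpha=3.0, beta=1.5, amplitude=100.0)
        t = np.arange(0.0, 30.0, 1e-3)
        c = simulate_pixel_curve(p, t)
        assert t[np.argmax(c)] == pytest.approx(4.0 + 3.0 * 1.5, abs=2e-3)

    def test_decays_to_baseline_without_leak(self):
        p = CurveParams(t0=2.0, alpha=3.0, beta=1.0, amplitude=50.0, baseline=5.0)
        t = np.arange(0.0, 60.0, 0.01)
        c = simulate_pixel_curve(p, t)
        after_peak = c[t > 5.0]
        assert np.all(np.diff(after_peak) <= 1e-9)
        assert c[-1] == pytest.approx(5.0, abs=0.01)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(alpha=0.0),
            dict(beta=-1.0),
            dict(tau_leak=0.0),
            dict(amplitude=0.0),
            dict(leak_frac=1.0),
            dict(leak_frac=-0.1),
            dict(baseline=-1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(t0=4.0, alpha=3.0, beta=1.5, amplitude=100.0)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            CurveParams(**kwargs)

    def test_times_must_increase(self):
        p = CurveParams(t0=4.0, alpha=3.0, beta=1.5, amplitude=100.0)
        with pytest.raises(ParameterError):
            simulate_pixel_curve(p, [0.0, 1.0, 0.5])


class TestSceneConfig:
    def test_duration_must_exceed_bolus_onset(self):
        with pytest.raises(ConfigError):
            SceneConfig(duration_s=4.0, bolus_onset_s=5.0)

    def test_class_arrival_ordering_enforced(self):
        cfg = SceneConfig()
        bad = dict(cfg.classes)
        bad["artery"] = dataclasses.replace(bad["artery"], t0_mean=9.0)
        with pytest.raises(ConfigError):
            SceneConfig(classes=bad)

    def test_disruption_identity_and_shift(self):
        base = SceneConfig()
        same = make_disruption_scenario(base, 0.0)
        assert same == base
        shifted = make_disruption_scenario(base, 0.3)
        for name, m in base.classes.items():
            assert shifted.classes[name].leak_frac_mean == pytest.approx(
                m.leak_frac_mean + 0.3
            )
            assert shifted.classes[name].t0_mean == m.t0_mean

    def test_disruption_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            make_disruption_scenario(SceneConfig(), 0.95)


class TestRenderVideo:
    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(shape=(24, 24), duration_s=12.0, seed=5)
        a, ta = render_video(cfg)
        b, tb = render_video(cfg)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(ta.labels, tb.labels)
        assert np.array_equal(ta.shifts, tb.shifts)

    def test_ground_truth_dimensions_match_video(self, tiny_scene):
        cfg, stack, truth = tiny_scene
        assert truth.labels.shape == stack.image_shape
        assert truth.shifts.shape == (stack.n_frames, 2)
        for arr in truth.params.values():
            assert arr.shape == stack.image_shape

    def test_analytic_dynamics_finite_on_foreground(self, tiny_scene):
        _, _, truth = tiny_scene
        fg = truth.labels != 0
        assert np.all(np.isfinite(truth.half_rise[fg]))
        assert np.all(np.isfinite(truth.offset[fg]))

    def test_prebolus_frames_are_baseline_only(self):
        cfg = SceneConfig(shape=(24, 24), duration_s=12.0, seed=5,
                          noise_sigma=0.0, noise_gain=0.0)
        stack, _ = render_video(cfg)
        base = stack.baseline_frames()
        # noiseless pre-bolus frames are constant in time at the baseline image
        assert np.all(base == base[0])

    def test_rendered_pixel_matches_curve_model(self, noiseless_retina):
        cfg, stack, truth, _ = noiseless_retina
        rr, cc = np.nonzero(truth.labels == 1)
        t = stack.analysis_times()
        for r, c in list(zip(rr, cc))[::200][:5]:
            p = CurveParams(**{k: float(truth.params[k][r, c]) for k in truth.params})
            expected = simulate_pixel_curve(p, t)
            recorded = stack.frames[:, r, c].astype(float) / cfg.gain
            # rendering differs only by digitizer rounding (float32 curve eval)
            assert np.abs(recorded - expected).max() < 1.0 / cfg.gain + 1e-3

    def test_motion_respects_amplitude_bound_and_starts_aligned(self):
        cfg = SceneConfig(shape=(24, 24), duration_s=12.0, seed=5,
                          motion_amplitude_px=3.0)
        _, truth = render_video(cfg)
        assert np.abs(truth.shifts).max() <= 3.0 + 1e-12
        assert truth.shifts[0] == pytest.approx((0.0, 0.0))

    def test_retina_class_median_half_rise_ordering(self):
        # the fill-timing ordering must hold in every rendered retina scene
        for seed in (0, 1, 2, 3):
            cfg = SceneConfig(shape=(48, 48), duration_s=30.0, seed=seed)
            _, truth = render_video(cfg)
            art = truth.class_median("artery", "half_rise")
            cap = truth.class_median("capillary_extravascular", "half_rise")
            vein = truth.class_median("vein", "half_rise")
            assert art < cap < vein

    def test_cortex_faster_than_retina(self):
        r = render_video(SceneConfig(shape=(48, 48), duration_s=30.0, seed=1))[1]
        c = render_video(
            SceneConfig(layout="cortex", shape=(48, 48), duration_s=30.0, seed=1)
        )[1]
        for cls in ("artery", "vein"):
            assert c.class_median(cls, "half_rise") < r.class_median(cls, "half_rise")
        # cortical residual fluorescence is far higher
        assert c.class_median("capillary_extravascular", "offset") > r.class_median(
            "capillary_extravascular", "offset"
        )


class TestAnalyticFeatures:
    def test_offset_strictly_increases_with_leak_frac(self):
        leaks = np.array([0.0, 0.05, 0.1, 0.2, 0.4, 0.6])
        n = leaks.size
        params = {
            "t0": np.full(n, 5.0),
            "alpha": np.full(n, 3.0),
            "beta": np.full(n, 1.2),
            "amplitude": np.full(n, 100.0),
            "leak_frac": leaks,
            "tau_leak": np.full(n, 10.0),
            "baseline": np.full(n, 10.0),
        }
        _, _, off = analytic_curve_features(params, t_end=55.0)
        assert np.all(np.diff(off) > 0)

    def test_offset_matches_closed_form_plateau(self):
        # peak = amplitude*(1 + leak*(1 - exp(-alpha*beta/tau))) since the
        # leakage term already contributes at the first-pass peak; the plateau
        # is leak*amplitude*saturation, so the normalized offset is their ratio
        t0, alpha, beta, tau, leak = 5.0, 3.0, 1.2, 10.0, 0.4
        params = {
            "t0": np.array([t0]),
            "alpha": np.array([alpha]),
            "beta": np.array([beta]),
            "amplitude": np.array([100.0]),
            "leak_frac": np.array([leak]),
            "tau_leak": np.array([tau]),
            "baseline": np.array([0.0]),
        }
        _, _, off = analytic_curve_features(params, t_end=55.0)
        window = np.linspace(50.0, 55.0, 501)
        saturation = np.mean(1.0 - np.exp(-(window - t0) / tau))
        peak_rel = 1.0 + leak * (1.0 - np.exp(-alpha * beta / tau))
        expected = 100.0 * leak * saturation / peak_rel
        assert off[0] == pytest.approx(expected, abs=0.5)
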