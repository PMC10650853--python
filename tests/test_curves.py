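import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footvel import (
    CycleCurve,
    N_NODES,
    cut_segments,
    detect_strides,
    ensemble_mean,
    normalize_segment,
    simulate_trial,
    stride_velocity,
)


class TestNormalizeSegment:
    def test_identity_on_101_uniform_samples(self):
        vals = np.sin(np.linspace(0, 3, N_NODES))
        out = normalize_segment(vals, duration=1.0)
        np.testing.assert_array_equal(out.values, vals)

    @pytest.mark.parametrize("n", [5, 23, 77])
    def test_linear_ramp_exact(self, n):
        vals = np.linspace(0.0, 10.0, n)
        out = normalize_segment(vals, duration=0.8)
        np.testing.assert_allclose(out.values, np.linspace(0, 10, N_NODES),
                                   atol=1e-12)

    def test_sine_interpolation_error_bound(self):
        # linear interpolation error <= h^2 max|f''| / 8 with h the sample
        # spacing in phase units
        n = 23
        x = np.linspace(0.0, 1.0, n)
        vals = np.sin(2 * np.pi * x)
        out = normalize_segment(vals, duration=1.0)
        analytic = np.sin(2 * np.pi * np.linspace(0, 1, N_NODES))
        h = 1.0 / (n - 1)
        bound = (2 * np.pi) ** 2 * h ** 2 / 8.0
        assert np.max(np.abs(out.values - analytic)) <= bound

    def test_endpoints_preserved_exactly(self):
        vals = np.random.default_rng(0).normal(size=17)
        out = normalize_segment(vals, duration=0.53)
        assert out.values[0] == vals[0]
        assert out.values[-1] == vals[-1]

    def test_too_short_segment(self):
        with pytest.raises(ValueError):
            normalize_segment([1.0], duration=0.1)


class TestStrideVelocity:
    def test_constant_angle_zero_velocity(self):
        out = stride_velocity(np.full(24, 7.5), 30.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_sine_matches_analytic_derivative(self):
        # central difference of A sin(2 pi t / T): relative amplitude error
        # (2 pi/(fs T))^2/6, plus the linear-interpolation bound on the grid
        fs, T, A = 30.0, 0.77, 20.0
        n = 24
        t = np.arange(n) / fs
        out = stride_velocity(A * np.sin(2 * np.pi * t / T), fs)
        dur = (n - 1) / fs
        tt = np.linspace(0.0, dur, N_NODES)
        analytic = (2 * np.pi * A / T) * np.cos(2 * np.pi * tt / T)
        w = 2 * np.pi / T
        fd = (w / fs) ** 2 / 6.0 * (2 * np.pi * A / T)
        interp = (w / fs) ** 2 / 8.0 * (2 * np.pi * A / T)
        interior = slice(5, N_NODES - 5)
        assert np.max(np.abs(out.values[interior] - analytic[interior])) \
            <= fd + interp

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            stride_velocity([1.0, 2.0, 3.0], 30.0)

    def test_integral_consistency_on_synthetic_strides(self, template,
                                                       quiet_cfg):
        """Trapezoidal integral of velocity equals the net angle change."""
        trial, _ = simulate_trial(template, quiet_cfg(), "S1", "left", "noFO")
        segments = cut_segments(detect_strides(trial))
        for seg in segments:
            vals = seg["dpf"]
            curve = stride_velocity(vals, trial.sampling_rate)
            integral = np.trapezoid(
                curve.values, dx=curve.duration / (N_NODES - 1)
            )
            net = vals[-1] - vals[0]
            assert abs(integral - net) <= 0.02 * np.ptp(vals)

    def test_noiseless_stride_matches_template_derivative(self, template,
                                                          quiet_cfg):
        """Measured velocity tracks the analytic template derivative within
        the 30 Hz finite-difference budget."""
        cfg = quiet_cfg(stride_frequency=1.25)
        trial, gt = simulate_trial(template, cfg, "S1", "left", "noFO")
        seg = cut_segments(detect_strides(trial))[0]["dpf"]
        L = len(seg)
        fs = trial.sampling_rate
        curve = stride_velocity(seg, fs)
        T = gt.stride_durations[0]
        # the cut segment spans samples 0..L-1, i.e. phase [0, (L-1)/L]
        u = np.linspace(0, (L - 1) / L, N_NODES)
        analytic = template.axes["dpf"].velocity(u) / T
        # derived error budget: central/one-sided differences are second
        # order, linear interpolation adds h^2 |v''| / 8
        fine = np.arange(8192) / 8192
        v_fine = template.axes["dpf"].velocity(fine) / T
        v2 = np.gradient(np.gradient(v_fine, fine / T), fine / T)
        dt = 1.0 / fs
        bound = dt ** 2 * np.abs(v2).max() * (1.0 / 3.0 + 1.0 / 8.0)
        assert np.max(np.abs(curve.values - analytic)) <= bound


class TestEnsembleMean:
    def test_identical_curves_zero_sd(self):
        c = CycleCurve(np.linspace(-3, 5, N_NODES), "angle", "dpf")
        ens = ensemble_mean([c, c, c])
        np.testing.assert_allclose(ens.mean.values, c.values, atol=1e-12)
        assert np.all(ens.sd < 1e-12)
        assert ens.n == 3

    def test_mean_of_zero_and_ramp_is_half_ramp(self):
        zero = CycleCurve(np.zeros(N_NODES), "angle", "dpf")
        ramp = CycleCurve(np.linspace(0, 10, N_NODES), "angle", "dpf")
        ens = ensemble_mean([zero, ramp])
        np.testing.assert_allclose(ens.mean.values,
                                   np.linspace(0, 5, N_NODES))

    def test_single_curve_sd_zero(self):
        c = CycleCurve(np.arange(N_NODES, dtype=float), "angle", "inev")
        ens = ensemble_mean([c])
        assert ens.n == 1
        np.testing.assert_array_equal(ens.sd, 0.0)

    def test_mixed_kinds_rejected(self):
        a = CycleCurve(np.zeros(N_NODES), "angle", "dpf")
        v = CycleCurve(np.zeros(N_NODES), "velocity", "dpf", duration=0.8)
        with pytest.raises(ValueError):
            ensemble_mean([a, v])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=-20, max_value=20, allow_nan=False),
           seed=st.integers(min_value=0, max_value=1000))
    def test_linearity(self, scale, seed):
        rng = np.random.default_rng(seed)
        curves = [CycleCurve(rng.normal(size=N_NODES), "angle", "dpf")
                  for _ in range(4)]
        scaled = [CycleCurve(scale * c.values, "angle", "dpf") for c in curves]
        np.testing.assert_allclose(
            ensemble_mean(scaled).mean.values,
            scale * ensemble_mean(curves).mean.values,
            atol=1e-9,
        )


def test_derivative_average_commute_on_equal_duration_strides(template,
                                                              quiet_cfg):
    """On noiseless equal-duration strides, derivative-then-average equals
    average-then-derivative."""
    cfg = quiet_cfg(stride_frequency=1.25)
    trial, _ = simulate_trial(template, cfg, "S1", "left", "noFO")
    segments = cut_segments(detect_strides(trial))
    fs = trial.sampling_rate
    vel_then_avg = ensemble_mean(
        [stride_velocity(s["dpf"], fs) for s in segments]
    ).mean.values
    mean_angle = np.mean([s["dpf"] for s in segments], axis=0)
    avg_then_vel = stride_velocity(mean_angle, fs).values
    np.testing.assert_allclose(vel_then_avg, avg_then_vel, atol=1e-9)


def test_group_curve_of_single_stride_cohort(template, quiet_cfg):
    from footvel import subject_mean_curves

    trial, _ = simulate_trial(template, quiet_cfg(), "S1", "left", "noFO")
    seg = cut_segments(detect_strides(trial))[0]
    curve = stride_velocity(seg["dpf"], trial.sampling_rate)
    subj, group, missing = subject_mean_curves(
        {("S1", "left", "noFO", "dpf"): [curve]}
    )
    assert not missing
    np.testing.assert_array_equal(
        group[("left", "noFO", "dpf")].mean.values, curve.values
    )
    assert group[("left", "noFO", "dpf")].n == 1


def test_symmetric_cohort_gives_identical_group_curves(template, quiet_cfg):
    from footvel import simulate_cohort, subject_mean_curves

    cfg = quiet_cfg(n_subjects=2, asymmetry_target=0.0)
    res = simulate_cohort(cfg, template=template)
    stride_curves = {}
    for (s, foot, cond), trial in res.trials.items():
        if cond != "noFO":
            continue
        segs = cut_segments(detect_strides(trial))
        stride_curves[(s, foot, cond, "dpf")] = [
            stride_velocity(seg["dpf"], 30.0) for seg in segs
        ]
    _, group, _ = subject_mean_curves(stride_curves)
    np.testing.assert_allclose(
        group[("left", "noFO", "dpf")].mean.values,
        group[("right", "noFO", "dpf")].mean.values,
        atol=1e-9,
    )
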