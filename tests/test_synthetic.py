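import numpy as np
import pytest

from footvel import (
    AXES,
    GaitTemplate,
    SimConfig,
    apply_condition_effect,
    cut_segments,
    detect_strides,
    ensemble_mean,
    impulse_mean,
    impulse_taper_window,
    simulate_cohort,
    simulate_trial,
    stride_velocity,
)
from footvel.synthetic import REFERENCE_STRIDE_FREQUENCY, AxisTemplate


def velocity_deg_s(mod, u):
    return mod.velocity(u) * REFERENCE_STRIDE_FREQUENCY


class TestDefaultTemplate:
    def test_velocity_extrema_locations(self, template):
        """Signed velocity minimum in 10-30% and maximum in 30-40% per axis."""
        u = np.arange(2000) / 2000
        for ax in AXES:
            v = velocity_deg_s(template.axes[ax], u)
            assert 0.10 <= u[np.argmin(v)] <= 0.30, ax
            assert 0.30 <= u[np.argmax(v)] <= 0.40, ax

    def test_sagittal_upward_zero_crossing_near_60pct(self, template):
        """Plantar-to-dorsiflexion transition (neg->pos velocity) near 60%."""
        u = np.arange(2000) / 2000
        v = velocity_deg_s(template.axes["dpf"], u)
        sign = np.sign(v)
        ups = u[1:][(sign[1:] > 0) & (sign[:-1] <= 0)]
        assert np.any((ups >= 0.55) & (ups <= 0.67))

    def test_sagittal_amplitude_dominates(self, template):
        amps = {ax: template.axes[ax].amplitude() for ax in AXES}
        assert amps["dpf"] > amps["inev"]
        assert amps["dpf"] > amps["abdadd"]

    def test_angle_maximum_at_cycle_start(self, template):
        u = np.arange(4096) / 4096
        theta = template.axes["dpf"].angle(u)
        assert u[np.argmax(theta)] < 0.002 or u[np.argmax(theta)] > 0.998

    def test_flat_template_rejected(self):
        zero = AxisTemplate(a0=0.0, c0=0.0, a=np.zeros(4), b=np.zeros(4))
        with pytest.raises(ValueError):
            GaitTemplate(axes={ax: zero for ax in AXES})


class TestSimulateTrial:
    def test_seed_determinism(self, template):
        cfg = SimConfig(n_subjects=1, rng_seed=42)
        t1, g1 = simulate_trial(template, cfg, "S1", "left", "FO")
        t2, g2 = simulate_trial(template, cfg, "S1", "left", "FO")
        np.testing.assert_array_equal(t1.dpf, t2.dpf)
        assert g1.stride_bounds == g2.stride_bounds

    def test_stride_count_matches_cadence(self, template, quiet_cfg):
        cfg = quiet_cfg()
        trial, gt = simulate_trial(template, cfg, "S1", "left", "noFO")
        expected = int(cfg.stride_frequency * cfg.duration)
        assert abs(gt.stride_count - expected) <= 1
        assert len(trial) == int(cfg.duration * cfg.sampling_rate)

    def test_noiseless_commensurate_strides_identical(self, template, quiet_cfg):
        # at 1.25 Hz a stride is exactly 24 samples, so every stride sees
        # the same sampling phase and the ensemble SD collapses to zero
        cfg = quiet_cfg(stride_frequency=1.25)
        trial, _ = simulate_trial(template, cfg, "S1", "left", "noFO")
        segments = cut_segments(detect_strides(trial))
        curves = [stride_velocity(s["dpf"], 30.0) for s in segments]
        ens = ensemble_mean(curves)
        assert ens.sd.max() < 1e-8
        np.testing.assert_allclose(ens.mean.values, curves[0].values, atol=1e-8)

    def test_too_short_duration_raises(self, template, quiet_cfg):
        with pytest.raises(ValueError):
            quiet_cfg(duration=2.0)

    def test_subject_factor_shared_across_cells(self, template):
        cfg = SimConfig(n_subjects=1, rng_seed=5)
        _, g1 = simulate_trial(template, cfg, "S9", "left", "noFO")
        _, g2 = simulate_trial(template, cfg, "S9", "right", "FO")
        assert g1.subject_factors == g2.subject_factors


class TestConditionEffect:
    def test_effect_confined_to_tapered_window(self, template):
        u = np.arange(1000) / 1000
        mods = apply_condition_effect(template, {"abdadd": 0.8})
        base_v = template.axes["abdadd"].velocity(u)
        mod_v = mods["abdadd"].velocity(u)
        outside = (u < 0.295) | (u > 0.605)
        np.testing.assert_allclose(mod_v[outside], base_v[outside],
                                   atol=1e-3 * np.abs(base_v).max())
        w = impulse_taper_window(u)
        np.testing.assert_allclose(
            mod_v, base_v * (1.0 - 0.2 * w), atol=1e-3 * np.abs(base_v).max()
        )
        # untouched axes share the base model object
        assert mods["dpf"] is template.axes["dpf"]

    def test_recovered_impulse_ratio_matches_programmed_effect(
        self, template, quiet_cfg
    ):
        c = 0.9
        cfg = quiet_cfg(condition_effect={"dpf": 1.0, "inev": 1.0, "abdadd": c})
        means = {}
        for cond in ("noFO", "FO"):
            trial, _ = simulate_trial(template, cfg, "S1", "left", cond)
            segs = cut_segments(detect_strides(trial))
            curves = [stride_velocity(s["abdadd"], 30.0, axis="abdadd")
                      for s in segs]
            means[cond] = impulse_mean(ensemble_mean(curves).mean)
        # analytic expectation from the generator's own definition: the
        # scaling acts through the tapered window, not the full window
        u = np.linspace(0.30, 0.60, 3001)
        v = template.axes["abdadd"].velocity(u)
        w = impulse_taper_window(u)
        expected_ratio = 1.0 + (c - 1.0) * float((w * v).sum() / v.sum())
        assert means["FO"] / means["noFO"] == pytest.approx(
            expected_ratio, abs=0.02
        )


class TestCohort:
    def test_paired_structure_and_manifest(self, template, quiet_cfg):
        cfg = quiet_cfg(n_subjects=2)
        res = simulate_cohort(cfg, template=template)
        assert len(res.manifest) == 8
        assert set(res.trials) == {
            (s, f, c)
            for s in ("S001", "S002")
            for f in ("left", "right")
            for c in ("noFO", "FO")
        }

    def test_zero_asymmetry_target_gives_symmetric_cohort(
        self, template, quiet_cfg
    ):
        cfg = quiet_cfg(asymmetry_target=0.0)
        res = simulate_cohort(cfg, template=template)
        left = res.trials[("S001", "left", "noFO")]
        right = res.trials[("S001", "right", "noFO")]
        np.testing.assert_allclose(left.abdadd, right.abdadd, atol=1e-9)

    def test_asymmetry_target_realised_in_noiseless_limit(
        self, template, quiet_cfg
    ):
        from footvel import asymmetry_index

        cfg = quiet_cfg(asymmetry_target={"dpf": 0.0, "inev": 0.0, "abdadd": 25.0})
        res = simulate_cohort(cfg, template=template)
        vals = {}
        for foot in ("left", "right"):
            trial = res.trials[("S001", foot, "noFO")]
            segs = cut_segments(detect_strides(trial))
            curves = [stride_velocity(s["abdadd"], 30.0, axis="abdadd")
                      for s in segs]
            vals[foot] = impulse_mean(ensemble_mean(curves).mean)
        assert asymmetry_index(vals["left"], vals["right"]) == pytest.approx(
            25.0, abs=1.0
        )

    def test_cohort_written_to_disk_round_trips(self, template, quiet_cfg,
                                                tmp_path):
        from footvel import read_manifest, read_trial

        cfg = quiet_cfg(n_subjects=1)
        res = simulate_cohort(cfg, template=template, out_dir=tmp_path)
        man = read_manifest(tmp_path / "manifest.csv")
        assert len(man) == 4
        trial = read_trial(tmp_path / man.entries[0].path)
        key = (man.entries[0].subject_id, man.entries[0].foot,
               man.entries[0].condition)
        np.testing.assert_array_equal(trial.dpf, res.trials[key].dpf)
        assert (tmp_path / "ground_truth.json").exists()
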