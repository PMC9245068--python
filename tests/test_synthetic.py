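"""Generator contracts: templates, determinism, ground-truth consistency."""

import numpy as np
import pytest

import gaitrel.synthetic as syn
from gaitrel.pipeline import process_cohort
from gaitrel.synthetic import (
    STP_PRIMITIVES,
    SyntheticCohortConfig,
    draw_error_curve,
    eval_error_curve,
    generate_cohort,
    joint_angle_template,
    warp_phase,
)

from conftest import ZERO_STP


class TestTemplate:
    def test_zero_coefficients_give_zero_everywhere(self):
        phases = np.linspace(0, 1, 17)
        vals = joint_angle_template("hip", "sagittal", phases, (0.0, []))
        assert np.all(vals == 0.0)

    def test_single_harmonic_is_analytic_sinusoid(self):
        # amplitude 30 deg, phase offset 0: value at 25% cycle is 30*sin(pi/2)
        v = joint_angle_template("knee", "sagittal", 0.25, (0.0, [(30.0, 0.0)]))
        assert v == pytest.approx(30.0 * np.sin(2 * np.pi * 0.25), abs=1e-12)

    def test_periodicity_for_random_coefficients(self):
        rng = np.random.default_rng(1)
        coeffs = (rng.normal(), [(rng.normal(), rng.normal()) for _ in range(5)])
        for joint, plane in (("hip", "sagittal"), ("ankle", "transverse")):
            v0 = joint_angle_template(joint, plane, 0.0, coeffs)
            v1 = joint_angle_template(joint, plane, 1.0, coeffs)
            assert v0 == pytest.approx(v1, abs=1e-9)

    def test_unknown_joint_plane_raises_naming_label(self):
        with pytest.raises(ValueError, match="elbow"):
            joint_angle_template("elbow", "sagittal", 0.5)

    def test_default_templates_match_reported_magnitudes(self):
        """RoM of the default curves sits in the normal-gait range."""
        grid = np.linspace(0, 1, 101)
        rom = {
            key: np.ptp(joint_angle_template(key[0], key[1], grid))
            for key in syn.DEFAULT_TEMPLATES
        }
        assert 40 < rom[("hip", "sagittal")] < 55
        assert 55 < rom[("knee", "sagittal")] < 70
        assert 30 < rom[("ankle", "sagittal")] < 45
        assert rom[("hip", "frontal")] < 12


class TestWarpPhase:
    def test_identity_at_template_stance_fraction(self):
        p = np.linspace(0, 1, 21)
        assert np.allclose(warp_phase(p, syn.TEMPLATE_STANCE_FRACTION), p)

    def test_maps_stance_boundary_and_stays_monotone(self):
        assert warp_phase(0.72, 0.72) == pytest.approx(syn.TEMPLATE_STANCE_FRACTION)
        p = np.linspace(0, 1, 101)
        w = warp_phase(p, 0.55)
        assert np.all(np.diff(w) > 0)
        assert w[0] == 0.0 and w[-1] == pytest.approx(1.0)


class TestErrorCurves:
    def test_pointwise_sd_is_stationary_and_equals_sigma(self):
        rng = np.random.default_rng(0)
        sd = 2.0
        phases = np.array([0.0, 0.17, 0.42, 0.73, 0.96])
        draws = np.array([
            eval_error_curve(draw_error_curve(rng, sd), phases) for _ in range(20000)
        ])
        assert np.allclose(draws.std(axis=0), sd, rtol=0.03)
        assert np.allclose(draws.mean(axis=0), 0.0, atol=0.05)

    def test_zero_sigma_is_exactly_zero(self):
        rng = np.random.default_rng(3)
        coeffs = draw_error_curve(rng, 0.0)
        assert np.all(coeffs == 0.0)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(n_subjects=1)
        with pytest.raises(ValueError):
            SyntheticCohortConfig(sampling_rate=0)
        with pytest.raises(ValueError):
            SyntheticCohortConfig(var_between_session={"angles": -1.0})
        with pytest.raises(ValueError):
            SyntheticCohortConfig(task="JOG")

    def test_rejection_sampling_bounded(self):
        # absurd stride-level noise makes plausible draws vanishingly rare;
        # the bounded retry loop must fail loudly, not distort silently
        cfg = SyntheticCohortConfig(
            n_subjects=2, passes_per_session=1, strides_per_pass=1, seed=0,
            var_between_stride={"gait_speed": 1e6, "stride_length": 1e6,
                                "stance_time": 1e6, "dls1_time": 1e6,
                                "dls2_time": 1e6, "step_width": 1e6,
                                "angles": 0.0},
        )
        with pytest.raises(RuntimeError, match="retries"):
            generate_cohort(cfg)


class TestGenerateCohort:
    def test_determinism_bit_identical(self, tiny_config):
        t1, g1 = generate_cohort(tiny_config)
        t2, g2 = generate_cohort(tiny_config)
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            assert a.trial_id == b.trial_id
            for key in a.angles:
                assert np.array_equal(a.angles[key], b.angles[key])
            for key in a.landmarks:
                assert np.array_equal(a.landmarks[key], b.landmarks[key])
        assert g1.session_values.equals(g2.session_values)

    def test_adding_subjects_preserves_existing_ones(self, tiny_config):
        from dataclasses import replace

        t_small, _ = generate_cohort(tiny_config)
        t_big, _ = generate_cohort(replace(tiny_config, n_subjects=5))
        small_ids = {t.trial_id for t in t_small}
        big_by_id = {t.trial_id: t for t in t_big}
        assert small_ids <= set(big_by_id)
        for t in t_small:
            other = big_by_id[t.trial_id]
            for key in t.angles:
                assert np.array_equal(t.angles[key], other.angles[key])

    def test_structure_and_metadata(self, tiny_config):
        trials, gt = generate_cohort(tiny_config)
        assert len(trials) == 3 * 2 * 2  # subjects x sessions x passes
        for t in trials:
            assert t.sampling_rate == 60.0
            assert t.task == "SSWS"
            assert t.leg_length == 0.84
            assert set(gt.events[t.trial_id]) == {"L", "R"}

    def test_zero_session_and_stride_variance_repeats_sessions(self, noise_free_config):
        """With no injected error both sessions yield identical feature values."""
        trials, _ = generate_cohort(noise_free_config)
        cohort, _ = process_cohort(trials, None)
        by = {(d.subject_id, d.session): d for d in cohort}
        for subject in {d.subject_id for d in cohort}:
            f1 = by[(subject, 1)].features
            f2 = by[(subject, 2)].features
            assert np.array_equal(f1.to_numpy(), f2.to_numpy())


class TestScaleSanity:
    def test_stp_sample_means_recover_configured_means(self):
        """Downstream per-stride estimates converge to the configured scales.

        With gait speed 1.35 m/s and stride length 1.43 m the implied mean
        stride time is 1.43/1.35 ~ 1.06 s; at >= 500 strides every primitive's
        sample mean lies within 3 standard errors (plus the sub-sample
        discretization floor of the 60 Hz grid) of its configured mean.
        """
        cfg = SyntheticCohortConfig(
            n_subjects=11, passes_per_session=6, strides_per_pass=4, seed=13
        )
        trials, _ = generate_cohort(cfg)
        cohort, _ = process_cohort(trials, None)
        import pandas as pd

        all_features = pd.concat([d.features for d in cohort], ignore_index=True)
        assert len(all_features) >= 500
        # strides are clustered within subjects, so the standard error of the
        # cohort mean comes from subject-level means, not raw stride counts
        subj_means = pd.concat(
            [d.features.assign(subject=d.subject_id) for d in cohort],
            ignore_index=True,
        ).groupby("subject").mean()
        n_subj = len(subj_means)
        grid_floor = {"stance_time": 1 / 60, "dls1_time": 1 / 60, "dls2_time": 1 / 60}
        for var, mean in cfg.stp_means.items():
            values = subj_means[var]
            se = values.std() / np.sqrt(n_subj)
            tol = 3 * se + grid_floor.get(var, 0.0)
            assert abs(values.mean() - mean) < tol, (var, values.mean(), mean, tol)
        implied_stride_time = cfg.stp_means["stride_length"] / cfg.stp_means["gait_speed"]
        st = subj_means["stride_time"]
        assert abs(st.mean() - implied_stride_time) < 3 * st.std() / np.sqrt(n_subj)


class TestGroundTruthConsistency:
    def test_session_values_cover_all_variables(self, tiny_config):
        from gaitrel.features import REGISTRY
        from gaitrel.spatiotemporal import STP_VARIABLES

        _, gt = generate_cohort(tiny_config)
        per_cell = gt.session_values.groupby(["subject_id", "session"])["variable"].nunique()
        expected = len(REGISTRY) + len(STP_VARIABLES)
        assert (per_cell == expected).all()

    def test_stride_draw_positivity(self, tiny_config):
        _, gt = generate_cohort(tiny_config)
        draws = gt.stride_draws
        for var in STP_PRIMITIVES:
            assert (draws[var] > 0).all()
        frac = draws["stance_time"] / draws["stride_time"]
        assert frac.between(0.45, 0.78).all()
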