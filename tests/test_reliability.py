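"""SEM, SEM%, RMSD, ICC cross-check and report assembly."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitrel.reliability import (
    SubjectSessionData,
    build_report,
    cohort_rmsd,
    ensemble_average,
    icc_cross_check,
    match_stride_counts,
    rmsd_between_sessions,
    sem_anova,
    sem_from_differences,
    sem_percent,
)
from gaitrel.synthetic import draw_subject_session_values


class TestEnsembleAverage:
    def test_single_stride_is_identity(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(1, 101))
        assert np.array_equal(ensemble_average(c), c[0])

    def test_mirrored_curves_cancel(self):
        c = np.vstack([np.linspace(-3, 3, 101), -np.linspace(-3, 3, 101)])
        assert np.allclose(ensemble_average(c), 0.0)

    def test_matches_pointwise_mean_oracle(self):
        rng = np.random.default_rng(1)
        curves = rng.normal(size=(7, 101))
        expected = np.array([
            sum(curves[i, j] for i in range(7)) / 7 for j in range(101)
        ])
        assert np.max(np.abs(ensemble_average(curves) - expected)) < 1e-12

    def test_zero_strides_raises(self):
        with pytest.raises(ValueError):
            ensemble_average(np.empty((0, 101)))


class TestRMSD:
    def test_identity_and_constant_offset(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=101)
        assert rmsd_between_sessions(c, c) == 0.0
        assert rmsd_between_sessions(c, c + 2.0) == pytest.approx(2.0, abs=1e-12)

    def test_sinusoidal_offset_tends_to_amplitude_over_sqrt2(self):
        amplitude = 3.0
        for n, rtol in ((101, 0.02), (10001, 2e-4)):
            p = np.linspace(0, 1, n)
            c = np.zeros(n)
            value = rmsd_between_sessions(c, c + amplitude * np.sin(2 * np.pi * p))
            assert value == pytest.approx(amplitude / math.sqrt(2), rel=rtol)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd_between_sessions(np.zeros(101), np.zeros(99))

    def test_cohort_rmsd_is_mean_of_subject_rmsds(self):
        rng = np.random.default_rng(3)
        ones = [rng.normal(size=101) for _ in range(4)]
        twos = [c + k for k, c in enumerate(ones)]
        expected = np.mean([rmsd_between_sessions(a, b) for a, b in zip(ones, twos)])
        assert cohort_rmsd(ones, twos) == pytest.approx(expected, abs=1e-12)


class TestSEM:
    def test_pure_systematic_shift_gives_zero(self):
        matrix = np.array([[10.0, 12.0], [20.0, 22.0], [30.0, 32.0]])
        assert sem_anova(matrix) == 0.0

    def test_hand_computed_two_subject_case(self):
        # per-subject differences d = {0, 2}: SD(d) = sqrt(2), SEM = 1
        matrix = np.array([[5.0, 5.0], [5.0, 7.0]])
        assert sem_anova(matrix) == pytest.approx(1.0, abs=1e-12)
        assert sem_from_differences(matrix) == pytest.approx(1.0, abs=1e-12)

    def test_identical_sessions_give_exact_zero(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=12)
        assert sem_anova(np.column_stack([col, col])) == 0.0

    def test_anova_and_difference_forms_agree(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = rng.normal(scale=rng.uniform(0.1, 50), size=(rng.integers(2, 30), 2))
            assert abs(sem_anova(m) - sem_from_differences(m)) <= 1e-12 * max(
                1.0, sem_anova(m)
            )

    @given(shift=st.floats(-100, 100), n=st.integers(3, 15))
    @settings(max_examples=25, deadline=None)
    def test_invariance_to_constant_shift(self, shift, n):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(n, 2))
        assert sem_anova(m + shift) == pytest.approx(sem_anova(m), abs=1e-9)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            sem_anova(np.array([[1.0, 2.0]]))

    def test_monte_carlo_recovery_of_injected_sigma(self):
        """Mean SEM over cohorts recovers the injected session-error SD."""
        rng = np.random.default_rng(7)
        sigma = 2.0
        estimates = [
            sem_anova(draw_subject_session_values(200, 10.0, 3.0, sigma, rng))
            for _ in range(50)
        ]
        assert np.mean(estimates) == pytest.approx(sigma, rel=0.05)


class TestSEMPercent:
    def test_printed_cadence_and_double_support_values(self):
        """Recomputing SEM% from session means reproduces printed values."""
        assert round(sem_percent(2.92, 109.5, 111.95), 1) == 2.6
        assert round(sem_percent(2.51, 134.9, 135.3), 1) == 1.9
        assert round(sem_percent(0.01, 0.13, 0.13), 1) == 7.7

    def test_zero_sem_is_zero_percent(self):
        assert sem_percent(0.0, 1.2, 1.3) == 0.0

    def test_zero_grand_mean_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="grand mean"):
            assert np.isnan(sem_percent(1.0, -2.0, 2.0))

    def test_scales_inversely_with_mean(self):
        assert sem_percent(1.0, 10.0, 10.0) == pytest.approx(
            2 * sem_percent(1.0, 20.0, 20.0)
        )


class TestICCCrossCheck:
    def test_perfect_reliability_limit(self):
        rng = np.random.default_rng(8)
        col = rng.normal(size=15)
        icc, sem_icc = icc_cross_check(np.column_stack([col, col]))
        assert icc == pytest.approx(1.0)
        assert sem_icc == pytest.approx(0.0, abs=1e-12)

    def test_no_subject_effect_gives_icc_near_zero(self):
        rng = np.random.default_rng(9)
        m = rng.normal(scale=1.0, size=(1000, 2))
        icc, sem_icc = icc_cross_check(m)
        assert abs(icc) < 0.1
        assert sem_icc == pytest.approx(1.0, rel=0.1)  # near the total SD

    def test_identity_with_anova_sem(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            m = rng.normal(scale=5, size=(rng.integers(3, 40), 2)) + rng.normal(
                scale=3, size=(1,)
            )
            sem = sem_anova(m)
            _, sem_icc = icc_cross_check(m)
            assert abs(sem - sem_icc) <= 1e-6 * max(sem, 1e-12)

    def test_degenerate_zero_variance_raises(self):
        with pytest.raises(ValueError, match="ICC undefined"):
            icc_cross_check(np.full((5, 2), 3.14))

    def test_against_pingouin_icc3(self):
        """Independent oracle: pingouin's ICC3 on long-format data."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        m = rng.normal(size=(12, 2)) + rng.normal(scale=2, size=(12, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "session": np.tile([1, 2], 12),
            "value": m.ravel(),
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pingouin.intraclass_corr(
                data=df, targets="subject", raters="session", ratings="value"
            )
        expected = res.loc[res["Type"].isin(["ICC3", "ICC(C,1)"]), "ICC"].iloc[0]
        icc, _ = icc_cross_check(m)
        assert icc == pytest.approx(expected, abs=1e-9)


class TestReportAssembly:
    def _subject_session(self, subject, session, value, n_strides=4):
        from gaitrel.features import REGISTRY
        from gaitrel.spatiotemporal import STP_VARIABLES

        cols = [s.key for s in REGISTRY] + list(STP_VARIABLES)
        features = pd.DataFrame(
            {c: np.full(n_strides, value + i) for i, c in enumerate(cols)}
        )
        curves = {
            (j, p): np.full((n_strides, 101), value)
            for j in ("hip", "knee", "ankle")
            for p in ("sagittal", "frontal", "transverse")
        }
        return SubjectSessionData(subject_id=subject, session=session,
                                  task="SSWS", features=features, curves=curves)

    def test_stride_matching_truncates_to_earliest(self):
        d1 = self._subject_session("S1", 1, 1.0, n_strides=5)
        d2 = self._subject_session("S1", 2, 2.0, n_strides=3)
        m1, m2 = match_stride_counts(d1, d2)
        assert m1.n_strides == m2.n_strides == 3
        assert m1.curves[("hip", "sagittal")].shape == (3, 101)

    def test_row_count_matches_registry_and_stp(self):
        cohort = [
            self._subject_session(f"S{i}", s, float(i + s))
            for i in range(3) for s in (1, 2)
        ]
        report = build_report(cohort)
        assert len(report.variables) == 32 + 15
        assert len(report.rmsd) == 9

    def test_subject_missing_session_excluded_and_logged(self):
        cohort = [
            self._subject_session("S1", 1, 1.0), self._subject_session("S1", 2, 1.5),
            self._subject_session("S2", 1, 2.0), self._subject_session("S2", 2, 2.5),
            self._subject_session("S3", 1, 3.0),  # no session 2
        ]
        report = build_report(cohort)
        assert {"task": "SSWS", "subject_id": "S3", "reason": "missing_session"} in report.exclusions
        assert (report.variables["n_subjects"] == 2).all()
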