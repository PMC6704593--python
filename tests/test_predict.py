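import numpy as np
import pytest

from anaerodyn import (ExposureRecord, PatientMeta, compile_courses,
                       forward_simulate_patient, predict_course_loss)
from anaerodyn.abundance import DensitySeries
from anaerodyn.predict import ALL_LABELS, CourseRecord, DayContext

from conftest import make_point_posterior


def mono_course(drug, duration, phase2=1):
    cov = tuple(int(lbl == drug) for lbl in ALL_LABELS)
    return CourseRecord(
        patient_id="p", drug=drug, start_day=0,
        days=tuple(DayContext(0, phase2, cov) for _ in range(duration)))


class TestForwardSimulation:
    def test_pure_decay_matches_closed_form(self):
        post = make_point_posterior(r=-0.5)
        series = DensitySeries("p", [(d, 1e10, 1e10, 1.0)
                                     for d in range(5)])
        meta = PatientMeta("p", "auto", -5, 8, -6, 20)
        df = forward_simulate_patient(post, series, [], meta,
                                      rng=np.random.default_rng(0))
        # phase flags are zero-effect here; N(4) = 1e10 * exp(-0.5 * 4)
        assert df["predicted"].iloc[-1] == pytest.approx(1e10 * np.exp(-2.0),
                                                         rel=1e-9)

    def test_all_zero_posterior_gives_flat_trajectory(self):
        post = make_point_posterior()
        series = DensitySeries("p", [(0, 3e9, 1e10, 1.0), (2, 1e8, 1e10, 1.0),
                                     (3, 1e7, 1e10, 1.0)])
        meta = PatientMeta("p", "auto", -5, 8, -6, 20)
        df = forward_simulate_patient(post, series, [], meta,
                                      rng=np.random.default_rng(0))
        assert np.allclose(df["predicted"], 3e9)

    def test_capacity_free_simulation_is_exponential(self):
        # with beta_c = 0 the trajectory is exactly exp(mu * t)
        post = make_point_posterior(r=0.3, phase2=-0.8)
        series = DensitySeries("p", [(d, 1e9, 1e10, 1.0) for d in range(4)])
        meta = PatientMeta("p", "auto", -5, 8, -6, 20)
        df = forward_simulate_patient(post, series, [], meta,
                                      rng=np.random.default_rng(0))
        mu = 0.3 - 0.8  # every step lies inside phase II
        assert np.allclose(df["predicted"],
                           1e9 * np.exp(mu * np.arange(4)), rtol=1e-9)


class TestCompileCourses:
    def test_coadministration_context(self):
        exposures = [
            ExposureRecord("p", "piperacillin-tazobactam", "iv", 3, 9),
            ExposureRecord("p", "metronidazole", "po", 5, 6),
        ]
        metas = [PatientMeta("p", "allo", -7, 12, -8, 20)]
        courses = compile_courses(exposures, metas)
        pt = next(c for c in courses if c.drug == "piperacillin-tazobactam")
        assert pt.duration == 7
        metro = ALL_LABELS.index("metronidazole")
        flags = [d.covariates[metro] for d in pt.days]
        # metronidazole overlaps course days 5 and 6 (0-indexed 2 and 3)
        assert flags == [0, 0, 1, 1, 0, 0, 0]
        assert all(d.phase2 == 1 for d in pt.days)

    def test_interrupted_administration_splits_into_two_courses(self):
        exposures = [ExposureRecord("p", "meropenem", "iv", 1, 2),
                     ExposureRecord("p", "meropenem", "iv", 5, 6)]
        metas = [PatientMeta("p", "allo", -7, 12, -8, 20)]
        courses = compile_courses(exposures, metas)
        assert [c.duration for c in courses] == [2, 2]

    def test_contiguous_records_merge_into_one_course(self):
        exposures = [ExposureRecord("p", "meropenem", "iv", 1, 3),
                     ExposureRecord("p", "meropenem", "iv", 4, 6)]
        metas = [PatientMeta("p", "allo", -7, 12, -8, 20)]
        assert [c.duration for c in compile_courses(exposures, metas)] == [6]

    def test_empty_exposures_empty_courses(self):
        assert compile_courses([], [PatientMeta("p", "allo", -7, 12, -8, 20)]) == []


class TestCourseLoss:
    def test_point_mass_seven_day_monotherapy_closed_form(self):
        post = make_point_posterior(**{"piperacillin-tazobactam": -1.5})
        course = mono_course("piperacillin-tazobactam", 7, phase2=0)
        est = predict_course_loss(post, [course], "piperacillin-tazobactam",
                                  n_resamples=500,
                                  rng=np.random.default_rng(0))
        assert est.residual_fraction == pytest.approx(np.exp(-10.5),
                                                      rel=1e-9)
        assert est.percent_loss > 99.0

    def test_zero_effect_means_zero_loss(self):
        post = make_point_posterior()
        course = mono_course("meropenem", 5, phase2=0)
        est = predict_course_loss(post, [course], "meropenem",
                                  n_resamples=200,
                                  rng=np.random.default_rng(0))
        assert est.residual_fraction == pytest.approx(1.0)
        assert est.percent_loss == pytest.approx(0.0)

    def test_two_course_mixture_converges_to_exact_average(self):
        post = make_point_posterior(meropenem=-1.0)
        courses = [mono_course("meropenem", 2, phase2=0),
                   mono_course("meropenem", 4, phase2=0)]
        est = predict_course_loss(post, courses, "meropenem",
                                  n_resamples=40_000,
                                  rng=np.random.default_rng(1))
        exact = 0.5 * (np.exp(-2.0) + np.exp(-4.0))
        # CLT tolerance: sd of the mixture / sqrt(n)
        se = 0.5 * (np.exp(-2.0) - np.exp(-4.0)) / np.sqrt(40_000)
        assert est.residual_fraction == pytest.approx(exact, abs=4 * se)

    def test_invariant_to_course_list_duplication(self):
        post = make_point_posterior(meropenem=-1.0)
        courses = [mono_course("meropenem", 2, phase2=0),
                   mono_course("meropenem", 4, phase2=0)]
        a = predict_course_loss(post, courses, "meropenem",
                                n_resamples=20_000,
                                rng=np.random.default_rng(2))
        b = predict_course_loss(post, courses * 3, "meropenem",
                                n_resamples=20_000,
                                rng=np.random.default_rng(3))
        assert a.residual_fraction == pytest.approx(b.residual_fraction,
                                                    rel=0.05)

    def test_stronger_kill_never_increases_residual(self):
        course = mono_course("meropenem", 5, phase2=0)
        residuals = []
        for beta in (0.0, -0.5, -1.0, -2.0):
            post = make_point_posterior(meropenem=beta)
            residuals.append(predict_course_loss(
                post, [course], "meropenem", n_resamples=100,
                rng=np.random.default_rng(4)).residual_fraction)
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))

    def test_no_courses_for_drug_is_an_error(self):
        post = make_point_posterior()
        with pytest.raises(ValueError, match="linezolid"):
            predict_course_loss(post, [mono_course("meropenem", 3)],
                                "linezolid", n_resamples=10)
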