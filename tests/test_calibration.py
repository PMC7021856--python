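import dataclasses
import math
import random

import numpy as np
import pytest

import qspectcal as q
from qspectcal import calibration as cal
from conftest import CF_TRUE, TAU_TRUE


def make_sample(activity, r_po, r_wo, **kw):
    return cal.AcquisitionSample(
        activity=activity, r_po=r_po,
        window_rates={"6W": r_wo, "photopeak": r_po}, **kw,
    )


class TestXw:
    def test_arithmetic(self):
        s = make_sample(100.0, 1000.0, 4000.0)
        assert cal.x_w(s, "6W") == 400.0

    def test_unit_ratio_gives_activity(self):
        s = make_sample(123.0, 500.0, 500.0)
        assert cal.x_w(s, "6W") == 123.0

    def test_simulator_ratio(self, camera):
        """The generative model fixes R_Wo/R_Po = k, so X_W = A*k."""
        phantom = q.air_2d()
        plan = q.AcquisitionPlan(activities=(1000.0,), noise=False, seed=0)
        (s,) = q.generate_series(camera, phantom, plan)
        assert cal.x_w(s, "6W") == pytest.approx(1000.0 * phantom.k)

    def test_zero_primary_rate_rejected(self):
        s = make_sample(10.0, 0.0, 100.0)
        with pytest.raises(ValueError, match="undefined"):
            cal.x_w(s, "6W")


class TestMethodACf:
    def test_exact_line(self):
        samples = [make_sample(1.0, 9.4, 40), make_sample(2.0, 18.8, 80)]
        cf, se = cal.fit_method_a_cf(samples)
        assert cf == pytest.approx(9.4)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_single_point(self):
        cf, se = cal.fit_method_a_cf([make_sample(10.0, 94.0, 400)])
        assert cf == pytest.approx(9.4)
        assert se == 0.0

    def test_no_samples(self):
        with pytest.raises(cal.FitError):
            cal.fit_method_a_cf([])


class TestSelectDtFree:
    def test_threshold_rate_closed_form(self):
        # f(R) = 1.01  <=>  R = ln(1.01) / (1.01 * tau)
        r_crit = math.log(1.01) / (1.01 * TAU_TRUE)
        below = make_sample(1.0, 10.0, 0.99 * r_crit)
        above = make_sample(1.0, 10.0, 1.01 * r_crit)
        kept = cal.select_dt_free([below, above], TAU_TRUE)
        assert kept == [below]

    def test_all_low_retained(self):
        samples = [make_sample(a, 9.36 * a, 40 * a) for a in (0.5, 0.8, 1.0)]
        assert cal.select_dt_free(samples, TAU_TRUE) == samples

    def test_none_left_raises(self):
        samples = [make_sample(1e4, 1e4, 3e5)]
        with pytest.raises(cal.FitError, match="dead-time-free"):
            cal.select_dt_free(samples, TAU_TRUE)


class TestRecovery:
    def test_method_b_noise_free_exact(self, noisefree_series):
        fit, usable = cal.calibrate_with_range(noisefree_series)
        assert fit.cf == pytest.approx(CF_TRUE, rel=1e-6)
        assert fit.tau == pytest.approx(TAU_TRUE, rel=1e-6)
        assert usable.reached  # the top sample is past saturation

    def test_methods_agree_noise_free(self, noisefree_series):
        fb, _ = cal.calibrate_with_range(noisefree_series, method="B")
        fa, _ = cal.calibrate_with_range(noisefree_series, method="A")
        assert fa.cf == pytest.approx(fb.cf, rel=5e-3)
        assert fa.tau == pytest.approx(fb.tau, rel=5e-3)
        assert fa.method == "A" and fb.method == "B"
        assert fa.samples_excluded  # high-rate samples left the CF stage

    def test_poisson_recovery_within_tolerance(self, camera):
        """Seeded noisy series recover CF within 1% and tau within 3%."""
        for seed in (1, 2, 3):
            plan = q.default_planar_plan(seed=seed)
            series = q.generate_series(camera, q.air_2d(), plan)
            fit, _ = cal.calibrate_with_range(series)
            assert abs(fit.cf - CF_TRUE) / CF_TRUE < 0.01
            assert abs(fit.tau - TAU_TRUE) / TAU_TRUE < 0.03

    def test_tau_within_reported_se(self, camera):
        plan = q.default_planar_plan(seed=9)
        series = q.generate_series(camera, q.air_2d(), plan)
        fit, _ = cal.calibrate_with_range(series)
        assert abs(fit.tau - TAU_TRUE) < 3 * fit.tau_se

    def test_ordering_invariance(self, noisy_series):
        shuffled = list(noisy_series)
        random.Random(5).shuffle(shuffled)
        f1 = cal.fit_method_b(noisy_series)
        f2 = cal.fit_method_b(shuffled)
        # identical up to the optimizer's floating-point accumulation order
        assert f1.cf == pytest.approx(f2.cf, rel=1e-8)
        assert f1.tau == pytest.approx(f2.tau, rel=1e-8)

    def test_duration_rescaling_invariance(self, noisy_series):
        rescaled = [
            dataclasses.replace(s, duration=s.duration * 7.0)
            for s in noisy_series
        ]
        f1 = cal.fit_method_b(noisy_series)
        f2 = cal.fit_method_b(rescaled)
        assert f1.cf == f2.cf and f1.tau == f2.tau

    def test_dt_free_only_data_warns_tau_unidentifiable(self):
        samples = [
            make_sample(a, CF_TRUE * a, 4 * CF_TRUE * a)
            for a in np.linspace(0.1, 2.0, 8)
        ]
        with pytest.warns(UserWarning, match="poorly identified"):
            cal.fit_method_b(samples)

    def test_too_few_samples(self):
        with pytest.raises(cal.FitError):
            cal.fit_method_b([make_sample(1.0, 9.4, 40)] * 2)


class TestUsableRange:
    def test_no_exclusions_on_exact_data(self, camera):
        plan = q.AcquisitionPlan(
            activities=tuple(np.geomspace(20, 8000, 10)),
            noise=False, seed=0,
        )
        series = q.generate_series(camera, q.air_2d(), plan)
        fit = cal.fit_method_b(series)
        ur = cal.detect_usable_range(series, fit)
        assert not ur.reached
        assert ur.excluded_indices == []

    def test_saturation_boundary_within_one_sample(self, camera,
                                                   noisefree_series):
        """The detected boundary brackets the simulator's saturation rate."""
        fit, ur = cal.calibrate_with_range(noisefree_series)
        assert ur.reached
        activities = sorted(s.activity for s in noisefree_series)
        idx = activities.index(ur.max_activity)
        # noise-free wide rate at the next activity must exceed saturation
        x_next = CF_TRUE * activities[idx + 1] * q.air_2d().k
        assert x_next * np.exp(-x_next * TAU_TRUE) > camera.saturation_rate
        assert ur.max_wide_rate <= camera.saturation_rate * 1.05

    def test_detector_divergence_detected(self, camera):
        plan = q.AcquisitionPlan(
            activities=tuple(np.geomspace(20, 8000, 10)),
            noise=False, seed=0,
        )
        avg = q.generate_series(camera, q.air_2d(), plan)
        fit = cal.fit_method_b(avg)
        d1 = list(avg)
        d2 = [
            dataclasses.replace(s, r_po=s.r_po * (0.8 if i >= 8 else 1.0))
            for i, s in enumerate(avg)
        ]
        ur = cal.detect_usable_range(avg, fit, per_detector={"1": d1, "2": d2})
        assert ur.reached
        assert ur.max_activity == avg[7].activity

    def test_single_sample_open_ended(self, camera):
        plan = q.AcquisitionPlan(activities=(100.0,), noise=False, seed=0)
        series = q.generate_series(camera, q.air_2d(), plan)
        fit = q.CalibrationFit(
            cf=CF_TRUE, tau=TAU_TRUE, cf_se=0, tau_se=0,
            method="B", combination="6W", n_used=1,
        )
        ur = cal.detect_usable_range(series, fit)
        assert not ur.reached
        assert ur.max_activity == 100.0


class TestSensitivityTable:
    def test_exact_model_gives_constant_sensitivity(self):
        samples = [make_sample(a, CF_TRUE * a, 0.0) for a in (1, 2, 5)]
        table = cal.sensitivity_table(samples)
        assert np.allclose(table["sensitivity_cps_per_MBq"], CF_TRUE)

    def test_corrected_column_is_flat(self, noisefree_series):
        fit, ur = cal.calibrate_with_range(noisefree_series)
        in_range = [
            s for s in noisefree_series if s.activity <= ur.max_activity
        ]
        table = cal.sensitivity_table(in_range, fit)
        raw = table["sensitivity_cps_per_MBq"].to_numpy()
        corr = table["corrected_sensitivity_cps_per_MBq"].to_numpy()
        order = np.argsort([s.activity for s in in_range])
        # uncorrected sensitivity declines monotonically with rate
        assert np.all(np.diff(raw[order]) < 0)
        assert np.allclose(corr, CF_TRUE, rtol=1e-6)

    def test_zero_activity_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_sample(0.0, 1.0, 1.0)
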