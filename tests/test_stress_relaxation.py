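import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from explantmech import (
    RecoilMeasurement,
    RelaxationTrace,
    SLSParameters,
    fit_sls,
    plastic_fraction,
    recoil_metrics,
    residual_stiffness_180,
    sls_stress,
    spring_stiffness,
    structural_stiffness_series,
)
from explantmech.synthetic import simulate_relaxation


def make_trace(force, time=None, strain=0.10, area=1.0, **kw):
    force = np.asarray(force, float)
    if time is None:
        time = np.arange(force.size, dtype=float)
    return RelaxationTrace(
        time_s=np.asarray(time, float),
        force_uN=force,
        imposed_strain=strain,
        area_mm2=area,
        **kw,
    )


class TestSlsStress:
    def test_at_zero(self):
        p = SLSParameters(10.0, 20.0, 60.0)
        assert sls_stress(0.0, p) == pytest.approx(30.0)

    def test_asymptote(self):
        p = SLSParameters(10.0, 20.0, 60.0)
        assert sls_stress(1000 * p.tau, p) == pytest.approx(10.0)

    def test_hand_evaluation(self):
        p = SLSParameters(10.0, 20.0, 60.0)
        assert sls_stress(60.0, p) == pytest.approx(10 + 20 / np.e)  # ≈ 17.358

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            sls_stress(-1.0, SLSParameters(1.0, 1.0, 1.0))

    @given(
        s_inf=st.floats(0.1, 50),
        s_sp=st.floats(0.1, 100),
        tau=st.floats(5, 300),
    )
    def test_strictly_decreasing_when_s_sp_positive(self, s_inf, s_sp, tau):
        p = SLSParameters(s_inf, s_sp, tau)
        # stay within ~5 e-foldings so the exponential does not underflow
        t = np.linspace(0, 5 * tau, 50)
        ss = sls_stress(t, p)
        assert np.all(np.diff(ss) < 0)

    def test_constant_when_s_sp_zero(self):
        p = SLSParameters(10.0, 0.0, 60.0)
        assert np.ptp(sls_stress(np.linspace(0, 600, 20), p)) == 0.0


class TestSLSParameters:
    def test_eta_identity_exact(self):
        p = SLSParameters(14.0, 25.0, 45.0)
        assert p.eta == 45.0 * 14.0

    @given(s_inf=st.floats(0, 50), tau=st.floats(1e-3, 300))
    def test_eta_identity_property(self, s_inf, tau):
        assert SLSParameters(s_inf, 1.0, tau).eta == tau * s_inf

    @pytest.mark.parametrize("kw", [dict(s_inf=-1.0), dict(s_sp=-1.0), dict(tau=0.0)])
    def test_invalid_parameters_rejected(self, kw):
        base = dict(s_inf=1.0, s_sp=1.0, tau=1.0)
        with pytest.raises(ValueError):
            SLSParameters(**{**base, **kw})


class TestStructuralStiffness:
    def test_forced_arithmetic(self):
        t, ss = structural_stiffness_series(make_trace([1.0], strain=0.10, area=1.0))
        assert ss[0] == pytest.approx(10.0)

    def test_zero_force(self):
        _, ss = structural_stiffness_series(make_trace([0.0]))
        assert ss[0] == 0.0

    def test_arithmetic_oracle(self):
        # 0.84 μN / 0.5 mm² / 0.12 → 14 Pa, the late-gastrula magnitude
        _, ss = structural_stiffness_series(make_trace([0.84], strain=0.12, area=0.5))
        assert ss[0] == pytest.approx(14.0)

    def test_realized_strain_supersedes_nominal(self):
        trace = RelaxationTrace(
            time_s=np.array([0.0, 1.0]),
            force_uN=np.array([1.0, 1.0]),
            imposed_strain=0.10,
            area_mm2=1.0,
            strain=np.array([0.2, 0.2]),
        )
        _, ss = structural_stiffness_series(trace)
        np.testing.assert_allclose(ss, 5.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            make_trace([1.0], area=0.0)

    def test_zero_strain_rejected(self):
        with pytest.raises(ValueError, match="strain"):
            make_trace([1.0], strain=0.0)


class TestFitSls:
    def test_noise_free_recovery(self):
        truth = SLSParameters(10.0, 20.0, 60.0)
        t = np.linspace(0, 300, 100)
        fit = fit_sls(t, sls_stress(t, truth))
        assert fit.converged
        assert fit.params.s_inf == pytest.approx(10.0, rel=1e-6)
        assert fit.params.s_sp == pytest.approx(20.0, rel=1e-6)
        assert fit.params.tau == pytest.approx(60.0, rel=1e-6)

    def test_constant_series_degenerate(self):
        t = np.linspace(0, 300, 50)
        fit = fit_sls(t, np.full_like(t, 10.0))
        assert fit.params.s_inf == pytest.approx(10.0)
        assert fit.params.s_sp == 0.0
        assert not fit.tau_identifiable
        assert "tau_unidentifiable" in fit.flags

    def test_noisy_recovery_within_5pct(self):
        truth = SLSParameters(14.0, 25.0, 45.0)
        trace = simulate_relaxation(truth, 0.12, 0.3, 0.02, 200, 300.0, seed=42)
        t, ss = structural_stiffness_series(trace)
        fit = fit_sls(t, ss)
        assert fit.params.s_inf == pytest.approx(14.0, rel=0.05)
        assert fit.params.s_sp == pytest.approx(25.0, rel=0.05)
        assert fit.params.tau == pytest.approx(45.0, rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            fit_sls(np.array([0.0, 10.0, 20.0]), np.array([3.0, 2.0, 1.5]))

    def test_ramp_samples_excluded(self):
        truth = SLSParameters(10.0, 20.0, 30.0)
        t = np.linspace(0, 300, 200)
        ss = sls_stress(t, truth)
        ss[t < 3.0] = 0.0  # corrupt the ramp; fit must ignore it
        fit = fit_sls(t, ss, ramp_end_s=3.0)
        assert fit.params.tau == pytest.approx(30.0, rel=1e-6)

    def test_unknown_method_rejected(self):
        t = np.linspace(0, 300, 50)
        with pytest.raises(ValueError, match="unknown fit method"):
            fit_sls(t, np.exp(-t / 60), method="nope")

    @settings(max_examples=25, deadline=None)
    @given(
        s_inf=st.floats(1, 50),
        s_sp=st.floats(1, 100),
        tau=st.floats(5, 300),
    )
    def test_round_trip_identity_property(self, s_inf, s_sp, tau):
        truth = SLSParameters(s_inf, s_sp, tau)
        t = np.linspace(0, max(300.0, 5 * tau), 200)
        fit = fit_sls(t, sls_stress(t, truth))
        assert fit.params.s_inf == pytest.approx(s_inf, rel=1e-5, abs=1e-8)
        assert fit.params.s_sp == pytest.approx(s_sp, rel=1e-5)
        assert fit.params.tau == pytest.approx(tau, rel=1e-5)


class TestResidualStiffness180:
    def test_arithmetic_oracle(self):
        t = np.array([0.0, 90.0, 180.0, 270.0])
        trace = make_trace([2.0, 1.5, 1.2, 1.1], time=t, strain=0.12, area=0.6)
        assert residual_stiffness_180(trace) == pytest.approx(1.2 / 0.6 / 0.12)  # 16.667

    def test_constant_force_consistency(self):
        t = np.linspace(0, 300, 31)
        trace = make_trace(np.full_like(t, 1.0), time=t, strain=0.10, area=1.0)
        _, ss = structural_stiffness_series(trace)
        assert residual_stiffness_180(trace) == pytest.approx(ss[0])

    def test_matches_closed_form_on_synthetic_trace(self):
        truth = SLSParameters(14.0, 25.0, 45.0)
        trace = simulate_relaxation(truth, 0.12, 0.3, 0.0, 601, 300.0, seed=0)
        assert residual_stiffness_180(trace) == pytest.approx(
            sls_stress(180.0, truth), rel=1e-6
        )

    def test_interpolation_converges_with_density(self):
        truth = SLSParameters(14.0, 25.0, 45.0)
        errs = []
        # sample counts chosen so 180 s is never exactly on the grid
        for n in (20, 200):
            trace = simulate_relaxation(truth, 0.12, 0.3, 0.0, n, 300.0, seed=0)
            errs.append(abs(residual_stiffness_180(trace) - sls_stress(180.0, truth)))
        assert errs[1] < errs[0]

    def test_short_trace_rejected(self):
        trace = make_trace([1.0, 0.9], time=[0.0, 100.0])
        with pytest.raises(ValueError, match="180"):
            residual_stiffness_180(trace)


class TestSpringStiffness:
    def test_forced_arithmetic(self):
        assert spring_stiffness(1.0, 0.10) == pytest.approx(10.0)

    def test_zero_force(self):
        assert spring_stiffness(0.0, 0.10) == 0.0

    def test_arithmetic_oracle(self):
        assert spring_stiffness(0.84, 0.12) == pytest.approx(7.0)

    def test_zero_strain_rejected(self):
        with pytest.raises(ValueError, match="strain"):
            spring_stiffness(1.0, 0.0)

    @given(force=st.floats(0.01, 10), strain=st.floats(0.01, 0.5))
    def test_round_trip_identity(self, force, strain):
        assert spring_stiffness(force, strain) * strain == pytest.approx(force)


class TestPlasticFraction:
    def test_paper_reconstruction(self):
        # 12% applied, recovered 3% longer → plastic fraction 25%
        plastic, residual = plastic_fraction(1000.0, 1120.0, 1030.0)
        assert plastic == pytest.approx(0.25)
        assert residual == pytest.approx(0.03)

    def test_full_recovery(self):
        plastic, residual = plastic_fraction(1000.0, 1120.0, 1000.0)
        assert plastic == 0.0 and residual == 0.0

    def test_fully_plastic(self):
        plastic, residual = plastic_fraction(1000.0, 1120.0, 1120.0)
        assert plastic == pytest.approx(1.0)
        assert residual == pytest.approx(0.12)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="initial <= recovered <= peak"):
            plastic_fraction(1000.0, 1120.0, 990.0)


class TestRecoilMetrics:
    def test_fractional_recoil_41pct(self):
        m = RecoilMeasurement(1.0, 0.41, 0.0093, 5.0)
        fractional, _ = recoil_metrics(m)
        assert fractional == pytest.approx(41.0)

    def test_recoil_rate_unit_conversion(self):
        # 0.93% of width in 5 s → 0.93/5·3600 ≈ 670 %/hr
        m = RecoilMeasurement(1.0, 0.41, 0.0093, 5.0)
        _, rate = recoil_metrics(m)
        assert rate == pytest.approx(669.6)

    def test_fully_elastic(self):
        m = RecoilMeasurement(1.0, 1.0, 0.01, 5.0)
        fractional, _ = recoil_metrics(m)
        assert fractional == pytest.approx(100.0)

    def test_zero_release_rejected(self):
        m = RecoilMeasurement(0.0, 0.0, 0.01, 5.0)
        with pytest.raises(ValueError, match="tension_released"):
            recoil_metrics(m)

    def test_recoil_exceeding_release_rejected(self):
        with pytest.raises(ValueError, match="immediate_recoil_tension"):
            RecoilMeasurement(1.0, 1.5, 0.01, 5.0)
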