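"""Closed-form two-compartment kinetics against the ODE oracle and its
structural invariants (superposition, dose proportionality, mass balance)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dexpopk.pk import (
    ConcProfile,
    DispositionParams,
    InfusionSchedule,
    InvalidInputError,
    InvalidParameterError,
    hybrid_constants,
    integrate_ode_oracle,
    predict_concentrations,
)


def random_case(rng):
    params = DispositionParams(
        cl=rng.uniform(5, 80),
        q=rng.uniform(5, 120),
        v_c=rng.uniform(5, 80),
        v_t=rng.uniform(20, 300),
    )
    edges = np.sort(rng.uniform(0, 40, size=rng.integers(2, 6)))
    rates = rng.uniform(10, 120, size=len(edges) - 1)
    schedule = InfusionSchedule(
        [(a, b, r) for a, b, r in zip(edges[:-1], edges[1:], rates)]
    )
    times = np.sort(rng.uniform(0, 60, size=12))
    return params, schedule, times


class TestClosedForm:
    def test_matches_ode_oracle_on_randomized_regimens(self):
        """Analytical solution agrees with stiff numerical integration to 1e-8
        relative across 100 random parameter/schedule draws."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            params, schedule, times = random_case(rng)
            closed = predict_concentrations(params, schedule, times).conc_central
            oracle = integrate_ode_oracle(params, schedule, times, tol=1e-12).conc_central
            # absolute floor at 1e-8 of the profile maximum: deep-washout
            # values sit at the integrator's own absolute-tolerance level
            np.testing.assert_allclose(
                closed, oracle, rtol=1e-8, atol=1e-8 * max(oracle.max(), 1e-12)
            )

    def test_zero_before_first_dose(self, ref_params):
        sched = InfusionSchedule([(5.0, 20.0, 50.0)])
        prof = predict_concentrations(ref_params, sched, np.array([0.0, 2.0, 4.9]))
        assert np.all(prof.conc_central == 0.0)

    def test_steady_state_is_rate_over_clearance(self, ref_params):
        """Constant infusion run to steady state: C_ss = R / CL."""
        sched = InfusionSchedule([(0.0, 5000.0, 35.0)])
        c = predict_concentrations(ref_params, sched, np.array([4999.0])).conc_central[0]
        assert c == pytest.approx(35.0 / 38.5, rel=1e-9)

    def test_concentration_continuous_at_segment_boundary(self, ref_params):
        sched = InfusionSchedule([(0.0, 10.0, 60.0), (10.0, 20.0, 30.0)])
        eps = 1e-9
        t = np.array([10.0 - eps, 10.0, 10.0 + eps])
        c = predict_concentrations(ref_params, sched, t).conc_central
        assert np.abs(c[1] - c[0]) < 1e-6 and np.abs(c[2] - c[1]) < 1e-6

    def test_monotone_washout_after_final_segment(self, ref_params):
        sched = InfusionSchedule([(0.0, 24.0, 55.0)])
        t = np.linspace(24.0, 60.0, 50)
        c = predict_concentrations(ref_params, sched, t).conc_central
        assert np.all(np.diff(c) < 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_superposition_of_schedules(self, seed, ref_params):
        """Profile of two overlapping regimens equals the sum of profiles."""
        rng = np.random.default_rng(seed)
        s1 = InfusionSchedule([(0.0, rng.uniform(5, 20), rng.uniform(20, 80))])
        s2 = InfusionSchedule([(rng.uniform(1, 8), rng.uniform(10, 30), rng.uniform(20, 80))])
        t = np.linspace(0, 40, 37)
        c1 = predict_concentrations(ref_params, s1, t).conc_central
        c2 = predict_concentrations(ref_params, s2, t).conc_central
        c12 = predict_concentrations(ref_params, s1.combine(s2), t).conc_central
        np.testing.assert_allclose(c12, c1 + c2, rtol=1e-10, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), factor=st.floats(0.25, 8.0))
    def test_dose_proportionality(self, seed, factor, ref_params):
        """Scaling all rates scales concentrations exactly linearly."""
        rng = np.random.default_rng(seed)
        _, schedule, times = random_case(rng)
        base = predict_concentrations(ref_params, schedule, times).conc_central
        scaled = predict_concentrations(
            ref_params, schedule.scaled(factor), times
        ).conc_central
        np.testing.assert_allclose(scaled, factor * base, rtol=1e-12)


class TestOdeOracle:
    def test_zero_rate_schedule_stays_zero(self, ref_params):
        sched = InfusionSchedule([(0.0, 10.0, 0.0)])
        prof = integrate_ode_oracle(ref_params, sched, np.linspace(0, 20, 11))
        assert np.all(prof.conc_central == 0.0)

    def test_mass_balance(self):
        """V_C·C_P + V_T·C_T + eliminated = dose infused, at all times."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            params, schedule, times = random_case(rng)
            prof, c_t, elim = integrate_ode_oracle(
                params, schedule, times, tol=1e-12, full_state=True
            )
            in_system = params.v_c * prof.conc_central + params.v_t * c_t + elim
            dose = np.array([schedule.dose_infused_by(t) for t in times])
            np.testing.assert_allclose(in_system, dose, rtol=1e-7, atol=1e-8)

    def test_rejects_nonpositive_tolerance(self, ref_params):
        with pytest.raises(InvalidInputError):
            integrate_ode_oracle(
                ref_params, InfusionSchedule([(0, 1, 1)]), np.array([1.0]), tol=0.0
            )


class TestHybridConstants:
    def test_eigen_solve_oracle_at_reference_values(self, ref_params):
        """Root-finder eigenvalues match a direct 2×2 eigendecomposition."""
        lam1, lam2 = hybrid_constants(ref_params)
        k10, k12, k21 = ref_params.micro_constants()
        # disposition matrix in concentration coordinates
        A = np.array([[-(k10 + k12), k12], [k21, -k21]])
        eig = np.sort(-np.linalg.eigvals(A))[::-1]
        assert lam1 == pytest.approx(eig[0], rel=1e-12)
        assert lam2 == pytest.approx(eig[1], rel=1e-12)

    def test_vieta_identities_for_random_params(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = DispositionParams(
                cl=rng.uniform(1, 100), q=rng.uniform(1, 200),
                v_c=rng.uniform(1, 100), v_t=rng.uniform(1, 400),
            )
            k10, k12, k21 = p.micro_constants()
            lam1, lam2 = hybrid_constants(p)
            assert lam1 > lam2 > 0
            assert lam1 * lam2 == pytest.approx(k10 * k21, rel=1e-12)
            assert lam1 + lam2 == pytest.approx(k10 + k12 + k21, rel=1e-12)

    def test_one_compartment_limit(self, ref_params):
        """As Q → 0 the hybrid constants approach {CL/V_C, Q/V_T}."""
        p = DispositionParams(cl=ref_params.cl, q=1e-9, v_c=ref_params.v_c, v_t=ref_params.v_t)
        lam1, lam2 = hybrid_constants(p)
        assert lam1 == pytest.approx(p.cl / p.v_c, rel=1e-6)
        assert lam2 == pytest.approx(p.q / p.v_t, rel=1e-6)


class TestValidation:
    def test_nonpositive_parameters_rejected(self):
        for bad in ({"cl": -1.0}, {"q": 0.0}, {"v_c": np.nan}, {"v_t": np.inf}):
            kwargs = {"cl": 38.5, "q": 46.4, "v_c": 27.0, "v_t": 87.6, **bad}
            with pytest.raises(InvalidParameterError):
                DispositionParams(**kwargs)

    def test_malformed_times_rejected(self, ref_params):
        sched = InfusionSchedule([(0, 10, 30)])
        with pytest.raises(InvalidInputError):
            predict_concentrations(ref_params, sched, np.array([3.0, 1.0]))
        with pytest.raises(InvalidInputError):
            predict_concentrations(ref_params, sched, np.array([-1.0, 1.0]))

    def test_malformed_schedules_rejected(self):
        with pytest.raises(InvalidInputError):
            InfusionSchedule([(0, 10, 30), (5, 15, 20)])  # overlap
        with pytest.raises(InvalidInputError):
            InfusionSchedule([(0, 0, 30)])  # empty segment
        with pytest.raises(InvalidInputError):
            InfusionSchedule([(0, 10, -5)])  # negative rate

    def test_total_dose(self):
        sched = InfusionSchedule([(0, 10, 60), (10, 20, 30)])
        assert sched.total_dose == pytest.approx(900.0)
        assert sched.dose_infused_by(15.0) == pytest.approx(750.0)
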