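import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

import polyadd as pa
from conftest import REF_U

rate_pairs = st.tuples(
    st.floats(min_value=1e-8, max_value=1e-2),  # kplus
    st.floats(min_value=0.0, max_value=1e-3),  # kminus
)


def bisection_steady_state(kappa: float, U: float) -> float:
    """Oracle: solve the Hill-Langmuir fixed point Pb = (1-Pb)U/((1-Pb)U + kappa)
    by bisection, independently of the quadratic formula."""
    if kappa == 0.0:
        return 1.0

    def f(p):
        return p - (1 - p) * U / ((1 - p) * U + kappa)

    return bisect(f, 0.0, 1.0, xtol=1e-15)


class TestSteadyState:
    def test_irreversible_limit(self):
        assert pa.steady_state_probability(
            pa.RateConstants(kplus=1e-4, kminus=0.0), 1.0
        ) == 1.0

    def test_reference_conditions(self, ref_rates):
        Pb = pa.steady_state_probability(ref_rates, REF_U)
        assert Pb == pytest.approx(0.8903, abs=5e-5)
        assert round(Pb, 2) == 0.89

    @given(rates=rate_pairs, U=st.floats(min_value=1e-3, max_value=10.0))
    def test_matches_bisection_oracle(self, rates, U):
        kp, km = rates
        rc = pa.RateConstants(kplus=kp, kminus=km)
        assert pa.steady_state_probability(rc, U) == pytest.approx(
            bisection_steady_state(rc.kappa, U), abs=1e-10
        )

    @given(rates=rate_pairs, U=st.floats(min_value=1e-3, max_value=10.0))
    def test_fixed_point_substitution(self, rates, U):
        kp, km = rates
        rc = pa.RateConstants(kplus=kp, kminus=km)
        Pb = pa.steady_state_probability(rc, U)
        rhs = (1 - Pb) * U / ((1 - Pb) * U + rc.kappa) if Pb < 1 else 1.0
        assert Pb == pytest.approx(rhs, rel=1e-12, abs=1e-12)

    def test_discarded_root_exceeds_one(self, ref_rates):
        kb = ref_rates.kappa_bar(REF_U)
        assert 1 + kb + math.sqrt(kb * (2 + kb)) > 1


class TestDpDt:
    def test_no_bonds_to_break(self, ref_rates):
        assert pa.dp_dt(0.0, ref_rates, REF_U) == ref_rates.kplus * REF_U

    def test_stationary_at_steady_state(self, ref_rates, ref_Pb):
        assert abs(pa.dp_dt(ref_Pb, ref_rates, REF_U)) < 1e-14 * ref_rates.kplus * REF_U

    def test_reference_midpoint_value(self, ref_rates):
        # 1 * 7.4e-5 * 0.25 - 1e-6 * 0.5
        assert pa.dp_dt(0.5, ref_rates, REF_U) == pytest.approx(1.8e-5, rel=1e-10)


class TestClosedForm:
    @pytest.mark.parametrize("p0", [0.0, 0.3, 0.8903129193269319, 0.95])
    def test_initial_condition(self, ref_rates, p0):
        assert pa.p_closed_form(0.0, p0, ref_rates, REF_U) == pytest.approx(p0, abs=1e-12)

    def test_long_time_reaches_steady_state(self, ref_rates, ref_Pb):
        sol = pa.solve_p(0.0, ref_rates, REF_U)
        t = 20.0 / sol.rate_scale
        assert sol.p(t) == pytest.approx(ref_Pb, abs=1e-8)
        assert round(sol.p(t), 4) == 0.8903

    @pytest.mark.parametrize("p0", [0.0, 0.5, 0.99])
    def test_matches_adaptive_integration(self, ref_rates, p0):
        sol = pa.solve_p(p0, ref_rates, REF_U)
        for t_end in [1e3, 1e4, 1e5, 1e6]:
            num = solve_ivp(
                lambda t, y: [pa.dp_dt(y[0], ref_rates, REF_U)],
                (0.0, t_end), [p0], rtol=1e-12, atol=1e-14,
            ).y[0, -1]
            assert sol.p(t_end) == pytest.approx(num, abs=1e-8)

    def test_branch_selection(self, ref_rates, ref_Pb):
        assert pa.solve_p(0.0, ref_rates, REF_U).branch == "coth"
        assert pa.solve_p(0.99, ref_rates, REF_U).branch == "tanh"
        assert pa.solve_p(ref_Pb, ref_rates, REF_U).branch == "constant"
        assert pa.solve_p(0.2, pa.RateConstants(kplus=1e-4, kminus=0.0), 1.0).branch == "irreversible"

    def test_irreversible_solution(self):
        rates = pa.RateConstants(kplus=1e-3, kminus=0.0)
        sol = pa.solve_p(0.25, rates, 2.0)
        t = np.geomspace(1.0, 1e7, 30)
        expected = 1.0 - 1.0 / (1.0 / 0.75 + 1e-3 * 2.0 * t)
        assert sol.p(t) == pytest.approx(expected, rel=1e-14)
        num = solve_ivp(
            lambda tt, y: [pa.dp_dt(y[0], rates, 2.0)], (0.0, 1e4), [0.25],
            rtol=1e-12, atol=1e-14,
        ).y[0, -1]
        assert sol.p(1e4) == pytest.approx(num, abs=1e-9)

    @pytest.mark.parametrize("p0", [0.0, 0.99])
    def test_monotone_and_bounded(self, ref_rates, ref_Pb, p0):
        sol = pa.solve_p(p0, ref_rates, REF_U)
        t = np.geomspace(1.0, 1e9, 200)
        p = sol.p(t)
        direction = np.sign(ref_Pb - p0)
        assert np.all(direction * np.diff(p) >= -1e-15)
        assert np.all(p >= min(p0, ref_Pb) - 1e-12)
        assert np.all(p <= max(p0, ref_Pb) + 1e-12)

    def test_huge_time_returns_asymptote_exactly(self, ref_rates, ref_Pb):
        assert pa.p_closed_form(1e300, 0.0, ref_rates, REF_U) == ref_Pb

    def test_nondimensional_consistency(self, ref_rates):
        # dp/dtau with tau = 2 k+ U t equals (1-p)^2/2 - kbar p
        p = 0.37
        kb = ref_rates.kappa_bar(REF_U)
        lhs = pa.dp_dt(p, ref_rates, REF_U) / (2 * ref_rates.kplus * REF_U)
        assert lhs == pytest.approx(0.5 * (1 - p) ** 2 - kb * p, rel=1e-12)

    def test_invalid_p0(self, ref_rates):
        with pytest.raises(pa.DomainError):
            pa.solve_p(1.0, ref_rates, REF_U)


class TestCriticalConcentration:
    def test_irreversible_is_zero(self):
        assert pa.critical_concentration(pa.RateConstants(kplus=1e-4, kminus=0.0)) == 0.0

    def test_reference_value(self, ref_rates):
        assert pa.critical_concentration(ref_rates) == pytest.approx(1e-6 / 7.4e-5)

    def test_monomer_concentration_increases_to_kappa(self, ref_rates):
        kappa = ref_rates.kappa
        n1 = []
        for ratio in [1e2, 1e4, 1e6]:
            U = ratio * kappa
            Pb = pa.steady_state_probability(ref_rates, U)
            n1.append((1 - Pb) ** 2 * U)
        assert n1[0] < n1[1] < n1[2] < kappa
        assert n1[2] == pytest.approx(kappa, rel=1e-2)


class TestDegreeOfPolymerization:
    def test_stationary_at_steady_state(self, ref_rates, ref_Pb):
        Xn = 1.0 / (1.0 - ref_Pb)
        assert abs(pa.dXn_dt(Xn, ref_rates, REF_U)) < 1e-12 * ref_rates.kplus * REF_U

    def test_irreversible_growth_is_linear(self):
        rates = pa.RateConstants(kplus=2e-4, kminus=0.0)
        for Xn in [1.0, 5.0, 100.0]:
            assert pa.dXn_dt(Xn, rates, 3.0) == 2e-4 * 3.0

    def test_consistent_with_chain_rule(self, ref_rates):
        # dXn/dt = (1-p)^-2 dp/dt with p = 1 - 1/Xn
        for Xn in [1.0, 2.0, 7.3]:
            p = 1.0 - 1.0 / Xn
            expected = pa.dp_dt(p, ref_rates, REF_U) / (1 - p) ** 2
            assert pa.dXn_dt(Xn, ref_rates, REF_U) == pytest.approx(expected, rel=1e-12)

    def test_finite_difference_along_closed_form(self, ref_rates):
        sol = pa.solve_p(0.0, ref_rates, REF_U)
        h = 1e-2
        for t in [1e3, 1e5, 1e6]:
            Xn = lambda tt: 1.0 / (1.0 - sol.p(tt))
            fd = (Xn(t + h) - Xn(t - h)) / (2 * h)
            assert fd == pytest.approx(pa.dXn_dt(Xn(t), ref_rates, REF_U), rel=1e-5)

    def test_rejects_sub_monomer(self, ref_rates):
        with pytest.raises(pa.DomainError):
            pa.dXn_dt(0.5, ref_rates, REF_U)


class TestRateFromThermo:
    def test_reference_kplus_from_rounded_probability(self):
        # kappa = (1-0.89)^2 / 0.89 then kplus = kminus/kappa: 7.4e-5 to 2 s.f.
        kappa = (1 - 0.89) ** 2 * 1.0 / 0.89
        kplus = 1e-6 / kappa
        assert float(f"{kplus:.2g}") == 7.4e-5

    # kminus bounded away from zero so Pb stays clear of logistic saturation
    @given(rates=st.tuples(st.floats(min_value=1e-8, max_value=1e-2),
                           st.floats(min_value=1e-9, max_value=1e-3)),
           U=st.floats(min_value=1e-2, max_value=5.0))
    def test_roundtrip_recovers_kplus(self, rates, U):
        kp, km = rates
        rc = pa.RateConstants(kplus=kp, kminus=km)
        Pb = pa.steady_state_probability(rc, U)
        dG = pa.energy_from_prob(Pb, 320.0)
        rec = pa.rate_from_thermo(km, dG, 320.0, U)
        assert rec.kplus == pytest.approx(kp, rel=1e-9)

    def test_symmetric_case(self):
        rec = pa.rate_from_thermo(1e-6, 0.0, 300.0, 2.0)
        assert rec.kplus == pytest.approx(2 * 1e-6 / 2.0, rel=1e-12)

    def test_zero_kminus_rejected(self):
        with pytest.raises(pa.DomainError):
            pa.rate_from_thermo(0.0, -1.0, 300.0, 1.0)
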