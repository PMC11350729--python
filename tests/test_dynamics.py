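"""Integration, equilibrium and relaxation-rate checks against closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hisfkin.dynamics import (
    equilibrium_state,
    integrate_scheme,
    kobs_hyperbolic,
    pfo_rate_matrix,
    project_observable,
    propagate_linear,
    relaxation_rates_pfo,
)
from hisfkin.schemes import RateParameterSet, build_scheme
from hisfkin.traces import ObservableModel
from hisfkin.util import EquilibriumError, IntegrationError, ValidationError


def pfo_closed_form(t, k1, km1, E0, S0):
    """Textbook pseudo-first-order one-step binding solution (the oracle)."""
    kobs = k1 * S0 + km1
    KD = km1 / k1
    return E0 * S0 / (KD + S0) * (1.0 - np.exp(-kobs * t))


class TestIntegration:
    def test_no_association_when_k1_zero(self, one_step):
        t = np.linspace(0, 5, 100)
        traj = integrate_scheme(
            one_step, RateParameterSet({"k1": 0.0, "k-1": 1.0}),
            {"E": 1.0, "S": 10.0}, t,
        )
        assert np.all(traj["ES"] == 0.0)

    def test_clamped_ligand_matches_closed_form(self, one_step):
        p = RateParameterSet({"k1": 0.1, "k-1": 1.0})
        t = np.linspace(0, 3, 400)
        traj = integrate_scheme(one_step, p, {"E": 0.1, "S": 10.0}, t, clamped={"S"})
        expected = pfo_closed_form(t, 0.1, 1.0, 0.1, 10.0)
        assert np.max(np.abs(traj["ES"] - expected)) < 1e-6

    @pytest.mark.parametrize("S0", [1.0, 5.0, 40.0])
    def test_full_ode_near_closed_form_in_excess(self, one_step, S0):
        """With >= 10x ligand excess the PFO formula holds to ~E0/S0 relative."""
        p = RateParameterSet({"k1": 0.1, "k-1": 1.0})
        E0 = S0 / 20.0
        t = np.linspace(0, 40.0 / (0.1 * S0 + 1.0), 300)
        traj = integrate_scheme(one_step, p, {"E": E0, "S": S0}, t)
        expected = pfo_closed_form(t, 0.1, 1.0, E0, S0)
        amp = expected[-1]
        assert np.max(np.abs(traj["ES"] - expected)) / amp < 2.5 * E0 / S0

    def test_ternary_relaxes_to_equilibrium(self, ternary, ternary_params):
        """Long-time ODE state satisfies every reaction's equilibrium ratio."""
        totals = {"E": 0.05, "I": 200.0, "A": 500.0}
        t = np.linspace(0, 10.0, 50)  # ~120 slow-relaxation times
        traj = integrate_scheme(
            ternary, ternary_params, {"E": 0.05, "I": 200.0, "A": 500.0}, t,
            method="BDF", rtol=1e-10, atol=1e-14,
        )
        end = {n: v[-1] for n, v in traj.items()}
        for rxn in ternary.reactions:
            q = np.prod([end[n] for n in rxn.products]) / np.prod(
                [end[n] for n in rxn.reactants]
            )
            keq = ternary_params[rxn.kf_name] / ternary_params[rxn.kr_name]
            assert q == pytest.approx(keq, rel=1e-6)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        logk2=st.floats(0, 2), logkm2=st.floats(2, 4),
        logk4=st.floats(0, 2), logkm4=st.floats(0, 2),
        e0=st.floats(0.01, 1.0), i0=st.floats(50, 500), a0=st.floats(50, 1000),
    )
    def test_conservation_property(self, ternary, logk2, logkm2, logk4, logkm4, e0, i0, a0):
        """Conserved totals stay constant to <= 1e-8 relative at all times."""
        p = RateParameterSet(
            {
                "k2": 10**logk2, "k-2": 10**logkm2,
                "k3": 10**logk2, "k-3": 10**logkm2,
                "k4": 10**logk4, "k-4": 10**logkm4,
            }
        )
        t = np.geomspace(1e-4, 1.0, 40)
        traj = integrate_scheme(ternary, p, {"E": e0, "I": i0, "A": a0}, t)
        vecs = ternary.conservation_vectors()
        totals = {"E": e0, "I": i0, "A": a0}
        X = np.array([traj[n] for n in ternary.names])
        for m, v in vecs.items():
            drift = np.abs(v @ X - totals[m]) / totals[m]
            assert np.max(drift) < 1e-8

    def test_negative_initial_rejected(self, one_step, if_params):
        with pytest.raises(ValidationError):
            integrate_scheme(
                one_step, RateParameterSet({"k1": 1, "k-1": 1}),
                {"E": -1.0, "S": 1.0}, np.linspace(0, 1, 10),
            )


class TestEquilibrium:
    def test_one_step_quadratic_root(self, one_step):
        """E0 = L0 = KD = 1 uM has the closed-form bound fraction (3-sqrt(5))/2."""
        eq = equilibrium_state(
            one_step, RateParameterSet({"k1": 1.0, "k-1": 1.0}), {"E": 1.0, "S": 1.0}
        )
        assert eq["ES"] == pytest.approx((3 - math.sqrt(5)) / 2, abs=1e-9)

    def test_no_binding_limit(self, one_step):
        eq = equilibrium_state(
            one_step, RateParameterSet({"k1": 0.0, "k-1": 1.0}), {"E": 1.0, "S": 1.0}
        )
        assert eq["ES"] == 0.0 and eq["S"] == pytest.approx(1.0)

    def test_irreversible_reaction_rejected(self, one_step):
        with pytest.raises(EquilibriumError, match="irreversible"):
            equilibrium_state(
                one_step, RateParameterSet({"k1": 1.0, "k-1": 0.0}), {"E": 1.0, "S": 1.0}
            )

    def test_ternary_cycle_closure(self, ternary, ternary_params):
        """Shared binding constants make the thermodynamic cycle exactly consistent."""
        eq = equilibrium_state(ternary, ternary_params, {"E": 0.1, "I": 30.0, "A": 100.0})
        lhs = (eq["EI"] / (eq["E"] * eq["I"])) * (eq["EIA"] / (eq["EI"] * eq["A"]))
        rhs = (eq["EA"] / (eq["E"] * eq["A"])) * (eq["EIA"] / (eq["EA"] * eq["I"]))
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_inconsistent_cycle_detected(self):
        s = build_scheme("TERNARY", tied=False)
        p = RateParameterSet(
            {
                "k2": 100.0, "k-2": 5000.0, "k3": 100.0, "k-3": 20000.0,
                "k2b": 100.0, "k-2b": 500.0,  # breaks detailed balance around the cycle
                "k3b": 100.0, "k-3b": 20000.0, "k4": 50.0, "k-4": 12.0,
            }
        )
        with pytest.raises(EquilibriumError, match="detailed balance"):
            equilibrium_state(s, p, {"E": 0.1, "I": 10.0, "A": 10.0})


class TestRelaxationRates:
    def test_one_step_linear_law(self, if_params):
        p = RateParameterSet({"k1": 0.1, "k-1": 1.0})
        assert relaxation_rates_pfo("ONE_STEP", p, 10.0) == pytest.approx([2.0])

    def test_one_step_monotone_in_ligand(self):
        p = RateParameterSet({"k1": 0.05, "k-1": 4.0})
        rates = [relaxation_rates_pfo("ONE_STEP", p, L)[0] for L in (0.5, 1, 5, 20, 40)]
        assert np.all(np.diff(rates) > 0)

    def test_induced_fit_matches_numpy_eigenvalues(self, if_params):
        """Independent 2x2 eigenvalue oracle built directly in the test."""
        L = 10.0
        k1, km1, kc, kmc = 10.0, 100.0, 40.0, 2.0
        A = np.array([[-(k1 * L + km1 + kc), -(k1 * L) + kmc], [kc, -kmc]])
        expected = sorted(np.abs(np.linalg.eigvals(A)), reverse=True)
        got = relaxation_rates_pfo("INDUCED_FIT", if_params, L)
        assert got == pytest.approx(expected, rel=1e-12)
        # the slow eigenvalue sits below the rapid-equilibrium hyperbola
        assert got[1] < kobs_hyperbolic(if_params, L)

    def test_rapid_equilibrium_limit(self):
        """Slow eigenvalue within 2% of the hyperbola once binding is >= 50x faster."""
        p = RateParameterSet({"k1": 1000.0, "k-1": 10000.0, "kconf": 40.0, "k-conf": 2.0})
        for S in (0.5, 5.0, 40.0):
            slow = relaxation_rates_pfo("INDUCED_FIT", p, S)[1]
            assert (p["k1"] * S + p["k-1"]) >= 50 * (p["kconf"] + p["k-conf"])
            assert slow == pytest.approx(kobs_hyperbolic(p, S), rel=0.02)

    def test_induced_fit_slow_rate_bounded_and_increasing(self, if_params):
        slows = [relaxation_rates_pfo("INDUCED_FIT", if_params, L)[1] for L in
                 (0.0, 1.0, 5.0, 20.0, 100.0, 1000.0)]
        assert np.all(np.diff(slows) > 0)
        assert slows[-1] < if_params["kconf"] + if_params["k-conf"]

    def test_zero_ligand_rate_product(self, if_params):
        """At L = 0 the eigenvalue product equals k-1 * k-conf exactly."""
        fast, slow = relaxation_rates_pfo("INDUCED_FIT", if_params, 0.0)
        assert fast * slow == pytest.approx(if_params["k-1"] * if_params["k-conf"], rel=1e-10)

    def test_negative_ligand_rejected(self, if_params):
        with pytest.raises(ValidationError):
            relaxation_rates_pfo("INDUCED_FIT", if_params, -1.0)


class TestKobsHyperbolic:
    def test_limits_and_midpoint(self, if_params):
        assert kobs_hyperbolic(if_params, 0.0) == pytest.approx(2.0)
        assert kobs_hyperbolic(if_params, 1e12) == pytest.approx(42.0)
        assert kobs_hyperbolic(if_params, 10.0) == pytest.approx(22.0)

    def test_saturating_monotone(self, if_params):
        S = np.geomspace(0.01, 1e6, 50)
        k = np.array([kobs_hyperbolic(if_params, s) for s in S])
        assert np.all(np.diff(k) > 0) and k[-1] <= 42.0


class TestProjectObservable:
    def _traj(self, kobs, t_end=0.05, n=2000):
        t = np.linspace(0, t_end, n)
        return t, {"ES": 1.0 - np.exp(-kobs * t)}

    def test_zero_dead_time_identity(self):
        t, traj = self._traj(5.0)
        obs = ObservableModel(0.5, {"ES": 2.0}, dead_time=0.0)
        tr = project_observable(t, traj, obs)
        assert tr.time.size == t.size
        assert np.allclose(tr.signal, 0.5 + 2.0 * traj["ES"])

    def test_fast_transient_flagged_obscured(self):
        """kobs = 1000 /s loses 1 - e^-2 ~ 86.5% of its amplitude in 2 ms."""
        t, traj = self._traj(1000.0, t_end=0.02, n=20000)
        obs = ObservableModel(0.0, {"ES": -1.0}, dead_time=0.002)
        tr = project_observable(t, traj, obs)
        assert tr.dead_time_obscured
        assert tr.time[0] >= 0.002
        remaining = abs(tr.signal[-1] - tr.signal[0]) / abs(traj["ES"][-1])
        assert remaining == pytest.approx(math.exp(-2.0), rel=1e-2)

    def test_slow_transient_not_flagged(self):
        t, traj = self._traj(1.0, t_end=5.0)
        obs = ObservableModel(0.0, {"ES": -1.0}, dead_time=0.002)
        assert not project_observable(t, traj, obs).dead_time_obscured

    def test_unknown_species_rejected(self):
        t, traj = self._traj(5.0)
        with pytest.raises(ValidationError, match="unknown"):
            project_observable(t, traj, ObservableModel(0.0, {"nope": 1.0}))


def test_linear_propagator_matches_ode(ternary, ternary_params):
    """PFO linear propagation agrees with the full ODE to the depletion scale."""
    free = {"I": 200.0, "A": 500.0}
    states, A = pfo_rate_matrix(ternary, ternary_params, free)
    x0 = np.zeros(len(states))
    x0[states.index("E")] = 0.05
    t = np.linspace(1e-4, 0.2, 100)
    X = propagate_linear(A, x0, t)
    traj = integrate_scheme(
        ternary, ternary_params, {"E": 0.05, "I": 200.0, "A": 500.0}, t,
        method="BDF", rtol=1e-10, atol=1e-14,
    )
    for i, n in enumerate(states):
        assert np.max(np.abs(X[:, i] - traj[n])) < 5e-6  # ~E0/L0 * E0
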