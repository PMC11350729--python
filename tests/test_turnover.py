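"""Steady-state (Michaelis-Menten), single-turnover and rate-limiting analysis."""

import math

import numpy as np
import pytest

from hisfkin.synthetic import default_turnover_params, gen_progress_curves
from hisfkin.turnover import (
    AssayConstants,
    MMResult,
    ProgressCurve,
    STResult,
    absorbance_to_velocity,
    diagnose_rate_limiting,
    extract_steady_velocity,
    fit_michaelis_menten,
    fit_single_turnover,
    kcat_upper_limit,
    propagate_kcat_over_km,
)
from hisfkin.util import DegenerateDataError, IdentifiabilityWarning, ValidationError


class TestAbsorbanceToVelocity:
    def test_reported_example(self):
        """The printed slope-to-velocity conversion: 1.08231e-3 A/s -> 0.192 uM/s."""
        assert absorbance_to_velocity(1.08231e-3) == pytest.approx(0.192, rel=1e-3)

    def test_unit_identity(self):
        assert absorbance_to_velocity(5.637e-3) == pytest.approx(1.0)

    def test_zero(self):
        assert absorbance_to_velocity(0.0) == 0.0

    def test_round_trip_linear(self):
        c = AssayConstants()
        for v in (0.01, 0.2, 3.0):
            assert absorbance_to_velocity(v * c.d_eps300_uM) == pytest.approx(v)


class TestSteadyVelocity:
    def test_pure_linear_depletion(self):
        t = np.linspace(0, 5, 200)
        a300 = 0.1 - 0.2 * 0.005637 * t  # 0.2 uM/s depletion
        c = ProgressCurve(t, a300, e_tot=0.1, s0=50.0, mode="multiple_turnover")
        v, se = extract_steady_velocity(c, burst_exclusion=False)
        assert v == pytest.approx(0.2, rel=1e-10)

    def test_planted_burst_recovered_within_1pct(self):
        t = np.linspace(0, 5, 400)
        a300 = 0.1 - 0.2 * 0.005637 * t + 0.05 * np.exp(-30.0 * t)
        c = ProgressCurve(t, a300, e_tot=0.1, s0=50.0, mode="multiple_turnover")
        v, se = extract_steady_velocity(c)
        assert v == pytest.approx(0.2, rel=0.01)

    def test_control_curve_flat(self):
        curves, _ = gen_progress_curves("control", s0_list=(10.0,), seed=7, sigma=0.0005)
        v, se = extract_steady_velocity(curves[0])
        assert abs(v) < 3 * max(se, 1e-4)

    def test_short_window_rejected(self):
        t = np.linspace(0, 1, 12)
        c = ProgressCurve(t, 0.1 - 1e-3 * t, e_tot=0.1, s0=0.01, mode="multiple_turnover")
        with pytest.raises(DegenerateDataError):
            extract_steady_velocity(c)


class TestMichaelisMenten:
    S = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 40.0])

    def test_generative_recovery(self):
        """kcat = 2.4 /s, KM = 4.5 uM (wild-type-like) recovered exactly."""
        v = 2.4 * 0.1 * self.S / (4.5 + self.S)
        mm = fit_michaelis_menten(np.c_[self.S, v], e_tot=0.1)
        assert mm.kcat == pytest.approx(2.4, rel=1e-6)
        assert mm.km == pytest.approx(4.5, rel=1e-6)

    def test_saturation_gives_kcat(self):
        v = 2.4 * 0.1 * self.S / (0.01 + self.S)
        mm = fit_michaelis_menten(np.c_[self.S, v], e_tot=0.1)
        assert mm.kcat == pytest.approx(2.4, rel=1e-4)

    def test_noisy_recovery_within_10pct(self, rng):
        v = 2.4 * 0.1 * self.S / (4.5 + self.S)
        vn = v * (1 + 0.05 * rng.standard_normal(v.size))
        mm = fit_michaelis_menten(np.c_[self.S, vn, 0.05 * v], e_tot=0.1)
        assert mm.kcat == pytest.approx(2.4, rel=0.10)
        assert mm.km == pytest.approx(4.5, rel=0.25)

    def test_all_zero_velocities_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_michaelis_menten(np.c_[self.S, np.zeros_like(self.S)], e_tot=0.1)

    def test_km_outside_range_warns(self):
        v = 2.4 * 0.1 * self.S / (1000.0 + self.S)
        with pytest.warns(IdentifiabilityWarning):
            fit_michaelis_menten(np.c_[self.S, v], e_tot=0.1)


class TestPropagation:
    def test_unit_case(self):
        v, se = propagate_kcat_over_km(1.0, 0.0, 1.0, 0.0)
        assert v == pytest.approx(1e6) and se == 0.0

    def test_wild_type_row(self):
        v, se = propagate_kcat_over_km(2.4, 0.2, 4.5, 0.5)
        assert v == pytest.approx(5.333e5, rel=1e-3)
        assert se == pytest.approx(7.41e4, rel=1e-2)

    def test_f23a_row_formula_value(self):
        # frozen from the propagation formula itself
        v, se = propagate_kcat_over_km(5.5e-3, 0.4e-3, 6.8, 1.3)
        assert v == pytest.approx(808.8, rel=1e-3)
        assert se == pytest.approx(165.4, rel=1e-2)

    def test_relative_error_quadrature(self):
        v, se = propagate_kcat_over_km(2.0, 0.2, 10.0, 1.0)
        assert se / v == pytest.approx(math.sqrt(0.01 + 0.01))


class TestKcatUpperLimit:
    def test_reported_bound(self):
        """No turnover seen at 0.1 uM enzyme -> kcat < 2e-3 /s for v_detect = 2e-4."""
        assert kcat_upper_limit(2.0e-4, 0.1) == pytest.approx(2.0e-3)

    def test_doubling_enzyme_halves_bound(self):
        assert kcat_upper_limit(1e-4, 0.2) == pytest.approx(kcat_upper_limit(1e-4, 0.1) / 2)

    def test_zero_detection_warns(self):
        with pytest.warns(UserWarning):
            assert kcat_upper_limit(0.0, 0.1) == 0.0


class TestSingleTurnover:
    def test_exact_decay(self):
        t = np.linspace(0, 3, 150)
        c = ProgressCurve(
            t, 0.3 * np.exp(-2.0 * t) + 0.05, e_tot=20.0, s0=10.0, mode="single_turnover"
        )
        k, se = fit_single_turnover(c)
        assert k == pytest.approx(2.0, rel=1e-8)

    def test_mode_violation(self):
        t = np.linspace(0, 3, 150)
        c = ProgressCurve(
            t, np.exp(-t), e_tot=5.0, s0=10.0, mode="single_turnover"
        )
        with pytest.raises(ValidationError, match="mode violation"):
            fit_single_turnover(c)

    def test_kobs_flat_across_substrate(self):
        """Substrate-independent chemistry: kobs varies < 2% over S0 = 2.5-10 uM."""
        curves, _ = gen_progress_curves("single_turnover", seed=4, sigma=0.0)
        ks = [fit_single_turnover(c)[0] for c in curves]
        st = STResult([c.s0 for c in curves], ks, [0.0] * len(ks))
        assert st.flatness < 0.02


class TestDiagnosis:
    def _mm(self, kcat):
        return MMResult(kcat=kcat, kcat_se=0.1 * kcat, km=4.5, km_se=0.5, ssr=0.0, n_points=6)

    def test_equal_rates_chemistry_limited(self):
        st = STResult([2.5, 5.0, 10.0], [2.4, 2.4, 2.4], [0.1] * 3)
        d = diagnose_rate_limiting(self._mm(2.4), st)
        assert d["verdict"] == "chemistry rate-limiting"
        assert d["ratio"] == pytest.approx(1.0)

    def test_fast_st_release_limited(self):
        st = STResult([2.5, 5.0, 10.0], [24.0, 24.0, 24.0], [0.5] * 3)
        d = diagnose_rate_limiting(self._mm(2.4), st)
        assert "product release" in d["verdict"]

    def test_full_cycle_simulation_chemistry_limited(self):
        """Chemistry 10x slower than binding/release: ST kobs ~ kcat within 5%."""
        mt, _ = gen_progress_curves("multiple_turnover", seed=3, sigma=0.0005)
        pts = [(c.s0, *extract_steady_velocity(c)) for c in mt]
        mm = fit_michaelis_menten(pts, e_tot=0.1)
        stc, _ = gen_progress_curves("single_turnover", seed=4, sigma=0.0005)
        ks = [fit_single_turnover(c) for c in stc]
        st = STResult([c.s0 for c in stc], [k for k, _ in ks], [s for _, s in ks])
        d = diagnose_rate_limiting(mm, st)
        assert d["verdict"] == "chemistry rate-limiting"
        assert st.mean_kobs == pytest.approx(mm.kcat, rel=0.05)

    def test_full_cycle_simulation_release_limited(self):
        """Product release 10x slower than chemistry flips the verdict."""
        p = dict(default_turnover_params())
        p["krel"] = p["kchem"] / 10.0
        mt, _ = gen_progress_curves("multiple_turnover", params=p, seed=5, sigma=0.0005)
        mm = fit_michaelis_menten(
            [(c.s0, *extract_steady_velocity(c)) for c in mt], e_tot=0.1
        )
        stc, _ = gen_progress_curves("single_turnover", params=p, seed=6, sigma=0.0005)
        ks = [fit_single_turnover(c) for c in stc]
        st = STResult([c.s0 for c in stc], [k for k, _ in ks], [s for _, s in ks])
        d = diagnose_rate_limiting(mm, st)
        assert "product release" in d["verdict"]
        assert d["ratio"] > 3
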