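"""Generator determinism, noise calibration and round-trip identities."""

import numpy as np
import pytest
from scipy import stats

from hisfkin.synthetic import (
    AmmoniaSpec,
    free_ammonia,
    gen_progress_curves,
    gen_secondary_plot,
    gen_ternary_dataset,
    gen_titration_series,
    gen_transient_series,
)
from hisfkin.transient import fit_exponential
from hisfkin.util import ValidationError


class TestFreeAmmonia:
    def test_study_buffer(self):
        """100 mM ammonium acetate at pH 8.5 leaves ~14.5 mM free NH3."""
        nh3 = free_ammonia(AmmoniaSpec(100.0, 8.5, 9.27))
        assert nh3 == pytest.approx(14.52, rel=1e-3)
        assert abs(nh3 - 14.4) / 14.4 < 0.01

    def test_half_at_pka(self):
        assert free_ammonia(AmmoniaSpec(80.0, 9.27, 9.27)) == pytest.approx(40.0)

    def test_high_ph_limit(self):
        assert free_ammonia(AmmoniaSpec(100.0, 13.9, 9.27)) == pytest.approx(100.0, rel=1e-3)

    def test_invalid_ph_rejected(self):
        with pytest.raises(ValidationError):
            AmmoniaSpec(100.0, 15.0, 9.27)


class TestDeterminism:
    def test_transients_bit_identical(self):
        a, ta = gen_transient_series(seed=42, n_points=100)
        b, tb = gen_transient_series(seed=42, n_points=100)
        for x, y in zip(a, b):
            assert np.array_equal(x.signal, y.signal)
        assert ta.to_dict() == tb.to_dict()

    def test_different_seeds_differ(self):
        a, _ = gen_transient_series(seed=1, n_points=100)
        b, _ = gen_transient_series(seed=2, n_points=100)
        assert not np.array_equal(a[0].signal, b[0].signal)

    def test_ternary_and_titration_deterministic(self):
        a, _ = gen_ternary_dataset(seed=3, n_points=60)
        b, _ = gen_ternary_dataset(seed=3, n_points=60)
        assert all(np.array_equal(x.signal, y.signal) for x, y in zip(a, b))
        sa, _ = gen_titration_series(seed=4, sigma=0.01)
        sb, _ = gen_titration_series(seed=4, sigma=0.01)
        assert np.array_equal(sa.fluorescence, sb.fluorescence)


class TestNoiseModel:
    def test_zero_sigma_is_noiseless_projection(self):
        a, _ = gen_transient_series(seed=5, sigma=0.0, n_points=120)
        b, _ = gen_transient_series(seed=6, sigma=0.0, n_points=120)
        for x, y in zip(a, b):
            assert np.array_equal(x.signal, y.signal)

    def test_noise_variance_matches_sigma(self):
        """Realized noise variance passes a chi-square check at alpha = 0.01."""
        sigma, n_avg = 0.004, 1
        noisy, truth = gen_transient_series(
            seed=7, sigma=sigma, n_average=n_avg, concs=(10.0,), n_points=10000
        )
        clean, _ = gen_transient_series(
            seed=8, sigma=0.0, n_average=n_avg, concs=(10.0,), n_points=10000
        )
        resid = noisy[0].signal - clean[0].signal
        n = resid.size
        chi2 = np.sum(resid**2) / sigma**2
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n)
        assert lo < chi2 < hi
        assert abs(np.mean(resid)) < 4 * sigma / np.sqrt(n)

    def test_replicate_mean_converges_to_clean_trace(self):
        """Mean of 200 noisy replicates approaches the noiseless trace pointwise."""
        clean, _ = gen_transient_series(seed=0, sigma=0.0, concs=(5.0,), n_points=60)
        sigma = 0.01
        acc = np.zeros_like(clean[0].signal)
        for r in range(200):
            ts, _ = gen_transient_series(
                seed=1000 + r, sigma=sigma, n_average=1, concs=(5.0,), n_points=60
            )
            acc += ts[0].signal
        mean = acc / 200
        tol = 4 * sigma / np.sqrt(200)  # pointwise, generous multiplier
        assert np.max(np.abs(mean - clean[0].signal)) < tol


class TestTernaryDataset:
    def test_sixteen_traces(self):
        ts, truth = gen_ternary_dataset(seed=1, n_points=60)
        assert len(ts) == 16
        assert truth.design["n_traces"] == 16

    def test_binary_only_traces_obscured(self):
        """Binary-complex formation at k2*[I] > 1000/s completes in the dead time."""
        ts, _ = gen_ternary_dataset(seed=1, n_points=400)
        only_binary = [
            tr for tr in ts
            if tr.label.startswith(("E+I", "E+A")) and tr.label.count("+") == 1
        ]
        assert len(only_binary) == 4
        assert all(tr.dead_time_obscured for tr in only_binary)
        ternary_traces = [tr for tr in ts if not any(tr is b for b in only_binary)]
        assert all(not tr.dead_time_obscured for tr in ternary_traces)

    def test_times_start_after_dead_time(self):
        ts, _ = gen_ternary_dataset(seed=1, n_points=60)
        assert all(tr.time[0] >= tr.dead_time for tr in ts)


class TestProgressCurves:
    def test_control_has_no_net_depletion(self):
        curves, _ = gen_progress_curves("control", s0_list=(10.0,), seed=2, sigma=0.0)
        c = curves[0]
        late = c.values[c.time > 0.5]  # after the mixing artifact has decayed
        assert np.ptp(late) < 1e-6

    def test_chemistry_limited_vmax(self):
        """kchem << release: v/E at saturating substrate equals kchem within 2%."""
        p = {"kon": 10.0, "koff": 20.0, "kchem": 2.0, "krel": 200.0, "kpon": 0.1}
        curves, _ = gen_progress_curves(
            "multiple_turnover", s0_list=(400.0,), params=p, e_tot=0.1,
            sigma=0.0, burst={"amp": 0.0, "rate": 30.0},
        )
        from hisfkin.turnover import extract_steady_velocity

        v, _ = extract_steady_velocity(curves[0], burst_exclusion=False)
        assert v / 0.1 == pytest.approx(2.0, rel=0.02)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValidationError):
            gen_progress_curves("bogus")


class TestRoundTrips:
    def test_transient_noiseless_kobs_recovery(self, if_params):
        """sigma = 0 transients refit to >= 4 significant digits in kobs."""
        from hisfkin.dynamics import relaxation_rates_pfo

        ts, _ = gen_transient_series(seed=0, sigma=0.0, concs=(5.0, 20.0), n_points=300)
        for tr, S in zip(ts, (5.0, 20.0)):
            fit = fit_exponential(tr, 2)
            expected = relaxation_rates_pfo("INDUCED_FIT", if_params, S)
            assert fit.rates[1] == pytest.approx(expected[1], rel=1e-4)

    def test_secondary_plot_noiseless_identity(self):
        pts, params = gen_secondary_plot("ONE_STEP", noise_frac=0.0, seed=0)
        slope = np.polyfit(pts[:, 0], pts[:, 1], 1)
        assert slope[0] == pytest.approx(params["k1"], rel=1e-9)
        assert slope[1] == pytest.approx(params["k-1"], rel=1e-9)

    def test_titration_noiseless_kd_recovery(self):
        import warnings

        from hisfkin.titration import fit_binding_isotherm

        ser, truth = gen_titration_series(ligand="I", protein_conc=0.2, sigma=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_binding_isotherm(ser)
        assert fit.kd_app == pytest.approx(50.0, rel=5e-3)  # k-2/k2 (+tiny receptor depletion)
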