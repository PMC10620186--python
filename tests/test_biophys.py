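"""Binding fits and the cooperative ternary-equilibrium model."""

import numpy as np
import pytest

from heliscreen.biophys import (
    BindingIsotherm,
    TernarySystem,
    biphasic,
    fit_4pl,
    fit_biphasic,
    fit_steady_state,
    four_pl,
    percent_ternary,
    solve_ternary,
    steady_state_model,
    ternary_signal,
)


class TestSteadyState:
    def test_noiseless_parameter_recovery(self):
        # generator setting mirrors a mid-nanomolar binder (530 nM)
        kd, rmax = 530.0, 120.0
        conc = np.array([25, 75, 200, 530, 1500, 4000, 12000], dtype=float)
        iso = BindingIsotherm(conc, steady_state_model(conc, kd, rmax))
        res = fit_steady_state(iso)
        assert res.converged
        assert res.params["kd"] == pytest.approx(kd, rel=1e-6)
        assert res.params["rmax"] == pytest.approx(rmax, rel=1e-6)

    def test_response_at_kd_is_half_max(self):
        assert steady_state_model(np.array([530.0]), 530.0, 100.0)[0] == pytest.approx(50.0)

    def test_all_zero_response_flagged(self):
        iso = BindingIsotherm(np.array([1.0, 10, 100, 1000]), np.zeros(4))
        res = fit_steady_state(iso)
        assert res.params["rmax"] == 0.0
        assert "kd_unidentifiable" in res.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_steady_state(BindingIsotherm(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])))


class TestPercentTernary:
    def test_observed_equals_expected_is_100(self):
        assert percent_ternary(60.0, 300.0, 25000, 2500, 2500) == pytest.approx(100.0)

    def test_zero_observed_is_zero(self):
        assert percent_ternary(0.0, 300.0, 25000, 2500, 2500) == 0.0

    def test_direct_formula(self):
        # R_immob 100, (MW_H + MW_analyte)/MW_immob = 2, Rmax_obs 130 -> 65%
        assert percent_ternary(130.0, 100.0, 25000, 20000, 30000) == pytest.approx(65.0)

    def test_linear_in_observed_and_scale_invariant(self):
        base = percent_ternary(40.0, 100.0, 25000, 2500, 22500)
        assert percent_ternary(80.0, 100.0, 25000, 2500, 22500) == pytest.approx(2 * base)
        rescaled = percent_ternary(40.0 * 3, 100.0 * 3, 25000, 2500, 22500)
        assert rescaled == pytest.approx(base)

    def test_zero_immobilized_mw_raises(self):
        with pytest.raises(ValueError):
            percent_ternary(1.0, 1.0, 0.0, 1.0, 1.0)


class TestFourPL:
    def test_noiseless_parameter_recovery(self):
        dose = np.logspace(-1, 4, 12)
        truth = dict(bottom=5.0, top=90.0, ec50=150.0, hill=1.3)
        res = fit_4pl(dose, four_pl(dose, **truth))
        assert res.converged
        for k, v in truth.items():
            assert res.params[k] == pytest.approx(v, rel=1e-6)

    def test_signal_at_ec50_is_midpoint(self):
        y = four_pl(np.array([150.0]), 10.0, 90.0, 150.0, 2.0)
        assert y[0] == pytest.approx(50.0)

    def test_descending_data_gets_negative_hill(self):
        dose = np.logspace(-1, 3, 9)
        res = fit_4pl(dose, four_pl(dose, 100.0, 5.0, 50.0, 1.0))
        # top < bottom with positive hill is the same curve as descending
        fitted = four_pl(dose, **res.params)
        assert fitted[0] > fitted[-1]


class TestBiphasic:
    def test_hook_peak_recovered_from_ternary_model(self):
        """Dose curves simulated from the alpha=1 bifunctional model are
        bell-shaped and the fitted peak lands within 20% of the true one."""
        doses = np.logspace(-1, 5, 25)
        signal = ternary_signal(doses, 100, 100, 50, 50, 1.0)
        true_peak = doses[np.argmax(signal)]
        res = fit_biphasic(doses, signal)
        assert res.converged and "monotone_fallback_4pl" not in res.flags
        assert res.params["peak_dose"] == pytest.approx(true_peak, rel=0.2)

    def test_symmetric_bell_peaks_at_geometric_mean(self):
        dose = np.logspace(-2, 4, 200)
        y = biphasic(dose, 0.0, 1.0, 10.0, 1000.0, 1.5)
        assert dose[np.argmax(y)] == pytest.approx(np.sqrt(10.0 * 1000.0), rel=0.05)

    def test_monotone_data_falls_back_to_4pl(self):
        dose = np.logspace(-1, 3, 10)
        res = fit_biphasic(dose, four_pl(dose, 0.0, 1.0, 30.0, 1.0))
        assert "monotone_fallback_4pl" in res.flags


class TestSolveTernary:
    def test_mass_balance_on_random_systems(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            sysm = TernarySystem(
                a_total=rng.uniform(1, 1e4),
                t_total=rng.uniform(1, 1e4),
                h_total=rng.uniform(1, 1e4),
                k_ah=rng.uniform(1, 1e4),
                k_th=rng.uniform(1, 1e4),
                alpha=10 ** rng.uniform(-1, 3),
            )
            sp = solve_ternary(sysm)
            assert sp["A"] + sp["AH"] + sp["ATH"] == pytest.approx(sysm.a_total, rel=1e-9)
            assert sp["T"] + sp["TH"] + sp["ATH"] == pytest.approx(sysm.t_total, rel=1e-9)
            assert sp["H"] + sp["AH"] + sp["TH"] + sp["ATH"] == pytest.approx(
                sysm.h_total, rel=1e-9
            )
            assert sp["AH"] == pytest.approx(sp["A"] * sp["H"] / sysm.k_ah, rel=1e-6)
            assert sp["ATH"] == pytest.approx(
                sysm.alpha * sp["A"] * sp["T"] * sp["H"] / (sysm.k_ah * sysm.k_th), rel=1e-6
            )

    def test_grid_search_oracle(self):
        """The solver agrees with a dense brute-force grid over free H/T."""
        sysm = TernarySystem(80.0, 60.0, 40.0, 25.0, 120.0, 30.0)
        sp = solve_ternary(sysm)
        kah, kth, alpha = sysm.k_ah, sysm.k_th, sysm.alpha

        def total_h(h: float) -> float:
            # independent reconstruction: scan free T densely, pick the value
            # consistent with total T, then rebuild total H
            t = np.linspace(0, sysm.t_total, 200001)
            a = sysm.a_total / (1 + h / kah + alpha * h * t / (kah * kth))
            tot_t = t * (1 + h / kth + alpha * h * a / (kah * kth))
            i = int(np.argmin(np.abs(tot_t - sysm.t_total)))
            return h * (1 + a[i] / kah + t[i] / kth + alpha * a[i] * t[i] / (kah * kth))

        grid = np.linspace(1e-6, sysm.h_total, 4001)
        totals = np.array([total_h(h) for h in grid[::40]])
        h_star = grid[::40][np.argmin(np.abs(totals - sysm.h_total))]
        assert sp["H"] == pytest.approx(h_star, abs=sysm.h_total / 100)

    def test_hook_limit_high_dose_kills_ternary(self):
        low = ternary_signal([100.0], 100, 100, 50, 50, 1.0)[0]
        huge = ternary_signal([1e8], 100, 100, 50, 50, 1.0)[0]
        assert huge < low / 100

    def test_bell_vs_cooperative_monotone(self):
        doses = 1e4 / 3.0 ** np.arange(10, -1, -1)  # 11-pt 3-fold series, top 10 uM
        hook = ternary_signal(doses, 100, 100, 100, 100, 1.0)
        assert 0 < np.argmax(hook) < len(doses) - 1  # interior peak: bell
        coop = ternary_signal(doses, 1e3, 1e3, 1000, 1e5, 500.0)
        assert np.all(np.diff(coop) >= -1e-9)  # non-decreasing across range

    def test_alpha_raises_ternary_occupancy(self):
        weak = ternary_signal([50.0], 100, 100, 200, 200, 1.0)[0]
        strong = ternary_signal([50.0], 100, 100, 200, 200, 100.0)[0]
        assert strong > weak
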