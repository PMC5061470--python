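"""Single-site ITC: displacement bookkeeping, isotherm, fitting, thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from bromobind import (
    Titration,
    binding_fraction,
    classify_affinity,
    correct_dilution,
    derive_thermodynamics,
    fit_single_site,
    injection_concentrations,
    simulate_injection_heats,
    to_isotherm,
)
from bromobind import simulate as sim
from bromobind.itc import SaturationWarning, default_schedule
from bromobind.reference import bsp_itc_panel


def make_titration(syringe=258.0, cell=20.0, heats=None, volumes=None):
    volumes = default_schedule() if volumes is None else volumes
    heats = np.zeros_like(volumes) if heats is None else heats
    return Titration(
        protein_id="P", compound_id="L", syringe_conc=syringe, cell_conc=cell,
        cell_volume=0.2003, injection_volumes=volumes, temperature=15.0, heats=heats,
    )


class TestInjectionConcentrations:
    def test_schedule_endpoint_displacement(self):
        """Hand-evaluated displacement formulas at the final injection."""
        t = make_titration()
        cell, titrant = injection_concentrations(t)
        dv, v0 = 38.3, 200.3
        assert cell[-1] == pytest.approx(20e-6 * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0)), rel=1e-12)
        assert titrant[-1] == pytest.approx(258e-6 * (dv / v0) / (1 + dv / (2 * v0)), rel=1e-12)
        assert cell.size == 39

    def test_first_injection_near_initial(self):
        t = make_titration()
        cell, titrant = injection_concentrations(t)
        # 0.3 ul into 200.3 ul barely dilutes the cell
        assert cell[0] == pytest.approx(20e-6, rel=2e-3)
        assert titrant[0] > 0

    def test_zero_syringe_concentration_rejected_but_heats_zero(self):
        t = make_titration()
        assert np.all(simulate_injection_heats(1.0, 100.0, 0.0, t) == 0.0)

    def test_overfilled_cell_raises(self):
        t = make_titration(volumes=np.full(40, 6.0))
        with pytest.raises(ValueError, match="overfilled"):
            injection_concentrations(t)


class TestBindingFraction:
    def test_no_titrant_means_no_binding(self):
        assert binding_fraction(20e-6, 0.0, 1.0, 1e8) == 0.0

    def test_stoichiometric_limit(self):
        # infinitely tight binding, sub-stoichiometric titrant
        theta = binding_fraction(20e-6, 10e-6, 1.0, 1e18)
        assert theta == pytest.approx(0.5, rel=1e-8)

    def test_bisection_oracle(self):
        """Mass-action occupancy cross-checked by bisection on K_B = B / ((M-B)(X-B))."""
        cell, titrant, n, kd = 20e-6, 10e-6, 1.0, 41.8e-9
        kb = 1.0 / kd
        sites = n * cell

        def f(bound):
            return kb * (sites - bound) * (titrant - bound) - bound

        bound = bisect(f, 0.0, min(sites, titrant), xtol=1e-22)
        assert binding_fraction(cell, titrant, n, kb) == pytest.approx(bound / sites, abs=1e-10)

    @given(
        cell=st.floats(1e-7, 1e-3),
        ratio=st.floats(0.01, 10.0),
        n=st.floats(0.5, 2.0),
        kd=st.floats(1e-10, 1e-3),
    )
    @settings(deadline=None, max_examples=300)
    def test_occupancy_bounds_and_oracle(self, cell, ratio, n, kd):
        titrant = ratio * cell
        theta = float(binding_fraction(cell, titrant, n, 1.0 / kd))
        assert 0.0 <= theta <= 1.0
        bound = theta * n * cell
        assert bound <= min(titrant, n * cell) * (1 + 1e-9)


class TestSimulatedHeats:
    def test_zero_enthalpy_zero_heats(self):
        t = make_titration()
        assert np.all(simulate_injection_heats(1.0, 41.8, 0.0, t) == 0.0)

    def test_tight_binding_step_isotherm(self):
        t = make_titration()
        heats = simulate_injection_heats(1.0, 1e-6, -10.0, t)  # kd = 1e-15 M
        iso = to_isotherm(make_titration(heats=heats), heats[1:])
        before = iso.ndh[iso.molar_ratio < 0.9]
        after = iso.ndh[iso.molar_ratio > 1.2]
        assert np.allclose(before, -10.0, rtol=0.02)
        assert np.all(np.abs(after) < 0.3)

    def test_panel_run_saturates_before_final_injection(self, brd4_titration):
        titration, _ = brd4_titration
        cell, titrant = injection_concentrations(titration)
        theta = binding_fraction(cell[-1], titrant[-1], 0.94, 1.0 / 41.8e-9)
        assert theta > 0.99

    def test_heat_conservation_tight_binding(self):
        t = make_titration()
        heats = simulate_injection_heats(1.0, 1e-3, -10.0, t)
        total = heats.sum()
        expected = 1.0 * 20e-6 * 0.2003e-3 * -10.0 * 1e9
        assert total == pytest.approx(expected, rel=0.05)

    def test_smaller_kd_steepens_isotherm(self):
        t = make_titration()
        steepness = []
        for kd in (1000.0, 100.0, 10.0):
            heats = simulate_injection_heats(1.0, kd, -10.0, t)
            iso = to_isotherm(make_titration(heats=heats), heats[1:])
            steepness.append(np.max(np.abs(np.diff(iso.ndh))))
        assert steepness[0] <= steepness[1] <= steepness[2]


class TestDilutionCorrection:
    def test_constant_per_ul_offset_fully_removed(self):
        volumes = default_schedule()
        heats = 0.5 * volumes
        corrected, baseline = correct_dilution(heats, volumes)
        assert baseline == pytest.approx(0.5, rel=1e-12)
        assert np.allclose(corrected, 0.0, atol=1e-12)

    def test_offset_recovered_on_synthetic_titration(self):
        titration, truth = sim.gen_titration(
            0.94, 41.8, -11.09, dilution_offset=0.5, noise_sd=0.0
        )
        _, baseline = correct_dilution(titration.heats, titration.injection_volumes)
        assert baseline == pytest.approx(0.5, rel=0.01)

    def test_single_injection_baseline_convention(self):
        volumes = default_schedule()
        heats = 0.7 * volumes
        _, baseline = correct_dilution(heats, volumes, n_baseline=1)
        assert baseline == pytest.approx(0.7, rel=1e-12)

    def test_unsaturated_titration_warns(self):
        titration, _ = sim.gen_titration(
            1.0, 50_000.0, -10.0, syringe_conc=50.0, cell_conc=20.0, noise_sd=0.0
        )
        with pytest.warns(SaturationWarning):
            correct_dilution(titration.heats, titration.injection_volumes)


class TestSingleSiteFit:
    def test_noiseless_recovery(self, brd4_titration):
        titration, truth = brd4_titration
        fit = fit_single_site(titration)
        p = truth.params
        assert abs(fit.n_sites - p["n_sites"]) / p["n_sites"] < 1e-4
        assert abs(fit.kd - p["kd_nM"]) / p["kd_nM"] < 1e-4
        assert abs(fit.dh - p["dh_kcal"]) / abs(p["dh_kcal"]) < 1e-4
        assert not fit.weak_binding

    def test_round_trip_across_c_range(self):
        """Recovery to < 1e-4 relative error over c in [5, 1000], noiseless."""
        rng = np.random.default_rng(3)
        for i in range(12):
            c = float(np.exp(rng.uniform(np.log(5.0), np.log(1000.0))))
            n_true = float(rng.uniform(0.8, 1.2))
            dh_true = float(rng.uniform(-18.0, -3.0))
            kd_true = n_true * 20.0 * 1e3 / c  # nM
            titration, _ = sim.gen_titration(n_true, kd_true, dh_true, noise_sd=0.0, seed=i)
            fit = fit_single_site(titration)
            assert abs(fit.kd - kd_true) / kd_true < 1e-4, f"c={c:.1f}"
            assert abs(fit.n_sites - n_true) / n_true < 1e-4
            assert abs(fit.dh - dh_true) / abs(dh_true) < 1e-4

    def test_noisy_coverage_and_error_scale(self):
        """With 0.1-ucal noise the fit SD tracks the true error (3-SD coverage)
        and the K_D error stays at the scale the information content allows."""
        errors, covered = [], 0
        runs = sim.gen_titration_ensemble(n_runs=30, seed=11, noise_sd=0.1)
        for titration, truth in runs:
            kd_true = truth.params["kd_nM"]
            fit = fit_single_site(titration)
            errors.append(abs(fit.kd - kd_true) / kd_true)
            if "kd" in fit.param_errors and abs(fit.kd - kd_true) <= 3 * fit.param_errors["kd"]:
                covered += 1
        assert covered >= 0.95 * len(runs) - 1
        assert np.median(errors) < 0.25

    def test_all_zero_heats_flag_weak(self):
        fit = fit_single_site(make_titration())
        assert fit.weak_binding

    def test_thermo_identities_hold_exactly(self, brd4_titration):
        titration, _ = brd4_titration
        fit = fit_single_site(titration)
        assert abs(fit.dg - (fit.dh - fit.tds)) < 1e-12
        t_k = titration.temperature + 273.15
        assert abs(fit.dg - 1.9872e-3 * t_k * np.log(fit.kd * 1e-9)) < 1e-12


class TestThermodynamics:
    @pytest.mark.parametrize(
        "kd_nM, expected_dg",
        [(41.8, -9.73), (8.0, -10.68), (41.7, -9.73), (42.7, -9.72), (4762.0, -7.02)],
    )
    def test_free_energy_from_kd(self, kd_nM, expected_dg):
        dg, _ = derive_thermodynamics(kd_nM, 0.0, 15.0)
        assert round(dg, 2) == expected_dg

    def test_entropy_decomposition(self):
        _, tds = derive_thermodynamics(41.8, -11.09, 15.0)
        assert round(tds, 2) == -1.36

    def test_standard_state(self):
        dg, _ = derive_thermodynamics(1e9, 0.0, 15.0)  # 1 M
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            derive_thermodynamics(0.0, -10.0, 15.0)

    def test_reference_panel_internally_consistent(self):
        """dG = dH - TdS within 0.015 kcal/mol for all quantified panel rows."""
        panel = bsp_itc_panel(include_weak=False)
        assert len(panel) == 25
        gap = (panel["dg_kcal_mol"] - (panel["dh_kcal_mol"] - panel["tds_kcal_mol"])).abs()
        assert gap.max() <= 0.015


class TestAffinityClasses:
    @pytest.mark.parametrize(
        "kd, label",
        [
            (41.8, "<=100 nM"),
            (100.0, "<=100 nM"),  # boundary inclusive
            (500.0, "100 nM-1 uM"),
            (4762.0, "1-10 uM"),
            (25000.0, ">10 uM"),
        ],
    )
    def test_binning(self, kd, label):
        assert classify_affinity(kd) == label

    def test_weak_flag_dominates(self):
        assert classify_affinity(50.0, weak_binding=True) == "weak"


class TestIsotherm:
    def test_zero_heats_zero_ndh(self):
        t = make_titration()
        iso = to_isotherm(t, np.zeros(38))
        assert np.all(iso.ndh == 0.0)
        assert np.all(np.diff(iso.molar_ratio) > 0)

    def test_sigmoid_inflection_near_stoichiometry(self, brd4_titration):
        titration, _ = brd4_titration
        iso = to_isotherm(titration)
        inflection_ratio = iso.molar_ratio[np.argmax(np.abs(np.diff(iso.ndh)))]
        assert inflection_ratio == pytest.approx(0.94, abs=0.15)
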