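"""Two-state melt model, curve fitting and plate-level dTm aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bromobind import (
    MeltCurve,
    delta_tm,
    eval_melt_model,
    fit_melt_curve,
    plate_summary,
    truncate_post_transition,
)
from bromobind.constants import R_KCAL
from bromobind.dsf import grid_sse_minimum
from bromobind import simulate as sim

from conftest import random_melt_spec


class TestMeltModel:
    def test_midpoint_of_flat_baselines(self):
        # logistic symmetry: halfway between baselines at T = Tm
        y = eval_melt_model(50.0, 50.0, 120.0, (1000.0, 0.0), (5000.0, 0.0))
        assert y == pytest.approx(3000.0, abs=1e-9)

    def test_step_function_limit(self):
        # infinitely cooperative unfolding: native value just below Tm
        y = eval_melt_model(49.0, 50.0, 1e8, (1000.0, 0.0), (5000.0, 0.0))
        assert y == pytest.approx(1000.0, abs=1e-6)

    def test_hand_evaluated_point(self):
        # independent evaluation of the sigmoid at Tm + 5 C
        tm_k, t_k = 50.0 + 273.15, 55.0 + 273.15
        dg = 120.0 * (1.0 - t_k / tm_k)
        expected = 1000.0 + 4000.0 / (1.0 + np.exp(dg / (R_KCAL * t_k)))
        assert eval_melt_model(55.0, 50.0, 120.0, (1000.0, 0.0), (5000.0, 0.0)) == pytest.approx(
            expected, rel=1e-12
        )

    @given(
        tm=st.floats(40.0, 80.0),
        dh=st.floats(30.0, 300.0),
        yf=st.floats(100.0, 2000.0),
        yu=st.floats(3000.0, 8000.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_midpoint_identity_property(self, tm, dh, yf, yu):
        y = eval_melt_model(tm, tm, dh, (yf, 0.0), (yu, 0.0))
        assert abs(y - (yf + yu) / 2.0) < 1e-9

    def test_monotone_between_baselines(self):
        T = np.linspace(25, 96, 200)
        y = eval_melt_model(T, 55.0, 100.0, (1000.0, 0.0), (5000.0, 0.0))
        assert np.all(np.diff(y) > 0)
        assert np.all((y >= 1000.0) & (y <= 5000.0))


class TestTruncation:
    def test_monotone_curve_unchanged(self, noiseless_melt_curve):
        out = truncate_post_transition(noiseless_melt_curve)
        assert out.temperatures.size == noiseless_melt_curve.temperatures.size

    def test_post_maximum_decay_removed(self):
        T = np.arange(25.0, 96.0, 0.5)
        y = np.where(T <= 70.0, (T - 25.0) * 50.0, (70.0 - 25.0) * 50.0 - (T - 70.0) * 100.0)
        curve = MeltCurve("A1", "P", None, 0.0, T, y)
        out = truncate_post_transition(curve, margin_c=2.0)
        assert out.temperatures.max() <= 70.0 + 2.0
        # idempotent
        again = truncate_post_transition(out, margin_c=2.0)
        assert again.temperatures.size == out.temperatures.size


class TestMeltFit:
    def test_noiseless_recovery(self, noiseless_melt_curve):
        fit = fit_melt_curve(noiseless_melt_curve)
        assert fit.converged
        assert fit.tm == pytest.approx(50.0, abs=1e-3)
        assert fit.dh_unfold == pytest.approx(120.0, rel=1e-3)

    def test_noisy_tm_error_bounded(self, flat_baseline_spec):
        # sigma = 1% of the baseline separation
        errors = []
        for seed in range(40):
            curves, _ = sim.gen_melt_plate([flat_baseline_spec], noise_sd=40.0, seed=seed)
            fit = fit_melt_curve(curves[0])
            assert fit.converged
            errors.append(abs(fit.tm - 50.0))
        assert np.mean(errors) < 0.2

    def test_flat_signal_unfittable(self):
        T = np.arange(25.0, 96.0, 0.5)
        curve = MeltCurve("A1", "P", None, 0.0, T, np.full(T.size, 1000.0))
        fit = fit_melt_curve(curve)
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            MeltCurve("A1", "P", None, 0.0, np.arange(5.0), np.arange(5.0))

    def test_grid_oracle_agreement(self):
        """Fitted optimum sits in the same SSE grid cell as brute force."""
        rng = np.random.default_rng(7)
        for i in range(20):
            spec = random_melt_spec(rng)
            curves, _ = sim.gen_melt_plate([spec], noise_sd=20.0, seed=100 + i)
            fit = fit_melt_curve(curves[0])
            assert fit.converged
            tm_g, dh_g, _ = grid_sse_minimum(
                fit.curve,
                (fit.tm - 1.5, fit.tm + 1.5),
                (max(fit.dh_unfold - 40.0, 5.0), fit.dh_unfold + 40.0),
            )
            assert abs(tm_g - fit.tm) <= 0.1 / 2 + 1e-9
            assert abs(dh_g - fit.dh_unfold) <= 5.0 / 2 + 1e-9

    def test_fitted_tm_monotone_in_true_tm(self, flat_baseline_spec):
        fitted = []
        for tm_true in (45.0, 50.0, 55.0, 60.0):
            spec = dict(flat_baseline_spec, tm=tm_true)
            curves, _ = sim.gen_melt_plate([spec], noise_sd=0.0)
            fitted.append(fit_melt_curve(curves[0]).tm)
        assert np.all(np.diff(fitted) > 0)


def _fits_for(tms, protein="P", compound="C"):
    """Converged fits at exact midpoints, via noiseless synthetic wells."""
    specs = [
        {
            "well": f"W{i}", "protein": protein, "compound": compound, "conc_uM": 10.0,
            "tm": tm, "dh_unfold": 120.0,
            "native_baseline": [1000.0, 0.0], "denatured_baseline": [5000.0, 0.0],
        }
        for i, tm in enumerate(tms)
    ]
    curves, _ = sim.gen_melt_plate(specs, noise_sd=0.0)
    return [fit_melt_curve(c) for c in curves]


class TestDeltaTm:
    def test_self_shift_is_zero(self):
        fits = _fits_for([50.0, 50.0, 50.0])
        res = delta_tm(fits, fits)
        assert res.delta_tm_mean == 0.0
        assert res.delta_tm_sd == 0.0

    def test_shift_against_scattered_references(self):
        refs = _fits_for([49.8, 50.0, 50.2], compound=None)
        samples = _fits_for([53.0, 53.0, 53.0])
        res = delta_tm(samples, refs)
        assert res.delta_tm_mean == pytest.approx(3.0, abs=1e-6)
        assert res.delta_tm_sd == pytest.approx(0.0, abs=1e-6)

    def test_replicate_sd_uses_n_minus_1(self):
        refs = _fits_for([50.0, 50.0, 50.0], compound=None)
        samples = _fits_for([52.0, 53.0, 54.0])
        res = delta_tm(samples, refs)
        assert res.delta_tm_mean == pytest.approx(3.0, abs=1e-6)
        assert res.delta_tm_sd == pytest.approx(1.0, abs=1e-6)

    def test_single_replicate_sd_is_none(self):
        refs = _fits_for([50.0], compound=None)
        res = delta_tm(_fits_for([52.0]), refs)
        assert res.delta_tm_sd is None
        assert res.n_replicates == 1

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            delta_tm(_fits_for([52.0]), [])


class TestPlateSummary:
    @staticmethod
    def _plate(proteins, compounds, tm_shift=3.0, n_rep=3, noise_sd=0.0, seed=0):
        specs = []
        for p_i, protein in enumerate(proteins):
            for r in range(n_rep):
                specs.append({
                    "well": f"R{p_i}_{r}", "protein": protein, "compound": None,
                    "conc_uM": 0.0, "tm": 50.0, "dh_unfold": 120.0,
                    "native_baseline": [1000.0, 0.0], "denatured_baseline": [5000.0, 0.0],
                })
            for c_i, compound in enumerate(compounds):
                for r in range(n_rep):
                    specs.append({
                        "well": f"S{p_i}_{c_i}_{r}", "protein": protein, "compound": compound,
                        "conc_uM": 10.0, "tm": 50.0 + tm_shift, "dh_unfold": 120.0,
                        "native_baseline": [1000.0, 0.0], "denatured_baseline": [5000.0, 0.0],
                    })
        curves, _ = sim.gen_melt_plate(specs, noise_sd=noise_sd, seed=seed)
        return [fit_melt_curve(c) for c in curves]

    def test_row_per_protein_compound(self):
        fits = self._plate(["P1", "P2"], ["C1"])
        table = plate_summary(fits)
        assert len(table) == 2
        assert set(table["protein"]) == {"P1", "P2"}

    def test_triplicate_panel_layout(self):
        # 12 proteins x 2 compounds in triplicate with per-protein references
        fits = self._plate([f"P{i}" for i in range(12)], ["Ca", "Cb"])
        table = plate_summary(fits)
        assert len(table) == 24
        assert (table["n"] == 3).all()
        assert np.allclose(table["delta_tm_mean_C"], 3.0, atol=1e-6)

    def test_unfittable_well_drops_replicate(self):
        fits = self._plate(["P1"], ["C1"])
        # replace one sample fit with a failed one
        broken = [f for f in fits if f.curve.compound_id == "C1"][0]
        broken.converged = False
        table = plate_summary(fits)
        assert table.loc[0, "n"] == 2

    def test_unknown_well_raises(self):
        import pandas as pd

        fits = self._plate(["P1"], ["C1"])
        pm = pd.DataFrame({"well": ["R0_0"], "protein": ["P1"], "compound": [""], "conc_uM": [0.0]})
        with pytest.raises(KeyError):
            plate_summary(fits, pm)
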