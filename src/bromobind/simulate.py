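"""Synthetic datasets with known ground truth for every assay modality.

Each generator draws from the same forward models the fitting code uses,
adds the documented noise, and returns the data together with a
:class:`SyntheticTruth` record of the generating parameters.  Reproducing a
dataset from (parameters, seed) is bit-identical.

Seeding: a top-level seed spawns per-dataset child generators through
``numpy.random.SeedSequence(seed, spawn_key=(index,))``, so adding a dataset
never shifts the noise of existing ones.

Defaults mirror the study conditions the analyses were designed for:
DSF ramp 25-96 C; ITC 0.2003-ml cell, one 0.3-ul control injection plus
38 x 1 ul at 15 C with the protein in the syringe; FRAP frames every 0.25 s
with five prescans and n = 30 cells; dose checkerboards of 8 x 8
concentrations spanning 0.7-11,392 nM and 37-4,728 nM.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .assays import DoseGrid
from .dsf import MeltCurve, eval_melt_model
from .frap import FrapTrace
from .itc import Titration, default_schedule, simulate_injection_heats

__all__ = [
    "SyntheticTruth",
    "child_rng",
    "gen_melt_plate",
    "gen_titration",
    "gen_frap_traces",
    "gen_dose_grid",
    "TITRATION_PRESETS",
]

#: Concentration presets ([P]_syringe uM, [L]_cell uM) for panel-style titrations.
TITRATION_PRESETS = {
    "BRD4(1)": (258.0, 20.0),
    "CECR2": (202.0, 16.0),
    "BRD9": (251.0, 25.0),
    "TAF1L(2)": (250.0, 20.0),
    "PCAF": (610.0, 13.0),
}


@dataclass
class SyntheticTruth:
    """Generating parameters attached to a simulated dataset."""

    modality: str
    params: dict
    noise: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


def child_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-dataset generator split from a top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


# ---------------------------------------------------------------- DSF


def gen_melt_plate(
    well_specs: list[dict],
    noise_sd: float = 40.0,
    seed: int = 0,
    t_min: float = 25.0,
    t_max: float = 96.0,
    t_step: float = 0.5,
) -> tuple[list[MeltCurve], SyntheticTruth]:
    """Simulate a DSF plate from per-well two-state parameters.

    Each well spec is a dict with keys well, protein, compound (None for
    reference), conc_uM, tm, dh_unfold, native_baseline, denatured_baseline.
    Noise is i.i.d. Gaussian in AU (default 1% of a typical 4000-AU window).
    """
    temperatures = np.arange(t_min, t_max + t_step / 2, t_step)
    curves = []
    for i, spec in enumerate(well_specs):
        rng = child_rng(seed, i)
        y = eval_melt_model(
            temperatures, spec["tm"], spec["dh_unfold"],
            tuple(spec["native_baseline"]), tuple(spec["denatured_baseline"]),
        )
        y = y + rng.normal(0.0, noise_sd, size=y.size) if noise_sd > 0 else y
        curves.append(
            MeltCurve(
                well_id=spec["well"], protein_id=spec["protein"],
                compound_id=spec.get("compound"), compound_conc=spec.get("conc_uM", 0.0),
                temperatures=temperatures, fluorescence=y,
            )
        )
    truth = SyntheticTruth(
        modality="dsf",
        params={"wells": well_specs, "t_min": t_min, "t_max": t_max, "t_step": t_step},
        noise={"distribution": "gaussian", "sd": noise_sd},
        seed=seed,
    )
    return curves, truth


# ---------------------------------------------------------------- ITC


def design_syringe_conc(
    n_sites: float,
    kd_nM: float,
    cell_conc: float,
    stock_range_uM: tuple[float, float] = (200.0, 650.0),
) -> float:
    """Syringe concentration (uM) following panel design practice.

    Reverse titrations are designed to saturate the cell species before the
    final injection: tight binders use roughly a 12-fold syringe excess over
    the cell concentration, and the excess grows with K_D (weak binders need
    a large excess to approach saturation), capped by the achievable protein
    stock (about 650 uM).  Reproduces the quantified reference-panel pairs,
    e.g. 260 uM for the 41.8 nM / 20 uM condition and the 650 uM cap for the
    micromolar binders.
    """
    kd_uM = kd_nM * 1e-3
    p = 12.0 * cell_conc * (1.0 + 2.0 * kd_uM) * max(n_sites, 0.5)
    return float(np.clip(p, *stock_range_uM))


def gen_titration(
    n_sites: float,
    kd_nM: float,
    dh_kcal: float,
    syringe_conc: float = 258.0,
    cell_conc: float = 20.0,
    cell_volume_ml: float = 0.2003,
    temperature_c: float = 15.0,
    schedule_ul: np.ndarray | None = None,
    dilution_offset: float = 0.0,  # ucal per ul injected
    noise_sd: float = 0.1,  # ucal
    seed: int = 0,
    protein_id: str = "protein",
    compound_id: str = "compound",
) -> tuple[Titration, SyntheticTruth]:
    """Simulate one reverse titration under the standard schedule."""
    volumes = default_schedule() if schedule_ul is None else np.asarray(schedule_ul, float)
    blank = Titration(
        protein_id=protein_id, compound_id=compound_id,
        syringe_conc=syringe_conc, cell_conc=cell_conc, cell_volume=cell_volume_ml,
        injection_volumes=volumes, temperature=temperature_c,
        heats=np.zeros_like(volumes),
    )
    heats = simulate_injection_heats(n_sites, kd_nM, dh_kcal, blank)
    heats = heats + dilution_offset * volumes
    if noise_sd > 0:
        heats = heats + child_rng(seed, 0).normal(0.0, noise_sd, size=heats.size)
    titration = dataclasses.replace(blank, heats=heats)
    truth = SyntheticTruth(
        modality="itc",
        params={
            "n_sites": n_sites, "kd_nM": kd_nM, "dh_kcal": dh_kcal,
            "syringe_conc_uM": syringe_conc, "cell_conc_uM": cell_conc,
            "cell_volume_ml": cell_volume_ml, "temperature_C": temperature_c,
            "dilution_offset_ucal_per_ul": dilution_offset,
        },
        noise={"distribution": "gaussian", "sd": noise_sd},
        seed=seed,
    )
    return titration, truth


def gen_titration_ensemble(
    n_runs: int = 50,
    seed: int = 0,
    noise_sd: float = 0.1,
    c_range: tuple[float, float] = (5.0, 1000.0),
) -> list[tuple[Titration, SyntheticTruth]]:
    """Panel-like random titrations spanning a range of c = N [L] / K_D.

    Each run draws cell concentration, enthalpy and stoichiometry from the
    reference-panel ranges (13-25 uM, -17 to -3 kcal/mol, 0.9-1.1), sets K_D
    from a log-uniform c, and designs the syringe concentration with
    :func:`design_syringe_conc`.
    """
    out = []
    for i in range(n_runs):
        rng = child_rng(seed, i)
        c = float(np.exp(rng.uniform(np.log(c_range[0]), np.log(c_range[1]))))
        cell = float(rng.uniform(13.0, 25.0))
        dh = float(rng.uniform(-17.0, -3.0))
        n_sites = float(rng.uniform(0.9, 1.1))
        kd_nM = n_sites * cell * 1e3 / c
        syringe = design_syringe_conc(n_sites, kd_nM, cell)
        out.append(
            gen_titration(
                n_sites, kd_nM, dh,
                syringe_conc=syringe, cell_conc=cell,
                noise_sd=noise_sd, seed=(seed * 100_003 + i) % (2**31 - 1),
            )
        )
    return out


# ---------------------------------------------------------------- FRAP


def gen_frap_traces(
    k: float,
    mobile: float = 0.8,
    bleach_depth: float = 0.7,
    n_cells: int = 30,
    noise_sd: float = 0.03,
    seed: int = 0,
    interval_s: float = 0.25,
    n_prebleach: int = 5,
    n_postbleach: int = 120,
    drift_rate: float = 0.0,  # fractional signal loss per second, joint on I and T
    background: float = 50.0,
    treatment: str = "",
) -> tuple[list[FrapTrace], SyntheticTruth]:
    """Simulate single-exponential FRAP recoveries for a group of cells.

    The underlying relative signal drops by ``bleach_depth`` at the bleach
    and recovers as depth * mobile * (1 - exp(-k t)).  A multiplicative
    acquisition-drift factor is applied jointly to the ROI and whole-nucleus
    channels (above background) to exercise the double normalization.
    """
    if not 0 < mobile <= 1 or not 0 < bleach_depth <= 1:
        raise ValueError("mobile and bleach_depth must lie in (0, 1]")
    n_frames = n_prebleach + n_postbleach
    times = np.arange(n_frames) * interval_s
    bleach_frame = n_prebleach
    t_post = times[bleach_frame:] - times[bleach_frame]
    traces = []
    for i in range(n_cells):
        rng = child_rng(seed, i)
        rel = np.ones(n_frames)
        rel[bleach_frame:] = (1.0 - bleach_depth) + bleach_depth * mobile * (
            1.0 - np.exp(-k * t_post)
        )
        drift = 1.0 / (1.0 + drift_rate * times)  # shared acquisition bleaching
        i_sig = 1000.0 * rel * drift
        t_sig = 5000.0 * np.ones(n_frames) * drift
        if noise_sd > 0:
            i_sig = i_sig * (1.0 + rng.normal(0.0, noise_sd, n_frames))
            t_sig = t_sig * (1.0 + rng.normal(0.0, noise_sd / 3.0, n_frames))
        traces.append(
            FrapTrace(
                times=times,
                bleached_roi=background + i_sig,
                whole_nucleus=background + t_sig,
                background=np.full(n_frames, background),
                bleach_frame=bleach_frame,
                n_prebleach=n_prebleach,
                cell_id=f"cell{i:03d}",
                treatment=treatment,
            )
        )
    truth = SyntheticTruth(
        modality="frap",
        params={
            "k_per_s": k, "mobile": mobile, "bleach_depth": bleach_depth,
            "n_cells": n_cells, "interval_s": interval_s,
            "n_prebleach": n_prebleach, "n_postbleach": n_postbleach,
            "drift_rate_per_s": drift_rate, "t_half_s": float(np.log(2.0) / k),
        },
        noise={"distribution": "gaussian", "sd": noise_sd},
        seed=seed,
    )
    return traces, truth


# ---------------------------------------------------------------- dose grids

#: Default checkerboard ranges (nM): drug A spans the BET-inhibitor range,
#: drug B the pan-bromodomain probe range.
DOSE_RANGE_A = (0.7, 11392.0)
DOSE_RANGE_B = (37.0, 4728.0)


def _median_effect_fa(dose, dm, m):
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(dose > 0, 1.0 / (1.0 + (dm / np.where(dose > 0, dose, 1.0)) ** m), 0.0)


def _loewe_fa(d1: float, d2: float, dm1: float, m1: float, dm2: float, m2: float) -> float:
    """Fraction affected of a Loewe-additive combination (CI = 1 by construction)."""

    def excess(logit):
        # fa/(1-fa) = exp(logit); dose of drug i alone giving fa
        dx1 = dm1 * np.exp(logit / m1)
        dx2 = dm2 * np.exp(logit / m2)
        return d1 / dx1 + d2 / dx2 - 1.0

    return 1.0 / (1.0 + np.exp(-brentq(excess, -200, 200, xtol=1e-14)))


def gen_dose_grid(
    ec50_a: float,
    ec50_b: float,
    hill_a: float = 1.0,
    hill_b: float = 1.0,
    interaction: str = "loewe",
    noise_sd: float = 0.0,
    seed: int = 0,
    n_doses: int = 8,
    range_a: tuple[float, float] = DOSE_RANGE_A,
    range_b: tuple[float, float] = DOSE_RANGE_B,
    drug_a: str = "drugA",
    drug_b: str = "drugB",
) -> tuple[DoseGrid, SyntheticTruth]:
    """Simulate a checkerboard viability grid under a chosen interaction rule.

    ``interaction``: 'loewe' (additive by construction), 'bliss'
    (independent action), or 'sham' (drug B is drug A: both axes share drug
    A's parameters and a combination behaves like dose d1 + d2 of drug A).
    """
    if interaction not in ("loewe", "bliss", "sham"):
        raise ValueError(f"unknown interaction {interaction!r}")
    doses_a = np.concatenate([[0.0], np.geomspace(range_a[0], range_a[1], n_doses)])
    if interaction == "sham":
        ec50_b, hill_b, range_b = ec50_a, hill_a, range_a
        doses_b = doses_a.copy()
    else:
        doses_b = np.concatenate([[0.0], np.geomspace(range_b[0], range_b[1], n_doses)])
    fa = np.zeros((doses_a.size, doses_b.size))
    for i, d1 in enumerate(doses_a):
        for j, d2 in enumerate(doses_b):
            if d1 == 0 and d2 == 0:
                fa[i, j] = 0.0
            elif d2 == 0:
                fa[i, j] = _median_effect_fa(d1, ec50_a, hill_a)
            elif d1 == 0:
                fa[i, j] = _median_effect_fa(d2, ec50_b, hill_b)
            elif interaction == "sham":
                fa[i, j] = _median_effect_fa(d1 + d2, ec50_a, hill_a)
            elif interaction == "loewe":
                fa[i, j] = _loewe_fa(d1, d2, ec50_a, hill_a, ec50_b, hill_b)
            else:  # bliss: surviving fractions multiply
                fu = (1 - _median_effect_fa(d1, ec50_a, hill_a)) * (
                    1 - _median_effect_fa(d2, ec50_b, hill_b)
                )
                fa[i, j] = 1.0 - fu
    if noise_sd > 0:
        fa = np.clip(fa + child_rng(seed, 0).normal(0.0, noise_sd, fa.shape), 0.0, 1.0)
    grid = DoseGrid(
        drug_a=drug_a, drug_b=drug_b,
        drug_a_doses=doses_a, drug_b_doses=doses_b, fa=fa,
    )
    truth = SyntheticTruth(
        modality="dose",
        params={
            "ec50_a_nM": ec50_a, "ec50_b_nM": ec50_b,
            "hill_a": hill_a, "hill_b": hill_b,
            "interaction": interaction, "n_doses": n_doses,
            "range_a_nM": list(range_a), "range_b_nM": list(range_b),
        },
        noise={"distribution": "gaussian", "sd": noise_sd},
        seed=seed,
    )
    return grid, truth
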