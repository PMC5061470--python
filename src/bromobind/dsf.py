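"""Differential scanning fluorimetry (thermal shift) analysis.

A dye-based melt curve reports unfolding of a protein as a sigmoidal rise in
fluorescence between a native and a denatured baseline.  The temperature
dependence is modelled as a two-state equilibrium,

    y(T) = y_F(T) + (y_U(T) - y_F(T)) / (1 + exp(dG_u(T) / (R T_K)))

with linear baselines y_F(T) = aF + bF*T and y_U(T) = aU + bU*T, and a
van 't Hoff free energy of unfolding with zero heat-capacity change,

    dG_u(T) = dH_u * (1 - T_K / Tm_K),       T_K = T(degC) + 273.15.

Ligand binding stabilises the fold; the readout is the shift of the melting
midpoint, dTm = Tm(sample) - mean Tm(reference wells on the same plate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL, celsius_to_kelvin

logger = logging.getLogger(__name__)

__all__ = [
    "MeltCurve",
    "MeltFitResults",
    "MeltCurveModel",
    "DeltaTmResult",
    "eval_melt_model",
    "fit_melt_curve",
    "truncate_post_transition",
    "delta_tm",
    "plate_summary",
    "grid_sse_minimum",
]


@dataclass
class MeltCurve:
    """One well's fluorescence-vs-temperature trace.

    ``compound_id`` of ``None`` marks a reference (apo protein) well.
    """

    well_id: str
    protein_id: str
    compound_id: str | None
    compound_conc: float  # uM; 0 for reference wells
    temperatures: np.ndarray  # degC, strictly increasing
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.size < 10:
            raise ValueError(f"well {self.well_id}: need >= 10 temperature points")
        if self.temperatures.size != self.fluorescence.size:
            raise ValueError(f"well {self.well_id}: temperature/fluorescence length mismatch")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError(f"well {self.well_id}: temperatures must be strictly increasing")
        if self.temperatures[0] < 0.0 or self.temperatures[-1] > 120.0:
            raise ValueError(f"well {self.well_id}: temperatures outside [0, 120] degC")

    @property
    def is_reference(self) -> bool:
        return self.compound_id is None


def eval_melt_model(
    T,
    tm: float,
    dh_unfold: float,
    native_baseline: tuple[float, float],
    denatured_baseline: tuple[float, float],
    gas_constant: float = R_KCAL,
):
    """Two-state melt model value at temperature ``T`` (degC).

    ``native_baseline`` and ``denatured_baseline`` are (intercept, slope)
    pairs in AU and AU/degC.  ``dh_unfold`` is the van 't Hoff unfolding
    enthalpy in kcal/mol and must be positive in a fitting context.
    """
    T = np.asarray(T, dtype=float)
    t_k = T + 273.15
    tm_k = celsius_to_kelvin(tm)
    if tm_k <= 0:
        raise ValueError("melting midpoint must be above 0 K")
    y_f = native_baseline[0] + native_baseline[1] * T
    y_u = denatured_baseline[0] + denatured_baseline[1] * T
    dg = dh_unfold * (1.0 - t_k / tm_k)
    frac_unfolded = 1.0 / (1.0 + np.exp(dg / (gas_constant * t_k)))
    return y_f + (y_u - y_f) * frac_unfolded


def _unfolded_fraction(T: np.ndarray, tm: float, dh_unfold: float) -> np.ndarray:
    t_k = T + 273.15
    tm_k = celsius_to_kelvin(tm)
    dg = dh_unfold * (1.0 - t_k / tm_k)
    return 1.0 / (1.0 + np.exp(dg / (R_KCAL * t_k)))


def truncate_post_transition(curve: MeltCurve, margin_c: float = 2.0) -> MeltCurve:
    """Drop the aggregation-driven decay after the fluorescence maximum.

    Keeps points with T <= T(global max) + ``margin_c``.  Idempotent on
    monotone curves (the maximum is then the final point).
    """
    # last occurrence of the maximum: plateaus and flat curves stay intact
    i_max = curve.fluorescence.size - 1 - int(np.argmax(curve.fluorescence[::-1]))
    t_cut = curve.temperatures[i_max] + margin_c
    keep = curve.temperatures <= t_cut
    if keep.all():
        return curve
    return MeltCurve(
        well_id=curve.well_id,
        protein_id=curve.protein_id,
        compound_id=curve.compound_id,
        compound_conc=curve.compound_conc,
        temperatures=curve.temperatures[keep],
        fluorescence=curve.fluorescence[keep],
    )


@dataclass
class MeltFitResults:
    """Fitted two-state melt parameters for one well."""

    tm: float  # degC
    dh_unfold: float  # kcal/mol
    native_baseline: tuple[float, float]
    denatured_baseline: tuple[float, float]
    rmse: float
    converged: bool
    curve: MeltCurve | None = None
    bse: dict = field(default_factory=dict)  # 1-SD parameter errors

    def predict(self, T):
        return eval_melt_model(
            T, self.tm, self.dh_unfold, self.native_baseline, self.denatured_baseline
        )

    def summary(self) -> str:
        lines = ["Two-state melt fit"]
        if self.curve is not None:
            lines.append(
                f"  well {self.curve.well_id}  protein {self.curve.protein_id}"
                f"  compound {self.curve.compound_id or '(reference)'}"
            )
        lines += [
            f"  Tm         {self.tm:10.3f} degC",
            f"  dH_unfold  {self.dh_unfold:10.2f} kcal/mol",
            f"  native baseline    {self.native_baseline[0]:.3g} + {self.native_baseline[1]:.3g}*T",
            f"  denatured baseline {self.denatured_baseline[0]:.3g} + {self.denatured_baseline[1]:.3g}*T",
            f"  rmse       {self.rmse:10.4g} AU",
            f"  converged  {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.curve is not None:
            ax.plot(self.curve.temperatures, self.curve.fluorescence, ".", label="data")
            grid = np.linspace(self.curve.temperatures[0], self.curve.temperatures[-1], 300)
            ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.axvline(self.tm, ls="--", color="grey")
        ax.set_xlabel("temperature (degC)")
        ax.set_ylabel("fluorescence (AU)")
        ax.legend()
        return ax


class MeltCurveModel:
    """Nonlinear least-squares model for one DSF well.

    Parameters
    ----------
    curve : MeltCurve
        The well trace; the post-transition decay is truncated first unless
        ``truncate=False``.
    noise_floor_factor : float
        A curve whose signal range is below ``noise_floor_factor`` times the
        median absolute successive difference is declared unfittable (flat).
    """

    def __init__(self, curve: MeltCurve, truncate: bool = True, noise_floor_factor: float = 5.0,
                 truncate_margin_c: float = 2.0):
        self.curve = truncate_post_transition(curve, truncate_margin_c) if truncate else curve
        self.noise_floor_factor = noise_floor_factor

    def _unfittable(self) -> bool:
        y = self.curve.fluorescence
        if y.size < 10:
            return True
        step = np.median(np.abs(np.diff(y)))
        return bool(np.ptp(y) < self.noise_floor_factor * max(step, np.finfo(float).tiny))

    def _initial_guess(self) -> np.ndarray:
        T, y = self.curve.temperatures, self.curve.fluorescence
        n10 = max(3, T.size // 10)
        # smoothed derivative locates the transition
        kernel = np.ones(min(5, y.size)) / min(5, y.size)
        ys = np.convolve(y, kernel, mode="same")
        dy = np.gradient(ys, T)
        interior = slice(n10, T.size - n10) if T.size > 2 * n10 + 2 else slice(None)
        tm0 = float(T[interior][np.argmax(dy[interior])])
        bf = np.polyfit(T[:n10], y[:n10], 1)
        bu = np.polyfit(T[-n10:], y[-n10:], 1)
        return np.array([tm0, 100.0, bf[1], bf[0], bu[1], bu[0]])

    @staticmethod
    def _residual(theta: np.ndarray, T: np.ndarray, y: np.ndarray) -> np.ndarray:
        tm, dh, af, bf, au, bu = theta
        return eval_melt_model(T, tm, dh, (af, bf), (au, bu)) - y

    def fit(self, init: np.ndarray | None = None) -> MeltFitResults:
        """Fit (Tm, dH_u, both baselines) jointly; never raises on failure."""
        T, y = self.curve.temperatures, self.curve.fluorescence
        failed = MeltFitResults(
            tm=float("nan"), dh_unfold=float("nan"),
            native_baseline=(float("nan"), float("nan")),
            denatured_baseline=(float("nan"), float("nan")),
            rmse=float("nan"), converged=False, curve=self.curve,
        )
        if self._unfittable():
            logger.warning("well %s: flat or short signal, unfittable", self.curve.well_id)
            return failed
        theta0 = np.asarray(init, dtype=float) if init is not None else self._initial_guess()
        lo = [T[0], 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [T[-1], 5000.0, np.inf, np.inf, np.inf, np.inf]
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = least_squares(
                self._residual, theta0, args=(T, y), bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, x_scale=[1.0, 50.0, 1.0, 1.0, 1.0, 1.0],
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            logger.exception("well %s: optimizer raised", self.curve.well_id)
            return failed
        tm, dh, af, bf, au, bu = sol.x
        in_window = T[0] < tm < T[-1]
        converged = bool(sol.success and in_window and dh > 0)
        rmse = float(np.sqrt(np.mean(sol.fun**2)))
        bse: dict = {}
        if converged and sol.fun.size > sol.x.size:
            try:
                jtj = sol.jac.T @ sol.jac
                cov = np.linalg.inv(jtj) * (sol.fun @ sol.fun) / (sol.fun.size - sol.x.size)
                sd = np.sqrt(np.clip(np.diag(cov), 0, None))
                bse = {"tm": float(sd[0]), "dh_unfold": float(sd[1])}
            except np.linalg.LinAlgError:
                pass
        return MeltFitResults(
            tm=float(tm), dh_unfold=float(dh),
            native_baseline=(float(af), float(bf)),
            denatured_baseline=(float(au), float(bu)),
            rmse=rmse, converged=converged, curve=self.curve, bse=bse,
        )


def fit_melt_curve(curve: MeltCurve, init: np.ndarray | None = None, **kwargs) -> MeltFitResults:
    """Functional wrapper around :class:`MeltCurveModel`."""
    return MeltCurveModel(curve, **kwargs).fit(init=init)


def grid_sse_minimum(
    curve: MeltCurve,
    tm_range: tuple[float, float],
    dh_range: tuple[float, float],
    tm_step: float = 0.1,
    dh_step: float = 5.0,
) -> tuple[float, float, float]:
    """Brute-force SSE grid search over (Tm, dH_u).

    For each grid cell the four baseline parameters enter the model linearly
    and are profiled out by exact linear least squares, so the returned
    minimum is an optimizer-independent check of the nonlinear fit at grid
    resolution.  Returns (tm, dh_unfold, sse) at the grid minimum.
    """
    T, y = curve.temperatures, curve.fluorescence
    tms = np.arange(tm_range[0], tm_range[1] + tm_step / 2, tm_step)
    dhs = np.arange(dh_range[0], dh_range[1] + dh_step / 2, dh_step)
    best = (math.nan, math.nan, math.inf)
    for tm in tms:
        for dh in dhs:
            f = _unfolded_fraction(T, tm, dh)
            X = np.column_stack([1.0 - f, T * (1.0 - f), f, T * f])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(np.sum((X @ coef - y) ** 2))
            if sse < best[2]:
                best = (float(tm), float(dh), sse)
    return best


@dataclass
class DeltaTmResult:
    """Replicate-aggregated thermal shift for one (protein, compound) pair."""

    protein_id: str
    compound_id: str
    delta_tm_mean: float  # degC
    delta_tm_sd: float | None  # None when n = 1
    n_replicates: int


def delta_tm(sample_fits: list[MeltFitResults], reference_fits: list[MeltFitResults]) -> DeltaTmResult:
    """Thermal shift of sample wells against same-plate reference wells.

    Each sample replicate's shift is its Tm minus the mean reference Tm;
    the result is the mean +/- sample SD (ddof=1) over sample replicates.
    """
    refs = [f for f in reference_fits if f.converged]
    if not refs:
        raise ValueError("no converged reference fit: missing plate reference")
    samples = [f for f in sample_fits if f.converged]
    if not samples:
        raise ValueError("no converged sample fit")
    ref_mean = float(np.mean([f.tm for f in refs]))
    shifts = np.array([f.tm for f in samples]) - ref_mean
    # mean of shifts computed as difference of means: exactly 0 for identical lists
    mean_shift = float(np.mean([f.tm for f in samples])) - ref_mean
    protein = samples[0].curve.protein_id if samples[0].curve else ""
    compound = samples[0].curve.compound_id if samples[0].curve else ""
    return DeltaTmResult(
        protein_id=protein,
        compound_id=compound or "",
        delta_tm_mean=mean_shift,
        delta_tm_sd=float(np.std(shifts, ddof=1)) if shifts.size > 1 else None,
        n_replicates=int(shifts.size),
    )


def plate_summary(fits: list[MeltFitResults], plate_map=None) -> "pandas.DataFrame":
    """One dTm row per (protein, compound) on a plate.

    ``plate_map`` (optional) is a DataFrame with columns well, protein,
    compound, conc_uM; when given, every fitted well must appear in it and
    its annotations override the curve metadata.  Unfittable wells are
    excluded and logged.
    """
    import pandas as pd

    annotated = []
    for fit in fits:
        if fit.curve is None:
            raise ValueError("plate_summary requires fits that carry their curve")
        well = fit.curve.well_id
        if plate_map is not None:
            row = plate_map.loc[plate_map["well"] == well]
            if row.empty:
                raise KeyError(f"well {well!r} present in data but absent from plate map")
            compound = row.iloc[0]["compound"]
            compound = None if (compound is None or (isinstance(compound, float) and np.isnan(compound)) or compound == "") else str(compound)
            annotated.append((str(row.iloc[0]["protein"]), compound, fit))
        else:
            annotated.append((fit.curve.protein_id, fit.curve.compound_id, fit))

    rows = []
    proteins = sorted({p for p, _, _ in annotated})
    for protein in proteins:
        refs = [f for p, c, f in annotated if p == protein and c is None]
        compounds = sorted({c for p, c, _ in annotated if p == protein and c is not None})
        for compound in compounds:
            group = [f for p, c, f in annotated if p == protein and c == compound]
            usable = [f for f in group if f.converged]
            n_dropped = len(group) - len(usable)
            if n_dropped:
                logger.warning("%s/%s: %d unfittable well(s) excluded", protein, compound, n_dropped)
            if not usable:
                continue
            res = delta_tm(usable, refs)
            rows.append(
                {
                    "protein": protein,
                    "compound": compound,
                    "delta_tm_mean_C": res.delta_tm_mean,
                    "delta_tm_sd_C": res.delta_tm_sd,
                    "n": res.n_replicates,
                }
            )
    return pd.DataFrame(rows, columns=["protein", "compound", "delta_tm_mean_C", "delta_tm_sd_C", "n"])
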