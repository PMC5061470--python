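"""Viability dose-response, drug-combination and qPCR quantification.

Viability readings are blanked and normalized to vehicle (DMSO) controls;
the fraction affected is fa = 1 - surviving.  Single agents are summarised
two ways: a four-parameter logistic (4PL) on log dose, and the median-effect
model

    fa / (1 - fa) = (D / Dm)^m

whose log-linear form log(fa/fu) = m log D - m log Dm is fitted by ordinary
least squares.  Checkerboard combinations are scored with the Chou-Talalay
combination index: at a combination point with fraction affected fa,

    Dx_i = Dm_i (fa / (1 - fa))^(1/m_i)        (dose of drug i alone giving fa)
    CI   = d1/Dx_1 + d2/Dx_2                   (mutually exclusive form)

CI < 1 synergy, CI = 1 additivity, CI > 1 antagonism.  The mutually
nonexclusive variant adds the cross term d1 d2 / (Dx_1 Dx_2).

qPCR fold changes use the 2^-ddCt method against a reference gene and a
vehicle-control condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DoseGrid",
    "DoseResponseResults",
    "DoseResponseModel",
    "MedianEffectResults",
    "MedianEffectModel",
    "CombinationResult",
    "normalize_viability",
    "fit_dose_response",
    "median_effect_fit",
    "combination_index",
    "ddct_fold_change",
]


def normalize_viability(raw, blank: float, vehicle) -> np.ndarray:
    """Fraction of cells surviving relative to vehicle-treated controls.

    (raw - blank) / (mean(vehicle) - blank), clipped to [0, 1.5] with
    clipping logged.  fa = 1 - surviving.
    """
    raw = np.asarray(raw, dtype=float)
    vehicle_mean = float(np.mean(vehicle))
    if vehicle_mean <= blank:
        raise ValueError("vehicle mean must exceed blank")
    surviving = (raw - blank) / (vehicle_mean - blank)
    n_clipped = int(np.sum((surviving < 0.0) | (surviving > 1.5)))
    if n_clipped:
        logger.warning("%d viability value(s) clipped to [0, 1.5]", n_clipped)
    return np.clip(surviving, 0.0, 1.5)


@dataclass
class DoseGrid:
    """Checkerboard of fractions affected; zero-dose row/column = single agents."""

    drug_a: str
    drug_b: str
    drug_a_doses: np.ndarray  # nM, increasing, first entry 0
    drug_b_doses: np.ndarray  # nM, increasing, first entry 0
    fa: np.ndarray  # (len_a, len_b), fraction affected in [0, 1]
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.drug_a_doses = np.asarray(self.drug_a_doses, dtype=float)
        self.drug_b_doses = np.asarray(self.drug_b_doses, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if np.any(self.drug_a_doses < 0) or np.any(self.drug_b_doses < 0):
            raise ValueError("doses must be nonnegative")
        if np.any(np.diff(self.drug_a_doses) <= 0) or np.any(np.diff(self.drug_b_doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.fa.shape != (self.drug_a_doses.size, self.drug_b_doses.size):
            raise ValueError("fa matrix shape must match the dose vectors")
        if np.any((self.fa < 0) | (self.fa > 1)):
            raise ValueError("fa must lie in [0, 1]")

    def single_agent(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(doses, fa) of one drug alone (the zero-dose column/row of the other)."""
        if which == "a":
            return self.drug_a_doses[1:], self.fa[1:, 0]
        if which == "b":
            return self.drug_b_doses[1:], self.fa[0, 1:]
        raise ValueError("which must be 'a' or 'b'")


def _logistic_survival(dose, ec50, hill, top, bottom):
    dose = np.asarray(dose, dtype=float)
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


@dataclass
class DoseResponseResults:
    ec50: float  # nM
    hill: float
    top: float
    bottom: float
    converged: bool
    ec50_in_range: bool
    fit_rmse: float = float("nan")

    def predict(self, dose):
        return _logistic_survival(dose, self.ec50, self.hill, self.top, self.bottom)

    def summary(self) -> str:
        return (
            "Four-parameter logistic fit\n"
            f"  EC50   {self.ec50:10.2f} nM ({'inside' if self.ec50_in_range else 'outside'} dose range)\n"
            f"  hill   {self.hill:10.3f}\n"
            f"  top    {self.top:10.3f}\n"
            f"  bottom {self.bottom:10.3f}\n"
            f"  converged {self.converged}"
        )


class DoseResponseModel:
    """4PL fit of surviving fraction vs dose (log-dose logistic)."""

    def __init__(self, doses, surviving):
        self.doses = np.asarray(doses, dtype=float)
        self.surviving = np.asarray(surviving, dtype=float)
        positive = self.doses > 0
        if np.unique(self.doses[positive]).size < 5:
            raise ValueError("need at least 5 distinct positive doses")

    def fit(self) -> DoseResponseResults:
        d, s = self.doses, self.surviving
        mask = d > 0
        d, s = d[mask], s[mask]
        if np.ptp(s) < 0.05:  # flat: no transition to anchor the fit
            return DoseResponseResults(
                ec50=float("nan"), hill=float("nan"), top=float(np.mean(s)),
                bottom=float(np.mean(s)), converged=False, ec50_in_range=False,
            )

        def residual(theta):
            ln_ec50, hill, top, bottom = theta
            return _logistic_survival(d, np.exp(ln_ec50), hill, top, bottom) - s

        mid = s.min() + np.ptp(s) / 2.0
        ec50_0 = d[np.argmin(np.abs(s - mid))]
        theta0 = np.array([np.log(ec50_0), 1.0, float(s.max()), float(s.min())])
        sol = least_squares(
            residual, theta0,
            bounds=([np.log(d.min() * 1e-3), 0.1, -0.5, -0.5],
                    [np.log(d.max() * 1e3), 10.0, 2.0, 2.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        ec50 = float(np.exp(sol.x[0]))
        return DoseResponseResults(
            ec50=ec50, hill=float(sol.x[1]), top=float(sol.x[2]), bottom=float(sol.x[3]),
            converged=bool(sol.success), ec50_in_range=bool(d.min() <= ec50 <= d.max()),
            fit_rmse=float(np.sqrt(np.mean(sol.fun**2))),
        )


def fit_dose_response(doses, surviving) -> DoseResponseResults:
    return DoseResponseModel(doses, surviving).fit()


@dataclass
class MedianEffectResults:
    """Median-effect (Chou) parameters of a single agent."""

    dm: float  # nM, dose giving fa = 0.5
    m: float  # slope
    r2: float
    n_points: int

    def fa(self, dose):
        """Model fraction affected at the given dose(s)."""
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 + (self.dm / dose) ** self.m)

    def dx(self, fa):
        """Dose of this agent alone producing fraction affected ``fa``."""
        fa = np.asarray(fa, dtype=float)
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def summary(self) -> str:
        return (
            "Median-effect fit\n"
            f"  Dm {self.dm:10.2f} nM\n"
            f"  m  {self.m:10.3f}\n"
            f"  r2 {self.r2:10.4f} (n = {self.n_points})"
        )


class MedianEffectModel:
    """Log-linear median-effect regression: log(fa/fu) on log dose.

    Fractions within ``fa_clip`` of the boundaries diverge on the logit
    scale and are excluded from the regression (with a log); at least 3
    interior points are required.
    """

    def __init__(self, doses, fa, fa_clip: float = 0.01):
        doses = np.asarray(doses, dtype=float)
        fa = np.asarray(fa, dtype=float)
        mask = (doses > 0) & (fa >= fa_clip) & (fa <= 1 - fa_clip)
        n_dropped = int(np.sum(doses > 0) - np.sum(mask))
        if n_dropped:
            logger.info("median-effect fit: %d boundary fa value(s) excluded", n_dropped)
        doses, fa = doses[mask], fa[mask]
        if doses.size < 3:
            raise ValueError("need at least 3 usable (dose, fa) points with 0 < fa < 1")
        self.doses, self.fa = doses, fa

    def fit(self) -> MedianEffectResults:
        x = np.log10(self.doses)
        y = np.log10(self.fa / (1.0 - self.fa))
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dm = 10.0 ** (-intercept / slope)
        return MedianEffectResults(dm=float(dm), m=float(slope), r2=r2, n_points=x.size)


def median_effect_fit(doses, fa, fa_clip: float = 0.01) -> MedianEffectResults:
    return MedianEffectModel(doses, fa, fa_clip=fa_clip).fit()


@dataclass
class CombinationResult:
    """Per-point combination indices for a checkerboard."""

    drug_a: str
    drug_b: str
    points: pd.DataFrame = field(default_factory=pd.DataFrame)  # d1, d2, fa, ci

    def summary(self) -> str:
        ci = self.points["ci"]
        return (
            f"Combination index: {self.drug_a} x {self.drug_b} "
            f"({len(self.points)} points)\n"
            f"  CI min/median/max: {ci.min():.3f} / {ci.median():.3f} / {ci.max():.3f}\n"
            f"  synergy (CI<0.9): {int((ci < 0.9).sum())}  "
            f"additive (0.9-1.1): {int(((ci >= 0.9) & (ci <= 1.1)).sum())}  "
            f"antagonism (CI>1.1): {int((ci > 1.1).sum())}"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.points["fa"], self.points["ci"])
        ax.axhline(1.0, ls="--", color="grey")
        ax.set_xlabel("fraction affected")
        ax.set_ylabel("combination index")
        return ax


def combination_index(
    grid: DoseGrid,
    fit_a: MedianEffectResults,
    fit_b: MedianEffectResults,
    mutually_exclusive: bool = True,
) -> CombinationResult:
    """Chou-Talalay CI for every checkerboard point with fa in (0, 1).

    Points with fa at 0 or 1 are skipped (logged).  The default is the
    two-term mutually exclusive form; ``mutually_exclusive=False`` adds the
    cross term.
    """
    rows = []
    n_skipped = 0
    for i, d1 in enumerate(grid.drug_a_doses):
        for j, d2 in enumerate(grid.drug_b_doses):
            if d1 == 0 and d2 == 0:
                continue
            fa = grid.fa[i, j]
            if not 0.0 < fa < 1.0:
                n_skipped += 1
                continue
            dx1 = float(fit_a.dx(fa))
            dx2 = float(fit_b.dx(fa))
            ci = d1 / dx1 + d2 / dx2
            if not mutually_exclusive:
                ci += (d1 * d2) / (dx1 * dx2)
            rows.append({"d1": d1, "d2": d2, "fa": fa, "ci": ci})
    if n_skipped:
        logger.info("combination_index: skipped %d point(s) with fa at 0 or 1", n_skipped)
    return CombinationResult(
        drug_a=grid.drug_a, drug_b=grid.drug_b,
        points=pd.DataFrame(rows, columns=["d1", "d2", "fa", "ci"]),
    )


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold change by the 2^-ddCt method."""
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
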