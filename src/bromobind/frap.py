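"""Fluorescence recovery after photobleaching (FRAP) of chromatin readers.

A bromodomain protein bound to acetylated chromatin recovers slowly after a
bleach pulse; displacement by an inhibitor speeds recovery.  Three regions
are recorded per frame: the bleached spot I_t, the whole nucleus T_t, and a
background region BG.  The double-normalized relative signal is

    rel(t) = (T_pre - BG)(I_t - BG) / [(T_t - BG)(I_pre - BG)]

with prebleach averages over the prescan frames; the division by the whole
nucleus cancels acquisition photobleaching.  The curve is then rescaled so
the prebleach level maps to 1 and the first post-bleach frame to 0, and a
single-exponential recovery y(t) = A (1 - exp(-k t)) is fitted on the
post-bleach frames; the half-time of recovery is t_half = ln 2 / k and the
plateau A is reported as the mobile fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "FrapTrace",
    "RecoveryResults",
    "RecoveryModel",
    "normalize_trace",
    "rescale",
    "fit_recovery",
    "compare_groups",
]


@dataclass
class FrapTrace:
    """Raw three-channel intensities for one cell."""

    times: np.ndarray  # s, strictly increasing
    bleached_roi: np.ndarray  # I_t, AU
    whole_nucleus: np.ndarray  # T_t, AU
    background: np.ndarray  # BG, AU
    bleach_frame: int  # index of the first post-bleach frame
    n_prebleach: int = 5
    cell_id: str = ""
    treatment: str = ""
    concentration: float = 0.0  # uM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleached_roi = np.asarray(self.bleached_roi, dtype=float)
        self.whole_nucleus = np.asarray(self.whole_nucleus, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.times.size
        if not (self.bleached_roi.size == self.whole_nucleus.size == self.background.size == n):
            raise ValueError("all channels must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.bleach_frame >= self.n_prebleach >= 2):
            raise ValueError("need bleach_frame >= n_prebleach >= 2")

    @property
    def prebleach_slice(self) -> slice:
        return slice(self.bleach_frame - self.n_prebleach, self.bleach_frame)


def normalize_trace(trace: FrapTrace) -> np.ndarray:
    """Double-normalized relative fluorescence per frame.

    Raises if any used denominator (T_t - BG at a frame, or the prebleach
    ROI average) is zero, naming the offending frame.
    """
    i_net = trace.bleached_roi - trace.background
    t_net = trace.whole_nucleus - trace.background
    pre = trace.prebleach_slice
    i_pre = float(np.mean(i_net[pre]))
    t_pre = float(np.mean(t_net[pre]))
    if i_pre == 0.0:
        raise ValueError("prebleach ROI average equals background (zero denominator)")
    zero = np.flatnonzero(t_net == 0.0)
    if zero.size:
        raise ValueError(f"whole-nucleus signal equals background at frame {int(zero[0])}")
    return t_pre * i_net / (t_net * i_pre)


def rescale(rel: np.ndarray, bleach_frame: int, n_prebleach: int = 5) -> np.ndarray:
    """Affine rescale: prebleach mean -> 1, first post-bleach frame -> 0."""
    rel = np.asarray(rel, dtype=float)
    pre_mean = float(np.mean(rel[bleach_frame - n_prebleach : bleach_frame]))
    r0 = float(rel[bleach_frame])
    if pre_mean == r0:
        raise ValueError("no bleach depth: prebleach mean equals first post-bleach value")
    return (rel - r0) / (pre_mean - r0)


@dataclass
class RecoveryResults:
    """Exponential-recovery fit for one cell."""

    t_half: float  # s
    mobile_fraction: float  # equals the plateau under the adopted scaling
    plateau: float
    rate: float  # 1/s
    fit_rmse: float
    converged: bool = True
    cell_id: str = ""
    treatment: str = ""

    def summary(self) -> str:
        return (
            f"FRAP recovery {self.cell_id or ''}".rstrip() + "\n"
            f"  t_half          {self.t_half:8.3f} s\n"
            f"  rate k          {self.rate:8.4f} 1/s\n"
            f"  mobile fraction {self.mobile_fraction:8.3f}\n"
            f"  rmse            {self.fit_rmse:8.4g}\n"
            f"  converged       {self.converged}"
        )


class RecoveryModel:
    """Normalize, rescale and fit a single FRAP trace.

    ``method='exponential'`` (default) fits y(t) = A (1 - exp(-k t)) on the
    post-bleach frames; ``method='interpolation'`` instead takes the plateau
    as the mean of the final quarter of frames and finds the half-recovery
    time by linear interpolation of the first crossing of A/2.
    """

    def __init__(self, trace: FrapTrace, method: str = "exponential"):
        if method not in ("exponential", "interpolation"):
            raise ValueError(f"unknown method {method!r}")
        self.trace = trace
        self.method = method
        if trace.times.size - trace.bleach_frame < 8:
            raise ValueError("need at least 8 post-bleach frames")
        rel = normalize_trace(trace)
        self.normalized = rescale(rel, trace.bleach_frame, trace.n_prebleach)

    def fit(self) -> RecoveryResults:
        b = self.trace.bleach_frame
        t = self.trace.times[b:] - self.trace.times[b]
        y = self.normalized[b:]
        failed = RecoveryResults(
            t_half=float("nan"), mobile_fraction=float("nan"), plateau=float("nan"),
            rate=float("nan"), fit_rmse=float("nan"), converged=False,
            cell_id=self.trace.cell_id, treatment=self.trace.treatment,
        )
        if self.method == "interpolation":
            plateau = float(np.mean(y[-max(3, y.size // 4):]))
            if plateau <= 0:
                return failed
            above = np.flatnonzero(y >= plateau / 2.0)
            above = above[above > 0]
            if above.size == 0:
                return failed
            j = int(above[0])
            frac = (plateau / 2.0 - y[j - 1]) / (y[j] - y[j - 1])
            t_half = float(t[j - 1] + frac * (t[j] - t[j - 1]))
            rate = np.log(2.0) / t_half
            rmse = float(np.sqrt(np.mean((y - plateau * (1 - np.exp(-rate * t))) ** 2)))
            return RecoveryResults(
                t_half=t_half, mobile_fraction=plateau, plateau=plateau, rate=rate,
                fit_rmse=rmse, converged=True,
                cell_id=self.trace.cell_id, treatment=self.trace.treatment,
            )

        def residual(theta):
            a, ln_k = theta
            return a * (1.0 - np.exp(-np.exp(ln_k) * t)) - y

        a0 = max(float(np.mean(y[-max(3, y.size // 4):])), 0.1)
        half_idx = np.flatnonzero(y >= a0 / 2.0)
        k0 = np.log(2.0) / max(float(t[half_idx[0]]), float(t[1])) if half_idx.size else 1.0 / t[-1]
        try:
            sol = least_squares(
                residual, np.array([a0, np.log(k0)]),
                bounds=([0.0, np.log(1e-6)], [2.0, np.log(1e4)]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            return failed
        if not sol.success:
            return failed
        a, k = float(sol.x[0]), float(np.exp(sol.x[1]))
        return RecoveryResults(
            t_half=float(np.log(2.0) / k), mobile_fraction=a, plateau=a, rate=k,
            fit_rmse=float(np.sqrt(np.mean(sol.fun**2))), converged=True,
            cell_id=self.trace.cell_id, treatment=self.trace.treatment,
        )


def fit_recovery(trace: FrapTrace, method: str = "exponential") -> RecoveryResults:
    """Functional wrapper around :class:`RecoveryModel`."""
    return RecoveryModel(trace, method=method).fit()


def compare_groups(
    treated: list[RecoveryResults], control: list[RecoveryResults], paired: bool = False
) -> tuple[float, float]:
    """Two-tailed t-test on half-times between two groups of cells.

    Returns (mean difference treated - control, p-value).  Non-converged
    fits are excluded.  Identical groups yield (0, 1) by convention.
    """
    x = np.array([r.t_half for r in treated if r.converged])
    y = np.array([r.t_half for r in control if r.converged])
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 converged results per group")
    diff = float(np.mean(x) - np.mean(y))
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal group sizes")
        d = x - y
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        res = stats.ttest_rel(x, y)
    else:
        if x.size == y.size and np.allclose(np.sort(x), np.sort(y)):
            return diff, 1.0
        res = stats.ttest_ind(x, y)
    return diff, float(res.pvalue)
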