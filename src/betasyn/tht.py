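"""Thioflavin-T fibrillation kinetics: simulation, logistic fits, classification.

ThT fluorescence increases on binding amyloid, so a fibrillation run traces a
sigmoid: baseline F0, amplitude A, and a half-max time t50 (the K_M of a
fibrillation curve).  Traces are fit with the 4-parameter logistic

    F(t) = F0 + A / (1 + exp(-k (t - t50)))

by bounded least squares.  A run classifies as fibrillating when the fit
converged, the amplitude is a meaningful multiple of the baseline, and t50
falls inside the observation window -- a flat trace (like the designed DNAC
mutant, which does not fibrillate) fails these checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class KineticsError(ValueError):
    pass


@dataclass
class KineticTrace:
    """Fluorescence vs time (minutes, strictly increasing)."""

    time: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape or self.time.ndim != 1:
            raise KineticsError("time and fluorescence must be equal-length 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise KineticsError("time must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_min": self.time, "fluorescence": self.fluorescence}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "KineticTrace":
        df = pd.read_csv(path, comment="#")
        if not {"time_min", "fluorescence"} <= set(df.columns):
            raise KineticsError("trace CSV needs columns time_min, fluorescence")
        return cls(time=df["time_min"].to_numpy(), fluorescence=df["fluorescence"].to_numpy())


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted logistic parameters; ``t50`` is the half-max (K_M) time."""

    F0: float
    A: float
    k: float
    t50: float
    rmse: float
    converged: bool
    message: str = ""

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _logistic(np.asarray(t, dtype=float), self.F0, self.A, self.k, self.t50)


def _logistic(t: np.ndarray, F0: float, A: float, k: float, t50: float) -> np.ndarray:
    return F0 + A / (1.0 + np.exp(-k * (t - t50)))


def simulate_trace(
    F0: float = 100.0,
    A: float = 1000.0,
    k: float = 0.1,
    t50: float = 75.0,
    n_points: int = 96,
    t_max: float = 480.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """Simulate a logistic ThT trace with additive Gaussian noise.

    Defaults emulate an NAC-like run: 96 reads over 8 h, half-max at 75 min.
    Deterministic for a fixed seed; at ``t == t50`` the noiseless signal is
    exactly ``F0 + A/2``.
    """
    if n_points < 2 or t_max <= 0:
        raise KineticsError("need n_points >= 2 and positive t_max")
    t = np.linspace(0.0, t_max, n_points)
    f = _logistic(t, F0, A, k, t50)
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, f.shape)
    return KineticTrace(time=t, fluorescence=f)


def fit_sigmoid(trace: KineticTrace) -> SigmoidFit:
    """Bounded least-squares fit of the 4-parameter logistic.

    Initial guesses: F0 = min, A = range, t50 = first half-range crossing,
    k = 4/(t90 - t10) from the quantile crossings of the rising phase.
    Non-convergence is reported via ``converged=False``, never raised.
    """
    if len(trace.time) < 6:
        raise KineticsError("need at least 6 points to fit a sigmoid")
    t, f = trace.time, trace.fluorescence
    fmin, fmax = float(f.min()), float(f.max())
    frange = fmax - fmin
    if frange <= 0:
        return SigmoidFit(F0=fmin, A=0.0, k=0.0, t50=float(t[0]), rmse=0.0,
                          converged=False, message="constant trace")

    def crossing(level: float) -> float:
        above = np.nonzero(f >= fmin + level * frange)[0]
        return float(t[above[0]]) if len(above) else float(t[-1])

    t10, t50_guess, t90 = crossing(0.1), crossing(0.5), crossing(0.9)
    k_guess = 4.0 / (t90 - t10) if t90 > t10 else 1.0 / max(t[-1] - t[0], 1.0)
    p0 = [fmin, frange, k_guess, t50_guess]
    span = float(t[-1] - t[0])
    bounds = (
        [fmin - 2 * frange, 0.0, 1e-6, t[0] - span],
        [fmax, 10 * frange, np.inf, t[-1] + span],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_logistic, t, f, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return SigmoidFit(F0=fmin, A=frange, k=k_guess, t50=t50_guess,
                          rmse=float("nan"), converged=False, message=str(exc))
    resid = f - _logistic(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return SigmoidFit(F0=float(popt[0]), A=float(popt[1]), k=float(popt[2]),
                      t50=float(popt[3]), rmse=rmse, converged=True)


def classify_fibrillation(
    fit: SigmoidFit,
    trace: KineticTrace | None = None,
    min_amplitude_ratio: float = 0.5,
    window: tuple[float, float] | None = None,
) -> bool:
    """True iff the fit describes a genuine fibrillation transition.

    Requires a converged fit, amplitude A >= ``min_amplitude_ratio`` x F0
    (strict at the boundary), and t50 inside the observation window (taken
    from ``trace`` when given).  DNAC-like flat traces return False.
    """
    if not fit.converged:
        return False
    if window is None and trace is not None:
        window = (float(trace.time[0]), float(trace.time[-1]))
    if fit.A < min_amplitude_ratio * max(fit.F0, 0.0) or fit.A <= 0:
        return False
    if window is not None and not (window[0] <= fit.t50 <= window[1]):
        return False
    return True
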