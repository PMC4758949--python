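"""Four-parameter sigmoid fitting of thermal-shift melt curves.

The model is

    y(T) = LL + (UL - LL) / (1 + exp((Tm - T) / a))

with LL/UL the lower/upper fluorescence plateaus, a the transition slope
(degrees C) and Tm the melting temperature (the curve midpoint: y(Tm) =
(LL + UL) / 2).  With a > 0 the signal rises towards UL as T increases,
which is the unfolding direction reported by environment-sensitive dyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class MeltFitError(RuntimeError):
    """Fit failure; carries the best iterate found, if any."""

    def __init__(self, message: str, best: "MeltFit | None" = None) -> None:
        super().__init__(message)
        self.best = best


@dataclass
class MeltCurve:
    """A melt curve: ascending temperatures (deg C) and signal values."""

    T: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, float)
        self.y = np.asarray(self.y, float)
        if self.T.size != self.y.size:
            raise ValueError("temperature and signal lengths differ")
        if self.T.size < 8:
            raise ValueError("melt curve needs >=8 points")
        if not np.all(np.diff(self.T) > 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    """Fitted sigmoid parameters and residual norm."""

    LL: float
    UL: float
    a: float
    Tm: float
    residual_norm: float

    def predict(self, T: np.ndarray) -> np.ndarray:
        return sigmoid(np.asarray(T, float), self.LL, self.UL, self.a, self.Tm)


def sigmoid(T: np.ndarray, LL: float, UL: float, a: float, Tm: float) -> np.ndarray:
    """The four-parameter melt sigmoid."""
    # clip the exponent: exp overflow would still converge to the correct
    # plateau but floods optimiser runs with warnings
    z = np.clip((Tm - T) / a, -700.0, 700.0)
    return LL + (UL - LL) / (1.0 + np.exp(z))


def _initial_guess(T: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    LL0, UL0 = float(y.min()), float(y.max())
    dy = np.gradient(y, T)
    Tm0 = float(T[np.argmax(dy)])
    a0 = max((T[-1] - T[0]) / 20.0, 1e-3)
    return LL0, UL0, a0, Tm0


def fit_melt_curve(curve: MeltCurve) -> MeltFit:
    """Nonlinear least-squares fit of the four-parameter sigmoid.

    Initialised from the data extremes and the steepest-slope temperature.
    Raises :class:`MeltFitError` on non-convergence or when the data show
    no transition (flat signal).
    """
    T, y = curve.T, curve.y
    spread = float(y.max() - y.min())
    if spread <= 0 or spread < 1e-12 * max(1.0, abs(float(y.mean()))):
        raise MeltFitError("signal is flat: no unfolding transition to fit")
    p0 = _initial_guess(T, y)
    try:
        popt, _pcov = curve_fit(sigmoid, T, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        best = MeltFit(*p0, residual_norm=float(np.linalg.norm(y - sigmoid(T, *p0))))
        raise MeltFitError(f"fit did not converge: {exc}", best=best) from exc
    LL, UL, a, Tm = map(float, popt)
    if a < 0:  # equivalent parameterisation; normalise to a rising sigmoid
        LL, UL, a = UL, LL, -a
    fit = MeltFit(LL=LL, UL=UL, a=a, Tm=Tm,
                  residual_norm=float(np.linalg.norm(y - sigmoid(T, LL, UL, a, Tm))))
    if not (UL > LL):
        raise MeltFitError("fitted plateaus inverted: no unfolding transition", best=fit)
    if not (T[0] <= Tm <= T[-1]):
        raise MeltFitError(
            f"fitted Tm {Tm:.2f} outside the data range [{T[0]:.1f}, {T[-1]:.1f}]",
            best=fit,
        )
    return fit
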