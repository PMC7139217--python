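"""Enzyme-kinetics curve fits: Michaelis-Menten activation and Hill-type
inhibitor titrations.

Two models are provided.  MT-activated ATPase follows
``v = Vmax * S / (K + S)`` where S is the activator (microtubule)
concentration and K the half-activation constant K_1/2.  Inhibitor
titrations follow the three-parameter inhibition curve
``y = a / (1 + (x / b)^c)`` with a the uninhibited level, b the IC50 and
c the Hill coefficient — the model value at x = b is a/2 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError


@dataclass
class MMFit:
    vmax: float
    k_half: float
    vmax_se: float
    k_half_se: float
    rss: float
    concentration_unit: str = ""

    def predict(self, s):
        s = np.asarray(s, float)
        return self.vmax * s / (self.k_half + s)


@dataclass
class HillIC50Fit:
    a: float
    b: float
    c: float
    r_squared: float
    a_se: float = float("nan")
    b_se: float = float("nan")
    c_se: float = float("nan")

    def predict(self, x):
        return hill_inhibition(np.asarray(x, float), self.a, self.b, self.c)


def michaelis_menten(s, vmax, k):
    s = np.asarray(s, float)
    return vmax * s / (k + s)


def hill_inhibition(x, a, b, c):
    x = np.asarray(x, float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / b) ** c, 0.0)
    return a / (1.0 + ratio)


def _interp_half_point(x: np.ndarray, y: np.ndarray, level: float) -> float:
    """Concentration at which y crosses `level`, by linear interpolation."""
    order = np.argsort(x)
    x, y = x[order], y[order]
    for i in range(len(x) - 1):
        lo, hi = sorted((y[i], y[i + 1]))
        if lo <= level <= hi and y[i] != y[i + 1]:
            t = (level - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + t * (x[i + 1] - x[i]))
    positive = x[x > 0]
    return float(np.median(positive)) if positive.size else 1.0


def fit_michaelis_menten(
    substrate: Sequence[float],
    rate: Sequence[float],
    concentration_unit: str = "",
) -> MMFit:
    """Nonlinear least-squares fit of v = Vmax*S/(K+S).

    Initialization: Vmax0 = max(rate); K0 = concentration at half-maximal
    rate by interpolation.  Parameters are constrained positive.
    """
    s = np.asarray(substrate, float)
    v = np.asarray(rate, float)
    if len(np.unique(s)) < 3:
        raise FitFailureError("need >= 3 distinct substrate concentrations")
    if np.any(v < 0):
        raise FitFailureError("rates must be nonnegative")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise FitFailureError(
            "all rates are zero; Vmax is at the boundary",
            diagnostics={"max_rate": vmax0},
        )
    k0 = max(_interp_half_point(s, v, vmax0 / 2.0), 1e-12)
    try:
        popt, pcov = curve_fit(
            michaelis_menten, s, v, p0=[vmax0, k0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10_000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"Michaelis-Menten fit did not converge: {exc}",
            diagnostics={"p0": [vmax0, k0]},
        ) from exc
    resid = v - michaelis_menten(s, *popt)
    se = np.sqrt(np.diag(pcov))
    return MMFit(
        vmax=float(popt[0]), k_half=float(popt[1]),
        vmax_se=float(se[0]), k_half_se=float(se[1]),
        rss=float((resid ** 2).sum()),
        concentration_unit=concentration_unit,
    )


def fit_ic50(
    conc: Sequence[float],
    activity: Sequence[float],
) -> HillIC50Fit:
    """Least-squares fit of the inhibition curve y = a/(1+(x/b)^c).

    Initialization: a0 = max(activity); b0 = concentration at half of a0
    by interpolation; c0 = 1.  All three parameters are free.  R^2 is
    reported as 1 - RSS/TSS.
    """
    x = np.asarray(conc, float)
    y = np.asarray(activity, float)
    if np.any(x < 0):
        raise FitFailureError("inhibitor concentrations must be >= 0")
    if len(x) < 3:
        raise FitFailureError("need >= 3 titration points")
    if np.allclose(y, y[0]):
        raise FitFailureError("all activities identical; curve is undetermined")
    a0 = float(y.max())
    b0 = max(_interp_half_point(x, y, a0 / 2.0), 1e-12)
    try:
        popt, pcov = curve_fit(
            hill_inhibition, x, y, p0=[a0, b0, 1.0],
            bounds=([1e-12, 1e-12, 1e-6], [np.inf, np.inf, 50.0]),
            maxfev=20_000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"IC50 fit did not converge: {exc}",
            diagnostics={"p0": [a0, b0, 1.0]},
        ) from exc
    resid = y - hill_inhibition(x, *popt)
    rss = float((resid ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    se = np.sqrt(np.diag(pcov))
    return HillIC50Fit(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
        r_squared=1.0 - rss / tss,
        a_se=float(se[0]), b_se=float(se[1]), c_se=float(se[2]),
    )
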