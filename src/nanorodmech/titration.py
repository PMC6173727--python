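"""Acid-base titration analysis of displayed amine groups.

The fraction of protonated amines, measured from the areas of the
neutral and protonated components of an N 1s photoemission spectrum,
falls with pH along a sigmoid

    f(pH) = A * 10^{B (pK - pH)} / (1 + 10^{B (pK - pH)}) + C

where ``A`` is the amplitude, ``B`` sets the slope of the transition,
``C`` is the high-pH baseline and ``pK`` is the pH at half-maximum.
This module computes protonated fractions from component areas and fits
the four sigmoid parameters by least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .errors import FitError, ParameterError

__all__ = [
    "TitrationData",
    "TitrationFit",
    "fraction_protonated",
    "eval_sigmoid",
    "fit_pk",
]

_LN10 = math.log(10.0)


def fraction_protonated(area_protonated: float, area_neutral: float) -> float:
    """Protonated fraction from the two N 1s component areas."""
    if area_protonated < 0 or area_neutral < 0:
        raise ParameterError("component areas must be non-negative")
    total = area_protonated + area_neutral
    if total == 0:
        raise ParameterError("both component areas are zero; fraction undefined")
    return area_protonated / total


def eval_sigmoid(ph, a: float, b: float, c: float, pk: float):
    """Evaluate the titration sigmoid; overflow-safe for any |pK - pH|.

    ``10^x / (1 + 10^x)`` is computed as the logistic function of
    ``x ln 10``.
    """
    if not b > 0:
        raise ParameterError("slope factor B must be positive")
    ph = np.asarray(ph, dtype=float)
    out = a * expit(_LN10 * b * (pk - ph)) + c
    return out if out.ndim else float(out)


@dataclass
class TitrationData:
    """Titration table: pH values and protonated fractions in [0, 1].

    Replicates (``n_replicates`` measurements per pH) are stored as
    individual rows, not pre-averaged.
    """

    ph: np.ndarray
    f: np.ndarray
    n_replicates: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if ph.shape != f.shape or ph.ndim != 1:
            raise ParameterError("pH and f must be equal-length 1D arrays")
        if not np.all(np.isfinite(ph)):
            raise ParameterError("pH values must be finite")
        if np.any((f < 0) | (f > 1)):
            raise ParameterError("fractions must lie in [0, 1]")
        self.ph = ph
        self.f = f

    def averaged(self) -> "TitrationData":
        """Collapse replicates to per-pH means."""
        ph_u = np.unique(self.ph)
        f_mean = np.array([self.f[self.ph == p].mean() for p in ph_u])
        return TitrationData(ph=ph_u, f=f_mean, n_replicates=1,
                             meta=dict(self.meta))


@dataclass(frozen=True)
class TitrationFit:
    """Fitted sigmoid parameters with covariance-based SDs."""

    a: float
    b: float
    c: float
    pk: float
    a_sd: float
    b_sd: float
    c_sd: float
    pk_sd: float
    rss: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise FitError("fitted slope factor B must be positive")

    def predict(self, ph):
        return eval_sigmoid(ph, self.a, self.b, self.c, self.pk)


def _initial_guess(ph: np.ndarray, f: np.ndarray) -> list[float]:
    """Deterministic initialization: C0 = min f, A0 = range of f, B0 = 1,
    pK0 = pH of the datum nearest the mid-fraction."""
    f_min, f_max = float(f.min()), float(f.max())
    mid = 0.5 * (f_min + f_max)
    pk0 = float(ph[int(np.argmin(np.abs(f - mid)))])
    a0 = max(f_max - f_min, 1e-3)
    return [a0, 1.0, f_min, pk0]


def fit_pk(data: TitrationData, average_replicates: bool = False) -> TitrationFit:
    """Least-squares fit of (A, B, C, pK) to a titration table.

    Replicates are fit as individual points unless
    ``average_replicates`` is set.  Requires at least 5 distinct pH
    values and a visible transition (non-constant f).  SDs come from the
    fit covariance; the procedure is deterministic for given data.
    """
    d = data.averaged() if average_replicates else data
    ph, f = d.ph, d.f
    if np.unique(ph).size < 5:
        raise ParameterError("need at least 5 distinct pH values")
    if float(f.max() - f.min()) < 1e-6:
        raise FitError("no transition in the data; sigmoid fit is degenerate")
    p0 = _initial_guess(ph, f)
    lo = [0.0, 1e-3, 0.0, float(ph.min()) - 5.0]
    hi = [2.0, 100.0, 1.0, float(ph.max()) + 5.0]
    p0 = [min(max(p, l), h) for p, l, h in zip(p0, lo, hi)]

    def model(x, a, b, c, pk):
        return a * expit(_LN10 * b * (pk - x)) + c

    try:
        popt, pcov = curve_fit(
            model, ph, f, p0=p0, bounds=(lo, hi),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    sds = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    sds = np.where(np.isfinite(sds), sds, 0.0)
    rss = float(np.sum((model(ph, *popt) - f) ** 2))
    return TitrationFit(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), pk=float(popt[3]),
        a_sd=float(sds[0]), b_sd=float(sds[1]), c_sd=float(sds[2]),
        pk_sd=float(sds[3]), rss=rss,
    )
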