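"""Expected-death surface for the lagged power-of-time risk model.

Expected recorded deaths at age ``A`` in year ``T`` are

    lambda[A, T] = p(T) * ( c * u[A, T] + B[A, T] )

with

    u[A, T] = P[A, T] * sum_{l=0}^{A} W(A - l) * D(T - l) * 2^(-l/H) * max(l - L, 0)^k

the asbestos-attributable component (each past year contributes the
collective dose ``D`` of that year, weighted by the exposure potential of
the age the person then was, attenuated by fibre clearance and amplified by
a power of time since exposure, lagged by ``L`` years; exposure before
birth contributes nothing), ``B`` the background cases, ``p`` the recorded
proportion (diagnostic trend) and ``c`` a proportionality constant.  With
normalisation on, ``c`` is chosen so that fitted deaths over the fit window
sum exactly to the observed total ``M``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import ExposureCurve
from .params import AGE_BAND_EDGES, ParameterSet
from .surfaces import MortalitySurface

__all__ = [
    "risk_weight",
    "clearance_factor",
    "age_weight",
    "diagnostic_proportion",
    "asbestos_surface",
    "background_surface",
    "fitted_surface",
    "FittedSurface",
    "LambdaComputer",
]

DIAGNOSIS_COMPLETE_YEAR = 1997
MISSED_AT_COMPLETE = 0.02  # diagnosis assumed 98% complete by 1997
_P_FLOOR = 1e-8


def risk_weight(l, L: int, k: float):
    """Power-of-time risk weight ``max(l - L, 0)^k`` for lag ``l`` years.

    Contributions with ``l <= L`` are zero: the lag is the minimum time
    between exposure and any disease contribution.
    """
    l = np.asarray(l, dtype=float)
    excess = l - L
    return np.where(excess > 0, np.maximum(excess, 0.0) ** k, 0.0)


def clearance_factor(l, H: float):
    """Fraction of fibres retained ``l`` years after exposure: ``2^(-l/H)``."""
    if H <= 0:
        raise ValueError("clearance half-life must be positive")
    return 2.0 ** (-np.asarray(l, dtype=float) / H)


def age_weight(A, W: np.ndarray):
    """Exposure potential at age ``A``: piecewise-constant over the 9 bands."""
    A = np.asarray(A)
    if np.any(A < 0):
        raise ValueError("negative age")
    band = np.searchsorted(AGE_BAND_EDGES, A, side="right") - 1
    return np.asarray(W, dtype=float)[band]


def diagnostic_proportion(years, alpha: float | None):
    """Proportion ``p(T)`` of mesothelioma deaths recorded in year ``T``.

    Diagnosis is assumed essentially complete (98%) from 1997 on.  Earlier
    years miss more cases: the missed fraction grows backwards in time by
    ``alpha`` percent per year.  ``alpha=None`` (trend off) gives ``p == 1``.
    """
    years = np.asarray(years, dtype=int)
    if alpha is None:
        return np.ones(years.shape, dtype=float)
    back = np.maximum(DIAGNOSIS_COMPLETE_YEAR - years, 0)
    missed = MISSED_AT_COMPLETE * (1.0 + alpha / 100.0) ** back
    return np.maximum(1.0 - missed, _P_FLOOR)


def background_surface(rate: float, pop: MortalitySurface, k: float, L: int) -> np.ndarray:
    """Background (non-asbestos) cases ``B[A, T]``.

    Each year contributes ``rate`` cases per million person-years in total,
    spread over ages proportionally to ``max(A - L, 0)^k`` — the same
    power-of-time shape as the asbestos risk, read as risk rising with age.
    """
    if rate < 0:
        raise ValueError("background rate must be nonnegative")
    yearly_total = rate * pop.person_years.sum(axis=0) / 1e6
    shape = risk_weight(pop.ages, L, k)
    total_shape = shape.sum()
    if total_shape == 0:
        # degenerate: all ages at or below the lag; spread uniformly
        dist = np.full(pop.ages.shape, 1.0 / pop.ages.size)
    else:
        dist = shape / total_shape
    return np.outer(dist, yearly_total)


class LambdaComputer:
    """Vectorised evaluator of the asbestos component on a fixed surface.

    Precomputes, for the surface's age and year grids, the band index of
    "age at exposure" for every (age-at-death, lag) pair and the calendar
    year ``T - l`` for every (year, lag) pair, so that one evaluation is a
    single matrix product::

        u = P * ( (W[bands] * mask * h) @ D_lag.T )

    where ``h[l] = 2^(-l/H) * max(l - L, 0)^k``.
    """

    def __init__(self, pop: MortalitySurface):
        self.pop = pop
        ages = pop.ages
        self.lags = np.arange(0, ages.max() + 1)  # l = 0 .. A_max
        exp_age = ages[:, None] - self.lags[None, :]  # age at exposure
        self.mask = exp_age >= 0
        self.band = np.searchsorted(AGE_BAND_EDGES, np.maximum(exp_age, 0), side="right") - 1
        self.exp_year = pop.years[:, None] - self.lags[None, :]  # (n_years, n_lags)

    def kernel(self, params: ParameterSet) -> np.ndarray:
        """Age x lag kernel ``W(A-l) * 2^(-l/H) * max(l-L,0)^k`` (masked)."""
        h = clearance_factor(self.lags, params.H) * risk_weight(self.lags, params.L, params.k)
        return params.W[self.band] * self.mask * h[None, :]

    def asbestos(self, params: ParameterSet, curve: ExposureCurve) -> np.ndarray:
        """Unnormalised asbestos component ``u[A, T]`` on the surface grid."""
        D_lag = curve.at(self.exp_year)  # (n_years, n_lags); 0 before curve start
        return self.pop.person_years * (self.kernel(params) @ D_lag.T)


def asbestos_surface(params: ParameterSet, curve: ExposureCurve, pop: MortalitySurface) -> np.ndarray:
    """Unnormalised asbestos-attributable component ``u[A, T]``."""
    return LambdaComputer(pop).asbestos(params, curve)


@dataclass(frozen=True)
class FittedSurface:
    """Expected recorded deaths and its components on a surface grid."""

    ages: np.ndarray
    years: np.ndarray
    lam: np.ndarray            # p * (c*u + B)
    asbestos: np.ndarray       # c * u  (unthinned)
    background: np.ndarray     # B      (unthinned)
    c: float                   # proportionality constant

    def yearly_totals(self) -> np.ndarray:
        return self.lam.sum(axis=0)

    def to_surface(self) -> MortalitySurface:
        return MortalitySurface(ages=self.ages, years=self.years, person_years=np.maximum(self.lam, _P_FLOOR))

    def to_csv(self, path) -> None:
        """Write the expected-death matrix in the standard surface layout."""
        import pandas as pd

        df = pd.DataFrame(self.lam, columns=self.years)
        df.insert(0, "age", self.ages)
        df.to_csv(path, index=False, float_format="%.17g")


def fitted_surface(
    params: ParameterSet,
    curve: ExposureCurve,
    pop: MortalitySurface,
    normalise_to: float | None = None,
    fit_window: tuple[int, int] | None = None,
    c: float | None = None,
    computer: LambdaComputer | None = None,
) -> FittedSurface:
    """Expected recorded deaths ``lambda[A, T]`` on ``pop``'s grid.

    Exactly one of ``normalise_to`` / ``c`` fixes the asbestos scale:

    * ``normalise_to=M`` solves ``sum(lambda) = M`` over ``fit_window``
      (default: the whole surface) for the proportionality constant ``c``,
      which then carries unchanged into any later years on the grid;
    * ``c`` uses an explicit absolute scale (as the synthetic-data
      generator must, to avoid normalising to its own output).
    """
    comp = computer if computer is not None else LambdaComputer(pop)
    u = comp.asbestos(params, curve)
    B = background_surface(params.rate, pop, params.k, params.L)
    p = diagnostic_proportion(pop.years, params.alpha)[None, :]

    if (normalise_to is None) == (c is None):
        raise ValueError("specify exactly one of normalise_to or c")
    if c is None:
        if fit_window is None:
            w = slice(None)
        else:
            lo, hi = fit_window
            w = slice(lo - pop.years[0], hi - pop.years[0] + 1)
        denom = (p[:, w] * u[:, w]).sum()
        numer = normalise_to - (p[:, w] * B[:, w]).sum()
        if denom <= 0:
            raise ValueError("asbestos component sums to zero; cannot normalise to observed total")
        c = numer / denom

    lam = p * (c * u + B)
    return FittedSurface(ages=pop.ages, years=pop.years, lam=lam, asbestos=c * u, background=B, c=float(c))
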