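"""Poisson likelihood, deviance, and deviance-residual diagnostics.

Observed counts are modelled as independent Poisson draws,
``Y[A, T] ~ Poisson(lambda[A, T])``.  Model adequacy is judged with
deviance residuals aggregated over age bands and calendar periods: under a
well-specified model they are approximately standard normal, so about 95%
should fall in [-2, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

__all__ = [
    "log_likelihood",
    "deviance",
    "deviance_residuals",
    "DevianceReport",
    "DEFAULT_AGE_BAND_EDGES",
    "default_period_edges",
]

# Default diagnostic banding: 14 five-year age bands (20-24 .. 85-89) by
# 9 calendar periods = 126 aggregated cells.  The period split is a
# convention chosen here (one 7-year then eight 4-year periods covering
# 1968-2006); outputs label it as such.
DEFAULT_AGE_BAND_EDGES = np.arange(20, 91, 5)


def default_period_edges(years: np.ndarray) -> np.ndarray:
    """Right-open period edges giving 9 periods over a 39-year window."""
    lo, hi = int(years[0]), int(years[-1])
    if hi - lo + 1 == 39:
        # one 7-year period then eight 4-year periods: 7 + 8*4 = 39
        return np.array([lo, lo + 7] + [lo + 7 + 4 * j for j in range(1, 9)])
    # fallback: ~4-year periods
    edges = list(range(lo, hi + 1, 4))
    if edges[-1] != hi + 1:
        edges.append(hi + 1)
    return np.array(edges)


def _check(Y: np.ndarray, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if Y.shape != lam.shape:
        raise ValueError("observed and fitted arrays must have equal shape")
    return Y, lam


def log_likelihood(Y, lam) -> float:
    """Poisson log-likelihood ``sum(Y ln lam - lam - ln Y!)``.

    Returns ``-inf`` if any cell has ``lam <= 0`` with ``Y > 0`` (an
    impossible observation) or ``lam < 0``; the sampler rejects such states.
    """
    Y, lam = _check(Y, lam)
    if np.any(lam < 0) or np.any((lam == 0) & (Y > 0)):
        return -np.inf
    with np.errstate(divide="ignore"):
        ll = xlogy(Y, lam) - lam - gammaln(Y + 1.0)
    return float(ll.sum())


def _dev_cells(Y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    # per-cell deviance contribution 2*[Y ln(Y/lam) - (Y - lam)]; xlogy
    # handles the Y=0 convention (0 ln 0 = 0)
    return 2.0 * (xlogy(Y, Y) - xlogy(Y, lam) - (Y - lam))


def deviance(Y, lam) -> float:
    """Poisson deviance: twice the log-likelihood gap to the saturated model."""
    Y, lam = _check(Y, lam)
    if np.any(lam <= 0) and np.any(Y[lam <= 0] > 0):
        return np.inf
    return float(_dev_cells(Y, lam).sum())


@dataclass(frozen=True)
class DevianceReport:
    """Banded deviance residuals and the in-[-2, 2] summary."""

    residuals: np.ndarray        # (n_age_bands, n_periods), signed
    age_labels: list[str]
    period_labels: list[str]
    total_deviance: float        # unbanded (cell-level) deviance

    @property
    def n_cells(self) -> int:
        return self.residuals.size

    @property
    def fraction_in_range(self) -> float:
        return float(np.mean(np.abs(self.residuals) <= 2.0))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, al in enumerate(self.age_labels):
            for j, pl in enumerate(self.period_labels):
                r = self.residuals[i, j]
                rows.append({"age_band": al, "period": pl, "residual": r, "in_range": abs(r) <= 2.0})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def deviance_residuals(
    Y,
    lam,
    ages: np.ndarray,
    years: np.ndarray,
    age_edges: np.ndarray | None = None,
    period_edges: np.ndarray | None = None,
) -> DevianceReport:
    """Signed deviance residuals on an aggregated age-band x period grid.

    Counts and fitted values are summed within each aggregated cell first;
    the residual is ``sign(Y - lam) * sqrt(cell deviance)``.  With the
    default banding (14 age bands x 9 periods) this yields 126 residuals.
    """
    Y, lam = _check(Y, lam)
    ages = np.asarray(ages)
    years = np.asarray(years)
    if age_edges is None:
        age_edges = DEFAULT_AGE_BAND_EDGES
    if period_edges is None:
        period_edges = default_period_edges(years)
    age_edges = np.asarray(age_edges)
    period_edges = np.asarray(period_edges)

    ai = np.searchsorted(age_edges, ages, side="right") - 1
    pi = np.searchsorted(period_edges, years, side="right") - 1
    n_a, n_p = age_edges.size - 1, period_edges.size - 1
    if np.any(ai < 0) or np.any(ai >= n_a) or np.any(pi < 0) or np.any(pi >= n_p):
        raise ValueError("banding does not cover the surface grid")

    Yb = np.zeros((n_a, n_p))
    Lb = np.zeros((n_a, n_p))
    aidx = np.broadcast_to(ai[:, None], Y.shape)
    pidx = np.broadcast_to(pi[None, :], Y.shape)
    np.add.at(Yb, (aidx, pidx), Y)
    np.add.at(Lb, (aidx, pidx), lam)
    if np.any((Yb == 0) & (Lb == 0)):
        raise ValueError("empty aggregation cell")

    cells = _dev_cells(Yb, Lb)
    resid = np.sign(Yb - Lb) * np.sqrt(np.maximum(cells, 0.0))
    age_labels = [f"{age_edges[i]}-{age_edges[i+1]-1}" for i in range(n_a)]
    period_labels = [f"{period_edges[j]}-{period_edges[j+1]-1}" for j in range(n_p)]
    return DevianceReport(
        residuals=resid,
        age_labels=age_labels,
        period_labels=period_labels,
        total_deviance=deviance(Y, lam),
    )
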