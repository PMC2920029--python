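"""Forward projection of mesothelioma mortality with uncertainty.

For each retained posterior draw the expected-death surface is evaluated on
the full horizon (fit window plus future population projections), keeping
the draw's own normalisation constant from the fit window.  Yearly totals
across draws give the 90% credible interval of the expectation; a Poisson
realisation of each draw's total adds sampling noise and gives the 90%
prediction interval.  Peak summaries, all-ages rescaling (deaths at ages
20-89 are ~99% of all male deaths, factor 1/0.99) and cumulative totals are
computed per draw and then summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .risk import LambdaComputer, fitted_surface
from .surfaces import MortalitySurface

__all__ = ["ProjectionResult", "project", "find_peak", "rescale_all_ages", "lag_sensitivity",
           "DEFAULT_ALL_AGES_FACTOR"]

DEFAULT_ALL_AGES_FACTOR = 1.0 / 0.99


def rescale_all_ages(series: np.ndarray, factor: float = DEFAULT_ALL_AGES_FACTOR) -> np.ndarray:
    """Rescale 20-89 totals to all-ages totals (factor >= 1)."""
    if factor < 1.0:
        raise ValueError("all-ages rescaling factor must be >= 1")
    return np.asarray(series, dtype=float) * factor


def find_peak(series: np.ndarray, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw peak (argmax) year and height of yearly-total series.

    ``series`` has shape (n_draws, n_years).  Ties break to the earlier
    year (first maximum).
    """
    series = np.atleast_2d(series)
    idx = np.argmax(series, axis=1)
    return np.asarray(years)[idx], series[np.arange(series.shape[0]), idx]


def _summ(x: np.ndarray, q=(5, 50, 95)) -> tuple[float, float, float]:
    lo, med, hi = np.percentile(x, q)
    return float(med), float(lo), float(hi)


@dataclass(frozen=True)
class ProjectionResult:
    """Per-year projection summaries plus peak and cumulative-total summaries."""

    table: pd.DataFrame           # year, median, ci_lo/ci_hi, pi_lo/pi_hi
    peak_year: dict               # median, mode, ci (90%)
    peak_deaths: dict             # median, pi (90%)
    cumulative: dict              # per-window {median, pi}
    all_ages_factor: float
    n_draws: int
    draw_series: np.ndarray = field(repr=False, default=None)  # (n_draws, n_years) lambda totals
    years: np.ndarray = field(repr=False, default=None)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        py, pd_ = self.peak_year, self.peak_deaths
        return (
            f"peak {pd_['median']:.0f} deaths (90% PI {pd_['pi'][0]:.0f}-{pd_['pi'][1]:.0f}) "
            f"in {py['mode']} (90% CI {py['ci'][0]}-{py['ci'][1]})"
        )


def project(
    results,
    pop_future: MortalitySurface,
    n_draws: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    all_ages_factor: float = DEFAULT_ALL_AGES_FACTOR,
    horizon: tuple[int, int] | None = None,
    scenario: str = "decline",
) -> ProjectionResult:
    """Project yearly mesothelioma deaths from a fitted model.

    Parameters
    ----------
    results : MesotheliomaResults
        A fitted model (the chain supplies parameter uncertainty).
    pop_future : MortalitySurface
        Person-years covering the projection years after the fit window.
    n_draws : int
        Number of (evenly thinned) posterior draws to propagate.
    all_ages_factor : float
        Applied per draw to convert 20-89 totals to all-male totals; set to
        1.0 to keep the 20-89 series.
    horizon : (int, int), optional
        Year range of the output table (default: fit start to pop end).
    scenario : str
        Exposure assumption after the estimated range: ``"decline"``
        (default anchors) or ``"levelled"``.
    """
    from .exposure import build_curve  # local to avoid cycle at import time

    model = results.model
    data = model.data
    if rng is None:
        rng = np.random.default_rng(seed)
    if horizon is None:
        horizon = (int(data.years[0]), int(pop_future.years[-1]))
    if pop_future.years[0] > data.years[-1] + 1:
        raise ValueError(
            f"future population starts in {pop_future.years[0]}; years "
            f"{data.years[-1] + 1}-{pop_future.years[0] - 1} are missing"
        )
    if pop_future.years[-1] < horizon[1]:
        raise ValueError(f"future population ends in {pop_future.years[-1]}, before horizon {horizon[1]}")

    # One combined person-years surface over the horizon.
    years = np.arange(horizon[0], horizon[1] + 1)
    P = np.empty((data.ages.size, years.size))
    for j, y in enumerate(years):
        if y <= data.years[-1]:
            P[:, j] = data.person_years[:, y - data.years[0]]
        else:
            P[:, j] = pop_future.person_years[:, y - pop_future.years[0]]
    pop_all = MortalitySurface(ages=data.ages, years=years, person_years=P)
    computer = LambdaComputer(pop_all)

    total = len(results.chain)
    take = np.unique(np.linspace(0, total - 1, min(n_draws, total)).astype(int))
    fit_window = (int(data.years[0]), int(data.years[-1]))

    lam_tot = np.empty((take.size, years.size))
    for i, d in enumerate(take):
        params = results.params_at(d)
        curve = build_curve(
            params.knots, params.peakyear,
            start=params.peakyear - model.curve_start_offset,
            end=int(years[-1]), scenario=scenario,
        )
        fit = fitted_surface(params, curve, pop_all, normalise_to=model.M,
                             fit_window=fit_window, computer=computer)
        lam_tot[i] = fit.lam.sum(axis=0)

    lam_tot = rescale_all_ages(lam_tot, all_ages_factor)
    counts = rng.poisson(lam_tot)

    rows = []
    for j, y in enumerate(years):
        med, ci_lo, ci_hi = _summ(lam_tot[:, j])
        _, pi_lo, pi_hi = _summ(counts[:, j])
        rows.append({"year": int(y), "median": med, "ci_lo": ci_lo, "ci_hi": ci_hi,
                     "pi_lo": pi_lo, "pi_hi": pi_hi})
    table = pd.DataFrame(rows)

    peak_years, peak_lam = find_peak(lam_tot, years)
    peak_counts = rng.poisson(peak_lam)
    vals, cnts = np.unique(peak_years, return_counts=True)
    # discrete year draws: round the interval outward so it covers >= 90%
    py_lo = int(np.percentile(peak_years, 5, method="lower"))
    py_hi = int(np.percentile(peak_years, 95, method="higher"))
    pd_med, pd_lo, pd_hi = _summ(peak_counts)
    peak_year = {"median": int(np.median(peak_years)), "mode": int(vals[np.argmax(cnts)]),
                 "ci": (py_lo, py_hi)}
    peak_deaths = {"median": pd_med, "pi": (pd_lo, pd_hi)}

    cumulative = {}
    for label, (lo, hi) in {"total": horizon, "future": (fit_window[1] + 1, horizon[1])}.items():
        if lo > hi:
            continue
        sl = slice(lo - years[0], hi - years[0] + 1)
        sums = rng.poisson(lam_tot[:, sl].sum(axis=1))
        cmed, clo, chi = _summ(sums)
        cumulative[label] = {"window": (int(lo), int(hi)), "median": cmed, "pi": (clo, chi)}

    return ProjectionResult(table=table, peak_year=peak_year, peak_deaths=peak_deaths,
                            cumulative=cumulative, all_ages_factor=all_ages_factor,
                            n_draws=take.size, draw_series=lam_tot, years=years)


def lag_sensitivity(
    data: MortalitySurface,
    pop_future: MortalitySurface,
    lags=(0, 5, 10, 15),
    fitter: str = "map",
    seed: int | None = None,
    model_kwargs: dict | None = None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Deviance and peak summaries as the assumed lag ``L`` varies.

    Each lag is fitted with identical priors; ``fitter="map"`` (default)
    uses the fast posterior-mode fit and a deterministic projection of the
    expected yearly totals, ``fitter="mh"`` runs the full sampler (slow).
    The minimum-deviance lag is flagged.
    """
    from . import likelihood as lik
    from .model import MesotheliomaModel

    rows = []
    for lag in lags:
        m = MesotheliomaModel(data, L=lag, **(model_kwargs or {}))
        if fitter == "map":
            params = m.fit_map(**(fit_kwargs or {}))
        elif fitter == "mh":
            res = m.fit(seed=seed, **(fit_kwargs or {}))
            params = res.posterior_median_params()
        else:
            raise ValueError("fitter must be 'map' or 'mh'")
        dev = lik.deviance(data.deaths, m.fitted(params).lam)

        # deterministic peak of the expected series on the full horizon
        years = np.arange(data.years[0], pop_future.years[-1] + 1)
        P = np.empty((data.ages.size, years.size))
        for j, y in enumerate(years):
            src = data if y <= data.years[-1] else pop_future
            P[:, j] = src.person_years[:, y - src.years[0]]
        pop_all = MortalitySurface(ages=data.ages, years=years, person_years=P)
        curve = m.curve_for(params)
        fit = fitted_surface(params, curve, pop_all, normalise_to=m.M,
                             fit_window=(int(data.years[0]), int(data.years[-1])))
        peak_years, peak_vals = find_peak(fit.lam.sum(axis=0), years)
        rows.append({"lag": lag, "deviance": dev, "peak_year": int(peak_years[0]),
                     "peak_deaths": float(peak_vals[0]), "k": params.k})
    out = pd.DataFrame(rows)
    out["min_deviance"] = out["deviance"] == out["deviance"].min()
    return out
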