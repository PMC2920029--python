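"""Reference simulation experiments: parameter recovery and calibration.

These drive the package's own validation studies: simulate a death surface
from the model at the reference truth, refit it blind, and check that the
generating values are recovered; calibrate deviance residuals and
prediction intervals against their nominal behaviour.  All entry points
take a single integer seed and derive independent sub-seeds from it, so a
whole study is reproducible from one number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import deviance_residuals
from .model import MesotheliomaModel, MesotheliomaResults
from .params import ParameterSet
from .projection import lag_sensitivity
from .risk import fitted_surface
from .surfaces import MortalitySurface
from .synthetic import DEFAULT_TARGET_DEATHS, calibrate_scale, default_truth, make_population, simulate_deaths

__all__ = ["RecoveryStudy", "run_recovery", "deviance_calibration", "prediction_interval_coverage",
           "lag_profile", "subseeds"]


def subseeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit seeds from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass
class RecoveryStudy:
    """Everything produced by one simulate-and-refit experiment."""

    truth: ParameterSet
    c_true: float
    data: MortalitySurface
    population: MortalitySurface
    model: MesotheliomaModel
    results: MesotheliomaResults

    def recovered(self) -> dict[str, dict]:
        """Posterior summaries of the headline parameters vs their truths."""
        s = self.results.summary()
        peak = self.results.peak_exposure_summary()
        out = {}
        for name, true_val in (("k", self.truth.k), ("rate", self.truth.rate),
                               ("W:30-39", float(self.truth.W[4]))):
            out[name] = {
                "truth": true_val,
                "median": float(s.loc[name, "median"]),
                "ci": (float(s.loc[name, "ci5"]), float(s.loc[name, "ci95"])),
            }
        out["peak_exposure_year"] = {"truth": self.truth.peakyear, **peak}
        return out


def run_recovery(
    seed: int,
    n_burn: int = 4_000,
    n_keep: int = 12_000,
    target_deaths: float = DEFAULT_TARGET_DEATHS,
) -> RecoveryStudy:
    """Simulate the reference world and refit it with the MH sampler.

    The default chain length is a scaled-down version of the reference run
    (20 000 burn-in / 35 000 retained): recovery studies need repetition
    more than they need single-chain Monte Carlo precision.
    """
    data_seed, chain_seed = subseeds(seed, 2)
    truth = default_truth()
    population = make_population()
    c_true = calibrate_scale(truth, population, target_deaths=target_deaths)
    data, _ = simulate_deaths(truth, population, c_true, seed=data_seed)
    model = MesotheliomaModel(data)
    results = model.fit(n_burn=n_burn, n_keep=n_keep, seed=chain_seed)
    return RecoveryStudy(truth=truth, c_true=c_true, data=data,
                         population=population, model=model, results=results)


def deviance_calibration(seed: int, n_seeds: int = 20) -> np.ndarray:
    """In-[-2, 2] fraction of the 126 banded residuals, per simulated dataset.

    Data are simulated from the model at the reference truth and judged
    against that same (well-specified) truth, so the residuals should be
    approximately standard normal and the fraction near 0.95.
    """
    truth = default_truth()
    population = make_population()
    c_true = calibrate_scale(truth, population)
    window = population.year_slice(1968, 2006)
    from .exposure import build_curve

    curve = build_curve(truth.knots, truth.peakyear, end=2006)
    lam = fitted_surface(truth, curve, window, c=c_true).lam
    fracs = []
    for s in subseeds(seed, n_seeds):
        data, _ = simulate_deaths(truth, population, c_true, seed=s)
        rep = deviance_residuals(data.deaths, lam, ages=data.ages, years=data.years)
        fracs.append(rep.fraction_in_range)
    return np.array(fracs)


def prediction_interval_coverage(
    study: RecoveryStudy,
    seed: int,
    n_replicates: int = 200,
    n_draws: int = 400,
) -> float:
    """Fraction of simulated future yearly totals inside the fitted 90% PI.

    Replicate futures are drawn from the *generating* truth (the model the
    data actually came from); the interval comes from the fitted chain.
    """
    rep_seed, proj_seed = subseeds(seed + 1, 2)
    future = study.population.year_slice(2007, 2050)
    proj = study.results.project(future, n_draws=n_draws, seed=proj_seed, all_ages_factor=1.0)
    from .exposure import build_curve

    curve = build_curve(study.truth.knots, study.truth.peakyear, end=2050)
    lam_future = fitted_surface(study.truth, curve, future, c=study.c_true).lam.sum(axis=0)
    rng = np.random.default_rng(rep_seed)
    reps = rng.poisson(lam_future, size=(n_replicates, lam_future.size))
    tab = proj.table.set_index("year").loc[future.years]
    lo = tab["pi_lo"].to_numpy()
    hi = tab["pi_hi"].to_numpy()
    return float(((reps >= lo) & (reps <= hi)).mean())


def lag_profile(seed: int, lags=(0, 5, 10, 15), target_deaths: float = DEFAULT_TARGET_DEATHS):
    """Deviance-vs-lag profile on data generated with the true lag of 10.

    Uses the fast posterior-mode fitter with the peak year pinned to the
    generating value (identical for every lag), a scaled-down stand-in for
    refitting the full sampler at each lag.
    """
    truth = default_truth()
    population = make_population()
    c_true = calibrate_scale(truth, population, target_deaths=target_deaths)
    data, _ = simulate_deaths(truth, population, c_true, seed=subseeds(seed, 1)[0])
    future = population.year_slice(2007, 2050)
    return lag_sensitivity(
        data, future, lags=lags,
        model_kwargs={"fixed": {"peakyear": truth.peakyear}},
        fit_kwargs={"peakyear_free": False, "n_rounds": 0},
    )
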