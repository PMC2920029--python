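"""Synthetic population surfaces and death counts.

The national mesothelioma register and official population projections are
not redistributable, so every stage of the pipeline is exercised on
synthetic stand-ins with the statistical structure the model assumes:

* :func:`make_population` builds a smooth, plausible male person-years
  surface — ages 20-89, a unimodal age structure that slowly ages, totals
  drifting from ~19 million (1968) through 21.3 million (2006) toward
  ~23 million (2050);
* :func:`simulate_deaths` runs the risk model forward at a chosen "truth"
  parameter set and draws Poisson death counts.

The generator uses an explicit absolute scale ``c`` (calibrated with
:func:`calibrate_scale` to a target fit-window death total, default
34 000) rather than the fitter's normalise-to-observed-total convention,
which would be circular when generating.  A truth manifest (parameters,
scale, seed) suffices to regenerate any dataset bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import build_curve
from .params import ParameterSet, reference_parameters
from .risk import fitted_surface
from .surfaces import MortalitySurface

__all__ = ["PopulationModel", "make_population", "simulate_deaths", "calibrate_scale",
           "default_truth", "DEFAULT_TARGET_DEATHS"]

#: Target observed-death total over the 1968-2006 fit window, matching the
#: scale of the British male register series.
DEFAULT_TARGET_DEATHS = 34_000.0


@dataclass(frozen=True)
class PopulationModel:
    """Smooth parametric male population surface, ages 20-89.

    Totals follow a monotone interpolation through ``total_anchors``; the
    age structure is a gamma-shaped density over age whose mode drifts
    linearly (population ageing).  ``jitter`` adds mild seeded lognormal
    roughness (0 = fully deterministic, the default).
    """

    years: tuple[int, int] = (1968, 2050)
    ages: tuple[int, int] = (20, 89)
    total_anchors: tuple[tuple[int, float], ...] = (
        (1968, 19.0e6), (1990, 20.3e6), (2006, 21.3e6), (2050, 23.0e6),
    )
    age_mode_anchors: tuple[tuple[int, float], ...] = ((1968, 38.0), (2050, 46.0))
    age_shape: float = 2.2
    jitter: float = 0.0

    def totals(self, years: np.ndarray) -> np.ndarray:
        xp = [y for y, _ in self.total_anchors]
        fp = [t for _, t in self.total_anchors]
        return np.interp(years, xp, fp)


def make_population(model: PopulationModel | None = None, seed: int | None = None) -> MortalitySurface:
    """Person-years surface from a :class:`PopulationModel` (deterministic given seed)."""
    model = model or PopulationModel()
    ages = np.arange(model.ages[0], model.ages[1] + 1)
    years = np.arange(model.years[0], model.years[1] + 1)
    totals = model.totals(years)
    mode_anchors = model.age_mode_anchors
    modes = np.interp(years, [y for y, _ in mode_anchors], [m for _, m in mode_anchors])

    # gamma-like density over age: (a - 18)^shape * exp(-(a - 18)/theta),
    # theta set so the mode lands at the target mode
    a = ages[:, None].astype(float) - 18.0
    theta = (modes[None, :] - 18.0) / model.age_shape
    dens = a ** model.age_shape * np.exp(-a / theta)
    dens /= dens.sum(axis=0, keepdims=True)
    P = dens * totals[None, :]
    if model.jitter > 0:
        rng = np.random.default_rng(seed)
        P = P * np.exp(rng.normal(0.0, model.jitter, size=P.shape))
    return MortalitySurface(ages=ages, years=years, person_years=P)


def default_truth() -> ParameterSet:
    """The canonical generating truth: the reference point estimates."""
    return reference_parameters()


def _curve(truth: ParameterSet, end: int = 2050):
    return build_curve(truth.knots, truth.peakyear, start=truth.peakyear - 80, end=end)


def calibrate_scale(
    truth: ParameterSet,
    pop: MortalitySurface,
    target_deaths: float = DEFAULT_TARGET_DEATHS,
    fit_window: tuple[int, int] = (1968, 2006),
) -> float:
    """Absolute asbestos scale ``c`` giving ``target_deaths`` expected deaths.

    Solves ``sum(p * (c*u + B)) = target`` over the fit window.
    """
    window = pop.year_slice(*fit_window)
    fit = fitted_surface(truth, _curve(truth, end=fit_window[1]), window,
                         normalise_to=target_deaths, fit_window=fit_window)
    return fit.c


def simulate_deaths(
    truth: ParameterSet,
    pop: MortalitySurface,
    c: float,
    fit_window: tuple[int, int] = (1968, 2006),
    seed: int | None = None,
) -> tuple[MortalitySurface, dict]:
    """Poisson death counts from the model at ``truth`` with scale ``c``.

    Returns the surface restricted to ``fit_window`` (deaths attached) and
    a truth manifest sufficient to regenerate it bit-identically.
    """
    window = pop.year_slice(*fit_window)
    fit = fitted_surface(truth, _curve(truth, end=fit_window[1]), window, c=c)
    if not np.all(np.isfinite(fit.lam)):
        raise ValueError("expected-death surface is not finite at the generating truth")
    rng = np.random.default_rng(seed)
    deaths = rng.poisson(fit.lam)
    surface = MortalitySurface(ages=window.ages, years=window.years,
                               person_years=window.person_years, deaths=deaths)
    manifest = {
        "truth": truth.to_dict(),
        "c": float(c),
        "fit_window": list(fit_window),
        "seed": seed,
        "rng": "numpy.random.default_rng(PCG64)",
    }
    return surface, manifest
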