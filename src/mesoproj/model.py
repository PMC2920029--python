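"""Model/Results interface for the mesothelioma mortality model.

:class:`MesotheliomaModel` wraps an observed death surface (ages 20-89 by
calendar year) and the model configuration — which parameters are free,
their uniform priors, the fixed clearance half-life ``H`` and lag ``L``.
``fit()`` runs component-wise Metropolis-Hastings and returns a
:class:`MesotheliomaResults` holding the posterior chain, with ``summary()``,
deviance diagnostics, and ``project()`` for forward mortality projections.
``fit_map()`` gives a fast posterior-mode point fit for sensitivity sweeps.

The sampled parameter vector (default free set) is::

    k, rate, peakyear, W:<band> for the eight non-baseline age bands,
    D:<offset> for the six estimated growth-rate knots

with ``alpha`` added when the diagnostic trend is switched on.  The
asbestos scale ``c`` is not sampled: at every likelihood evaluation it is
profiled out by normalising total fitted deaths over the fit window to the
observed total ``M``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from . import likelihood as lik
from . import sampler as smp
from .exposure import ConfigurationError, ExposureCurve, GrowthRateKnots, build_curve
from .params import AGE_BANDS, BASELINE_BAND, ParameterSet
from .risk import FittedSurface, LambdaComputer, fitted_surface
from .surfaces import MortalitySurface

__all__ = ["MesotheliomaModel", "MesotheliomaResults", "default_priors", "FREE_KNOT_OFFSETS"]

FREE_KNOT_OFFSETS = (-35, -25, -15, -5, 5, 15)
FREE_W_BANDS = tuple(b for i, b in enumerate(AGE_BANDS) if i != BASELINE_BAND)


def default_priors(diagnostic_trend: bool = False) -> smp.PriorSpec:
    """Non-informative uniform priors over plausible ranges.

    k ~ U(0, 10); each free age weight W ~ U(0, 10); each free growth-rate
    knot ~ U(-100, 200) %/year; background rate ~ U(0, 20) per million;
    peak year discrete uniform on 1950-2000; diagnostic trend alpha
    ~ U(-7, 9) %/year when enabled.
    """
    bounds: dict[str, tuple[float, float]] = {
        "k": (0.0, 10.0),
        "rate": (0.0, 20.0),
        "peakyear": (1950, 2000),
    }
    for band in FREE_W_BANDS:
        bounds[f"W:{band}"] = (0.0, 10.0)
    for off in FREE_KNOT_OFFSETS:
        bounds[f"D:{off}"] = (-100.0, 200.0)
    if diagnostic_trend:
        bounds["alpha"] = (-7.0, 9.0)
    return smp.PriorSpec(bounds=bounds, integer=frozenset({"peakyear"}))


class MesotheliomaModel:
    """Bayesian Poisson regression of a mesothelioma death surface.

    Parameters
    ----------
    data : MortalitySurface
        Deaths and person-years on the fit window (deaths required).
    H, L : float, int
        Fixed clearance half-life (years; the default of 1e6 means
        essentially no clearance) and exposure-to-disease lag (years).
    diagnostic_trend : bool
        Sample the under-recording trend ``alpha`` (default off: recording
        is treated as complete, ``p == 1``).
    priors : PriorSpec, optional
        Override the default uniform priors.
    curve_start_offset : int
        Exposure history starts at ``peakyear - curve_start_offset``.
    fixed : dict, optional
        Pin any sampled parameter (e.g. ``{"peakyear": 1963}``) to a value;
        it is removed from the free set.
    """

    def __init__(
        self,
        data: MortalitySurface,
        H: float = 1_000_000.0,
        L: int = 10,
        diagnostic_trend: bool = False,
        priors: smp.PriorSpec | None = None,
        curve_start_offset: int = 80,
        fixed: dict[str, float] | None = None,
    ):
        if data.deaths is None:
            raise ValueError("model data must include observed deaths")
        self.data = data
        self.H = float(H)
        self.L = int(L)
        self.diagnostic_trend = diagnostic_trend
        self.curve_start_offset = int(curve_start_offset)
        self.fixed = dict(fixed or {})
        base = priors if priors is not None else default_priors(diagnostic_trend)
        bounds = {n: b for n, b in base.bounds.items() if n not in self.fixed}
        self.priors = smp.PriorSpec(bounds=bounds, integer=base.integer & set(bounds))
        self.M = data.total_deaths
        self._computer = LambdaComputer(data)
        # Likelihood constants: sum ln Y! and masks for the xlogy term.
        Y = data.deaths.astype(float)
        self._Y = Y
        self._lgamma_const = float(gammaln(Y + 1.0).sum())
        self._curve_cache: dict[tuple, ExposureCurve] = {}
        self._u_cache: dict[tuple, np.ndarray] = {}

    @classmethod
    def from_csv(cls, person_years_path, deaths_path, **kwargs) -> "MesotheliomaModel":
        return cls(MortalitySurface.from_csv(person_years_path, deaths_path), **kwargs)

    # ---- parameter plumbing ---------------------------------------------

    def state_to_params(self, state: dict[str, float]) -> ParameterSet:
        """Assemble a ParameterSet from a sampler state dict (plus fixed values)."""
        get = lambda n, d=None: state.get(n, self.fixed.get(n, d))
        W = []
        for i, band in enumerate(AGE_BANDS):
            W.append(1.0 if i == BASELINE_BAND else float(get(f"W:{band}")))
        knots = GrowthRateKnots({off: float(get(f"D:{off}")) for off in FREE_KNOT_OFFSETS})
        alpha = get("alpha") if (self.diagnostic_trend or "alpha" in self.fixed) else None
        return ParameterSet(
            k=float(get("k")),
            rate=float(get("rate")),
            peakyear=int(round(get("peakyear"))),
            knots=knots,
            W=np.asarray(W),
            H=self.H,
            L=self.L,
            alpha=None if alpha is None else float(alpha),
        )

    def params_to_state(self, params: ParameterSet) -> dict[str, float]:
        state: dict[str, float] = {"k": params.k, "rate": params.rate, "peakyear": params.peakyear}
        for i, band in enumerate(AGE_BANDS):
            if i != BASELINE_BAND:
                state[f"W:{band}"] = float(params.W[i])
        for off in FREE_KNOT_OFFSETS:
            state[f"D:{off}"] = params.knots.rates[off]
        if params.alpha is not None:
            state["alpha"] = params.alpha
        return {n: v for n, v in state.items() if n in self.priors.bounds}

    def curve_for(self, params: ParameterSet) -> ExposureCurve:
        key = (params.peakyear, tuple(sorted(params.knots.rates.items())))
        curve = self._curve_cache.get(key)
        if curve is None:
            curve = build_curve(
                params.knots, params.peakyear,
                start=params.peakyear - self.curve_start_offset,
                end=max(2050, int(self.data.years[-1])),
            )
            if len(self._curve_cache) > 8:
                self._curve_cache.clear()
            self._curve_cache[key] = curve
        return curve

    # ---- likelihood ------------------------------------------------------

    def fitted(self, params: ParameterSet, c: float | None = None) -> FittedSurface:
        """Expected-death surface at ``params`` (normalised to M unless ``c`` given)."""
        return fitted_surface(
            params, self.curve_for(params), self.data,
            normalise_to=None if c is not None else self.M, c=c,
            computer=self._computer,
        )

    def loglike(self, params: ParameterSet) -> float:
        """Poisson log-likelihood at ``params`` with c profiled to match M."""
        try:
            fit = self.fitted(params)
        except (ValueError, ConfigurationError):
            return -np.inf
        lam = fit.lam
        if np.any(lam <= 0):
            return -np.inf
        return float(xlogy(self._Y, lam).sum() - lam.sum() - self._lgamma_const)

    def log_post(self, state: dict[str, float]) -> float:
        """Log-posterior up to a constant (uniform priors: likelihood on support)."""
        try:
            params = self.state_to_params(state)
        except (ValueError, ConfigurationError):
            return -np.inf
        return self.loglike(params)

    # ---- fitting ---------------------------------------------------------

    def start_state(self, overrides: dict[str, float] | None = None) -> dict[str, float]:
        """Default chain start: prior midpoints, peak year 1975."""
        state = self.priors.midpoint()
        if "peakyear" in state:
            state["peakyear"] = 1975
        if overrides:
            state.update({n: v for n, v in overrides.items() if n in state})
        return state

    def fit(
        self,
        n_burn: int = 20_000,
        n_keep: int = 35_000,
        seed: int | None = None,
        start: dict[str, float] | ParameterSet | None = None,
        proposals: smp.ProposalSpec | None = None,
        tune: bool = True,
        tune_rounds: int = 12,
        tune_sweeps: int = 50,
    ) -> "MesotheliomaResults":
        """Run the Metropolis-Hastings sampler and return results.

        The reference run uses a burn-in of 20 000 sweeps and 35 000
        retained draws; scaled-down runs (a few thousand retained draws)
        are adequate for synthetic-data work.
        """
        rng = np.random.default_rng(seed)
        if isinstance(start, ParameterSet):
            start = self.params_to_state(start)
        if start is None:
            # The peak-year label and the peak-relative knots are strongly
            # coupled; a midpoint start strands the chain in a shifted local
            # basin.  Initialise from a coarse profile-likelihood grid.
            state = self.params_to_state(self.fit_map(n_rounds=1))
        else:
            state = self.start_state(start)
        if tune:
            proposals, state = smp.tune_proposals(
                self.log_post, self.priors, state, rng,
                proposals=proposals, n_rounds=tune_rounds, sweeps_per_round=tune_sweeps,
            )
        elif proposals is None:
            raise ValueError("tune=False requires explicit proposals")
        chain = smp.run_chain(self.log_post, self.priors, proposals, state,
                              n_burn=n_burn, n_keep=n_keep, seed=seed, rng=rng)
        return MesotheliomaResults(self, chain, proposals)

    def _optimise_continuous(self, state: dict[str, float], maxiter: int = 400) -> dict[str, float]:
        """L-BFGS-B over the continuous parameters in prior-width-normalised
        coordinates (the knot rates span hundreds of %/year while k spans
        units; unnormalised finite differences misbehave)."""
        from scipy.optimize import minimize

        cont = [n for n in self.priors.names if n != "peakyear"]
        lo = np.array([self.priors.bounds[n][0] for n in cont])
        hi = np.array([self.priors.bounds[n][1] for n in cont])
        width = hi - lo

        def neg(z: np.ndarray) -> float:
            s = dict(state)
            s.update(zip(cont, lo + z * width))
            lp = self.log_post(s)
            return -lp if np.isfinite(lp) else 1e12

        z0 = (np.array([state[n] for n in cont]) - lo) / width
        res = minimize(neg, np.clip(z0, 1e-6, 1 - 1e-6), method="L-BFGS-B",
                       bounds=[(1e-6, 1 - 1e-6)] * len(cont),
                       options={"maxiter": maxiter, "eps": 1e-6})
        out = dict(state)
        out.update(zip(cont, lo + res.x * width))
        return out

    def canonicalise_label(self, state: dict[str, float]) -> dict[str, float]:
        """Re-anchor the peak-year label to the realised curve maximum.

        The label and the peak-relative knots are jointly degenerate: a
        shifted label with compensating knot rates can describe nearly the
        same calendar curve.  This move relabels the state so the label
        coincides with the realised argmax year, re-deriving each free knot
        rate from the old curve's year-on-year growth at the new offsets
        (clipped into the prior).  The result approximates the same curve
        and is meant to be re-optimised afterwards.
        """
        if "peakyear" not in self.priors.bounds:
            return dict(state)
        params = self.state_to_params(state)
        curve = self.curve_for(params)
        sel = curve.years <= params.peakyear + 15
        ystar = int(curve.years[sel][np.argmax(curve.D[sel])])
        lo, hi = self.priors.bounds["peakyear"]
        ystar = int(np.clip(ystar, lo, hi))
        if ystar == params.peakyear:
            return dict(state)
        new = dict(state)
        new["peakyear"] = ystar
        D, yrs = curve.D, curve.years
        for off in FREE_KNOT_OFFSETS:
            i = ystar + off - yrs[0]
            r = 100.0 * (D[i + 1] / D[i] - 1.0) if 0 <= i < D.size - 1 and D[i] > 0 else 0.0
            blo, bhi = self.priors.bounds[f"D:{off}"]
            new[f"D:{off}"] = float(np.clip(r, blo + 1e-6, bhi - 1e-6))
        return new

    def fit_map(
        self,
        start: dict[str, float] | ParameterSet | None = None,
        peakyear_free: bool = True,
        peakyear_grid: int = 5,
        n_rounds: int = 2,
    ) -> ParameterSet:
        """Posterior-mode (maximum-likelihood under flat priors) point fit.

        The peak year and the growth-rate knots are strongly coupled (the
        knots are anchored to the peak year), so a naive joint search finds
        shifted local modes.  The fit therefore profiles over a coarse
        integer grid of peak years (spacing ``peakyear_grid``, warm-starting
        each fit from the running best), then polishes the winner with a
        +/-1 hill-climb alternating with continuous re-optimisation.  Used
        for fast sensitivity sweeps; the MH sampler remains the inferential
        tool.
        """
        if isinstance(start, ParameterSet):
            start = self.params_to_state(start)
        state = self.start_state(start)

        if peakyear_free and "peakyear" in state:
            lo, hi = (int(b) for b in self.priors.bounds["peakyear"])
            candidates = list(range(lo, hi + 1, peakyear_grid))
            best_state, best_lp = None, -np.inf
            warm = dict(state)
            for py in candidates:
                warm = dict(warm)
                warm["peakyear"] = py
                warm = self._optimise_continuous(warm, maxiter=150)
                lp = self.log_post(warm)
                if lp > best_lp:
                    best_state, best_lp = dict(warm), lp
            state = best_state
        state = self._optimise_continuous(state)

        if peakyear_free and "peakyear" in state:
            # Relabel to the realised curve maximum and re-converge; keep
            # whichever basin fits better.  Two optimiser restarts per
            # branch: restarting L-BFGS-B resets its curvature estimate and
            # reliably closes the last few log-units on this ridged surface.
            canon = self.canonicalise_label(state)
            if canon["peakyear"] != state["peakyear"]:
                canon = self._optimise_continuous(canon, maxiter=800)
                canon = self._optimise_continuous(canon, maxiter=800)
                state = self._optimise_continuous(state, maxiter=800)
                if self.log_post(canon) > self.log_post(state):
                    state = canon
            else:
                state = self._optimise_continuous(state, maxiter=800)

        for _ in range(n_rounds):
            if not peakyear_free or "peakyear" not in state:
                break
            lo, hi = self.priors.bounds["peakyear"]
            best_lp = self.log_post(state)
            improved = True
            while improved:
                improved = False
                for step in (-2, -1, 1, 2):
                    cand = dict(state)
                    cand["peakyear"] = state["peakyear"] + step
                    if not lo <= cand["peakyear"] <= hi:
                        continue
                    cand = self._optimise_continuous(cand, maxiter=100)
                    lp = self.log_post(cand)
                    if lp > best_lp:
                        state, best_lp, improved = cand, lp, True
                        break
            state = self._optimise_continuous(state)
        return self.state_to_params(state)


@dataclass
class MesotheliomaResults:
    """Posterior chain plus convenience summaries, diagnostics and projection."""

    model: MesotheliomaModel
    chain: smp.PosteriorChain
    proposals: smp.ProposalSpec | None = None

    def summary(self) -> pd.DataFrame:
        """Posterior median, 90% credible interval and acceptance per parameter."""
        return smp.summarise(self.chain, integer=self.model.priors.integer)

    def params_at(self, draw: int) -> ParameterSet:
        state = dict(zip(self.chain.names, self.chain.draws[draw]))
        return self.model.state_to_params(state)

    def posterior_median_params(self) -> ParameterSet:
        """ParameterSet at componentwise posterior medians (peak year: mode)."""
        s = self.summary()
        state = {n: s.loc[n, "median"] for n in self.chain.names}
        if "peakyear" in state and "mode" in s.columns and np.isfinite(s.loc["peakyear", "mode"]):
            state["peakyear"] = s.loc["peakyear", "mode"]
        return self.model.state_to_params(state)

    def peak_exposure_years(self, max_draws: int = 2000) -> np.ndarray:
        """Calendar year of maximum realised exposure, per posterior draw.

        The peak-year *label* parameter is only weakly identified (the
        peak-relative knots can translate to mimic the same calendar
        curve), but the argmax year of the realised exposure curve is well
        identified and is the quantity of scientific interest.  Draws are
        evenly thinned to at most ``max_draws``.
        """
        total = len(self.chain)
        take = np.unique(np.linspace(0, total - 1, min(max_draws, total)).astype(int))
        years = np.empty(take.size, dtype=int)
        for i, d in enumerate(take):
            params = self.params_at(d)
            curve = self.model.curve_for(params)
            # restrict to the estimated range: the assumed post-range tail
            # never exceeds the peak by construction
            sel = curve.years <= params.peakyear + 15
            years[i] = int(curve.years[sel][np.argmax(curve.D[sel])])
        return years

    def peak_exposure_summary(self, max_draws: int = 2000) -> dict:
        """Mode, median and 90% interval of the realised peak-exposure year."""
        years = self.peak_exposure_years(max_draws)
        vals, counts = np.unique(years, return_counts=True)
        lo, med, hi = np.percentile(years, [5, 50, 95])
        return {"mode": int(vals[np.argmax(counts)]), "median": int(round(med)),
                "ci": (int(round(lo)), int(round(hi)))}

    # ---- diagnostics -----------------------------------------------------

    def fitted(self, params: ParameterSet | None = None) -> FittedSurface:
        return self.model.fitted(params or self.posterior_median_params())

    def deviance(self, params: ParameterSet | None = None) -> float:
        return lik.deviance(self.model.data.deaths, self.fitted(params).lam)

    def deviance_report(self, params: ParameterSet | None = None, **kwargs) -> lik.DevianceReport:
        fit = self.fitted(params)
        return lik.deviance_residuals(
            self.model.data.deaths, fit.lam,
            ages=self.model.data.ages, years=self.model.data.years, **kwargs,
        )

    # ---- projection ------------------------------------------------------

    def project(self, pop_future: MortalitySurface, **kwargs):
        """Forward projection; see :func:`mesoproj.projection.project`."""
        from .projection import project
        return project(self, pop_future, **kwargs)

    # ---- plots -----------------------------------------------------------

    def plot_trace(self, names: list[str] | None = None, ax=None):
        import matplotlib.pyplot as plt

        names = names or self.chain.names
        fig, axes = plt.subplots(len(names), 1, figsize=(8, 1.6 * len(names)), sharex=True)
        axes = np.atleast_1d(axes)
        for a, name in zip(axes, names):
            a.plot(self.chain.column(name), lw=0.5)
            a.set_ylabel(name)
        axes[-1].set_xlabel("retained draw")
        return fig

    def plot_fit(self, ax=None):
        """Observed vs fitted yearly totals over the fit window."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        years = self.model.data.years
        ax.plot(years, self.model.data.deaths.sum(axis=0), "k.", label="observed")
        ax.plot(years, self.fitted().yearly_totals(), "-", label="fitted")
        ax.set_xlabel("year"); ax.set_ylabel("deaths"); ax.legend()
        return ax
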