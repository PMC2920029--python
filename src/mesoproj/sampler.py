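"""Component-wise random-walk Metropolis-Hastings.

A generic sampler over a named parameter vector with independent uniform
priors.  Each sweep updates one parameter at a time in a fixed order with a
symmetric random walk: Gaussian steps for continuous parameters, and for
integer parameters (the peak-exposure year) a symmetric integer step of
magnitude ``max(1, round(|N(0, s)|))``.  Proposals outside the prior
support are rejected outright (posterior ratio zero).  Proposal scales are
tuned in pilot rounds toward a 20-45% acceptance band and frozen before
burn-in, so adaptation never contaminates retained draws.

The RNG is ``numpy.random.Generator`` with the PCG64 bit generator
throughout; chains are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["PriorSpec", "ProposalSpec", "PosteriorChain", "mh_step", "tune_proposals", "run_chain", "summarise"]

ACCEPTANCE_BAND = (0.20, 0.45)


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: ``name -> (low, high)``; integer names noted."""

    bounds: dict[str, tuple[float, float]]
    integer: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r}: lower bound {lo} not below upper {hi}")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def in_support(self, name: str, value: float) -> bool:
        lo, hi = self.bounds[name]
        return lo <= value <= hi

    def midpoint(self) -> dict[str, float]:
        out = {}
        for name, (lo, hi) in self.bounds.items():
            mid = 0.5 * (lo + hi)
            out[name] = int(round(mid)) if name in self.integer else mid
        return out


@dataclass
class ProposalSpec:
    """Per-parameter random-walk scales (standard deviations)."""

    scales: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.scales.items():
            if s <= 0:
                raise ValueError(f"proposal scale for {name!r} must be positive")

    def copy(self) -> "ProposalSpec":
        return ProposalSpec(dict(self.scales))


@dataclass
class PosteriorChain:
    """Ordered retained draws with acceptance bookkeeping."""

    names: list[str]
    draws: np.ndarray                   # (n_keep, n_params)
    acceptance: dict[str, float]
    n_burn: int
    seed: int | None = None
    log_post: np.ndarray | None = None  # log-posterior at each retained draw

    def __len__(self) -> int:
        return self.draws.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_burn: int = 0, seed: int | None = None) -> "PosteriorChain":
        df = pd.read_csv(path)
        return cls(names=list(df.columns), draws=df.to_numpy(dtype=float),
                   acceptance={}, n_burn=n_burn, seed=seed)


def _propose(value: float, scale: float, integer: bool, rng: np.random.Generator) -> float:
    if integer:
        step = max(1, int(round(abs(rng.normal(0.0, scale)))))
        return value + step * (1 if rng.random() < 0.5 else -1)
    return value + rng.normal(0.0, scale)


def mh_step(
    state: dict[str, float],
    name: str,
    log_post: Callable[[dict[str, float]], float],
    current_lp: float,
    priors: PriorSpec,
    proposals: ProposalSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, float], float, bool]:
    """One Metropolis-Hastings update of parameter ``name``.

    Returns ``(state, log-posterior, accepted)``.  The proposal is
    symmetric, so the acceptance probability is ``min(1, pi(new)/pi(old))``.
    """
    if not np.isfinite(current_lp):
        raise ValueError(f"chain is at a state with non-finite posterior (updating {name!r})")
    proposal = _propose(state[name], proposals.scales[name], name in priors.integer, rng)
    if not priors.in_support(name, proposal):
        return state, current_lp, False
    cand = dict(state)
    cand[name] = proposal
    cand_lp = log_post(cand)
    if np.log(rng.random()) < cand_lp - current_lp:
        return cand, cand_lp, True
    return state, current_lp, False


def _sweeps(
    state: dict[str, float],
    lp: float,
    n: int,
    log_post,
    priors: PriorSpec,
    proposals: ProposalSpec,
    rng: np.random.Generator,
    store: np.ndarray | None = None,
    store_lp: np.ndarray | None = None,
) -> tuple[dict[str, float], float, dict[str, int]]:
    names = priors.names
    accepted = {name: 0 for name in names}
    for i in range(n):
        for name in names:
            state, lp, acc = mh_step(state, name, log_post, lp, priors, proposals, rng)
            accepted[name] += acc
        if store is not None:
            store[i] = [state[name] for name in names]
            store_lp[i] = lp
    return state, lp, accepted


def tune_proposals(
    log_post: Callable[[dict[str, float]], float],
    priors: PriorSpec,
    init: dict[str, float],
    rng: np.random.Generator,
    proposals: ProposalSpec | None = None,
    n_rounds: int = 12,
    sweeps_per_round: int = 50,
) -> tuple[ProposalSpec, dict[str, float]]:
    """Pilot-tune random-walk scales into the 20-45% acceptance band.

    Runs short pilot rounds; after each, any parameter outside the band has
    its scale multiplied (acceptance too high) or divided (too low) by a
    factor shrinking toward the measured/target ratio.  Returns the frozen
    spec and the final pilot state (a convenient over-dispersion-free start
    for burn-in).  A parameter stuck at zero acceptance on the final round
    raises: its scale cannot be made sane automatically.
    """
    if proposals is None:
        scales = {}
        for name, (lo, hi) in priors.bounds.items():
            scales[name] = max(1.0, 0.05 * (hi - lo)) if name in priors.integer else 0.05 * (hi - lo)
        proposals = ProposalSpec(scales)
    else:
        proposals = proposals.copy()

    state = dict(init)
    lp = log_post(state)
    if not np.isfinite(lp):
        raise ValueError("log-posterior is not finite at the tuning start state")
    lo_t, hi_t = ACCEPTANCE_BAND
    target = 0.30
    last_acc: dict[str, float] = {}
    for rnd in range(n_rounds):
        state, lp, accepted = _sweeps(state, lp, sweeps_per_round, log_post, priors, proposals, rng)
        last_acc = {k: v / sweeps_per_round for k, v in accepted.items()}
        all_ok = True
        for name, acc in last_acc.items():
            if lo_t <= acc <= hi_t:
                continue
            all_ok = False
            # multiplicative update, damped; floor protects against collapse
            factor = np.clip((acc + 0.02) / target, 0.25, 4.0)
            s = proposals.scales[name] * factor
            if name in priors.integer:
                s = max(s, 0.5)  # keeps the integer step at >= 1
            proposals.scales[name] = max(s, 1e-12)
        if all_ok:
            break
    # "Stuck" means unfixable: a continuous scale driven to a vanishing
    # fraction of its prior width with still no acceptance.  Integer
    # parameters at the minimal step (1) are exempt — a sharply peaked
    # discrete posterior legitimately sits near zero acceptance at its
    # mode — as are short tuning runs that simply ran out of rounds.
    def _width(name: str) -> float:
        lo, hi = priors.bounds[name]
        return hi - lo

    stuck = [
        name for name, acc in last_acc.items()
        if acc == 0.0
        and not (name in priors.integer and proposals.scales[name] <= 1.0)
        and proposals.scales[name] < 1e-9 * _width(name)
    ]
    if stuck:
        raise RuntimeError(f"proposal tuning failed: zero acceptance for {stuck}")
    return proposals, state


def run_chain(
    log_post: Callable[[dict[str, float]], float],
    priors: PriorSpec,
    proposals: ProposalSpec,
    init: dict[str, float],
    n_burn: int = 20_000,
    n_keep: int = 35_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PosteriorChain:
    """Burn in, then retain ``n_keep`` sweeps of component-wise MH draws.

    One retained draw per full sweep (no thinning).  Deterministic given
    the seed.  Per-parameter acceptance rates are measured over the
    retained phase.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = priors.names
    for name in names:
        if not priors.in_support(name, init[name]):
            raise ValueError(f"initial value of {name!r} outside prior support")
    state = dict(init)
    lp = log_post(state)
    if not np.isfinite(lp):
        raise ValueError("log-posterior is not finite at the initial state")

    state, lp, _ = _sweeps(state, lp, n_burn, log_post, priors, proposals, rng)
    draws = np.empty((n_keep, len(names)))
    lps = np.empty(n_keep)
    state, lp, accepted = _sweeps(state, lp, n_keep, log_post, priors, proposals, rng, draws, lps)
    denom = max(n_keep, 1)
    acc = {name: accepted[name] / denom for name in names}
    return PosteriorChain(names=names, draws=draws, acceptance=acc,
                          n_burn=n_burn, seed=seed, log_post=lps)


def summarise(chain: PosteriorChain, integer: frozenset[str] | set[str] = frozenset()) -> pd.DataFrame:
    """Posterior median and 90% equal-tailed credible interval per parameter.

    Integer-valued parameters additionally report the posterior mode.
    Percentiles use linear interpolation.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    rows = []
    for j, name in enumerate(chain.names):
        x = chain.draws[:, j]
        med, lo, hi = np.percentile(x, [50, 5, 95])
        row = {"parameter": name, "median": med, "ci5": lo, "ci95": hi,
               "acceptance": chain.acceptance.get(name, np.nan)}
        if name in integer:
            vals, counts = np.unique(np.round(x).astype(int), return_counts=True)
            row["mode"] = int(vals[np.argmax(counts)])
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
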