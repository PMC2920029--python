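"""Model parameters.

A :class:`ParameterSet` is one point in parameter space for the mesothelioma
risk model:

* ``k`` — exponent of time since (lagged) exposure; risk grows as
  ``(l - L)^k`` with ``l`` years since exposure,
* ``H`` — clearance half-life of asbestos fibres in the lung (years); the
  fibre burden from exposure ``l`` years ago is attenuated by ``2^(-l/H)``,
* ``L`` — lag (years) between exposure and any possibility of disease,
* ``rate`` — background (non-asbestos) mesothelioma deaths per million
  person-years,
* ``alpha`` — diagnostic-trend parameter: annual percent decrease in missed
  cases working back from 1997 (``None`` disables the trend, the default),
* ``peakyear`` — calendar year of maximum population exposure,
* ``knots`` — growth-rate knots defining the exposure curve shape,
* ``W`` — relative exposure potential for nine age bands, baseline 1 at
  ages 20-29.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exposure import GrowthRateKnots

__all__ = ["AGE_BANDS", "AGE_BAND_EDGES", "ParameterSet", "reference_parameters"]

#: The nine exposure-potential age bands (inclusive bounds).
AGE_BANDS: tuple[str, ...] = (
    "0-4", "5-15", "16-19", "20-29", "30-39", "40-49", "50-59", "60-64", "65+",
)
#: Left edges of the bands; band of age A = last edge <= A.
AGE_BAND_EDGES = np.array([0, 5, 16, 20, 30, 40, 50, 60, 65])

BASELINE_BAND = 3  # 20-29


@dataclass(frozen=True)
class ParameterSet:
    k: float
    rate: float
    peakyear: int
    knots: GrowthRateKnots
    W: np.ndarray
    H: float = 1_000_000.0
    L: int = 10
    alpha: float | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape != (9,):
            raise ValueError("W must have nine age-band weights")
        if np.any(W < 0):
            raise ValueError("age-band weights must be nonnegative")
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        if self.H <= 0:
            raise ValueError("clearance half-life must be positive")
        if self.rate < 0:
            raise ValueError("background rate must be nonnegative")
        if self.L < 0:
            raise ValueError("lag must be nonnegative")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "peakyear", int(self.peakyear))

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "rate": self.rate,
            "peakyear": self.peakyear,
            "knots": {str(o): r for o, r in self.knots.rates.items()},
            "W": self.W.tolist(),
            "H": self.H,
            "L": self.L,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            k=float(d["k"]),
            rate=float(d["rate"]),
            peakyear=int(d["peakyear"]),
            knots=GrowthRateKnots({int(o): float(r) for o, r in d["knots"].items()}),
            W=np.asarray(d["W"], dtype=float),
            H=float(d.get("H", 1_000_000.0)),
            L=int(d.get("L", 10)),
            alpha=None if d.get("alpha") is None else float(d["alpha"]),
        )


def reference_parameters() -> ParameterSet:
    """Point estimates for the British male mortality series, 1968-2006.

    Posterior medians from fitting the model to the national register data:
    peak exposure in 1963, risk rising as the 2.42 power of lagged time
    since exposure, essentially no fibre clearance (H fixed at a million
    years), a background rate of 1.08 cases per million, exposure potential
    concentrated at working ages 30-49, and no diagnostic trend.  Used as
    the canonical generating truth for synthetic-data experiments.
    """
    return ParameterSet(
        k=2.42,
        rate=1.08,
        peakyear=1963,
        knots=GrowthRateKnots(
            {-35: -91.3, -25: 104.6, -15: -25.5, -5: 36.6, 5: -7.5, 15: -18.6}
        ),
        W=np.array([0.0019, 0.0023, 0.25, 1.00, 1.79, 1.59, 0.13, 0.56, 0.42]),
        H=1_000_000.0,
        L=10,
        alpha=None,
    )
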