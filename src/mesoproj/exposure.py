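"""Reconstruction of the relative population asbestos-exposure curve.

The yearly collective dose ``D(T)`` — a unit-free index of average asbestos
exposure in the male breathing zone — is parameterised by annual growth
rates pinned at a small set of knot years placed symmetrically around the
peak-exposure year (``peakyear``), at offsets -65, -55, -45, -35, -25, -15,
-5, +5 and +15 years.  Rates for intermediate years come from linear
interpolation between knots; the rate at the peak year itself is zero by
definition.  The curve evolves multiplicatively year on year,
``D(T+1) = D(T) * (1 + rate(T)/100)``, within the estimated range
``peakyear-65 .. peakyear+15``.

Exposure after the estimated range cannot be identified from mortality data
(latency is too long), so the curve is completed by assumption: a linear
decline from ``D(peakyear+15)`` to 4% of the peak level in 2000, then
linear interpolation through anchors of 2% of peak in 2010 and 0.75% of
peak in 2050.  The whole curve is normalised so that ``D(peakyear) = 1``;
the absolute scale of risk is carried elsewhere by a proportionality
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KNOT_OFFSETS",
    "FIXED_KNOT_RATES",
    "DEFAULT_ANCHORS",
    "GrowthRateKnots",
    "ExposureCurve",
    "interpolate_rates",
    "build_curve",
]

#: Knot offsets (years relative to the peak-exposure year) carrying growth
#: rates.  Offset 0 is the peak year itself, where the rate is 0 by
#: definition and is never estimated.
KNOT_OFFSETS: tuple[int, ...] = (-65, -55, -45, -35, -25, -15, -5, 0, 5, 15)

#: Rates (percent per year) held fixed rather than estimated: the early part
#: of the curve is forced to a negligible level rising steeply, and the rate
#: at the peak year is zero.  The -45 rate is conventionally 100 000 %/year;
#: pass an explicit rate to override.
FIXED_KNOT_RATES: dict[int, float] = {-65: 0.0, -55: 1000.0, -45: 100_000.0, 0: 0.0}

#: Post-2000 exposure assumptions: (calendar year, fraction of peak level).
DEFAULT_ANCHORS: tuple[tuple[int, float], ...] = ((2000, 0.04), (2010, 0.02), (2050, 0.0075))


class ConfigurationError(ValueError):
    """Raised when a knot set or curve request is internally inconsistent."""


@dataclass(frozen=True)
class GrowthRateKnots:
    """Growth/decline rates (percent per year) at the knot offsets.

    Parameters
    ----------
    rates : dict[int, float]
        Mapping ``offset -> rate``.  Offsets must be a subset of
        :data:`KNOT_OFFSETS`; any offset in :data:`FIXED_KNOT_RATES` that is
        missing is filled with its fixed default.  All rates must exceed
        -100 (exposure stays positive).
    """

    rates: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(FIXED_KNOT_RATES)
        merged.update(self.rates)
        missing = [o for o in KNOT_OFFSETS if o not in merged]
        if missing:
            raise ConfigurationError(f"missing growth-rate knots at offsets {missing}")
        extra = [o for o in merged if o not in KNOT_OFFSETS]
        if extra:
            raise ConfigurationError(f"unknown knot offsets {extra}; expected {KNOT_OFFSETS}")
        if merged[0] != 0.0:
            raise ConfigurationError("the rate at the peak year (offset 0) is 0 by definition")
        low = [o for o, r in merged.items() if r <= -100.0]
        if low:
            raise ConfigurationError(
                f"rates at offsets {low} are <= -100 %/year; exposure would become non-positive"
            )
        object.__setattr__(self, "rates", merged)

    @property
    def offsets(self) -> tuple[int, ...]:
        return KNOT_OFFSETS

    def as_array(self) -> np.ndarray:
        return np.array([self.rates[o] for o in KNOT_OFFSETS], dtype=float)

    def replace(self, **offset_rates: float) -> "GrowthRateKnots":
        """Return a copy with the rates at ``offset=rate`` keyword pairs changed.

        Keywords use ``m`` for minus, e.g. ``replace(m35=-90.0, p5=-8.0)``.
        """
        new = dict(self.rates)
        for key, rate in offset_rates.items():
            sign = -1 if key[0] == "m" else 1
            new[sign * int(key[1:])] = float(rate)
        return GrowthRateKnots(new)


@dataclass(frozen=True)
class ExposureCurve:
    """Yearly relative exposure ``D(T)``, normalised to 1 at the peak year."""

    years: np.ndarray
    D: np.ndarray
    peakyear: int

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        D = np.asarray(self.D, dtype=float)
        if years.shape != D.shape:
            raise ValueError("years and D must have equal length")
        if np.any(np.diff(years) != 1):
            raise ValueError("years must be consecutive")
        if np.any(D < 0):
            raise ValueError("exposure index must be nonnegative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "D", D)

    def at(self, years: np.ndarray) -> np.ndarray:
        """``D`` evaluated at (integer) ``years``; 0 before the curve starts.

        Years after the curve's end are a coverage error: the caller is
        asking about exposure the curve does not describe.
        """
        years = np.asarray(years, dtype=int)
        if years.size and years.max() > self.years[-1]:
            raise ValueError(
                f"exposure curve ends in {self.years[-1]} but year "
                f"{int(years.max())} was requested"
            )
        idx = years - self.years[0]
        out = np.zeros(years.shape, dtype=float)
        inside = idx >= 0
        out[inside] = self.D[idx[inside]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "D": self.D})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, peakyear: int | None = None) -> "ExposureCurve":
        df = pd.read_csv(path)
        years = df["year"].to_numpy(dtype=int)
        D = df["D"].to_numpy(dtype=float)
        if peakyear is None:
            peakyear = int(years[np.argmax(D)])
        return cls(years=years, D=D, peakyear=int(peakyear))


def interpolate_rates(knots: GrowthRateKnots, peakyear: int) -> pd.Series:
    """Per-year growth rates (%/year) over ``peakyear-65 .. peakyear+15``.

    Rates at knot years equal the knot values; intermediate years are linear
    interpolations between neighbouring knots.  Indexed by calendar year.
    """
    years = np.arange(peakyear - 65, peakyear + 15 + 1)
    knot_years = np.array(KNOT_OFFSETS, dtype=float) + peakyear
    knot_rates = knots.as_array()
    rates = np.interp(years, knot_years, knot_rates)
    return pd.Series(rates, index=years, name="rate")


def build_curve(
    knots: GrowthRateKnots,
    peakyear: int,
    start: int | None = None,
    end: int = 2050,
    anchors: tuple[tuple[int, float], ...] = DEFAULT_ANCHORS,
    scenario: str = "decline",
) -> ExposureCurve:
    """Assemble the full exposure curve from knots plus post-range assumptions.

    Parameters
    ----------
    knots, peakyear
        Estimated (and fixed) growth rates and the calendar peak year.
    start
        First year of the exposure history; defaults to ``peakyear - 80``.
        Years before ``peakyear - 65`` use the (fixed) rate of the -65 knot.
    end
        Last year of the curve (default 2050).
    anchors
        ``(year, fraction-of-peak)`` assumptions applied after the estimated
        range, linearly interpolated in ``D``.  The estimated range is
        bridged to the first anchor beyond it by a linear decline.
    scenario
        ``"decline"`` (default) applies the anchors; ``"levelled"`` holds
        exposure constant at its ``peakyear + 15`` level thereafter — the
        pessimistic sensitivity case.

    Returns
    -------
    ExposureCurve
        Normalised so ``D(peakyear) = 1``.
    """
    if start is None:
        start = peakyear - 80
    est_lo, est_hi = peakyear - 65, peakyear + 15
    if start > est_lo:
        raise ConfigurationError(f"start year {start} is after the estimated range begins ({est_lo})")
    if end < est_hi:
        raise ConfigurationError(f"end year {end} precedes the estimated range end ({est_hi})")

    rates = interpolate_rates(knots, peakyear)
    years = np.arange(start, end + 1)
    D = np.empty(years.shape, dtype=float)
    D[0] = 1.0
    # Multiplicative growth through the estimated range, stepping with the
    # rate of the source year; pre-range years use the -65 knot's rate.
    for i in range(len(years) - 1):
        year = years[i]
        if year >= est_hi:
            D[i + 1 :] = D[i]
            break
        r = rates.get(year, rates.iloc[0]) if year >= est_lo else knots.rates[-65]
        step = 1.0 + r / 100.0
        if step <= 0.0:
            raise ConfigurationError(f"rate {r} %/year in {year} drives exposure non-positive")
        D[i + 1] = D[i] * step

    peak_idx = peakyear - start
    D /= D[peak_idx]

    if scenario == "levelled":
        if end > est_hi:
            D[est_hi - start :] = D[est_hi - start]
        return ExposureCurve(years=years, D=D, peakyear=peakyear)
    if scenario != "decline":
        raise ConfigurationError(f"unknown scenario {scenario!r}; expected 'decline' or 'levelled'")

    future = [(y, f) for (y, f) in sorted(anchors) if y > est_hi and y <= end]
    if future:
        # Linear bridge from the end of the estimated range to the first
        # anchor, then piecewise linear between anchors, constant after the
        # last one.  Anchor fractions are relative to the peak, which is 1
        # after normalisation, so they can be used directly.
        xp = [est_hi] + [y for y, _ in future]
        fp = [D[est_hi - start]] + [f for _, f in future]
        tail = np.arange(est_hi, end + 1)
        D[est_hi - start :] = np.interp(tail, xp, fp)
    return ExposureCurve(years=years, D=D, peakyear=peakyear)
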