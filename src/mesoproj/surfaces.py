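"""Age x calendar-year mortality surfaces.

The unit of data is a rectangular surface over single years of age (rows)
and calendar years (columns): person-years at risk ``P[A, T]`` and,
optionally, observed death counts ``Y[A, T]``.  The default grid is ages
20-89 — virtually all male mesothelioma deaths occur in this range — with a
fit window of 1968-2006 and projections out to 2050.

CSV layout: one matrix per file, first column ``age``, remaining column
headers the calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MortalitySurface", "DEFAULT_AGES", "FIT_YEARS"]

DEFAULT_AGES = np.arange(20, 90)
FIT_YEARS = (1968, 2006)


@dataclass(frozen=True)
class MortalitySurface:
    """Person-years at risk and (optionally) death counts on an age x year grid.

    Attributes
    ----------
    ages, years : 1-D int arrays (consecutive)
    person_years : 2-D float array, shape ``(n_ages, n_years)``, strictly positive
    deaths : 2-D int array of the same shape, or None for a population-only
        surface (e.g. future population projections)
    """

    ages: np.ndarray
    years: np.ndarray
    person_years: np.ndarray
    deaths: np.ndarray | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        years = np.asarray(self.years, dtype=int)
        P = np.asarray(self.person_years, dtype=float)
        if np.any(np.diff(ages) != 1) or np.any(np.diff(years) != 1):
            raise ValueError("ages and years must be consecutive integers")
        if ages.min() < 0:
            raise ValueError("negative ages are not meaningful")
        if P.shape != (ages.size, years.size):
            raise ValueError(f"person_years shape {P.shape} != (n_ages, n_years)")
        if np.any(P <= 0):
            raise ValueError("person-years must be positive everywhere")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "person_years", P)
        if self.deaths is not None:
            Y = np.asarray(self.deaths)
            if Y.shape != P.shape:
                raise ValueError("deaths and person_years shapes differ")
            if np.any(Y < 0):
                raise ValueError("death counts must be nonnegative")
            object.__setattr__(self, "deaths", Y.astype(np.int64))

    @property
    def total_deaths(self) -> int:
        """Total observed deaths over the whole surface (``M`` for a fit window)."""
        if self.deaths is None:
            raise ValueError("surface carries no death counts")
        return int(self.deaths.sum())

    def year_slice(self, start: int, stop: int) -> "MortalitySurface":
        """Sub-surface over calendar years ``start..stop`` inclusive."""
        if start < self.years[0] or stop > self.years[-1]:
            raise ValueError(
                f"requested years {start}-{stop} exceed surface coverage "
                f"{self.years[0]}-{self.years[-1]}"
            )
        i0 = start - self.years[0]
        i1 = stop - self.years[0] + 1
        return MortalitySurface(
            ages=self.ages,
            years=self.years[i0:i1],
            person_years=self.person_years[:, i0:i1],
            deaths=None if self.deaths is None else self.deaths[:, i0:i1],
        )

    def yearly_totals(self, which: str = "deaths") -> pd.Series:
        arr = self.deaths if which == "deaths" else self.person_years
        if arr is None:
            raise ValueError("surface carries no death counts")
        return pd.Series(arr.sum(axis=0), index=self.years, name=which)

    # ---- CSV round-trip --------------------------------------------------

    def _frame(self, arr: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(arr, columns=self.years)
        df.insert(0, "age", self.ages)
        return df

    def to_csv(self, person_years_path, deaths_path=None) -> None:
        # %.17g preserves float64 exactly across the round trip
        self._frame(self.person_years).to_csv(person_years_path, index=False, float_format="%.17g")
        if deaths_path is not None:
            if self.deaths is None:
                raise ValueError("surface carries no death counts")
            self._frame(self.deaths).to_csv(deaths_path, index=False)

    @classmethod
    def from_csv(cls, person_years_path, deaths_path=None) -> "MortalitySurface":
        pf = pd.read_csv(person_years_path, float_precision="round_trip")
        ages = pf["age"].to_numpy(dtype=int)
        years = np.array([int(c) for c in pf.columns[1:]])
        P = pf.iloc[:, 1:].to_numpy(dtype=float)
        deaths = None
        if deaths_path is not None:
            df = pd.read_csv(deaths_path)
            if not np.array_equal(df["age"].to_numpy(dtype=int), ages):
                raise ValueError("deaths and person-years age grids differ")
            dyears = np.array([int(c) for c in df.columns[1:]])
            if not np.array_equal(dyears, years):
                raise ValueError("deaths and person-years year grids differ")
            deaths = df.iloc[:, 1:].to_numpy()
        return cls(ages=ages, years=years, person_years=P, deaths=deaths)
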