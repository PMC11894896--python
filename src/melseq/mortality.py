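"""General-population background mortality and the rate floor.

Extrapolated disease-model death rates must never fall below the
age- and sex-specific all-cause mortality of the general population:
the engine replaces the modeled death intensity by the life-table rate
whenever the model rate is lower.  The cohort cannot track individual
ages, so a single mix-weighted rate (configured male fraction) at the
cohort's current integer age is used per cycle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = ["LifeTable", "floored_death_rate"]


class LifeTable:
    """Annual all-cause mortality rates by age and sex.

    Built from rows (age, sex, annual_mortality_rate); ages beyond the
    last row extend with the last rate.
    """

    def __init__(self, df: pd.DataFrame):
        if df is None or not len(df):
            raise ConfigError("life table is empty")
        df = df.copy()
        df["sex"] = df["sex"].map(_norm_sex)
        if (df["rate"] <= 0).any():
            raise ConfigError("life-table rates must be positive")
        self._rates = {}
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            if ages.max() < 100:
                raise ConfigError("life table must extend to age >= 100")
            if np.any(np.diff(ages) != 1):
                raise ConfigError("life-table ages must be contiguous")
            self._rates[sex] = (int(ages[0]), grp["rate"].to_numpy(dtype=float))
        if set(self._rates) != {0, 1}:
            raise ConfigError("life table needs both sexes")

    def rate(self, age: float, male_fraction: float = 0.5) -> float:
        """Mix-weighted annual mortality rate at integer age ``floor(age)``."""
        a = int(np.floor(age))
        out = 0.0
        for sex, w in ((1, male_fraction), (0, 1.0 - male_fraction)):
            a0, rates = self._rates[sex]
            idx = int(np.clip(a - a0, 0, len(rates) - 1))
            out += w * rates[idx]
        return out

    def rate_vector(self, start_age: float, n_cycles: int, dt: float,
                    male_fraction: float = 0.5) -> np.ndarray:
        """Floor rate per cycle as the cohort ages from ``start_age``."""
        return np.array([self.rate(start_age + t * dt, male_fraction)
                         for t in range(n_cycles)])

    def survival(self, start_age: float, times_years, male_fraction=0.5):
        """S(t) for a general-population cohort (piecewise-constant rates)."""
        times = np.asarray(times_years, dtype=float)
        tmax = float(times.max(initial=0.0))
        # integrate the stepwise rate over integer-age segments,
        # with edges expressed as time offsets from start_age
        edges = [0.0]
        nxt = float(np.floor(start_age)) + 1.0
        while nxt - start_age < tmax:
            edges.append(nxt - start_age)
            nxt += 1.0
        edges.append(max(tmax, edges[-1] + 1e-12))
        edges = np.asarray(edges)
        seg_rates = np.array([self.rate(start_age + e, male_fraction)
                              for e in edges[:-1]])
        cum = np.concatenate([[0.0], np.cumsum(seg_rates * np.diff(edges))])
        H = np.interp(times, edges, cum)
        return np.exp(-H)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        rows = []
        for sex, (a0, rates) in sorted(self._rates.items()):
            for i, r in enumerate(rates):
                rows.append({"age": a0 + i, "sex": sex, "rate": r})
        pd.DataFrame(rows).to_csv(path, index=False)


def _norm_sex(v):
    if v in (1, "1", "m", "M", "male"):
        return 1
    if v in (0, "0", "f", "F", "female"):
        return 0
    raise ConfigError(f"unrecognized sex code {v!r}")


def floored_death_rate(model_rate, age, male_fraction, life_table: LifeTable):
    """max(model rate, mix-weighted life-table rate at the current age)."""
    floor = life_table.rate(age, male_fraction)
    return np.maximum(np.asarray(model_rate, dtype=float), floor)
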