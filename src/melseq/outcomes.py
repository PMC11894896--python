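"""Reducing a cohort trace to reported outcomes.

Life expectancy is the sum over cycles of alive-state occupancy times
the cycle length (optionally half-cycle corrected); mean time per
state sums each state's occupancy the same way; survival at a time
point interpolates linearly between cycles, and the median overall
survival is the earliest interpolated time at which survival reaches
one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace

__all__ = [
    "OutcomeSet",
    "life_expectancy",
    "mean_time_in_state",
    "survival_at",
    "median_survival",
    "compute_outcomes",
]

MONTHS_PER_YEAR = 12.0


def _state_sum(occ: np.ndarray, dt: float, half_cycle: bool) -> float:
    if half_cycle:
        return float(0.5 * (occ[:-1] + occ[1:]).sum() * dt)
    return float(occ[:-1].sum() * dt)


def life_expectancy(trace: CohortTrace, half_cycle: bool = True) -> float:
    """Mean years alive over the trace horizon (trapezoidal by default)."""
    return _state_sum(trace.alive(), trace.dt, half_cycle)


def mean_time_in_state(trace: CohortTrace, state: str,
                       half_cycle: bool = True) -> float:
    """Mean years spent in one health state (PD tunnels already collapsed)."""
    if state not in trace.occupancy.columns:
        raise KeyError(f"unknown state {state!r}; "
                       f"available: {list(trace.occupancy.columns)}")
    return _state_sum(trace.occupancy[state].to_numpy(), trace.dt, half_cycle)


def survival_at(trace: CohortTrace, t_years: float) -> float:
    """1 - death occupancy, linearly interpolated between cycles."""
    times = trace.times
    if t_years < 0 or t_years > times[-1] + 1e-12:
        raise ValueError(f"t={t_years} outside trace horizon {times[-1]:.3f}")
    surv = 1.0 - trace.occupancy["D"].to_numpy()
    return float(np.interp(t_years, times, surv))


def median_survival(trace: CohortTrace):
    """Median overall survival in months; None when not reached."""
    surv = 1.0 - trace.occupancy["D"].to_numpy()
    times = trace.times
    below = np.nonzero(surv <= 0.5)[0]
    if len(below) == 0:
        return None
    i = below[0]
    if i == 0:
        return 0.0
    t = times[i - 1] + (surv[i - 1] - 0.5) * (times[i] - times[i - 1]) \
        / (surv[i - 1] - surv[i])
    return float(t * MONTHS_PER_YEAR)


@dataclass
class OutcomeSet:
    """Headline outcomes of one model run."""

    life_expectancy: float                 # years
    mean_time_per_state: dict              # state -> years
    survival_2y: float
    survival_5y: float
    median_os: float | None                # months; None = not reached

    def to_dict(self):
        return {
            "life_expectancy_years": self.life_expectancy,
            "mean_time_per_state_years": self.mean_time_per_state,
            "survival_2y": self.survival_2y,
            "survival_5y": self.survival_5y,
            "median_os_months": self.median_os,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_csv(self, path, **labels):
        """One-row CSV; ``labels`` (e.g., subgroup/sequence/scenario)
        become leading columns."""
        import pandas as pd
        row = dict(labels)
        d = self.to_dict()
        times = d.pop("mean_time_per_state_years")
        row.update(d)
        row.update({f"time_{s}_years": v for s, v in times.items()})
        pd.DataFrame([row]).to_csv(path, index=False)


def compute_outcomes(trace: CohortTrace, half_cycle: bool = True) -> OutcomeSet:
    states = [c for c in trace.occupancy.columns if c != "D"]
    horizon = trace.times[-1]
    return OutcomeSet(
        life_expectancy=life_expectancy(trace, half_cycle),
        mean_time_per_state={s: mean_time_in_state(trace, s, half_cycle)
                             for s in states},
        survival_2y=survival_at(trace, min(2.0, horizon)),
        survival_5y=survival_at(trace, min(5.0, horizon)),
        median_os=median_survival(trace),
    )
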