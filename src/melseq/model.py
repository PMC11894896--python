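"""High-level modelling front-end.

`SequenceModel` bundles everything a run needs — fitted transition
hazards, the hazard-ratio table, the life table, the effect policy and
the cohort profile — and `run()` produces a `SequenceResults` holding
the cohort trace and the reduced outcomes, with `summary()` for a
readable report.  `run_psa()` propagates parameter uncertainty and
`run_scenarios()` tabulates the base case against the four standard
alternative-assumption scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .effects import MIX, EffectPolicy, HazardRatioTable, SCENARIOS
from .engine import CohortTrace, TransitionSet, run_model
from .events import Subgroup, n_named_lines
from .exceptions import ConfigError
from .mortality import LifeTable
from .outcomes import OutcomeSet, compute_outcomes
from .psa import PsaConfig, PsaResult, run_psa

__all__ = ["SequenceModel", "SequenceResults"]


class SequenceModel:
    """Semi-Markov treatment-sequence model for one patient subgroup."""

    def __init__(self, transitions: TransitionSet, subgroup: Subgroup,
                 hr_table: HazardRatioTable | None = None,
                 life_table: LifeTable | None = None,
                 policy: EffectPolicy | str | None = None,
                 start_age: float = 60.0, male_fraction: float = 0.56,
                 covariates=None, dt: float = 1.0 / 12,
                 horizon_years: float | None = None,
                 half_cycle: bool = True):
        if isinstance(policy, str):
            policy = EffectPolicy.for_scenario(policy)
        self.transitions = transitions
        self.subgroup = subgroup
        self.hr_table = hr_table
        self.life_table = life_table
        self.policy = policy or EffectPolicy()
        self.start_age = start_age
        self.male_fraction = male_fraction
        self.covariates = covariates
        self.dt = dt
        self.horizon_years = horizon_years
        self.half_cycle = half_cycle

    @classmethod
    def from_cohort(cls, cohort, subgroup: Subgroup, families=None, seed=0,
                    **kwargs):
        """Fit all transitions from a patient cohort, then build the model."""
        from .pipeline import DEFAULT_FAMILIES, build_transition_set
        ts, _ = build_transition_set(cohort, families or DEFAULT_FAMILIES,
                                     seed=seed)
        return cls(ts, subgroup, **kwargs)

    def validate_sequence(self, sequence):
        sequence = [MIX] if sequence in (None, MIX) else list(sequence)
        L = n_named_lines(self.subgroup.braf)
        if len(sequence) > L:
            raise ConfigError(
                f"sequence names {len(sequence)} lines; subgroup "
                f"{self.subgroup.label()} allows at most {L}")
        return sequence

    def run(self, sequence=(MIX,), param_draws=None,
            hr_table=None) -> "SequenceResults":
        sequence = self.validate_sequence(sequence)
        trace = run_model(
            self.transitions, self.subgroup, sequence,
            hr_table=hr_table if hr_table is not None else self.hr_table,
            policy=self.policy, life_table=self.life_table,
            start_age=self.start_age, male_fraction=self.male_fraction,
            covariates=self.covariates, dt=self.dt,
            horizon_years=self.horizon_years, param_draws=param_draws)
        return SequenceResults(self, sequence, trace,
                               compute_outcomes(trace, self.half_cycle))

    def run_psa(self, sequences, psa_config: PsaConfig | None = None) -> PsaResult:
        """PSA over one or more sequences with shared per-iteration draws."""
        if not isinstance(sequences, dict):
            sequences = {"+".join(self.validate_sequence(sequences)):
                         sequences}
        psa_config = psa_config or PsaConfig()

        def run_one(sequence, param_draws, hr_draws):
            return self.run(sequence, param_draws=param_draws,
                            hr_table=hr_draws).outcomes

        return run_psa(run_one, self.transitions, self.hr_table, sequences,
                       psa_config)

    def run_scenarios(self, sequence=(MIX,)) -> pd.DataFrame:
        """Deterministic outcomes under the base case and scenarios 1-4."""
        rows = []
        saved = self.policy, self.horizon_years
        try:
            for scen in SCENARIOS:
                self.policy = EffectPolicy.for_scenario(scen)
                res = self.run(sequence)
                row = {"scenario": scen, **res.outcomes.to_dict()}
                row.pop("mean_time_per_state_years")
                rows.append(row)
        finally:
            self.policy, self.horizon_years = saved
        return pd.DataFrame(rows)


@dataclass
class SequenceResults:
    """One deterministic run: the trace plus its reduced outcomes."""

    model: SequenceModel
    sequence: list
    trace: CohortTrace
    outcomes: OutcomeSet

    def summary(self) -> str:
        o = self.outcomes
        med = "not reached" if o.median_os is None else f"{o.median_os:.1f} mo"
        lines = [
            f"Treatment sequence model — subgroup {self.model.subgroup.label()}",
            f"sequence: {' -> '.join(self.sequence)}   scenario: "
            f"{self.model.policy.scenario}",
            f"start age {self.model.start_age:.0f} y, "
            f"{100 * self.model.male_fraction:.0f}% male, cycle "
            f"{self.model.dt * 12:.1f} mo, horizon "
            f"{self.trace.times[-1]:.1f} y",
            "",
            f"life expectancy: {o.life_expectancy:.2f} years",
            f"median OS:       {med}",
            f"2-y survival:    {100 * o.survival_2y:.1f}%",
            f"5-y survival:    {100 * o.survival_5y:.1f}%",
            "mean time per state (years):",
        ]
        for state, yrs in o.mean_time_per_state.items():
            lines.append(f"  {state:<5} {yrs:7.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_trace
        return plot_trace(self.trace, ax=ax)
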