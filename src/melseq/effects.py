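"""Relative treatment effects applied to baseline transition hazards.

Baseline hazards are estimated from a registry in which patients
received a mix of treatments, so they represent a population-average
intensity.  To predict outcomes under one named treatment j, the
hazard is rescaled by HR_j divided by the mix-weighted mean hazard
ratio sum_j p_j HR_j of the population the hazard was estimated from;
averaging the rescaled hazards over the mix recovers the baseline
exactly.

The progression effect (HR_PFS) applies to PF->PD only, and only
within a class-specific effect-duration window measured on the
line-start clock (chemotherapy and immunotherapy 2 years, targeted
therapy 0.5 years by default).  The survival effect (HR_OS) applies to
PF->D and PD->D for the whole line; under the beyond-line scenario an
immunotherapy's OS effect additionally carries over multiplicatively
to death transitions of all later lines.  Switch transitions
(PF->next, PD->next) are never adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, MelseqError

__all__ = [
    "REFERENCE_TREATMENT",
    "TREATMENT_CLASSES",
    "SCENARIOS",
    "HazardRatioEntry",
    "HazardRatioTable",
    "EffectPolicy",
    "mean_population_hr",
    "adjust_hazard",
    "effective_hazard",
    "pfs_multiplier_vector",
]

REFERENCE_TREATMENT = "dacarbazine"
TREATMENT_CLASSES = ("chemotherapy", "immunotherapy", "targeted")
SCENARIOS = ("base", "s1", "s2", "s3", "s4")

#: sentinel sequence entry meaning "the observed treatment mix"
MIX = "mix"

ENCORAFENIB = "encorafenib+binimetinib"
DABRAFENIB = "dabrafenib+trametinib"


@dataclass(frozen=True)
class HazardRatioEntry:
    treatment: str
    treatment_class: str
    hr_pfs: float
    hr_pfs_ci: tuple
    hr_os: float
    hr_os_ci: tuple

    def __post_init__(self):
        if self.treatment_class not in TREATMENT_CLASSES:
            raise ConfigError(f"unknown treatment class {self.treatment_class!r}")
        for med, (lb, ub) in ((self.hr_pfs, self.hr_pfs_ci),
                              (self.hr_os, self.hr_os_ci)):
            if not (0 < lb <= med <= ub):
                raise ConfigError(
                    f"{self.treatment}: invalid HR/CI ({lb}, {med}, {ub})")


class HazardRatioTable:
    """Per-treatment hazard ratios with credible bounds."""

    def __init__(self, entries):
        self.entries = {e.treatment: e for e in entries}

    def __contains__(self, treatment):
        return treatment in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def get(self, treatment, alias_encorafenib=True) -> HazardRatioEntry:
        name = treatment
        if alias_encorafenib and name == ENCORAFENIB and name not in self.entries:
            name = DABRAFENIB
        try:
            return self.entries[name]
        except KeyError:
            raise MelseqError(f"no hazard ratios for treatment {treatment!r}") from None

    def with_values(self, draws: dict):
        """Copy with (hr_pfs, hr_os) replaced per treatment (PSA draws)."""
        new = []
        for e in self:
            if e.treatment in draws:
                pfs, os_ = draws[e.treatment]
                e = replace(e, hr_pfs=pfs, hr_os=os_,
                            hr_pfs_ci=(min(pfs, e.hr_pfs_ci[0]), max(pfs, e.hr_pfs_ci[1])),
                            hr_os_ci=(min(os_, e.hr_os_ci[0]), max(os_, e.hr_os_ci[1])))
            new.append(e)
        return HazardRatioTable(new)

    # CSV I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls([HazardRatioEntry(
            r["treatment"], r["class"],
            r["hr_pfs"], (r["hr_pfs_lb"], r["hr_pfs_ub"]),
            r["hr_os"], (r["hr_os_lb"], r["hr_os_ub"])) for _, r in df.iterrows()])

    def to_csv(self, path):
        pd.DataFrame([{
            "treatment": e.treatment, "class": e.treatment_class,
            "hr_pfs": e.hr_pfs, "hr_pfs_lb": e.hr_pfs_ci[0], "hr_pfs_ub": e.hr_pfs_ci[1],
            "hr_os": e.hr_os, "hr_os_lb": e.hr_os_ci[0], "hr_os_ub": e.hr_os_ci[1],
        } for e in self]).to_csv(path, index=False)


@dataclass
class EffectPolicy:
    """Effect-duration windows and scenario switches.

    ``pfs_window`` maps treatment class to the duration (years) the
    PFS hazard ratio stays applied on the line clock; ``os_scope``
    is ``within_line`` (base) or ``beyond_line`` (immunotherapy OS
    effect carries to later lines); ``horizon_years`` caps the model
    horizon when set.
    """

    pfs_window: dict = field(default_factory=lambda: {
        "chemotherapy": 2.0, "immunotherapy": 2.0, "targeted": 0.5})
    os_scope: str = "within_line"
    encorafenib_alias: bool = True
    scenario: str = "base"
    horizon_years: float | None = None
    # treatment-duration caps: carried for a future cost layer, no effect here
    max_treatment_years: dict = field(default_factory=lambda: {
        "immunotherapy": 2.0, "targeted": 5.0})

    def __post_init__(self):
        if self.os_scope not in ("within_line", "beyond_line"):
            raise ConfigError(f"unknown os_scope {self.os_scope!r}")
        if any(w <= 0 for w in self.pfs_window.values()):
            raise ConfigError("pfs_window entries must be positive")

    @classmethod
    def for_scenario(cls, scenario: str) -> "EffectPolicy":
        if scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
        pol = cls(scenario=scenario)
        if scenario == "s1":
            pol.pfs_window["targeted"] = 0.25
        elif scenario == "s2":
            pol.pfs_window["targeted"] = 1.0
        elif scenario == "s3":
            pol.os_scope = "beyond_line"
        elif scenario == "s4":
            pol.horizon_years = 10.0
        return pol


# ---------------------------------------------------------------------------
# the adjustment itself
# ---------------------------------------------------------------------------

def mean_population_hr(mix: dict, hrs: dict) -> float:
    """Mix-weighted mean hazard ratio sum_j p_j HR_j."""
    missing = [t for t in mix if t not in hrs]
    if missing:
        raise MelseqError(f"missing hazard ratios for {missing}")
    values = {hrs[t] for t in mix}
    if len(values) == 1:
        # all treatments share one HR: the mean is that HR exactly, so
        # the adjustment ratio is exactly 1 (no floating-point residue)
        return float(values.pop())
    return float(sum(p * hrs[t] for t, p in mix.items()))


def adjust_hazard(h, hr_j: float, mean_hr: float):
    """h * HR_j / mean_HR."""
    if mean_hr <= 0:
        raise MelseqError("mean population HR must be positive")
    if hr_j <= 0:
        raise MelseqError("hazard ratio must be positive")
    return np.asarray(h) * (hr_j / mean_hr)


def _line_factors(treatment, mix, table: HazardRatioTable, policy: EffectPolicy):
    """(class, pfs factor, os factor) for one treatment within one line."""
    if treatment == MIX:
        return None, 1.0, 1.0
    entry = table.get(treatment, policy.encorafenib_alias)
    pfs_hrs = {t: table.get(t, policy.encorafenib_alias).hr_pfs for t in mix}
    os_hrs = {t: table.get(t, policy.encorafenib_alias).hr_os for t in mix}
    f_pfs = entry.hr_pfs / mean_population_hr(mix, pfs_hrs)
    f_os = entry.hr_os / mean_population_hr(mix, os_hrs)
    return entry.treatment_class, f_pfs, f_os


def effective_hazard(to_state, from_state, treatment, mix, table, policy,
                     t_line, baseline_rate, carryover_os=1.0):
    """Adjusted transition intensity at line time ``t_line``.

    PF->PD uses the PFS factor while ``t_line`` is inside the class
    window and reverts to baseline afterwards; PF->D and PD->D use the
    OS factor for the whole line (times any beyond-line carryover);
    switch transitions are never adjusted.
    """
    if t_line < 0:
        raise ValueError("t_line must be nonnegative")
    cls, f_pfs, f_os = _line_factors(treatment, mix, table, policy)
    rate = np.asarray(baseline_rate, dtype=float)
    if to_state == "D":
        return rate * f_os * carryover_os
    if to_state == "PD" and from_state == "PF":
        if cls is None:
            return rate * carryover_pd(carryover_os)
        window = policy.pfs_window.get(cls)
        if window is None:
            raise ConfigError(f"no PFS window for class {cls!r}")
        return rate * (f_pfs if t_line < window else 1.0)
    return rate  # next-line switches


def carryover_pd(_):
    # progression transitions never receive OS carryover
    return 1.0


def pfs_multiplier_vector(treatment, mix, table, policy, ages_years):
    """Vector of PF->PD multipliers over a grid of line ages (cycle starts)."""
    cls, f_pfs, _ = _line_factors(treatment, mix, table, policy)
    ages = np.asarray(ages_years, dtype=float)
    if cls is None:
        return np.ones_like(ages)
    window = policy.pfs_window[cls]
    return np.where(ages < window, f_pfs, 1.0)


def os_factor(treatment, mix, table, policy):
    """Constant PF->D / PD->D multiplier for one line."""
    _, _, f_os = _line_factors(treatment, mix, table, policy)
    return f_os


def treatment_class(treatment, table: HazardRatioTable, policy: EffectPolicy):
    if treatment == MIX:
        return None
    return table.get(treatment, policy.encorafenib_alias).treatment_class
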