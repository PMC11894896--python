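"""Registry-like synthetic data with known ground truth.

The generator emulates the inputs the model needs — a line-structured
patient cohort, a hazard-ratio table and a general-population life
table — so the whole pipeline is testable without any external data.
Per patient and per line, competing event times (progression, next
treatment, death) are drawn from known cause-specific parametric
hazards on the correct clocks (line clock from progression-free,
progression clock from progressive disease), assembled into dated
histories, and administratively censored at a fixed study cutoff with
uniform accrual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .effects import HazardRatioEntry, HazardRatioTable
from .events import DAYS_PER_YEAR, PatientRecord
from .families import get_family
from .mortality import LifeTable

__all__ = [
    "TrueHazard",
    "GeneratorSpec",
    "reference_spec",
    "simulate_cohort",
    "make_life_table",
    "make_hr_table",
    "sample_time",
    "true_death_times",
]

_COV_ORDER = ("age", "sex", "ecog", "ldh", "brain_mets")


@dataclass(frozen=True)
class TrueHazard:
    """One true cause-specific hazard: family, natural parameters, coefs.

    ``coefs`` maps covariate name to a log-linear effect on the
    family's location parameter (AFT time scale or PH log rate), with
    age centered at 60 — the same link the fitting module uses.
    """

    family: str
    params: tuple          # natural scale
    coefs: dict = field(default_factory=dict)

    def theta(self):
        fam = get_family(self.family)
        return np.array([np.log(p) if lg else p
                         for p, lg in zip(self.params, fam.log_scale)])

    def linpred(self, cov: dict) -> float:
        lp = 0.0
        for name, beta in self.coefs.items():
            x = cov[name] - 60.0 if name == "age" else cov[name]
            lp += beta * x
        return lp

    def natural_for(self, cov: dict):
        return get_family(self.family).natural_params(self.theta(),
                                                      self.linpred(cov))

    def cumhaz(self, t, cov: dict):
        return get_family(self.family).cumhaz(t, self.natural_for(cov))


def sample_time(hazard: TrueHazard, cov: dict, rng) -> float:
    """Inverse-CDF draw of an event time (years); may be infinite."""
    fam = get_family(hazard.family)
    nat = hazard.natural_for(cov)
    u = rng.uniform()
    if fam.name == "exponential":
        return -np.log(u) / nat[0]
    if fam.name == "weibull":
        shape, scale = nat
        return scale * (-np.log(u)) ** (1.0 / shape)
    if fam.name == "gompertz":
        b, a = nat
        if abs(b) < 1e-12:
            return -np.log(u) / a
        arg = 1.0 - b * np.log(u) / a
        return np.inf if arg <= 0 else np.log(arg) / b
    # remaining families via scipy inverse survival functions
    from scipy import stats
    if fam.name == "log_normal":
        mu, sigma = nat
        return float(stats.lognorm.isf(u, sigma, scale=np.exp(mu)))
    if fam.name == "log_logistic":
        shape, scale = nat
        return float(stats.fisk.isf(u, shape, scale=scale))
    if fam.name == "gamma":
        shape, inv_rate = nat
        return float(stats.gamma.isf(u, shape, scale=inv_rate))
    # generalized gamma / F: numeric inversion of the survival function
    from scipy import optimize
    logu = np.log(u)
    f = lambda t: fam.logsf(t, nat) - logu
    hi = 1.0
    while f(hi) > 0 and hi < 1e6:
        hi *= 2
    return float(optimize.brentq(f, 1e-12, hi))


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic registry.

    Defaults mirror a registry of advanced-melanoma patients: about
    59% BRAF-mutant, 63% with favorable prognostic factors, mean age
    60 (SD 12, floored at 18), 56% male, two modeled treatment lines
    plus a subsequent-therapy phase, uniform accrual over two years
    with an administrative cutoff four years after study start.
    """

    n_patients: int = 1000
    braf_prop: float = 0.59
    favorable_prop: float = 0.63
    age_mean: float = 60.0
    age_sd: float = 12.0
    male_prop: float = 0.56
    ecog1_prop: float = 0.30
    n_lines: int = 2
    accrual_years: float = 2.0
    study_years: float = 4.0
    hazards: dict = field(default_factory=lambda: dict(_REFERENCE_HAZARDS))
    treatment_mixes: dict = field(default_factory=lambda: dict(_REFERENCE_MIXES))

    def to_yaml(self, path):
        data = asdict(self)
        data["hazards"] = {
            f"{line}:{frm}:{to}": {"family": h.family,
                                   "params": list(h.params),
                                   "coefs": dict(h.coefs)}
            for (line, frm, to), h in self.hazards.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        hazards = {}
        for key, h in data.pop("hazards").items():
            line, frm, to = key.split(":")
            hazards[(int(line), frm, to)] = TrueHazard(
                h["family"], tuple(h["params"]), dict(h.get("coefs", {})))
        mixes = {int(k): v for k, v in data.pop("treatment_mixes").items()}
        return cls(hazards=hazards, treatment_mixes=mixes, **data)


# True transition hazards, keyed (line, from_state, to_state); year units.
# Death transitions carry prognostic-factor effects (elevated LDH, brain
# metastases, ECOG 1) on the PH/AFT location, matching the fitting link.
_REFERENCE_HAZARDS = {
    (1, "PF", "PD"): TrueHazard("weibull", (1.3, 1.5),
                                {"ldh": -0.4, "brain_mets": -0.25}),
    (1, "PF", "next"): TrueHazard("exponential", (0.08,)),
    (1, "PF", "D"): TrueHazard("exponential", (0.10,),
                               {"ldh": 0.7, "brain_mets": 0.4, "ecog": 0.15}),
    (1, "PD", "next"): TrueHazard("exponential", (0.9,)),
    (1, "PD", "D"): TrueHazard("weibull", (0.85, 1.2), {"ldh": -0.4}),
    (2, "PF", "PD"): TrueHazard("weibull", (1.1, 1.0), {"ldh": -0.4}),
    (2, "PF", "next"): TrueHazard("exponential", (0.10,)),
    (2, "PF", "D"): TrueHazard("exponential", (0.18,),
                               {"ldh": 0.6, "brain_mets": 0.3}),
    (2, "PD", "next"): TrueHazard("exponential", (0.7,)),
    (2, "PD", "D"): TrueHazard("weibull", (0.85, 0.8), {"ldh": -0.3}),
    (3, "PF", "D"): TrueHazard("exponential", (0.35,), {"ldh": 0.5}),
}

_REFERENCE_MIXES = {
    1: {"nivolumab": 0.35, "pembrolizumab": 0.25,
        "nivolumab+ipilimumab": 0.25, "dacarbazine": 0.15},
    2: {"ipilimumab": 0.40, "nivolumab+ipilimumab": 0.30,
        "nivolumab": 0.20, "chemotherapy": 0.10},
    3: {"chemotherapy": 0.60, "ipilimumab": 0.40},
}


def reference_spec(n_patients=1000) -> GeneratorSpec:
    """The versioned default study conditions."""
    return GeneratorSpec(n_patients=n_patients)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _draw_covariates(spec: GeneratorSpec, rng):
    braf = rng.uniform() < spec.braf_prop
    favorable = rng.uniform() < spec.favorable_prop
    if favorable:
        ldh = brain = 0
    else:  # intermediate: elevated LDH and/or asymptomatic brain metastases
        which = rng.integers(3)
        ldh = int(which in (0, 2))
        brain = int(which in (1, 2))
    return {
        "age": max(18.0, rng.normal(spec.age_mean, spec.age_sd)),
        "sex": int(rng.uniform() < spec.male_prop),
        "ecog": int(rng.uniform() < spec.ecog1_prop),
        "ldh": ldh,
        "brain_mets": brain,
    }, braf


def _days(years: float) -> float:
    if not np.isfinite(years):
        return np.inf
    return max(1.0, round(years * DAYS_PER_YEAR))


def _draw_treatment(mix: dict, rng) -> str:
    names = list(mix)
    p = np.array([mix[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=p / p.sum())]


def simulate_cohort(spec: GeneratorSpec, seed=0):
    """Simulate the registry cohort; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(spec.n_patients):
        cov, braf = _draw_covariates(spec, rng)
        accrual = rng.uniform(0, spec.accrual_years)
        fu_days = round((spec.study_years - accrual) * DAYS_PER_YEAR)
        origin = pd.Timestamp("2018-01-01") + pd.Timedelta(
            days=round(accrual * DAYS_PER_YEAR))
        rec = _simulate_patient(str(i), cov, braf, fu_days, spec, rng, origin)
        cohort.append(rec)
    return cohort


def _simulate_patient(pid, cov, braf, fu_days, spec, rng, origin):
    starts, progs, trts = [], [], []
    death = None
    day = 0.0
    line = 1
    while True:
        starts.append(day)
        progs.append(None)
        mix = spec.treatment_mixes.get(line, {"chemotherapy": 1.0})
        trts.append(_draw_treatment(mix, rng))
        if line > spec.n_lines:  # subsequent-therapy phase: death only
            t_d = sample_time(spec.hazards[(spec.n_lines + 1, "PF", "D")], cov, rng)
            d_day = day + _days(t_d)
            if d_day <= fu_days:
                death = d_day
            break
        t_pd = sample_time(spec.hazards[(line, "PF", "PD")], cov, rng)
        t_nx = sample_time(spec.hazards[(line, "PF", "next")], cov, rng)
        t_d = sample_time(spec.hazards[(line, "PF", "D")], cov, rng)
        first = min(t_pd, t_nx, t_d)
        event_day = day + _days(first)
        if event_day > fu_days:
            break
        if first == t_d:
            death = event_day
            break
        if first == t_nx:
            day = event_day
            line += 1
            continue
        # progression within the line: PD clock starts here
        progs[-1] = event_day
        t_nx2 = sample_time(spec.hazards[(line, "PD", "next")], cov, rng)
        t_d2 = sample_time(spec.hazards[(line, "PD", "D")], cov, rng)
        first2 = min(t_nx2, t_d2)
        event_day2 = event_day + _days(first2)
        if event_day2 > fu_days:
            break
        if first2 == t_d2:
            death = event_day2
            break
        day = event_day2
        line += 1
    return PatientRecord(
        id=pid, age=cov["age"], sex=cov["sex"], ecog=cov["ecog"],
        ldh=cov["ldh"], brain_mets=cov["brain_mets"], braf=braf,
        treatments=trts, line_starts=starts, progressions=progs,
        death=death, last_visit=float(fu_days), origin=origin)


def transition_set_from_truth(spec: GeneratorSpec, subgroup, profile=None):
    """TransitionSet carrying the generator's true hazards (no fitting).

    The generator's line numbering maps directly onto the subgroup's
    named lines; the ``n_lines + 1`` death hazard feeds the
    subsequent-therapy state.
    """
    from .engine import TransitionSet
    from .events import TransitionKey
    from .survival import ParametricSurvivalResults

    fits = {}
    for (line, frm, to), h in spec.hazards.items():
        names = tuple(h.coefs)
        fits[TransitionKey(subgroup, line, frm, to)] = \
            ParametricSurvivalResults.from_params(
                h.family, h.params, [h.coefs[c] for c in names],
                exog_names=names)
    if profile is None:
        profile = {"age": 60.0, "sex": 0.56, "ecog": spec.ecog1_prop,
                   "ldh": 0.0, "brain_mets": 0.0}
    mixes = {(subgroup, line): dict(mix)
             for line, mix in spec.treatment_mixes.items()}
    return TransitionSet(fits, mixes, {subgroup: dict(profile)})


def true_death_times(spec: GeneratorSpec, cov: dict, n: int, seed=0):
    """Death times (years) microsimulated from the generator's own truth.

    Follows the same event cascade with no administrative censoring;
    this is the generator-side oracle for engine life expectancy.
    """
    big = GeneratorSpec(**{**asdict_shallow(spec), "n_patients": 0,
                           "study_years": np.inf, "accrual_years": 0.0})
    rng = np.random.default_rng(seed)
    times = np.empty(n)
    for i in range(n):
        rec = _simulate_patient(str(i), cov, False, np.inf, big, rng,
                                pd.Timestamp("2018-01-01"))
        times[i] = rec.death / DAYS_PER_YEAR
    return times


def asdict_shallow(spec: GeneratorSpec) -> dict:
    return {f: getattr(spec, f) for f in spec.__dataclass_fields__}


# ---------------------------------------------------------------------------
# life table and hazard-ratio table
# ---------------------------------------------------------------------------

def make_life_table(makeham=(5e-4, 3e-5, 0.095), max_age=110) -> LifeTable:
    """Gompertz-Makeham rates a + b exp(c age), male/female offsets."""
    a, b, c = makeham
    if a <= 0 or b < 0 or c < 0:
        raise ValueError("Makeham parameters must be positive (b, c >= 0)")
    ages = np.arange(0, max_age + 1)
    base = a + b * np.exp(c * ages)
    rows = []
    for sex, mult in ((1, 1.25), (0, 0.80)):
        for age, r in zip(ages, base * mult):
            rows.append({"age": int(age), "sex": sex, "rate": float(r)})
    return LifeTable(pd.DataFrame(rows))


_HR_ROWS = [
    # treatment, class, hr_pfs (lb, ub), hr_os (lb, ub)
    ("dacarbazine", "chemotherapy", 1.00, (1.00, 1.00), 1.00, (1.00, 1.00)),
    ("chemotherapy", "chemotherapy", 1.00, (0.85, 1.18), 1.00, (0.85, 1.18)),
    ("ipilimumab", "immunotherapy", 0.85, (0.70, 1.03), 0.64, (0.50, 0.82)),
    ("nivolumab", "immunotherapy", 0.55, (0.44, 0.69), 0.46, (0.36, 0.59)),
    ("pembrolizumab", "immunotherapy", 0.57, (0.45, 0.72), 0.50, (0.39, 0.64)),
    ("nivolumab+ipilimumab", "immunotherapy", 0.42, (0.32, 0.55), 0.40, (0.30, 0.53)),
    ("dabrafenib+trametinib", "targeted", 0.23, (0.18, 0.30), 0.37, (0.28, 0.49)),
    ("vemurafenib+cobimetinib", "targeted", 0.25, (0.19, 0.33), 0.41, (0.31, 0.54)),
]


def make_hr_table(alias_encorafenib=True) -> HazardRatioTable:
    """Plausible relative-effect table with the chemotherapy reference."""
    entries = [HazardRatioEntry(t, cls, pfs, pci, os_, oci)
               for t, cls, pfs, pci, os_, oci in _HR_ROWS]
    if alias_encorafenib:
        d = next(e for e in entries if e.treatment == "dabrafenib+trametinib")
        entries.append(HazardRatioEntry(
            "encorafenib+binimetinib", "targeted",
            d.hr_pfs, d.hr_pfs_ci, d.hr_os, d.hr_os_ci))
    return HazardRatioTable(entries)
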