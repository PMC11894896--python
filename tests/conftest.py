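import numpy as np
import pytest

from melseq import (
    Subgroup,
    TransitionKey,
    TransitionSet,
    make_hr_table,
    make_life_table,
    reference_spec,
    simulate_cohort,
)
from melseq.survival import ParametricSurvivalResults

WT = Subgroup(False, "favorable")
BRAF = Subgroup(True, "favorable")

FLAT_PROFILE = {"age": 60.0, "sex": 0.5, "ecog": 0.0, "ldh": 0.0,
                "brain_mets": 0.0}


def exp_fit(rate):
    return ParametricSurvivalResults.from_params("exponential", (rate,))


def weibull_fit(shape, scale):
    return ParametricSurvivalResults.from_params("weibull", (shape, scale))


def make_transition_set(subgroup, fits_by_key, mixes=None):
    """TransitionSet from {(line, from, to): ParametricSurvivalResults}."""
    fits = {TransitionKey(subgroup, line, f, t): fit
            for (line, f, t), fit in fits_by_key.items()}
    return TransitionSet(fits, mixes or {}, {subgroup: dict(FLAT_PROFILE)})


#: 2-line configuration with duration-dependent (Weibull) PD exit hazards
def two_line_fits():
    return {
        (1, "PF", "PD"): exp_fit(0.45),
        (1, "PF", "next"): exp_fit(0.08),
        (1, "PF", "D"): exp_fit(0.10),
        (1, "PD", "next"): exp_fit(0.8),
        (1, "PD", "D"): weibull_fit(0.8, 1.2),
        (2, "PF", "PD"): exp_fit(0.5),
        (2, "PF", "next"): exp_fit(0.10),
        (2, "PF", "D"): exp_fit(0.18),
        (2, "PD", "next"): exp_fit(0.6),
        (2, "PD", "D"): weibull_fit(0.85, 0.8),
        (3, "PF", "D"): exp_fit(0.35),
    }


@pytest.fixture(scope="session")
def wt_subgroup():
    return WT


@pytest.fixture(scope="session")
def two_line_ts():
    return make_transition_set(WT, two_line_fits())


@pytest.fixture(scope="session")
def hr_table():
    return make_hr_table()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def ref_cohort():
    return simulate_cohort(reference_spec(n_patients=1500), seed=7)


@pytest.fixture(scope="session")
def ref_transitions(ref_cohort):
    from melseq.pipeline import build_transition_set
    ts, report = build_transition_set(
        ref_cohort, families=("exponential", "weibull", "gompertz"), seed=3)
    return ts


@pytest.fixture(scope="session")
def mix_only():
    """Uniform single-treatment mixes so Eq.-1 factors are well defined."""
    table = make_hr_table()
    mix = {t.treatment: 1.0 / len(list(table.entries))
           for t in table}
    return {(WT, 1): mix, (WT, 2): mix}
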