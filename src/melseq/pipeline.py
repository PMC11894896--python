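"""From a patient cohort to a fitted TransitionSet.

Each allowed transition's dataset is fitted over a list of candidate
families and the best fit by AIC is kept.  Sparse datasets (fewer than
10 events) are restricted to families with at most two parameters —
later-line risk sets are small and the flexible three- and
four-parameter families are not identifiable there.  Covariates that
are constant within a dataset (e.g., LDH within the favorable
prognostic group, which is defined by a normal LDH) are dropped from
that fit.
"""

from __future__ import annotations

import json

import numpy as np

from .engine import TransitionSet
from .events import (Subgroup, TransitionKey, build_all_datasets,
                     n_named_lines, subgroup_profile, treatment_mix)
from .exceptions import FitError
from .families import get_family
from .survival import COVARIATE_NAMES, ParametricSurvivalResults, select_model

__all__ = ["DEFAULT_FAMILIES", "SPARSE_EVENT_THRESHOLD",
           "build_transition_set", "transition_set_to_json",
           "transition_set_from_json"]

DEFAULT_FAMILIES = ("exponential", "weibull", "gamma", "log_logistic",
                    "log_normal", "gompertz")
SPARSE_EVENT_THRESHOLD = 10


def _usable_covariates(df, covariate_mask):
    mask = covariate_mask if covariate_mask is not None else COVARIATE_NAMES
    return tuple(c for c in mask if df[c].nunique() > 1)


def build_transition_set(cohort, families=DEFAULT_FAMILIES,
                         covariate_mask=None, seed=0, log=None):
    """Fit every allowed transition and collect line treatment mixes.

    Returns ``(TransitionSet, report)``; ``report`` lists per key the
    chosen family and any skipped/empty datasets.  Keys whose dataset
    has no events are left out of the set (the engine raises if such a
    transition is later required).
    """
    datasets, counts = build_all_datasets(cohort)
    fits, report = {}, []
    for key, df in datasets.items():
        n_events = int(df["status"].sum()) if len(df) else 0
        if n_events == 0:
            report.append({"key": key.label(), "family": None,
                           "note": "empty risk set or no events"})
            continue
        fams = list(families)
        if n_events < SPARSE_EVENT_THRESHOLD:
            fams = [f for f in fams if get_family(f).n_params <= 2]
            note = f"sparse ({n_events} events): restricted to <=2-param families"
        else:
            note = ""
        cov = _usable_covariates(df, covariate_mask)
        try:
            ranked, failures = select_model(df, fams, covariate_mask=cov,
                                            seed=seed)
        except FitError as exc:
            report.append({"key": key.label(), "family": None, "note": str(exc)})
            continue
        fits[key] = ranked[0]
        report.append({"key": key.label(), "family": ranked[0].family.name,
                       "n_obs": len(df), "n_events": n_events, "note": note,
                       "failed_families": sorted(failures)})
        if log is not None:
            log.info("fit %s: %s (AIC %.1f)", key.label(),
                     ranked[0].family.name, ranked[0].aic)

    subgroups = {r.subgroup for r in cohort}
    mixes, profiles = {}, {}
    for sg in subgroups:
        profiles[sg] = subgroup_profile(cohort, sg)
        for line in range(1, n_named_lines(sg.braf) + 1):
            try:
                mixes[(sg, line)] = treatment_mix(cohort, sg, line)
            except Exception:
                pass  # nobody reached this line in this subgroup
    return TransitionSet(fits, mixes, profiles), report


# ---------------------------------------------------------------------------
# JSON round-trip for fitted transition sets
# ---------------------------------------------------------------------------

def transition_set_to_json(ts: TransitionSet, path):
    data = {
        "fits": [{
            "subgroup": {"braf": k.subgroup.braf,
                         "prognostic": k.subgroup.prognostic},
            "line": k.line, "from_state": k.from_state, "to_state": k.to_state,
            "fit": f.to_dict(),
        } for k, f in ts.fits.items()],
        "mixes": [{
            "subgroup": {"braf": sg.braf, "prognostic": sg.prognostic},
            "line": line, "mix": mix,
        } for (sg, line), mix in ts.mixes.items()],
        "profiles": [{
            "subgroup": {"braf": sg.braf, "prognostic": sg.prognostic},
            "profile": prof,
        } for sg, prof in ts.profiles.items()],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def transition_set_from_json(path) -> TransitionSet:
    with open(path) as fh:
        data = json.load(fh)
    fits = {}
    for row in data["fits"]:
        sg = Subgroup(bool(row["subgroup"]["braf"]), row["subgroup"]["prognostic"])
        key = TransitionKey(sg, int(row["line"]), row["from_state"],
                            row["to_state"])
        fits[key] = ParametricSurvivalResults.from_dict(row["fit"])
    mixes = {}
    for row in data.get("mixes", []):
        sg = Subgroup(bool(row["subgroup"]["braf"]), row["subgroup"]["prognostic"])
        mixes[(sg, int(row["line"]))] = dict(row["mix"])
    profiles = {}
    for row in data.get("profiles", []):
        sg = Subgroup(bool(row["subgroup"]["braf"]), row["subgroup"]["prognostic"])
        profiles[sg] = dict(row["profile"])
    return TransitionSet(fits, mixes, profiles)
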