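"""Turning line-structured patient histories into transition datasets.

A patient history records, per treatment line, the start date, an
optional progression date and the treatment received, plus a death or
last-visit date.  Each allowed transition of the multistate model gets
its own right-censored time-to-event dataset: times run on the line
clock for transitions out of progression-free (PF) states and on the
progression clock for transitions out of progressive-disease (PD)
states; a patient is censored at the earliest competing event, or at
the last registered visit when no event occurred.

Dates coinciding with a next-line start or with death are resolved by
moving the progression date one day earlier, so every extracted time is
strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError, MelseqError

__all__ = [
    "DAYS_PER_YEAR",
    "PatientRecord",
    "TransitionKey",
    "Subgroup",
    "n_named_lines",
    "allowed_keys",
    "resolve_same_day",
    "extract_transition",
    "build_all_datasets",
    "treatment_mix",
    "subgroup_profile",
    "cohort_to_csv",
    "cohort_from_csv",
]

DAYS_PER_YEAR = 365.25

PF, PD, DEATH, NEXT = "PF", "PD", "D", "next"


@dataclass(frozen=True)
class Subgroup:
    braf: bool
    prognostic: str  # "favorable" | "intermediate"

    def __post_init__(self):
        if self.prognostic not in ("favorable", "intermediate"):
            raise ValueError(f"unknown prognostic group {self.prognostic!r}")

    def label(self):
        return f"{'braf' if self.braf else 'wt'}-{self.prognostic}"


@dataclass(frozen=True)
class TransitionKey:
    """(subgroup, line, from-state, to-state); the clock is implied."""

    subgroup: Subgroup
    line: int
    from_state: str  # PF | PD
    to_state: str    # PD | next | D

    @property
    def clock(self) -> str:
        return "line_start" if self.from_state == PF else "pd_entry"

    def label(self):
        return f"{self.subgroup.label()}/L{self.line}:{self.from_state}->{self.to_state}"


def n_named_lines(braf: bool) -> int:
    """3 treatment lines for BRAF-mutant disease, 2 for wild-type."""
    return 3 if braf else 2


def allowed_keys(subgroup: Subgroup):
    """The allowed transitions: 16 for BRAF-mutant, 11 for wild-type."""
    L = n_named_lines(subgroup.braf)
    keys = []
    for line in range(1, L + 1):
        keys += [
            TransitionKey(subgroup, line, PF, PD),
            TransitionKey(subgroup, line, PF, NEXT),
            TransitionKey(subgroup, line, PF, DEATH),
            TransitionKey(subgroup, line, PD, NEXT),
            TransitionKey(subgroup, line, PD, DEATH),
        ]
    keys.append(TransitionKey(subgroup, L + 1, PF, DEATH))  # subsequent therapies
    return keys


@dataclass
class PatientRecord:
    """One patient: baseline covariates plus a per-line event history.

    All dates are integer day offsets from the first-line start
    (``line_starts[0] == 0``); ``origin`` anchors them to calendar time
    for CSV round-trips.
    """

    id: str
    age: float
    sex: int
    ecog: int
    ldh: int
    brain_mets: int
    braf: bool
    treatments: list = field(default_factory=list)
    line_starts: list = field(default_factory=list)      # days, one per line
    progressions: list = field(default_factory=list)     # days or None, per line
    death: Optional[float] = None
    last_visit: float = 0.0
    origin: pd.Timestamp = pd.Timestamp("2018-01-01")

    @property
    def prognostic(self) -> str:
        return "favorable" if (self.ldh == 0 and self.brain_mets == 0) else "intermediate"

    @property
    def subgroup(self) -> Subgroup:
        return Subgroup(self.braf, self.prognostic)

    def covariates(self) -> dict:
        return {"age": self.age, "sex": self.sex, "ecog": self.ecog,
                "ldh": self.ldh, "brain_mets": self.brain_mets}


# ---------------------------------------------------------------------------
# same-day resolution
# ---------------------------------------------------------------------------

def resolve_same_day(record: PatientRecord) -> PatientRecord:
    """Shift progression dates that coincide with a next-line start or death.

    A progression registered on the day a new treatment starts is moved
    one day earlier; likewise for a progression registered on the day of
    death.  Idempotent; raises if a progression postdates death.
    """
    progs = list(record.progressions)
    for i, p in enumerate(progs):
        if p is None:
            continue
        if record.death is not None and p > record.death:
            raise DataIntegrityError(
                f"patient {record.id}: progression after death")
        nxt = record.line_starts[i + 1] if i + 1 < len(record.line_starts) else None
        if nxt is not None and p == nxt:
            p = p - 1
        if record.death is not None and p == record.death:
            p = p - 1
        progs[i] = p
    return replace(record, progressions=progs)


# ---------------------------------------------------------------------------
# per-transition extraction
# ---------------------------------------------------------------------------

def _line_events(record: PatientRecord, line: int):
    """Competing exit events from PF of ``line``: (to_state, day)."""
    idx = line - 1
    events = []
    if idx < len(record.progressions) and record.progressions[idx] is not None:
        events.append((PD, record.progressions[idx]))
    if idx + 1 < len(record.line_starts):
        events.append((NEXT, record.line_starts[idx + 1]))
    if record.death is not None:
        events.append((DEATH, record.death))
    return events


def extract_transition(record: PatientRecord, key: TransitionKey):
    """(time_years, status) for one transition, or None if not at risk.

    ``status`` is 1 when the key's destination event happened first, 0
    when the patient was censored by a competing event or the last
    visit.  The record must already be same-day resolved.
    """
    L = n_named_lines(record.braf)
    idx = key.line - 1
    if idx >= len(record.line_starts):
        return None  # never entered this line

    if key.line == L + 1:  # subsequent-therapy state: exit to death only
        entry = record.line_starts[idx]
        competing = [(DEATH, record.death)] if record.death is not None else []
    elif key.from_state == PF:
        entry = record.line_starts[idx]
        competing = _line_events(record, key.line)
    else:  # PD state of a named line
        prog = record.progressions[idx] if idx < len(record.progressions) else None
        if prog is None:
            return None
        nxt = record.line_starts[idx + 1] if idx + 1 < len(record.line_starts) else None
        if nxt is not None and prog > nxt:
            return None  # progression recorded after switching: PD never entered in-line
        entry = prog
        competing = []
        if nxt is not None:
            competing.append((NEXT, nxt))
        if record.death is not None:
            competing.append((DEATH, record.death))

    if competing:
        first_state, first_day = min(competing, key=lambda e: e[1])
        status = int(first_state == key.to_state)
        day = first_day
    else:
        status, day = 0, record.last_visit

    time_years = (day - entry) / DAYS_PER_YEAR
    if time_years < 0:
        raise DataIntegrityError(
            f"patient {record.id}: negative time for {key.label()}")
    if time_years == 0:
        if status:
            raise DataIntegrityError(
                f"patient {record.id}: zero-time event for {key.label()}")
        return None  # zero follow-up contributes nothing
    return time_years, status


def build_all_datasets(cohort, resolve=True):
    """One right-censored dataset per allowed transition per subgroup.

    Returns ``(datasets, counts)``: ``datasets`` maps TransitionKey to a
    DataFrame (time_years, status, covariates); ``counts`` tabulates
    n_obs / n_events per key (empty risk sets appear with n_obs 0).
    """
    if not len(cohort):
        raise MelseqError("cohort is empty")
    if resolve:
        cohort = [resolve_same_day(r) for r in cohort]
    rows: dict[TransitionKey, list] = {}
    for sg in {r.subgroup for r in cohort}:
        for key in allowed_keys(sg):
            rows[key] = []
    for rec in cohort:
        for key in allowed_keys(rec.subgroup):
            out = extract_transition(rec, key)
            if out is None:
                continue
            t, s = out
            rows[key].append({"time_years": t, "status": s, **rec.covariates()})
    cols = ["time_years", "status", "age", "sex", "ecog", "ldh", "brain_mets"]
    datasets = {k: pd.DataFrame(v, columns=cols) for k, v in rows.items()}
    counts = pd.DataFrame(
        [{"key": k.label(), "n_obs": len(df), "n_events": int(df["status"].sum())}
         for k, df in datasets.items()])
    return datasets, counts


def treatment_mix(cohort, subgroup: Subgroup, line: int) -> dict:
    """Observed treatment proportions p_j at one line of one subgroup."""
    counts: dict[str, int] = {}
    for rec in cohort:
        if rec.subgroup != subgroup or line - 1 >= len(rec.line_starts):
            continue
        if line - 1 < len(rec.treatments):
            trt = rec.treatments[line - 1]
            counts[trt] = counts.get(trt, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise MelseqError(
            f"no patients received line {line} in subgroup {subgroup.label()}")
    return {k: v / total for k, v in sorted(counts.items())}


def subgroup_profile(cohort, subgroup: Subgroup) -> dict:
    """Mean baseline covariates of a subgroup (engine evaluation profile)."""
    rows = [r.covariates() for r in cohort if r.subgroup == subgroup]
    if not rows:
        raise MelseqError(f"no patients in subgroup {subgroup.label()}")
    df = pd.DataFrame(rows)
    return df.mean().to_dict()


# ---------------------------------------------------------------------------
# CSV round-trip (ISO-8601 dates, one row per patient)
# ---------------------------------------------------------------------------

_MAX_LINES = 4


def cohort_to_csv(cohort, path):
    rows = []
    for r in cohort:
        row = {"id": r.id, "age": r.age, "sex": r.sex, "ecog": r.ecog,
               "ldh": r.ldh, "brain_mets": r.brain_mets, "braf": int(r.braf)}
        for i in range(_MAX_LINES):
            start = r.line_starts[i] if i < len(r.line_starts) else None
            prog = r.progressions[i] if i < len(r.progressions) else None
            trt = r.treatments[i] if i < len(r.treatments) else ""
            row[f"line{i+1}_treatment"] = trt
            row[f"line{i+1}_start"] = _day_to_iso(r.origin, start)
            row[f"line{i+1}_prog"] = _day_to_iso(r.origin, prog)
        row["death"] = _day_to_iso(r.origin, r.death)
        row["last_visit"] = _day_to_iso(r.origin, r.last_visit)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_from_csv(path):
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True)
    cohort = []
    for _, row in df.iterrows():
        origin = pd.Timestamp(row["line1_start"])
        starts, progs, trts = [], [], []
        for i in range(_MAX_LINES):
            s = _iso_to_day(origin, row.get(f"line{i+1}_start"))
            if s is None:
                break
            starts.append(s)
            progs.append(_iso_to_day(origin, row.get(f"line{i+1}_prog")))
            trts.append(str(row.get(f"line{i+1}_treatment", "") or ""))
        cohort.append(PatientRecord(
            id=str(row["id"]), age=float(row["age"]), sex=int(row["sex"]),
            ecog=int(row["ecog"]), ldh=int(row["ldh"]),
            brain_mets=int(row["brain_mets"]), braf=bool(int(row["braf"])),
            treatments=trts, line_starts=starts, progressions=progs,
            death=_iso_to_day(origin, row.get("death")),
            last_visit=_iso_to_day(origin, row.get("last_visit")) or 0.0,
            origin=origin))
    return cohort


def _day_to_iso(origin, day):
    if day is None:
        return ""
    return (origin + pd.Timedelta(days=float(day))).date().isoformat()


def _iso_to_day(origin, value):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float((pd.Timestamp(value) - origin).days)
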