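"""Event-history extraction: same-day rules, censoring, risk sets."""

import numpy as np
import pytest

from melseq.events import (
    DAYS_PER_YEAR,
    PatientRecord,
    Subgroup,
    TransitionKey,
    allowed_keys,
    build_all_datasets,
    cohort_from_csv,
    cohort_to_csv,
    extract_transition,
    resolve_same_day,
    treatment_mix,
)
from melseq.exceptions import DataIntegrityError, MelseqError
from melseq.synthetic import reference_spec, simulate_cohort

WT = Subgroup(False, "favorable")


def make_record(**kw):
    base = dict(id="p1", age=62.0, sex=1, ecog=0, ldh=0, brain_mets=0,
                braf=False, treatments=["nivolumab"], line_starts=[0.0],
                progressions=[None], death=None, last_visit=700.0)
    base.update(kw)
    return PatientRecord(**base)


class TestAllowedKeys:
    def test_transition_counts_match_model_structure(self):
        assert len(allowed_keys(Subgroup(True, "favorable"))) == 16
        assert len(allowed_keys(WT)) == 11

    def test_wild_type_has_no_third_line_keys(self):
        assert not any(k.line == 3 and k.from_state == "PD"
                       for k in allowed_keys(WT))

    def test_clock_convention(self):
        key_pf = TransitionKey(WT, 1, "PF", "PD")
        key_pd = TransitionKey(WT, 1, "PD", "D")
        assert key_pf.clock == "line_start"
        assert key_pd.clock == "pd_entry"


class TestResolveSameDay:
    def test_progression_on_next_line_start_moves_back_one_day(self):
        rec = make_record(line_starts=[0.0, 68.0], progressions=[68.0, None],
                          treatments=["a", "b"])
        out = resolve_same_day(rec)
        assert out.progressions[0] == 67.0

    def test_progression_on_death_day_moves_back_one_day(self):
        rec = make_record(progressions=[68.0], death=68.0)
        out = resolve_same_day(rec)
        assert out.progressions[0] == 67.0

    def test_no_coincidence_is_identity_and_idempotent(self):
        rec = make_record(line_starts=[0.0, 100.0], progressions=[50.0, None],
                          treatments=["a", "b"], death=300.0)
        once = resolve_same_day(rec)
        assert once.progressions == rec.progressions
        twice = resolve_same_day(resolve_same_day(rec))
        assert twice.progressions == once.progressions

    def test_progression_after_death_raises(self):
        rec = make_record(progressions=[90.0], death=80.0)
        with pytest.raises(DataIntegrityError, match="after death"):
            resolve_same_day(rec)


class TestExtractTransition:
    def test_progression_event_on_line_clock(self):
        rec = make_record(progressions=[183.0])
        t, s = extract_transition(rec, TransitionKey(WT, 1, "PF", "PD"))
        assert s == 1
        assert t == pytest.approx(183.0 / DAYS_PER_YEAR, abs=1e-12)

    def test_censoring_at_competing_next_line(self):
        rec = make_record(line_starts=[0.0, 100.0], treatments=["a", "b"],
                          progressions=[None, None])
        t, s = extract_transition(rec, TransitionKey(WT, 1, "PF", "PD"))
        assert s == 0
        assert t == pytest.approx(100.0 / DAYS_PER_YEAR, abs=1e-12)

    def test_pd_clock_runs_from_progression(self):
        rec = make_record(progressions=[100.0], death=250.0)
        t, s = extract_transition(rec, TransitionKey(WT, 1, "PD", "D"))
        assert (t, s) == (pytest.approx(150.0 / DAYS_PER_YEAR), 1)

    def test_not_at_risk_without_progression(self):
        rec = make_record()
        assert extract_transition(rec, TransitionKey(WT, 1, "PD", "D")) is None

    def test_censored_at_last_visit_when_no_event(self):
        rec = make_record(last_visit=400.0)
        t, s = extract_transition(rec, TransitionKey(WT, 1, "PF", "D"))
        assert (s, t) == (0, pytest.approx(400.0 / DAYS_PER_YEAR))


class TestBuildAllDatasets:
    def test_death_only_patient_contributes_one_event(self):
        rec = make_record(death=200.0)
        datasets, counts = build_all_datasets([rec])
        assert datasets[TransitionKey(WT, 1, "PF", "D")]["status"].sum() == 1
        assert datasets[TransitionKey(WT, 1, "PF", "PD")]["status"].sum() == 0
        assert datasets[TransitionKey(WT, 1, "PF", "next")]["status"].sum() == 0

    def test_competing_events_conserved(self, ref_cohort):
        """Across competing transitions out of PF1, each patient
        contributes at most one event, and total events equal the number
        of patients exiting the state."""
        datasets, _ = build_all_datasets(ref_cohort)
        for sg in {r.subgroup for r in ref_cohort}:
            exits = sum(
                int(datasets[TransitionKey(sg, 1, "PF", to)]["status"].sum())
                for to in ("PD", "next", "D"))
            n_exited = sum(
                1 for r in ref_cohort if r.subgroup == sg and (
                    (r.progressions and r.progressions[0] is not None)
                    or len(r.line_starts) > 1 or r.death is not None))
            assert exits <= n_exited
        # per-patient: risk sets of competing keys share entry times
        df_pd = datasets[TransitionKey(sg, 1, "PF", "PD")]
        df_d = datasets[TransitionKey(sg, 1, "PF", "D")]
        assert len(df_pd) == len(df_d)

    def test_empty_cohort_raises(self):
        with pytest.raises(MelseqError):
            build_all_datasets([])

    def test_nelson_aalen_recovers_true_cumulative_hazard(self):
        """Cause-specific Nelson-Aalen from the extracted first-line
        progression dataset tracks the generating Weibull cumulative
        hazard (favorable patients carry no covariate effects)."""
        lifelines = pytest.importorskip("lifelines")
        spec = reference_spec(n_patients=4000)
        cohort = simulate_cohort(spec, seed=21)
        datasets, _ = build_all_datasets(cohort)
        frames = [datasets[TransitionKey(sg, 1, "PF", "PD")]
                  for sg in ({r.subgroup for r in cohort})
                  if sg.prognostic == "favorable"]
        import pandas as pd
        df = pd.concat(frames)
        naf = lifelines.NelsonAalenFitter()
        naf.fit(df["time_years"], df["status"])
        truth = spec.hazards[(1, "PF", "PD")]
        for t in (0.5, 1.0, 1.5):
            est = float(naf.cumulative_hazard_at_times(t).iloc[0])
            true_H = float(truth.cumhaz(t, {"age": 60, "sex": 0, "ecog": 0,
                                            "ldh": 0, "brain_mets": 0}))
            assert est == pytest.approx(true_H, rel=0.12)


class TestTreatmentMix:
    def test_proportions(self):
        recs = [make_record(id=str(i), treatments=[t])
                for i, t in enumerate(["a", "a", "b", "b"])]
        assert treatment_mix(recs, WT, 1) == {"a": 0.5, "b": 0.5}

    def test_invariant_to_ordering(self):
        recs = [make_record(id=str(i), treatments=[t])
                for i, t in enumerate(["a", "b", "a"])]
        assert treatment_mix(recs, WT, 1) == treatment_mix(recs[::-1], WT, 1)

    def test_empty_line_raises(self):
        with pytest.raises(MelseqError):
            treatment_mix([make_record()], WT, 2)


def test_cohort_csv_round_trip(tmp_path, ref_cohort):
    path = tmp_path / "cohort.csv"
    cohort_to_csv(ref_cohort[:200], path)
    back = cohort_from_csv(path)
    assert len(back) == 200
    for a, b in zip(ref_cohort[:200], back):
        assert a.line_starts == b.line_starts
        assert a.progressions == b.progressions
        assert a.death == b.death
        assert a.subgroup == b.subgroup
        assert a.treatments == b.treatments
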