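"""Synthetic registry generator: determinism, marginals, round trips."""

import numpy as np
import pytest

from melseq.events import Subgroup, build_all_datasets
from melseq.mortality import LifeTable
from melseq.synthetic import (
    GeneratorSpec,
    TrueHazard,
    make_hr_table,
    make_life_table,
    reference_spec,
    sample_time,
    simulate_cohort,
    true_death_times,
)

FLAT = {"age": 60.0, "sex": 0, "ecog": 0, "ldh": 0, "brain_mets": 0}


def single_line_spec(death_rate=0.5):
    """One modeled line, death only, effectively no censoring."""
    tiny = TrueHazard("exponential", (1e-9,))
    return GeneratorSpec(
        n_patients=10_000, n_lines=1, accrual_years=0.0, study_years=1e6,
        braf_prop=0.0, favorable_prop=1.0,
        hazards={(1, "PF", "PD"): tiny, (1, "PF", "next"): tiny,
                 (1, "PF", "D"): TrueHazard("exponential", (death_rate,)),
                 (1, "PD", "next"): tiny, (1, "PD", "D"): tiny,
                 (2, "PF", "D"): TrueHazard("exponential", (death_rate,))},
        treatment_mixes={1: {"dacarbazine": 1.0}})


class TestSimulateCohort:
    def test_empty_cohort(self):
        spec = reference_spec(n_patients=0)
        assert simulate_cohort(spec, seed=0) == []

    def test_same_seed_identical(self):
        spec = reference_spec(n_patients=100)
        a = simulate_cohort(spec, seed=3)
        b = simulate_cohort(spec, seed=3)
        for ra, rb in zip(a, b):
            assert (ra.line_starts, ra.progressions, ra.death, ra.treatments) \
                == (rb.line_starts, rb.progressions, rb.death, rb.treatments)

    def test_exponential_death_time_mean(self):
        """Pure exponential death at rate 0.5/yr: sample mean ~ 2 years."""
        cohort = simulate_cohort(single_line_spec(0.5), seed=9)
        times = np.array([r.death for r in cohort if r.death is not None])
        assert len(times) > 9_900
        mean_years = times.mean() / 365.25
        se = 2.0 / np.sqrt(len(times))
        assert abs(mean_years - 2.0) < 3 * se + 0.005  # + day rounding slack

    def test_covariate_marginals(self):
        cohort = simulate_cohort(reference_spec(n_patients=4000), seed=1)
        male = np.mean([r.sex for r in cohort])
        favorable = np.mean([r.prognostic == "favorable" for r in cohort])
        braf = np.mean([r.braf for r in cohort])
        age = np.mean([r.age for r in cohort])
        assert abs(male - 0.56) < 0.03
        assert abs(favorable - 0.63) < 0.03
        assert abs(braf - 0.59) < 0.03
        assert abs(age - 60.0) < 1.0
        assert all(r.age >= 18 for r in cohort)

    def test_histories_are_internally_consistent(self, ref_cohort):
        for r in ref_cohort:
            assert r.line_starts[0] == 0.0
            assert sorted(r.line_starts) == r.line_starts
            if r.death is not None:
                assert r.death <= r.last_visit
                assert all(s < r.death for s in r.line_starts)


class TestLifeTable:
    def test_zero_gompertz_term_gives_constant_rates(self):
        lt = make_life_table(makeham=(4e-4, 0.0, 0.1))
        assert lt.rate(30, 0.5) == pytest.approx(lt.rate(90, 0.5))

    def test_rates_increase_with_age(self, life_table):
        rates = [life_table.rate(a, 0.5) for a in range(20, 105, 5)]
        assert np.all(np.diff(rates) > 0)

    def test_doubling_makeham_level_doubles_constant_rate(self):
        a = make_life_table(makeham=(4e-4, 0.0, 0.1))
        b = make_life_table(makeham=(8e-4, 0.0, 0.1))
        assert b.rate(50, 0.5) == pytest.approx(2 * a.rate(50, 0.5))

    def test_csv_round_trip(self, tmp_path, life_table):
        path = tmp_path / "life.csv"
        life_table.to_csv(path)
        back = LifeTable.from_csv(path)
        for age in (40, 60, 85, 104):
            assert back.rate(age, 0.56) == pytest.approx(
                life_table.rate(age, 0.56))


class TestHrTable:
    def test_reference_row_is_unity(self, hr_table):
        ref = hr_table.get("dacarbazine")
        assert ref.hr_pfs == 1.0 and ref.hr_pfs_ci == (1.0, 1.0)

    def test_entries_satisfy_invariants(self, hr_table):
        for e in hr_table:
            assert 0 < e.hr_pfs_ci[0] <= e.hr_pfs <= e.hr_pfs_ci[1]
            assert 0 < e.hr_os_ci[0] <= e.hr_os <= e.hr_os_ci[1]

    def test_alias_flag_controls_encorafenib_row(self):
        with_alias = make_hr_table(alias_encorafenib=True)
        without = make_hr_table(alias_encorafenib=False)
        assert "encorafenib+binimetinib" in with_alias
        assert "encorafenib+binimetinib" not in without


def test_generator_spec_yaml_round_trip(tmp_path):
    spec = reference_spec(n_patients=123)
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    back = GeneratorSpec.from_yaml(path)
    assert back.n_patients == 123
    assert back.hazards == spec.hazards
    assert back.treatment_mixes == spec.treatment_mixes


class TestPipelineRoundTrip:
    def test_fit_recovers_true_hazards_at_scale(self):
        """simulate -> extract -> fit covers the generating parameters."""
        from melseq.events import TransitionKey
        from melseq.survival import fit_mle
        spec = reference_spec(n_patients=4000)
        cohort = simulate_cohort(spec, seed=13)
        datasets, _ = build_all_datasets(cohort)
        sg = Subgroup(False, "favorable")
        df = datasets[TransitionKey(sg, 1, "PF", "next")]
        res = fit_mle(df, "exponential", covariate_mask=())
        lo, hi = res.conf_int()[0]
        assert lo < np.log(0.08) < hi

    def test_engine_reproduces_generator_microsimulation(self):
        """The cohort engine run on the generator's *true* hazards
        reproduces the generator's own microsimulated life expectancy
        within 2% (residual: day rounding and cycle discretization)."""
        from melseq.model import SequenceModel
        from melseq.synthetic import transition_set_from_truth
        spec = reference_spec()
        sg = Subgroup(False, "favorable")
        ts = transition_set_from_truth(spec, sg)
        profile = ts.profiles[sg]
        model = SequenceModel(ts, sg, horizon_years=60, covariates=profile)
        le_engine = model.run(["mix"]).outcomes.life_expectancy
        le_truth = true_death_times(spec, profile, n=40_000, seed=99).mean()
        assert abs(le_engine - le_truth) / le_truth < 0.02

    def test_fitted_pipeline_consistent_within_its_own_uncertainty(self):
        """generate -> fit -> engine life expectancy falls within the
        parameter uncertainty band (3 sigma from the fitted
        variance-covariance matrices) around the generator's truth."""
        from melseq.model import SequenceModel
        from melseq.pipeline import build_transition_set
        from melseq.psa import PsaConfig
        spec = reference_spec(n_patients=6000)
        cohort = simulate_cohort(spec, seed=17)
        ts, _ = build_transition_set(
            cohort, families=("exponential", "weibull"), seed=1)
        sg = Subgroup(False, "favorable")
        profile = ts.profiles[sg]
        model = SequenceModel(ts, sg, horizon_years=60, covariates=profile)
        le_engine = model.run(["mix"]).outcomes.life_expectancy
        le_truth = true_death_times(spec, profile, n=20_000, seed=99).mean()
        psa = model.run_psa(["mix"], PsaConfig(n_iter=40, seed=5))
        sigma = psa.iterations["life_expectancy_years"].std()
        assert sigma / le_engine < 0.12  # the band is informative
        assert abs(le_engine - le_truth) < 3 * sigma
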