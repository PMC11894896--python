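"""Cohort engine: cycle embedding, tunnels, composition, flooring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    FLAT_PROFILE,
    WT,
    exp_fit,
    make_transition_set,
    two_line_fits,
    weibull_fit,
)
from _microsim import flat_chain_occupancy, microsimulate
from melseq.engine import (
    TransitionSet,
    compose_traces,
    rates_to_probs,
    run_line_trace,
    run_model,
    state_names,
)
from melseq.events import Subgroup, TransitionKey
from melseq.exceptions import EngineError
from melseq.mortality import floored_death_rate
from melseq.outcomes import life_expectancy


class TestRatesToProbs:
    def test_zero_rates_stay_put(self):
        probs, stay = rates_to_probs({"a": 0.0, "b": 0.0}, 1 / 12)
        assert stay == 1.0 and probs == {"a": 0.0, "b": 0.0}

    def test_single_rate_closed_form(self):
        probs, stay = rates_to_probs({"d": 0.6}, 1 / 12)
        assert probs["d"] == pytest.approx(1 - np.exp(-0.05), rel=1e-12)
        assert stay + probs["d"] == pytest.approx(1.0)

    def test_negative_rate_raises(self):
        with pytest.raises(ValueError):
            rates_to_probs({"a": -0.1}, 1 / 12)

    def test_against_competing_exponential_microsimulation(self):
        """Continuous-time competing draws reproduce the cycle probabilities."""
        r1, r2, dt, n = 0.8, 0.3, 1 / 12, 200_000
        rng = np.random.default_rng(9)
        t1 = rng.exponential(1 / r1, n)
        t2 = rng.exponential(1 / r2, n)
        p1_hat = np.mean((t1 < dt) & (t1 < t2))
        p2_hat = np.mean((t2 < dt) & (t2 < t1))
        probs, _ = rates_to_probs({"a": r1, "b": r2}, dt)
        for hat, p in ((p1_hat, probs["a"]), (p2_hat, probs["b"])):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(hat - p) < 3 * se

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 5.0), min_size=1, max_size=4))
    def test_probabilities_partition_unity(self, rates):
        probs, stay = rates_to_probs(dict(enumerate(rates)), 1 / 12)
        assert stay + sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= p <= 1 for p in probs.values())


class TestFloor:
    def test_model_rate_dominates(self, life_table):
        assert floored_death_rate(0.5, 60, 0.5, life_table) == pytest.approx(0.5)

    def test_table_rate_dominates_at_old_age(self, life_table):
        r = floored_death_rate(0.001, 95, 0.5, life_table)
        assert r == pytest.approx(life_table.rate(95, 0.5))
        assert r > 0.001

    def test_monotone_in_both_inputs(self, life_table):
        ages = [60, 70, 80, 90, 100, 109, 120]
        rates = [floored_death_rate(0.001, a, 0.5, life_table) for a in ages]
        assert rates == sorted(rates)
        assert floored_death_rate(0.3, 60, 0.5, life_table) >= \
            floored_death_rate(0.2, 60, 0.5, life_table)

    def test_zero_disease_hazard_reproduces_life_table_survival(self, life_table):
        """With the floor active and no disease mortality, the model is the
        general-population cohort."""
        fits = {k: exp_fit(0.0) for k in two_line_fits()}
        ts = make_transition_set(WT, fits)
        trace = run_model(ts, WT, ["mix"], life_table=life_table,
                          start_age=60, male_fraction=0.56,
                          horizon_years=40, stop_when_dead=False)
        surv_model = trace.alive()
        surv_table = life_table.survival(60, trace.times, 0.56)
        assert np.max(np.abs(surv_model - surv_table)) < 1e-6

    def test_death_hazard_never_below_table_rate(self, life_table):
        fits = dict(two_line_fits())
        ts = make_transition_set(WT, fits)
        trace = run_model(ts, WT, ["mix"], life_table=life_table,
                          horizon_years=45, stop_when_dead=False)
        surv = trace.alive()
        dt = trace.dt
        keep = surv[:-1] > 1e-9
        implied = -np.log(np.maximum(surv[1:], 1e-300)
                          / np.maximum(surv[:-1], 1e-300)) / dt
        floor = np.array([life_table.rate(60 + t * dt, 0.56)
                          for t in range(len(implied))])
        assert np.all(implied[keep] >= floor[keep] - 1e-9)


class TestLineTrace:
    def test_pure_death_occupancy_closed_form(self, two_line_ts):
        fits = {(1, "PF", "PD"): exp_fit(0.0), (1, "PF", "next"): exp_fit(0.0),
                (1, "PF", "D"): exp_fit(0.3), (1, "PD", "next"): exp_fit(0.0),
                (1, "PD", "D"): exp_fit(0.0)}
        ts = make_transition_set(WT, fits)
        tr = run_line_trace(ts, WT, 1, n_cycles=600)
        m = np.arange(601)
        assert np.max(np.abs(tr.occupancy["PF"].to_numpy()
                             - np.exp(-0.3 * m / 12))) < 1e-12

    def test_zero_hazards_stay_forever(self):
        fits = {k: exp_fit(0.0) for k in two_line_fits()}
        ts = make_transition_set(WT, fits)
        tr = run_line_trace(ts, WT, 1, n_cycles=240)
        assert np.all(tr.occupancy["PF"].to_numpy() == 1.0)

    def test_duration_dependent_pd_matches_microsimulation(self, two_line_ts):
        """PD exit hazards run on the progression clock; a 40k-path
        individual-level simulation shows only binomial sampling noise
        (99% of cells inside 3 SE, none beyond 5 SE)."""
        n, T = 40_000, 120
        trace = run_model(two_line_ts, WT, ["mix"], horizon_years=10,
                          stop_when_dead=False)
        occ = trace.occupancy.to_numpy()[: T + 1]
        ms = microsimulate(two_line_ts, WT, ["mix"], n_paths=n, n_cycles=T,
                           dt=1 / 12, seed=2)
        se = np.sqrt(occ * (1 - occ) / n)
        diff = np.abs(ms - occ)
        assert np.mean(diff <= 3 * se + 3 / n) > 0.99
        assert np.all(diff <= 5 * se + 3 / n)


class TestCompose:
    def test_no_exits_equals_relabelled_line_trace(self):
        fits = dict(two_line_fits())
        for key in list(fits):
            if key[2] == "next":
                fits[key] = exp_fit(0.0)
        fits[(1, "PD", "next")] = exp_fit(0.0)
        ts = make_transition_set(WT, fits)
        lt1 = run_line_trace(ts, WT, 1, n_cycles=300)
        lts = [lt1, run_line_trace(ts, WT, 2, n_cycles=300),
               run_line_trace(ts, WT, 3, n_cycles=300)]
        comp = compose_traces(lts, WT)
        assert np.allclose(comp.occupancy["PF1"], lt1.occupancy["PF"],
                           atol=1e-14)
        assert np.allclose(comp.occupancy["PD1"], lt1.occupancy["PD"],
                           atol=1e-14)
        assert np.allclose(comp.occupancy[["PF2", "PD2", "PF3"]].sum(axis=1),
                           0.0, atol=1e-14)

    def test_flat_exponential_chain_oracle(self):
        """All-exponential hazards: tunnel/convolution machinery must
        reproduce the stationary flat chain solved independently."""
        rates = {(1, "PF", "PD"): 0.45, (1, "PF", "next"): 0.08,
                 (1, "PF", "D"): 0.10, (1, "PD", "next"): 0.8,
                 (1, "PD", "D"): 0.5, (2, "PF", "PD"): 0.5,
                 (2, "PF", "next"): 0.10, (2, "PF", "D"): 0.18,
                 (2, "PD", "next"): 0.6, (2, "PD", "D"): 0.55,
                 (3, "PF", "D"): 0.35}
        ts = make_transition_set(WT, {k: exp_fit(v) for k, v in rates.items()})
        T = 360
        tr = run_model(ts, WT, ["mix"], horizon_years=30, stop_when_dead=False,
                       entry_correction=False)
        oracle = flat_chain_occupancy(rates, WT, T, 1 / 12)
        assert np.max(np.abs(tr.occupancy.to_numpy()[: T + 1] - oracle)) < 1e-12

    def test_compose_agrees_with_global_engine(self, two_line_ts):
        """With entry-time-invariant line dynamics (plain embedding), the
        per-line convolution equals the global layered engine."""
        T = 360
        tr = run_model(two_line_ts, WT, ["mix"], horizon_years=30,
                       stop_when_dead=False, entry_correction=False)
        lts = [run_line_trace(two_line_ts, WT, line, n_cycles=T,
                              entry_correction=False)
               for line in (1, 2, 3)]
        comp = compose_traces(lts, WT)
        assert np.max(np.abs(comp.occupancy.to_numpy()
                             - tr.occupancy.to_numpy()[: T + 1])) < 1e-12

    def test_mass_conservation(self, two_line_ts, life_table):
        tr = run_model(two_line_ts, WT, ["mix"], life_table=life_table)
        assert tr.check_conservation(1e-10)


class TestRunModel:
    def test_deterministic(self, two_line_ts, hr_table, life_table, mix_only):
        ts = TransitionSet(two_line_ts.fits, mix_only, two_line_ts.profiles)
        kw = dict(hr_table=hr_table, life_table=life_table)
        a = run_model(ts, WT, ["nivolumab"], **kw)
        b = run_model(ts, WT, ["nivolumab"], **kw)
        assert np.array_equal(a.occupancy.to_numpy(), b.occupancy.to_numpy())

    def test_missing_fit_names_transition(self):
        fits = dict(two_line_fits())
        del fits[(2, "PD", "D")]
        ts = make_transition_set(WT, fits)
        with pytest.raises(EngineError, match=r"L2:PD->D"):
            run_model(ts, WT, ["mix"])

    def test_braf_three_line_structure(self):
        braf = Subgroup(True, "favorable")
        fits = {}
        for line in (1, 2, 3):
            fits.update({(line, "PF", "PD"): weibull_fit(1.2, 1.5),
                         (line, "PF", "next"): exp_fit(0.1),
                         (line, "PF", "D"): exp_fit(0.12),
                         (line, "PD", "next"): exp_fit(0.7),
                         (line, "PD", "D"): exp_fit(0.5)})
        fits[(4, "PF", "D")] = exp_fit(0.35)
        ts = make_transition_set(braf, fits)
        tr = run_model(ts, braf, ["mix"])
        assert list(tr.occupancy.columns) == [
            "PF1", "PD1", "PF2", "PD2", "PF3", "PD3", "PF4", "D"]
        assert tr.check_conservation(1e-10)

    def test_horizon_cap_truncates_trace(self, two_line_ts):
        tr = run_model(two_line_ts, WT, ["mix"], horizon_years=10)
        assert len(tr.occupancy) == 121

    def test_sequence_too_long_rejected(self, two_line_ts):
        from melseq.exceptions import ConfigError
        with pytest.raises(ConfigError):
            run_model(two_line_ts, WT, ["a", "b", "c"])

    def test_dt_refinement_stability(self, two_line_ts, life_table):
        """Quartering the cycle length moves life expectancy by <0.5%."""
        le = {}
        for dt in (1 / 12, 1 / 48):
            tr = run_model(two_line_ts, WT, ["mix"], life_table=life_table,
                           dt=dt, horizon_years=40, stop_when_dead=False)
            le[dt] = life_expectancy(tr)
        assert abs(le[1 / 48] - le[1 / 12]) / le[1 / 12] < 0.005

    def test_trace_csv_export(self, two_line_ts, tmp_path):
        tr = run_model(two_line_ts, WT, ["mix"], horizon_years=5)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        import pandas as pd
        back = pd.read_csv(path)
        assert list(back.columns) == ["time_years"] + state_names(False) \
            + ["survival"]
        assert len(back) == 61
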