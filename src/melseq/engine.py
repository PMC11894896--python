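"""Semi-Markov cohort engine with tunnel states and clock resets.

The model unrolls treatment lines: within line l the cohort sits in a
progression-free state PF_l (clock = time since line start) or a
progressive-disease state PD_l (clock = time since progression), and
can exit to the next line, to death, or from PF_l to PD_l.  The final
"subsequent therapies" state has only an exit to death.  Duration
dependence is exact at cycle resolution: every state keeps one
occupancy layer per clock age (tunnel states), and transition
intensities are evaluated on the state's own clock.

Per cycle, cause-specific intensities are converted to probabilities by
the competing-exponential embedding: with total intensity H over a
cycle of length dt, the stay probability is exp(-H dt) and cause k
exits with (r_k/H)(1 - exp(-H dt)).  The per-cycle intensity is the
average hazard (H((u+1)dt) - H(u dt))/dt, which is exact for the
single-risk marginal and finite for families with infinite hazard at
t=0.  Death intensities are floored by the general-population mortality
rate at the cohort's attained age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import MIX, EffectPolicy, HazardRatioTable, os_factor, \
    pfs_multiplier_vector, treatment_class
from .events import DEATH, NEXT, PD, PF, Subgroup, TransitionKey, n_named_lines
from .exceptions import ConfigError, EngineError
from .mortality import LifeTable
from .survival import ParametricSurvivalResults

__all__ = [
    "MAX_AGE",
    "TransitionSet",
    "LineTrace",
    "CohortTrace",
    "rates_to_probs",
    "cycle_rates",
    "run_line_trace",
    "compose_traces",
    "run_model",
    "state_names",
]

MAX_AGE = 110.0
_D_TOL = 1e-6  # lifetime horizon stops once death occupancy exceeds 1 - tol


def state_names(braf: bool):
    """Global state labels: PF/PD per line, terminal PF, death."""
    L = n_named_lines(braf)
    names = []
    for line in range(1, L + 1):
        names += [f"PF{line}", f"PD{line}"]
    names.append(f"PF{L + 1}")  # subsequent therapies
    names.append("D")
    return names


@dataclass
class TransitionSet:
    """Fitted hazards for every allowed transition plus line treatment mixes."""

    fits: dict  # TransitionKey -> ParametricSurvivalResults
    mixes: dict = field(default_factory=dict)   # (subgroup, line) -> {trt: p}
    profiles: dict = field(default_factory=dict)  # subgroup -> covariate dict

    def fit_for(self, key: TransitionKey) -> ParametricSurvivalResults:
        try:
            return self.fits[key]
        except KeyError:
            raise EngineError(f"missing transition fit for {key.label()}") from None

    def mix_for(self, subgroup: Subgroup, line: int) -> dict:
        return self.mixes.get((subgroup, line), {})

    def profile_for(self, subgroup: Subgroup):
        return self.profiles.get(subgroup)


def rates_to_probs(rates: dict, dt: float):
    """Competing-exponential cycle embedding.

    Returns ``(probs, stay)`` with ``probs[k] = (r_k/H)(1 - exp(-H dt))``
    and ``stay = exp(-H dt)``; all-zero rates give stay 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    vals = np.array([rates[k] for k in rates], dtype=float)
    if np.any(vals < 0):
        raise ValueError("rates must be nonnegative")
    H = vals.sum()
    if H == 0:
        return {k: 0.0 for k in rates}, 1.0
    stay = np.exp(-H * dt)
    return {k: float(v / H * (1 - stay)) for k, v in zip(rates, vals)}, float(stay)


def cycle_rates(fit: ParametricSurvivalResults, covariates, n_cycles, dt,
                params=None, offset=0.0):
    """Average hazard per cycle from the fitted cumulative hazard.

    ``offset`` (in cycles) shifts the clock grid; entrant-fed states
    use offset 1/2 because mass arriving mid-cycle has mean time in
    state (d + 1/2) dt when its tunnel layer index is d.
    """
    grid = (np.arange(n_cycles + 1) + offset) * dt
    H = fit.cumhaz(grid, covariates, params=params)
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        # deep-tail survival underflow: carry the last finite value forward
        last = np.where(np.isfinite(H))[0]
        if len(last) == 0:
            raise EngineError("cumulative hazard not finite anywhere")
        H = np.minimum.accumulate(np.where(np.isfinite(H), H, np.inf))
        H = np.where(np.isfinite(H), H, H[last[-1]])
    return np.maximum(np.diff(H) / dt, 0.0)


# ---------------------------------------------------------------------------
# one treatment line as a layered block
# ---------------------------------------------------------------------------

class _LineBlock:
    """Occupancy layers and precomputed rate vectors for one line.

    ``pf_*``/``pd_*`` are intensity vectors indexed by clock age (cycle
    units); the subsequent-therapy block has only a PF layer with a
    death exit.  ``pf_half``/``pd_half`` hold the average intensities
    over the first half cycle in the state, used for the arrival
    half-step of the mid-cycle entry correction: mass that changes
    state during a cycle arrives, on average, halfway through it and
    is exposed to the new state's hazard for the remaining half cycle.
    Second-generation moves within the arrival half-step land in their
    destination's first tunnel layer without a further half-step.
    """

    def __init__(self, n_cycles, dt, pf_death, pf_pd=None, pf_next=None,
                 pd_next=None, pd_death=None, pf_half=None, pd_half=None):
        self.T = n_cycles
        self.dt = dt
        self.pf = np.zeros(n_cycles + 1)
        self.pd = np.zeros(n_cycles + 1)
        z = np.zeros(n_cycles)
        self.pf_death = np.asarray(pf_death, dtype=float)
        self.pf_pd = z if pf_pd is None else np.asarray(pf_pd, dtype=float)
        self.pf_next = z if pf_next is None else np.asarray(pf_next, dtype=float)
        self.pd_next = z if pd_next is None else np.asarray(pd_next, dtype=float)
        self.pd_death = z if pd_death is None else np.asarray(pd_death, dtype=float)
        self.has_pd = pd_death is not None or pd_next is not None
        # (pd, next, death) half-cycle intensities; None disables the
        # arrival half-step (mass then enters layer 0 untouched)
        self.pf_half = pf_half
        self.pd_half = pd_half

    @staticmethod
    def _exit_fractions(rates, dt):
        """(stay, frac) with frac = (1 - exp(-H dt))/H; p_k = r_k * frac."""
        H = np.sum(rates, axis=0)
        stay = np.exp(-H * dt)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(H > 0, (1.0 - stay) / np.where(H == 0, 1.0, H), 0.0)
        return stay, frac

    def _half_step(self, mass, half_rates, floor_rate):
        """Expose arriving mass for half a cycle; returns
        (stayers, to_next, to_pd, deaths)."""
        if mass == 0.0:
            return 0.0, 0.0, 0.0, 0.0
        r_pd, r_nx, r_d = half_rates
        r_d = max(r_d, floor_rate)
        stay, frac = self._exit_fractions(np.array([r_pd, r_nx, r_d]),
                                          self.dt / 2)
        return (mass * float(stay), mass * r_nx * float(frac),
                mass * r_pd * float(frac), mass * r_d * float(frac))

    def step(self, t, floor_rate, inflow_half, inflow_direct=0.0):
        """Advance one cycle.

        ``inflow_half`` is first-generation mass arriving from the
        previous line during this cycle (gets the arrival half-step);
        ``inflow_direct`` is second-generation mass that already used
        its half-step upstream.  Returns (first-generation exits to the
        next line, second-generation exits, deaths).
        """
        A = min(t + 1, self.T)
        dt = self.dt
        deaths = 0.0
        to_pd = 0.0
        to_next = 0.0
        # PF layers (clock age 0..A-1)
        occ = self.pf[:A]
        if occ.any():
            r_d = np.maximum(self.pf_death[:A], floor_rate)
            r_pd = self.pf_pd[:A]
            r_nx = self.pf_next[:A]
            stay, frac = self._exit_fractions([r_pd, r_nx, r_d], dt)
            to_pd = float(np.sum(occ * r_pd * frac))
            to_next = float(np.sum(occ * r_nx * frac))
            deaths += float(np.sum(occ * r_d * frac))
            self.pf[1:A + 1] = occ * stay
        else:
            self.pf[1:A + 1] = 0.0
        # PD tunnel layers (clock age = time since progression)
        if self.has_pd:
            occ = self.pd[:A]
            if occ.any():
                r_d = np.maximum(self.pd_death[:A], floor_rate)
                r_nx = self.pd_next[:A]
                stay, frac = self._exit_fractions([r_nx, r_d], dt)
                to_next += float(np.sum(occ * r_nx * frac))
                deaths += float(np.sum(occ * r_d * frac))
                self.pd[1:A + 1] = occ * stay
            else:
                self.pd[1:A + 1] = 0.0
        # arrival half-steps
        second_gen = 0.0
        pd_entry = to_pd
        pf_entry = inflow_half
        if self.has_pd and self.pd_half is not None and pd_entry:
            stayers, nx2, _, d2 = self._half_step(pd_entry, self.pd_half,
                                                  floor_rate)
            pd_entry = stayers
            second_gen += nx2
            deaths += d2
        if self.pf_half is not None and pf_entry:
            stayers, nx2, pd2, d2 = self._half_step(pf_entry, self.pf_half,
                                                    floor_rate)
            pf_entry = stayers
            second_gen += nx2
            pd_entry += pd2       # no second half-step for these
            deaths += d2
        if self.has_pd:
            self.pd[0] = pd_entry
        self.pf[0] = pf_entry + inflow_direct
        return to_next, second_gen, deaths

    def occupancy(self, t):
        """(PF, PD) mass at cycle t, summing only occupied layers."""
        A = min(t + 1, self.T + 1)
        return float(self.pf[:A].sum()), float(self.pd[:A].sum())


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

@dataclass
class LineTrace:
    """Line-local trace: PF/PD occupancy, exits to the next line, deaths."""

    occupancy: pd.DataFrame       # columns PF, PD, D over local cycles 0..U
    exit_flow: np.ndarray         # arrivals to the next line at local cycle u
    dt: float

    def __post_init__(self):
        alive = self.occupancy[["PF", "PD"]].sum(axis=1)
        total = alive + self.occupancy["D"] + np.cumsum(
            np.concatenate([[0.0], self.exit_flow[1:]]))
        if np.abs(total - 1.0).max() > 1e-9:
            raise EngineError("line trace does not conserve mass")


@dataclass
class CohortTrace:
    """Occupancy of every health state per monthly cycle (tunnels collapsed)."""

    occupancy: pd.DataFrame       # columns from state_names(braf)
    dt: float
    start_age: float
    male_fraction: float
    entry_flows: dict = field(default_factory=dict)  # line -> arrivals per cycle

    @property
    def n_cycles(self) -> int:
        return len(self.occupancy) - 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.occupancy)) * self.dt

    def alive(self) -> np.ndarray:
        cols = [c for c in self.occupancy.columns if c != "D"]
        return self.occupancy[cols].sum(axis=1).to_numpy()

    def check_conservation(self, tol=1e-10):
        total = self.occupancy.sum(axis=1).to_numpy()
        if np.abs(total - 1.0).max() > tol:
            raise EngineError("cohort trace does not conserve mass")
        d = self.occupancy["D"].to_numpy()
        if np.any(np.diff(d) < -tol):
            raise EngineError("death occupancy is not monotone")
        return True

    def to_csv(self, path):
        out = self.occupancy.copy()
        out.insert(0, "time_years", self.times)
        out["survival"] = self.alive()
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# building rate vectors for one configured run
# ---------------------------------------------------------------------------

def _line_rate_vectors(transitions: TransitionSet, subgroup: Subgroup, line: int,
                       treatment, hr_table, policy, covariates, n_cycles, dt,
                       carry_os=1.0, param_draws=None, entry_correction=True,
                       pf_entrant=None):
    """Adjusted intensity vectors (and half-step rates) for one line.

    With the mid-cycle entry correction, entrant-fed states (PD of any
    line, PF of lines past the first) evaluate tunnel layer d at time
    in state (d + 1/2) dt and expose arrivals for half a cycle at the
    state's initial average hazard.
    """
    L = n_named_lines(subgroup.braf)
    if pf_entrant is None:
        pf_entrant = line > 1
    pf_offset = 0.5 if (entry_correction and pf_entrant) else 0.0
    pd_offset = 0.5 if entry_correction else 0.0

    def rates(from_state, to_state, offset=0.0):
        key = TransitionKey(subgroup, line, from_state, to_state)
        fit = transitions.fit_for(key)
        draws = None if param_draws is None else param_draws.get(key)
        return cycle_rates(fit, covariates, n_cycles, dt, params=draws,
                           offset=offset)

    def half(from_state, to_state):
        # average intensity over the first half cycle in the state
        key = TransitionKey(subgroup, line, from_state, to_state)
        fit = transitions.fit_for(key)
        draws = None if param_draws is None else param_draws.get(key)
        H = float(np.asarray(fit.cumhaz(dt / 2, covariates, params=draws)))
        return H / (dt / 2)

    mix = transitions.mix_for(subgroup, line)
    if treatment == MIX or hr_table is None:
        f_os, pfs_mult, pfs_mult0 = 1.0, 1.0, 1.0
    else:
        f_os = os_factor(treatment, mix, hr_table, policy)
        ages = (np.arange(n_cycles) + pf_offset) * dt
        pfs_mult = pfs_multiplier_vector(treatment, mix, hr_table, policy, ages)
        pfs_mult0 = float(pfs_multiplier_vector(treatment, mix, hr_table,
                                                policy, np.array([dt / 4]))[0])
    if line <= L:
        out = dict(
            pf_pd=rates(PF, PD, pf_offset) * pfs_mult,
            pf_next=rates(PF, NEXT, pf_offset),
            pf_death=rates(PF, DEATH, pf_offset) * f_os * carry_os,
            pd_next=rates(PD, NEXT, pd_offset),
            pd_death=rates(PD, DEATH, pd_offset) * f_os * carry_os,
        )
        if entry_correction:
            out["pd_half"] = (0.0, half(PD, NEXT),
                              half(PD, DEATH) * f_os * carry_os)
            if pf_entrant:
                out["pf_half"] = (half(PF, PD) * pfs_mult0, half(PF, NEXT),
                                  half(PF, DEATH) * f_os * carry_os)
        return out
    out = dict(pf_death=rates(PF, DEATH, pf_offset) * carry_os)
    if entry_correction and pf_entrant:
        out["pf_half"] = (0.0, 0.0, half(PF, DEATH) * carry_os)
    return out


def _carryover_factors(sequence, transitions, subgroup, hr_table, policy):
    """Cumulative beyond-line OS multipliers entering each line.

    Under the beyond-line scenario an immunotherapy's normalized OS
    factor keeps multiplying death intensities of every later line.
    """
    L = n_named_lines(subgroup.braf)
    carry = [1.0]
    for line in range(1, L + 1):
        trt = sequence[line - 1] if line - 1 < len(sequence) else MIX
        factor = carry[-1]
        if (policy.os_scope == "beyond_line" and trt != MIX
                and hr_table is not None
                and treatment_class(trt, hr_table, policy) == "immunotherapy"):
            mix = transitions.mix_for(subgroup, line)
            factor = factor * os_factor(trt, mix, hr_table, policy)
        carry.append(factor)
    return carry  # carry[line-1] applies within line `line`


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def _resolve_horizon(horizon_years, start_age, dt, policy=None):
    if policy is not None and policy.horizon_years is not None:
        horizon_years = policy.horizon_years if horizon_years is None \
            else min(horizon_years, policy.horizon_years)
    if horizon_years is None:
        horizon_years = max(MAX_AGE - start_age, dt)
    return int(np.ceil(horizon_years / dt - 1e-9))


def run_model(transitions: TransitionSet, subgroup: Subgroup, sequence,
              hr_table: HazardRatioTable | None = None,
              policy: EffectPolicy | None = None,
              life_table: LifeTable | None = None,
              start_age: float = 60.0, male_fraction: float = 0.56,
              covariates=None, dt: float = 1.0 / 12,
              horizon_years: float | None = None,
              param_draws=None, stop_when_dead=True,
              entry_correction=True) -> CohortTrace:
    """Run the full multi-line cohort model and return its trace.

    ``sequence`` lists the treatment per line (``"mix"`` for the
    observed mix); unspecified lines default to the mix.  The trace is
    deterministic given the fits, hazard ratios, policy and horizon.
    ``entry_correction=False`` disables the mid-cycle arrival
    half-step, recovering the plain entrants-next-cycle embedding.
    """
    policy = policy or EffectPolicy()
    L = n_named_lines(subgroup.braf)
    sequence = list(sequence)
    if len(sequence) > L:
        raise ConfigError(
            f"sequence has {len(sequence)} lines but subgroup allows {L}")
    if covariates is None:
        covariates = transitions.profile_for(subgroup)
    lifetime = horizon_years is None and policy.horizon_years is None
    T = _resolve_horizon(horizon_years, start_age, dt, policy)

    carry = _carryover_factors(sequence, transitions, subgroup, hr_table, policy)
    blocks = []
    for line in range(1, L + 2):
        trt = sequence[line - 1] if line - 1 < len(sequence) else MIX
        vecs = _line_rate_vectors(
            transitions, subgroup, line, trt, hr_table, policy, covariates,
            T, dt, carry_os=carry[min(line, L) - 1] if line <= L else carry[L],
            param_draws=param_draws, entry_correction=entry_correction)
        blocks.append(_LineBlock(T, dt, **vecs))

    floor = (life_table.rate_vector(start_age, T, dt, male_fraction)
             if life_table is not None else np.zeros(T))

    names = state_names(subgroup.braf)
    occ = np.zeros((T + 1, len(names)))
    entry_flows = {line: np.zeros(T + 1) for line in range(2, L + 2)}
    blocks[0].pf[0] = 1.0
    dead = 0.0
    t_end = T
    for t in range(T + 1):
        col = 0
        for line, blk in enumerate(blocks, start=1):
            pf_occ, pd_occ = blk.occupancy(t)
            occ[t, col] = pf_occ
            col += 1
            if line <= L:
                occ[t, col] = pd_occ
                col += 1
        occ[t, -1] = dead
        if t == T:
            break
        if stop_when_dead and lifetime and dead >= 1.0 - _D_TOL:
            t_end = t
            break
        inflow_half = 0.0
        inflow_direct = 0.0
        for line, blk in enumerate(blocks, start=1):
            out_first, out_second, deaths = blk.step(
                t, floor[t], inflow_half, inflow_direct)
            dead += deaths
            inflow_half, inflow_direct = out_first, out_second
            if line + 1 in entry_flows:
                entry_flows[line + 1][t + 1] = out_first + out_second
        # the terminal block has no next-line exits
        dead += inflow_half + inflow_direct

    occ = occ[: t_end + 1]
    trace = CohortTrace(pd.DataFrame(occ, columns=names), dt, start_age,
                        male_fraction,
                        {k: v[: t_end + 1] for k, v in entry_flows.items()})
    trace.check_conservation(1e-9)
    return trace


def run_line_trace(transitions: TransitionSet, subgroup: Subgroup, line: int,
                   treatment=MIX, hr_table=None, policy=None,
                   life_table=None, start_age=60.0, male_fraction=0.56,
                   covariates=None, dt=1.0 / 12, n_cycles=None,
                   carry_os=1.0, param_draws=None,
                   entry_correction=True) -> LineTrace:
    """Line-local semi-Markov trace: the whole cohort enters PF at cycle 0.

    The mortality-floor age runs from ``start_age`` with local time
    (the caller supplies the age at line entry).  The line-local view
    starts its PF clock exactly at cycle 0, so the PF grid is never
    half-shifted here; the entry correction still applies to the PD
    tunnel.
    """
    policy = policy or EffectPolicy()
    if n_cycles is None:
        n_cycles = _resolve_horizon(None, start_age, dt)
    if covariates is None:
        covariates = transitions.profile_for(subgroup)
    vecs = _line_rate_vectors(transitions, subgroup, line, treatment,
                              hr_table, policy, covariates, n_cycles, dt,
                              carry_os=carry_os, param_draws=param_draws,
                              entry_correction=entry_correction,
                              pf_entrant=False)
    blk = _LineBlock(n_cycles, dt, **vecs)
    floor = (life_table.rate_vector(start_age, n_cycles, dt, male_fraction)
             if life_table is not None else np.zeros(n_cycles))
    blk.pf[0] = 1.0
    rows = np.zeros((n_cycles + 1, 3))
    exit_flow = np.zeros(n_cycles + 1)
    dead = 0.0
    for t in range(n_cycles + 1):
        pf_occ, pd_occ = blk.occupancy(t)
        rows[t] = (pf_occ, pd_occ, dead)
        if t == n_cycles:
            break
        out_first, out_second, deaths = blk.step(t, floor[t], 0.0, 0.0)
        dead += deaths
        exit_flow[t + 1] = out_first + out_second
    return LineTrace(pd.DataFrame(rows, columns=["PF", "PD", "D"]),
                     exit_flow, dt)


def compose_traces(line_traces, subgroup: Subgroup, start_age=60.0,
                   male_fraction=0.56) -> CohortTrace:
    """Compose per-line local traces into one global trace by convolution.

    ``line_traces`` is ordered line 1..L plus the subsequent-therapy
    line; entrants to line l+1 at global cycle k are line l's exit flow
    convolved with line l's own entry distribution, and each entrant
    cohort follows the local trace offset by its entry cycle.  Valid
    when line dynamics do not depend on the entry time.
    """
    L = n_named_lines(subgroup.braf)
    if len(line_traces) != L + 1:
        raise EngineError(f"expected {L + 1} line traces, got {len(line_traces)}")
    T = min(len(tr.occupancy) - 1 for tr in line_traces)
    dt = line_traces[0].dt
    if any(abs(tr.dt - dt) > 1e-15 for tr in line_traces):
        raise EngineError("line traces have mismatched cycle lengths")

    names = state_names(subgroup.braf)
    occ = np.zeros((T + 1, len(names)))
    entrants = np.zeros(T + 1)
    entrants[0] = 1.0
    entry_flows = {}
    col = 0
    for line, tr in enumerate(line_traces, start=1):
        pf_local = tr.occupancy["PF"].to_numpy()[: T + 1]
        pd_local = tr.occupancy["PD"].to_numpy()[: T + 1]
        occ[:, col] += _conv(entrants, pf_local, T)
        col += 1
        if line <= L:
            occ[:, col] += _conv(entrants, pd_local, T)
            col += 1
        entrants = _conv(entrants, tr.exit_flow[: T + 1], T)
        if line < L + 1:
            entry_flows[line + 1] = entrants.copy()
    occ[:, -1] = 1.0 - occ[:, :-1].sum(axis=1)
    trace = CohortTrace(pd.DataFrame(occ, columns=names), dt, start_age,
                        male_fraction, entry_flows)
    trace.check_conservation(1e-9)
    return trace


def _conv(a, b, T):
    return np.convolve(a, b)[: T + 1]
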