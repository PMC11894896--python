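"""Independent patient-level oracles for the cohort engine.

The cohort engine propagates occupancy through per-cycle competing
transition probabilities; these helpers simulate individual paths
through the same piecewise-constant-hazard process (and, for the
time-homogeneous case, solve the flat continuous-time chain directly)
so engine bookkeeping — tunnel clocks, clock resets, line composition,
flooring — is validated against an implementation that shares none of
its code.
"""

import numpy as np

from melseq.engine import _line_rate_vectors, state_names
from melseq.events import n_named_lines


def microsimulate(transitions, subgroup, sequence, n_paths, n_cycles, dt,
                  seed=0, hr_table=None, policy=None, floor=None,
                  covariates=None, entry_correction=True):
    """Path-level simulation; returns occupancy fractions (cycle x state).

    Each patient carries (line, substate PF/PD, clock age); per cycle
    the cause-specific rates at the patient's clock age are converted
    to competing probabilities and one uniform draw decides the move.
    With the entry correction, a patient who changes state draws an
    additional arrival half-step in the new state (half-cycle
    exposure); a second move within that half-step lands in its
    destination's first layer without a further half-step.
    """
    from melseq.effects import EffectPolicy, MIX

    policy = policy or EffectPolicy()
    L = n_named_lines(subgroup.braf)
    if covariates is None:
        covariates = transitions.profile_for(subgroup)
    vecs = []
    for line in range(1, L + 2):
        trt = sequence[line - 1] if line - 1 < len(sequence) else MIX
        vecs.append(_line_rate_vectors(
            transitions, subgroup, line, trt, hr_table, policy, covariates,
            n_cycles, dt, entry_correction=entry_correction))
    if floor is None:
        floor = np.zeros(n_cycles)

    rng = np.random.default_rng(seed)
    line_ix = np.zeros(n_paths, dtype=int)     # 0..L (L = terminal block)
    is_pd = np.zeros(n_paths, dtype=bool)
    clock = np.zeros(n_paths, dtype=int)
    alive = np.ones(n_paths, dtype=bool)

    names = state_names(subgroup.braf)
    occ = np.zeros((n_cycles + 1, len(names)))

    def record(t):
        for li in range(L + 1):
            sel = alive & (line_ix == li)
            if li < L:
                occ[t, 2 * li] = np.sum(sel & ~is_pd)
                occ[t, 2 * li + 1] = np.sum(sel & is_pd)
            else:
                occ[t, 2 * L] = np.sum(sel)
        occ[t, -1] = np.sum(~alive)

    def competing_draw(r, uu, dt_eff):
        """Cause index per path (-1 stay) from stacked rates and uniforms."""
        H = r.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_exit = np.where(H > 0, -np.expm1(-H * dt_eff), 0.0)
            frac = np.where(H > 0, p_exit / np.where(H == 0, 1, H), 0.0)
        p = r * frac
        c = np.cumsum(p, axis=0)
        cause = np.full(uu.shape, -1)
        cause[uu < c[2]] = 2
        cause[uu < c[1]] = 1
        cause[uu < c[0]] = 0
        return cause

    def half_rates(li, pd_state, n):
        v = vecs[li]
        key = "pd_half" if pd_state else "pf_half"
        hr = v.get(key)
        if hr is None:
            return None
        return np.tile(np.asarray(hr, dtype=float)[:, None], (1, n))

    for t in range(n_cycles + 1):
        record(t)
        if t == n_cycles:
            break
        u = rng.uniform(size=n_paths)
        u2 = rng.uniform(size=n_paths)
        new_line = line_ix.copy()
        new_pd = is_pd.copy()
        new_clock = clock + 1
        new_alive = alive.copy()
        for li in range(L + 1):
            v = vecs[li]
            for pd_state in (False, True):
                sel = alive & (line_ix == li) & (is_pd == pd_state)
                if not sel.any():
                    continue
                ages = clock[sel]
                z = np.zeros(len(ages))
                if li < L and not pd_state:
                    r = np.stack([v["pf_pd"][ages], v["pf_next"][ages],
                                  np.maximum(v["pf_death"][ages], floor[t])])
                elif li < L:
                    r = np.stack([z, v["pd_next"][ages],
                                  np.maximum(v["pd_death"][ages], floor[t])])
                else:
                    r = np.stack([z, z,
                                  np.maximum(v["pf_death"][ages], floor[t])])
                idx = np.flatnonzero(sel)
                cause = competing_draw(r, u[sel], dt)
                # cause 0: -> PD of this line; 1: -> next line PF; 2: death
                mv_pd = idx[cause == 0]
                mv_nx = idx[cause == 1]
                new_alive[idx[cause == 2]] = False

                # arrival half-step into PD of this line
                hr = half_rates(li, True, len(mv_pd))
                if len(mv_pd) and hr is not None:
                    hr[2] = np.maximum(hr[2], floor[t])
                    c2 = competing_draw(hr, u2[mv_pd], dt / 2)
                    new_alive[mv_pd[c2 == 2]] = False
                    # PD -> next within the half-step: direct to next PF
                    sec = mv_pd[c2 == 1]
                    new_line[sec] = li + 1
                    new_pd[sec] = False
                    new_clock[sec] = 0
                    stay = mv_pd[c2 == -1]
                    new_pd[stay] = True
                    new_clock[stay] = 0
                elif len(mv_pd):
                    new_pd[mv_pd] = True
                    new_clock[mv_pd] = 0

                # arrival half-step into the next line's PF
                dest = min(li + 1, L)
                hr = half_rates(dest, False, len(mv_nx))
                new_line[mv_nx] = li + 1
                new_pd[mv_nx] = False
                new_clock[mv_nx] = 0
                if len(mv_nx) and hr is not None:
                    hr[2] = np.maximum(hr[2], floor[t])
                    c2 = competing_draw(hr, u2[mv_nx], dt / 2)
                    new_alive[mv_nx[c2 == 2]] = False
                    # PF -> PD within the half-step: direct to that PD
                    to_pd2 = mv_nx[c2 == 0]
                    new_pd[to_pd2] = True
                    # PF -> next-next line within the half-step
                    sec = mv_nx[c2 == 1]
                    new_line[sec] = li + 2
        line_ix, is_pd, clock, alive = new_line, new_pd, new_clock, new_alive
    return occ / n_paths


def flat_chain_occupancy(rates, subgroup, n_cycles, dt):
    """Time-homogeneous oracle: the flat chain iterated directly.

    With constant intensities no clocks matter, so the model reduces to
    one stationary stochastic matrix over the named states (one jump
    per cycle, competing-exponential embedding) iterated from PF1 —
    none of the engine's tunnel/convolution machinery is involved.
    ``rates`` maps (line, from_state, to_state) to a constant intensity.
    """
    names = state_names(subgroup.braf)
    L = n_named_lines(subgroup.braf)
    index = {name: i for i, name in enumerate(names)}
    exits = {name: [] for name in names}

    for line in range(1, L + 1):
        exits[f"PF{line}"] = [(f"PD{line}", rates[(line, "PF", "PD")]),
                              (f"PF{line+1}", rates[(line, "PF", "next")]),
                              ("D", rates[(line, "PF", "D")])]
        exits[f"PD{line}"] = [(f"PF{line+1}", rates[(line, "PD", "next")]),
                              ("D", rates[(line, "PD", "D")])]
    exits[f"PF{L+1}"] = [("D", rates[(L + 1, "PF", "D")])]

    P = np.eye(len(names))
    for frm, outs in exits.items():
        if not outs:
            continue
        H = sum(r for _, r in outs)
        if H == 0:
            continue
        i = index[frm]
        P[i, i] = np.exp(-H * dt)
        for to, r in outs:
            P[i, index[to]] += r / H * (1 - np.exp(-H * dt))

    occ = np.zeros((n_cycles + 1, len(names)))
    occ[0, 0] = 1.0
    for t in range(1, n_cycles + 1):
        occ[t] = occ[t - 1] @ P
    return occ
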