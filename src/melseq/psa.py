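"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by redrawing, per iteration, (a)
every transition fit's parameter vector from a multivariate normal
centered at the MLE with the fit's variance-covariance matrix (via its
lower Cholesky factor) and (b) every treatment's hazard ratios from
log-normal distributions matching the reported 95% credible intervals.
Each iteration reruns the full engine; summaries are the mean and the
2.5/97.5 percentiles across iterations.  Within an iteration the same
draws are reused for every sequence (common random numbers), so
incremental life-years are computed on paired draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MelseqError

__all__ = ["PsaConfig", "PsaResult", "draw_coefficients", "draw_hr", "run_psa"]

_Z975 = 1.959963984540054


@dataclass
class PsaConfig:
    n_iter: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _cholesky_with_jitter(vcov, max_jitter=1e-10):
    vcov = np.asarray(vcov, dtype=float)
    if vcov.size == 0 or not vcov.any():
        return np.zeros_like(vcov), 0.0  # degenerate: exact zero factor
    jitter = 0.0
    for _ in range(2):
        try:
            return np.linalg.cholesky(vcov + jitter * np.eye(len(vcov))), jitter
        except np.linalg.LinAlgError:
            jitter = max_jitter
    # PSD but singular: eigenvalue square root
    w, v = np.linalg.eigh(vcov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise MelseqError("variance-covariance matrix is not PSD after jitter")
    return v * np.sqrt(np.clip(w, 0.0, None)), jitter


def draw_coefficients(fit, rng) -> np.ndarray:
    """One multivariate-normal draw: MLE + L z with L the Cholesky factor."""
    L, jitter = _cholesky_with_jitter(fit.vcov)
    if jitter:
        fit._jitter_used = jitter
    z = rng.standard_normal(len(fit.params))
    return fit.params + L @ z


def draw_hr(median, lb, ub, rng) -> float:
    """Log-normal draw matching a reported 95% credible interval.

    The location is the log-midpoint of the interval, so the empirical
    2.5/97.5 percentiles reproduce (lb, ub) exactly; for the near
    log-symmetric intervals typical of network meta-analyses this
    coincides with log(median).
    """
    if not (0 < lb <= median <= ub):
        raise MelseqError(f"invalid HR bounds ({lb}, {median}, {ub})")
    if lb == ub:
        return float(median)
    loc = 0.5 * (np.log(lb) + np.log(ub))
    scale = (np.log(ub) - np.log(lb)) / (2 * _Z975)
    return float(np.exp(loc + scale * rng.standard_normal()))


@dataclass
class PsaResult:
    """Per-iteration outcomes and their summaries."""

    iterations: pd.DataFrame       # columns: iteration, sequence, outcomes
    summary: pd.DataFrame          # index (sequence, outcome): mean, p2.5, p97.5
    n_failed: int = 0
    seed: int = 0

    def to_csv(self, path):
        self.iterations.to_csv(path, index=False)


_OUTCOME_COLS = ("life_expectancy_years", "survival_2y", "survival_5y",
                 "median_os_months")


def run_psa(run_one, transitions, hr_table, sequences, config: PsaConfig,
            max_redraws=3):
    """Propagate parameter uncertainty through the engine.

    ``run_one(sequence, param_draws, hr_draws)`` must return an
    OutcomeSet; it is called once per sequence per iteration with the
    iteration's shared draws.  Failed iterations are redrawn (counted).
    """
    rng = np.random.default_rng(config.seed)
    records = []
    n_failed = 0
    it = 0
    attempts = 0
    while it < config.n_iter:
        attempts += 1
        if attempts > config.n_iter * (max_redraws + 1):
            raise MelseqError("too many failed PSA iterations")
        param_draws = {k: draw_coefficients(f, rng)
                       for k, f in transitions.fits.items()}
        hr_draws = None
        if hr_table is not None:
            hr_draws = hr_table.with_values({
                e.treatment: (
                    draw_hr(e.hr_pfs, *e.hr_pfs_ci, rng),
                    draw_hr(e.hr_os, *e.hr_os_ci, rng),
                ) for e in hr_table})
        try:
            row_set = []
            for seq_name, sequence in sequences.items():
                out = run_one(sequence, param_draws, hr_draws)
                row = {"iteration": it, "sequence": seq_name}
                d = out.to_dict()
                for col in _OUTCOME_COLS:
                    row[col] = d[col]
                for state, val in d["mean_time_per_state_years"].items():
                    row[f"time_{state}_years"] = val
                row_set.append(row)
        except MelseqError:
            n_failed += 1
            continue
        records.extend(row_set)
        it += 1
    iterations = pd.DataFrame(records)
    summary = _summarize(iterations)
    return PsaResult(iterations, summary, n_failed=n_failed, seed=config.seed)


def _summarize(iterations: pd.DataFrame) -> pd.DataFrame:
    value_cols = [c for c in iterations.columns
                  if c not in ("iteration", "sequence")]
    rows = []
    for seq, grp in iterations.groupby("sequence", sort=False):
        for col in value_cols:
            vals = grp[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            rows.append({
                "sequence": seq, "outcome": col,
                "mean": float(np.mean(finite)) if len(finite) else np.nan,
                "p2.5": float(np.percentile(finite, 2.5)) if len(finite) else np.nan,
                "p97.5": float(np.percentile(finite, 97.5)) if len(finite) else np.nan,
                "n_not_reached": int(np.sum(~np.isfinite(vals))),
            })
    return pd.DataFrame(rows).set_index(["sequence", "outcome"])
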