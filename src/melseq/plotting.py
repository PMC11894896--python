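"""Matplotlib helpers for traces and fit diagnostics."""

from __future__ import annotations

import numpy as np


def plot_trace(trace, ax=None):
    """Stacked state-occupancy plot over time plus the survival curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    times = trace.times
    cols = [c for c in trace.occupancy.columns if c != "D"]
    ax.stackplot(times, [trace.occupancy[c] for c in cols], labels=cols,
                 alpha=0.8)
    ax.plot(times, trace.alive(), "k-", lw=1.5, label="overall survival")
    ax.set_xlabel("years since first-line start")
    ax.set_ylabel("proportion of cohort")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_fit_vs_data(fit, data, ax=None, t_max=None):
    """Fitted survival curve over the Kaplan-Meier-style empirical curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = np.asarray(data["time_years"], dtype=float)
    d = np.asarray(data["status"], dtype=int)
    order = np.argsort(t)
    t, d = t[order], d[order]
    # product-limit estimate
    at_risk = len(t) - np.arange(len(t))
    factors = np.where(d == 1, 1.0 - 1.0 / at_risk, 1.0)
    km = np.cumprod(factors)
    ax.step(t, km, where="post", label="empirical")
    grid = np.linspace(0, t_max or t.max(), 200)
    ax.plot(grid, fit.survival(grid), label=f"{fit.family.name} fit")
    ax.set_xlabel("years")
    ax.set_ylabel("survival")
    ax.legend()
    return ax
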