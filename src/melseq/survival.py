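"""Maximum-likelihood fitting of parametric transition hazards.

`ParametricSurvivalModel` is a statsmodels-style model object holding
right-censored times, an event indicator and an optional covariate
matrix; `fit()` returns a `ParametricSurvivalResults` carrying the MLE,
its variance-covariance matrix (inverse observed information), the
maximized log-likelihood and AIC/BIC.  `select_model` fits a list of
families and ranks them by AIC.

The log-likelihood is the standard right-censored one,
sum_events log h(t) + sum_all log S(t), equivalently
sum_events log f(t) + sum_censored log S(t).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

from .exceptions import ConvergenceError, FitError
from .families import Family, get_family

__all__ = [
    "COVARIATE_NAMES",
    "AGE_REFERENCE",
    "ParametricSurvivalModel",
    "ParametricSurvivalResults",
    "fit_mle",
    "select_model",
    "information_criteria",
    "hazard_value",
    "survival_value",
]

#: baseline covariates, in canonical column order
COVARIATE_NAMES = ("age", "sex", "ecog", "ldh", "brain_mets")

#: age (years) subtracted before fitting so intercepts refer to a
#: 60-year-old reference profile
AGE_REFERENCE = 60.0

_N_RESTARTS = 5
_GTOL = 1e-8


def center_covariates(df: pd.DataFrame, mask=None) -> np.ndarray:
    """Design matrix in canonical order with age centered at the reference."""
    cols = list(mask) if mask is not None else list(COVARIATE_NAMES)
    X = np.column_stack([np.asarray(df[c], dtype=float) for c in cols]) if cols \
        else np.empty((len(df), 0))
    if "age" in cols:
        X[:, cols.index("age")] -= AGE_REFERENCE
    return X


class ParametricSurvivalModel:
    """Right-censored parametric survival model.

    Parameters
    ----------
    time : array-like of float
        Event or censoring times in years, strictly positive.
    status : array-like of {0, 1}
        1 for an observed event, 0 for right censoring.
    exog : ndarray, optional
        Covariate matrix (already centered); columns named by
        ``exog_names``.
    family : str or Family
        One of the eight supported families.
    """

    def __init__(self, time, status, exog=None, exog_names=(),
                 family="exponential"):
        self.time = np.asarray(time, dtype=float)
        self.status = np.asarray(status, dtype=int)
        if self.time.ndim != 1 or self.time.shape != self.status.shape:
            raise ValueError("time and status must be 1-d and aligned")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("times must be finite and strictly positive")
        if exog is None:
            exog = np.empty((len(self.time), 0))
        self.exog = np.asarray(exog, dtype=float)
        self.exog_names = tuple(exog_names)
        if self.exog.shape != (len(self.time), len(self.exog_names)):
            raise ValueError("exog shape does not match exog_names")
        self.family: Family = family if isinstance(family, Family) else get_family(family)
        self.n_obs = len(self.time)
        self.n_events = int(self.status.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family="exponential",
                       covariate_mask=None):
        """Build from a frame with ``time_years``, ``status`` and covariates.

        ``covariate_mask`` selects a subset of the canonical covariates
        (all five by default); pass an empty tuple for no covariates.
        """
        mask = tuple(covariate_mask) if covariate_mask is not None else COVARIATE_NAMES
        for c in mask:
            if c not in COVARIATE_NAMES:
                raise ValueError(f"unknown covariate {c!r}")
        X = center_covariates(df, mask)
        return cls(df["time_years"], df["status"], X, mask, family)

    # -- likelihood ---------------------------------------------------------

    def _unpack(self, theta):
        k = self.family.n_params
        return theta[:k], theta[k:]

    def loglike(self, theta):
        params, beta = self._unpack(np.asarray(theta, dtype=float))
        linpred = self.exog @ beta if beta.size else 0.0
        natural = self.family.natural_params(params, linpred)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp = self.family.logpdf(self.time, natural)
            ls = self.family.logsf(self.time, natural)
            ll = np.where(self.status == 1, lp, ls)
        if not np.all(np.isfinite(ll)):
            return -np.inf
        return float(ll.sum())

    def _neg_loglike(self, theta):
        ll = self.loglike(theta)
        return 1e10 if not np.isfinite(ll) else -ll

    # -- starting values ----------------------------------------------------

    def _start_params(self):
        t, d = self.time, self.status
        rate = max(d.sum(), 0.5) / t.sum()
        logt = np.log(t[d == 1]) if d.any() else np.log(t)
        mu0 = float(np.mean(logt))
        sigma0 = float(np.std(logt)) or 0.5
        name = self.family.name
        if name == "exponential":
            core = [np.log(rate)]
        elif name in ("weibull", "log_logistic"):
            core = [0.0, -np.log(rate)]          # shape 1, scale 1/rate
        elif name == "gamma":
            core = [0.0, -np.log(rate)]          # shape 1, inv-rate 1/rate
        elif name == "log_normal":
            core = [mu0, np.log(sigma0)]
        elif name == "generalized_gamma":
            core = [mu0, np.log(sigma0), 1.0]    # Q=1 start (Weibull)
        elif name == "generalized_f":
            core = [mu0, np.log(sigma0), 0.5, np.log(1.0)]
        elif name == "gompertz":
            core = [0.01, np.log(rate)]
        else:  # pragma: no cover
            raise AssertionError(name)
        return np.array(core + [0.0] * len(self.exog_names))

    # -- fitting ------------------------------------------------------------

    def fit(self, maxiter=500, n_restarts=_N_RESTARTS, seed=0):
        """Maximize the right-censored likelihood (BFGS with restarts)."""
        if self.n_events == 0:
            raise FitError("cannot fit: data contain no events")
        if self.exog.shape[1]:
            rank = np.linalg.matrix_rank(
                np.column_stack([np.ones(self.n_obs), self.exog]))
            if rank < self.exog.shape[1] + 1:
                raise FitError("design matrix is rank deficient")
        x0 = self._start_params()
        rng = np.random.default_rng(seed)
        best = None
        for i in range(n_restarts + 1):
            start = x0 if i == 0 else x0 + rng.normal(scale=0.3, size=x0.size)
            res = optimize.minimize(
                self._neg_loglike, start, method="BFGS",
                options={"maxiter": maxiter, "gtol": _GTOL})
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < 1e9 and np.linalg.norm(best.jac) < 1e-4:
                break
        if best.fun >= 1e9:
            raise ConvergenceError("likelihood never finite", best_result=best)
        theta = best.x
        hess = approx_hess(theta, self._neg_loglike)
        vcov = _safe_inverse(hess)
        return ParametricSurvivalResults(self, theta, vcov, -best.fun,
                                         converged=bool(best.fun < 1e9))


def _safe_inverse(hess):
    hess = 0.5 * (hess + hess.T)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(hess)
    vcov = 0.5 * (vcov + vcov.T)
    # clip tiny negative eigenvalues arising from finite differencing
    w, v = np.linalg.eigh(vcov)
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        vcov = (v * w) @ v.T
        vcov = 0.5 * (vcov + vcov.T)
    return vcov


@dataclass
class ParametricSurvivalResults:
    """Fitted transition hazard: family, MLE, vcov, log-likelihood."""

    model: ParametricSurvivalModel
    params: np.ndarray          # transformed scale: (family params, coefs)
    vcov: np.ndarray
    loglik: float
    converged: bool = True
    _jitter_used: float = field(default=0.0, init=False)

    @classmethod
    def from_params(cls, family, params, coefs=(), exog_names=None,
                    vcov=None, loglik=float("nan"), n_obs=0, n_events=0):
        """Results object from known parameters (no data attached).

        ``params`` are natural-scale family parameters; coefficients
        are on the log-linear scale.  Used for synthetic truths and
        for reloading exported fits.
        """
        fam = family if isinstance(family, Family) else get_family(family)
        with np.errstate(divide="ignore"):  # rate 0 -> log-rate -inf is valid
            theta = np.array([np.log(p) if lg else p
                              for p, lg in zip(params, fam.log_scale)], dtype=float)
        coefs = np.asarray(coefs, dtype=float)
        if exog_names is None:
            exog_names = tuple(COVARIATE_NAMES[: len(coefs)])
        full = np.concatenate([theta, coefs])
        if vcov is None:
            vcov = np.zeros((len(full), len(full)))
        dummy = ParametricSurvivalModel(
            [1.0], [1], np.zeros((1, len(exog_names))), exog_names, fam)
        dummy.n_obs, dummy.n_events = n_obs, n_events
        return cls(dummy, full, np.asarray(vcov, dtype=float), loglik)

    @classmethod
    def from_dict(cls, d):
        """Inverse of :meth:`to_dict` (stored params are transformed-scale)."""
        fam = get_family(d["family"])
        exog_names = tuple(n[len("beta_"):] for n in d["param_names"]
                           if n.startswith("beta_"))
        params = np.concatenate([np.asarray(d["params"], dtype=float),
                                 np.asarray(d["coefs"], dtype=float)])
        dummy = ParametricSurvivalModel(
            [1.0], [1], np.zeros((1, len(exog_names))), exog_names, fam)
        dummy.n_obs, dummy.n_events = d.get("n_obs", 0), d.get("n_events", 0)
        return cls(dummy, params, np.asarray(d["vcov"], dtype=float),
                   d.get("loglik", float("nan")))

    # structural accessors -------------------------------------------------

    @property
    def family(self) -> Family:
        return self.model.family

    @property
    def family_params(self):
        return self.params[: self.family.n_params]

    @property
    def coefs(self):
        return self.params[self.family.n_params:]

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_events(self) -> int:
        return self.model.n_events

    @property
    def bse(self):
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def conf_int(self, alpha=0.05):
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    @property
    def aic(self):
        return 2 * self.k_params - 2 * self.loglik

    @property
    def bic(self):
        return self.k_params * np.log(self.n_obs) - 2 * self.loglik

    # hazard / survival evaluation ----------------------------------------

    def _natural(self, covariates=None, params=None):
        theta = self.family_params if params is None else \
            np.asarray(params, dtype=float)[: self.family.n_params]
        beta = self.coefs if params is None else \
            np.asarray(params, dtype=float)[self.family.n_params:]
        linpred = 0.0
        if len(beta):
            x = _covariate_array(covariates, self.model.exog_names)
            linpred = float(x @ beta)
        return self.family.natural_params(theta, linpred)

    def hazard(self, t, covariates=None, params=None):
        """Hazard rate per year at time(s) ``t`` (years)."""
        nat = self._natural(covariates, params)
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be nonnegative")
        return self.family.hazard(np.maximum(t, 1e-300), nat)

    def cumhaz(self, t, covariates=None, params=None):
        nat = self._natural(covariates, params)
        t = np.asarray(t, dtype=float)
        out = np.where(t > 0, self.family.cumhaz(np.maximum(t, 1e-300), nat), 0.0)
        return out

    def survival(self, t, covariates=None, params=None):
        """S(t) = exp(-integral of the hazard); S(0) = 1."""
        return np.exp(-self.cumhaz(t, covariates, params))

    # reporting -------------------------------------------------------------

    def param_names(self):
        fam = self.family
        names = [f"{n}{'(log)' if lg else ''}"
                 for n, lg in zip(fam.param_names, fam.log_scale)]
        return names + [f"beta_{c}" for c in self.model.exog_names]

    def summary(self) -> str:
        lines = [
            f"Parametric survival fit: {self.family.name}",
            f"n_obs={self.n_obs}  n_events={self.n_events}  "
            f"loglik={self.loglik:.3f}  AIC={self.aic:.2f}  BIC={self.bic:.2f}",
            f"{'parameter':<16}{'estimate':>12}{'std err':>12}"
            f"{'[0.025':>12}{'0.975]':>12}",
        ]
        ci = self.conf_int()
        for name, est, se, (lo, hi) in zip(
                self.param_names(), self.params, self.bse, ci):
            lines.append(f"{name:<16}{est:>12.4f}{se:>12.4f}{lo:>12.4f}{hi:>12.4f}")
        return "\n".join(lines)

    def to_dict(self):
        return {
            "family": self.family.name,
            "params": self.family_params.tolist(),
            "coefs": self.coefs.tolist(),
            "param_names": self.param_names(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _covariate_array(covariates, names):
    """Accept dict / Series / array; center age; order canonically."""
    if covariates is None:
        return np.zeros(len(names))
    if isinstance(covariates, (dict, pd.Series)):
        x = np.array([float(covariates[n]) for n in names])
    else:
        x = np.asarray(covariates, dtype=float)
        if x.shape != (len(names),):
            raise ValueError("covariate vector has wrong length")
        return x  # assumed already centered
    if "age" in names:
        x[list(names).index("age")] -= AGE_REFERENCE
    return x


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def fit_mle(data: pd.DataFrame, family="exponential", covariate_mask=None,
            seed=0) -> ParametricSurvivalResults:
    """Fit one family to a time-to-event frame (time_years, status, covariates)."""
    model = ParametricSurvivalModel.from_dataframe(data, family, covariate_mask)
    return model.fit(seed=seed)


def information_criteria(fit: ParametricSurvivalResults):
    """(AIC, BIC) with k counting all free parameters including coefficients."""
    return fit.aic, fit.bic


def select_model(data: pd.DataFrame, families, covariate_mask=None, seed=0):
    """Fit each requested family; rank successes by AIC.

    Returns ``(ranked_fits, failures)`` where ``failures`` maps family
    name to the exception raised.  The final choice stays with the
    caller (visual fit of overall survival may override the criteria).
    """
    families = list(families)
    if not families:
        raise ValueError("families must be nonempty")
    fits, failures = [], {}
    for fam in families:
        try:
            fits.append(fit_mle(data, fam, covariate_mask, seed=seed))
        except Exception as exc:  # recorded, not fatal
            failures[fam if isinstance(fam, str) else fam.name] = exc
    if not fits:
        raise FitError(f"all families failed: { {k: str(v) for k, v in failures.items()} }")
    fits.sort(key=lambda f: f.aic)
    return fits, failures


def hazard_value(fit: ParametricSurvivalResults, covariates=None, t=0.0):
    """Transition intensity (per year) at time ``t`` for a covariate profile."""
    return fit.hazard(t, covariates)


def survival_value(fit: ParametricSurvivalResults, covariates=None, t=0.0):
    return fit.survival(t, covariates)
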