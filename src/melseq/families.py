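"""Parametric time-to-event families used for transition hazards.

Eight families are supported: exponential, Weibull, gamma, generalized
gamma (Prentice), generalized F (Prentice), log-logistic, log-normal and
Gompertz.  Each family exposes its log-density, log-survival, hazard and
cumulative hazard on the *natural* parameter scale, together with the
transform between the natural scale and the unconstrained scale used by
the optimizer (positive parameters are stored on the log scale).

Covariates act log-linearly on one "location" parameter per family: the
accelerated-failure-time location for the AFT families (Weibull, gamma,
generalized gamma, generalized F, log-logistic, log-normal) and the log
rate/level for the proportional-hazards families (exponential, Gompertz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special, stats

__all__ = ["Family", "get_family", "FAMILY_NAMES"]

_EPS_SHAPE = 1e-12  # treat |Q| or |b| below this as the limiting family


# ---------------------------------------------------------------------------
# log-density / log-survival per family, natural parameters, vectorized.
# Parameter entries may be scalars or arrays broadcastable against t.
# ---------------------------------------------------------------------------

def _exp_logpdf(t, p):
    rate = p[0]
    return np.log(rate) - rate * t


def _exp_logsf(t, p):
    return -p[0] * t


def _weibull_logpdf(t, p):
    shape, scale = p
    return stats.weibull_min.logpdf(t, shape, scale=scale)


def _weibull_logsf(t, p):
    shape, scale = p
    return -np.power(t / scale, shape)


def _gamma_logpdf(t, p):
    shape, rate = p
    return stats.gamma.logpdf(t, shape, scale=1.0 / rate)


def _gamma_logsf(t, p):
    shape, rate = p
    return stats.gamma.logsf(t, shape, scale=1.0 / rate)


def _lnorm_logpdf(t, p):
    mu, sigma = p
    return stats.lognorm.logpdf(t, sigma, scale=np.exp(mu))


def _lnorm_logsf(t, p):
    mu, sigma = p
    return stats.lognorm.logsf(t, sigma, scale=np.exp(mu))


def _llogis_logpdf(t, p):
    shape, scale = p
    return stats.fisk.logpdf(t, shape, scale=scale)


def _llogis_logsf(t, p):
    shape, scale = p
    # S(t) = 1 / (1 + (t/scale)^shape)
    z = shape * (np.log(t) - np.log(scale))
    return -np.logaddexp(0.0, z)


def _gompertz_cumhaz(t, p):
    b, a = p  # shape (real), level (>0); h(t) = a * exp(b t)
    t = np.asarray(t, dtype=float)
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    bt = b * t
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(np.abs(b) < _EPS_SHAPE, a * t, a * np.expm1(bt) / np.where(b == 0, 1.0, b))
    return h


def _gompertz_logpdf(t, p):
    b, a = p
    return np.log(a) + b * np.asarray(t, dtype=float) - _gompertz_cumhaz(t, p)


def _gompertz_logsf(t, p):
    return -_gompertz_cumhaz(t, p)


def _gengamma_logpdf(t, p):
    """Prentice generalized gamma: location mu, scale sigma>0, shape Q (real)."""
    mu, sigma, Q = (np.asarray(v, dtype=float) for v in p)
    t = np.asarray(t, dtype=float)
    w = (np.log(t) - mu) / sigma
    lognorm_branch = (
        -0.5 * np.log(2 * np.pi) - np.log(sigma) - np.log(t) - 0.5 * w**2
    )
    Qs = np.where(np.abs(Q) < _EPS_SHAPE, 1.0, Q)  # placeholder to avoid /0
    q2 = Qs**-2
    qw = Qs * w
    with np.errstate(over="ignore"):
        gamma_branch = (
            np.log(np.abs(Qs))
            - np.log(sigma)
            - np.log(t)
            + q2 * np.log(q2)
            - special.gammaln(q2)
            + q2 * (qw - np.exp(qw))
        )
    return np.where(np.abs(Q) < _EPS_SHAPE, lognorm_branch, gamma_branch)


def _gengamma_logsf(t, p):
    mu, sigma, Q = (np.asarray(v, dtype=float) for v in p)
    t = np.asarray(t, dtype=float)
    w = (np.log(t) - mu) / sigma
    lognorm_branch = stats.norm.logsf(w)
    Qs = np.where(np.abs(Q) < _EPS_SHAPE, 1.0, Q)
    q2 = Qs**-2
    with np.errstate(over="ignore"):
        u = q2 * np.exp(Qs * w)
    upper = special.gammaincc(np.broadcast_to(q2, u.shape), u)  # P(Gamma(q2) > u)
    lower = special.gammainc(np.broadcast_to(q2, u.shape), u)
    sf = np.where(Qs > 0, upper, lower)
    with np.errstate(divide="ignore"):
        gamma_branch = np.log(sf)
    return np.where(np.abs(Q) < _EPS_SHAPE, lognorm_branch, gamma_branch)


def _genf_s1s2(Q, P):
    d2 = Q * Q + 2.0 * P
    delta = np.sqrt(d2)
    s1 = 2.0 / (d2 + Q * delta)
    s2 = 2.0 / (d2 - Q * delta)
    return delta, s1, s2


def _genf_logpdf(t, p):
    """Prentice generalized F: mu, sigma>0, shape Q (real), shape P>0."""
    mu, sigma, Q, P = (np.asarray(v, dtype=float) for v in p)
    t = np.asarray(t, dtype=float)
    w = (np.log(t) - mu) / sigma
    delta, s1, s2 = _genf_s1s2(Q, P)
    dw = delta * w
    # log f = log d + s1*dw + s1*log(s1/s2) - log(sigma t)
    #         - (s1+s2)*log1p(s1 e^{dw}/s2) - lbeta(s1, s2)
    log_ratio_term = np.logaddexp(0.0, np.log(s1) - np.log(s2) + dw)
    return (
        np.log(delta)
        + s1 * dw
        + s1 * (np.log(s1) - np.log(s2))
        - np.log(sigma)
        - np.log(t)
        - (s1 + s2) * log_ratio_term
        - special.betaln(s1, s2)
    )


def _genf_logsf(t, p):
    mu, sigma, Q, P = (np.asarray(v, dtype=float) for v in p)
    t = np.asarray(t, dtype=float)
    w = (np.log(t) - mu) / sigma
    delta, s1, s2 = _genf_s1s2(Q, P)
    dw = delta * w
    # U = s1 e^{dw} / (s2 + s1 e^{dw}) ~ Beta(s1, s2);  S = I_{1-U}(s2, s1)
    log_den = np.logaddexp(np.log(s2), np.log(s1) + dw)
    one_minus_u = np.exp(np.log(s2) - log_den)
    shape = np.broadcast_shapes(np.shape(one_minus_u), np.shape(s1))
    sf = special.betainc(
        np.broadcast_to(s2, shape), np.broadcast_to(s1, shape),
        np.broadcast_to(one_minus_u, shape),
    )
    with np.errstate(divide="ignore"):
        return np.log(sf)


# ---------------------------------------------------------------------------
# Family descriptor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Family:
    """One parametric time-to-event family.

    ``param_names`` are natural-scale names; ``log_scale`` flags which of
    them are stored on the log scale in the unconstrained vector.
    ``location_index`` is the natural parameter shifted (on its stored
    scale) by the linear predictor x'beta; ``link`` records whether that
    shift is an AFT time-scale shift or a proportional-hazards log-rate
    shift (the sign convention of the shift differs, see
    :meth:`natural_params`).
    """

    name: str
    param_names: tuple[str, ...]
    log_scale: tuple[bool, ...]
    location_index: int
    link: str  # "aft" or "ph"
    _logpdf: Callable
    _logsf: Callable

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_shape_params(self) -> int:
        return self.n_params - 1

    def natural_params(self, theta, linpred=0.0):
        """Map unconstrained parameters + linear predictor to natural scale.

        AFT families: the location acts multiplicatively on time, so the
        stored (log) location gains ``+linpred`` (longer times for positive
        coefficients).  PH families: the stored log rate gains ``+linpred``
        (higher hazard for positive coefficients).
        """
        theta = np.asarray(theta, dtype=float)
        out = []
        for i in range(self.n_params):
            v = theta[i]
            if i == self.location_index:
                # aft: shift of the (log) time scale; ph: shift of the log rate
                v = v + linpred
            with np.errstate(over="ignore"):
                out.append(np.exp(v) if self.log_scale[i] else v)
        # gamma's AFT location is the log *inverse* rate: handled in transform
        return out

    def logpdf(self, t, natural):
        return self._logpdf(np.asarray(t, dtype=float), natural)

    def logsf(self, t, natural):
        return self._logsf(np.asarray(t, dtype=float), natural)

    def cumhaz(self, t, natural):
        return -self.logsf(t, natural)

    def hazard(self, t, natural):
        with np.errstate(over="ignore"):
            return np.exp(self.logpdf(t, natural) - self.logsf(t, natural))


def _gamma_natural_wrapper(fn):
    # gamma is parameterized (shape, rate) but AFT acts on log(1/rate):
    # store theta = (log shape, log inverse-rate); natural rate = exp(-(theta1+xb))
    def wrapped(t, p):
        shape, inv_rate = p
        return fn(t, (shape, 1.0 / inv_rate))
    return wrapped


_REGISTRY: dict[str, Family] = {}


def _register(fam: Family):
    _REGISTRY[fam.name] = fam


_register(Family("exponential", ("rate",), (True,), 0, "ph",
                 _exp_logpdf, _exp_logsf))
_register(Family("weibull", ("shape", "scale"), (True, True), 1, "aft",
                 _weibull_logpdf, _weibull_logsf))
_register(Family("gamma", ("shape", "inv_rate"), (True, True), 1, "aft",
                 _gamma_natural_wrapper(_gamma_logpdf),
                 _gamma_natural_wrapper(_gamma_logsf)))
_register(Family("generalized_gamma", ("mu", "sigma", "Q"),
                 (False, True, False), 0, "aft",
                 _gengamma_logpdf, _gengamma_logsf))
_register(Family("generalized_f", ("mu", "sigma", "Q", "P"),
                 (False, True, False, True), 0, "aft",
                 _genf_logpdf, _genf_logsf))
_register(Family("log_logistic", ("shape", "scale"), (True, True), 1, "aft",
                 _llogis_logpdf, _llogis_logsf))
_register(Family("log_normal", ("mu", "sigma"), (False, True), 0, "aft",
                 _lnorm_logpdf, _lnorm_logsf))
_register(Family("gompertz", ("shape", "level"), (False, True), 1, "ph",
                 _gompertz_logpdf, _gompertz_logsf))

FAMILY_NAMES = tuple(_REGISTRY)


def get_family(name: str) -> Family:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; choose from {FAMILY_NAMES}"
        ) from None
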