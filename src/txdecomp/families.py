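"""Observation families for the decomposition model.

Counts in sparse genomic bins are zero-heavy: heterochromatic or poorly
mappable regions yield structural zeros beyond what a negative binomial
produces.  Two zero-augmented NB families are provided:

* ``hurdle`` (default): an explicit zero mass ``p`` and a zero-truncated
  NB(mu, k) on the positive counts with probability ``1 - p``.  Zeros carry
  no information about the latent log-rate, so the zero mass separates from
  the field in the likelihood.
* ``zinb``: the mixture form, ``p + (1-p) NB(0; mu, k)`` at zero; zeros then
  do inform the latent field.

A ``gaussian`` family (identity link, known precision) exists for validation
against the exact sparse linear-Gaussian solve.

All families expose the per-observation log-likelihood and its first and
second derivatives with respect to the linear predictor
``eta = log mu = nu + log E`` (or the mean itself for the Gaussian).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["hurdle_nb_loglik", "zinb_loglik", "get_family", "Hurdle", "ZINB", "Gaussian"]


def _nb_logpmf(y, mu, k):
    """log NB(y; mu, k) in the mean/size parameterisation."""
    mu = np.asarray(mu, dtype=float)
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1.0)
        + k * (np.log(k) - np.log(k + mu))
        + y * (np.log(mu) - np.log(k + mu))
    )


def _nb_logp0(mu, k):
    """log NB(0; mu, k) = k log(k/(k+mu))."""
    return k * (np.log(k) - np.log(k + np.asarray(mu, dtype=float)))


def hurdle_nb_loglik(y, p, mu, k):
    """Log-probability under the hurdle negative binomial.

    ``P(Y=0) = p``; for y >= 1, ``P(Y=y) = (1-p) NB(y; mu, k) / (1 - NB(0; mu, k))``.
    """
    y = np.asarray(y)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if np.any(np.asarray(mu) <= 0) or k <= 0:
        raise ValueError("mu and k must be positive")
    with np.errstate(divide="ignore"):
        out = np.where(
            y == 0,
            np.log(np.asarray(p, dtype=float)),
            np.log1p(-np.asarray(p, dtype=float))
            + _nb_logpmf(np.maximum(y, 1), mu, k)
            - np.log1p(-np.exp(_nb_logp0(mu, k))),
        )
    return out if out.shape else float(out)


def zinb_loglik(y, p, mu, k):
    """Log-probability under the mixture zero-inflated negative binomial."""
    y = np.asarray(y)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if np.any(np.asarray(mu) <= 0) or k <= 0:
        raise ValueError("mu and k must be positive")
    q0 = np.exp(_nb_logp0(mu, k))
    with np.errstate(divide="ignore"):
        out = np.where(
            y == 0,
            np.log(p + (1.0 - p) * q0),
            np.log1p(-np.asarray(p, dtype=float)) + _nb_logpmf(np.maximum(y, 1), mu, k),
        )
    return out if out.shape else float(out)


def _safe_mu(eta):
    # keep exp(eta) strictly positive and finite under extreme trial steps
    return np.exp(np.clip(eta, -500.0, 500.0))


class Hurdle:
    """Hurdle NB family; derivatives are with respect to eta = log mu."""

    name = "hurdle"
    n_shape_params = 1  # k; the zero mass has a closed-form estimate

    @staticmethod
    def loglik(y, eta, p, k):
        return hurdle_nb_loglik(y, p, _safe_mu(eta), k)

    @staticmethod
    def derivatives(y, eta, p, k):
        """Return (g, h): d/deta and d^2/deta^2 of the log-likelihood.

        Zeros contribute constants only.  For y >= 1 with mu = e^eta,
        q0 = (k/(k+mu))^k and t = k mu/(k+mu):
            g = y - (y+k) mu/(mu+k) - t q0/(1-q0)
            h = -(y+k) t/(mu+k)  + q0 t^2/(1-q0)^2 - q0 t'/(1-q0) ... (see code)
        """
        y = np.asarray(y, dtype=float)
        mu = _safe_mu(eta)
        pos = y > 0
        g = np.zeros_like(mu)
        h = np.zeros_like(mu)
        if np.any(pos):
            yp = y[pos]
            m = mu[pos]
            frac = m / (m + k)
            q0 = np.exp(k * (np.log(k) - np.log(k + m)))
            t = k * frac  # k mu / (k + mu)
            om = 1.0 - q0
            g[pos] = yp - (yp + k) * frac - t * q0 / om
            tprime = t * k / (k + m)  # d t / d eta
            # d/deta [ -t q0 / (1-q0) ]  with  dq0/deta = -q0 t
            trunc_h = q0 * t * t / om**2 - q0 * tprime / om
            h[pos] = -(yp + k) * k * frac / (m + k) + trunc_h
        return g, h


class ZINB:
    """Mixture ZINB family; derivatives with respect to eta = log mu."""

    name = "zinb"
    n_shape_params = 2  # k and the zero-inflation probability

    @staticmethod
    def loglik(y, eta, p, k):
        return zinb_loglik(y, p, _safe_mu(eta), k)

    @staticmethod
    def derivatives(y, eta, p, k):
        y = np.asarray(y, dtype=float)
        mu = _safe_mu(eta)
        frac = mu / (mu + k)
        t = k * frac
        g = np.empty_like(mu)
        h = np.empty_like(mu)
        pos = y > 0
        # positive counts: plain NB score/curvature
        yp = y[pos]
        g[pos] = yp - (yp + k) * frac[pos]
        h[pos] = -(yp + k) * k * frac[pos] / (mu[pos] + k)
        # zeros: d/deta log(p + (1-p) q0)
        z = ~pos
        if np.any(z):
            q0 = np.exp(k * (np.log(k) - np.log(k + mu[z])))
            denom = p + (1.0 - p) * q0
            w = (1.0 - p) * q0 / denom  # weight of the NB-zero branch
            tz = t[z]
            g[z] = -w * tz
            tprime = tz * k / (k + mu[z])
            # d/deta [-w t] ; dw/deta = -w (1-w) t
            h[z] = w * (1.0 - w) * tz * tz - w * tprime
        return g, h


class Gaussian:
    """Gaussian observations with known precision tau_obs; eta is the mean."""

    name = "gaussian"
    n_shape_params = 0

    def __init__(self, tau_obs: float = 1.0):
        if tau_obs <= 0:
            raise ValueError("tau_obs must be positive")
        self.tau_obs = float(tau_obs)

    def loglik(self, y, eta, p=None, k=None):
        r = np.asarray(y, dtype=float) - eta
        return 0.5 * np.log(self.tau_obs / (2 * np.pi)) - 0.5 * self.tau_obs * r * r

    def derivatives(self, y, eta, p=None, k=None):
        g = self.tau_obs * (np.asarray(y, dtype=float) - eta)
        h = np.full_like(g, -self.tau_obs)
        return g, h


def get_family(name, **kwargs):
    if isinstance(name, (Hurdle, ZINB, Gaussian)):
        return name
    table = {"hurdle": Hurdle, "zinb": ZINB, "gaussian": Gaussian}
    try:
        cls = table[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; expected one of {sorted(table)}")
    return cls(**kwargs) if cls is Gaussian else cls()
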