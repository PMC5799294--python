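"""Transcriptional decomposition of binned expression counts.

The model splits the expected log expression of genomic bin ``i`` into an
intercept, a positionally dependent (PD) and a positionally independent (PI)
component::

    nu_i = alpha + PD_i + PI_i,        mu_ir = E_r * exp(nu_i)

with replicate library depths ``E_r`` entering as offsets.  The PD component
is a first-order random walk (consecutive differences ``N(0, 1/tau_rw)``),
capturing expression shared between neighbouring bins -- the signature of
chromatin-neighbourhood organisation.  The PI component is iid Gaussian with
precision ``tau_iid``, capturing bin-local regulation.  Counts follow a
hurdle (default) or mixture zero-inflated negative binomial; a Gaussian
family is available for validation.

Inference is Laplace-approximate maximum a posteriori over the latent field
(damped Newton iterations on the sparse posterior precision) with
empirical-Bayes optimisation of the Laplace marginal likelihood over the
hyperparameters.  The RW1 structure is scaled to unit average generalised-
inverse variance so ``1/tau_rw`` is the average marginal prior variance, and
the intrinsic level is fixed by a per-chromosome sum-to-zero constraint on
PD (the intercept absorbs the mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize
from scipy.stats import norm, pearsonr

from .families import Gaussian, get_family
from .rw1 import rw1_structure
from .stats import bh_adjust

__all__ = [
    "DecompositionModel",
    "DecompositionResults",
    "PriorSpec",
    "fit_joint",
    "grid_select_hyperparameters",
    "component_fraction",
    "differential_components",
]


@dataclass
class PriorSpec:
    """Hyperpriors for the empirical-Bayes objective.

    Log-gamma priors (shape, rate) on the precisions tau_rw and tau_iid,
    a gamma prior on the NB size k and a Gaussian prior on the logit zero
    probability.  Defaults are weakly informative.
    """

    tau_shape: float = 1.0
    tau_rate: float = 5e-5
    k_shape: float = 1.0
    k_rate: float = 0.01
    logit_p_mean: float = 0.0
    logit_p_prec: float = 0.001
    alpha_prec: float = 1e-6

    def log_tau(self, log_tau: float) -> float:
        # log-gamma density over theta = log tau (up to a constant)
        return self.tau_shape * log_tau - self.tau_rate * np.exp(log_tau)

    def log_k(self, log_k: float) -> float:
        return self.k_shape * log_k - self.k_rate * np.exp(log_k)

    def log_p(self, logit_p: float) -> float:
        return -0.5 * self.logit_p_prec * (logit_p - self.logit_p_mean) ** 2


@dataclass
class _FitState:
    x: np.ndarray
    lu: object
    obj: float
    loglik: float
    n_iter: int
    converged: bool


class DecompositionModel:
    """Latent Gaussian decomposition of one chromosome for one cell type.

    Parameters
    ----------
    counts : ndarray (n_bins, n_reps)
        Replicate tag counts per bin (real-valued observations for the
        Gaussian family).
    depths : ndarray (n_reps,), optional
        Library depths E_r; offsets are log(E_r).  Defaults to the column
        sums of ``counts``.  Ignored by the Gaussian family.
    family : {"hurdle", "zinb", "gaussian"} or family instance
    priors : PriorSpec, optional
    """

    def __init__(self, counts, depths=None, family="hurdle", priors=None, tau_obs=1.0):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim == 1:
            counts = counts[:, None]
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 bins")
        self.family = get_family(family, **({"tau_obs": tau_obs} if family == "gaussian" else {}))
        self._gaussian = isinstance(self.family, Gaussian)
        if not self._gaussian:
            if np.any(counts < 0) or np.any(counts != np.round(counts)):
                raise ValueError("count families require non-negative integer counts")
            if counts.sum() == 0:
                raise ValueError("all-zero chromosome cannot be decomposed")
        self.endog = counts
        self.n_bins, self.n_reps = counts.shape
        if depths is None:
            depths = counts.sum(axis=0) if not self._gaussian else np.ones(self.n_reps)
        depths = np.asarray(depths, dtype=float)
        if depths.shape != (self.n_reps,):
            raise ValueError("depths must have one entry per replicate")
        if not self._gaussian and np.any(depths <= 0):
            raise ValueError("library depths must be positive")
        self.depths = depths
        self.offset = np.log(depths) if not self._gaussian else np.zeros(self.n_reps)
        self.priors = priors if priors is not None else PriorSpec()
        n = self.n_bins
        self.S, self.rw1_scale = rw1_structure(n)
        self._I = sp.identity(n, format="csc")
        # constraint vector: sum of PD block is zero
        a = np.zeros(2 * n + 1)
        a[:n] = 1.0
        self._a = a

    @classmethod
    def from_count_matrix(cls, count_matrix, chrom, cell_type=None, **kwargs):
        """Build a model from a :class:`~txdecomp.binning.CountMatrix`."""
        Y = count_matrix.chromosome_counts(chrom, cell_type=cell_type)
        E = count_matrix.depths_for(cell_type)
        return cls(Y, depths=E, **kwargs)

    # ---- likelihood plumbing -------------------------------------------

    def _nu(self, x):
        n = self.n_bins
        return x[:n] + x[n : 2 * n] + x[2 * n]

    def _loglik(self, nu, p, k):
        eta = nu[:, None] + self.offset[None, :]
        return float(np.sum(self.family.loglik(self.endog, eta, p, k)))

    def _score_curvature(self, nu, p, k):
        """Per-bin sums over replicates of dl/dnu and d2l/dnu2."""
        eta = nu[:, None] + self.offset[None, :]
        g, h = self.family.derivatives(self.endog, eta, p, k)
        return g.sum(axis=1), h.sum(axis=1)

    def _prior_precision(self, tau_rw, tau_iid):
        n = self.n_bins
        Qpd = tau_rw * self.S
        Qpi = tau_iid * self._I
        return Qpd, Qpi

    def _assemble(self, Qpd, Qpi, W, ridge):
        """Posterior precision over x = [PD, PI, alpha]."""
        n = self.n_bins
        Wd = sp.diags(W)
        w = W[:, None]
        Q = sp.bmat(
            [
                [Qpd + Wd, Wd, sp.csc_matrix(w)],
                [Wd, Qpi + Wd, sp.csc_matrix(w)],
                [sp.csc_matrix(w.T), sp.csc_matrix(w.T), sp.csc_matrix([[W.sum() + self.priors.alpha_prec]])],
            ],
            format="csc",
        )
        if ridge:
            Q = Q + ridge * sp.identity(2 * n + 1, format="csc")
        return Q

    def _penalised(self, x, Qpd, Qpi, p, k):
        n = self.n_bins
        pd_, pi_, al = x[:n], x[n : 2 * n], x[2 * n]
        ll = self._loglik(self._nu(x), p, k)
        pen = 0.5 * (pd_ @ (Qpd @ pd_) + pi_ @ (Qpi @ pi_) + self.priors.alpha_prec * al * al)
        return ll - pen, ll

    def _newton(self, tau_rw, tau_iid, p, k, x0=None, ridge_stages=(1.0, 0.0), maxiter=100, tol=1e-10):
        """Damped Newton ascent of the penalised log-likelihood.

        A first pass with a unit ridge on the latent precision stabilises
        early steps; the converged state seeds a second, unridged pass.
        The sum-to-zero constraint on PD is enforced exactly at every step.
        """
        n = self.n_bins
        m = 2 * n + 1
        Qpd, Qpi = self._prior_precision(tau_rw, tau_iid)
        x = np.zeros(m) if x0 is None else x0.copy()
        # feasible start
        x[:n] -= x[:n].mean()
        a = self._a
        lu = None
        obj, ll = self._penalised(x, Qpd, Qpi, p, k)
        total_iter = 0
        converged = False
        for ridge in ridge_stages:
            for _ in range(maxiter):
                g, h = self._score_curvature(self._nu(x), p, k)
                W = np.maximum(-h, 1e-12)
                grad = np.concatenate([g, g, [g.sum()]])
                grad[:n] -= Qpd @ x[:n]
                grad[n : 2 * n] -= Qpi @ x[n : 2 * n]
                grad[2 * n] -= self.priors.alpha_prec * x[2 * n]
                Q = self._assemble(Qpd, Qpi, W, ridge)
                lu = spla.splu(Q)
                step = lu.solve(grad)
                v = lu.solve(a)
                # constrained Newton target: a @ (x + step_c) = 0
                trial = x + step
                trial -= v * (a @ trial) / (a @ v)
                step_c = trial - x
                # damped line search on the penalised objective
                lam = 1.0
                new_obj = None
                for _ in range(30):
                    cand = x + lam * step_c
                    new_obj, new_ll = self._penalised(cand, Qpd, Qpi, p, k)
                    if np.isfinite(new_obj) and new_obj >= obj - 1e-12:
                        break
                    lam *= 0.5
                total_iter += 1
                delta = abs(new_obj - obj) / (abs(obj) + 1.0)
                x = cand
                obj, ll = new_obj, new_ll
                if delta < tol:
                    converged = True
                    break
            else:
                converged = False
        # final factorisation at the mode without ridge, for logdet / SDs
        g, h = self._score_curvature(self._nu(x), p, k)
        W = np.maximum(-h, 1e-12)
        Q = self._assemble(Qpd, Qpi, W, 0.0)
        lu = spla.splu(Q)
        return _FitState(x=x, lu=lu, obj=obj, loglik=ll, n_iter=total_iter, converged=converged)

    # ---- marginal likelihood -------------------------------------------

    def _log_marginal(self, tau_rw, tau_iid, p, k, state):
        """Laplace approximation to log p(y | theta), up to theta-free constants."""
        n = self.n_bins
        # generalised log-determinant of the prior precision (constants dropped)
        logdet_prior = (n - 1) * np.log(tau_rw) + n * np.log(tau_iid)
        U = state.lu.U.diagonal()
        logdet_post = float(np.sum(np.log(np.abs(U))))
        return state.obj + 0.5 * logdet_prior - 0.5 * logdet_post

    def _hurdle_p_hat(self):
        y = self.endog
        return float(np.mean(y == 0))

    # ---- public fitting API --------------------------------------------

    def fit(
        self,
        tau_rw=None,
        tau_iid=None,
        k=None,
        p0=None,
        start_params=None,
        maxiter=100,
        optimizer="L-BFGS-B",
        compute_sd=True,
    ):
        """Fit the decomposition; free hyperparameters are optimised.

        Any of ``tau_rw``, ``tau_iid``, ``k`` (count families) left ``None``
        is estimated by maximising the Laplace marginal likelihood plus the
        hyperpriors.  For the hurdle family the zero probability has a
        closed-form estimate (the observed zero fraction); for the ZINB
        mixture it is optimised unless ``p0`` is given.
        """
        pri = self.priors
        fixed = {"tau_rw": tau_rw, "tau_iid": tau_iid, "k": k, "p0": p0}
        if self._gaussian:
            fixed["k"] = 1.0
            fixed["p0"] = 0.0
        elif self.family.name == "hurdle" and p0 is None:
            fixed["p0"] = self._hurdle_p_hat()

        free = [name for name in ("tau_rw", "tau_iid", "k", "p0") if fixed[name] is None]
        start = {"tau_rw": 10.0, "tau_iid": 10.0, "k": 2.0, "p0": max(self._endog_zero_frac(), 0.01)}
        if start_params:
            start.update(start_params)

        warm = {"x": None}

        def unpack(theta):
            vals = dict(fixed)
            for name, t in zip(free, theta):
                if name == "p0":
                    vals[name] = 1.0 / (1.0 + np.exp(-t))
                else:
                    vals[name] = np.exp(t)
            return vals

        def neg_ml(theta):
            vals = unpack(theta)
            state = self._newton(
                vals["tau_rw"], vals["tau_iid"], vals["p0"], vals["k"], x0=warm["x"], maxiter=maxiter
            )
            warm["x"] = state.x
            ml = self._log_marginal(vals["tau_rw"], vals["tau_iid"], vals["p0"], vals["k"], state)
            ml += pri.log_tau(np.log(vals["tau_rw"])) + pri.log_tau(np.log(vals["tau_iid"]))
            if not self._gaussian:
                ml += pri.log_k(np.log(vals["k"]))
            if "p0" in free:
                q = vals["p0"]
                ml += pri.log_p(np.log(q / (1 - q)))
            return -ml

        opt_info = None
        if free:
            theta0 = []
            bounds = []
            for name in free:
                if name == "p0":
                    q = start[name]
                    theta0.append(np.log(q / (1 - q)))
                    bounds.append((-8.0, 8.0))
                elif name == "k":
                    theta0.append(np.log(start[name]))
                    bounds.append((-4.0, 10.0))
                else:
                    theta0.append(np.log(start[name]))
                    bounds.append((-12.0, 14.0))
            # FD step must sit well above the inner-Newton noise floor
            options = {"maxiter": 200}
            if optimizer == "L-BFGS-B":
                options.update({"eps": 1e-4, "ftol": 1e-10, "gtol": 1e-4})
            res = minimize(
                neg_ml,
                np.asarray(theta0),
                method=optimizer,
                bounds=bounds if optimizer in ("L-BFGS-B", "Powell") else None,
                options=options,
            )
            vals = unpack(res.x)
            opt_info = res
        else:
            vals = dict(fixed)

        state = self._newton(vals["tau_rw"], vals["tau_iid"], vals["p0"], vals["k"], x0=warm["x"], maxiter=maxiter)
        log_ml = self._log_marginal(vals["tau_rw"], vals["tau_iid"], vals["p0"], vals["k"], state)

        n = self.n_bins
        if compute_sd:
            sd = self._posterior_sd(state)
        else:
            sd = np.full(2 * n + 1, np.nan)
        x = state.x
        return DecompositionResults(
            model=self,
            alpha=float(x[2 * n]),
            alpha_sd=float(sd[2 * n]),
            pd=x[:n].copy(),
            pd_sd=sd[:n].copy(),
            pi=x[n : 2 * n].copy(),
            pi_sd=sd[n : 2 * n].copy(),
            tau_rw=float(vals["tau_rw"]),
            tau_iid=float(vals["tau_iid"]),
            k=float(vals["k"]),
            p0=float(vals["p0"]),
            log_marginal=float(log_ml),
            n_iter=state.n_iter,
            converged=bool(state.converged and (opt_info is None or opt_info.success)),
            estimated_hyperparameters=tuple(free),
        )

    def _endog_zero_frac(self):
        return float(np.mean(self.endog == 0)) if not self._gaussian else 0.0

    def _posterior_sd(self, state, chunk=512):
        """Marginal posterior SDs: diagonal of the constrained inverse precision.

        diag(Sigma_c) = diag(Q^-1) - (Q^-1 a)^2 / (a' Q^-1 a), computed by
        chunked column solves to bound memory.
        """
        m = 2 * self.n_bins + 1
        diag = np.empty(m)
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            rhs = np.zeros((m, hi - lo))
            rhs[np.arange(lo, hi), np.arange(hi - lo)] = 1.0
            sol = state.lu.solve(rhs)
            diag[lo:hi] = sol[np.arange(lo, hi), np.arange(hi - lo)]
        v = state.lu.solve(self._a)
        var = diag - v * v / (self._a @ v)
        return np.sqrt(np.maximum(var, 0.0))


@dataclass
class DecompositionResults:
    """Posterior summaries of a fitted transcriptional decomposition."""

    model: DecompositionModel = field(repr=False)
    alpha: float
    alpha_sd: float
    pd: np.ndarray
    pd_sd: np.ndarray
    pi: np.ndarray
    pi_sd: np.ndarray
    tau_rw: float
    tau_iid: float
    k: float
    p0: float
    log_marginal: float
    n_iter: int
    converged: bool
    estimated_hyperparameters: tuple = ()

    @property
    def nu(self):
        """Fitted linear predictor per bin (before the depth offset)."""
        return self.alpha + self.pd + self.pi

    @property
    def n_bins(self):
        return self.pd.shape[0]

    def to_frame(self, grid=None, chrom=None):
        """Per-bin component table; includes coordinates when a grid is given."""
        df = pd.DataFrame(
            {
                "pd_mean": self.pd,
                "pd_sd": self.pd_sd,
                "pi_mean": self.pi,
                "pi_sd": self.pi_sd,
            }
        )
        df.insert(0, "alpha", self.alpha)
        if grid is not None and chrom is not None:
            starts = grid.bin_starts(chrom)
            df.insert(0, "chrom", chrom)
            df.insert(1, "start", starts)
            df.insert(2, "end", starts + grid.width - 1)
        return df

    def summary(self):
        """Human-readable fit summary."""
        lines = [
            "Transcriptional decomposition results",
            "=" * 46,
            f"family:          {self.model.family.name}",
            f"bins:            {self.n_bins}",
            f"replicates:      {self.model.n_reps}",
            f"converged:       {self.converged} ({self.n_iter} Newton steps)",
            f"log marginal:    {self.log_marginal:.3f}",
            "-" * 46,
            f"alpha:           {self.alpha:.4f} (sd {self.alpha_sd:.4f})",
            f"tau_rw:          {self.tau_rw:.4g}" + self._est_flag("tau_rw"),
            f"tau_iid:         {self.tau_iid:.4g}" + self._est_flag("tau_iid"),
        ]
        if self.model.family.name != "gaussian":
            lines.append(f"k (NB size):     {self.k:.4g}" + self._est_flag("k"))
            lines.append(f"p0 (zero mass):  {self.p0:.4f}")
        lines.append("-" * 46)
        lines.append(
            f"PD: mean {self.pd.mean():+.4f}, sd {self.pd.std():.4f}; "
            f"PI: mean {self.pi.mean():+.4f}, sd {self.pi.std():.4f}"
        )
        return "\n".join(lines)

    def _est_flag(self, name):
        return "  [estimated]" if name in self.estimated_hyperparameters else "  [fixed]"


def fit_joint(count_matrices, depths=None, family="hurdle", priors=None, fix=None, **fit_kwargs):
    """Fit several cell types jointly with shared hyperparameters.

    The Laplace marginal likelihoods of the per-cell models are summed and
    maximised over one common set of hyperparameters; latent fields stay
    independent per cell type.  ``fix`` may pin any of tau_rw / tau_iid / k
    to reference values (used when decomposing large panels against
    reference estimates).

    Returns a list of :class:`DecompositionResults`, one per cell type.
    """
    fix = dict(fix or {})
    if depths is None:
        depths = [None] * len(count_matrices)
    models = [
        DecompositionModel(Y, depths=E, family=family, priors=priors)
        for Y, E in zip(count_matrices, depths)
    ]
    if len({m.n_bins for m in models}) != 1:
        raise ValueError("all cell types must share the same bin grid")
    if not models:
        raise ValueError("no cell types supplied")

    free = [name for name in ("tau_rw", "tau_iid", "k") if name not in fix]
    if models[0]._gaussian:
        free = [f for f in free if f != "k"]
    if not free:
        return [m.fit(**fix, **fit_kwargs) for m in models]

    pri = models[0].priors
    p_hats = [
        m._hurdle_p_hat() if (not m._gaussian and m.family.name == "hurdle") else 0.0 for m in models
    ]
    warm = [None] * len(models)

    def unpack(theta):
        vals = dict(fix)
        for name, t in zip(free, theta):
            vals[name] = np.exp(t)
        vals.setdefault("k", 1.0)
        return vals

    def neg_ml(theta):
        vals = unpack(theta)
        total = 0.0
        for j, m in enumerate(models):
            state = m._newton(vals["tau_rw"], vals["tau_iid"], p_hats[j], vals["k"], x0=warm[j])
            warm[j] = state.x
            total += m._log_marginal(vals["tau_rw"], vals["tau_iid"], p_hats[j], vals["k"], state)
        total += pri.log_tau(np.log(vals["tau_rw"])) + pri.log_tau(np.log(vals["tau_iid"]))
        if "k" in free:
            total += pri.log_k(np.log(vals["k"]))
        return -total

    theta0 = np.log([{"tau_rw": 10.0, "tau_iid": 10.0, "k": 2.0}[f] for f in free])
    bounds = [(-4.0, 10.0) if f == "k" else (-12.0, 14.0) for f in free]
    res = minimize(
        neg_ml,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200, "eps": 1e-4, "ftol": 1e-10, "gtol": 1e-4},
    )
    vals = unpack(res.x)
    return [
        m.fit(tau_rw=vals["tau_rw"], tau_iid=vals["tau_iid"], k=(None if m._gaussian else vals["k"]), **fit_kwargs)
        for m in models
    ]


def grid_select_hyperparameters(
    counts,
    reference_pd,
    mask,
    base_tau_rw,
    base_tau_iid,
    depths=None,
    offsets=range(-3, 4),
    family="hurdle",
    **fit_kwargs,
):
    """Select (tau_rw, tau_iid) for a chromosome by matching a reference PD track.

    Every combination of multiplicative log-scale offsets (default -3..+3
    around each base value, 49 candidates) is fitted with fixed
    hyperparameters; the pair whose PD component correlates most strongly
    (Pearson) with ``reference_pd`` over the ``mask`` bins wins.  Typical
    use: transferring CAGE-estimated hyperparameters to RNA-seq counts,
    masking bins not near any transcription unit.

    Returns ``(tau_rw, tau_iid, table)`` with the full candidate table.
    """
    mask = np.asarray(mask, dtype=bool)
    reference_pd = np.asarray(reference_pd, dtype=float)
    if mask.sum() == 0:
        raise ValueError("mask excludes every bin")
    model = DecompositionModel(counts, depths=depths, family=family)
    rows = []
    best = (-np.inf, None, None)
    for d1 in offsets:
        for d2 in offsets:
            t_rw = base_tau_rw * np.exp(d1)
            t_iid = base_tau_iid * np.exp(d2)
            res = model.fit(tau_rw=t_rw, tau_iid=t_iid, compute_sd=False, **fit_kwargs)
            r = pearsonr(res.pd[mask], reference_pd[mask])[0] if mask.sum() > 1 else np.nan
            rows.append({"offset_rw": d1, "offset_iid": d2, "tau_rw": t_rw, "tau_iid": t_iid, "pearson_r": r})
            if np.isfinite(r) and r > best[0]:
                best = (r, t_rw, t_iid)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


def component_fraction(results, counts, min_mean_count=50):
    """Per-bin fraction PD/(PD+PI) among well-expressed, both-positive bins.

    Bins are kept when their mean count across replicates exceeds
    ``min_mean_count`` (strict) and both components are positive; the
    fraction is then within (0, 1).  Returns a Series indexed by bin.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    mean_count = counts.mean(axis=1)
    keep = (mean_count > min_mean_count) & (results.pd > 0) & (results.pi > 0)
    idx = np.flatnonzero(keep)
    frac = results.pd[idx] / (results.pd[idx] + results.pi[idx])
    return pd.Series(frac, index=idx, name="pd_fraction")


def differential_components(
    results_a, results_b, expressed_mask, component="pd", fdr=0.01
):
    """Posterior z-score differential test of a component between two fits.

    The per-bin difference is Delta = comp_A - comp_B with SD
    ``sqrt(sd_A^2 + sd_B^2)`` (independence of the two fits assumed).
    Two-sided Gaussian p-values are Benjamini-Hochberg adjusted over the
    ``expressed_mask`` bins only; ``significant`` marks q < ``fdr``.
    """
    if results_a.n_bins != results_b.n_bins:
        raise ValueError("results are on different grids")
    comp_a = getattr(results_a, component)
    comp_b = getattr(results_b, component)
    sd_a = getattr(results_a, component + "_sd")
    sd_b = getattr(results_b, component + "_sd")
    mask = np.asarray(expressed_mask, dtype=bool)
    delta = comp_a - comp_b
    sd = np.sqrt(sd_a**2 + sd_b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, delta / sd, np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    p = 2.0 * norm.sf(np.abs(z))
    q = np.full_like(p, np.nan)
    q[mask] = bh_adjust(p[mask])
    table = pd.DataFrame(
        {
            "delta": delta,
            "sd": sd,
            "z": z,
            "p": p,
            "q": q,
            "expressed": mask,
            "significant": mask & (q < fdr),
        }
    )
    return table
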