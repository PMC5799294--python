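"""Seeded synthetic data with the statistical structure the method assumes.

Each generator draws from the generative model a pipeline stage expects --
replicated hurdle-NB counts over a planted RW1 + iid latent structure,
piecewise-constant multi-cell PD tracks with planted boundaries, candidate
pair universes with planted logistic interaction labels, and block-structured
contact matrices -- and returns the planted truth alongside the data, so
recovery can be measured without any external download.  All generators are
pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .rw1 import sample_rw1

__all__ = [
    "SyntheticTruth",
    "simulate_counts",
    "simulate_multicell",
    "simulate_universe",
    "simulate_contacts",
    "UNIVERSE_FEATURES",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth stored alongside generated data."""

    seed: int
    params: dict = field(default_factory=dict)
    pd: np.ndarray | None = None
    pi: np.ndarray | None = None
    alpha: float | None = None
    boundaries: np.ndarray | None = None
    labels: np.ndarray | None = None
    coefficients: np.ndarray | None = None


def simulate_counts(
    n_bins=2000,
    n_reps=3,
    tau_rw=1.0,
    tau_iid=4.0,
    alpha=None,
    k=5.0,
    p0=0.3,
    depths=None,
    family="hurdle",
    seed=0,
):
    """Replicated zero-augmented NB counts over a planted RW1 + iid field.

    PD is a sum-to-zero draw from the scaled RW1 prior with precision
    ``tau_rw``; PI is iid ``N(0, 1/tau_iid)``.  Counts follow
    ``mu_ir = E_r exp(alpha + PD_i + PI_i)`` with either a hurdle (explicit
    zero mass ``p0``, zero-truncated NB positives) or mixture-ZINB family.
    Defaults mirror the recovery conditions used throughout the tests:
    2,000 bins, 3 replicates, tau_rw=1, tau_iid=4, k=5, p0=0.3.

    ``alpha`` defaults so that a depth-1e6 library yields single-digit mean
    counts per expressed bin (alpha = log(5e-6)); ``depths`` default to
    1e6 per replicate.

    Returns ``(Y, depths, truth)`` with ``Y`` of shape (n_bins, n_reps).
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    if tau_rw <= 0 or tau_iid <= 0 or k <= 0:
        raise ValueError("precisions and k must be positive")
    rng = np.random.default_rng(seed)
    if depths is None:
        depths = np.full(n_reps, 1e6)
    depths = np.asarray(depths, dtype=float)
    if alpha is None:
        alpha = float(np.log(5e-6))
    pd_true = sample_rw1(n_bins, tau_rw, rng)
    pi_true = rng.normal(0.0, 1.0 / np.sqrt(tau_iid), size=n_bins)
    mu = depths[None, :] * np.exp(alpha + pd_true + pi_true)[:, None]
    pnb = k / (k + mu)
    zero = rng.random((n_bins, n_reps)) < p0
    if family == "hurdle":
        # zero-truncated NB via inverse-cdf above the zero mass
        q0 = pnb**k
        u = q0 + (1.0 - q0) * rng.random((n_bins, n_reps))
        y = nbinom.ppf(u, k, pnb)
        y[zero] = 0
    elif family == "zinb":
        y = rng.negative_binomial(k, pnb)
        y = np.asarray(y, dtype=float)
        y[zero] = 0
    else:
        raise ValueError("family must be 'hurdle' or 'zinb'")
    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            n_bins=n_bins, n_reps=n_reps, tau_rw=tau_rw, tau_iid=tau_iid,
            alpha=alpha, k=k, p0=p0, family=family,
        ),
        pd=pd_true,
        pi=pi_true,
        alpha=alpha,
    )
    return y.astype(np.int64), depths, truth


def simulate_multicell(
    n_cells=3,
    n_bins=5000,
    boundary_positions=None,
    step_sizes=None,
    noise=0.05,
    sd_level=0.1,
    sd_noise=0.02,
    seed=0,
):
    """Piecewise-constant PD tracks shared across cells, with planted steps.

    A base track steps by ``step_sizes[j]`` at each planted boundary
    position (forward-difference convention: the step lies between bin
    ``b-1`` and ``b``); each cell observes the base plus iid Gaussian noise.
    Per-cell posterior-SD tracks (positive, near ``sd_level``) are emitted
    so stability scores are derivable.

    Returns ``(pd_tracks, sd_tracks, truth)``; tracks have shape
    (n_cells, n_bins); ``truth.boundaries`` holds the planted step bins.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    if boundary_positions is None:
        boundary_positions = np.sort(rng.choice(np.arange(50, n_bins - 50), size=20, replace=False))
    boundary_positions = np.asarray(boundary_positions, dtype=int)
    if np.any(np.diff(boundary_positions) < 1):
        raise ValueError("boundary positions must be strictly increasing")
    if np.any((boundary_positions < 1) | (boundary_positions >= n_bins)):
        raise ValueError("boundary positions must lie within the grid")
    if step_sizes is None:
        step_sizes = rng.choice([-1.0, 1.0], size=boundary_positions.size) * rng.uniform(
            0.8, 1.5, size=boundary_positions.size
        )
    step_sizes = np.asarray(step_sizes, dtype=float)
    base = np.zeros(n_bins)
    incr = np.zeros(n_bins)
    incr[boundary_positions] = step_sizes
    base = np.cumsum(incr)
    base += 1.0 - base.min()  # keep PD positive so every bin is rankable
    tracks = base[None, :] + rng.normal(0.0, noise, size=(n_cells, n_bins))
    # posterior-SD differences between cells are depth-driven: one offset per
    # cell plus a small per-bin ripple, so the cross-cell SD never collapses
    # to zero at isolated bins
    cell_offsets = rng.normal(0.0, sd_noise, size=(n_cells, 1))
    ripple = rng.normal(0.0, sd_noise / 10.0, size=(n_cells, n_bins))
    sds = np.abs(sd_level + cell_offsets + ripple) + 1e-6
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_cells=n_cells, n_bins=n_bins, noise=noise, sd_level=sd_level),
        boundaries=boundary_positions,
    )
    truth.params["step_sizes"] = step_sizes
    return tracks, sds, truth


#: feature schema of the simulated pair universe (a compact stand-in for the
#: full expression-feature table; the planted coefficient vector indexes it)
UNIVERSE_FEATURES = [
    "pd_bait", "pd_targ", "pd_sd_bait", "pd_sd_targ",
    "pi_bait", "pi_targ", "eRNA_bait", "eRNA_targ",
    "nbounds", "kendall_pd", "distance",
]


def simulate_universe(n_pairs=10000, coefficients=None, intercept=0.0, seed=0):
    """Candidate bait-target pairs with planted logistic interaction labels.

    Distances are log-uniform on [6, 200] bins, expression features
    log-normal, insulation a distance-coupled Poisson capped at 3, and
    labels Bernoulli(logistic(intercept + beta . x_std)) over standardised
    features -- so a negative distance coefficient makes positives decay
    with distance, mimicking the scarcity of long-range contacts.

    Returns ``(features, labels, truth)`` with ``features`` a DataFrame
    over :data:`UNIVERSE_FEATURES`.
    """
    rng = np.random.default_rng(seed)
    if coefficients is None:
        coefficients = np.zeros(len(UNIVERSE_FEATURES))
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (len(UNIVERSE_FEATURES),):
        raise ValueError(
            f"coefficients must match the {len(UNIVERSE_FEATURES)}-feature schema"
        )
    d = np.exp(rng.uniform(np.log(6), np.log(200), size=n_pairs))
    d = np.clip(np.round(d), 6, 200).astype(int)
    X = pd.DataFrame(
        {
            "pd_bait": rng.normal(0.5, 1.0, n_pairs),
            "pd_targ": rng.normal(0.5, 1.0, n_pairs),
            "pd_sd_bait": np.abs(rng.normal(0.3, 0.1, n_pairs)),
            "pd_sd_targ": np.abs(rng.normal(0.3, 0.1, n_pairs)),
            "pi_bait": rng.normal(0.0, 1.0, n_pairs),
            "pi_targ": rng.normal(0.0, 1.0, n_pairs),
            "eRNA_bait": rng.lognormal(0.0, 1.0, n_pairs),
            "eRNA_targ": rng.lognormal(0.0, 1.0, n_pairs),
            "nbounds": np.minimum(rng.poisson(d / 80.0), 3),
            "kendall_pd": np.clip(rng.normal(0.0, 0.4, n_pairs), -1, 1),
            "distance": d,
        }
    )[UNIVERSE_FEATURES]
    Xs = (X - X.mean()) / X.std(ddof=0)
    logit = intercept + Xs.to_numpy() @ coefficients
    prob = 1.0 / (1.0 + np.exp(-logit))
    labels = (rng.random(n_pairs) < prob).astype(int)
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_pairs=n_pairs, intercept=intercept),
        labels=labels,
        coefficients=coefficients,
    )
    return X, labels, truth


def simulate_contacts(n_bins=200, block_edges=(100,), within=10.0, between=1.0, noise=False, seed=0):
    """Symmetric block contact matrix (optionally Poisson-noised).

    ``block_edges`` are the first bins of each new block; contacts are
    ``within`` inside a block and ``between`` across blocks.
    """
    if not within > between >= 0:
        raise ValueError("require within > between >= 0")
    edges = np.concatenate([[0], np.asarray(block_edges, dtype=int), [n_bins]])
    block_of = np.zeros(n_bins, dtype=int)
    for j in range(len(edges) - 1):
        block_of[edges[j] : edges[j + 1]] = j
    same = block_of[:, None] == block_of[None, :]
    M = np.where(same, within, between).astype(float)
    if noise:
        rng = np.random.default_rng(seed)
        upper = rng.poisson(M)
        M = np.triu(upper) + np.triu(upper, 1).T
        M = M.astype(float)
    return M
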