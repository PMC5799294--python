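"""First-order random-walk (RW1) structure matrices for the positional component.

The positionally dependent (PD) component is an intrinsic Gaussian Markov
random field: consecutive-bin differences are independent Gaussians,
``PD_i - PD_{i+1} ~ N(0, 1/tau_rw)``.  Its structure matrix is the path-graph
Laplacian ``R = D'D`` (D the first-difference operator), which is rank n-1.
So that the precision ``tau_rw`` is interpretable across chromosome lengths,
the structure is rescaled so the average marginal variance of the field --
the mean diagonal of the generalised inverse -- equals one.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["rw1_structure", "rw1_scale_factor", "sample_rw1"]


def rw1_scale_factor(n: int) -> float:
    """Scale factor s = mean(diag(R+)) for the RW1 structure on ``n`` bins.

    Computed from the spectrum of the path-graph Laplacian,
    ``lambda_j = 4 sin^2(pi j / (2n))`` for j = 1..n-1, using
    ``mean(diag(R+)) = tr(R+)/n = (1/n) sum_j 1/lambda_j``.
    """
    if n < 2:
        raise ValueError("RW1 structure requires at least 2 bins")
    j = np.arange(1, n)
    lam = 4.0 * np.sin(np.pi * j / (2.0 * n)) ** 2
    return float(np.sum(1.0 / lam) / n)


def rw1_structure(n: int, *, sparse: bool = True):
    """Return ``(S, s)``: the scaled RW1 structure matrix ``S = s*R`` and s.

    The generalised inverse of ``S`` has average diagonal exactly 1, so a
    field with precision matrix ``tau * S`` has average marginal prior
    variance ``1/tau``.
    """
    if n < 2:
        raise ValueError("RW1 structure requires at least 2 bins")
    s = rw1_scale_factor(n)
    main = np.full(n, 2.0)
    main[0] = main[-1] = 1.0
    off = np.full(n - 1, -1.0)
    R = sp.diags([off, main, off], offsets=[-1, 0, 1], format="csc")
    if not sparse:
        return s * R.toarray(), s
    return (s * R).tocsc(), s


def sample_rw1(n: int, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a sum-to-zero sample from the scaled RW1 prior with precision tau.

    Increments are iid ``N(0, 1/(tau*s))``; the cumulative sum is centred to
    fix the intrinsic level (sum-to-zero gauge).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if tau <= 0:
        raise ValueError("tau must be positive")
    s = rw1_scale_factor(n)
    incr = rng.normal(0.0, 1.0 / np.sqrt(tau * s), size=n - 1)
    x = np.concatenate([[0.0], np.cumsum(incr)])
    return x - x.mean()
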