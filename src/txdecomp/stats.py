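"""Small statistical utilities shared across the pipeline."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "chi2_2x2", "odds_ratio_2x2"]


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi2_2x2(table):
    """Pearson chi-square statistic and p-value for a 2x2 table, no continuity correction."""
    from scipy.stats import chi2_contingency

    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if t.sum() == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return np.nan, np.nan
    stat, p, _, _ = chi2_contingency(t, correction=False)
    return float(stat), float(p)


def odds_ratio_2x2(table, haldane=True):
    """Cross-product odds ratio a*d/(b*c); Haldane-Anscombe 0.5 on zero cells.

    Returns ``(odds_ratio, corrected)`` where ``corrected`` flags that the
    0.5 adjustment was applied.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    corrected = False
    if haldane and np.any(t == 0):
        t = t + 0.5
        corrected = True
    a, b = t[0]
    c, d = t[1]
    return float(a * d / (b * c)), corrected
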