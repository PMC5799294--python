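"""Expression-only feature tables for bait-target interaction prediction.

Candidate pairs are intra-chromosomal bait-target bin pairs separated by 6
to 200 bins (>50 kb to 2 Mb at 10-kb resolution).  Each pair is described
purely from expression-derived quantities: component values, differences,
posterior SDs and cross-cell stabilities at both ends, XAD boundary
insulation (capped at 3), enhancer RNA output, active-enhancer and
supporting-cell counts, transcriptional directionality, CAGE peak counts,
cross-cell Kendall correlations of the component profiles, the first
eigenvector of the per-chromosome cross-correlation matrix, and distance.

The exact composition of the original feature list is reconstructed from
the quantities named in the method description; the schema is versioned
(:data:`FEATURE_SCHEMA_VERSION`) so additions stay explicit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

__all__ = [
    "FEATURE_SCHEMA_VERSION",
    "FEATURE_COLUMNS",
    "enumerate_pairs",
    "insulation_count",
    "cross_cell_correlation",
    "correlation_eigenvector",
    "assemble_features",
    "mark_classifier",
]

FEATURE_SCHEMA_VERSION = "reconstructed-v1"

#: ordered feature columns of the assembled pair table (besides identifiers)
FEATURE_COLUMNS = [
    "pd_bait", "pd_diff_bait", "pd_sd_bait", "pd_stab_bait",
    "pi_bait", "pi_diff_bait", "pi_sd_bait", "pi_stab_bait",
    "pd_targ", "pd_diff_targ", "pd_sd_targ", "pd_stab_targ",
    "pi_targ", "pi_diff_targ", "pi_sd_targ", "pi_stab_targ",
    "nbounds",
    "eRNA_bait", "eRNA_targ",
    "n_active_enhancers", "n_supporting_celltypes",
    "dir_bait", "dir_targ",
    "npeaks_bait", "npeaks_targ",
    "kendall_pd", "kendall_pi",
    "eigen_bait", "eigen_targ",
    "distance",
]


def enumerate_pairs(bait_bins, n_bins, target_mask=None, enhancer_mask=None,
                    min_dist=6, max_dist=200, chrom="chr1"):
    """All (bait, target) pairs within the distance range, target-filtered.

    ``target_mask`` (boolean per bin) restricts eligible targets, e.g. to
    bins with CAGE tags in more than one replicate; ``enhancer_mask`` flags
    targets overlapping at least one active CAGE-defined enhancer, recorded
    in the ``enhancer_target`` column.

    Returns a DataFrame (chrom, bait, target, distance, enhancer_target).
    """
    bait_bins = np.asarray(bait_bins, dtype=int)
    if target_mask is None:
        target_mask = np.ones(n_bins, dtype=bool)
    target_mask = np.asarray(target_mask, dtype=bool)
    if enhancer_mask is None:
        enhancer_mask = np.zeros(n_bins, dtype=bool)
    enhancer_mask = np.asarray(enhancer_mask, dtype=bool)
    rows = []
    for bait in bait_bins:
        lo = max(0, bait - max_dist)
        hi = min(n_bins - 1, bait + max_dist)
        targets = np.arange(lo, hi + 1)
        d = np.abs(targets - bait)
        ok = (d >= min_dist) & (d <= max_dist) & target_mask[targets]
        for t in targets[ok]:
            rows.append((chrom, int(bait), int(t), int(abs(t - bait)), bool(enhancer_mask[t])))
    return pd.DataFrame(rows, columns=["chrom", "bait", "target", "distance", "enhancer_target"])


def insulation_count(bait, target, boundary_bins, cap=3):
    """Number of boundary bins strictly between bait and target, capped.

    Endpoints are excluded; counts above ``cap`` saturate at ``cap``.
    """
    lo, hi = (bait, target) if bait <= target else (target, bait)
    b = np.asarray(boundary_bins)
    n = int(np.sum((b > lo) & (b < hi)))
    return min(n, cap)


def cross_cell_correlation(bait_profile, target_profile):
    """Kendall tau between the cross-cell profiles of bait and target.

    Constant profiles (ties everywhere) give 0 rather than NaN: with only a
    handful of cell types the statistic must be total.
    """
    a = np.asarray(bait_profile, dtype=float)
    b = np.asarray(target_profile, dtype=float)
    if a.size != b.size:
        raise ValueError("profiles must have equal length")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return 0.0
    tau = kendalltau(a, b).statistic
    return 0.0 if not np.isfinite(tau) else float(tau)


def correlation_eigenvector(corr):
    """First eigenvector of a symmetric cross-correlation matrix.

    Sign fixed so the entry sum is non-negative; an eigenvalue tie is broken
    by the lowest index and flagged.  Returns ``(vector, tied)``.
    """
    C = np.asarray(corr, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("correlation matrix has non-finite entries")
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(-vals, kind="stable")
    v = vecs[:, order[0]]
    tied = bool(order.size > 1 and np.isclose(vals[order[0]], vals[order[1]]))
    if v.sum() < 0:
        v = -v
    return v, tied


def assemble_features(
    pairs,
    results_by_cell,
    focal_cell,
    boundary_bins,
    stab_pd=None,
    stab_pi=None,
    erna=None,
    n_active_enhancers=None,
    n_supporting_celltypes=None,
    directionality=None,
    n_peaks=None,
):
    """Assemble the full per-pair feature table for one chromosome.

    Parameters
    ----------
    pairs : DataFrame from :func:`enumerate_pairs`
    results_by_cell : dict cell type -> DecompositionResults (same grid)
    focal_cell : the cell type providing the single-cell features
    boundary_bins : XAD boundary bins of the focal cell
    stab_pd, stab_pi : per-bin cross-cell stabilities (default: SD across
        cells of the per-cell posterior SDs)
    erna, n_active_enhancers, n_supporting_celltypes, directionality,
    n_peaks : optional per-bin tracks; missing tracks contribute zeros.

    Assembly is pure: identical inputs give an identical table.
    """
    cells = list(results_by_cell)
    if focal_cell not in results_by_cell:
        raise KeyError(f"focal cell {focal_cell!r} missing from results")
    res = results_by_cell[focal_cell]
    n = res.n_bins
    for c in cells:
        if results_by_cell[c].n_bins != n:
            raise ValueError("decomposition results are on different grids")

    pd_mat = np.stack([results_by_cell[c].pd for c in cells])
    pi_mat = np.stack([results_by_cell[c].pi for c in cells])
    pd_sd_mat = np.stack([results_by_cell[c].pd_sd for c in cells])
    pi_sd_mat = np.stack([results_by_cell[c].pi_sd for c in cells])
    if stab_pd is None:
        stab_pd = pd_sd_mat.std(axis=0, ddof=1) if len(cells) > 1 else np.zeros(n)
    if stab_pi is None:
        stab_pi = pi_sd_mat.std(axis=0, ddof=1) if len(cells) > 1 else np.zeros(n)

    def track(x):
        return np.zeros(n) if x is None else np.asarray(x, dtype=float)

    erna = track(erna)
    n_active = track(n_active_enhancers)
    n_support = track(n_supporting_celltypes)
    direction = track(directionality)
    peaks = track(n_peaks)

    def fdiff(x):
        d = np.empty_like(x)
        d[:-1] = np.diff(x)
        d[-1] = 0.0
        return d

    pd_f, pi_f = res.pd, res.pi
    pd_d, pi_d = fdiff(pd_f), fdiff(pi_f)
    pd_sd, pi_sd = res.pd_sd, res.pi_sd

    # per-chromosome first eigenvector of the bin-bin cross-cell correlation
    eig_pd = _profile_eigenvector(pd_mat)

    b = pairs["bait"].to_numpy()
    t = pairs["target"].to_numpy()
    bset = np.asarray(boundary_bins)
    out = pairs.copy()
    out["pd_bait"], out["pd_targ"] = pd_f[b], pd_f[t]
    out["pd_diff_bait"], out["pd_diff_targ"] = pd_d[b], pd_d[t]
    out["pd_sd_bait"], out["pd_sd_targ"] = pd_sd[b], pd_sd[t]
    out["pd_stab_bait"], out["pd_stab_targ"] = stab_pd[b], stab_pd[t]
    out["pi_bait"], out["pi_targ"] = pi_f[b], pi_f[t]
    out["pi_diff_bait"], out["pi_diff_targ"] = pi_d[b], pi_d[t]
    out["pi_sd_bait"], out["pi_sd_targ"] = pi_sd[b], pi_sd[t]
    out["pi_stab_bait"], out["pi_stab_targ"] = stab_pi[b], stab_pi[t]
    out["nbounds"] = [insulation_count(bi, ti, bset) for bi, ti in zip(b, t)]
    out["eRNA_bait"], out["eRNA_targ"] = erna[b], erna[t]
    out["n_active_enhancers"] = n_active[t]
    out["n_supporting_celltypes"] = n_support[t]
    out["dir_bait"], out["dir_targ"] = direction[b], direction[t]
    out["npeaks_bait"], out["npeaks_targ"] = peaks[b], peaks[t]
    out["kendall_pd"] = [cross_cell_correlation(pd_mat[:, bi], pd_mat[:, ti]) for bi, ti in zip(b, t)]
    out["kendall_pi"] = [cross_cell_correlation(pi_mat[:, bi], pi_mat[:, ti]) for bi, ti in zip(b, t)]
    out["eigen_bait"], out["eigen_targ"] = eig_pd[b], eig_pd[t]
    return out[["chrom", "bait", "target", "enhancer_target"] + FEATURE_COLUMNS]


def _profile_eigenvector(mat):
    """First eigenvector of the bin x bin correlation of cross-cell profiles.

    Bins with a constant cross-cell profile get correlation 0 with
    everything (and eigenvector weight from the tie-broken decomposition).
    """
    m = np.asarray(mat, dtype=float)
    centred = m - m.mean(axis=0, keepdims=True)
    sd = centred.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = centred / safe
    C = (z.T @ z) / m.shape[0]
    np.fill_diagonal(C, 1.0)
    v, _ = correlation_eigenvector(C)
    return v


def mark_classifier(features, labels, n_trees=500, seed=0):
    """Out-of-bag class probabilities for a binary mark from component features.

    One tree ensemble per (mark, component), trained on the component's
    per-bin feature set (value, first-order difference, posterior SD,
    stability); returns ``(oob_probabilities, oob_auc, model)``.
    """
    X = pd.DataFrame(features)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("mark labels are single-class")
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    prob = rf.oob_decision_function_[:, list(rf.classes_).index(1)]
    return prob, float(roc_auc_score(y, prob)), rf
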