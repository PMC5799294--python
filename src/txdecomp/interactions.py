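"""Training and evaluation of the expression-based interaction classifier.

Bait-target pairs are labelled from interaction-score tables (capture Hi-C
style: score >= cutoff is positive, absent pairs negative), balanced per
distance stratum by synthetic minority oversampling plus negative
undersampling, and classified with a 10-fold cross-validated random forest.
Held-out probabilities are thresholded per distance band at the
F1-maximising cutoff.  Because the negative:positive ratio grows steeply
with distance, balancing is always stratified by bait-target separation,
and cross-validation folds are defined on the original pairs with balancing
applied inside each training fold only (no synthetic leakage into test
folds).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

__all__ = [
    "DEFAULT_BANDS",
    "BAND_MODEL_BANDS",
    "label_pairs",
    "subsample_np",
    "smote_balance",
    "train_cv",
    "InteractionModel",
    "distance_band_models",
    "optimize_thresholds",
    "evaluate",
    "predict_celltypes",
    "interaction_sharing",
    "similarity_1l1",
]

#: distance bands (in bins of 10 kb) for threshold optimisation:
#: (50,100], (100,250], (250,500], (500,1000], (1000,2000] kb
DEFAULT_BANDS = [(5, 10), (10, 25), (25, 50), (50, 100), (100, 200)]

#: coarser bands for per-band feature-importance models:
#: (50,250], (250,500], (500,2000] kb
BAND_MODEL_BANDS = [(5, 25), (25, 50), (50, 200)]


def label_pairs(pairs, interaction_table, cutoff=3.0):
    """Binary labels from an interaction-score table.

    ``interaction_table`` has columns (bait, target, score); label 1 iff
    score >= cutoff, pairs absent from the table are negative.  Duplicate
    (bait, target) entries keep the highest score with a warning.
    """
    tab = pd.DataFrame(interaction_table)[["bait", "target", "score"]].copy()
    if tab.duplicated(["bait", "target"]).any():
        warnings.warn("duplicate pair entries in interaction table; keeping highest score")
        tab = tab.sort_values("score").drop_duplicates(["bait", "target"], keep="last")
    merged = pairs.merge(tab, on=["bait", "target"], how="left")
    score = merged["score"].fillna(-np.inf)
    labels = (score >= cutoff).astype(int).to_numpy()
    return labels


def subsample_np(features, labels, ratio=20, seed=0):
    """Fixed negative:positive evaluation set, stratified by distance.

    Per distance, ``ratio`` negatives are sampled per positive -- with
    replacement when fewer are available -- and all positives are kept.
    Returns the row indices of the subsample (positives first within each
    distance stratum).
    """
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("no positive pairs to anchor the NP subsample")
    d = np.asarray(features["distance"])
    rng = np.random.default_rng(seed)
    keep = []
    for dist in np.unique(d):
        idx = np.flatnonzero(d == dist)
        pos = idx[labels[idx] == 1]
        neg = idx[labels[idx] == 0]
        if pos.size == 0:
            continue
        need = ratio * pos.size
        take = rng.choice(neg, size=need, replace=neg.size < need) if neg.size else np.array([], dtype=int)
        keep.extend(pos.tolist())
        keep.extend(take.tolist())
    return np.asarray(keep, dtype=int)


def smote_balance(X, y, distance, perc_over=200, perc_under=150, k=5, seed=0):
    """Per-distance SMOTE oversampling plus negative undersampling to 1:1.

    In each distance stratum with n >= 2 positives, ``perc_over/100 * n``
    synthetic positives are interpolated between a random positive and one
    of its ``k`` nearest positive neighbours (uniform weight on [0, 1]),
    and negatives are downsampled to ``perc_under/100`` of the synthetic
    count.  With the default 200/150 the stratum comes out at 3n positives
    (n real + 2n synthetic) against 3n negatives -- exactly balanced.
    Strata with a single positive are passed through with a warning.

    Returns ``(X_bal, y_bal, origin, dist_bal)``: ``origin`` holds the
    source row index for real rows and -1 for synthetic ones; ``dist_bal``
    the distance stratum of every balanced row.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    distance = np.asarray(distance)
    if y.sum() == 0:
        raise ValueError("no positive pairs at any distance")
    rng = np.random.default_rng(seed)
    parts_X, parts_y, parts_o, parts_d = [], [], [], []
    passed_through = []
    for dist in np.unique(distance):
        idx = np.flatnonzero(distance == dist)
        pos = idx[y[idx] == 1]
        neg = idx[y[idx] == 0]
        if pos.size == 0:
            continue
        if pos.size < 2:
            passed_through.append(dist)
            parts_X.append(X[idx])
            parts_y.append(y[idx])
            parts_o.append(idx)
            parts_d.append(np.full(idx.size, dist))
            continue
        n_syn = int(round(perc_over / 100.0 * pos.size))
        Xp = X[pos]
        # k nearest positive neighbours by Euclidean distance
        d2 = np.sum((Xp[:, None, :] - Xp[None, :, :]) ** 2, axis=2)
        np.fill_diagonal(d2, np.inf)
        kk = min(k, pos.size - 1)
        nn = np.argsort(d2, axis=1)[:, :kk]
        src = rng.integers(0, pos.size, size=n_syn)
        pick = nn[src, rng.integers(0, kk, size=n_syn)]
        lam = rng.random(n_syn)[:, None]
        synth = Xp[src] + lam * (Xp[pick] - Xp[src])
        n_neg = int(round(perc_under / 100.0 * n_syn))
        take = rng.choice(neg, size=n_neg, replace=neg.size < n_neg) if neg.size else np.array([], dtype=int)
        parts_X.extend([X[pos], synth, X[take]])
        parts_y.extend([np.ones(pos.size, dtype=int), np.ones(n_syn, dtype=int), np.zeros(take.size, dtype=int)])
        parts_o.extend([pos, np.full(n_syn, -1), take])
        parts_d.append(np.full(pos.size + n_syn + take.size, dist))
    if passed_through:
        warnings.warn(
            f"{len(passed_through)} distance strata had fewer than 2 positives "
            "and were passed through unbalanced"
        )
    return (
        np.concatenate(parts_X),
        np.concatenate(parts_y),
        np.concatenate(parts_o),
        np.concatenate(parts_d),
    )


class InteractionModel:
    """Ten fold-trained forests with held-out predictions and importances."""

    def __init__(self, models, feature_names, oob_probabilities, fold_of, importances=None):
        self.models = models
        self.feature_names = list(feature_names)
        self.heldout_probabilities = oob_probabilities
        self.fold_of = fold_of
        self.importances = importances

    def predict_proba(self, X):
        """Mean predicted interaction probability over the fold models."""
        X = np.asarray(X, dtype=float)
        probs = np.stack([
            m.predict_proba(X)[:, list(m.classes_).index(1)] for m in self.models
        ])
        return probs.mean(axis=0)


def train_cv(
    features,
    labels,
    feature_names=None,
    n_folds=10,
    n_trees=500,
    seed=0,
    balance=True,
    compute_importance=False,
    importance_repeats=3,
):
    """Cross-validated random-forest interaction classifier.

    Folds partition the *original* pairs; SMOTE balancing (per distance) is
    applied inside each training fold only, so no synthetic row derived
    from a held-out pair ever enters training.  Every pair receives exactly
    one held-out probability.  Permutation importances (mean decrease
    accuracy) on each held-out fold are averaged when requested.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns) if feature_names is None else feature_names
        X = features[feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=int)
    if "distance" in feature_names:
        dist = X[:, feature_names.index("distance")]
    else:
        dist = np.zeros(len(y))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    fold_of = np.empty(len(y), dtype=int)
    fold_of[order] = np.arange(len(y)) % n_folds
    heldout = np.empty(len(y))
    models = []
    imps = []
    for f in range(n_folds):
        train = fold_of != f
        test = ~train
        if y[train].sum() == 0:
            warnings.warn(f"fold {f} has no training positives; re-splitting")
            order = rng.permutation(len(y))
            fold_of[order] = np.arange(len(y)) % n_folds
            train = fold_of != f
            test = ~train
        if balance:
            Xb, yb, _, _ = smote_balance(X[train], y[train], dist[train], seed=seed + 17 * f + 1)
        else:
            Xb, yb = X[train], y[train]
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + f, n_jobs=1)
        rf.fit(Xb, yb)
        one = list(rf.classes_).index(1)
        heldout[test] = rf.predict_proba(X[test])[:, one]
        models.append(rf)
        if compute_importance:
            pi = permutation_importance(
                rf, X[test], y[test], n_repeats=importance_repeats,
                random_state=seed + f, n_jobs=1,
            )
            imps.append(pi.importances_mean)
    importances = None
    if compute_importance:
        importances = pd.Series(np.mean(imps, axis=0), index=feature_names).sort_values(ascending=False)
    return InteractionModel(models, feature_names, heldout, fold_of, importances)


def distance_band_models(features, labels, bands=None, **train_kwargs):
    """One cross-validated model per distance band, with averaged importances.

    Bands are half-open ``(lo, hi]`` in bins so no pair falls in two bands;
    empty bands are skipped with a warning.  Returns dict band ->
    importances Series.
    """
    bands = bands if bands is not None else BAND_MODEL_BANDS
    d = np.asarray(features["distance"])
    out = {}
    for lo, hi in bands:
        sel = (d > lo) & (d <= hi)
        if not sel.any() or len(np.unique(np.asarray(labels)[sel])) < 2:
            warnings.warn(f"band ({lo}, {hi}] empty or single-class; skipped")
            continue
        model = train_cv(
            features.loc[sel].reset_index(drop=True),
            np.asarray(labels)[sel],
            compute_importance=True,
            **train_kwargs,
        )
        out[(lo, hi)] = model.importances
    return out


def optimize_thresholds(probabilities, labels, distances, bands=None, step=0.005):
    """Per-band F1-maximising probability cutoffs by exhaustive grid search.

    A pair is called at probability >= cutoff; the grid is 0, step, ...,
    1.  Ties take the lowest cutoff.  Bands without positives get a NaN
    cutoff, flagged in the table.

    Returns a DataFrame (lo, hi, cutoff, f1, n_pos, defined).
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    d = np.asarray(distances)
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    rows = []
    for lo, hi in bands:
        sel = (d > lo) & (d <= hi)
        ysel, psel = y[sel], p[sel]
        if ysel.sum() == 0:
            rows.append({"lo": lo, "hi": hi, "cutoff": np.nan, "f1": np.nan,
                         "n_pos": 0, "defined": False})
            continue
        best_f1, best_c = -1.0, 0.0
        for c in grid:
            calls = psel >= c
            tp = int(np.sum(calls & (ysel == 1)))
            fp = int(np.sum(calls & (ysel == 0)))
            fn = int(np.sum(~calls & (ysel == 1)))
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best_f1:
                best_f1, best_c = f1, c
        rows.append({"lo": lo, "hi": hi, "cutoff": float(best_c), "f1": float(best_f1),
                     "n_pos": int(ysel.sum()), "defined": True})
    return pd.DataFrame(rows)


def evaluate(probabilities, labels, thresholds=None, distances=None, chroms=None):
    """ROC-AUC plus thresholded precision/recall/F1, pooled and per chromosome.

    ``thresholds`` is an :func:`optimize_thresholds` table applied per
    distance band (requires ``distances``); without it a 0.5 cutoff is
    used.  Single-class label sets give NaN AUC, flagged.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    calls = _apply_thresholds(p, distances, thresholds)

    def block(pp, yy, cc):
        single = len(np.unique(yy)) < 2
        return {
            "auc": np.nan if single else float(roc_auc_score(yy, pp)),
            "precision": float(precision_score(yy, cc, zero_division=0)),
            "recall": float(recall_score(yy, cc, zero_division=0)),
            "f1": float(f1_score(yy, cc, zero_division=0)),
            "n": int(yy.size),
            "n_pos": int(yy.sum()),
            "single_class": single,
        }

    out = {"pooled": block(p, y, calls)}
    if chroms is not None:
        chroms = np.asarray(chroms)
        out["per_chromosome"] = {
            c: block(p[chroms == c], y[chroms == c], calls[chroms == c])
            for c in pd.unique(chroms)
        }
    return out


def _apply_thresholds(p, distances, thresholds):
    if thresholds is None:
        return p >= 0.5
    if distances is None:
        raise ValueError("distance-band thresholds need per-pair distances")
    d = np.asarray(distances)
    calls = np.zeros(p.size, dtype=bool)
    for _, row in thresholds.iterrows():
        if not row.get("defined", True) or not np.isfinite(row["cutoff"]):
            continue
        sel = (d > row["lo"]) & (d <= row["hi"])
        calls[sel] = p[sel] >= row["cutoff"]
    return calls


def predict_celltypes(model, feature_tables, thresholds, focal_cell=None):
    """Predicted interaction calls per cell type from one trained model.

    Probabilities for each cell type are the mean over the fold models;
    for the focal (training) cell type, held-out probabilities are used
    instead so its calls are not optimistically biased.  Calls apply the
    per-band cutoffs.

    Returns dict cell type -> DataFrame (pairs + probability + call).
    """
    out = {}
    for cell, table in feature_tables.items():
        if list(table.columns[-len(model.feature_names):]) != model.feature_names and not set(
            model.feature_names
        ).issubset(table.columns):
            raise ValueError(f"feature schema mismatch for cell {cell!r}")
        X = table[model.feature_names].to_numpy(dtype=float)
        if cell == focal_cell:
            prob = model.heldout_probabilities
        else:
            prob = model.predict_proba(X)
        calls = _apply_thresholds(prob, table["distance"].to_numpy(), thresholds)
        res = table.copy()
        res["probability"] = prob
        res["call"] = calls
        out[cell] = res
    return out


def interaction_sharing(calls_by_cell):
    """Exact-k sharing histogram and 1-L1 similarity of call sets.

    ``calls_by_cell``: dict cell -> boolean call vector on a common pair
    universe.  Returns ``(histogram, similarity)``: ``histogram[k]`` is the
    number of pairs called in exactly k cell types (k = 1..n_cells);
    ``similarity`` is the cell x cell matrix of
    ``1 - mean |call_a - call_b|``.
    """
    cells = list(calls_by_cell)
    M = np.stack([np.asarray(calls_by_cell[c], dtype=int) for c in cells])
    counts = M.sum(axis=0)
    hist = pd.Series(
        {k: int(np.sum(counts == k)) for k in range(1, len(cells) + 1)}, name="n_interactions"
    )
    sim = similarity_1l1(M.T, labels=cells)
    return hist, sim


def similarity_1l1(binary_matrix, labels=None):
    """Pairwise 1 - mean-absolute-difference similarity of binary columns.

    Normalising the L1 distance by the vector length keeps the similarity
    in [0, 1] regardless of how many rows are compared.
    """
    B = np.asarray(binary_matrix, dtype=float)
    n = B.shape[1]
    S = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            s = 1.0 - np.mean(np.abs(B[:, i] - B[:, j]))
            S[i, j] = S[j, i] = s
    if labels is not None:
        return pd.DataFrame(S, index=labels, columns=labels)
    return S
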