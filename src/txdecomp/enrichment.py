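"""Trait-SNP enrichment over components, boundaries and interactions.

Components are binarised per cell type (PD positive; PI above 0.1, the
offset guarding against non-expressed bins with tiny positive estimates),
cell-type similarity is 1 minus the mean absolute difference of the binary
columns, and trait-associated SNPs are tested for enrichment in per-cell
foregrounds with Pearson chi-square tests on 2x2 tables (no continuity
correction; Haldane-Anscombe 0.5 on zero cells), Benjamini-Hochberg
corrected within each component across all trait x cell tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .interactions import similarity_1l1
from .stats import bh_adjust, chi2_2x2, odds_ratio_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "binarize_components",
    "similarity_matrix",
    "assign_snps_to_bins",
    "snp_enrichment",
    "count_enriched_celltypes",
]

PI_OFFSET = 0.1


def binarize_components(tracks_by_cell, component="pd", pi_offset=PI_OFFSET):
    """Binary bins x cells matrix: PD entry 1 iff PD > 0; PI iff PI > 0.1."""
    cells = list(tracks_by_cell)
    thr = 0.0 if component == "pd" else pi_offset
    cols = {c: (np.asarray(tracks_by_cell[c], dtype=float) > thr).astype(int) for c in cells}
    return pd.DataFrame(cols)


def similarity_matrix(binary_matrix):
    """Cell x cell similarity 1 - mean|difference|; symmetric, unit diagonal."""
    if isinstance(binary_matrix, pd.DataFrame):
        return similarity_1l1(binary_matrix.to_numpy(), labels=list(binary_matrix.columns))
    return similarity_1l1(np.asarray(binary_matrix))


def assign_snps_to_bins(snps, grid):
    """Map SNPs (trait, chrom, pos) to bin indices; off-grid SNPs dropped."""
    out = snps.copy()
    bins = np.full(len(out), -1)
    for chrom, sub in out.groupby("chrom"):
        if chrom in grid.n_bins:
            bins[sub.index.to_numpy()] = grid.bin_of(chrom, sub["pos"].to_numpy())
    out["bin"] = bins
    dropped = int((bins < 0).sum())
    if dropped:
        logger.warning("%d SNPs fell outside the bin grid and were dropped", dropped)
    return out[out["bin"] >= 0].reset_index(drop=True)


def snp_enrichment(snp_bins, foregrounds, backgrounds, component="PD", min_snps=50):
    """Chi-square trait-SNP enrichment per (trait, cell type).

    Parameters
    ----------
    snp_bins : DataFrame (trait, chrom, bin) of trait-associated SNPs.
    foregrounds : dict cell -> set/array of (chrom, bin) foreground bins for
        this component in that cell (e.g. positive-PD bins; XAD boundary
        bins +-2; enhancer-target bins).
    backgrounds : dict cell -> the comparison bin set (foreground-eligible
        bins of other cells, per the component's definition).

    For each trait with at least ``min_snps`` assigned SNPs and each cell,
    the 2x2 table crosses (this trait's SNPs vs all other traits' SNPs)
    with (foreground vs non-foreground membership); the statistic is the
    Pearson chi-square without continuity correction and the cross-product
    odds ratio.  BH correction runs over all trait x cell tests of the
    component.  Empty foregrounds yield flagged undefined rows.
    """
    snp_bins = snp_bins.copy()
    trait_counts = snp_bins.groupby("trait").size()
    traits = trait_counts.index[trait_counts >= min_snps]
    loc = list(zip(snp_bins["chrom"], snp_bins["bin"]))
    snp_bins["_loc"] = loc
    rows = []
    for cell in foregrounds:
        fg = set(map(tuple, foregrounds[cell]))
        bg = set(map(tuple, backgrounds[cell]))
        in_fg = snp_bins["_loc"].isin(fg).to_numpy()
        in_bg = snp_bins["_loc"].isin(bg).to_numpy()
        in_universe = in_fg | in_bg
        for trait in traits:
            is_trait = (snp_bins["trait"] == trait).to_numpy()
            a = int(np.sum(is_trait & in_fg))
            b = int(np.sum(is_trait & in_universe & ~in_fg))
            c = int(np.sum(~is_trait & in_fg))
            d = int(np.sum(~is_trait & in_universe & ~in_fg))
            if a + c == 0:  # empty foreground coverage
                rows.append({"trait": trait, "cell": cell, "component": component,
                             "a": a, "b": b, "c": c, "d": d,
                             "odds_ratio": np.nan, "chi2": np.nan, "p": np.nan,
                             "defined": False, "or_corrected": False})
                continue
            stat, p = chi2_2x2([[a, b], [c, d]])
            oratio, corrected = odds_ratio_2x2([[a, b], [c, d]])
            rows.append({"trait": trait, "cell": cell, "component": component,
                         "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": oratio, "chi2": stat, "p": p,
                         "defined": bool(np.isfinite(p)), "or_corrected": corrected})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = np.nan
        ok = table["defined"].to_numpy()
        if ok.any():
            table.loc[ok, "fdr"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table


def count_enriched_celltypes(results, fdr=0.01, or_min=1.25, normalise=False):
    """Trait x component counts of cell types with FDR < fdr and OR > or_min.

    ``results`` concatenates :func:`snp_enrichment` tables (possibly over
    several components).  Both thresholds are strict.  With ``normalise``
    the counts are scaled to each trait's maximum.
    """
    res = pd.DataFrame(results)
    hit = res[(res["fdr"] < fdr) & (res["odds_ratio"] > or_min)]
    counts = (
        hit.groupby(["trait", "component"]).size().unstack(fill_value=0)
        .reindex(index=res["trait"].unique(), columns=res["component"].unique(), fill_value=0)
    )
    if normalise:
        m = counts.max(axis=1).replace(0, 1)
        counts = counts.div(m, axis=0)
    return counts
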