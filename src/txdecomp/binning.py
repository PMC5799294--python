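"""Genomic bin grids, replicate count matrices and per-bin expression scores.

Tag-level 5' end data (CTSS-style BED: one genomic position per row with a
tag count and strand) are aggregated into fixed-width bins per chromosome.
Bins are 1-based closed intervals ``[start, start + width - 1]`` beginning
at coordinate 1; the grid extends two bins past the last tag-containing bin.
BED input/output converts to and from 0-based half-open coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinGrid",
    "CountMatrix",
    "EnhancerSet",
    "build_bin_grid",
    "read_ctss_bed",
    "count_tags_into_bins",
    "qc_filter_samples",
    "tpm_normalize",
    "call_active_enhancers",
    "bin_directionality",
]


@dataclass
class BinGrid:
    """Fixed-width, consecutive, non-overlapping bins per chromosome.

    ``n_bins`` maps chromosome -> bin count; bin ``i`` (0-based index)
    covers 1-based positions ``[i*width + 1, (i+1)*width]``.
    """

    width: int
    n_bins: dict

    @property
    def chroms(self):
        return list(self.n_bins)

    def total_bins(self):
        return sum(self.n_bins.values())

    def bin_starts(self, chrom):
        """1-based start coordinate of every bin on ``chrom``."""
        return np.arange(self.n_bins[chrom]) * self.width + 1

    def bin_of(self, chrom, pos):
        """0-based bin index containing 1-based position(s); -1 if off-grid."""
        pos = np.asarray(pos)
        idx = (pos - 1) // self.width
        n = self.n_bins.get(chrom, 0)
        return np.where((pos >= 1) & (idx < n), idx, -1).astype(int)

    def to_bed(self, chrom=None):
        """Bins as a 0-based half-open BED DataFrame."""
        chroms = [chrom] if chrom else self.chroms
        frames = []
        for c in chroms:
            starts = self.bin_starts(c)
            frames.append(
                pd.DataFrame({"chrom": c, "start": starts - 1, "end": starts - 1 + self.width})
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class CountMatrix:
    """Replicate tag counts on a bin grid, with library depths.

    ``counts`` is a DataFrame indexed by (chrom, bin) with one column per
    sample; ``depths`` maps sample -> library depth (total mapped tags in
    tag clusters); ``cell_types`` maps sample -> cell-type label.
    """

    grid: BinGrid
    counts: pd.DataFrame
    depths: pd.Series
    cell_types: pd.Series | None = None
    dropped: dict = field(default_factory=dict)

    @property
    def samples(self):
        return list(self.counts.columns)

    def chromosome_counts(self, chrom, cell_type=None):
        """(n_bins, n_reps) integer array for one chromosome."""
        cols = self.samples_for(cell_type)
        sub = self.counts.loc[chrom, cols]
        return sub.to_numpy()

    def samples_for(self, cell_type=None):
        if cell_type is None or self.cell_types is None:
            return self.samples
        return [s for s in self.samples if self.cell_types.get(s) == cell_type]

    def depths_for(self, cell_type=None):
        return self.depths[self.samples_for(cell_type)].to_numpy()


def build_bin_grid(tag_positions, width=10_000):
    """Construct per-chromosome bin grids from tag coordinates.

    ``tag_positions`` maps chromosome -> iterable of 1-based positions.
    Each grid starts at coordinate 1 and runs in consecutive complete bins
    up to two bins past the one containing the last tag.  Chromosomes with
    no tags produce no bins (logged, not fatal).
    """
    if width < 1:
        raise ValueError("bin width must be positive")
    n_bins = {}
    for chrom, positions in tag_positions.items():
        positions = np.asarray(list(positions))
        if positions.size == 0:
            logger.warning("chromosome %s has no tags; no bins emitted", chrom)
            continue
        if np.any(positions < 1):
            raise ValueError(f"positions on {chrom} must be positive (1-based)")
        last_bin = int((positions.max() - 1) // width)  # 0-based
        n_bins[chrom] = last_bin + 1 + 2
    return BinGrid(width=width, n_bins=n_bins)


def read_ctss_bed(path, sample=None):
    """Read a CTSS BED file (chrom, start, end, name, count, strand).

    Returns a DataFrame with 1-based ``pos`` (= BED start + 1), ``count``
    and ``strand``; ``sample`` tags the rows when given.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 4, 5],
        names=["chrom", "start", "count", "strand"],
        dtype={"chrom": str, "start": np.int64, "count": np.int64, "strand": str},
        comment="#",
    )
    df["pos"] = df["start"] + 1
    df = df[["chrom", "pos", "count", "strand"]]
    if sample is not None:
        df["sample"] = sample
    return df


def count_tags_into_bins(records, grid, depths=None, cell_types=None):
    """Sum per-position tag counts into bins, per sample.

    ``records`` is a DataFrame with columns chrom, pos (1-based), count and
    sample (strand is ignored for binning).  Positions beyond the grid are
    dropped; their per-sample tallies are recorded on the result and warned
    about.  Library depths default to the binned totals per sample.
    """
    required = {"chrom", "pos", "count", "sample"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    samples = list(pd.unique(records["sample"]))
    index = pd.MultiIndex.from_tuples(
        [(c, i) for c in grid.chroms for i in range(grid.n_bins[c])], names=["chrom", "bin"]
    )
    out = pd.DataFrame(0, index=index, columns=samples, dtype=np.int64)
    dropped = {s: 0 for s in samples}
    for (chrom, sample), sub in records.groupby(["chrom", "sample"], sort=False):
        bins = grid.bin_of(chrom, sub["pos"].to_numpy()) if chrom in grid.n_bins else np.full(len(sub), -1)
        ok = bins >= 0
        n_drop = int(sub.loc[~ok, "count"].sum())
        if n_drop:
            dropped[sample] += n_drop
        if ok.any():
            sums = pd.Series(sub.loc[ok, "count"].to_numpy()).groupby(bins[ok]).sum()
            out.loc[[(chrom, int(b)) for b in sums.index], sample] += sums.to_numpy()
    total_dropped = sum(dropped.values())
    if total_dropped:
        warnings.warn(f"{total_dropped} tags fell outside the bin grid and were dropped")
    if depths is None:
        depths = out.sum(axis=0).astype(float)
    else:
        depths = pd.Series(depths, dtype=float)[samples]
    ct = pd.Series(cell_types) if cell_types is not None else None
    return CountMatrix(grid=grid, counts=out, depths=depths, cell_types=ct, dropped=dropped)


def qc_filter_samples(tag_totals, min_tags=500_000):
    """Retain libraries with more than ``min_tags`` tags in tag clusters.

    ``tag_totals`` maps sample -> total mapped tags within tag clusters.
    The threshold is strict: exactly ``min_tags`` is excluded.
    """
    totals = pd.Series(tag_totals)
    kept = list(totals.index[totals > min_tags])
    if not kept:
        warnings.warn("no library passed the tag-total QC threshold")
    return kept


def tpm_normalize(counts, totals):
    """Tags-per-million: count * 1e6 / library total.

    ``counts`` may be a Series/DataFrame (columns = samples) or array;
    ``totals`` the matching library totals.  Zero or negative totals are
    invalid libraries.
    """
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("library totals must be positive")
    if isinstance(counts, pd.DataFrame):
        return counts * 1e6 / totals
    return np.asarray(counts, dtype=float) * 1e6 / totals


@dataclass
class EnhancerSet:
    """Enhancer intervals with per-library expression and activity flags."""

    intervals: pd.DataFrame  # chrom, start, end
    expression: pd.DataFrame  # enhancers x libraries (TPM)
    active: pd.DataFrame | None = None  # same shape, boolean


def call_active_enhancers(enhancer_expr, background_expr, tag_counts=None, quantile=0.999):
    """Flag enhancers as active per library, and optionally per cell.

    Library-level: an enhancer is active in a library when its expression
    exceeds the ``quantile`` (default 99.9th) of that library's genomic
    background expression distribution (linear interpolation between order
    statistics).  Cell-level (when ``tag_counts`` replicate counts are
    given): active iff at least one tag in at least one replicate.

    ``enhancer_expr``: DataFrame enhancers x libraries; ``background_expr``:
    dict/DataFrame of background values per library.

    Returns ``(library_active, cell_active)``; ``cell_active`` is ``None``
    without ``tag_counts``.
    """
    if isinstance(background_expr, pd.DataFrame):
        background = {c: background_expr[c].to_numpy() for c in background_expr.columns}
    else:
        background = {k: np.asarray(v, dtype=float) for k, v in background_expr.items()}
    active = pd.DataFrame(index=enhancer_expr.index, columns=enhancer_expr.columns, dtype=bool)
    for lib in enhancer_expr.columns:
        bg = background[lib]
        if bg.size == 0:
            raise ValueError(f"empty background distribution for library {lib}")
        thr = np.quantile(bg, quantile)
        active[lib] = enhancer_expr[lib] > thr
    cell_active = None
    if tag_counts is not None:
        cell_active = (np.asarray(tag_counts) >= 1).any(axis=1)
        cell_active = pd.Series(cell_active, index=enhancer_expr.index)
    return active, cell_active


def bin_directionality(forward, reverse):
    """Transcriptional directionality score (F - R)/(F + R) in [-1, 1].

    Computed on replicate-pooled tag counts; bins with no tags score 0.
    """
    f = np.asarray(forward, dtype=float)
    r = np.asarray(reverse, dtype=float)
    if np.any(f < 0) or np.any(r < 0):
        raise ValueError("tag counts must be non-negative")
    tot = f + r
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(tot > 0, (f - r) / np.where(tot > 0, tot, 1.0), 0.0)
    return score if score.shape else float(score)
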