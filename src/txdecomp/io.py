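"""Readers and writers for the plain-text formats the pipeline exchanges.

Bin-level tables travel as TSV, per-bin tracks as bedGraph (0-based
half-open), contact matrices as whitespace triplets (bin_i, bin_j, value)
and hyperparameters as a small key-value text file.  Writers are
deterministic: fixed column order, fixed float formatting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "write_component_tsv",
    "write_bedgraph",
    "read_contact_triplets",
    "write_contact_triplets",
    "write_hyperparameters",
    "read_counts_tsv",
    "write_counts_tsv",
]

FLOAT_FMT = "%.6g"


def write_component_tsv(path, results, grid=None, chrom=None):
    """Per-bin component table (chrom, start, end, alpha, pd/pi mean and sd)."""
    df = results.to_frame(grid=grid, chrom=chrom)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_bedgraph(path, chrom, values, width, start0=0):
    """Track values as bedGraph lines over consecutive ``width`` bins."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            s = start0 + i * width
            fh.write(f"{chrom}\t{s}\t{s + width}\t{FLOAT_FMT % v}\n")


def write_counts_tsv(path, count_matrix):
    """Bin counts as TSV: chrom, start, end then one column per sample."""
    grid = count_matrix.grid
    parts = []
    for chrom in grid.chroms:
        starts = grid.bin_starts(chrom) - 1  # 0-based BED-style
        sub = count_matrix.counts.loc[chrom].reset_index(drop=True)
        head = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + grid.width})
        parts.append(pd.concat([head, sub], axis=1))
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path):
    """Read a counts TSV back into (counts DataFrame indexed by (chrom, bin), width)."""
    df = pd.read_csv(path, sep="\t")
    width = int(df["end"].iloc[0] - df["start"].iloc[0])
    df["bin"] = df["start"] // width
    df = df.set_index(["chrom", "bin"]).drop(columns=["start", "end"])
    return df, width


def read_contact_triplets(path, n_bins=None):
    """Square contact matrix from whitespace triplets (i, j, value).

    Entries are symmetrised (each triplet fills both (i,j) and (j,i)).
    """
    t = pd.read_csv(path, sep=r"\s+", header=None, names=["i", "j", "value"])
    n = int(max(t["i"].max(), t["j"].max())) + 1 if n_bins is None else n_bins
    M = np.zeros((n, n))
    M[t["i"], t["j"]] = t["value"]
    M[t["j"], t["i"]] = t["value"]
    return M


def write_contact_triplets(path, matrix):
    """Upper triangle (incl. diagonal) of a symmetric matrix as triplets."""
    M = np.asarray(matrix)
    with open(path, "w") as fh:
        for i in range(M.shape[0]):
            for j in range(i, M.shape[1]):
                if M[i, j] != 0:
                    fh.write(f"{i}\t{j}\t{FLOAT_FMT % M[i, j]}\n")


def write_hyperparameters(path, results):
    """Hyperparameter estimates as a small key-value text file."""
    with open(path, "w") as fh:
        for key in ("tau_rw", "tau_iid", "k", "p0", "alpha", "log_marginal"):
            fh.write(f"{key}\t{FLOAT_FMT % getattr(results, key)}\n")
        fh.write(f"converged\t{results.converged}\n")
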