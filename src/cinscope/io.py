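"""Plain-text input/output: counts TSV, segment tables, BED, trees.

All genomic intervals are 0-based half-open, BED-style.  The counts
format is a TSV with bin coordinates in the first three columns
(chrom/start/end) and one integer column per cell; the genome layout is
reconstructed from the bin coordinates on load, with strict validation
(sorted, non-overlapping bins; integer counts).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeLayout, make_genome
from .qc import CellCounts

__all__ = [
    "write_counts",
    "load_counts",
    "write_tsv",
    "read_gene_bed",
    "write_gene_bed",
    "sha256_of",
]


def write_counts(counts: CellCounts, path) -> None:
    """Write a cells-by-bins count matrix as a bin-rows TSV."""
    bins = counts.layout.bins_frame()
    matrix = pd.DataFrame(counts.counts.T, columns=counts.cell_ids)
    pd.concat([bins, matrix], axis=1).to_csv(path, sep="\t", index=False)


def load_counts(path) -> tuple[CellCounts, GenomeLayout]:
    """Load a counts TSV, validating the schema and rebuilding the layout.

    Raises ``ValueError`` on unsorted or overlapping bins, non-integer
    counts, or a malformed header.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"counts file must start with columns {required}")
    cell_cols = list(df.columns[3:])
    if not cell_cols:
        raise ValueError("counts file contains no cell columns")

    chroms = df["chrom"].astype(str).to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if np.any(ends <= starts):
        raise ValueError("bins must have positive width")
    # per-chromosome: sorted, non-overlapping, starting at 0 and tiled
    seen = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        s, e = starts[sel], ends[sel]
        if s[0] != 0:
            raise ValueError(f"{chrom}: bins must start at 0")
        if np.any(np.diff(s) <= 0):
            raise ValueError(f"{chrom}: bins out of coordinate order")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"{chrom}: overlapping bins")
        if np.any(s[1:] != e[:-1]):
            raise ValueError(f"{chrom}: bins must tile the chromosome without gaps")
        seen.append((chrom, int(e[-1])))
    widths = ends - starts
    bin_size = int(np.bincount(widths).argmax()) if len(widths) else 0
    layout = make_genome({c: length for c, length in seen}, bin_size=bin_size)
    if not np.array_equal(layout.bin_start, starts) or not np.array_equal(
        np.asarray([str(c) for c in layout.bin_chrom]), chroms
    ):
        raise ValueError("bins do not form a fixed-width tiling")

    matrix = df[cell_cols].to_numpy()
    if not np.issubdtype(matrix.dtype, np.integer):
        as_float = df[cell_cols].to_numpy(dtype=float)
        if np.any(as_float != np.round(as_float)) or np.any(~np.isfinite(as_float)):
            raise ValueError("counts must be integers")
        matrix = as_float.astype(np.int64)
    counts = CellCounts(cell_cols, matrix.T.copy(), layout)
    return counts, layout


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    """Write genes as BED6 (no header)."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = genes.copy()
    for c, default in (("score", 0), ("strand", "+")):
        if c not in out.columns:
            out[c] = default
    out[cols].to_csv(path, sep="\t", index=False, header=False)


def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED file of gene intervals (first four columns used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("gene BED needs at least chrom/start/end/name columns")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    if np.any(df["end"].to_numpy() <= df["start"].to_numpy()):
        raise ValueError("gene intervals must have positive length")
    return df


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
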