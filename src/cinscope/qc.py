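"""Count normalisation (GC, mappability, blacklist) and cell-level QC filters.

Single-cell copy-number calling starts from integer read counts per cell
per genomic bin.  Before segmentation the counts are corrected for
GC-content bias and mappability, blacklisted bins are masked out, and
cells are filtered on total read count and evenness of coverage: only
cells inside the configured read range with even genome-wide coverage are
kept for copy-number analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinTrack, GenomeLayout

__all__ = [
    "CellCounts",
    "normalize_bin_widths",
    "correct_gc",
    "correct_mappability",
    "spikiness",
    "filter_cells",
    "DEFAULT_MIN_READS",
    "DEFAULT_MAX_READS",
    "DEFAULT_MAX_SPIKINESS",
]

# Read-count window for keeping a cell, at full (unscaled) genome size.
# Bounds are inclusive; divide by the genome scale factor for toy genomes
# so the per-bp coverage regime is preserved.
DEFAULT_MIN_READS = 500_000
DEFAULT_MAX_READS = 3_000_000
DEFAULT_MAX_SPIKINESS = 1.0


@dataclass
class CellCounts:
    """Integer read counts for a set of cells over the bins of one layout."""

    cell_ids: list[str]
    counts: np.ndarray  # (n_cells, n_bins) non-negative integers
    layout: GenomeLayout
    qc_flags: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (cells x bins) matrix")
        if self.counts.shape != (len(self.cell_ids), self.layout.n_bins):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {self.layout.n_bins} bins"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def total_reads(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset(self, cell_ids: list[str]) -> "CellCounts":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [index[c] for c in cell_ids]
        return CellCounts(list(cell_ids), self.counts[rows], self.layout)


def normalize_bin_widths(counts: np.ndarray, layout: GenomeLayout) -> np.ndarray:
    """Rescale counts to full-bin equivalents.

    The last bin of a chromosome may be shorter than ``bin_size``; dividing
    by the relative width puts all bins on a common per-bp footing so that
    copy-number amplitude is comparable across bins.
    """
    rel_width = layout.bin_widths / layout.bin_size
    return np.asarray(counts, dtype=float) / rel_width


def _gc_fit(
    values: np.ndarray, gc: np.ndarray, n_windows: int, trim: float = 0.3
) -> np.ndarray:
    """Fitted GC effect per bin: local medians over equal-count GC windows,
    linearly interpolated between window centres and clamped at the ends.

    The curve is fitted on approximately-neutral bins only (values within
    ``trim`` of the global median, relative): copy-number-altered regions
    would otherwise drag the window medians toward their own level and
    the correction would compress genuine copy-number amplitude.
    """
    def window_fit(fit_values, fit_gc):
        order = np.argsort(fit_gc, kind="stable")
        splits = np.array_split(order, n_windows)
        centres, medians = [], []
        for idx in splits:
            if len(idx) == 0:
                continue
            centres.append(np.median(fit_gc[idx]))
            medians.append(np.median(fit_values[idx]))
        centres = np.asarray(centres)
        medians = np.asarray(medians)
        # collapse duplicate centres (heavily tied GC values) for np.interp
        uniq, inv = np.unique(centres, return_inverse=True)
        if len(uniq) < len(centres):
            med = np.array([np.median(medians[inv == i]) for i in range(len(uniq))])
            centres, medians = uniq, med
        return np.interp(gc, centres, medians)

    fit = window_fit(values, gc)
    # second pass: refit on approximately-neutral bins only, judged after
    # removing the first-pass curve — copy-number-altered regions would
    # otherwise drag window medians toward their own level and the
    # correction would compress genuine amplitude
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = values / fit
    med = np.nanmedian(ratio)
    neutral = np.abs(ratio - med) <= trim * med
    if neutral.sum() >= max(2 * n_windows, 20):
        fit = window_fit(values[neutral], gc[neutral])
    return fit


def correct_gc(
    counts: CellCounts | np.ndarray,
    track: BinTrack,
    layout: GenomeLayout | None = None,
    n_windows: int = 20,
) -> np.ndarray:
    """GC-correct binned counts, one cell at a time.

    Per cell, a smooth GC-effect curve is fitted as the local median of
    bin values over ``n_windows`` equal-count GC windows (linear
    interpolation in between); values are divided by the fitted curve and
    rescaled so the cell's mean over usable bins is preserved.  Blacklisted
    bins are excluded from the fit and returned as NaN.

    Returns a float matrix (cells x bins) with NaN on blacklisted bins.
    Cells with no usable signal are returned all-NaN with a warning rather
    than raising.
    """
    if isinstance(counts, CellCounts):
        layout = counts.layout
        matrix = counts.counts
    else:
        matrix = np.atleast_2d(np.asarray(counts, dtype=float))
    if layout is not None:
        values = normalize_bin_widths(matrix, layout)
    else:
        values = np.asarray(matrix, dtype=float).copy()
    out = np.full(values.shape, np.nan)
    for i in range(values.shape[0]):
        usable = ~track.blacklisted & np.isfinite(values[i])
        row = values[i, usable]
        if len(row) < n_windows or np.median(row) <= 0:
            warnings.warn(f"cell row {i}: no usable signal for GC correction")
            continue
        fit = _gc_fit(row, track.gc[usable], n_windows)
        fit = np.where(fit <= 0, np.nan, fit)
        corrected = row / fit
        good = np.isfinite(corrected)
        if not good.any():
            warnings.warn(f"cell row {i}: GC fit degenerate")
            continue
        # Rescale so the cell's mean over usable bins is preserved.
        corrected *= row[good].mean() / corrected[good].mean()
        out[i, usable] = corrected
    return out


def correct_mappability(
    values: np.ndarray, track: BinTrack, min_mappability: float = 0.2
) -> np.ndarray:
    """Divide values by per-bin mappability.

    Bins below ``min_mappability`` behave like blacklisted bins and are
    set to NaN (dividing by a tiny alignability would amplify noise more
    than it restores signal).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mapp = np.where(track.mappability < min_mappability, np.nan, track.mappability)
    return np.squeeze(values / mapp)


def spikiness(values: np.ndarray) -> float:
    """Evenness-of-coverage statistic for one cell.

    Defined as the largest absolute deviation of any usable bin value from
    the cell's median, divided by that median.  A perfectly even cell
    scores well below 1; a cell concentrating a large share of its reads
    in a handful of bins scores far above 1.  Scale-free, so it can be
    thresholded identically across sequencing depths.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return np.inf
    med = np.median(values)
    if med <= 0:
        return np.inf
    return float(np.max(np.abs(values - med)) / med)


def filter_cells(
    counts: CellCounts,
    min_reads: int = DEFAULT_MIN_READS,
    max_reads: int = DEFAULT_MAX_READS,
    evenness_stat_max: float = DEFAULT_MAX_SPIKINESS,
    track: BinTrack | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply cell-level QC: read-count range and evenness of coverage.

    A cell is kept iff ``min_reads <= total <= max_reads`` (inclusive on
    both ends) and its spikiness does not exceed ``evenness_stat_max``.
    Spikiness is computed on GC-corrected values when a ``track`` is
    given, otherwise on width-normalised raw counts.

    Returns the kept cell ids (input order preserved) and a per-cell QC
    report with columns cell_id, total_reads, spikiness, kept, reason.
    """
    if min_reads >= max_reads:
        raise ValueError(f"min_reads ({min_reads}) must be < max_reads ({max_reads})")
    totals = counts.total_reads
    if track is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values = correct_gc(counts, track)
    else:
        values = normalize_bin_widths(counts.counts, counts.layout)
    spk = np.array([spikiness(values[i]) for i in range(counts.n_cells)])

    kept, reasons = [], []
    for i in range(counts.n_cells):
        if totals[i] < min_reads:
            reasons.append("low_reads")
        elif totals[i] > max_reads:
            reasons.append("high_reads")
        elif spk[i] > evenness_stat_max:
            reasons.append("uneven_coverage")
        else:
            reasons.append("")
            kept.append(counts.cell_ids[i])
    report = pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "total_reads": totals,
            "spikiness": spk,
            "kept": [int(r == "") for r in reasons],
            "reason": reasons,
        }
    )
    return kept, report
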