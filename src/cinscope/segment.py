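"""E-divisive change-point segmentation and integer copy-number calling.

The segmentation follows the e-divisive scheme: within each chromosome,
candidate change points are found by hierarchical bisection, choosing at
each step the split that maximises the scaled between-sample energy
statistic

    Q(l, r) = (|l||r| / (|l|+|r|)) *
              (2 * mean|x_l - x_r|^alpha
               - mean|x_l - x_l'|^alpha - mean|x_r - x_r'|^alpha)

with the within-sample means taken over unordered pairs (U-statistic
denominators).  A split is accepted when its permutation p-value over
``n_permutations`` random relabelings of the segment is at or below the
significance threshold, and the procedure recurses into both halves.

Integer states are then assigned by a scale-fit over a ploidy grid: for
each candidate ploidy the segment means are rescaled and the state is the
nearest integer; the ploidy minimising the length-weighted rounding error
wins (ties to the lowest ploidy).  This makes state calling scale
invariant and fully deterministic.

Finally, copy-number alterations shorter than a minimum genomic size
(0.8 Mb by default) are reassigned to their flanking segment's state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout

__all__ = [
    "Breakpoints",
    "CopyNumberProfile",
    "edivisive_segment",
    "segment_cell",
    "call_states",
    "filter_small_cnas",
    "DEFAULT_ALPHA",
    "DEFAULT_P_THRESHOLD",
    "DEFAULT_N_PERMUTATIONS",
    "DEFAULT_MIN_SEG_BINS",
    "DEFAULT_PLOIDY_GRID",
    "DEFAULT_MAX_STATE",
    "DEFAULT_MIN_CNA_SIZE",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1.0
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_N_PERMUTATIONS = 199
DEFAULT_MIN_SEG_BINS = 2
DEFAULT_PLOIDY_GRID = np.round(np.arange(1.5, 6.0 + 1e-9, 0.05), 10)
DEFAULT_MAX_STATE = 10
DEFAULT_MIN_CNA_SIZE = 800_000


@dataclass
class Breakpoints:
    """Per-chromosome segment start indices (bin indices, chromosome-local).

    Every chromosome's list starts at 0 and is strictly increasing; an
    entry ``k`` means a new segment starts at the chromosome's ``k``-th bin.
    """

    starts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, s in self.starts.items():
            arr = np.asarray(s, dtype=np.int64)
            if len(arr) == 0 or arr[0] != 0:
                arr = np.concatenate([[0], arr])
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{chrom}: breakpoints must be strictly increasing")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative bin index")
            clean[chrom] = arr
        self.starts = clean

    def n_segments(self) -> int:
        return sum(len(v) for v in self.starts.values())


@dataclass
class CopyNumberProfile:
    """Integer copy-number states per bin for one cell or sample.

    ``states`` is fully filled (masked bins inherit their segment's
    state); ``mask`` marks bins that carry no direct evidence
    (blacklisted / low-mappability) and are excluded from all length
    denominators downstream.  Segment tables and the mean ploidy are
    always derived on demand, never stored.
    """

    states: np.ndarray
    layout: GenomeLayout
    mask: np.ndarray | None = None
    cell_id: str | None = None
    ploidy_fit: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if len(self.states) != self.layout.n_bins:
            raise ValueError("states length must equal the number of bins")
        if np.any(self.states < 0):
            raise ValueError("states must be >= 0")
        if self.mask is None:
            self.mask = np.zeros(self.layout.n_bins, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def mean_ploidy(self) -> float:
        """Length-weighted mean state over non-masked bins."""
        w = self.layout.bin_widths.astype(float)
        w = np.where(self.mask, 0.0, w)
        if w.sum() == 0:
            raise ValueError("profile is fully masked")
        return float((self.states * w).sum() / w.sum())

    def segments(self) -> pd.DataFrame:
        """Maximal constant-state runs per chromosome, BED-like, half-open."""
        rows = []
        for chrom, sl in self.layout.chrom_slices().items():
            s = self.states[sl]
            m = self.mask[sl]
            starts = self.layout.bin_start[sl]
            ends = self.layout.bin_end[sl]
            widths = self.layout.bin_widths[sl]
            run_start = 0
            for i in range(1, len(s) + 1):
                if i == len(s) or s[i] != s[run_start]:
                    valid = ~m[run_start:i]
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(starts[run_start]),
                            "end": int(ends[i - 1]),
                            "state": int(s[run_start]),
                            "n_bins": int(valid.sum()),
                            "length": int(widths[run_start:i][valid].sum()),
                        }
                    )
                    run_start = i
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Energy-statistic machinery
# ---------------------------------------------------------------------------

def _pair_q_from_prefix(P: np.ndarray, min_seg_bins: int) -> np.ndarray:
    """Q for every candidate (split k1, right end k2) from 2-D prefix sums.

    ``P`` is the inclusive 2-D prefix sum of the pairwise distance matrix
    (leading batch dimensions allowed).  Returns an array ``Q[..., k1, k2]``
    over the full index grid, with invalid candidates set to -inf.  The
    left sample is ``x[0:k1]``, the right sample ``x[k1:k2]``; the tail
    beyond ``k2`` takes no part, which is what lets a short interior event
    be isolated against its left flank.  Valid candidates require both
    samples to span at least ``min_seg_bins``.
    """
    n = P.shape[-1]
    k1 = np.arange(1, n + 1)[:, None]  # left sample size
    k2 = np.arange(1, n + 1)[None, :]  # right end (exclusive)
    diag = np.diagonal(P, axis1=-2, axis2=-1)     # P[..., i, i]
    left_block = diag[..., :, None]               # sum over i,j < k1
    cross = P - left_block                        # i < k1 <= j < k2
    right_block = diag[..., None, :] - 2.0 * P + left_block
    m = (k2 - k1).astype(float)
    k = np.broadcast_to(k1, (n, n)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_cross = cross / (k * m)
        mean_wl = np.where(k > 1, left_block / (k * (k - 1) / 2.0), 0.0) / 2.0
        mean_wr = np.where(m > 1, right_block / (m * (m - 1) / 2.0), 0.0) / 2.0
        Q = (k * m / (k + m)) * (2.0 * mean_cross - mean_wl - mean_wr)
    valid = (k1 >= min_seg_bins) & (k2 - k1 >= min_seg_bins) & (k2 <= n)
    return np.where(valid, Q, -np.inf)


def energy_split_statistic(
    x: np.ndarray, alpha: float = DEFAULT_ALPHA, min_seg_bins: int = DEFAULT_MIN_SEG_BINS
) -> np.ndarray:
    """Q over all candidate (k1, k2) pairs of a series.

    Entry ``[k1-1, k2-1]`` scores left sample ``x[:k1]`` against right
    sample ``x[k1:k2]``; invalid pairs are -inf.
    """
    x = np.asarray(x, dtype=float)
    D = np.abs(x[:, None] - x[None, :]) ** alpha
    P = D.cumsum(axis=0).cumsum(axis=1)
    return _pair_q_from_prefix(P, min_seg_bins)


def _best_split(D: np.ndarray, min_seg_bins: int) -> tuple[int | None, int | None, float]:
    """Best candidate change of one segment: argmax over (k1, k2).

    Candidates are scored on the series and on its reversal — a short
    event near the segment start would otherwise be weighted only by its
    few left-flank neighbours — and the boundaries of the winner are
    mapped back to forward coordinates.  Returns the two boundary
    positions (the second equals the segment length when the right
    sample extends to the end) and the maximal Q.  Ties break to the
    forward orientation, then the smallest (k1, k2).
    """
    n = D.shape[0]
    if n < 2 * min_seg_bins:
        return None, None, -np.inf
    P = D.cumsum(axis=0).cumsum(axis=1)
    Q = _pair_q_from_prefix(P, min_seg_bins)
    Prev = D[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)
    Qrev = _pair_q_from_prefix(Prev, min_seg_bins)
    flat_f = int(np.argmax(Q))
    flat_r = int(np.argmax(Qrev))
    qf = float(Q.ravel()[flat_f])
    qr = float(Qrev.ravel()[flat_r])
    if not (np.isfinite(qf) or np.isfinite(qr)):
        return None, None, -np.inf
    if qf >= qr:
        k1, k2 = np.unravel_index(flat_f, Q.shape)
        return int(k1) + 1, int(k2) + 1, qf
    k1r, k2r = np.unravel_index(flat_r, Qrev.shape)
    # reversed sample [k1r+1 left elems | window ending at k2r+1] maps to
    # forward boundaries n-k2r-1 and n-k1r-1
    b1, b2 = n - int(k2r) - 1, n - int(k1r) - 1
    if b1 == 0:
        return b2, n, qr
    return b1, b2, qr


def _permutation_pvalue(
    D: np.ndarray,
    q_obs: float,
    min_seg_bins: int,
    n_permutations: int,
    rng: np.random.Generator,
    chunk: int = 32,
) -> float:
    """Permutation p-value for the best candidate of one segment.

    Observations within the segment are randomly relabelled (the distance
    matrix is re-indexed) and the maximal Q over all (k1, k2) candidates
    is recomputed per permutation; the p-value uses the add-one
    estimator.  Stops early once the p-value can no longer fall below
    0.1 (the test is one-sided and only small p-values are acted on).
    """
    n = D.shape[0]
    exceed = 0
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        Dp = D[perms[:, :, None], perms[:, None, :]]
        P = Dp.cumsum(axis=1).cumsum(axis=2)
        Qp = _pair_q_from_prefix(P, min_seg_bins).reshape(b, -1).max(axis=1)
        Prev = Dp[:, ::-1, ::-1].cumsum(axis=1).cumsum(axis=2)
        Qpr = _pair_q_from_prefix(Prev, min_seg_bins).reshape(b, -1).max(axis=1)
        exceed += int((np.maximum(Qp, Qpr) >= q_obs - 1e-12).sum())
        done += b
        if (1 + exceed) / (n_permutations + 1) > 0.1:
            return (1 + exceed) / (n_permutations + 1)
    return (1 + exceed) / (n_permutations + 1)


def _refine_breakpoints(
    x: np.ndarray,
    D: np.ndarray,
    breakpoints: list[int],
    min_seg_bins: int,
    window: int = 2,
) -> list[int]:
    """Re-localise each breakpoint within +/-``window`` bins.

    The greedy (k1, k2) search can settle a boundary a bin or two off
    under noise; each boundary is polished by maximising the two-sample
    energy statistic of its two flanking segments over nearby positions.
    Deterministic; ties keep the original position.
    """
    bps = sorted(breakpoints)
    n = len(x)
    for idx, b in enumerate(bps):
        a = bps[idx - 1] if idx > 0 else 0
        c = bps[idx + 1] if idx + 1 < len(bps) else n
        lo = max(a + min_seg_bins, b - window)
        hi = min(c - min_seg_bins, b + window)
        if lo > hi:
            continue
        best_b, best_q = b, -np.inf
        for cand in range(lo, hi + 1):
            Dl = D[a:cand, a:cand]
            Dr = D[cand:c, cand:c]
            Dx = D[a:cand, cand:c]
            k, m = cand - a, c - cand
            cross = Dx.mean()
            wl = Dl.sum() / (k * (k - 1)) if k > 1 else 0.0
            wr = Dr.sum() / (m * (m - 1)) if m > 1 else 0.0
            q = (k * m / (k + m)) * (2.0 * cross - wl - wr)
            if q > best_q + 1e-12:
                best_q, best_b = q, cand
        bps[idx] = best_b
    return sorted(set(bps))


def edivisive_segment(
    values: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    seed: int = 0,
) -> np.ndarray:
    """Change points of a single 1-D series (one chromosome).

    Returns sorted segment start indices, always beginning with 0.
    Missing values must be removed by the caller (see
    :func:`segment_cell` for mask handling).
    """
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must lie in (0, 2), got {alpha}")
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("values must be finite; drop missing bins first")
    n = len(x)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E6]))
    breakpoints: list[int] = []
    if n < 2 * min_seg_bins:
        logger.warning("segment of %d bins is too short to split", n)
        return np.array([0], dtype=np.int64)
    D_full = np.abs(x[:, None] - x[None, :]) ** alpha

    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_seg_bins:
            continue
        D = D_full[lo:hi, lo:hi]
        k1, k2, q_obs = _best_split(D, min_seg_bins)
        if k1 is None or q_obs <= 0:
            continue
        p = _permutation_pvalue(D, q_obs, min_seg_bins, n_permutations, rng)
        if p <= p_threshold:
            # the accepted candidate delimits the sample x[k1:k2] against
            # its left flank: both edges are validated boundaries
            breakpoints.append(lo + k1)
            stack.append((lo, lo + k1))
            if k2 < hi - lo:
                breakpoints.append(lo + k2)
                stack.append((lo + k1, lo + k2))
                stack.append((lo + k2, hi))
            else:
                stack.append((lo + k1, hi))
    refined = _refine_breakpoints(x, D_full, breakpoints, min_seg_bins)
    return np.array(sorted({0} | set(refined)), dtype=np.int64)


def segment_cell(
    values: np.ndarray,
    layout: GenomeLayout,
    alpha: float = DEFAULT_ALPHA,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    seed: int = 0,
) -> Breakpoints:
    """Segment one cell's corrected values, chromosome by chromosome.

    ``values`` is the full-genome vector with NaN on masked bins; masked
    bins are dropped before segmentation and breakpoint indices are
    mapped back to genuine bin positions, so a breakpoint never lands
    inside a masked run.  Chromosomes shorter than ``2 * min_seg_bins``
    usable bins are left unsegmented with a warning.

    Each chromosome gets its own RNG stream derived from ``seed`` and
    the chromosome index, keeping results independent of execution
    order.
    """
    values = np.asarray(values, dtype=float)
    starts: dict[str, np.ndarray] = {}
    for ci, (chrom, sl) in enumerate(layout.chrom_slices().items()):
        v = values[sl]
        valid = np.flatnonzero(np.isfinite(v))
        if len(valid) < 2 * min_seg_bins:
            if len(v) >= 2 * min_seg_bins:
                logger.warning("%s: only %d usable bins, not segmented", chrom, len(valid))
            starts[chrom] = np.array([0], dtype=np.int64)
            continue
        bp_local = edivisive_segment(
            v[valid],
            alpha=alpha,
            p_threshold=p_threshold,
            n_permutations=n_permutations,
            min_seg_bins=min_seg_bins,
            seed=int(np.random.SeedSequence([seed, ci]).generate_state(1)[0] % (2**31)),
        )
        starts[chrom] = np.unique(np.concatenate([[0], valid[bp_local]]))
    return Breakpoints(starts)


# ---------------------------------------------------------------------------
# Integer state assignment
# ---------------------------------------------------------------------------

def call_states(
    values: np.ndarray,
    breakpoints: Breakpoints,
    layout: GenomeLayout,
    ploidy_grid: np.ndarray = DEFAULT_PLOIDY_GRID,
    max_state: int = DEFAULT_MAX_STATE,
    cell_id: str | None = None,
) -> CopyNumberProfile:
    """Assign integer copy-number states to segments by a ploidy scale-fit.

    For each candidate ploidy ``f`` the segment means are rescaled by
    ``c = f / (length-weighted mean of segment means)`` and the
    length-weighted distance of ``c * m_s`` to the nearest integers is
    accumulated; the ploidy with the smallest error wins, ties going to
    the lowest ploidy.  States are the rounded rescaled means, clipped to
    ``[0, max_state]``.  Masked (NaN) bins inherit their segment's state
    and are flagged in the profile mask.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isfinite(values)
    if mask.all():
        raise ValueError("all bins are missing; cannot call states")
    seg_mean, seg_len, seg_slices = [], [], []
    slices = layout.chrom_slices()
    for chrom, bp in breakpoints.starts.items():
        sl = slices[chrom]
        v = values[sl]
        w = layout.bin_widths[sl].astype(float)
        edges = list(bp) + [sl.stop - sl.start]
        for a, b in zip(edges[:-1], edges[1:]):
            seg = v[a:b]
            wseg = w[a:b]
            good = np.isfinite(seg)
            seg_slices.append((sl.start + a, sl.start + b))
            if good.any():
                seg_mean.append(float(np.average(seg[good], weights=wseg[good])))
                seg_len.append(float(wseg[good].sum()))
            else:
                seg_mean.append(np.nan)
                seg_len.append(0.0)
    seg_mean = np.asarray(seg_mean)
    seg_len = np.asarray(seg_len)
    good = np.isfinite(seg_mean) & (seg_len > 0)
    wmean = float(np.average(seg_mean[good], weights=seg_len[good]))
    if wmean <= 0:
        raise ValueError("non-positive mean signal; cannot call states")

    grid = np.asarray(ploidy_grid, dtype=float)
    m = seg_mean[good]
    w = seg_len[good]
    c0 = grid[:, None] / wmean
    n_cand = np.clip(np.round(c0 * m[None, :]), 0, max_state)  # (n_f, n_seg)
    # refit the scale to each integer assignment: grid quantisation must
    # not decide between integer-rescaled aliases such as 2/4 vs 3/6
    denom_ls = (w * m * m).sum()
    c_ls = (n_cand * (w * m)[None, :]).sum(axis=1) / denom_ls
    err = (np.abs(c_ls[:, None] * m[None, :] - n_cand) * w[None, :]).sum(axis=1)
    # a candidate is only admissible if the ploidy it implies matches it:
    # otherwise the grid's lower bound could be bypassed by rescaling
    implied = (n_cand * w[None, :]).sum(axis=1) / w.sum()
    err = np.where(np.abs(implied - grid) <= 0.5 + 1e-9, err, np.inf)
    if not np.isfinite(err).any():
        raise ValueError("no admissible ploidy in the grid for this profile")
    best = int(np.argmin(err))  # first minimum = lowest admissible ploidy
    f = float(implied[best])
    states_seg = np.full(len(seg_mean), np.nan)
    states_seg[good] = n_cand[best]

    states = np.zeros(layout.n_bins, dtype=np.int64)
    for (a, b), s in zip(seg_slices, states_seg):
        states[a:b] = 0 if np.isnan(s) else int(s)
    return CopyNumberProfile(states, layout, mask=mask, cell_id=cell_id, ploidy_fit=f)


# ---------------------------------------------------------------------------
# Minimum CNA size filter
# ---------------------------------------------------------------------------

def filter_small_cnas(
    profile: CopyNumberProfile, min_size: int = DEFAULT_MIN_CNA_SIZE
) -> CopyNumberProfile:
    """Remove copy-number alterations spanning less than ``min_size`` bp.

    A maximal constant-state run shorter than ``min_size`` whose state
    differs from both flanking runs is reassigned to the longer flank's
    state (ties to the left flank); a short run at a chromosome end takes
    its single neighbour's state.  Applied to fixpoint, so the output has
    no sub-threshold alterations left.
    """
    states = profile.states.copy()
    widths = profile.layout.bin_widths
    for chrom, sl in profile.layout.chrom_slices().items():
        s = states[sl]
        w = widths[sl]
        changed = True
        while changed:
            changed = False
            # run-length encode
            bounds = [0] + list(np.flatnonzero(np.diff(s)) + 1) + [len(s)]
            runs = list(zip(bounds[:-1], bounds[1:]))
            if len(runs) == 1:
                break
            lengths = [int(w[a:b].sum()) for a, b in runs]
            for ri, ((a, b), length) in enumerate(zip(runs, lengths)):
                if length >= min_size:
                    continue
                if ri == 0:
                    s[a:b] = s[runs[1][0]]
                elif ri == len(runs) - 1:
                    s[a:b] = s[runs[ri - 1][0]]
                else:
                    left_len = lengths[ri - 1]
                    right_len = lengths[ri + 1]
                    src = runs[ri - 1] if left_len >= right_len else runs[ri + 1]
                    s[a:b] = s[src[0]]
                changed = True
                break  # re-encode runs after each merge
        states[sl] = s
    return CopyNumberProfile(
        states, profile.layout, mask=profile.mask.copy(),
        cell_id=profile.cell_id, ploidy_fit=profile.ploidy_fit,
    )
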