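"""Copy-number phylogenetics: shared segmentation, event distances, clades.

To cluster cells by their copy-number profiles the module:

1. builds the **minimum consistent segmentation** (MCS) of a population —
   the fewest shared segments that exactly represent every cell's per-bin
   states (boundaries are placed exactly where at least one cell changes
   state, which is provably minimal and lossless);
2. computes the pairwise **minimum event distance** on total copy
   numbers: the smallest number of segmental events, each adding +1 or -1
   to one contiguous run of segments within a chromosome, needed to turn
   one profile into another.  States can never go below zero and a
   segment at state 0 can never be changed again, so the distance is
   directed; it is symmetrised as the minimum of the two directions.  A
   pair is flagged *blocked* when neither direction is feasible (both
   profiles have a zero where the other is non-zero);
3. builds a **neighbor-joining tree** from the distance matrix and cuts
   it into k clades by removing the k-1 longest internal branches (k
   either fixed or chosen by silhouette score over 2..8);
4. forms **pseudobulk** profiles by summing raw counts over a cell
   subset (typically a clade) and re-running the correction /
   segmentation / state-calling path at purity 1.

The ±1-run event distance is a single-step approximation: it has no
whole-genome-doubling event, so genome-doubled cells legitimately appear
as a distant clade rather than one WGD step away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .genome import BinTrack, GenomeLayout
from .heterogeneity import CellPopulation
from .qc import CellCounts, correct_gc, correct_mappability
from .segment import CopyNumberProfile, call_states, filter_small_cnas, segment_cell

__all__ = [
    "ConsistentSegmentation",
    "EventDistanceMatrix",
    "minimum_consistent_segmentation",
    "event_distance",
    "event_distance_matrix",
    "build_tree",
    "pseudobulk",
    "pseudobulk_profile",
]


@dataclass
class ConsistentSegmentation:
    """Shared segment boundaries and the cells x segments state matrix.

    ``segments`` has columns chrom, start, end (bp, half-open) and
    n_bins; ``states[i, s]`` is cell i's state on shared segment s.
    Expanding each segment back to its bins reproduces every input
    profile exactly.
    """

    segments: pd.DataFrame
    states: np.ndarray
    cell_ids: list[str]
    layout: GenomeLayout

    @property
    def segment_chrom(self) -> np.ndarray:
        return self.segments["chrom"].to_numpy()

    def expand(self, cell_index: int) -> np.ndarray:
        """Reconstruct one cell's per-bin states from the shared segments."""
        out = np.empty(self.layout.n_bins, dtype=np.int64)
        slices = self.layout.chrom_slices()
        for s, (_, row) in enumerate(self.segments.iterrows()):
            sl = slices[row["chrom"]]
            sel = (self.layout.bin_start[sl] >= row["start"]) & (
                self.layout.bin_start[sl] < row["end"]
            )
            out[sl.start + np.flatnonzero(sel)] = self.states[cell_index, s]
        return out


@dataclass
class EventDistanceMatrix:
    """Symmetric minimum-event distances between cells, with blocked flags."""

    distances: np.ndarray
    cell_ids: list[str]
    blocked: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        self.distances = d

    def to_skbio(self) -> DistanceMatrix:
        return DistanceMatrix(self.distances, ids=self.cell_ids)


def minimum_consistent_segmentation(population: CellPopulation) -> ConsistentSegmentation:
    """Fewest shared segments that exactly represent every cell.

    A boundary is placed before a bin iff at least one cell changes state
    there.  Any consistent segmentation must contain those boundaries
    (dropping one would merge bins on which some cell differs), and
    adding none keeps every pair of adjacent shared segments different in
    at least one cell — so the result is exactly the minimal consistent
    segmentation.
    """
    layout = population.layout
    states = np.stack([p.states for p in population.profiles])  # (cells, bins)
    rows = []
    seg_states: list[np.ndarray] = []
    for chrom, sl in layout.chrom_slices().items():
        block = states[:, sl]
        n = block.shape[1]
        change = np.any(block[:, 1:] != block[:, :-1], axis=0)
        bounds = [0] + list(np.flatnonzero(change) + 1) + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(layout.bin_start[sl.start + a]),
                    "end": int(layout.bin_end[sl.start + b - 1]),
                    "n_bins": b - a,
                }
            )
            seg_states.append(block[:, a])
    return ConsistentSegmentation(
        segments=pd.DataFrame(rows),
        states=np.stack(seg_states, axis=1),
        cell_ids=population.cell_ids(),
        layout=layout,
    )


def _directed_event_count(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum events to turn ``a`` into ``b`` within one chromosome.

    Closed form on the difference profile: with gains
    ``g_i = max(b_i - a_i, 0)`` and losses ``l_i = max(a_i - b_i, 0)``,
    the cost is ``sum_i max(0, g_i - g_{i-1}) + max(0, l_i - l_{i-1})``
    (boundary g_0 = l_0 = 0) — every unit increase in the requirement
    profile opens a new event, exactly as in the skyline problem.
    Positions where ``a`` is 0 can never be covered by an event; they
    force ``g = l = 0`` there, splitting runs, and make the direction
    infeasible (inf) when ``b`` is non-zero at such a position.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if np.any((a == 0) & (b != 0)):
        return np.inf
    diff = b - a
    g = np.maximum(diff, 0)
    l = np.maximum(-diff, 0)
    cost = np.maximum(0, np.diff(g, prepend=0)).sum()
    cost += np.maximum(0, np.diff(l, prepend=0)).sum()
    return float(cost)


def event_distance(
    a: np.ndarray,
    b: np.ndarray,
    chrom_labels: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Symmetrised minimum event distance between two total-CN vectors.

    Computed per chromosome (events never span chromosomes) and summed;
    the two directed distances are symmetrised as their minimum because a
    zero state is absorbing, making the relation asymmetric.  Returns
    ``(distance, blocked)``: when both directions are infeasible the
    distance falls back to the skyline cost with the zero-absorption
    constraint lifted, and ``blocked`` is True.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("state vectors must have equal length")
    if chrom_labels is None:
        chrom_labels = np.zeros(len(a), dtype=np.int64)
    chrom_labels = np.asarray(chrom_labels)
    d_ab = d_ba = 0.0
    for c in pd.unique(chrom_labels):
        sel = chrom_labels == c
        d_ab += _directed_event_count(a[sel], b[sel])
        d_ba += _directed_event_count(b[sel], a[sel])
    d = min(d_ab, d_ba)
    if np.isinf(d):
        # both directions blocked by opposing zero states; report the
        # unconstrained skyline cost with a flag
        diff = (b - a).astype(np.int64)
        cost = 0.0
        for c in pd.unique(chrom_labels):
            dd = diff[chrom_labels == c]
            g = np.maximum(dd, 0)
            l = np.maximum(-dd, 0)
            cost += np.maximum(0, np.diff(g, prepend=0)).sum()
            cost += np.maximum(0, np.diff(l, prepend=0)).sum()
        return float(cost), True
    return float(d), False


def event_distance_matrix(segmentation: ConsistentSegmentation) -> EventDistanceMatrix:
    """All pairwise event distances on a shared segmentation."""
    states = segmentation.states
    chroms = segmentation.segment_chrom
    n = states.shape[0]
    dist = np.zeros((n, n))
    blocked = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d, blk = event_distance(states[i], states[j], chroms)
            dist[i, j] = dist[j, i] = d
            blocked[i, j] = blocked[j, i] = blk
    return EventDistanceMatrix(dist, segmentation.cell_ids, blocked)


# ---------------------------------------------------------------------------
# Tree building and clade assignment
# ---------------------------------------------------------------------------

def _tree_cut(tree: TreeNode, cell_ids: list[str], k: int) -> list[int]:
    """Cut a tree into k groups by removing the k-1 longest internal branches.

    Ties are broken deterministically by the lexicographically smallest
    tip name below the branch; leaves always stay attached through their
    terminal branch, so every group is a connected clade of the tree.
    """
    tree = tree.copy()
    internal = [
        node
        for node in tree.non_tips(include_self=False)
        if node.length is not None
    ]
    order = {c: i for i, c in enumerate(cell_ids)}
    internal.sort(
        key=lambda nd: (
            -(nd.length or 0.0),
            min(order[t.name] for t in nd.tips()),
        )
    )
    cut = internal[: max(0, k - 1)]
    cut_set = set(id(nd) for nd in cut)
    # union-find over tips: tips in the same component share all
    # non-removed edges on their path; label by walking from each tip up
    # to the first removed edge or root.
    labels: dict[str, int] = {}
    next_label = 0
    component_of_node: dict[int, int] = {}

    def component(node) -> int:
        nonlocal next_label
        path = []
        cur = node
        while cur is not None:
            if id(cur) in component_of_node:
                base = component_of_node[id(cur)]
                break
            path.append(cur)
            if id(cur) in cut_set or cur.parent is None:
                base = next_label
                next_label += 1
                break
            cur = cur.parent
        for nd in path:
            component_of_node[id(nd)] = base
        return base

    for tip in tree.tips():
        labels[tip.name] = component(tip)
    # relabel components in cell-id order for determinism
    remap: dict[int, int] = {}
    out = []
    for cid in cell_ids:
        c = labels[cid]
        if c not in remap:
            remap[c] = len(remap)
        out.append(remap[c])
    return out


def build_tree(
    distances: EventDistanceMatrix,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
) -> tuple[TreeNode, list[int], int]:
    """Neighbor-joining tree plus clade assignment.

    ``k`` fixes the number of clades; when None, k is chosen by the best
    silhouette score of the tree-cut partitions over ``k_range`` (ties to
    the smallest k).  Negative NJ branch lengths (possible for
    non-additive matrices) are clamped to zero before cutting.

    Returns ``(tree, clade_labels, k_used)`` with labels aligned to
    ``distances.cell_ids``.
    """
    from sklearn.metrics import silhouette_score

    dm = distances.to_skbio()
    tree = nj(dm)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    ids = distances.cell_ids
    if k is not None:
        labels = _tree_cut(tree, ids, k)
        return tree, labels, k
    best_k, best_score, best_labels = None, -np.inf, None
    for kk in range(k_range[0], min(k_range[1], len(ids) - 1) + 1):
        labels = _tree_cut(tree, ids, kk)
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(distances.distances, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = kk, score, labels
    if best_labels is None:  # degenerate matrix: a single clade
        return tree, [0] * len(ids), 1
    return tree, best_labels, best_k


# ---------------------------------------------------------------------------
# Pseudobulk
# ---------------------------------------------------------------------------

def pseudobulk(counts: CellCounts, cell_subset: list[str]) -> np.ndarray:
    """Bin-wise sum of raw counts over a subset of cells."""
    if not cell_subset:
        raise ValueError("cell subset must not be empty")
    index = {c: i for i, c in enumerate(counts.cell_ids)}
    rows = [index[c] for c in cell_subset]
    return counts.counts[rows].sum(axis=0)


def pseudobulk_profile(
    counts: CellCounts,
    cell_subset: list[str],
    track: BinTrack,
    seed: int = 0,
    min_cna_size: int | None = None,
    **segment_kwargs,
) -> CopyNumberProfile:
    """Merged-count profile of a cell subset, called like a pure sample.

    Sums raw counts over the subset, applies GC and mappability
    correction, segments, and calls integer states (purity 1: cell lines
    and clades are pure tumour).  ``segment_kwargs`` pass through to
    :func:`cinscope.segment.segment_cell`.
    """
    from .segment import DEFAULT_MIN_CNA_SIZE

    layout = counts.layout
    summed = pseudobulk(counts, cell_subset)
    from .qc import normalize_bin_widths

    values = normalize_bin_widths(summed[None, :], layout)
    values = np.atleast_2d(correct_mappability(values, track))
    corrected = np.atleast_2d(correct_gc(values, track))[0]
    bp = segment_cell(corrected, layout, seed=seed, **segment_kwargs)
    profile = call_states(corrected, bp, layout, cell_id="pseudobulk")
    size = DEFAULT_MIN_CNA_SIZE if min_cna_size is None else min_cna_size
    return filter_small_cnas(profile, min_size=size)
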