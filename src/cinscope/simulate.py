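"""Synthetic single-cell and bulk copy-number datasets with known truth.

This module emulates the two kinds of input the analysis pipeline
consumes, at desk scale and with full ground truth attached:

* **Single-cell counts** in the DLP+ regime: hundreds of cells over 500 kb
  bins, 0.5-3 million reads per cell at full genome size (scaled down with
  the genome), a clonal substructure of shared and private copy-number
  events, optional whole-genome doubling of chosen clones, GC bias,
  overdispersed counts, and a fraction of dropout cells emitted below the
  minimum read count.
* **Low-pass bulk counts** as tumour/normal mixtures: expected signal per
  bin follows ``rho * state + 2 * (1 - rho)`` for tumour fraction
  (cellularity) ``rho``, with optional extra bin-level noise for FFPE
  material, and focal amplifications/deletions injected over known genes.

Counts are drawn as Dirichlet-multinomial: the per-cell total is fixed
inside the configured read range and allocated to bins with
negative-binomial-type overdispersion around the proportionality law.
This keeps per-cell totals exactly inside their range (dropouts excepted)
while matching the empirical variance of single-cell bin counts better
than a multinomial.

Every generator is deterministic given its seed, and every dataset
carries its truth (clone profiles, cell labels, event logs) for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinTrack, GenomeLayout
from .qc import CellCounts

__all__ = [
    "CloneSpec",
    "NoiseModel",
    "simulate_bin_track",
    "simulate_clones",
    "simulate_cell_counts",
    "simulate_bulk",
    "simulate_tumour_profile",
    "balanced_tumour_profile",
    "high_amplitude_tumour_profile",
    "inject_focal_events",
    "simulate_gene_bed",
    "DEFAULT_CIN_GENES",
]

# Cancer genes the focal-event screen flags as chromosomal-instability
# associated by default (overridable via configuration).
DEFAULT_CIN_GENES = ("CCNE1", "BRCA1", "MDM2", "KRAS", "CDK6", "CDK13")


@dataclass(frozen=True)
class CloneSpec:
    """One simulated clone: an integer copy-number profile plus metadata.

    ``events`` records every segmental event applied (phase "shared" or
    "private", chromosome, bin span, +/-1 delta) so a test can replay the
    history independently; ``wgd`` marks clones whose genome was doubled
    after the shared events and before the private ones.
    """

    clone_id: str
    profile: np.ndarray
    proportion: float
    wgd: bool = False
    events: tuple[tuple, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        profile = np.asarray(self.profile, dtype=np.int64)
        object.__setattr__(self, "profile", profile)
        if np.any(profile < 0):
            raise ValueError("copy-number states must be >= 0")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("clone proportion must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Noise regime for count simulation.

    Parameters
    ----------
    reads_per_cell:
        (min, max) target total reads for a non-dropout cell.  Defaults to
        the 0.5-3 million single-cell window scaled to a 1/5 genome.
    gc_bias_coeffs:
        Quadratic coefficients (c0, c1, c2) of the GC effect
        ``c0 + c1*gc + c2*gc**2``, normalised to mean 1 over bins when
        applied.  The default is a mild concave bias peaking near GC 0.5.
    overdispersion:
        Dirichlet concentration per expected read; smaller means noisier
        counts (negative-binomial-like with variance ``mu * (1 + mu_bar /
        overdispersion)``).  Must be > 0.
    dropout_rate:
        Fraction of cells emitted with totals below the minimum read
        count, emulating empty wells and failed libraries.
    ffpe_noise_sd:
        Log-normal sd of extra multiplicative bin-level noise for FFPE
        bulk material; 0 disables it.
    """

    reads_per_cell: tuple[int, int] = (100_000, 600_000)
    gc_bias_coeffs: tuple[float, float, float] = (-0.8, 8.0, -8.0)
    overdispersion: float = 150.0
    dropout_rate: float = 0.13
    ffpe_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.reads_per_cell
        if not lo < hi:
            raise ValueError("reads_per_cell must satisfy min < max")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    def gc_effect(self, gc: np.ndarray) -> np.ndarray:
        """Quadratic GC effect, clipped positive and normalised to mean 1."""
        c0, c1, c2 = self.gc_bias_coeffs
        if c0 == c1 == c2 == 0:
            return np.ones_like(np.asarray(gc, dtype=float))
        effect = c0 + c1 * gc + c2 * gc**2
        effect = np.clip(effect, 0.05, None)
        return effect / effect.mean()


def simulate_bin_track(
    layout: GenomeLayout,
    seed: int,
    gc_range: tuple[float, float] = (0.32, 0.60),
    blacklist_fraction: float = 0.02,
    low_mappability_fraction: float = 0.03,
) -> BinTrack:
    """Synthetic GC/mappability/blacklist annotation for a layout.

    GC varies smoothly along each chromosome (a smoothed random walk
    rescaled into ``gc_range``), mimicking isochore-scale GC structure; a
    small fraction of bins is blacklisted and another small fraction gets
    reduced mappability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB17]))
    n = layout.n_bins
    gc = np.empty(n)
    for sl in layout.chrom_slices().values():
        m = sl.stop - sl.start
        walk = np.cumsum(rng.normal(size=m + 8))
        kernel = np.ones(5) / 5
        smooth = np.convolve(walk, kernel, mode="valid")[:m]
        lo, hi = smooth.min(), smooth.max()
        span = hi - lo if hi > lo else 1.0
        gc[sl] = gc_range[0] + (smooth - lo) / span * (gc_range[1] - gc_range[0])
    mappability = np.ones(n)
    n_low = int(round(low_mappability_fraction * n))
    low = rng.choice(n, size=n_low, replace=False)
    mappability[low] = rng.uniform(0.5, 0.95, size=n_low)
    blacklisted = np.zeros(n, dtype=bool)
    n_black = int(round(blacklist_fraction * n))
    blacklisted[rng.choice(n, size=n_black, replace=False)] = True
    return BinTrack(gc=gc, mappability=mappability, blacklisted=blacklisted)


def _draw_event(
    rng: np.random.Generator,
    layout: GenomeLayout,
    event_length_range: tuple[int, int],
) -> tuple[str, int, int, int]:
    """One segmental event: (chrom, first bin, last bin + 1, delta).

    The chromosome is chosen with probability proportional to its length
    and the event is placed uniformly inside it; events never cross a
    chromosome boundary.  Lengths are drawn in bp and snapped to whole
    bins (at least one).
    """
    lo, hi = event_length_range
    longest = max(length for _, length in layout.chromosomes)
    if lo > longest:
        raise ValueError(
            f"event length {lo} exceeds the longest chromosome ({longest} bp)"
        )
    slices = layout.chrom_slices()
    # only chromosomes long enough to host the event, weighted by length
    names = [c for c in layout.chrom_names if layout.chrom_lengths[c] >= lo]
    lengths = np.array([layout.chrom_lengths[c] for c in names], dtype=float)
    while True:
        chrom = names[rng.choice(len(names), p=lengths / lengths.sum())]
        sl = slices[chrom]
        n_bins_chrom = sl.stop - sl.start
        length_bp = rng.uniform(lo, min(hi, layout.chrom_lengths[chrom]))
        n_bins_event = max(1, int(round(length_bp / layout.bin_size)))
        if n_bins_event > n_bins_chrom:
            continue  # reject events that would cross the boundary
        start = int(rng.integers(0, n_bins_chrom - n_bins_event + 1))
        delta = int(rng.choice([-1, 1]))
        return chrom, start, start + n_bins_event, delta


def _draw_spaced_events(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n_events: int,
    event_length_range: tuple[int, int],
    used_edges: set[tuple[str, int]],
    spacing_bins: int,
    edge_margin_bins: int = 2,
    max_tries: int = 200,
) -> list[tuple[str, int, int, int]]:
    """Draw events whose breakpoints keep a minimum spacing.

    Rejects candidates whose edges fall within ``spacing_bins`` bins of a
    previously placed edge on the same chromosome, or whose *internal*
    edges sit closer than ``edge_margin_bins`` to a chromosome end
    (events may still start or end exactly at a telomere).  At 500 kb
    resolution real chromosomes span hundreds of bins and essentially
    never stack breakpoints into adjacent bins nor within a bin or two
    of the telomere; on a shrunken genome rejection sampling is needed
    to keep those properties true.  ``used_edges`` is updated in place.
    """
    slices = layout.chrom_slices()
    events = []
    for _ in range(n_events):
        for _try in range(max_tries):
            chrom, lo, hi, delta = _draw_event(rng, layout, event_length_range)
            n_chrom = slices[chrom].stop - slices[chrom].start
            if 0 < lo < edge_margin_bins or n_chrom - edge_margin_bins < lo:
                continue
            if hi < n_chrom and not (edge_margin_bins <= hi <= n_chrom - edge_margin_bins):
                continue
            edges = [(chrom, lo), (chrom, hi)]
            clash = any(
                c == uc and abs(e - ue) < spacing_bins
                for c, e in edges
                for uc, ue in used_edges
            )
            if not clash:
                break
        else:
            raise RuntimeError(
                "could not place events with the requested breakpoint spacing"
            )
        used_edges.update(edges)
        events.append((chrom, lo, hi, delta))
    return events


def apply_events(
    profile: np.ndarray,
    events,
    layout: GenomeLayout,
    max_state: int,
) -> np.ndarray:
    """Replay a list of (chrom, lo, hi, delta) events onto a profile."""
    out = np.asarray(profile, dtype=np.int64).copy()
    slices = layout.chrom_slices()
    for chrom, lo, hi, delta in events:
        sl = slices[chrom]
        out[sl.start + lo : sl.start + hi] += delta
    return np.clip(out, 0, max_state)


def simulate_clones(
    genome: GenomeLayout,
    n_clones: int,
    n_shared_events: int = 5,
    n_private_events: int = 5,
    event_length_range: tuple[int, int] = (2_000_000, 6_000_000),
    wgd_clones: set[str] | None = None,
    max_state: int = 10,
    proportions: list[float] | None = None,
    breakpoint_spacing_bins: int = 3,
    seed: int = 0,
) -> list[CloneSpec]:
    """Simulate a clonal population of integer copy-number profiles.

    All clones descend from a diploid ancestor carrying the shared events;
    clones named in ``wgd_clones`` then have their genome doubled, and
    each clone finally acquires its own private events.  States are
    clipped to ``[0, max_state]``.  Breakpoints within one lineage keep a
    spacing of ``breakpoint_spacing_bins`` bins so events stay resolvable
    at the binned resolution.  Event order and placement are fully
    reproducible from ``seed``; every applied event is logged on the
    clone so tests can replay the history.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if event_length_range[0] < genome.bin_size:
        raise ValueError("event lengths must be at least one bin")
    wgd_clones = set(wgd_clones or ())
    if proportions is None:
        proportions = [1.0 / n_clones] * n_clones
    if len(proportions) != n_clones or abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("clone proportions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC104E]))

    shared_edges: set[tuple[str, int]] = set()
    shared = _draw_spaced_events(
        rng, genome, n_shared_events, event_length_range, shared_edges,
        breakpoint_spacing_bins,
    )
    ancestor = apply_events(np.full(genome.n_bins, 2), shared, genome, max_state)

    clones: list[CloneSpec] = []
    for i in range(n_clones):
        clone_id = f"clone{i}"
        profile = ancestor.copy()
        wgd = clone_id in wgd_clones
        if wgd:
            profile = np.clip(profile * 2, 0, max_state)
        private = _draw_spaced_events(
            rng, genome, n_private_events, event_length_range, set(shared_edges),
            breakpoint_spacing_bins,
        )
        profile = apply_events(profile, private, genome, max_state)
        events = tuple(
            [("shared",) + ev for ev in shared] + [("private",) + ev for ev in private]
        )
        clones.append(
            CloneSpec(clone_id, profile, float(proportions[i]), wgd=wgd, events=events)
        )
    return clones


def _expected_weights(
    state: np.ndarray, layout: GenomeLayout, noise: NoiseModel, track: BinTrack
) -> np.ndarray:
    """Unnormalised expected read weight per bin under the count model."""
    widths = layout.bin_widths / layout.bin_size
    return state * widths * noise.gc_effect(track.gc) * track.mappability


def _dirichlet_multinomial(
    rng: np.random.Generator, total: int, p: np.ndarray, overdispersion: float
) -> np.ndarray:
    """Overdispersed allocation of ``total`` reads to bins with mean p*total."""
    alpha = overdispersion * len(p) * p
    alpha = np.clip(alpha, 1e-9, None)
    q = rng.dirichlet(alpha)
    return rng.multinomial(total, q)


def simulate_cell_counts(
    clones: list[CloneSpec],
    n_cells: int,
    noise: NoiseModel,
    bin_track: BinTrack,
    layout: GenomeLayout,
    seed: int = 0,
) -> tuple[CellCounts, pd.DataFrame]:
    """Simulate binned read counts for single cells drawn from clones.

    Each cell is assigned a clone with probability equal to the clone
    proportion; its expected count per bin is proportional to copy state
    x bin width x GC effect x mappability, scaled so the total drawn lies
    uniformly in the configured read range.  A ``dropout_rate`` fraction
    of cells is emitted far below the minimum read count (0.1-30% of the
    minimum), emulating empty wells and failed libraries.

    Each cell draws its counts from a dedicated RNG stream derived from
    the global seed and the cell index, so results do not depend on
    evaluation order.

    Returns the counts and a truth table with columns cell_id, clone_id,
    dropout, target_reads.
    """
    if not clones:
        raise ValueError("clone list must not be empty")
    props = np.array([c.proportion for c in clones])
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("clone proportions must sum to 1")
    root = np.random.SeedSequence([seed, 0xCE11])
    rng = np.random.default_rng(root)
    lo, hi = noise.reads_per_cell

    assignments = rng.choice(len(clones), size=n_cells, p=props)
    dropouts = rng.random(n_cells) < noise.dropout_rate

    weights = {
        c.clone_id: _expected_weights(c.profile, layout, noise, bin_track) for c in clones
    }
    counts = np.zeros((n_cells, layout.n_bins), dtype=np.int64)
    cell_ids, truth_rows = [], []
    for i in range(n_cells):
        cell_id = f"cell{i:04d}"
        cell_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCE11, i]))
        clone = clones[assignments[i]]
        if dropouts[i]:
            target = int(cell_rng.uniform(0.001 * lo, 0.3 * lo))
        else:
            target = int(cell_rng.integers(lo, hi + 1))
        w = weights[clone.clone_id]
        if w.sum() <= 0:
            raise ValueError(f"clone {clone.clone_id} has zero total expected signal")
        counts[i] = _dirichlet_multinomial(cell_rng, target, w / w.sum(), noise.overdispersion)
        cell_ids.append(cell_id)
        truth_rows.append(
            {
                "cell_id": cell_id,
                "clone_id": clone.clone_id,
                "dropout": int(dropouts[i]),
                "target_reads": target,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return CellCounts(cell_ids, counts, layout), truth


def simulate_bulk(
    tumour_profile: np.ndarray,
    cellularity: float,
    total_reads: int,
    noise: NoiseModel,
    bin_track: BinTrack,
    layout: GenomeLayout,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a bulk tumour/normal mixture as binned read counts.

    The expected count per bin follows the mixture law
    ``rho * state + 2 * (1 - rho)`` for cellularity ``rho`` against a
    diploid normal background, modulated by bin width, GC effect and
    mappability.  If ``noise.ffpe_noise_sd > 0``, extra multiplicative
    log-normal noise per bin emulates the degraded, wavier coverage of
    FFPE material.
    """
    if not 0.0 < cellularity <= 1.0:
        raise ValueError(f"cellularity must lie in (0, 1], got {cellularity}")
    state = np.asarray(tumour_profile, dtype=float)
    if len(state) != layout.n_bins:
        raise ValueError("tumour profile length must equal the number of bins")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB011]))
    mixture = cellularity * state + 2.0 * (1.0 - cellularity)
    w = _expected_weights(mixture, layout, noise, bin_track)
    if noise.ffpe_noise_sd > 0:
        w = w * rng.lognormal(mean=0.0, sigma=noise.ffpe_noise_sd, size=len(w))
    return _dirichlet_multinomial(rng, int(total_reads), w / w.sum(), noise.overdispersion)


def simulate_tumour_profile(
    layout: GenomeLayout,
    seed: int = 0,
    p_chrom_alteration: float = 0.4,
    n_segmental_events: int = 6,
    event_length_range: tuple[int, int] = (4_000_000, 20_000_000),
    max_state: int = 6,
) -> np.ndarray:
    """One bulk tumour copy-number profile with chromosome- and arm-level CNAs.

    Each chromosome is whole-chromosome altered (state 1 or 3, equal
    odds) with probability ``p_chrom_alteration``; ``n_segmental_events``
    sub-chromosomal +/-1 events are then layered on top, emulating the
    mixed whole- and subchromosomal alteration landscape of low-pass
    tumour genomes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x70B0]))
    profile = np.full(layout.n_bins, 2, dtype=np.int64)
    for _, sl in layout.chrom_slices().items():
        if rng.random() < p_chrom_alteration:
            profile[sl] = int(rng.choice([1, 3]))
    events = [
        _draw_event(rng, layout, event_length_range) for _ in range(n_segmental_events)
    ]
    return apply_events(profile, events, layout, max_state)


def balanced_tumour_profile(
    layout: GenomeLayout,
    gain_states: tuple[int, ...] = (3, 4, 5),
    loss_states: tuple[int, ...] = (1, 0),
) -> np.ndarray:
    """A high-contrast tumour profile with mean ploidy balanced to ~2.

    Assigns whole-chromosome gains (states from ``gain_states``) to the
    largest chromosomes, then greedily assigns whole-chromosome losses to
    later chromosomes so the length-weighted mean state returns as close
    to 2 as whole-chromosome moves allow.  Deterministic, no RNG; used to
    validate purity/ploidy fitting where many distinct states and a known
    ploidy are required.
    """
    profile = np.full(layout.n_bins, 2, dtype=np.int64)
    slices = layout.chrom_slices()
    names = layout.chrom_names
    weights = {c: slices[c].stop - slices[c].start for c in names}
    imbalance = 0  # sum of w * (state - 2)
    for c, s in zip(names, gain_states):
        profile[slices[c]] = s
        imbalance += weights[c] * (s - 2)
    pool = names[len(gain_states):]
    for c in pool:
        best = min(
            [2, *loss_states],
            key=lambda s: abs(imbalance + weights[c] * (s - 2)),
        )
        profile[slices[c]] = best
        imbalance += weights[c] * (best - 2)
    return profile


def high_amplitude_tumour_profile(
    layout: GenomeLayout,
    strong_states: tuple[int, ...] = (4, 0, 5, 0, 6),
    neutral_fraction: float = 0.55,
) -> np.ndarray:
    """A tumour profile whose alterations are all strong (|state - 2| >= 2).

    The largest chromosomes stay diploid until they cover at least
    ``neutral_fraction`` of the genome — keeping the genome-wide median
    anchored on neutral territory, which relative-profile normalisation
    relies on — and ``strong_states`` cycle over the remaining
    chromosomes.  Because every alteration sits at least two states from
    diploid, its gain/loss call is insensitive to the assumed
    cellularity: the regime in which a cellularity sweep leaves the
    profile qualitatively unchanged.
    """
    profile = np.full(layout.n_bins, 2, dtype=np.int64)
    slices = layout.chrom_slices()
    names = layout.chrom_names
    total = layout.n_bins
    covered = 0
    altered: list[str] = []
    for c in names:
        n = slices[c].stop - slices[c].start
        if covered < neutral_fraction * total:
            covered += n
        else:
            altered.append(c)
    for i, c in enumerate(altered):
        profile[slices[c]] = strong_states[i % len(strong_states)]
    return profile


def simulate_gene_bed(
    layout: GenomeLayout,
    n_genes: int = 30,
    names: list[str] | None = None,
    gene_length: tuple[int, int] = (50_000, 300_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene intervals (BED6-style, 0-based half-open) on a layout.

    The default name list starts with the chromosomal-instability gene
    panel (:data:`DEFAULT_CIN_GENES`) followed by numbered placeholders.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E7E]))
    if names is None:
        names = list(DEFAULT_CIN_GENES) + [
            f"GENE{i}" for i in range(n_genes - len(DEFAULT_CIN_GENES))
        ]
    names = names[:n_genes]
    chrom_names = layout.chrom_names
    lengths = np.array([layout.chrom_lengths[c] for c in chrom_names], dtype=float)
    rows = []
    for name in names:
        chrom = chrom_names[rng.choice(len(chrom_names), p=lengths / lengths.sum())]
        size = int(rng.integers(gene_length[0], gene_length[1] + 1))
        size = min(size, layout.chrom_lengths[chrom] - 1)
        start = int(rng.integers(0, layout.chrom_lengths[chrom] - size))
        rows.append(
            {"chrom": chrom, "start": start, "end": start + size,
             "name": name, "score": 0, "strand": "+"}
        )
    df = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(chrom_names)}
    return df.sort_values(
        ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)


def inject_focal_events(
    profile: np.ndarray,
    gene_bed: pd.DataFrame,
    layout: GenomeLayout,
    n_amps: int = 1,
    n_dels: int = 0,
    amp_state: int = 20,
    del_state: int = 0,
    max_len: int = 3_000_000,
    min_len: int = 1_000_000,
    avoid_bins: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Place focal amplifications/deletions over randomly chosen genes.

    Each event covers the bins overlapping one gene, extended on both
    sides so its total span is uniform between ``min_len`` and
    ``max_len``, clipped at the chromosome ends.  Events overwrite the
    profile with ``amp_state`` or ``del_state``.  Genes are drawn
    without replacement; the returned event log records interval, type,
    state and the overlapped gene names, and is the truth the
    focal-event caller is tested against.

    ``avoid_bins`` (e.g. the blacklist of a :class:`BinTrack`) rejects
    placements whose bins or immediate flanking bins are masked: events
    abutting no-data bins have intrinsically ambiguous boundaries and do
    not constitute usable truth.
    """
    out = np.asarray(profile, dtype=np.int64).copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF0CA1]))
    n_events = n_amps + n_dels
    log_rows: list[dict] = []
    if n_events == 0:
        return out, pd.DataFrame(
            columns=["chrom", "start", "end", "type", "state", "genes"]
        )
    if n_events > len(gene_bed):
        raise ValueError("not enough genes to place the requested events")
    slices = layout.chrom_slices()
    order = rng.permutation(len(gene_bed))
    types = ["amp"] * n_amps + ["del"] * n_dels
    occupied = np.zeros(layout.n_bins, dtype=bool)
    gi_iter = iter(order)
    for etype in types:
        for gi in gi_iter:
            gene = gene_bed.iloc[int(gi)]
            sl = slices[gene["chrom"]]
            chrom_bins = sl.stop - sl.start
            g_lo = int(gene["start"]) // layout.bin_size
            g_hi = min((int(gene["end"]) - 1) // layout.bin_size + 1, chrom_bins)
            span_bins = max(1, int(round(rng.uniform(min_len, max_len) / layout.bin_size)))
            span_bins = max(span_bins, g_hi - g_lo)
            extra = span_bins - (g_hi - g_lo)
            left = int(rng.integers(0, extra + 1))
            lo = max(0, g_lo - left)
            hi = min(chrom_bins, lo + span_bins)
            flank_lo = max(0, lo - 1)
            flank_hi = min(chrom_bins, hi + 1)
            if avoid_bins is not None and np.any(
                np.asarray(avoid_bins)[sl.start + flank_lo : sl.start + flank_hi]
            ):
                continue  # try the next gene
            if np.any(occupied[sl.start + flank_lo : sl.start + flank_hi]):
                continue  # events must not overlap or abut each other
            if np.any(out[sl.start + lo : sl.start + hi] != 2):
                # focal events are modelled on neutral background: an
                # amplification from a gained arm or a homozygous loss
                # inside a hemizygous deletion carry different semantics
                continue
            occupied[sl.start + lo : sl.start + hi] = True
            break
        else:
            raise ValueError("not enough placeable genes for the requested events")
        state = amp_state if etype == "amp" else del_state
        out[sl.start + lo : sl.start + hi] = state
        start_bp = int(layout.bin_start[sl.start + lo])
        end_bp = int(layout.bin_end[sl.start + hi - 1])
        covered = gene_bed[
            (gene_bed["chrom"] == gene["chrom"])
            & (gene_bed["start"] < end_bp)
            & (gene_bed["end"] > start_bp)
        ]["name"].tolist()
        log_rows.append(
            {
                "chrom": gene["chrom"],
                "start": start_bp,
                "end": end_bp,
                "type": etype,
                "state": state,
                "genes": ",".join(covered),
            }
        )
    return out, pd.DataFrame(log_rows)
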