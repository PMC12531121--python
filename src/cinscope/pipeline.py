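"""End-to-end orchestration: presets, configuration, staged pipeline runs.

Two presets mirror the two experimental designs the package emulates:

* ``single-cell`` — a clonal cell-line population sequenced one cell at a
  time (384 cells seeded by default, with dropouts): simulate -> QC ->
  per-cell segmentation and state calling -> heterogeneity metrics ->
  copy-number phylogeny with clades and pseudobulk profiles.
* ``bulk-ffpe`` — a cohort of low-pass whole-genome FFPE tumours with
  matched adjacent normals (33 + 33 by default, tumour cellularity 0.3,
  a subset of tumours carrying focal amplifications/deletions):
  simulate -> correction -> segmentation -> purity/ploidy fit and
  absolute calling -> cohort CNA frequency -> focal events with gene
  annotation.

Every run writes its resolved configuration next to its outputs and a
manifest of SHA-256 checksums, so identical configuration + seed must
reproduce identical output files bit for bit.

Length thresholds that are *relative to chromosome size* (the focal-event
cap) scale with the toy-genome factor; thresholds tied to *bin
resolution* (the 0.8 Mb minimum CNA size) do not, because bins stay
500 kb on the scaled genomes.  Read-count windows scale with the genome
so per-bp coverage matches the full-size regime.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import absolute, events, heterogeneity, io, phylo, qc, segment, simulate
from .genome import toy_genome

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with study-condition defaults.

    Fields whose default is None are derived from the preset and genome
    scale when the pipeline resolves the configuration.
    """

    preset: str = "single-cell"  # "single-cell" | "bulk-ffpe"
    seed: int = 0
    outdir: str = "cinscope_out"

    # genome
    genome_scale: int = 5
    bin_size: int = 500_000

    # clone / population structure (single-cell)
    n_cells: int = 384
    n_clones: int = 3
    n_shared_events: int = 5
    n_private_events: int = 5
    event_length_range: tuple[int, int] = (2_000_000, 6_000_000)
    wgd_clones: tuple[str, ...] = ("clone2",)
    clone_proportions: tuple[float, ...] | None = None
    max_state: int = 10

    # noise
    reads_per_cell: tuple[int, int] | None = None
    overdispersion: float | None = None  # 150 single-cell, 500 bulk
    dropout_rate: float = 0.13
    gc_bias_coeffs: tuple[float, float, float] = (-0.8, 8.0, -8.0)
    ffpe_noise_sd: float = 0.05

    # QC
    min_reads: int | None = None
    max_reads: int | None = None
    max_spikiness: float = qc.DEFAULT_MAX_SPIKINESS

    # segmentation / state calling
    alpha: float = segment.DEFAULT_ALPHA
    p_threshold: float = segment.DEFAULT_P_THRESHOLD
    n_permutations: int = segment.DEFAULT_N_PERMUTATIONS
    min_seg_bins: int = segment.DEFAULT_MIN_SEG_BINS
    min_cna_size: int = segment.DEFAULT_MIN_CNA_SIZE

    # absolute fitting (bulk)
    n_tumours: int = 33
    cellularity: float = 0.3
    fit_grid: bool = False  # False: fixed cellularity as for the FFPE cohort
    bulk_total_reads: int | None = None
    penalty: float = absolute.DEFAULT_PENALTY
    sweep_rhos: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

    # focal events
    n_focal_tumours: int = 8
    n_amps: int = 2
    n_dels: int = 1
    amp_state: int = 20
    max_focal_length: int | None = None  # scaled from 20 Mb by genome_scale
    n_genes: int = 30
    cin_genes: tuple[str, ...] = simulate.DEFAULT_CIN_GENES

    # phylogeny / metrics
    k_clades: int | None = None
    entropy_base: float = 2.0

    def resolved(self) -> "PipelineConfig":
        """Fill in preset- and scale-derived defaults."""
        cfg = dataclasses.replace(self)
        if cfg.preset not in ("single-cell", "bulk-ffpe"):
            raise ValueError(f"unknown preset {cfg.preset!r}")
        s = cfg.genome_scale
        if cfg.reads_per_cell is None:
            cfg.reads_per_cell = (500_000 // s, 3_000_000 // s)
        if cfg.min_reads is None:
            cfg.min_reads = 500_000 // s
        if cfg.max_reads is None:
            cfg.max_reads = 3_000_000 // s
        if cfg.overdispersion is None:
            cfg.overdispersion = 150.0 if cfg.preset == "single-cell" else 500.0
        if cfg.bulk_total_reads is None:
            cfg.bulk_total_reads = 2_000_000 // s
        if cfg.max_focal_length is None:
            cfg.max_focal_length = events.DEFAULT_MAX_FOCAL_LENGTH // s
        return cfg

    # -- (de)serialisation ---------------------------------------------
    def to_yaml(self, path) -> None:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            return v

        data = {k: plain(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        tuple_fields = {
            f.name for f in dataclasses.fields(cls)
            if "tuple" in str(f.type)
        }
        coerced = {
            k: (tuple(v) if k in tuple_fields and isinstance(v, list) else v)
            for k, v in data.items()
        }
        return cls(**coerced)

    def noise_model(self) -> simulate.NoiseModel:
        return simulate.NoiseModel(
            reads_per_cell=tuple(self.reads_per_cell),
            gc_bias_coeffs=tuple(self.gc_bias_coeffs),
            overdispersion=float(self.overdispersion),
            dropout_rate=self.dropout_rate if self.preset == "single-cell" else 0.0,
            ffpe_noise_sd=self.ffpe_noise_sd if self.preset == "bulk-ffpe" else 0.0,
        )


def _corrected_values(counts, track, layout):
    # mappability first, then GC, matching the bulk pipeline convention;
    # low-mappability bins are masked before they can distort the GC fit
    matrix = counts.counts if isinstance(counts, qc.CellCounts) else np.atleast_2d(counts)
    values = qc.normalize_bin_widths(matrix, layout)
    values = np.atleast_2d(qc.correct_mappability(values, track))
    return qc.correct_gc(values, track)


def _segment_and_call(values, layout, cfg: PipelineConfig, seed: int, cell_id=None):
    bp = segment.segment_cell(
        values, layout,
        alpha=cfg.alpha, p_threshold=cfg.p_threshold,
        n_permutations=cfg.n_permutations, min_seg_bins=cfg.min_seg_bins,
        seed=seed,
    )
    profile = segment.call_states(values, bp, layout, max_state=cfg.max_state, cell_id=cell_id)
    return bp, segment.filter_small_cnas(profile, min_size=cfg.min_cna_size)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage of the configured preset; returns the output directory.

    Writes, per stage, plain-text TSV/BED/Newick outputs plus a
    ``manifest.tsv`` of SHA-256 checksums and the resolved configuration
    (``config.yaml``).  Any stage failure aborts with the stage named and
    a FAILED marker left in the output directory.
    """
    cfg = config.resolved()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    stage_log: list[dict] = []

    stages = (
        _SINGLE_CELL_STAGES if cfg.preset == "single-cell" else _BULK_STAGES
    )
    ctx: dict = {"cfg": cfg, "outdir": outdir}
    for name, fn in stages:
        t0 = time.time()
        try:
            fn(ctx)
        except Exception:
            (outdir / "FAILED").write_text(f"stage {name} failed\n")
            logger.exception("stage %s failed", name)
            raise
        stage_log.append({"stage": name, "seconds": round(time.time() - t0, 3)})
        logger.info("stage %s done in %.2fs", name, stage_log[-1]["seconds"])

    io.write_tsv(pd.DataFrame(stage_log), outdir / "stage_log.tsv")
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.tsv"
    )
    manifest = pd.DataFrame(
        {"path": [str(p.relative_to(outdir)) for p in files],
         "sha256": [io.sha256_of(p) for p in files]}
    )
    io.write_tsv(manifest, outdir / "manifest.tsv")
    return outdir


# ---------------------------------------------------------------------------
# single-cell preset stages
# ---------------------------------------------------------------------------

def _sc_simulate(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    layout = toy_genome(scale=cfg.genome_scale, bin_size=cfg.bin_size)
    track = simulate.simulate_bin_track(layout, seed=cfg.seed)
    clones = simulate.simulate_clones(
        layout,
        n_clones=cfg.n_clones,
        n_shared_events=cfg.n_shared_events,
        n_private_events=cfg.n_private_events,
        event_length_range=tuple(cfg.event_length_range),
        wgd_clones=set(cfg.wgd_clones),
        max_state=cfg.max_state,
        proportions=list(cfg.clone_proportions) if cfg.clone_proportions else None,
        seed=cfg.seed,
    )
    counts, truth = simulate.simulate_cell_counts(
        clones, cfg.n_cells, cfg.noise_model(), track, layout, seed=cfg.seed
    )
    ctx.update(layout=layout, track=track, clones=clones, counts=counts, truth=truth)
    io.write_counts(counts, ctx["outdir"] / "counts.tsv")
    io.write_tsv(truth, ctx["outdir"] / "truth_cells.tsv")
    clone_df = layout.bins_frame()
    for c in clones:
        clone_df[c.clone_id] = c.profile
    io.write_tsv(clone_df, ctx["outdir"] / "truth_clone_profiles.tsv")
    io.write_tsv(track.to_frame(layout), ctx["outdir"] / "bin_track.tsv")


def _sc_qc(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    kept, report = qc.filter_cells(
        ctx["counts"],
        min_reads=cfg.min_reads, max_reads=cfg.max_reads,
        evenness_stat_max=cfg.max_spikiness, track=ctx["track"],
    )
    ctx["kept"] = kept
    io.write_tsv(report, ctx["outdir"] / "qc_report.tsv")


def _sc_segment(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    counts = ctx["counts"].subset(ctx["kept"])
    values = _corrected_values(counts, ctx["track"], ctx["layout"])
    profiles = []
    seg_rows = []
    for i, cid in enumerate(counts.cell_ids):
        _, profile = _segment_and_call(
            values[i], ctx["layout"], cfg, seed=cfg.seed + 17 * i + 1, cell_id=cid
        )
        profiles.append(profile)
        segs = profile.segments()
        segs.insert(3, "cell_id", cid)
        seg_rows.append(segs)
    ctx["profiles"] = profiles
    io.write_tsv(pd.concat(seg_rows, ignore_index=True), ctx["outdir"] / "segments.tsv")


def _sc_metrics(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    truth = ctx["truth"].set_index("cell_id")
    groups = [truth.loc[p.cell_id, "clone_id"] for p in ctx["profiles"]]
    pop = heterogeneity.CellPopulation(ctx["profiles"], groups=groups)
    report = heterogeneity.heterogeneity_report(pop, entropy_base=cfg.entropy_base)
    io.write_tsv(report, ctx["outdir"] / "heterogeneity.tsv")
    io.write_tsv(
        heterogeneity.group_summary(report).reset_index(), ctx["outdir"] / "group_summary.tsv"
    )
    io.write_tsv(heterogeneity.cna_frequency(pop), ctx["outdir"] / "cna_frequency.tsv")
    ctx["population"] = pop


def _sc_phylo(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    mcs = phylo.minimum_consistent_segmentation(ctx["population"])
    dist = phylo.event_distance_matrix(mcs)
    tree, clades, k = phylo.build_tree(dist, k=cfg.k_clades)
    ctx.update(mcs=mcs, distances=dist, tree=tree, clades=clades)
    seg_df = mcs.segments.copy()
    for i, cid in enumerate(mcs.cell_ids):
        seg_df[cid] = mcs.states[i]
    io.write_tsv(seg_df, ctx["outdir"] / "shared_segments.tsv")
    io.write_tsv(
        pd.DataFrame(dist.distances, index=dist.cell_ids, columns=dist.cell_ids)
        .rename_axis("cell_id").reset_index(),
        ctx["outdir"] / "event_distances.tsv",
    )
    tree.write(str(ctx["outdir"] / "tree.nwk"))
    io.write_tsv(
        pd.DataFrame({"cell_id": dist.cell_ids, "clade": clades, "k": k}),
        ctx["outdir"] / "clades.tsv",
    )


def _sc_pseudobulk(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    counts = ctx["counts"].subset(ctx["kept"])
    rows = []
    for clade in sorted(set(ctx["clades"])):
        members = [c for c, lab in zip(ctx["distances"].cell_ids, ctx["clades"]) if lab == clade]
        profile = phylo.pseudobulk_profile(
            counts, members, ctx["track"], seed=cfg.seed + 1000 + clade,
            min_cna_size=cfg.min_cna_size,
            alpha=cfg.alpha, p_threshold=cfg.p_threshold,
            n_permutations=cfg.n_permutations, min_seg_bins=cfg.min_seg_bins,
        )
        segs = profile.segments()
        segs.insert(0, "clade", clade)
        segs["n_cells"] = len(members)
        rows.append(segs)
    io.write_tsv(pd.concat(rows, ignore_index=True), ctx["outdir"] / "pseudobulk_segments.tsv")


_SINGLE_CELL_STAGES = [
    ("simulate", _sc_simulate),
    ("qc", _sc_qc),
    ("segment", _sc_segment),
    ("metrics", _sc_metrics),
    ("phylo", _sc_phylo),
    ("pseudobulk", _sc_pseudobulk),
]


# ---------------------------------------------------------------------------
# bulk-ffpe preset stages
# ---------------------------------------------------------------------------

def _bulk_simulate(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    layout = toy_genome(scale=cfg.genome_scale, bin_size=cfg.bin_size)
    track = simulate.simulate_bin_track(layout, seed=cfg.seed)
    genes = simulate.simulate_gene_bed(layout, n_genes=cfg.n_genes, seed=cfg.seed)
    noise = cfg.noise_model()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0407]))
    focal_ids = set(
        rng.choice(cfg.n_tumours, size=min(cfg.n_focal_tumours, cfg.n_tumours), replace=False)
    )
    samples, truth_rows, event_logs = {}, [], []
    profiles_true = {}
    for t in range(cfg.n_tumours):
        profile = simulate.simulate_tumour_profile(layout, seed=cfg.seed + 31 * t)
        log = pd.DataFrame()
        if t in focal_ids:
            profile, log = simulate.inject_focal_events(
                profile, genes, layout,
                n_amps=cfg.n_amps, n_dels=cfg.n_dels, amp_state=cfg.amp_state,
                min_len=max(cfg.bin_size, cfg.max_focal_length * 5 // 8),
                max_len=max(cfg.bin_size, cfg.max_focal_length * 7 // 8),
                seed=cfg.seed + 31 * t + 7,
            )
            log.insert(0, "sample", f"tumour{t:02d}")
            event_logs.append(log)
        tumour_counts = simulate.simulate_bulk(
            profile, cfg.cellularity, cfg.bulk_total_reads, noise, track, layout,
            seed=cfg.seed + 31 * t + 1,
        )
        normal_counts = simulate.simulate_bulk(
            np.full(layout.n_bins, 2), 1.0, cfg.bulk_total_reads, noise, track, layout,
            seed=cfg.seed + 31 * t + 2,
        )
        samples[f"tumour{t:02d}"] = tumour_counts
        samples[f"normal{t:02d}"] = normal_counts
        profiles_true[f"tumour{t:02d}"] = profile
        truth_rows.append(
            {"sample": f"tumour{t:02d}", "cellularity": cfg.cellularity,
             "has_focal": int(t in focal_ids)}
        )
    ctx.update(layout=layout, track=track, genes=genes, samples=samples,
               profiles_true=profiles_true)
    sample_ids = list(samples)
    counts = qc.CellCounts(sample_ids, np.stack([samples[s] for s in sample_ids]), layout)
    ctx["counts"] = counts
    io.write_counts(counts, ctx["outdir"] / "bulk_counts.tsv")
    io.write_tsv(pd.DataFrame(truth_rows), ctx["outdir"] / "truth_samples.tsv")
    truth_profiles = layout.bins_frame()
    for s, p in profiles_true.items():
        truth_profiles[s] = p
    io.write_tsv(truth_profiles, ctx["outdir"] / "truth_tumour_profiles.tsv")
    if event_logs:
        io.write_tsv(pd.concat(event_logs, ignore_index=True), ctx["outdir"] / "truth_focal_events.tsv")
    io.write_gene_bed(genes, ctx["outdir"] / "genes.bed")


def _bulk_fit(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    layout = ctx["layout"]
    values = _corrected_values(ctx["counts"], ctx["track"], layout)
    fit_rows, abs_rows = [], []
    absolute_profiles = {}
    for i, sid in enumerate(ctx["counts"].cell_ids):
        bp = segment.segment_cell(
            values[i], layout, alpha=cfg.alpha, p_threshold=cfg.p_threshold,
            n_permutations=cfg.n_permutations, min_seg_bins=cfg.min_seg_bins,
            seed=cfg.seed + 7919 * i,
        )
        rel = absolute.make_relative_profile(values[i], bp, layout, sample_id=sid)
        if cfg.fit_grid:
            fit = absolute.fit_purity_ploidy(rel, penalty=cfg.penalty)
            rho, psi, err = fit.best
        else:
            # the FFPE cohort protocol: fixed cellularity, diploid ploidy,
            # for tumours and adjacent normals alike
            rho, psi, err = cfg.cellularity, 2.0, np.nan
        prof = absolute.to_absolute(rel, rho, psi)
        prof = segment.filter_small_cnas(prof, min_size=cfg.min_cna_size)
        prof.ploidy_fit = psi
        absolute_profiles[sid] = prof
        fit_rows.append({"sample": sid, "rho": rho, "psi": psi, "error": err})
        segs = prof.segments()
        segs.insert(0, "sample", sid)
        abs_rows.append(segs)
    ctx["absolute_profiles"] = absolute_profiles
    io.write_tsv(pd.DataFrame(fit_rows), ctx["outdir"] / "fit_report.tsv")
    io.write_tsv(pd.concat(abs_rows, ignore_index=True), ctx["outdir"] / "absolute_segments.tsv")


def _bulk_metrics(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    tumour_ids = [s for s in ctx["absolute_profiles"] if s.startswith("tumour")]
    profiles = [ctx["absolute_profiles"][s] for s in tumour_ids]
    pop = heterogeneity.CellPopulation(profiles, groups=["tumour"] * len(profiles))
    report = heterogeneity.heterogeneity_report(pop, entropy_base=cfg.entropy_base)
    report = report.rename(columns={"cell_id": "sample"})
    io.write_tsv(report, ctx["outdir"] / "tumour_metrics.tsv")
    io.write_tsv(heterogeneity.cna_frequency(pop), ctx["outdir"] / "cohort_cna_frequency.tsv")


def _bulk_focal(ctx):
    cfg: PipelineConfig = ctx["cfg"]
    rows = []
    for sid, prof in ctx["absolute_profiles"].items():
        evs = events.call_focal_events(
            prof, max_focal_length=cfg.max_focal_length, ploidy=2.0
        )
        evs = events.annotate_genes(evs, ctx["genes"], cin_list=cfg.cin_genes)
        df = events.events_frame(evs)
        df.insert(0, "sample", sid)
        rows.append(df)
    io.write_tsv(pd.concat(rows, ignore_index=True), ctx["outdir"] / "focal_events.tsv")


_BULK_STAGES = [
    ("simulate", _bulk_simulate),
    ("fit", _bulk_fit),
    ("metrics", _bulk_metrics),
    ("focal", _bulk_focal),
]
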