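# Methods

This note documents the models, estimators and numerical choices behind
`cinscope`, what the synthetic-data generator does and does not emulate,
and the known limitations.  It states no empirical result that the test
suite and `scripts/acceptance.py` do not themselves compute.

## The binned copy-number model

All analysis operates on fixed-width, half-open genomic bins (500 kb by
default; the last bin of each chromosome may be shorter).  A cell or
sample is a vector of integer copy-number states per bin; read counts
are treated as proportional to state × bin width × GC effect ×
mappability.  For a bulk tumour/normal mixture with tumour fraction
(cellularity) ρ and tumour ploidy ψ, a segment at state n has expected
signal relative to the genome baseline

    E(n; ρ, ψ) = (ρ·n + 2(1−ρ)) / (ρ·ψ + 2(1−ρ)),

the non-tumour fraction contributing a diploid background.  E(2; ρ, 2)
= 1 for every ρ — a diploid segment in a near-diploid genome is always
the fixed point of the mixture.

## Desk-scale genome

The default study genome is the 22 human autosomes with every
chromosome shrunk 5-fold (≈1,160 bins of 500 kb; 19–100 bins per
chromosome).  The scale was chosen so that the *ratios* that govern
statistical behaviour match real data: events of a few Mb remain small
relative to their chromosome, per-chromosome event density stays
realistic, and permutation tests retain combinatorial resolution (a
chromosome of fewer than ~8 bins cannot yield a significant split at
any effect size, so a more aggressive shrink would cap breakpoint
recall by construction, not by noise).  Read-count windows scale with
the genome (0.5–3 million reads per cell at full size → 100–600
thousand here), preserving per-bin coverage.

## Synthetic data

The generator emulates two designs:

* **Single cells** (DLP+-like): clones descend from a diploid ancestor
  through shared segmental ±1 events; designated clones undergo
  whole-genome doubling after the shared events and before their
  private ones; states clip to [0, 10].  Cells draw a clone by
  proportion and a read total uniformly inside the window; a
  `dropout_rate` fraction (default 0.13, matching the observed failed
  fraction of seeded wells) is emitted far below the minimum.
* **Bulk FFPE tumours**: whole-chromosome and segmental alterations,
  mixed with diploid normal at cellularity ρ (0.3 by default), ~400,000
  reads per sample (the 1–2 million of a full genome, scaled), with
  optional focal amplifications/deletions injected over genes.

Counts are Dirichlet-multinomial: the total is fixed and allocated to
bins with concentration `overdispersion × n_bins × p`, giving
negative-binomial-like variance μ(1 + μ̄/overdispersion) while keeping
per-cell totals exactly inside their window.  Defaults: overdispersion
150 for single cells (≈2× Poisson at the simulated coverage, in line
with published single-cell WGS count variance) and 500 for bulk, plus
multiplicative log-normal noise (σ = 0.05) for FFPE material.  The GC
effect is quadratic in GC fraction, normalised to mean 1 — the simplest
shape the correction stage can invert.  Bin annotation (smooth GC,
2% blacklist, 3% reduced mappability) is itself simulated.

Event placement is uniform over chromosomes weighted by length, never
crossing a chromosome boundary, with two resolvability constraints that
mirror real 500-kb data, where chromosomes span hundreds of bins:
breakpoints of one lineage keep ≥3 bins of spacing, and internal
breakpoints keep ≥2 bins from chromosome ends (a 1-bin flank can never
host a boundary when segments must span ≥2 bins).  Injected focal
events span 2.5–3.5 Mb (5–7 bins) on diploid background away from
blacklisted bins: at cellularity 0.3 and ~350 reads per bin a
homozygous deletion is a −30% signal with ~4–5% segment-median noise,
so shorter deletions cross the 0-vs-1 rounding boundary in a
non-negligible fraction of draws — a resolution limit of the assay
regime, not of the caller — and events abutting no-data bins have
intrinsically ambiguous boundaries.

**What passing tests do and do not show.**  The generator reproduces
the moments the estimators consume: proportionality, the mixture law,
realistic per-bin dispersion, GC/mappability bias, dropout, blacklist
gaps.  It does not model replication-timing waves, sequence-context
FFPE artifacts, supercoiling/accessibility bias, doublets, or S-phase
cells; recovery rates on real data can be lower accordingly.

## Correction and QC

Mappability correction divides by the per-bin fraction (bins below 0.2
are masked); GC correction then divides by a per-cell curve — local
medians over 20 equal-count GC windows, linearly interpolated — fitted
in two passes, the second restricted to approximately-neutral bins
(first-pass ratio within 30% of its median).  The second pass matters:
fitted on all bins, the curve absorbs real copy-number signal and
compresses amplitude, which biases purity estimates downward.  The
correction preserves each cell's mean over usable bins to numerical
precision.  Cell filters: inclusive read window, and "spikiness" — the
largest absolute deviation of any usable bin from the cell's median,
divided by that median (≤1 by default).  A scale-free statistic was
chosen because it can be thresholded identically across depths; it is
a stand-in for an unspecified "even coverage" criterion and is
surfaced in the QC report.

## Segmentation

Per chromosome, hierarchical e-divisive search: the candidate is the
pair (τ₁, τ₂) maximising the two-sample energy statistic between the
left flank x[..τ₁) and the window x[τ₁..τ₂), with U-statistic
within-sample means and the scale factor |L||R|/(|L|+|R|); candidates
are evaluated on the series and its reversal, because a short event
near a segment's start is otherwise weighted only by its few left-flank
neighbours.  The two-argument form is essential: the single-split
statistic is provably blind to interior events that return to baseline
(its expected value for a clean pulse of m bins among n is
O(m²·h/n) — effectively zero), whereas the windowed form scores them at
full amplitude.  A candidate is accepted when its permutation p-value
(199 within-segment permutations of both orientations, add-one
estimator, early stopping once p > 0.1 is certain) is ≤ 0.05 — the
conventional significance level for this method; both validated edges
become boundaries and the recursion continues in all sub-segments.
A final deterministic pass re-localises each boundary within ±2 bins by
maximising the energy between its two flanking segments.  Masked bins
are removed before segmentation, indices are mapped back so boundaries
never land inside masked runs, and chromosomes with fewer than 4 usable
bins are left unsegmented with a warning.  Each chromosome derives its
own RNG stream from the global seed and chromosome index, so results do
not depend on execution order.

False-positive control follows from exchangeability: on pure noise the
first split is accepted at most at the significance level (verified
over 200 replicates); spurious boundaries that do slip through are
benign downstream because equal-state segments merge during state
calling.

## Integer state calling

Segment means are rescaled by a candidate ploidy grid (1.5–6.0, step
0.05).  For each candidate the nearest-integer assignment is taken,
the scale is then *refit* to that assignment by least squares, and the
length-weighted absolute rounding error is scored; candidates whose
implied ploidy (length-weighted mean of assigned states) strays more
than half a state from the candidate value are inadmissible.  The
refit prevents grid quantisation from arbitrating between
integer-rescaled aliases (states 2/4 versus 3/6); the admissibility
rule stops rescaled solutions from escaping the grid's range; the
first minimum wins, i.e. ties break to the lowest consistent ploidy.
Consequence, stated rather than hidden: a featureless tetraploid
genome is called diploid — total copy number cannot distinguish the
two, and only segments at odd true states (half-integer rescaled
means) anchor the doubled solution.  CNAs spanning less than 0.8 Mb
are then reassigned to their longer flanking segment's state, to
fixpoint; ties go to the left flank.

## Absolute copy number

`make_relative_profile` divides segment medians by the genome baseline:
the median over the bins of the dominant cluster of segment medians
(maximum total weight within an 8% span).  The anchor deserves this
care because a global scale error is *exactly* degenerate with the
fitted ploidy — s·E(n; ρ, ψ) = E(n; ρ, ψ′) with ψ′ = (d/s − 2(1−ρ))/ρ —
so anchor noise propagates one-to-one into ψ̂ amplified by d/ρ; a plain
genome median drifts inside the modal cluster whenever gained and lost
fractions are unequal.

The grid fit (ρ: 0.05–1.00 step 0.01; ψ: 1.5–5.5 step 0.05) scores the
length-weighted squared residual to the nearest attainable integer
levels.  Relative profiles are intrinsically aliased — the "+1 state"
reinterpretation at ψ = 3, ρ′ = 2ρ/(2−ρ) reproduces any near-diploid
profile exactly, low-purity/high-ploidy corners make the level grid
dense enough to fit noise, and genome doublings halve/double exactly —
so two small additive priors break ties the way a practitioner
assuming a near-diploid genome would: 5·10⁻⁴·(1−ρ)² against needless
impurity and 2·10⁻³·(ψ−2)² toward the near-diploid reading.  Both are
sized to decide only between near-exact aliases (their scale is a few
times the residual quantisation noise and far below any genuinely
misfitting assignment).  All local minima of the penalised surface are
ranked and returned: a genome-doubled sample legitimately shows its
halved/doubled partner, and flat profiles are flagged unidentifiable
instead of fitted.  The cellularity sweep re-derives integer states at
assumed ρ from 0.1 to 1.0 and reports the weight fraction of segments
whose gain/neutral/loss class changes against the ρ = 0.3 reference;
single-copy changes legitimately fade at assumed purities far above
the true one, so qualitative invariance is a property of strong
(|state − 2| ≥ 2) alterations anchored by a neutral majority.

## Heterogeneity metrics

FGA is the non-masked length fraction deviating from a baseline —
diploid (2) or, ploidy-corrected, the population's length-weighted mean
state rounded half-up (per-cell baselines are available by option; the
population baseline is primary).  Shannon entropy is computed per cell
over the length distribution of states, base 2 (bits) by default with
the base configurable; a per-bin population entropy is provided as a
secondary statistic.  Blacklisted bins never enter numerators or
denominators.  Group comparisons use the pooled-variance two-sample
t-test, with Welch available.

## Phylogeny

The minimum consistent segmentation places a boundary exactly where at
least one cell changes state; this is provably the unique minimal
segmentation that reconstructs every cell bit-exactly (dropping any
such boundary merges bins on which some cell differs; no extra boundary
is ever added).  The pairwise distance is the minimum number of
contiguous ±1 segmental events transforming one total-copy-number
vector into another, with states never negative and state 0 absorbing:
in closed form, per chromosome, Σ max(0, gᵢ−gᵢ₋₁) over the gain
requirement g = max(b−a, 0) plus the analogous loss term (g₀ = 0);
positions where the source is 0 force both requirements to zero and
block the direction entirely when the target is non-zero there.  The
two directed values are symmetrised by their minimum; pairs blocked in
both directions fall back to the unconstrained skyline cost and carry a
flag.  This single-step distance has no whole-genome-doubling event, so
doubled cells appear as a distant clade — consistent with
ploidy-separated clusters in real populations — rather than one step
away.  Trees are neighbor-joining (negative branch lengths clamped to
zero); clades come from removing the k−1 longest internal branches,
with k fixed or chosen by silhouette over 2–8 and all ties broken by
cell-id order.  Pseudobulks merge raw counts — not called states — and
re-enter the correction/segmentation/calling path at purity 1.

## Focal events

A focal event is a maximal constant-state run spanning at most
`max_focal_length` (20 Mb at full genome scale, scaled with the genome
because "focal" is relative to chromosome size) whose state is at least
2·round(ψ)+1 (amplification) or at most round(ψ)−2, floored at 0 (deep
deletion), relative to the sample's fitted ploidy.  No consensus
numeric definition of "focal" exists; these thresholds are explicit,
configurable defaults.  Adjacent qualifying runs of the same type
separated by less than one bin merge.  Gene annotation is half-open
interval overlap (abutting intervals do not overlap), reported in
positional order regardless of input order, with a configurable
chromosomal-instability panel flagged.

## Pipeline and reproducibility

Both presets write plain-text outputs (TSV matrices, BED genes,
BED-like segment tables, Newick trees), echo their fully resolved
configuration, and record a SHA-256 manifest.  All randomness descends
from the configured seed through named per-cell and per-chromosome
streams, so identical configuration and seed reproduce every data file
bit-for-bit; the manifest comparison excludes only the configuration
echo (which contains the output path) and the wall-clock stage log.

## Problem sizes used in validation

The automated checks run at deliberately modest sizes chosen to
exercise every code path with adequate statistical resolution:
breakpoint/state recovery over 12–20 cells at the 1-million-read
equivalent; purity recovery at ρ ∈ {0.2, 0.3, 0.5, 0.8} on a balanced
six-state profile; clone recovery with 3 clones × 40–60 cells; focal
recovery over 10–16 tumours; oracle equivalence exhaustively for
length-3 state vectors (and sampled at lengths 4–5) and on ≤200-bin
segmentation instances; pipeline determinism on reduced cohorts.

## Known limitations

* Total copy number only: no allele-specific states, no BAF, no SNVs.
* The e-divisive search is quadratic in segment length per candidate
  evaluation; it is comfortable at hundreds of bins per chromosome but
  not designed for 10-kb binning of a full genome.
* Integer calling aliases clean whole-genome doublings to diploid (see
  above); purity fitting near ρ ≤ 0.2 approaches the regime where
  state spacing meets segment noise, and errors of one grid step in ψ
  occur there.
* The spikiness QC statistic and the focal thresholds are declared
  stand-ins for criteria that have no community-standard definition.
* The event distance is an approximation to a full minimum-evolution
  model: no whole-genome doubling move, and symmetrisation by the
  minimum of the two directions.
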