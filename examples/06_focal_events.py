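"""Call focal amplifications/deletions and screen them against genes.

Injects high-level focal events over known genes into a bulk tumour at
cellularity 0.3, re-calls them from the simulated counts through the
segmentation -> absolute-copy-number path, and annotates the calls with
overlapping genes, flagging those on the chromosomal-instability panel
(CCNE1, BRCA1, MDM2, KRAS, CDK6, CDK13 by default).
"""

import numpy as np

from cinscope import (
    NoiseModel,
    make_relative_profile,
    simulate_bin_track,
    simulate_bulk,
    simulate_gene_bed,
    simulate_tumour_profile,
    toy_genome,
)
from cinscope.absolute import to_absolute
from cinscope.events import annotate_genes, call_focal_events, events_frame
from cinscope.pipeline import _corrected_values
from cinscope.segment import filter_small_cnas, segment_cell
from cinscope.simulate import inject_focal_events

layout = toy_genome(scale=5)
track = simulate_bin_track(layout, seed=1)
genes = simulate_gene_bed(layout, n_genes=30, seed=2)

profile = simulate_tumour_profile(layout, seed=42)
profile, log = inject_focal_events(
    profile, genes, layout, n_amps=2, n_dels=1, amp_state=20,
    min_len=2_500_000, max_len=3_500_000, avoid_bins=track.blacklisted, seed=43,
)
print("injected truth:")
print(log[["chrom", "start", "end", "type", "state", "genes"]].to_string(index=False))

noise = NoiseModel(overdispersion=500, ffpe_noise_sd=0.05, dropout_rate=0)
counts = simulate_bulk(profile, 0.3, 400_000, noise, track, layout, seed=44)
values = _corrected_values(counts[None, :], track, layout)[0]
breakpoints = segment_cell(values, layout, seed=45)
relative = make_relative_profile(values, breakpoints, layout)
absolute = filter_small_cnas(to_absolute(relative, 0.3, 2.0))

calls = call_focal_events(absolute, max_focal_length=4_000_000, ploidy=2.0)
calls = annotate_genes(calls, genes)
print("\nrecalled focal events (cin_flag: gene on the instability panel):")
print(events_frame(calls).to_string(index=False))
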