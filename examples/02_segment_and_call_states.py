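"""Correct, segment and call integer copy numbers for single cells.

Takes one simulated cell through the full calling path: bin-width
normalisation, mappability and GC correction, e-divisive change-point
detection (energy statistic with permutation significance), ploidy
scale-fit to integer states, and the minimum-CNA-size filter.  Compares
the result with the clone's true profile.
"""

import numpy as np

from cinscope import (
    NoiseModel,
    simulate_bin_track,
    simulate_cell_counts,
    simulate_clones,
    toy_genome,
)
from cinscope.pipeline import _corrected_values
from cinscope.segment import call_states, filter_small_cnas, segment_cell

layout = toy_genome(scale=5)
track = simulate_bin_track(layout, seed=1)
clones = simulate_clones(layout, 1, n_shared_events=8, n_private_events=0, seed=4)
counts, _ = simulate_cell_counts(
    clones, 1, NoiseModel(dropout_rate=0), track, layout, seed=5
)

values = _corrected_values(counts, track, layout)[0]
breakpoints = segment_cell(values, layout, seed=6)
profile = call_states(values, breakpoints, layout, cell_id="cell0000")
profile = filter_small_cnas(profile)  # drop CNAs under 0.8 Mb

true = clones[0].profile
accuracy = (profile.states == true).mean()
print(f"fitted ploidy: {profile.ploidy_fit:.2f}")
print(f"bins with correct integer state: {100 * accuracy:.1f}%")

segments = profile.segments()
altered = segments[segments["state"] != 2]
print(f"\ncalled segments: {len(segments)} total, {len(altered)} non-diploid:")
print(altered.to_string(index=False))
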