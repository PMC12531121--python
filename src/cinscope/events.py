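"""Focal amplification/deletion calling and cancer-gene annotation.

A *focal* event is a short, high-amplitude copy-number segment — the
classic carrier of driver-gene amplifications — as opposed to arm- or
chromosome-level dosage changes.  Because no universal numeric definition
exists, the thresholds here are explicit and configurable: a segment is
focal when its genomic span is at most ``max_focal_length`` and its state
is far from the sample's fitted ploidy (at least ``2 * round(psi) + 1``
for amplifications; at most ``round(psi) - 2``, floored at 0, for deep
deletions).  Events are annotated with overlapping genes (half-open
interval overlap, any overlap counts) and flagged when a gene is on the
configured chromosomal-instability panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import CopyNumberProfile
from .simulate import DEFAULT_CIN_GENES

__all__ = [
    "FocalEvent",
    "call_focal_events",
    "annotate_genes",
    "events_frame",
    "DEFAULT_MAX_FOCAL_LENGTH",
]

DEFAULT_MAX_FOCAL_LENGTH = 20_000_000  # bp, at full genome scale


@dataclass
class FocalEvent:
    """One focal amplification or deletion (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    type: str  # "amp" | "del"
    state: int
    genes: list[str] = field(default_factory=list)
    cin_flag: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def call_focal_events(
    profile: CopyNumberProfile,
    max_focal_length: int = DEFAULT_MAX_FOCAL_LENGTH,
    amp_min_state: int | None = None,
    del_max_state: int | None = None,
    ploidy: float | None = None,
) -> list[FocalEvent]:
    """Short high-amplitude segments of an absolute copy-number profile.

    Thresholds default to the sample's fitted ploidy: amplification at
    ``2 * round(psi) + 1`` or more, deep deletion at ``round(psi) - 2``
    or less (0 for near-diploid genomes, i.e. homozygous loss).  Runs
    longer than ``max_focal_length`` are dosage changes, not focal
    events.  Adjacent qualifying runs of the same type separated by less
    than one bin are merged.
    """
    if ploidy is None:
        ploidy = profile.ploidy_fit if profile.ploidy_fit is not None else profile.mean_ploidy
    base = int(np.floor(ploidy + 0.5))
    if amp_min_state is None:
        amp_min_state = 2 * base + 1
    if del_max_state is None:
        del_max_state = max(0, base - 2)

    segs = profile.segments()
    events: list[FocalEvent] = []
    for _, row in segs.iterrows():
        span = int(row["end"]) - int(row["start"])
        if span > max_focal_length:
            continue
        state = int(row["state"])
        if state >= amp_min_state:
            etype = "amp"
        elif state <= del_max_state:
            etype = "del"
        else:
            continue
        ev = FocalEvent(row["chrom"], int(row["start"]), int(row["end"]), etype, state)
        if (
            events
            and events[-1].chrom == ev.chrom
            and events[-1].type == ev.type
            and ev.start - events[-1].end < profile.layout.bin_size
        ):
            prev = events[-1]
            merged_state = max(prev.state, state) if etype == "amp" else min(prev.state, state)
            events[-1] = FocalEvent(prev.chrom, prev.start, ev.end, etype, merged_state)
        else:
            events.append(ev)
    return [e for e in events if e.length <= max_focal_length]


def annotate_genes(
    events: list[FocalEvent],
    genes: pd.DataFrame,
    cin_list: tuple[str, ...] = DEFAULT_CIN_GENES,
) -> list[FocalEvent]:
    """Attach overlapping gene names (and CIN flags) to focal events.

    ``genes`` is a BED-like DataFrame (chrom, start, end, name), 0-based
    half-open; any overlap counts, so an event ending exactly where a
    gene starts does not overlap it.  Gene lists are reported in
    positional (BED-sorted) order regardless of input row order.
    """
    genes = genes.sort_values(["chrom", "start", "end"], kind="stable")
    cin = set(cin_list)
    out = []
    for ev in events:
        sel = genes[
            (genes["chrom"] == ev.chrom)
            & (genes["start"].astype(int) < ev.end)
            & (genes["end"].astype(int) > ev.start)
        ]
        names = sel["name"].tolist()
        out.append(
            FocalEvent(
                ev.chrom, ev.start, ev.end, ev.type, ev.state,
                genes=names, cin_flag=any(n in cin for n in names),
            )
        )
    return out


def events_frame(events: list[FocalEvent]) -> pd.DataFrame:
    """Focal events as a BED-like DataFrame for reporting."""
    return pd.DataFrame(
        [
            {
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "type": e.type,
                "state": e.state,
                "length": e.length,
                "genes": ",".join(e.genes),
                "cin_flag": int(e.cin_flag),
            }
            for e in events
        ],
        columns=["chrom", "start", "end", "type", "state", "length", "genes", "cin_flag"],
    )
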