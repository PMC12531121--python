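"""Population heterogeneity metrics for single-cell copy-number profiles.

Implements the chromosomal-instability readouts used to compare cell
populations:

* **FGA** — fraction of genome altered: the length fraction of a cell's
  (non-masked) genome whose state deviates from a baseline, either the
  diploid state 2 or the population's rounded mean ploidy ("ploidy
  corrected"), the latter preventing a clean whole-genome doubling from
  scoring as 100% altered.
* **Shannon entropy** — per cell, the entropy of the length distribution
  of its genome across copy-number states (bits by default): 0 for a
  single-state genome, log2(K) for K states in equal shares.
* **CNA frequency** — per bin, the fraction of cells gained/lost against
  their group baseline, the track drawn under population heatmaps.
* **Group comparison** — two-sample t-tests (pooled or Welch) on any
  per-cell metric between two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segment import CopyNumberProfile

__all__ = [
    "CellPopulation",
    "fga",
    "ploidy_baseline",
    "fga_ploidy_corrected",
    "shannon_entropy",
    "population_state_entropy",
    "cna_frequency",
    "heterogeneity_report",
    "compare_groups",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class CellPopulation:
    """A list of copy-number profiles on one shared layout, with group labels."""

    profiles: list[CopyNumberProfile]
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("population must contain at least one profile")
        layout = self.profiles[0].layout
        for p in self.profiles[1:]:
            if p.layout != layout:
                raise ValueError("all profiles must share one genome layout")
        if self.groups is None:
            self.groups = ["all"] * len(self.profiles)
        if len(self.groups) != len(self.profiles):
            raise ValueError("one group label per profile required")

    @property
    def layout(self):
        return self.profiles[0].layout

    def cell_ids(self) -> list[str]:
        return [p.cell_id or f"cell{i}" for i, p in enumerate(self.profiles)]


def _usable_weights(profile: CopyNumberProfile) -> np.ndarray:
    w = profile.layout.bin_widths.astype(float)
    return np.where(profile.mask, 0.0, w)


def fga(profile: CopyNumberProfile, baseline: int = 2) -> float:
    """Fraction of genome altered relative to an integer baseline.

    Sum of the lengths of segments deviating from ``baseline`` divided by
    the total non-masked genome length.  Invariant to how segments are
    subdivided, since it is computed per bin.
    """
    w = _usable_weights(profile)
    total = w.sum()
    if total == 0:
        raise ValueError("profile is fully masked")
    return float(w[profile.states != baseline].sum() / total)


def ploidy_baseline(population: CellPopulation, group: str | None = None) -> int:
    """Rounded length-weighted mean state of a population (or one group).

    Rounds half-up (3.5 -> 4) so the baseline is deterministic.
    """
    num = den = 0.0
    for p, g in zip(population.profiles, population.groups):
        if group is not None and g != group:
            continue
        w = _usable_weights(p)
        num += float((p.states * w).sum())
        den += float(w.sum())
    if den == 0:
        raise ValueError(f"no usable bins in group {group!r}")
    return _round_half_up(num / den)


def fga_ploidy_corrected(
    profile: CopyNumberProfile,
    population: CellPopulation | None = None,
    baseline: int | None = None,
    per_cell: bool = False,
) -> float:
    """FGA against the population's (or the cell's own) rounded mean ploidy.

    By default the baseline is the rounded length-weighted mean state of
    the whole population; pass ``per_cell=True`` to use the cell's own
    mean ploidy instead, or give an explicit ``baseline``.
    """
    if baseline is None:
        if per_cell or population is None:
            baseline = _round_half_up(profile.mean_ploidy)
        else:
            baseline = ploidy_baseline(population)
    return fga(profile, baseline=baseline)


def shannon_entropy(profile: CopyNumberProfile, base: float = 2.0) -> float:
    """Entropy of the genome-length distribution over copy-number states.

    ``H = -sum_k p_k log(p_k)`` with ``p_k`` the non-masked length
    fraction in state ``k``; base 2 gives bits.
    """
    w = _usable_weights(profile)
    total = w.sum()
    if total == 0:
        raise ValueError("profile is fully masked")
    shares = pd.Series(w).groupby(profile.states).sum().to_numpy() / total
    shares = shares[shares > 0]
    return float(-(shares * (np.log(shares) / np.log(base))).sum())


def population_state_entropy(population: CellPopulation, base: float = 2.0) -> np.ndarray:
    """Secondary statistic: per-bin entropy of states across cells."""
    states = np.stack([p.states for p in population.profiles])
    masks = np.stack([p.mask for p in population.profiles])
    n_bins = states.shape[1]
    out = np.zeros(n_bins)
    for b in range(n_bins):
        s = states[~masks[:, b], b]
        if len(s) == 0:
            out[b] = np.nan
            continue
        _, counts = np.unique(s, return_counts=True)
        p = counts / counts.sum()
        out[b] = float(-(p * (np.log(p) / np.log(base))).sum())
    return out


def cna_frequency(
    population: CellPopulation, per_group_baseline: bool = True
) -> pd.DataFrame:
    """Per-bin gain and loss frequency across the population.

    A cell counts as gained at a bin when its state exceeds its group's
    rounded mean-ploidy baseline (lost when below).  Masked bins of a
    cell are excluded from that cell's tally.
    """
    baselines = {}
    for g in set(population.groups):
        baselines[g] = ploidy_baseline(population, group=g if per_group_baseline else None)
    n_bins = population.layout.n_bins
    gain = np.zeros(n_bins)
    loss = np.zeros(n_bins)
    denom = np.zeros(n_bins)
    for p, g in zip(population.profiles, population.groups):
        usable = ~p.mask
        b = baselines[g]
        gain[usable] += p.states[usable] > b
        loss[usable] += p.states[usable] < b
        denom[usable] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        df = population.layout.bins_frame()
        df["gain_freq"] = np.where(denom > 0, gain / denom, np.nan)
        df["loss_freq"] = np.where(denom > 0, loss / denom, np.nan)
    return df


def heterogeneity_report(
    population: CellPopulation, entropy_base: float = 2.0
) -> pd.DataFrame:
    """Per-cell heterogeneity metrics: FGA, ploidy-corrected FGA, entropy.

    The ploidy-corrected baseline is computed per group.
    """
    rows = []
    group_baseline = {g: ploidy_baseline(population, group=g) for g in set(population.groups)}
    for p, g, cid in zip(population.profiles, population.groups, population.cell_ids()):
        rows.append(
            {
                "cell_id": cid,
                "group": g,
                "mean_ploidy": p.mean_ploidy,
                "fga": fga(p),
                "fga_ploidy_corrected": fga(p, baseline=group_baseline[g]),
                "entropy": shannon_entropy(p, base=entropy_base),
            }
        )
    return pd.DataFrame(rows)


def group_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and n per group for every numeric metric in a report."""
    metrics = [c for c in report.columns if c not in ("cell_id", "group")]
    return report.groupby("group")[metrics].agg(["mean", "std", "count"])


def compare_groups(
    report: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test on a per-cell metric between two groups.

    Pooled-variance (classic independent t-test) by default; set
    ``welch=True`` for the unequal-variance variant.  Returns
    ``(t_statistic, p_value)``.  Identical groups give t = 0, p = 1.
    """
    a = report.loc[report["group"] == group_a, metric].to_numpy(dtype=float)
    b = report.loc[report["group"] == group_b, metric].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two cells")
    if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
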