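import numpy as np
import pytest
from scipy import stats

from cinscope.genome import BinTrack, toy_genome
from cinscope.simulate import (
    CloneSpec,
    NoiseModel,
    apply_events,
    inject_focal_events,
    simulate_bin_track,
    simulate_bulk,
    simulate_cell_counts,
    simulate_clones,
    simulate_gene_bed,
)


@pytest.fixture(scope="module")
def toy():
    return toy_genome(5)


@pytest.fixture(scope="module")
def flat_track(toy):
    return BinTrack.uniform(toy.n_bins)


class TestSimulateClones:
    def test_single_clone_no_events_is_diploid(self, toy):
        (clone,) = simulate_clones(toy, 1, n_shared_events=0, n_private_events=0, seed=1)
        assert np.all(clone.profile == 2)

    def test_wgd_doubles_diploid_to_tetraploid(self, toy):
        (clone,) = simulate_clones(
            toy, 1, n_shared_events=0, n_private_events=0, wgd_clones={"clone0"}, seed=1
        )
        assert clone.wgd and np.all(clone.profile == 4)

    def test_event_replay_reproduces_profiles(self, toy):
        """Replaying each clone's logged event list must rebuild its profile,
        and pairwise Hamming distances must match the replayed profiles."""
        clones = simulate_clones(toy, 3, n_shared_events=5, n_private_events=5, seed=7)
        replayed = []
        for c in clones:
            shared = [e[1:] for e in c.events if e[0] == "shared"]
            private = [e[1:] for e in c.events if e[0] == "private"]
            p = apply_events(np.full(toy.n_bins, 2), shared, toy, max_state=10)
            if c.wgd:
                p = np.clip(p * 2, 0, 10)
            p = apply_events(p, private, toy, max_state=10)
            replayed.append(p)
            assert np.array_equal(p, c.profile)
        for i in range(3):
            for j in range(3):
                assert (clones[i].profile != clones[j].profile).sum() == (
                    replayed[i] != replayed[j]
                ).sum()

    def test_deterministic_under_seed(self, toy):
        a = simulate_clones(toy, 2, seed=5)
        b = simulate_clones(toy, 2, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.profile, y.profile)

    def test_oversized_event_rejected(self, toy):
        with pytest.raises(ValueError):
            simulate_clones(toy, 1, event_length_range=(10**9, 2 * 10**9), seed=1)

    def test_proportions_must_sum_to_one(self, toy):
        with pytest.raises(ValueError):
            simulate_clones(toy, 2, proportions=[0.6, 0.6], seed=1)


class TestSimulateCellCounts:
    def test_mean_counts_match_uniform_law(self, toy, flat_track):
        """Diploid cells, no GC bias, weak overdispersion: per-bin mean over
        full-width bins approaches reads/n_bins within 3 standard errors."""
        noise = NoiseModel(
            reads_per_cell=(200_000, 200_001),
            gc_bias_coeffs=(0, 0, 0),
            overdispersion=1e6,
            dropout_rate=0.0,
        )
        (clone,) = simulate_clones(toy, 1, n_shared_events=0, n_private_events=0, seed=1)
        counts, _ = simulate_cell_counts([clone], 50, noise, flat_track, toy, seed=2)
        full = toy.bin_widths == toy.bin_size
        weights = toy.bin_widths / toy.bin_widths.sum()
        expected = 200_000 * weights[full]
        observed = counts.counts[:, full].mean(axis=0)
        se = np.sqrt(expected / 50)
        assert np.all(np.abs(observed - expected) < 4 * se)

    def test_state_doubling_doubles_mean(self, toy, flat_track):
        profile = np.full(toy.n_bins, 2)
        profile[:40] = 4
        clone = CloneSpec("c", profile, 1.0)
        noise = NoiseModel(
            reads_per_cell=(200_000, 200_001), gc_bias_coeffs=(0, 0, 0), dropout_rate=0
        )
        counts, _ = simulate_cell_counts([clone], 100, noise, flat_track, toy, seed=3)
        mean4 = counts.counts[:, :40].mean()
        mean2 = counts.counts[:, 40:][:, flat_track.blacklisted[40:] == False][
            :, toy.bin_widths[40:] == toy.bin_size
        ].mean()
        assert mean4 / mean2 == pytest.approx(2.0, rel=0.05)

    def test_dropout_rate_matches_study_regime(self, toy, flat_track):
        """dropout_rate 0.13 on 384 seeded cells gives ~50 dropouts."""
        noise = NoiseModel(dropout_rate=0.13)
        (clone,) = simulate_clones(toy, 1, n_shared_events=0, n_private_events=0, seed=1)
        _, truth = simulate_cell_counts([clone], 384, noise, flat_track, toy, seed=4)
        n_drop = truth["dropout"].sum()
        lo, hi = stats.binom.interval(0.999, 384, 0.13)
        assert lo <= n_drop <= hi

    def test_totals_conserved_within_read_range(self, toy, flat_track):
        noise = NoiseModel(reads_per_cell=(100_000, 600_000), dropout_rate=0.2)
        (clone,) = simulate_clones(toy, 1, seed=1)
        counts, truth = simulate_cell_counts([clone], 60, noise, flat_track, toy, seed=5)
        totals = counts.total_reads
        drop = truth["dropout"].to_numpy(bool)
        assert np.all(totals[~drop] >= 100_000) and np.all(totals[~drop] <= 600_000)
        assert np.all(totals[drop] < 100_000)

    def test_empty_clone_list_rejected(self, toy, flat_track):
        with pytest.raises(ValueError):
            simulate_cell_counts([], 5, NoiseModel(), flat_track, toy, seed=1)

    def test_bit_identical_under_seed(self, toy, flat_track):
        (clone,) = simulate_clones(toy, 1, seed=1)
        a, _ = simulate_cell_counts([clone], 5, NoiseModel(), flat_track, toy, seed=9)
        b, _ = simulate_cell_counts([clone], 5, NoiseModel(), flat_track, toy, seed=9)
        assert np.array_equal(a.counts, b.counts)


class TestSimulateBulk:
    def test_mixture_ratio_recovered(self, toy, flat_track):
        """A state-6 segment at cellularity 0.3 shows relative signal
        (0.3*6+1.4)/(0.3*2+1.4) = 1.6 against the diploid background."""
        profile = np.full(toy.n_bins, 2)
        profile[100:160] = 6
        noise = NoiseModel(gc_bias_coeffs=(0, 0, 0), overdispersion=1e5)
        counts = simulate_bulk(profile, 0.3, 5_000_000, noise, flat_track, toy, seed=6)
        full = toy.bin_widths == toy.bin_size
        seg = counts[100:160].mean()
        bg_sel = full.copy()
        bg_sel[100:160] = False
        bg = counts[bg_sel].mean()
        assert seg / bg == pytest.approx(1.6, rel=0.02)

    def test_cellularity_one_diploid_is_flat(self, toy, flat_track):
        noise = NoiseModel(gc_bias_coeffs=(0, 0, 0), overdispersion=1e5)
        counts = simulate_bulk(np.full(toy.n_bins, 2), 1.0, 2_000_000, noise, flat_track, toy, seed=7)
        full = toy.bin_widths == toy.bin_size
        cv = counts[full].std() / counts[full].mean()
        assert cv < 0.05

    def test_invalid_cellularity_rejected(self, toy, flat_track):
        for rho in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                simulate_bulk(np.full(toy.n_bins, 2), rho, 1000, NoiseModel(), flat_track, toy)


class TestInjectFocalEvents:
    def test_no_events_identity(self, toy):
        genes = simulate_gene_bed(toy, seed=1)
        profile = np.full(toy.n_bins, 2)
        out, log = inject_focal_events(profile, genes, toy, n_amps=0, n_dels=0, seed=1)
        assert np.array_equal(out, profile) and len(log) == 0

    def test_event_log_contains_target_gene(self, toy):
        genes = simulate_gene_bed(toy, seed=1)
        profile = np.full(toy.n_bins, 2)
        out, log = inject_focal_events(profile, genes, toy, n_amps=1, amp_state=20, seed=2)
        assert len(log) == 1
        assert log.iloc[0]["genes"] != ""
        assert (out == 20).any()
        # the amp really covers the logged interval
        row = log.iloc[0]
        sl = toy.chrom_slices()[row["chrom"]]
        lo = row["start"] // toy.bin_size
        hi = (row["end"] - 1) // toy.bin_size + 1
        assert np.all(out[sl][lo:hi] == 20)

    def test_events_do_not_overlap(self, toy):
        genes = simulate_gene_bed(toy, n_genes=30, seed=1)
        profile = np.full(toy.n_bins, 2)
        out, log = inject_focal_events(profile, genes, toy, n_amps=3, n_dels=2, seed=3)
        assert len(log) == 5
        spans = []
        for _, r in log.iterrows():
            for c, a, b in spans:
                assert not (c == r["chrom"] and r["start"] < b and r["end"] > a)
            spans.append((r["chrom"], r["start"], r["end"]))


class TestBinTrackSimulation:
    def test_track_shapes_and_fractions(self, toy):
        track = simulate_bin_track(toy, seed=3)
        assert track.n_bins == toy.n_bins
        assert 0 < track.blacklisted.mean() < 0.05
        assert np.all((track.gc > 0.2) & (track.gc < 0.7))

    def test_deterministic(self, toy):
        a = simulate_bin_track(toy, seed=3)
        b = simulate_bin_track(toy, seed=3)
        assert np.array_equal(a.gc, b.gc) and np.array_equal(a.blacklisted, b.blacklisted)
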