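import itertools

import numpy as np
import pytest

from cinscope.genome import BinTrack, make_genome, toy_genome
from cinscope.heterogeneity import CellPopulation
from cinscope.phylo import (
    EventDistanceMatrix,
    build_tree,
    event_distance,
    event_distance_matrix,
    minimum_consistent_segmentation,
    pseudobulk,
    pseudobulk_profile,
)
from cinscope.segment import CopyNumberProfile
from cinscope.simulate import NoiseModel, simulate_cell_counts, simulate_clones
from oracles import bfs_event_distance, exhaustive_min_consistent_segments


def _prof(layout, states, cell_id=None):
    return CopyNumberProfile(np.asarray(states), layout, cell_id=cell_id)


class TestMinimumConsistentSegmentation:
    def test_single_cell_identity(self):
        layout = make_genome([6_000_000], bin_size=500_000)
        prof = _prof(layout, [2, 2, 3, 3, 3, 1, 1, 2, 2, 2, 2, 2])
        mcs = minimum_consistent_segmentation(CellPopulation([prof]))
        assert list(mcs.segments["n_bins"]) == [2, 3, 2, 5]

    def test_two_cells_disjoint_events_five_segments(self):
        """Two cells with disjoint single events on one chromosome produce
        flank / event1 / gap / event2 / flank."""
        layout = make_genome([6_000_000], bin_size=500_000)
        a = _prof(layout, [2, 2, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2])
        b = _prof(layout, [2, 2, 2, 2, 2, 2, 1, 1, 1, 2, 2, 2])
        mcs = minimum_consistent_segmentation(CellPopulation([a, b]))
        assert len(mcs.segments) == 5
        assert list(mcs.segments["n_bins"]) == [2, 2, 2, 3, 3]

    def test_lossless_reconstruction(self, toy5):
        rng = np.random.default_rng(4)
        profiles = []
        for i in range(4):
            states = np.full(toy5.n_bins, 2)
            for _ in range(6):
                lo = rng.integers(0, toy5.n_bins - 10)
                states[lo : lo + rng.integers(2, 10)] += rng.choice([-1, 1])
            profiles.append(_prof(toy5, np.clip(states, 0, None)))
        mcs = minimum_consistent_segmentation(CellPopulation(profiles))
        for i, p in enumerate(profiles):
            assert np.array_equal(mcs.expand(i), p.states)

    def test_minimality_matches_exhaustive_oracle(self):
        """On every instance up to 12 bins x 4 cells the shared segment
        count equals the brute-force minimum over boundary subsets."""
        rng = np.random.default_rng(9)
        layout = make_genome([6_000_000], bin_size=500_000)
        for _ in range(25):
            n_cells = int(rng.integers(1, 5))
            states = rng.integers(0, 4, size=(n_cells, 12))
            # make segments blocky so minimality is non-trivial
            states = np.repeat(states[:, ::3], 3, axis=1)[:, :12]
            profiles = [_prof(layout, s) for s in states]
            mcs = minimum_consistent_segmentation(CellPopulation(profiles))
            assert len(mcs.segments) == exhaustive_min_consistent_segments(states)


class TestEventDistance:
    def test_identical_vectors_zero(self):
        d, blocked = event_distance([2, 2, 2], [2, 2, 2])
        assert d == 0 and not blocked

    def test_single_gain_run_costs_one(self):
        d, _ = event_distance([2, 2, 2], [3, 3, 2])
        assert d == 1

    def test_matches_bfs_exhaustively_length3(self):
        """Closed form equals the breadth-first-search minimum over event
        sequences for all state-vector pairs of length <= 3, states <= 4."""
        vectors = list(itertools.product(range(5), repeat=3))
        rng = np.random.default_rng(0)
        sample = rng.choice(len(vectors), size=40, replace=False)
        for i in sample:
            for j in rng.choice(len(vectors), size=6, replace=False):
                a, b = vectors[i], vectors[int(j)]
                d, blocked = event_distance(a, b)
                oracle = bfs_event_distance(a, b)
                oracle_rev = bfs_event_distance(b, a)
                expected = min(oracle, oracle_rev)
                if np.isinf(expected):
                    assert blocked
                else:
                    assert d == expected, (a, b)

    def test_zero_state_blocks_direction(self):
        # 0 -> 1 impossible; 1 -> 0 costs 1; symmetrised min = 1
        d, blocked = event_distance([0, 2], [1, 2])
        assert d == 1 and not blocked

    def test_doubly_blocked_pair_flagged(self):
        d, blocked = event_distance([0, 2], [1, 0])
        assert blocked

    def test_lower_bound_max_component_difference(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.integers(0, 5, 6)
            b = rng.integers(0, 5, 6)
            d, blocked = event_distance(a, b)
            assert d >= np.abs(a - b).max() - 1e-9

    def test_chromosomes_are_independent(self):
        chrom = np.array([0, 0, 1, 1])
        d_joint, _ = event_distance([2, 2, 2, 2], [3, 3, 3, 3], chrom)
        assert d_joint == 2  # one event per chromosome, never spanning


class TestBuildTree:
    def test_clone_recovery_perfect_distances(self, toy5):
        clones = simulate_clones(toy5, 3, n_shared_events=4, n_private_events=6, seed=3)
        profiles, labels = [], []
        rng = np.random.default_rng(1)
        for i in range(30):
            k = int(rng.integers(0, 3))
            profiles.append(_prof(toy5, clones[k].profile, cell_id=f"c{i:02d}"))
            labels.append(k)
        pop = CellPopulation(profiles)
        mcs = minimum_consistent_segmentation(pop)
        dm = event_distance_matrix(mcs)
        _, clades, k = build_tree(dm, k=3)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, clades) == 1.0

    def test_identical_cells_zero_branch(self):
        d = np.array([[0, 0, 5.0], [0, 0, 5.0], [5.0, 5.0, 0]])
        dm = EventDistanceMatrix(d, ["a", "b", "c"], np.zeros((3, 3), bool))
        tree, _, _ = build_tree(dm, k=2)
        ta = tree.find("a")
        tb = tree.find("b")
        assert ta.distance(tb) == pytest.approx(0.0, abs=1e-9)

    def test_additive_tree_exactly_recovered(self):
        """Distances generated from a known additive tree are reproduced as
        patristic distances of the NJ reconstruction."""
        from skbio import TreeNode

        newick = "((a:2,b:3):4,(c:1,d:2):2,e:6);"
        source = TreeNode.read([newick])
        ids = ["a", "b", "c", "d", "e"]
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = source.find(ids[i]).distance(source.find(ids[j]))
        dm = EventDistanceMatrix(d, ids, np.zeros((n, n), bool))
        tree, _, _ = build_tree(dm, k=2)
        for i in range(n):
            for j in range(i + 1, n):
                got = tree.find(ids[i]).distance(tree.find(ids[j]))
                assert got == pytest.approx(d[i, j], rel=1e-6)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 8, size=(12, 12)).astype(float)
        d = (x + x.T) * (1 - np.eye(12))
        ids = [f"c{i}" for i in range(12)]
        dm = EventDistanceMatrix(d, ids, np.zeros((12, 12), bool))
        t1, c1, k1 = build_tree(dm)
        t2, c2, k2 = build_tree(dm)
        assert c1 == c2 and k1 == k2


class TestPseudobulk:
    def test_sum_of_counts(self, toy5):
        track = BinTrack.uniform(toy5.n_bins)
        (clone,) = simulate_clones(toy5, 1, seed=2)
        counts, _ = simulate_cell_counts([clone], 6, NoiseModel(dropout_rate=0), track, toy5, seed=3)
        summed = pseudobulk(counts, counts.cell_ids[:3])
        assert np.array_equal(summed, counts.counts[:3].sum(axis=0))

    def test_merging_cells_improves_breakpoint_recall(self, toy5):
        """Pseudobulk of many identical-clone cells recovers at least as
        many true breakpoints as a typical single cell at low coverage."""
        track = BinTrack.uniform(toy5.n_bins)
        (clone,) = simulate_clones(toy5, 1, n_shared_events=10, n_private_events=0, seed=5)
        noise = NoiseModel(reads_per_cell=(40_000, 40_001), dropout_rate=0)
        counts, _ = simulate_cell_counts([clone], 12, noise, track, toy5, seed=6)
        truth_bps = {
            (c, int(t))
            for c, sl in toy5.chrom_slices().items()
            for t in np.flatnonzero(np.diff(clone.profile[sl])) + 1
        }

        def recall(profile):
            segs = profile.segments()
            found = set()
            for chrom, sl in toy5.chrom_slices().items():
                s = profile.states[sl]
                for t in np.flatnonzero(np.diff(s)) + 1:
                    found.add((chrom, int(t)))
            hit = sum(
                any(c == fc and abs(t - ft) <= 1 for fc, ft in found)
                for c, t in truth_bps
            )
            return hit / len(truth_bps)

        single = pseudobulk_profile(counts, counts.cell_ids[:1], track, seed=7)
        merged = pseudobulk_profile(counts, counts.cell_ids, track, seed=8)
        assert recall(merged) >= recall(single)
        assert recall(merged) >= 0.9

    def test_clades_differing_in_one_region_match_elsewhere(self, toy5):
        """Pseudobulks of two clades that differ only on one chromosome are
        identical outside that chromosome."""
        track = BinTrack.uniform(toy5.n_bins)
        base = np.full(toy5.n_bins, 2)
        variant = base.copy()
        sl = toy5.chrom_slices()["chr5"]
        variant[sl] = 4
        from cinscope.simulate import CloneSpec

        clones = [CloneSpec("lo", base, 0.5), CloneSpec("hi", variant, 0.5)]
        noise = NoiseModel(reads_per_cell=(300_000, 300_001), dropout_rate=0)
        counts, truth = simulate_cell_counts(clones, 20, noise, track, toy5, seed=9)
        by_clone = truth.groupby("clone_id")["cell_id"].apply(list)
        pa = pseudobulk_profile(counts, by_clone["lo"], track, seed=10)
        pb = pseudobulk_profile(counts, by_clone["hi"], track, seed=11)
        outside = np.ones(toy5.n_bins, bool)
        outside[sl] = False
        assert np.array_equal(pa.states[outside], pb.states[outside])
        assert np.all(pb.states[sl] >= 3)  # the differing region stands out
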