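"""Distances, single-linkage MOTU clustering, threshold sweep, representatives."""

import numpy as np
import pytest

from motudiet import (
    DistanceMatrix,
    ThresholdSweep,
    cluster_at_threshold,
    pairwise_distance,
    pick_representatives,
    select_infliction_threshold,
    sweep_thresholds,
)
from motudiet.amplicon import Haplotype


def mutate(seq: str, positions, base_map={"A": "C", "C": "G", "G": "T", "T": "A"}):
    chars = list(seq)
    for p in positions:
        chars[p] = base_map[chars[p]]
    return "".join(chars)


def brute_force_components(distances: np.ndarray, threshold: float) -> list[set[int]]:
    """Exhaustive transitive closure over the <=-threshold graph."""
    n = len(distances)
    unvisited = set(range(n))
    components = []
    while unvisited:
        frontier = {unvisited.pop()}
        comp = set(frontier)
        while frontier:
            node = frontier.pop()
            links = {
                j for j in list(unvisited) if distances[node, j] <= threshold
            }
            unvisited -= links
            comp |= links
            frontier |= links
        components.append(comp)
    return components


class TestPairwiseDistance:
    def test_identical_sequences_have_zero_distance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=157))
        assert pairwise_distance(seq, seq) == 0.0

    def test_single_internal_mismatch_is_one_over_length(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=157))
        other = mutate(seq, [80])
        assert pairwise_distance(seq, other) == pytest.approx(1 / 157)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=60))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(50, 70)))
            assert pairwise_distance(a, b) == pairwise_distance(b, a)

    def test_distinct_sequences_have_positive_distance(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=30))
            b = "".join(rng.choice(list("ACGT"), size=30))
            if a != b:
                assert pairwise_distance(a, b) > 0

    def test_internal_gap_counts_toward_divergence(self):
        a = "ACGT" * 40
        b = a[:57] + a[58:]  # one internal deletion
        assert 0 < pairwise_distance(a, b) < 0.02

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance("", "ACGT")


class TestClusterAtThreshold:
    def test_zero_threshold_gives_one_motu_per_sequence(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(8)]
        dm = DistanceMatrix.from_sequences([f"H{i}" for i in range(8)], seqs)
        clusters = cluster_at_threshold(dm, 0.0)
        assert len(clusters) == len(set(seqs))

    def test_chain_links_transitively(self, rng):
        # A-B at ~1.5%, B-C at ~1.5%, A-C at ~3%: one MOTU at 2%
        base = "".join(rng.choice(list("ACGT"), size=200))
        a = base
        b = mutate(base, [10, 50, 90])          # 3/200 = 1.5% from A
        c = mutate(b, [120, 150, 180])          # 1.5% from B, 3% from A
        dm = DistanceMatrix.from_sequences(["A", "B", "C"], [a, b, c])
        assert dm.distances[0, 2] == pytest.approx(0.03)
        clusters = cluster_at_threshold(dm, 0.02)
        assert len(clusters) == 1
        assert clusters[0].member_haplotypes == {"A", "B", "C"}

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        raw = rng.uniform(0, 0.08, size=(n, n))
        d = np.round(np.triu(raw, 1) + np.triu(raw, 1).T, 6)
        dm = DistanceMatrix([f"H{i}" for i in range(n)], d)
        threshold = float(rng.uniform(0, 0.08))
        expected = {
            frozenset(comp) for comp in brute_force_components(d, round(threshold, 6))
        }
        got = {
            frozenset(dm.haplotype_ids.index(m) for m in c.member_haplotypes)
            for c in cluster_at_threshold(dm, threshold)
        }
        assert got == expected

    def test_partition_covers_every_haplotype_once(self, rng):
        n = 10
        raw = rng.uniform(0, 0.1, size=(n, n))
        d = np.round(np.triu(raw, 1) + np.triu(raw, 1).T, 6)
        dm = DistanceMatrix([f"H{i}" for i in range(n)], d)
        clusters = cluster_at_threshold(dm, 0.03)
        members = [m for c in clusters for m in c.member_haplotypes]
        assert sorted(members) == sorted(dm.haplotype_ids)

    def test_hierarchy_partitions_nest(self, rng):
        n = 12
        raw = rng.uniform(0, 0.1, size=(n, n))
        d = np.round(np.triu(raw, 1) + np.triu(raw, 1).T, 6)
        dm = DistanceMatrix([f"H{i}" for i in range(n)], d)
        fine = cluster_at_threshold(dm, 0.02)
        coarse = cluster_at_threshold(dm, 0.05)
        for c_fine in fine:
            assert any(
                c_fine.member_haplotypes <= c_coarse.member_haplotypes
                for c_coarse in coarse
            )


class TestSweep:
    def test_identical_haplotypes_always_one_motu(self):
        dm = DistanceMatrix.from_sequences(["a", "b", "c"], ["ACGT" * 40] * 3)
        sweep = sweep_thresholds(dm)
        assert set(sweep.motu_counts) == {1}

    def test_simulated_panel_plateaus_at_taxon_count(self, panel5):
        seqs, ids = [], []
        for t in panel5:
            for v, s in enumerate(t.sequences):
                ids.append(f"{t.taxon_id}.{v}")
                seqs.append(s)
        dm = DistanceMatrix.from_sequences(ids, seqs)
        sweep = sweep_thresholds(dm)
        counts = dict(zip(sweep.thresholds, sweep.motu_counts))
        assert counts[0.02] == counts[0.03] == 5  # plateau across [2%, 4%)

    def test_counts_non_increasing_for_random_inputs(self, rng):
        n = 15
        raw = rng.uniform(0, 0.12, size=(n, n))
        d = np.clip(np.round(np.triu(raw, 1) + np.triu(raw, 1).T, 6), 0, 1)
        dm = DistanceMatrix([f"H{i}" for i in range(n)], d)
        sweep = sweep_thresholds(dm)
        assert all(
            a >= b for a, b in zip(sweep.motu_counts, sweep.motu_counts[1:])
        )


class TestInflectionSelection:
    def test_first_zero_drop_after_curve_falls(self):
        sweep = ThresholdSweep([0, 0.01, 0.02, 0.03, 0.04], [100, 60, 50, 50, 49])
        assert select_infliction_threshold(sweep, 0) == 0.02

    def test_strictly_decreasing_counts_fall_back_with_warning(self):
        sweep = ThresholdSweep([0, 0.01, 0.02], [5, 4, 3])
        with pytest.warns(UserWarning):
            assert select_infliction_threshold(sweep, 0) == 0.02

    def test_constant_counts_select_first_threshold(self):
        sweep = ThresholdSweep([0, 0.01, 0.02], [7, 7, 7])
        assert select_infliction_threshold(sweep, 0) == 0.0


class TestRepresentatives:
    def haps(self):
        return {
            f"S{i}": Haplotype(f"S{i}", seq, a, {})
            for i, (seq, a) in enumerate(
                [("AAAA", 10), ("CCCC", 5), ("GGGG", 2), ("TTTT", 1)], start=1
            )
        }

    def test_three_most_abundant_chosen_in_order(self):
        haps = self.haps()
        reps = pick_representatives(set(haps), haps)
        assert reps == ["AAAA", "CCCC", "GGGG"]

    def test_small_cluster_returns_all_members(self):
        haps = self.haps()
        reps = pick_representatives({"S1", "S2"}, haps)
        assert reps == ["AAAA", "CCCC"]

    def test_tie_broken_lexicographically(self):
        haps = {
            "a": Haplotype("a", "TTTT", 5, {}),
            "b": Haplotype("b", "AAAA", 5, {}),
        }
        assert pick_representatives(set(haps), haps) == ["AAAA", "TTTT"]
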