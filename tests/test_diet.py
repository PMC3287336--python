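"""Utilization matrices and the dietary descriptors (breadth, diversity, overlap)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motudiet import (
    UtilizationMatrix,
    build_matrix,
    family_share,
    levins_breadth,
    percent_fo_by_order,
    pianka_overlap,
    sample_summary,
    shannon_diversity,
)

count_vectors = st.lists(
    st.integers(min_value=0, max_value=50), min_size=2, max_size=8
).filter(lambda v: sum(v) > 0)


class TestBuildMatrix:
    def test_counts_samples_containing_resource(self):
        presence = {
            ("f1", "P1"): {"R"},
            ("f2", "P1"): {"R", "Q"},
            ("f3", "P1"): {"Q"},
        }
        m = build_matrix(presence)
        assert m.data.at["R", "P1"] == 2 and m.data.at["Q", "P1"] == 2

    def test_empty_presence_gives_empty_matrix(self):
        m = build_matrix({})
        assert m.resources == []

    def test_sample_cannot_belong_to_two_predators(self):
        with pytest.raises(ValueError):
            build_matrix({("f1", "P1"): {"R"}, ("f1", "P2"): {"R"}})

    def test_table1_fixture_round_trips(self, table1):
        # expand the fixture into synthetic per-sample presence sets and
        # rebuild: the counts must come back identical
        presence: dict = {}
        for predator in table1.predators:
            col = table1.data[predator]
            for resource, count in col.items():
                for i in range(count):
                    key = (f"{predator}_s{i:02d}", predator)
                    presence.setdefault(key, set()).add(resource)
        rebuilt = build_matrix(presence)
        aligned = rebuilt.data.reindex(
            index=table1.resources, columns=table1.predators
        ).fillna(0).astype(int)
        assert aligned.equals(table1.data)


class TestLevins:
    def test_uniform_use_is_maximal_breadth(self):
        b, ba = levins_breadth([3, 3, 3, 3])
        assert b == pytest.approx(4) and ba == pytest.approx(1)

    def test_single_resource_is_minimal_breadth(self):
        b, ba = levins_breadth([7], n_resources=1)
        assert b == pytest.approx(1) and ba == 0.0

    def test_hand_evaluated_case(self):
        b, ba = levins_breadth([2, 1, 1], n_resources=3)
        assert b == pytest.approx(8 / 3)
        assert ba == pytest.approx(5 / 6)

    @given(counts=count_vectors, scale=st.integers(min_value=2, max_value=9))
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_scale_invariance(self, counts, scale):
        b, ba = levins_breadth(counts)
        b2, ba2 = levins_breadth([c * scale for c in counts])
        assert 0 <= ba <= 1 + 1e-12
        assert b == pytest.approx(b2) and ba == pytest.approx(ba2)


class TestShannon:
    def test_uniform_maximum(self):
        assert shannon_diversity([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_single_resource_is_zero(self):
        assert shannon_diversity([9]) == 0.0

    def test_hand_evaluated_case(self):
        assert shannon_diversity([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    @given(counts=count_vectors)
    @settings(deadline=None, max_examples=50)
    def test_bounded_by_log_richness(self, counts):
        h = shannon_diversity(counts)
        n_used = sum(1 for c in counts if c > 0)
        assert 0 <= h <= np.log(max(n_used, 1)) + 1e-12


class TestPianka:
    def test_identical_distributions_give_one(self):
        assert pianka_overlap([3, 1, 2], [3, 1, 2]) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        assert pianka_overlap([1, 1, 0, 0], [0, 0, 2, 5]) == 0.0

    def test_hand_evaluated_case(self):
        assert pianka_overlap([2, 1, 1, 0], [1, 1, 0, 2]) == pytest.approx(0.5)

    def test_all_zero_vector_fails(self):
        with pytest.raises(ValueError):
            pianka_overlap([0, 0], [1, 2])

    @given(
        counts=st.tuples(count_vectors, count_vectors).filter(
            lambda t: len(t[0]) == len(t[1])
        ),
        scale=st.integers(min_value=2, max_value=9),
    )
    @settings(deadline=None, max_examples=50)
    def test_symmetry_bounds_scale_invariance(self, counts, scale):
        a, b = counts
        o = pianka_overlap(a, b)
        assert 0 <= o <= 1 + 1e-12
        assert o == pytest.approx(pianka_overlap(b, a))
        assert o == pytest.approx(pianka_overlap([x * scale for x in a], b))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_direct_formula_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=5) + np.array([1, 0, 0, 0, 0])
        b = rng.integers(0, 10, size=5) + np.array([1, 0, 0, 0, 0])
        pa, pb = a / a.sum(), b / b.sum()
        direct = sum(x * y for x, y in zip(pa, pb)) / np.sqrt(
            sum(x * x for x in pa) * sum(y * y for y in pb)
        )
        assert pianka_overlap(a, b) == pytest.approx(direct)


class TestPercentFO:
    def test_printed_definition(self, table1):
        samples = {"f1": {"Lep", "Dip"}, "f2": {"Lep"}, "f3": {"Lep"}}
        fo = percent_fo_by_order(table1, "P. austriacus", samples)
        assert fo == {"Dip": 25.0, "Lep": 75.0}

    def test_single_order_is_hundred_percent(self, table1):
        fo = percent_fo_by_order(table1, "P. auritus", {"f1": {"Lep"}})
        assert fo == {"Lep": 100.0}

    @pytest.mark.parametrize("seed", range(3))
    def test_sums_to_hundred(self, table1, seed):
        rng = np.random.default_rng(seed)
        orders = ["Lep", "Dip", "Col", "Ara"]
        samples = {
            f"f{i}": {o for o in orders if rng.random() < 0.5} | {"Lep"}
            for i in range(10)
        }
        fo = percent_fo_by_order(table1, "P. auritus", samples)
        assert sum(fo.values()) == pytest.approx(100, abs=0.01)


class TestFamilyShare:
    def test_noctuid_share_for_both_predators(self, table1):
        assert family_share(table1, "P. austriacus", "Lepidoptera", "Noctuidae") == 71.0
        assert family_share(table1, "P. auritus", "Lepidoptera", "Noctuidae") == 83.3

    def test_family_equal_to_order_saturates(self, table1):
        assert family_share(table1, "P. austriacus", "Neuroptera", "Chrysopidae") == 100.0

    def test_absent_order_fails(self, table1):
        with pytest.raises(ValueError):
            family_share(table1, "P. austriacus", "Araneae", "Anyphaenidae")


class TestSampleSummary:
    def test_arithmetic(self):
        s = sample_summary({"a": {1, 2, 3}, "b": {1, 2, 3, 4, 5}, "c": set(range(7))})
        assert (s.mean, s.min, s.max) == (5.0, 3, 7)

    def test_single_sample_sd_zero(self):
        assert sample_summary({"a": {1, 2}}).sd == 0.0

    def test_matches_planted_counts_at_zero_error(self, panel5):
        from motudiet import ReadSimConfig, run_filter_chain, simulate_reads

        ids = [t.taxon_id for t in panel5]
        diet = {"S0": ids[:2], "S1": ids[:4], "S2": ids}
        config = ReadSimConfig(
            reads_per_sample=300, substitution_error_rate=0.0, seed=6
        )
        reads, truth, tag_map = simulate_reads(panel5, diet, config)
        planted = truth.groupby("sample_id")["taxon_id"].nunique()
        summary = sample_summary(
            {s: set(g["taxon_id"]) for s, g in truth.groupby("sample_id")}
        )
        assert summary.per_sample_counts == planted.tolist()


class TestUtilizationMatrix:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            UtilizationMatrix(pd.DataFrame({"P": [-1, 2]}, index=["a", "b"]))

    def test_tsv_roundtrip(self, table1, tmp_path):
        path = tmp_path / "m.tsv"
        table1.to_tsv(path)
        back = UtilizationMatrix.from_tsv(path)
        assert back.data.equals(table1.data)
        assert list(back.annotations["order"]) == list(table1.annotations["order"])
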