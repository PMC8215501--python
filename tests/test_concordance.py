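"""Concordance: Venn overlaps, concurrent detection, trio de novo rates."""

import pytest

from svtrr.concordance import (concurrent_detection, denovo_rate,
                               overlap_rate_percent, pairwise_overlap,
                               three_way_overlap)
from svtrr.regions import Region, RegionSet
from svtrr.synthetic import (CallsetProfile, SyntheticConfig, TrioConfig,
                             derive_callset, generate_trio, generate_truth)
from _helpers import mk

BENCH = RegionSet("bench", [Region("1", 0, 10_000_000),
                            Region("2", 0, 10_000_000),
                            Region("3", 0, 10_000_000)])


class TestPairwiseOverlap:
    def test_identical_sets_fully_shared(self):
        a = [mk("INS", pos=p) for p in (1000, 5000, 9000)]
        summary = pairwise_overlap(a, list(a))
        assert summary.venn_counts["A"]["AB"] == 3
        assert summary.overlap_rate["A"] == 1.0

    def test_disjoint_sets_share_nothing(self):
        a = [mk("INS", pos=1000)]
        b = [mk("INS", pos=900_000)]
        summary = pairwise_overlap(a, b)
        assert summary.venn_counts["A"] == {"A": 1, "AB": 0}
        assert summary.overlap_rate["B"] == 0.0

    def test_planted_shared_fraction_recovered(self):
        bundle = generate_truth(SyntheticConfig(seed=5, n_truth=300))
        derive_callset(bundle, CallsetProfile("a", fn_rate=0.2, fp_rate=0.1), seed=1)
        derive_callset(bundle, CallsetProfile("b", fn_rate=0.4, fp_rate=0.1), seed=2)
        a, b = bundle.callsets["a"], bundle.callsets["b"]
        ids = lambda recs: {r.extras["label"].split(":")[1] for r in recs
                            if r.extras["label"].startswith("TP:")}
        expected_shared = len(ids(a) & ids(b))
        summary = pairwise_overlap(a, b, names=("a", "b"))
        assert summary.venn_counts["a"]["ab"] == expected_shared

    def test_venn_reconstruction(self):
        a = [mk("INS", pos=p) for p in (1000, 5000)]
        b = [mk("INS", pos=1020)]
        summary = pairwise_overlap(a, b)
        assert sum(summary.venn_counts["A"].values()) == len(a)
        assert sum(summary.venn_counts["B"].values()) == len(b)


class TestThreeWayOverlap:
    def test_identical_sets_all_in_center(self):
        a = [mk("INS", pos=p) for p in (1000, 5000, 9000)]
        summary = three_way_overlap(a, list(a), list(a))
        for name in "ABC":
            assert summary.venn_counts[name] == {"ABC": 3}

    def test_pairwise_disjoint_plants_only_unique_regions(self):
        a = [mk("INS", pos=1000)]
        b = [mk("INS", pos=500_000)]
        c = [mk("DEL", pos=900_000, end=900_400)]
        summary = three_way_overlap(a, b, c)
        assert summary.venn_counts == {"A": {"A": 1}, "B": {"B": 1}, "C": {"C": 1}}

    def test_per_set_reconstruction_and_rate_order_invariance(self):
        bundle = generate_truth(SyntheticConfig(seed=6, n_truth=200))
        for seed, (name, fn) in enumerate((("x", 0.1), ("y", 0.3), ("z", 0.5))):
            derive_callset(bundle, CallsetProfile(name, fn_rate=fn, fp_rate=0.1),
                           seed=seed + 1)
        x, y, z = (bundle.callsets[n] for n in "xyz")
        s1 = three_way_overlap(x, y, z, names=("x", "y", "z"))
        for name, recs in (("x", x), ("y", y), ("z", z)):
            assert sum(s1.venn_counts[name].values()) == len(recs)
        s2 = three_way_overlap(x, z, y, names=("x", "z", "y"))
        assert s1.overlap_rate["x"] == s2.overlap_rate["x"]


class TestConcurrentDetection:
    def test_truth_found_by_all_callsets(self):
        truth = [mk("INS", pos=p) for p in (1000, 5000)]
        callsets = {f"c{i}": [mk("INS", pos=p + 10) for p in (1000, 5000)]
                    for i in range(3)}
        hist = concurrent_detection(truth, callsets, BENCH)
        assert hist["proportions"][3] == 1.0

    def test_empty_callsets_put_all_mass_at_zero(self):
        truth = [mk("INS", pos=1000)]
        hist = concurrent_detection(truth, {"a": [], "b": []}, BENCH)
        assert hist["proportions"][0] == 1.0

    def test_planted_detection_pattern(self):
        truth = [mk("INS", pos=p) for p in (1000, 5000, 9000, 13_000)]
        near = lambda *idx: [mk("INS", pos=truth[i].pos + 20) for i in idx]
        callsets = {"a": near(0, 1, 2), "b": near(0, 1), "c": near(0)}
        hist = concurrent_detection(truth, callsets, BENCH)
        assert hist["counts"] == {0: 1, 1: 1, 2: 1, 3: 1}
        assert sum(hist["proportions"].values()) == pytest.approx(1.0)


class TestOverlapRatePercent:
    def test_rounding_to_nearest_percent(self):
        assert overlap_rate_percent(1, 3) == 33
        assert overlap_rate_percent(2, 3) == 67

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            overlap_rate_percent(1, 0)


class TestDenovoRate:
    TRR = RegionSet("trr", [Region("1", 0, 10_000_000)])

    def test_son_fully_inherited_gives_zero(self):
        father = [mk("INS", pos=1000)]
        mother = [mk("DEL", pos=5000, end=5300)]
        son = [mk("INS", pos=1010), mk("DEL", pos=5010, end=5310)]
        res = denovo_rate(son, father, mother, self.TRR)
        assert res["all"].denovo_rate == 0.0

    def test_empty_parents_give_rate_one(self):
        son = [mk("INS", pos=1000)]
        res = denovo_rate(son, [], [], self.TRR)
        assert res["all"].denovo_rate == 1.0

    def test_empty_son_is_undefined(self):
        res = denovo_rate([], [mk("INS", pos=1000)], [], self.TRR)
        assert res["all"].denovo_rate is None

    def test_planted_rate_recovered_exactly(self):
        config = SyntheticConfig(seed=9, n_truth=500,
                                 trio=TrioConfig(denovo_rate=0.2))
        trio = generate_trio(config)
        res = denovo_rate(trio["son"], trio["father"], trio["mother"], trio["trr"])
        assert res["all"].denovo_rate == trio["expected"]["denovo_rate"] == 0.2

    def test_growing_parent_callsets_cannot_increase_rate(self):
        config = SyntheticConfig(seed=10, n_truth=300,
                                 trio=TrioConfig(denovo_rate=0.3))
        trio = generate_trio(config)
        full = denovo_rate(trio["son"], trio["father"], trio["mother"],
                           trio["trr"])["all"].denovo_rate
        half = denovo_rate(trio["son"], trio["father"][: len(trio["father"]) // 2],
                           trio["mother"], trio["trr"])["all"].denovo_rate
        assert full <= half
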