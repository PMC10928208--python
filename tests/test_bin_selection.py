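import numpy as np
import pytest

from corebin import bin_selection as bs
from corebin.io_formats import Bin, BinSet, Contig, ContigPool


def brute_force_inliers(values, k):
    """Quartiles by explicit linear interpolation of order statistics."""
    xs = sorted(values)
    n = len(xs)

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[hi] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    tol = 1e-9 * max(1.0, abs(lo), abs(hi))  # edges may equal data points
    return [i for i, x in enumerate(values) if lo - tol <= x <= hi + tol]


class TestCoverageRange:
    def test_tied_depths_keep_everything_inclusive(self):
        rng = bs.core_coverage_range([10.0] * 5, k=0)
        assert rng.iqr == 0
        assert all(rng.contains(10.0) for _ in range(5))
        # the literal strict reading would void the bin
        assert not rng.contains(10.0, strict=True)

    def test_single_extreme_outlier(self):
        depths = [10.0, 10.0, 10.0, 1000.0]
        rng = bs.core_coverage_range(depths, k=2)
        flags = [rng.contains(d) for d in depths]
        assert flags == [True, True, True, False]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            bs.core_coverage_range([], k=0)

    @pytest.mark.parametrize("k", [0.0, 0.5, 1.0, 2.0])
    def test_matches_brute_force_oracle(self, k):
        rng_gen = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng_gen.integers(1, 40))
            vals = np.exp(rng_gen.normal(3, 1, size=n))
            band = bs.core_coverage_range(vals, k)
            got = [i for i, v in enumerate(vals) if band.contains(v)]
            assert got == brute_force_inliers(vals, k)


class TestEquationArithmetic:
    def _pairs(self, ratios):
        return [bs.InlierPair("a", "b", 100.0, 2000, 2000, r * 10.0, 10.0)
                for r in ratios]

    def test_constant_ratio(self):
        assert bs.depth_normalization_ratio(self._pairs([2, 2, 2])) == pytest.approx(2.0)

    def test_identity_ratio(self):
        assert bs.depth_normalization_ratio(self._pairs([1, 1])) == pytest.approx(1.0)

    def test_mixed_ratios(self):
        pairs = [bs.InlierPair("a", "b", 100.0, 2000, 2000, ca, cb)
                 for ca, cb in [(20, 10), (30, 20), (45, 30)]]
        assert bs.depth_normalization_ratio(pairs) == pytest.approx(5 / 3)

    def test_no_pairs_is_the_no_evidence_path(self):
        with pytest.raises(ValueError):
            bs.depth_normalization_ratio([])

    def test_delta_exact_proportionality(self):
        assert bs.delta_coverage(30, 15, 2.0) == 0.0

    def test_delta_direct_arithmetic(self):
        assert bs.delta_coverage(50, 20, 2.0) == pytest.approx(10.0)

    def test_delta_swap_consistency(self):
        # swapping bins with x' = 1/x rescales delta by exactly x'
        rng = np.random.default_rng(3)
        for _ in range(50):
            mu_a, mu_b, x = rng.uniform(1, 50, size=3)
            d1 = bs.delta_coverage(mu_a, mu_b, x)
            d2 = bs.delta_coverage(mu_b, mu_a, 1 / x)
            assert d1 == pytest.approx(x * d2)


def _make_pool(n, seed=0, depth=10.0):
    from conftest import random_dna
    rng = np.random.default_rng(seed)
    pool = ContigPool()
    pool.samples = ["s0"]
    for i in range(n):
        pool.add(Contig(f"c{i}", random_dna(rng, 2000), np.array([depth])))
    return pool


class TestHybridMerging:
    def test_identical_bins_merge_and_deduplicate(self):
        pool = _make_pool(3)
        sets = [BinSet("x", [Bin("b1", ["c0", "c1", "c2"])]),
                BinSet("y", [Bin("b2", ["c0", "c1", "c2"])])]
        hybrid = bs.merge_hybrid_bins(sets, pool)
        assert len(hybrid) == 1
        assert sorted(hybrid.bins[0].contig_ids) == ["c0", "c1", "c2"]

    def test_overlap_threshold_splits_merge_from_no_merge(self):
        pool = _make_pool(20)
        big = [f"c{i}" for i in range(10)]
        mostly_same = big[:9] + ["c10"]      # 90% shared bp
        barely_same = big[:1] + [f"c{i}" for i in range(11, 20)]  # 10% shared
        sets = [BinSet("x", [Bin("b1", big)]),
                BinSet("y", [Bin("b2", mostly_same), Bin("b3", barely_same)])]
        hybrid = bs.merge_hybrid_bins(sets, pool)
        names = sorted(b.bin_id for b in hybrid)
        assert len(hybrid) == 2
        assert any(b.bin_id.startswith("hybrid_") for b in hybrid)
        merged = next(b for b in hybrid if b.bin_id.startswith("hybrid_"))
        assert set(merged.contig_ids) == set(big) | {"c10"}

    def test_disjoint_bins_pass_through(self):
        pool = _make_pool(6)
        sets = [BinSet("x", [Bin("b1", ["c0", "c1"]), Bin("b2", ["c2", "c3"]),
                             Bin("b3", ["c4", "c5"])])]
        hybrid = bs.merge_hybrid_bins(sets, pool)
        assert sorted(b.bin_id for b in hybrid) == ["b1", "b2", "b3"]


class TestGrouping:
    def test_single_linkage_chains_transitively(self):
        """A~B and B~C grouped even though A and C share nothing."""
        from conftest import random_dna
        rng = np.random.default_rng(9)
        seg1, seg2 = random_dna(rng, 12_000), random_dna(rng, 12_000)
        pool = ContigPool()
        pool.samples = ["s0"]
        pool.add(Contig("a1", seg1, np.array([10.0])))
        pool.add(Contig("b1", seg1, np.array([10.0])))
        pool.add(Contig("b2", seg2, np.array([10.0])))
        pool.add(Contig("c1", seg2, np.array([10.0])))
        pool.add(Contig("d1", random_dna(rng, 12_000), np.array([10.0])))
        binset = BinSet("g", [Bin("A", ["a1"]), Bin("B", ["b1", "b2"]),
                              Bin("C", ["c1"]), Bin("D", ["d1"])])
        groups = bs.group_bins(binset, pool)
        assert ["A", "B", "C"] in groups and ["D"] in groups

    def test_all_distinct_bins_stay_singletons(self):
        from conftest import random_dna
        rng = np.random.default_rng(10)
        pool = ContigPool()
        pool.samples = ["s0"]
        bins = []
        for i in range(3):
            pool.add(Contig(f"x{i}", random_dna(rng, 8000), np.array([10.0])))
            bins.append(Bin(f"B{i}", [f"x{i}"]))
        groups = bs.group_bins(BinSet("g", bins), pool)
        assert groups == [["B0"], ["B1"], ["B2"]]


class TestPairing:
    def test_copies_pair_one_to_one_at_full_identity(self):
        from conftest import random_dna
        rng = np.random.default_rng(12)
        pool = ContigPool()
        pool.samples = ["s0"]
        for i in range(5):
            seq = random_dna(rng, 3000)
            pool.add(Contig(f"a{i}", seq, np.array([20.0])))
            pool.add(Contig(f"b{i}", seq, np.array([10.0])))
        pairs = bs.pair_inliers(Bin("A", [f"a{i}" for i in range(5)]),
                                Bin("B", [f"b{i}" for i in range(5)]), pool)
        assert len(pairs) == 5
        assert all(p.ani == 100.0 for p in pairs)
        assert {(p.contig_a, p.contig_b) for p in pairs} == \
            {(f"a{i}", f"b{i}") for i in range(5)}

    def test_short_contigs_never_pair(self):
        from conftest import random_dna
        rng = np.random.default_rng(13)
        pool = ContigPool()
        pool.samples = ["s0"]
        seq = random_dna(rng, 800)  # below the 1000 bp pairing threshold
        pool.add(Contig("a0", seq, np.array([20.0])))
        pool.add(Contig("b0", seq, np.array([10.0])))
        assert bs.pair_inliers(Bin("A", ["a0"]), Bin("B", ["b0"]), pool) == []

    def test_unrelated_genomes_never_pair(self):
        from conftest import random_dna
        rng = np.random.default_rng(14)
        pool = ContigPool()
        pool.samples = ["s0"]
        for i in range(3):
            pool.add(Contig(f"a{i}", random_dna(rng, 3000), np.array([20.0])))
            pool.add(Contig(f"b{i}", random_dna(rng, 3000), np.array([10.0])))
        assert bs.pair_inliers(Bin("A", ["a0", "a1", "a2"]),
                               Bin("B", ["b0", "b1", "b2"]), pool) == []


class TestClassification:
    def _decision(self, delta, n_pairs=5):
        d = bs.RedundancyDecision("A", "B", n_pairs, 1.0, 10.0, 10.0, delta,
                                  float("nan"), "")
        d.features = {f: 1.0 for f in bs.FEATURE_ORDER}
        return d

    def test_threshold_mode(self):
        assert bs.classify_redundancy(self._decision(0.0), w=5.0).verdict == "redundant"
        assert bs.classify_redundancy(self._decision(9.0), w=5.0).verdict == "nonredundant"

    def test_no_evidence_retains_both(self):
        d = self._decision(float("nan"), n_pairs=0)
        assert bs.classify_redundancy(d).verdict == "no-evidence"

    def test_model_mode_requires_model(self):
        with pytest.raises(ValueError, match="threshold"):
            bs.classify_redundancy(self._decision(1.0), mode="model")


class TestSelection:
    def test_exact_scaled_copy_gives_xbar_c_delta_zero(self):
        """A2 = A1 with depths scaled by c exactly: X = c, delta = 0."""
        from conftest import random_dna
        rng = np.random.default_rng(15)
        c = 1.7
        pool = ContigPool()
        pool.samples = ["s0", "s1"]
        for i in range(12):
            seq = random_dna(rng, 2500)
            d = rng.uniform(5, 40, size=2)
            pool.add(Contig(f"a{i}", seq, d))
            pool.add(Contig(f"b{i}", seq, d / c))
        dec = bs.evaluate_pair(Bin("A", [f"a{i}" for i in range(12)]),
                               Bin("B", [f"b{i}" for i in range(12)]), pool)
        assert dec.x_bar == pytest.approx(c, abs=1e-9)
        assert dec.delta == pytest.approx(0.0, abs=1e-9)

    def test_survivor_is_larger_inlier_bp(self):
        from conftest import random_dna
        rng = np.random.default_rng(16)
        pool = ContigPool()
        pool.samples = ["s0"]
        a_ids, b_ids = [], []
        for i in range(10):
            seq = random_dna(rng, 2000)
            pool.add(Contig(f"a{i}", seq, np.array([20.0])))
            a_ids.append(f"a{i}")
            if i < 9:  # B misses one contig: ~10% less bp
                pool.add(Contig(f"b{i}", seq, np.array([10.0])))
                b_ids.append(f"b{i}")
        binset = BinSet("h", [Bin("A", a_ids), Bin("B", b_ids)], stage="hybrid")
        dec = bs.evaluate_pair(Bin("A", a_ids), Bin("B", b_ids), pool)
        dec = bs.classify_redundancy(dec, w=5.0)
        assert dec.verdict == "redundant"
        selected, archived = bs.select_nonredundant(binset, [["A", "B"]], [dec], pool)
        assert [b.bin_id for b in selected] == ["A"]
        assert [b.bin_id for b in archived] == ["B"]

    def test_empty_decisions_keep_everything(self, small_pool):
        binset = BinSet("h", [Bin("A", ["c0"]), Bin("B", ["c1"])], stage="hybrid")
        selected, archived = bs.select_nonredundant(
            binset, [["A"], ["B"]], [], small_pool)
        assert len(selected) == 2 and len(archived) == 0

    def test_never_removes_both_bins_of_a_pair(self, redundancy40):
        p = redundancy40
        decisions = []
        groups = []
        for a, b, _ in p.labels.redundant_pairs:
            d = bs.evaluate_pair(p.binset.get(a), p.binset.get(b), p.pool)
            decisions.append(bs.classify_redundancy(d))
            groups.append(sorted([a, b]))
        selected, archived = bs.select_nonredundant(p.binset, groups, decisions, p.pool)
        kept = {b.bin_id for b in selected}
        gone = {b.bin_id for b in archived}
        for a, b, _ in p.labels.redundant_pairs:
            assert (a in kept) or (b in kept)
        assert kept | gone == {b.bin_id for b in p.binset}
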