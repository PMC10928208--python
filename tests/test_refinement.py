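import numpy as np
import pytest

from corebin import refinement as rf
from corebin.io_formats import Bin, BinSet, Contig, ContigPool, LinkTable


class TestCCC:
    def _contig(self, depths):
        return Contig("c", "ACGT" * 300, np.asarray(depths, dtype=float))

    def test_two_samples_single_ratio(self):
        assert rf.compute_ccc(self._contig([4, 2]), 2) == pytest.approx([2.0])

    def test_equal_depths_all_ones(self):
        assert rf.compute_ccc(self._contig([5, 5, 5]), 3) == pytest.approx([1, 1, 1])

    def test_three_samples_pair_order(self):
        # pairs (0,1), (0,2), (1,2)
        assert rf.compute_ccc(self._contig([6, 3, 2]), 3) == \
            pytest.approx([2.0, 3.0, 1.5])

    def test_single_sample_empty_vector(self):
        assert rf.compute_ccc(self._contig([6]), 1).size == 0

    def test_zero_denominator_pseudocount(self):
        v = rf.compute_ccc(self._contig([1, 0]), 2)
        assert v[0] == pytest.approx(1 / 0.01)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            rf.compute_ccc(self._contig([1, 2]), 3)


def _community_bin(seed=21, n=20, depth=20.0, n_samples=3):
    """A homogeneous single-genome bin with NB-like depth jitter."""
    from conftest import random_dna
    rng = np.random.default_rng(seed)
    # one compositional model for the whole bin: reuse chunks of one genome
    genome = random_dna(rng, n * 3000)
    pool = ContigPool()
    pool.samples = [f"s{i}" for i in range(n_samples)]
    ids = []
    for i in range(n):
        depths = depth * rng.gamma(50, 1 / 50, size=n_samples)
        pool.add(Contig(f"n{i}", genome[i * 3000:(i + 1) * 3000], depths))
        ids.append(f"n{i}")
    return pool, ids


class TestMultidimOutliers:
    def test_homogeneous_bin_has_no_outliers(self):
        pool, ids = _community_bin()
        verdicts = rf.multidim_iqr_outliers(Bin("b", ids), pool)
        assert not any(v.is_outlier for v in verdicts)

    def test_planted_foreign_contigs_flagged(self):
        from conftest import random_dna
        pool, ids = _community_bin()
        rng = np.random.default_rng(99)
        for i in range(3):  # 5x deeper than the bin's native coverage
            pool.add(Contig(f"f{i}", random_dna(rng, 3000),
                            100.0 * rng.gamma(50, 1 / 50, size=3)))
        all_ids = ids + ["f0", "f1", "f2"]
        verdicts = {v.contig_id: v
                    for v in rf.multidim_iqr_outliers(Bin("b", all_ids), pool,
                                                      operative_k=2.0)}
        assert all(verdicts[f"f{i}"].is_outlier for i in range(3))
        assert not any(verdicts[i].is_outlier for i in ids)
        # the diagnostic bands at the smaller k agree on the planted contigs
        assert all(verdicts[f"f{i}"].flags_by_k[1.0] for i in range(3))

    def test_tiny_bin_never_removes(self):
        pool, ids = _community_bin(n=3)
        pool["n2"].depths = np.array([500.0, 500.0, 500.0])  # wild outlier
        verdicts = rf.multidim_iqr_outliers(Bin("b", ids), pool)
        assert not any(v.is_outlier for v in verdicts)
        assert all(not v.is_outlier for v in verdicts)

    def test_flagged_dims_nonempty_iff_outlier(self):
        pool, ids = _community_bin()
        pool["n0"].depths = np.array([900.0, 900.0, 900.0])
        for v in rf.multidim_iqr_outliers(Bin("b", ids), pool):
            assert v.is_outlier == bool(v.flagged_dims)


class TestRemoveOutliers:
    def test_flagged_contigs_move_to_pool(self):
        pool, ids = _community_bin()
        verdicts = {"b": [rf.OutlierVerdict(i, 0.0, ["depth"] if i in ("n0", "n1") else [],
                                            i in ("n0", "n1")) for i in ids]}
        odbs, pooled = rf.remove_outliers(BinSet("s", [Bin("b", ids)]), verdicts,
                                          pool, floor_bp=1000)
        assert len(odbs.get("b").contig_ids) == 18
        assert sorted(pooled) == ["n0", "n1"]

    def test_no_flags_is_identity(self):
        pool, ids = _community_bin()
        odbs, pooled = rf.remove_outliers(BinSet("s", [Bin("b", ids)]), {}, pool,
                                          floor_bp=1000)
        assert odbs.get("b").contig_ids == ids and pooled == []

    def test_bin_below_floor_dissolves_entirely(self):
        pool, ids = _community_bin(n=20)  # 60 kb total
        verdicts = {"b": [rf.OutlierVerdict(i, 0.0, ["depth"], True)
                          for i in ids[:11]]}  # 33 kb flagged -> 27 kb left
        odbs, pooled = rf.remove_outliers(BinSet("s", [Bin("b", ids)]), verdicts,
                                          pool, floor_bp=50_000)
        assert len(odbs) == 0
        assert sorted(pooled) == sorted(ids)

    def test_contig_multiset_conserved(self, contamination10x5):
        p = contamination10x5
        verdicts = {b.bin_id: rf.multidim_iqr_outliers(b, p.pool) for b in p.binset}
        odbs, pooled = rf.remove_outliers(p.binset, verdicts, p.pool)
        before = sorted(c for b in p.binset for c in b.contig_ids)
        after = sorted([c for b in odbs for c in b.contig_ids] + pooled)
        assert before == after


def _retrieval_pool():
    """Two-genome community; per genome the two contigs most central in
    coverage and composition are withheld (inliers by construction, as
    the retrieval gate expects) and can be re-homed by link evidence."""
    from corebin import synthetic as syn
    com = syn.simulate_community(syn.CommunitySpec(n_genomes=2, seed=31))
    pool = com.pool
    tnf = rf._TnfCache(pool)
    bins, withheld = [], {}
    for b, gid in enumerate(sorted(com.order)):
        ids = com.order[gid]
        dims = rf._dimension_values(ids, pool, tnf)
        score = {}
        for cid in ids:
            parts = []
            for vals in dims.values():
                arr = np.asarray(list(vals.values()))
                q1, q3 = np.percentile(arr, [25, 75])
                spread = max(q3 - q1, 1e-9)
                parts.append(abs(vals[cid] - np.median(arr)) / spread)
            score[cid] = max(parts)
        w0, w1 = sorted(ids, key=lambda c: score[c])[:2]
        bins.append(Bin(f"bin{b}", [c for c in ids if c not in (w0, w1)]))
        withheld[f"g{b}_w0"], withheld[f"g{b}_w1"] = w0, w1
    return pool, BinSet("odb", bins), withheld


class TestRetrieval:
    def test_linked_inlier_assigned_first_iteration(self):
        pool, odbs, wh = _retrieval_pool()
        w0, anchor = wh["g0_w0"], odbs.get("bin0").contig_ids[-1]
        links = LinkTable([(w0, anchor, 5)])
        res = rf.retrieve_sequences(odbs, [w0], pool, links)
        assert res.log == [(1, w0, "bin0", 5)]
        assert w0 in res.binset.get("bin0").contig_ids

    def test_support_tie_never_assigns(self):
        pool, odbs, wh = _retrieval_pool()
        w0 = wh["g0_w0"]
        links = LinkTable([(w0, odbs.get("bin0").contig_ids[0], 4),
                           (w0, odbs.get("bin1").contig_ids[0], 4)])
        res = rf.retrieve_sequences(odbs, [w0], pool, links)
        assert res.log == [] and res.unbinned == [w0]

    def test_zero_links_never_assigns(self):
        pool, odbs, wh = _retrieval_pool()
        res = rf.retrieve_sequences(odbs, [wh["g0_w0"]], pool, LinkTable())
        assert res.log == []

    def test_below_min_support_never_assigns(self):
        pool, odbs, wh = _retrieval_pool()
        w0 = wh["g0_w0"]
        links = LinkTable([(w0, odbs.get("bin0").contig_ids[0], 2)])
        res = rf.retrieve_sequences(odbs, [w0], pool, links, min_support=3)
        assert res.log == []

    def test_two_hop_chain_needs_two_iterations(self):
        pool, odbs, wh = _retrieval_pool()
        w0, w1 = wh["g0_w0"], wh["g0_w1"]
        # w1 links only to w0; w0 links to the bin
        links = LinkTable([(w0, odbs.get("bin0").contig_ids[-1], 5), (w1, w0, 5)])
        res = rf.retrieve_sequences(odbs, [w0, w1], pool, links)
        entries = {c: it for it, c, b, s in res.log}
        assert entries == {w0: 1, w1: 2}

    def test_fixpoint_idempotence(self, retrieval10):
        p = retrieval10
        res = rf.retrieve_sequences(p.binset, p.unbinned, p.pool, p.links)
        res2 = rf.retrieve_sequences(res.binset, res.unbinned, p.pool, p.links)
        assert res2.log == []

    def test_contig_conservation_through_refinement(self, retrieval10):
        p = retrieval10
        before = sorted([c for b in p.binset for c in b.contig_ids] + list(p.unbinned))
        res = rf.retrieve_sequences(p.binset, p.unbinned, p.pool, p.links)
        after = sorted([c for b in res.binset for c in b.contig_ids] + res.unbinned)
        assert before == after
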