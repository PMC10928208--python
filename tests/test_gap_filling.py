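import numpy as np
import pytest

from corebin import gap_filling as gf
from corebin.io_formats import Bin, BinSet, Contig, ContigPool


@pytest.fixture()
def genome_pool():
    """A known genome cut into two bin contigs with a 200 bp internal
    gap, plus donors engineered around the rOLC thresholds."""
    from conftest import random_dna
    rng = np.random.default_rng(41)
    genome = random_dna(rng, 30_000)
    pool = ContigPool()
    pool.samples = ["s0"]
    # T1 = genome[0:12000], gap 200, T2 = genome[12200:24000]
    pool.add(Contig("T1", genome[:12_000], np.array([20.0])))
    pool.add(Contig("T2", genome[12_200:24_000], np.array([20.0])))
    return genome, pool


def test_exact_bridge_arithmetic(genome_pool):
    genome, pool = genome_pool
    pool.add(Contig("D", genome[11_600:12_600], np.array([20.0])))  # 400 bp flanks
    bins = BinSet("r", [Bin("b", ["T1", "T2"])], stage="refined")
    out, events = gf.rolc_round(bins, {"b": ["D"]}, pool, min_overlap=300)
    (e,) = events
    assert e.kind == "bridge" and e.target_ids == ("T1", "T2")
    assert e.merged_len == 12_000 + 11_800 + 200  # l1 + l2 + gap
    merged = pool[e.merged_id].seq
    assert merged == genome[:24_000]
    assert len(out.get("b").contig_ids) == 1


def test_bridge_rejected_below_min_overlap(genome_pool):
    genome, pool = genome_pool
    pool.add(Contig("D", genome[11_750:12_450], np.array([20.0])))  # 250 bp flanks
    bins = BinSet("r", [Bin("b", ["T1", "T2"])], stage="refined")
    _, events = gf.rolc_round(bins, {"b": ["D"]}, pool, min_overlap=300)
    assert events == []


def test_second_round_threshold_is_stricter(genome_pool):
    genome, pool = genome_pool
    pool.add(Contig("D", genome[11_600:12_600], np.array([20.0])))  # 400 bp flanks
    bins = BinSet("r", [Bin("b", ["T1", "T2"])], stage="refined")
    _, events = gf.rolc_round(bins, {"b": ["D"]}, pool, min_overlap=500)
    assert events == []


def test_merged_length_cap_rejects_long_gap():
    """A bridge whose product exceeds 105% of the summed targets is refused."""
    from conftest import random_dna
    rng = np.random.default_rng(42)
    genome = random_dna(rng, 30_000)
    pool = ContigPool()
    pool.samples = ["s0"]
    # 2 kb targets around a 1 kb gap: merged 5000 >= 1.05 * 4000
    pool.add(Contig("T1", genome[:2000], np.array([20.0])))
    pool.add(Contig("T2", genome[3000:5000], np.array([20.0])))
    pool.add(Contig("D", genome[1500:3500], np.array([20.0])))
    bins = BinSet("r", [Bin("b", ["T1", "T2"])], stage="refined")
    _, events = gf.rolc_round(bins, {"b": ["D"]}, pool, min_overlap=300)
    assert all(e.kind != "bridge" for e in events)


def test_double_protruding_donor_rejected_as_extension():
    from conftest import random_dna
    rng = np.random.default_rng(43)
    genome = random_dna(rng, 10_000)
    pool = ContigPool()
    pool.samples = ["s0"]
    pool.add(Contig("T1", genome[4000:6000], np.array([20.0])))  # contained in donor
    pool.add(Contig("D", genome[3000:7000], np.array([20.0])))
    bins = BinSet("r", [Bin("b", ["T1"])], stage="refined")
    _, events = gf.rolc_round(bins, {"b": ["D"]}, pool, min_overlap=300)
    assert events == []


def test_exact_extension_arithmetic():
    from conftest import random_dna
    rng = np.random.default_rng(44)
    genome = random_dna(rng, 12_000)
    pool = ContigPool()
    pool.samples = ["s0"]
    pool.add(Contig("T1", genome[:10_000], np.array([20.0])))
    pool.add(Contig("D", genome[9_600:10_400], np.array([20.0])))  # extends right 400
    bins = BinSet("r", [Bin("b", ["T1"])], stage="refined")
    _, events = gf.rolc_round(bins, {"b": ["D"]}, pool, min_overlap=300)
    (e,) = events
    assert e.kind == "extend"
    assert e.merged_len == 10_000 + 800 - 400  # l1 + ld - overlap
    assert pool[e.merged_id].seq == genome[:10_400]


def test_no_donors_is_a_no_op(genome_pool):
    _, pool = genome_pool
    bins = BinSet("r", [Bin("b", ["T1", "T2"])], stage="refined")
    out, events, stats = gf.gap_fill(bins, BinSet("a", []), [], pool)
    assert events == []
    assert out.get("b").contig_ids == ["T1", "T2"]


def test_low_identity_donor_never_merges(genome_pool):
    genome, pool = genome_pool
    donor = list(genome[11_600:12_600])
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in range(0, len(donor), 40):  # 2.5% divergence < 99% identity
        donor[p] = sub[donor[p]]
    pool.add(Contig("D", "".join(donor), np.array([20.0])))
    bins = BinSet("r", [Bin("b", ["T1", "T2"])], stage="refined")
    _, events = gf.rolc_round(bins, {"b": ["D"]}, pool, min_overlap=300)
    assert events == []


def test_donor_scoping_by_group(contamination10x5):
    """Archived donors reach only bins of their own ANI group."""
    p = contamination10x5
    bins = [b for b in p.binset]
    refined = BinSet("r", bins[:2], stage="refined")
    archive = BinSet("a", [Bin("arch0", list(bins[0].contig_ids), source="archived")])
    groups = [[bins[0].bin_id, "arch0"], [bins[1].bin_id]]
    donors = gf.collect_donors(archive, refined, groups, p.pool)
    assert donors[bins[1].bin_id] == []
    # own contigs are never donors to their own bin
    assert set(donors[bins[0].bin_id]).isdisjoint(set(bins[0].contig_ids))


def test_gapfill_fixture_end_to_end(gapfill5):
    p = gapfill5
    before_n50 = gf.n50([p.pool[c].length for c in p.binset.get("bin_g00").contig_ids])
    out, events, stats = gf.gap_fill(p.binset, BinSet("a", []), [], p.pool,
                                     unbinned=p.unbinned)
    genome = p.community.references["g00"]
    s = stats["bin_g00"]
    assert s["after"]["n50"] > before_n50
    assert s["after"]["total_bp"] >= s["before"]["total_bp"]
    for b in out:
        for cid in b.contig_ids:
            assert p.pool[cid].seq in genome  # no invented bases


def test_event_log_deterministic(gapfill5):
    import copy
    from corebin import synthetic as syn
    runs = []
    for _ in range(2):
        p = syn.make_benchmark("gapfill5", seed=1)
        _, events, _ = gf.gap_fill(p.binset, BinSet("a", []), [], p.pool,
                                   unbinned=p.unbinned)
        runs.append([(e.kind, e.target_ids, e.donor_id, e.merged_len) for e in events])
    assert runs[0] == runs[1]
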