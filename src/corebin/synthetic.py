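"""Deterministic synthetic-community generator.

Every pipeline input can be emulated here: genomes with distinct
compositional signatures (order-k Markov chains perturbed from a
shared base model), fragmentation into contigs, multi-sample
negative-binomial read depths, planted redundant bins (re-fragmented
duplicates at a rescaled coverage), planted contaminant contigs,
withheld contigs with link evidence, and labeled truth throughout.
All randomness flows from a single seeded generator, so equal seeds
give byte-identical artifacts.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import (Bin, BinSet, Contig, ContigPool, LinkTable,
                         write_binset, write_contig_pool, write_depth_table,
                         write_link_table)

__all__ = ["CommunitySpec", "Community", "simulate_community",
           "DefectLabels", "PlantedCommunity", "plant_defects",
           "make_benchmark", "BENCHMARKS"]

READ_LEN = 150


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for one synthetic community.

    Defaults describe a desk-scale community: modest genome sizes keep
    every stage runnable in seconds while preserving the statistics the
    pipeline exercises (dozens of >=1 kb contigs per genome, lognormal
    abundances across samples, moderate NB coverage overdispersion).
    """

    n_genomes: int = 10
    genome_len_range: tuple[int, int] = (100_000, 160_000)
    markov_order: int = 3
    divergence: float = 0.1
    n_samples: int = 3
    abundance_mu: float = 3.0      # log-scale; median depth ~ e^3 ~ 20x
    abundance_sigma: float = 0.7
    depth_noise: float = 50.0      # NB dispersion r; per-contig depth CV ~ 1/sqrt(r)
    contig_len_mu: float = math.log(3000.0)
    contig_len_sigma: float = 0.5
    min_contig_len: int = 1000
    seed: int = 1

    def __post_init__(self):
        if self.n_genomes < 1 or self.n_samples < 1:
            raise ValueError("counts must be >= 1")
        if self.min_contig_len > self.genome_len_range[0]:
            raise ValueError("minimum contig length exceeds minimum genome length")


@dataclass
class Community:
    spec: CommunitySpec
    references: dict[str, str]
    pool: ContigPool
    truth: dict[str, str]                 # contig id -> genome id
    order: dict[str, list[str]]           # genome id -> contig ids in genomic order
    abundances: np.ndarray                # genomes x samples mean depth


def _base_transitions(rng: np.random.Generator, order: int) -> np.ndarray:
    n_ctx = 4 ** order
    return rng.dirichlet(np.full(4, 5.0), size=n_ctx)


def _perturb(base: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    logits = np.log(base) + divergence * rng.normal(size=base.shape)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def _markov_seq(trans: np.ndarray, length: int, order: int,
                rng: np.random.Generator) -> str:
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0
    mask = 4 ** order - 1
    bases = np.empty(length, dtype=np.uint8)
    u = rng.random(length)
    ctx = int(rng.integers(0, 4 ** order))
    for i in range(length):
        row = cum[ctx]
        b = 0
        x = u[i]
        while row[b] < x:
            b += 1
        bases[i] = b
        ctx = ((ctx << 2) | b) & mask
    return "".join("ACGT"[b] for b in bases)


def _fragment_lengths(total: int, spec: CommunitySpec, rng: np.random.Generator) -> list[int]:
    lens = []
    left = total
    while left > 0:
        ln = int(rng.lognormal(spec.contig_len_mu, spec.contig_len_sigma))
        ln = max(ln, spec.min_contig_len)
        if left - ln < spec.min_contig_len:
            ln = left
        lens.append(min(ln, left))
        left -= lens[-1]
    return lens


def _nb_depth(mean_depth: float, length: int, r: float, rng: np.random.Generator) -> float:
    """Depth via a negative-binomial read count at the given mean."""
    mean_reads = mean_depth * length / READ_LEN
    if mean_reads <= 0:
        return 0.0
    reads = rng.negative_binomial(r, r / (r + mean_reads))
    return reads * READ_LEN / length


def simulate_community(spec: CommunitySpec) -> Community:
    """Sample genomes, fragment them, and assign per-sample depths."""
    rng = np.random.default_rng(spec.seed)
    base = _base_transitions(rng, spec.markov_order)
    references: dict[str, str] = {}
    pool = ContigPool()
    pool.samples = [f"sample_{s}" for s in range(spec.n_samples)]
    truth: dict[str, str] = {}
    order: dict[str, list[str]] = {}
    abundances = np.exp(rng.normal(spec.abundance_mu, spec.abundance_sigma,
                                   size=(spec.n_genomes, spec.n_samples)))
    for gi in range(spec.n_genomes):
        gid = f"g{gi:02d}"
        glen = int(rng.integers(spec.genome_len_range[0], spec.genome_len_range[1] + 1))
        trans = _perturb(base, spec.divergence, rng)
        genome = _markov_seq(trans, glen, spec.markov_order, rng)
        references[gid] = genome
        order[gid] = []
        pos = 0
        for ci, ln in enumerate(_fragment_lengths(glen, spec, rng)):
            cid = f"{gid}_c{ci:03d}"
            depths = np.array([_nb_depth(abundances[gi, s], ln, spec.depth_noise, rng)
                               for s in range(spec.n_samples)])
            pool.add(Contig(cid, genome[pos:pos + ln], depths))
            truth[cid] = gid
            order[gid].append(cid)
            pos += ln
    return Community(spec, references, pool, truth, order, abundances)


# ---------------------------------------------------------------------------
# Planting defects

@dataclass
class DefectLabels:
    """Exhaustive, exclusive defect bookkeeping for a planted community."""

    redundant_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    distinct_pairs: list[tuple[str, str]] = field(default_factory=list)
    contaminants: dict[str, tuple[str, str]] = field(default_factory=dict)  # contig -> (true genome, host bin)
    withheld: dict[str, str] = field(default_factory=dict)                   # contig -> true bin


@dataclass
class PlantedCommunity:
    community: Community
    binset: BinSet
    unbinned: list[str]
    links: LinkTable
    labels: DefectLabels

    @property
    def pool(self) -> ContigPool:
        return self.community.pool


LINK_RATE = 0.3          # expected link support per unit mean depth
FALSE_LINK_RATE = 0.02   # false cross-genome links per true link
DUP_DROP_RANGE = (0.1, 0.3)


def _refragment_duplicate(community: Community, gid: str, tag: str,
                          scale_factor: float,
                          rng: np.random.Generator,
                          drop_range: tuple[float, float] = DUP_DROP_RANGE,
                          keep_n: int | None = None) -> list[str]:
    """New contig entries for a duplicate bin: fresh fragment
    boundaries over the same genome, a random 10-30% of contigs
    dropped, depths rescaled by ``scale_factor`` and re-drawn with NB
    noise — a bin of the same genome recovered from a second
    assembly."""
    spec = community.spec
    genome = community.references[gid]
    gi = int(gid[1:])
    lens = _fragment_lengths(len(genome), spec, rng)
    if keep_n is None:
        drop = rng.uniform(*drop_range)
        keep = rng.random(len(lens)) >= drop
    else:
        keep = np.zeros(len(lens), dtype=bool)
        keep[rng.choice(len(lens), size=min(keep_n, len(lens)), replace=False)] = True
    ids = []
    pos = 0
    for ci, ln in enumerate(lens):
        if keep[ci]:
            cid = f"{gid}_{tag}_c{ci:03d}"
            scale = scale_factor
            depths = np.array([
                _nb_depth(scale * community.abundances[gi, s], ln, spec.depth_noise, rng)
                for s in range(spec.n_samples)])
            community.pool.add(Contig(cid, genome[pos:pos + ln], depths))
            community.order.setdefault(f"{gid}:{tag}", []).append(cid)
            community.truth[cid] = gid
            ids.append(cid)
        pos += ln
    return ids


def plant_defects(community: Community,
                  redundancy_rate: float = 0.0,
                  contamination_rate: float = 0.0,
                  withheld_rate: float = 0.0,
                  coverage_scale_range: tuple[float, float] = (0.5, 2.0),
                  distinct_rate: float = 0.0,
                  link_rate: float = LINK_RATE,
                  false_link_rate: float = FALSE_LINK_RATE,
                  seed: int | None = None) -> PlantedCommunity:
    """Build bins from truth, then plant labeled defects.

    redundancy_rate: fraction of genomes that get a proportional
    re-fragmented duplicate bin (coverage rescaled by one factor drawn
    from coverage_scale_range) — the true redundant pairs.
    distinct_rate: fraction that get a NON-proportional duplicate
    (independent per-contig coverage scaling) — labeled negatives that
    still pass the ANI grouping.
    contamination_rate: fraction of each bin's contigs swapped into a
    different genome's bin. withheld_rate: fraction moved to the
    un-binned pool. Links join genome-adjacent contigs with
    depth-proportional Poisson support (min 1), plus a rate of false
    cross-genome links.
    """
    for r in (redundancy_rate, contamination_rate, withheld_rate, distinct_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(community.spec.seed + 100_003 if seed is None else seed)
    labels = DefectLabels()
    genomes = sorted(community.references)
    bins: dict[str, list[str]] = {f"bin_{g}": list(community.order[g]) for g in genomes}

    n_dup = int(round(redundancy_rate * len(genomes)))
    n_distinct = int(round(distinct_rate * len(genomes)))
    dup_targets = list(rng.permutation(genomes))
    for gid in dup_targets[:n_dup]:
        c = float(rng.uniform(*coverage_scale_range))
        ids = _refragment_duplicate(community, gid, "dup", c, rng)
        bins[f"bin_{gid}_dup"] = ids
        labels.redundant_pairs.append((f"bin_{gid}", f"bin_{gid}_dup", c))
    if n_dup + n_distinct > len(genomes):
        raise ValueError("redundancy_rate + distinct_rate exceed the genome count")
    for gid in dup_targets[n_dup:n_dup + n_distinct]:
        # a chimeric look-alike: shares the genome's sequence (so it
        # groups at ANI >= 99) but ~half its bp comes from another
        # genome at that genome's own abundance, so its coverage
        # structure is not a rescaling of the original bin's
        c1 = float(rng.uniform(*coverage_scale_range))
        ids = _refragment_duplicate(community, gid, "alt", c1, rng)
        # the second component must carry an abundance contrast, else the
        # chimera's coverage is a coincidental rescaling of the host bin
        # and no coverage-based method could label it distinct
        host_mu = c1 * float(np.mean(community.abundances[int(gid[1:])]))
        others = [x for x in genomes if x != gid]
        contrasted = [x for x in others
                      if not 1 / 1.6 < np.mean(community.abundances[int(x[1:])]) / host_mu < 1.6]
        pick_from = contrasted or others
        h = pick_from[int(rng.integers(len(pick_from)))]
        # balance the two components by contig count: a minority
        # component would be stripped by the core filter, leaving a
        # clean (genuinely redundant) core
        ids += _refragment_duplicate(community, h, f"alt_{gid}", 1.0, rng,
                                     keep_n=len(ids))
        bins[f"bin_{gid}_alt"] = ids
        labels.distinct_pairs.append((f"bin_{gid}", f"bin_{gid}_alt"))

    if contamination_rate > 0 and len(genomes) > 1:
        for g in genomes:
            host = f"bin_{g}"
            n_cont = int(round(contamination_rate * len(community.order[g])))
            others = [c for og in genomes if og != g for c in community.order[og]
                      if c in set(bins[f"bin_{og}"])]
            pick = rng.choice(len(others), size=min(n_cont, len(others)), replace=False)
            for idx in sorted(pick):
                cid = others[idx]
                src = community.truth[cid]
                if cid in bins[f"bin_{src}"]:
                    bins[f"bin_{src}"].remove(cid)
                    bins[host].append(cid)
                    labels.contaminants[cid] = (src, host)

    unbinned: list[str] = []
    if withheld_rate > 0:
        for g in genomes:
            bid = f"bin_{g}"
            native = [c for c in bins[bid] if community.truth[c] == g]
            n_wh = int(round(withheld_rate * len(native)))
            pick = rng.choice(len(native), size=n_wh, replace=False)
            for idx in sorted(pick):
                cid = native[idx]
                bins[bid].remove(cid)
                unbinned.append(cid)
                labels.withheld[cid] = bid

    links = LinkTable()
    true_links = 0
    for series in sorted(community.order):
        ids = community.order[series]
        for a, b in zip(ids, ids[1:]):
            lam = link_rate * 0.5 * (community.pool[a].mean_depth
                                     + community.pool[b].mean_depth)
            support = max(1, int(rng.poisson(lam)))
            links.add(a, b, support)
            true_links += 1
    n_false = int(round(false_link_rate * true_links))
    all_ids = sorted(community.pool)
    made = 0
    while made < n_false:
        a, b = (all_ids[i] for i in rng.integers(0, len(all_ids), size=2))
        if a == b or community.truth.get(a) == community.truth.get(b):
            continue
        links.add(a, b, 1 + int(rng.poisson(0.7)))
        made += 1

    blist = [Bin(bid, ids, source="planted") for bid, ids in sorted(bins.items()) if ids]
    return PlantedCommunity(community, BinSet("planted", blist, stage="initial"),
                            unbinned, links, labels)


# ---------------------------------------------------------------------------
# Standard benchmark fixtures

BENCHMARKS = ("redundancy40", "contamination10x5", "retrieval10", "gapfill5")


def make_benchmark(name: str, seed: int = 1):
    """Emit one of the standard fixture bundles (pinned study conditions).

    redundancy40  — 20 proportional-duplicate (redundant) and 20
                    non-proportional-duplicate (distinct) labeled pairs.
    contamination10x5 — 10 genomes, 3 samples, 5% planted foreign
                    contigs per bin.
    retrieval10   — 10 genomes, 10% of each bin's contigs withheld with
                    adjacency links.
    gapfill5      — one genome split into 5 contigs with short internal
                    gaps plus 3 junction-spanning donors (>=400 bp flanks).
    """
    if name == "redundancy40":
        # a moderately even community: the fixed-threshold mode shares one
        # w across all pairs, so the benchmark keeps the abundance range
        # narrow enough for an absolute coverage delta to be comparable
        spec = CommunitySpec(n_genomes=40, genome_len_range=(120_000, 180_000),
                             abundance_sigma=0.35, seed=seed)
        community = simulate_community(spec)
        return plant_defects(community, redundancy_rate=0.5, distinct_rate=0.5,
                             coverage_scale_range=(0.5, 2.0))
    if name == "contamination10x5":
        spec = CommunitySpec(n_genomes=10, n_samples=3, seed=seed)
        community = simulate_community(spec)
        return plant_defects(community, contamination_rate=0.05)
    if name == "retrieval10":
        spec = CommunitySpec(n_genomes=10, n_samples=3, seed=seed)
        community = simulate_community(spec)
        return plant_defects(community, withheld_rate=0.10)
    if name == "gapfill5":
        return _gapfill_fixture(seed)
    raise ValueError(f"unknown benchmark {name!r}; options: {', '.join(BENCHMARKS)}")


def standard_defect_community(seed: int = 1) -> PlantedCommunity:
    """The all-defects community used for end-to-end checks: planted
    redundant duplicates, foreign contigs and withheld contigs with
    link evidence, all in one bin set."""
    spec = CommunitySpec(n_genomes=10, n_samples=3, seed=seed)
    community = simulate_community(spec)
    return plant_defects(community, redundancy_rate=0.3,
                         contamination_rate=0.05, withheld_rate=0.10,
                         coverage_scale_range=(0.5, 2.0))


GAPFILL_FLANK = (400, 600)
GAPFILL_GAP = (100, 300)


def _gapfill_fixture(seed: int) -> PlantedCommunity:
    """One genome cut into 5 contigs; 3 of the 4 junctions carry an
    internal gap spanned by an un-binned donor with >=400 bp flanks."""
    spec = CommunitySpec(n_genomes=1, genome_len_range=(60_000, 60_000), seed=seed)
    rng = np.random.default_rng(seed + 77)
    base = _base_transitions(np.random.default_rng(seed), spec.markov_order)
    trans = _perturb(base, spec.divergence, np.random.default_rng(seed))
    genome = _markov_seq(trans, 60_000, spec.markov_order, np.random.default_rng(seed + 1))
    cuts = sorted(int(c) for c in rng.integers(8_000, 52_000, size=4))
    while np.min(np.diff([0] + cuts + [60_000])) < 5_000:
        cuts = sorted(int(c) for c in rng.integers(8_000, 52_000, size=4))
    bounds = [0] + cuts + [60_000]
    gap_junctions = [0, 1, 3]  # junction index i joins contig i and i+1
    pool = ContigPool()
    pool.samples = ["sample_0"]
    order = []
    segs = []
    for i in range(5):
        s, e = bounds[i], bounds[i + 1]
        if i - 1 in gap_junctions:  # gap eats into this contig's head
            s += int(rng.integers(*GAPFILL_GAP))
        segs.append((s, e))
    for i, (s, e) in enumerate(segs):
        cid = f"g00_c{i:03d}"
        pool.add(Contig(cid, genome[s:e], np.array([20.0])))
        order.append(cid)
    donors = []
    for j in gap_junctions:
        tail_end = segs[j][1]
        head_start = segs[j + 1][0]
        flank_l = int(rng.integers(*GAPFILL_FLANK))
        flank_r = int(rng.integers(*GAPFILL_FLANK))
        did = f"donor_j{j}"
        pool.add(Contig(did, genome[tail_end - flank_l: head_start + flank_r],
                        np.array([20.0])))
        donors.append(did)
    community = Community(spec, {"g00": genome}, pool,
                          {c: "g00" for c in order}, {"g00": order},
                          np.array([[20.0]]))
    binset = BinSet("planted", [Bin("bin_g00", order, source="planted")],
                    stage="initial")
    return PlantedCommunity(community, binset, donors, LinkTable(), DefectLabels())


def write_bundle(planted: PlantedCommunity, out_dir) -> None:
    """Write the full fixture bundle with the io_formats contracts."""
    os.makedirs(out_dir, exist_ok=True)
    com = planted.community
    write_contig_pool(com.pool, os.path.join(out_dir, "contigs.fa"))
    write_depth_table(com.pool, os.path.join(out_dir, "depth.tsv"))
    write_link_table(planted.links, os.path.join(out_dir, "links.tsv"))
    refs = ContigPool(Contig(g, s) for g, s in sorted(com.references.items()))
    write_contig_pool(refs, os.path.join(out_dir, "references.fa"))
    write_binset(planted.binset, os.path.join(out_dir, "bins"), com.pool, overwrite=True)
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("contig\tgenome\n")
        for cid in sorted(com.truth):
            fh.write(f"{cid}\t{com.truth[cid]}\n")
    with open(os.path.join(out_dir, "unbinned.txt"), "w") as fh:
        for cid in sorted(planted.unbinned):
            fh.write(cid + "\n")
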