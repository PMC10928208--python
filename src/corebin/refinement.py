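"""Refinement: outlier removal (OR) and link-based sequence retrieval.

Outlier removal tests every contig of a bin along several dimensions:

* composition — Euclidean distance of the contig's canonical TNF
  vector to the bin's length-weighted mean TNF (a single scalar
  dimension; per-dimension testing over 136 TNF components would flag
  nearly everything);
* coverage correlation — CCC_ab = cov_a / cov_b for every unordered
  sample pair (a < b), one dimension per pair;
* mean depth across samples.

Each dimension gets the IQR band Q1 - k*IQR .. Q3 + k*IQR at
k in {0, 0.5, 1, 2}; a contig is an outlier when it falls outside ANY
dimension's band at the operative k (default 2, the most conservative
of the listed values). Flagged contigs are pooled, not discarded, so
mis-homed multi-copy sequence can be re-assigned during retrieval.

Sequence retrieval assigns an un-binned contig to a bin when its
summed read-pair/long-read link support to that bin reaches
min_support, the bin is the unique support maximizer, and the contig
passes the bin's composition+coverage inlier test; newly assigned
contigs contribute links in the next iteration, to a fix point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Bin, BinSet, ContigPool, LinkTable
from .bin_selection import EPSILON, core_coverage_range
from . import seq_stats

__all__ = [
    "compute_ccc",
    "OutlierVerdict",
    "multidim_iqr_outliers",
    "remove_outliers",
    "RetrievalResult",
    "retrieve_sequences",
]

K_VALUES = (0.0, 0.5, 1.0, 2.0)
OPERATIVE_K = 2.0
MIN_CONTIGS_FOR_REMOVAL = 4    # below this, quartiles are meaningless
DISSOLUTION_FLOOR_BP = 50_000  # bins smaller than this dissolve into the pool
MIN_LINK_SUPPORT = 3
MAX_RETRIEVAL_ITERATIONS = 20


def compute_ccc(contig, sample_count: int) -> np.ndarray:
    """Pairwise coverage ratios cov_a/cov_b for sample pairs a < b.

    With a single sample there are no pairs and the vector is empty;
    zero denominators are guarded by a pseudocount.
    """
    d = np.asarray(contig.depths, dtype=float)
    if d.size != sample_count:
        raise ValueError(f"contig {contig.id!r}: depth vector length {d.size} != {sample_count}")
    return np.asarray([d[a] / max(d[b], EPSILON)
                       for a in range(sample_count)
                       for b in range(a + 1, sample_count)], dtype=float)


class _TnfCache(dict):
    def __init__(self, pool: ContigPool):
        super().__init__()
        self.pool = pool

    def __missing__(self, cid: str) -> np.ndarray:
        v = seq_stats.compute_tnf(self.pool[cid].seq)
        self[cid] = v
        return v


def _bin_centroid(contig_ids, pool: ContigPool, tnf: _TnfCache) -> np.ndarray:
    """Length-weighted mean TNF; long contigs anchor the composition."""
    lens = np.array([pool[c].length for c in contig_ids], dtype=float)
    mat = np.stack([tnf[c] for c in contig_ids])
    return (mat * lens[:, None]).sum(axis=0) / lens.sum()


def _dimension_values(contig_ids, pool: ContigPool, tnf: _TnfCache) -> dict[str, dict[str, float]]:
    """dim name -> {contig id -> scalar value} for a set of contigs."""
    centroid = _bin_centroid(contig_ids, pool, tnf)
    n_samples = len(pool.samples) if pool.samples else len(pool[contig_ids[0]].depths)
    dims: dict[str, dict[str, float]] = {
        "tnf": {c: seq_stats.tnf_distance(tnf[c], centroid) for c in contig_ids},
        "depth": {c: pool[c].mean_depth for c in contig_ids},
    }
    pair_names = [f"ccc_{a}_{b}" for a in range(n_samples) for b in range(a + 1, n_samples)]
    if pair_names:
        ccc = {c: compute_ccc(pool[c], n_samples) for c in contig_ids}
        for i, name in enumerate(pair_names):
            dims[name] = {c: float(ccc[c][i]) for c in contig_ids}
    return dims


@dataclass
class OutlierVerdict:
    contig_id: str
    tnf_distance: float
    flagged_dims: list[str]
    is_outlier: bool
    flags_by_k: dict[float, list[str]] = field(default_factory=dict)


def multidim_iqr_outliers(bin_: Bin, pool: ContigPool,
                          k_values=K_VALUES,
                          operative_k: float = OPERATIVE_K,
                          tnf: _TnfCache | None = None) -> list[OutlierVerdict]:
    """Flag contigs outside the IQR band of any dimension at the
    operative k; bands at all listed k are reported for diagnostics.

    Bins with fewer than four contigs get no removal — too few points
    for quartiles — and every verdict is is_outlier=False.
    """
    tnf = tnf if tnf is not None else _TnfCache(pool)
    dims = _dimension_values(bin_.contig_ids, pool, tnf)
    small = len(bin_.contig_ids) < MIN_CONTIGS_FOR_REMOVAL
    ranges = {k: {name: core_coverage_range(vals.values(), k)
                  for name, vals in dims.items()}
              for k in k_values}
    verdicts = []
    for cid in bin_.contig_ids:
        flags_by_k = {
            k: [name for name, vals in dims.items()
                if not ranges[k][name].contains(vals[cid])]
            for k in k_values
        }
        flagged = flags_by_k.get(operative_k, [])
        verdicts.append(OutlierVerdict(
            cid, dims["tnf"][cid], flagged,
            is_outlier=bool(flagged) and not small,
            flags_by_k=flags_by_k))
    return verdicts


def remove_outliers(binset: BinSet, verdicts: dict[str, list[OutlierVerdict]],
                    pool: ContigPool,
                    floor_bp: int = DISSOLUTION_FLOOR_BP) -> tuple[BinSet, list[str]]:
    """Move flagged contigs to the un-binned pool; dissolve stub bins.

    Returns (outlier-depleted BinSet, pooled contig ids). A bin whose
    surviving contigs total less than ``floor_bp`` is dissolved whole:
    below any plausible genome size its fragments serve retrieval
    better than a stub bin.
    """
    odbs, pooled = [], []
    for b in binset:
        flagged = {v.contig_id for v in verdicts.get(b.bin_id, []) if v.is_outlier}
        keep = [c for c in b.contig_ids if c not in flagged]
        drop = [c for c in b.contig_ids if c in flagged]
        if keep and pool.total_bp(keep) >= floor_bp:
            odbs.append(Bin(b.bin_id, keep, source="refined"))
            pooled.extend(drop)
        else:
            pooled.extend(b.contig_ids)
    return BinSet("odb", odbs, stage="refined"), pooled


@dataclass
class RetrievalResult:
    binset: BinSet
    unbinned: list[str]
    log: list[tuple[int, str, str, int]]  # iteration, contig, bin, support
    iterations: int


def retrieve_sequences(odbs: BinSet, unbinned: list[str], pool: ContigPool,
                       links: LinkTable,
                       min_support: int = MIN_LINK_SUPPORT,
                       gate_k: float = OPERATIVE_K,
                       max_iterations: int = MAX_RETRIEVAL_ITERATIONS) -> RetrievalResult:
    """Iteratively re-home un-binned contigs through link evidence.

    Assignments within one iteration are computed against the bin
    membership at the start of that iteration, so a chain c1-c2-bin
    (c1 linked only to c2) resolves over exactly two iterations.
    """
    tnf = _TnfCache(pool)
    members = {b.bin_id: list(b.contig_ids) for b in odbs}
    free = sorted(set(unbinned))
    log: list[tuple[int, str, str, int]] = []
    iteration = 0
    while free and iteration < max_iterations:
        iteration += 1
        # bin dimension bands at the gate k, from current members
        bands = {}
        centroids = {}
        for bid, ids in members.items():
            dims = _dimension_values(ids, pool, tnf)
            bands[bid] = {name: core_coverage_range(vals.values(), gate_k)
                          for name, vals in dims.items()}
            centroids[bid] = _bin_centroid(ids, pool, tnf)
        membership = {c: bid for bid, ids in members.items() for c in ids}
        n_samples = len(pool.samples) if pool.samples else None
        assigned: list[tuple[str, str, int]] = []
        for cid in free:
            support: dict[str, int] = {}
            for other, s in links.neighbours(cid):
                bid = membership.get(other)
                if bid is not None:
                    support[bid] = support.get(bid, 0) + s
            if not support:
                continue
            top = max(support.values())
            if top < min_support:
                continue
            winners = [b for b, s in support.items() if s == top]
            if len(winners) != 1:
                continue  # strict tie: never guess
            bid = winners[0]
            if _passes_gate(cid, bid, pool, tnf, bands, centroids, n_samples):
                assigned.append((cid, bid, top))
        if not assigned:
            break
        for cid, bid, sup in assigned:
            members[bid].append(cid)
            log.append((iteration, cid, bid, sup))
        taken = {c for c, _, _ in assigned}
        free = [c for c in free if c not in taken]
    bins = [Bin(bid, ids, source="refined") for bid, ids in members.items()]
    return RetrievalResult(BinSet("refined", bins, stage="refined"), free, log, iteration)


def _passes_gate(cid, bid, pool, tnf, bands, centroids, n_samples) -> bool:
    band = bands[bid]
    vals = {
        "tnf": seq_stats.tnf_distance(tnf[cid], centroids[bid]),
        "depth": pool[cid].mean_depth,
    }
    if n_samples and n_samples >= 2:
        ccc = compute_ccc(pool[cid], n_samples)
        i = 0
        for a in range(n_samples):
            for b in range(a + 1, n_samples):
                vals[f"ccc_{a}_{b}"] = float(ccc[i])
                i += 1
    return all(band[name].contains(v) for name, v in vals.items() if name in band)
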