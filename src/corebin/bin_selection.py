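"""Bin selection: hybrid-bin merging, ANI/AF grouping, core sequence
identification (CSI) and redundant-bin removal.

CSI works on contig coverage. For each bin the core (inlier) contigs
are those whose across-sample mean depth x_i lies in the IQR band

    Q1 - k*IQR  <=  x_i  <=  Q3 + k*IQR          (k = 0 for core ID)

Inliers of two grouped bins are then paired by sequence identity
(ANI >= 99%, both >= 1000 bp). The depth normalization ratio

    X_bar = (1/n) * sum_i cov(a_i) / cov(b_i)

rescales the second bin's coverage onto the first's scale, and the
delta coverage

    Delta = | mu_A - X_bar * mu_B |

over ALL inliers (paired and unpaired) measures whether the two bins
sample the same underlying genome population: Delta < w flags the pair
redundant. The decision threshold w is either a fixed calibrated value
or a small fully connected classifier trained on labeled synthetic
pairs (a transparent surrogate for an unpublished network).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import Bin, BinSet, ContigPool
from .seq_stats import SequenceIndex, best_fragment_hits

__all__ = [
    "CoverageRange",
    "core_coverage_range",
    "split_inliers",
    "merge_hybrid_bins",
    "group_bins",
    "InlierPair",
    "pair_inliers",
    "depth_normalization_ratio",
    "delta_coverage",
    "RedundancyDecision",
    "evaluate_pair",
    "classify_redundancy",
    "calibrate_threshold",
    "RedundancyModel",
    "select_nonredundant",
]

EPSILON = 0.01          # pseudocount guarding zero denominators
PAIR_ANI_MIN = 99.0     # inlier pairing identity threshold (percent)
PAIR_MIN_LEN = 1000     # inlier pairing length threshold (bp)
GROUP_ANI_MIN = 99.0    # bin grouping ANI threshold (percent)
GROUP_AF_MIN = 50.0     # bin grouping aligned-fraction threshold (percent)
MERGE_OVERLAP_MIN = 0.8  # length-weighted contig overlap for hybrid merging
DEFAULT_W = 2.0          # fixed decision threshold, calibrated on synthetic pairs


# ---------------------------------------------------------------------------
# Eq. 1 — core coverage range

@dataclass
class CoverageRange:
    """IQR-based inlier band for a set of per-contig depths."""

    q1: float
    q3: float
    k: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lo(self) -> float:
        return self.q1 - self.k * self.iqr

    @property
    def hi(self) -> float:
        return self.q3 + self.k * self.iqr

    def contains(self, x: float, strict: bool = False) -> bool:
        if strict:
            return self.lo < x < self.hi
        # band edges often coincide with data points (e.g. IQR = 0);
        # a relative tolerance keeps the comparison robust to the
        # floating-point path that produced the quartiles
        tol = 1e-9 * max(1.0, abs(self.lo), abs(self.hi))
        return self.lo - tol <= x <= self.hi + tol


def core_coverage_range(depths, k: float) -> CoverageRange:
    """Quartiles by linear interpolation between order statistics.

    Inclusive bounds are the default: with tied quartiles (IQR = 0,
    the common case for a uniform-coverage bin at k = 0) a literal
    strict inequality would void the whole bin.
    """
    depths = np.asarray(list(depths), dtype=float)
    if depths.size == 0:
        raise ValueError("core_coverage_range needs at least one depth value")
    q1, q3 = np.percentile(depths, [25, 75])
    if k < 0:
        raise ValueError("k must be non-negative")
    return CoverageRange(float(q1), float(q3), float(k))


def split_inliers(bin_: Bin, pool: ContigPool, k: float = 0.0,
                  strict: bool = False) -> tuple[list[str], list[str]]:
    """Partition a bin's contigs into (inliers, outliers) by mean depth."""
    depths = {cid: pool[cid].mean_depth for cid in bin_.contig_ids}
    rng = core_coverage_range(depths.values(), k)
    inl = [cid for cid in bin_.contig_ids if rng.contains(depths[cid], strict)]
    out = [cid for cid in bin_.contig_ids if cid not in set(inl)]
    return inl, out


# ---------------------------------------------------------------------------
# Hybrid-bin merging (same-contig redundancy across binners/thresholds)

def merge_hybrid_bins(binsets: list[BinSet], pool: ContigPool,
                      overlap_min: float = MERGE_OVERLAP_MIN) -> BinSet:
    """Merge bins that comprise the same contigs into hybrid bins.

    Bins are nodes; an edge joins two bins whose length-weighted contig
    overlap (shared bp / min bin bp) reaches ``overlap_min``. Each
    connected component becomes one hybrid bin (union of contigs,
    deduplicated); singletons pass through unchanged.
    """
    bins: list[tuple[str, Bin]] = []
    for bs in binsets:
        for b in bs:
            bins.append((f"{bs.name}/{b.bin_id}", b))
    g = nx.Graph()
    g.add_nodes_from(range(len(bins)))
    sets = [set(b.contig_ids) for _, b in bins]
    bps = [pool.total_bp(s) for s in sets]
    for i in range(len(bins)):
        for j in range(i + 1, len(bins)):
            shared = pool.total_bp(sets[i] & sets[j])
            denom = min(bps[i], bps[j])
            if denom > 0 and shared / denom >= overlap_min:
                g.add_edge(i, j)
    out = []
    comps = sorted(nx.connected_components(g), key=lambda c: min(bins[i][0] for i in c))
    for comp in comps:
        members = sorted(comp, key=lambda i: bins[i][0])
        if len(members) == 1:
            b = bins[members[0]][1]
            out.append(Bin(b.bin_id, list(b.contig_ids), source="hybrid"))
        else:
            seen, ids = set(), []
            for i in members:
                for cid in bins[i][1].contig_ids:
                    if cid not in seen:
                        seen.add(cid)
                        ids.append(cid)
            name = "hybrid_" + "+".join(bins[i][1].bin_id for i in members)
            out.append(Bin(name, ids, source="hybrid"))
    # resolve bin-id collisions across source sets deterministically
    counts: dict[str, int] = {}
    final = []
    for b in out:
        n = counts.get(b.bin_id, 0)
        counts[b.bin_id] = n + 1
        final.append(Bin(b.bin_id if n == 0 else f"{b.bin_id}.{n}", b.contig_ids, b.source))
    return BinSet("hybrid", final, stage="hybrid")


# ---------------------------------------------------------------------------
# Best-bins grouping by ANI / AF

def _bin_ani(query: Bin, index: SequenceIndex, pool: ContigPool) -> tuple[float, float]:
    """(ani, af) of a whole bin against another bin's index."""
    seqs = {cid: pool[cid].seq for cid in query.contig_ids}
    total_bp = sum(len(s) for s in seqs.values())
    hits = best_fragment_hits(seqs, index)
    if not hits or total_bp == 0:
        return float("nan"), 0.0
    ani = float(np.mean([h.identity for h in hits]))
    af = 100.0 * sum(h.qlen for h in hits) / total_bp
    return ani, af


def group_bins(binset: BinSet, pool: ContigPool, ani_min: float = GROUP_ANI_MIN,
               af_min: float = GROUP_AF_MIN) -> list[list[str]]:
    """Single-linkage groups of bins at ANI >= ani_min and AF >= af_min.

    ANI/AF is computed in both directions; an edge exists when either
    direction passes (AF is query-relative, so a small bin inside a
    large one passes in the small-to-large direction).
    """
    indexes = {b.bin_id: SequenceIndex({c: pool[c].seq for c in b.contig_ids})
               for b in binset}
    g = nx.Graph()
    g.add_nodes_from(b.bin_id for b in binset)
    blist = sorted(binset, key=lambda b: b.bin_id)
    for i, a in enumerate(blist):
        for b in blist[i + 1:]:
            for q, t in ((a, b), (b, a)):
                ani, af = _bin_ani(q, indexes[t.bin_id], pool)
                if np.isfinite(ani) and ani >= ani_min and af >= af_min:
                    g.add_edge(a.bin_id, b.bin_id)
                    break
    return sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])


# ---------------------------------------------------------------------------
# Eq. 2-3 — inlier pairing and redundancy statistics

@dataclass
class InlierPair:
    contig_a: str
    contig_b: str
    ani: float
    len_a: int
    len_b: int
    cov_a: float
    cov_b: float


def pair_inliers(bin_a: Bin, bin_b: Bin, pool: ContigPool,
                 ani_min: float = PAIR_ANI_MIN,
                 min_len: int = PAIR_MIN_LEN) -> list[InlierPair]:
    """Pair inlier contigs of two bins by sequence identity.

    Only contigs >= min_len on both sides qualify; candidate pairs need
    contig-level ANI >= ani_min; the matching is greedy by descending
    ANI (ties: longer alignment, then lexicographic ids) and each
    contig joins at most one pair.
    """
    a_ids = [c for c in bin_a.contig_ids if pool[c].length >= min_len]
    b_ids = [c for c in bin_b.contig_ids if pool[c].length >= min_len]
    if not a_ids or not b_ids:
        return []
    index = SequenceIndex({c: pool[c].seq for c in b_ids})
    candidates = []
    for ca in a_ids:
        hits = best_fragment_hits({ca: pool[ca].seq}, index)
        if not hits:
            continue
        by_target: dict[str, list] = {}
        for h in hits:
            by_target.setdefault(h.target_id, []).append(h)
        for cb, hs in by_target.items():
            aligned = sum(h.qlen for h in hs)
            ani = float(np.mean([h.identity for h in hs]))
            if ani >= ani_min:
                candidates.append((ani, aligned, ca, cb))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for ani, _, ca, cb in candidates:
        if ca in used_a or cb in used_b:
            continue
        used_a.add(ca)
        used_b.add(cb)
        pairs.append(InlierPair(ca, cb, ani, pool[ca].length, pool[cb].length,
                                pool[ca].mean_depth, pool[cb].mean_depth))
    return pairs


def depth_normalization_ratio(pairs: list[InlierPair], eps: float = EPSILON) -> float:
    """X_bar: mean over pairs of cov_a / cov_b (mean depth across samples)."""
    if not pairs:
        raise ValueError("depth_normalization_ratio needs >= 1 pair (no-evidence path)")
    return float(np.mean([p.cov_a / max(p.cov_b, eps) for p in pairs]))


def delta_coverage(mu_a: float, mu_b: float, x_bar: float) -> float:
    """Delta = | mu_a - x_bar * mu_b | over all inliers of each bin."""
    return abs(mu_a - x_bar * mu_b)


@dataclass
class RedundancyDecision:
    bin_a: str
    bin_b: str
    n_pairs: int
    x_bar: float
    mu_a: float
    mu_b: float
    delta: float
    w: float
    verdict: str  # redundant | nonredundant | no-evidence
    features: dict = field(default_factory=dict)


def _pair_features(n_pairs, x_bar, mu_a, mu_b, delta, bin_a, bin_b, pool,
                   inliers_a, inliers_b) -> dict:
    da = [pool[c].mean_depth for c in inliers_a]
    db = [pool[c].mean_depth for c in inliers_b]
    return {
        "delta": delta,
        "delta_rel": delta / max(mu_a, EPSILON),
        "x_bar": x_bar,
        "n_pairs": n_pairs,
        "bp_a": pool.total_bp(inliers_a),
        "bp_b": pool.total_bp(inliers_b),
        "cv_a": float(np.std(da) / max(np.mean(da), EPSILON)),
        "cv_b": float(np.std(db) / max(np.mean(db), EPSILON)),
    }


FEATURE_ORDER = ["delta", "delta_rel", "x_bar", "n_pairs", "bp_a", "bp_b", "cv_a", "cv_b"]


def evaluate_pair(bin_a: Bin, bin_b: Bin, pool: ContigPool, k: float = 0.0) -> RedundancyDecision:
    """Compute the full CSI statistics for one bin pair (verdict unset)."""
    inl_a, _ = split_inliers(bin_a, pool, k)
    inl_b, _ = split_inliers(bin_b, pool, k)
    pairs = pair_inliers(Bin(bin_a.bin_id, inl_a), Bin(bin_b.bin_id, inl_b), pool) \
        if inl_a and inl_b else []
    mu_a = float(np.mean([pool[c].mean_depth for c in inl_a])) if inl_a else 0.0
    mu_b = float(np.mean([pool[c].mean_depth for c in inl_b])) if inl_b else 0.0
    if not pairs:
        return RedundancyDecision(bin_a.bin_id, bin_b.bin_id, 0, float("nan"),
                                  mu_a, mu_b, float("nan"), float("nan"), "no-evidence",
                                  _pair_features(0, 1.0, mu_a, mu_b, 0.0,
                                                 bin_a, bin_b, pool, inl_a, inl_b))
    x_bar = depth_normalization_ratio(pairs)
    delta = delta_coverage(mu_a, mu_b, x_bar)
    feats = _pair_features(len(pairs), x_bar, mu_a, mu_b, delta,
                           bin_a, bin_b, pool, inl_a, inl_b)
    return RedundancyDecision(bin_a.bin_id, bin_b.bin_id, len(pairs), x_bar,
                              mu_a, mu_b, delta, float("nan"), "", feats)


class RedundancyModel:
    """Small fully connected classifier over CSI pair features.

    A transparent stand-in for a learned decision threshold: trained
    with scikit-learn on labeled synthetic pairs, persisted as plain
    JSON (standardisation parameters plus layer weights), evaluated
    with an explicit ReLU/logistic forward pass.
    """

    def __init__(self, mean, scale, coefs, intercepts):
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.coefs = [np.asarray(c, dtype=float) for c in coefs]
        self.intercepts = [np.asarray(b, dtype=float) for b in intercepts]

    @classmethod
    def train(cls, decisions: list[RedundancyDecision], labels: list[bool],
              seed: int = 0, hidden=(16, 8)) -> "RedundancyModel":
        from sklearn.neural_network import MLPClassifier
        from sklearn.preprocessing import StandardScaler

        X = np.array([[d.features[f] for f in FEATURE_ORDER] for d in decisions])
        X = np.log1p(np.abs(X)) * np.sign(X)
        y = np.asarray(labels, dtype=int)
        scaler = StandardScaler().fit(X)
        clf = MLPClassifier(hidden_layer_sizes=hidden, max_iter=5000,
                            random_state=seed, alpha=1e-3)
        clf.fit(scaler.transform(X), y)
        return cls(scaler.mean_, scaler.scale_, clf.coefs_, clf.intercepts_)

    def predict_proba(self, decision: RedundancyDecision) -> float:
        x = np.array([decision.features[f] for f in FEATURE_ORDER], dtype=float)
        x = np.log1p(np.abs(x)) * np.sign(x)
        h = (x - self.mean) / self.scale
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        z = float((h @ self.coefs[-1] + self.intercepts[-1]).item())
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path) -> None:
        obj = {"mean": self.mean.tolist(), "scale": self.scale.tolist(),
               "coefs": [c.tolist() for c in self.coefs],
               "intercepts": [b.tolist() for b in self.intercepts]}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path) -> "RedundancyModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["mean"], obj["scale"], obj["coefs"], obj["intercepts"])


def classify_redundancy(decision: RedundancyDecision, mode: str = "threshold",
                        w: float = DEFAULT_W,
                        model: RedundancyModel | None = None) -> RedundancyDecision:
    """Assign the keep/remove verdict to a computed pair decision.

    threshold mode: redundant iff Delta < w. model mode: classifier
    probability >= 0.5. A pair with no qualifying inlier pairs always
    takes the no-evidence path and both bins are retained.
    """
    if decision.n_pairs == 0:
        decision.verdict = "no-evidence"
        return decision
    if mode == "threshold":
        decision.w = w
        decision.verdict = "redundant" if decision.delta < w else "nonredundant"
    elif mode == "model":
        if model is None:
            raise ValueError(
                "model mode needs a trained RedundancyModel; train one with "
                "RedundancyModel.train on labeled synthetic pairs or use mode='threshold'"
            )
        p = model.predict_proba(decision)
        decision.w = float("nan")
        decision.verdict = "redundant" if p >= 0.5 else "nonredundant"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return decision


def calibrate_threshold(deltas_redundant, deltas_distinct) -> float:
    """Pick w between the labeled delta populations (geometric midpoint
    of the closest boundary values, clipped to separate the medians)."""
    r = np.sort(np.asarray(list(deltas_redundant), dtype=float))
    d = np.sort(np.asarray(list(deltas_distinct), dtype=float))
    if r.size == 0 or d.size == 0:
        raise ValueError("both labeled populations are required")
    hi = max(r.max(), EPSILON)
    lo = max(d.min(), EPSILON)
    return float(np.sqrt(hi * lo)) if lo > hi else float(0.5 * (hi + lo))


# ---------------------------------------------------------------------------
# Survivor selection

def select_nonredundant(binset: BinSet, groups: list[list[str]],
                        decisions: list[RedundancyDecision],
                        pool: ContigPool) -> tuple[BinSet, BinSet]:
    """Drop one bin of every redundant pair; archive what was removed.

    Redundant pairs are processed strongest-evidence-first (ascending
    Delta); the bin with the smaller total inlier bp is removed (ties:
    the lexicographically larger id); pairs touching an already-removed
    bin are skipped. Returns (selected BinSet, archived BinSet).
    """
    inlier_bp = {}
    for b in binset:
        inl, _ = split_inliers(b, pool, k=0.0)
        inlier_bp[b.bin_id] = pool.total_bp(inl)
    removed: set[str] = set()
    red = sorted((d for d in decisions if d.verdict == "redundant"),
                 key=lambda d: (d.delta, d.bin_a, d.bin_b))
    for d in red:
        if d.bin_a in removed or d.bin_b in removed:
            continue
        a, b = d.bin_a, d.bin_b
        if (inlier_bp[a], b) > (inlier_bp[b], a):
            removed.add(b)
        else:
            removed.add(a)
    kept = [Bin(b.bin_id, list(b.contig_ids), source="selected")
            for b in binset if b.bin_id not in removed]
    arch = [Bin(b.bin_id, list(b.contig_ids), source="archived")
            for b in binset if b.bin_id in removed]
    return (BinSet("selected", kept, stage="selected"),
            BinSet("archived", arch, stage="archived"))
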