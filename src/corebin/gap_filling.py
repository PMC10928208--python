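"""Restrained Overlap-Layout-Consensus (rOLC) gap filling.

Inlier sequences from redundant bins removed during selection —
filtered once more by outlier removal — plus remaining un-binned
contigs act as donors that extend bin contigs or bridge two of them.
The Layout step is restrained to keep contamination out of target
bins: overlaps must be at least 300 bp (round 1) / 500 bp (round 2)
at >= 99% identity, a donor protruding beyond the target at both ends
is rejected, and a merged sequence must stay below 105% of the summed
target length. Consensus keeps the target's base wherever target and
donor disagree — targets passed refinement QC, donors did not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Bin, BinSet, Contig, ContigPool
from .refinement import OPERATIVE_K, multidim_iqr_outliers
from .seq_stats import OverlapCandidate, OverlapIndex, revcomp

__all__ = [
    "MergeEvent",
    "collect_donors",
    "rolc_round",
    "gap_fill",
    "n50",
    "ROUND1_MIN_OVERLAP",
    "ROUND2_MIN_OVERLAP",
    "MIN_IDENTITY",
]

ROUND1_MIN_OVERLAP = 300
ROUND2_MIN_OVERLAP = 500
MIN_IDENTITY = 99.0
MAX_LENGTH_RATIO = 1.05  # merged length < 105% of summed target length


@dataclass
class MergeEvent:
    target_ids: tuple[str, ...]
    donor_id: str
    merged_id: str
    merged_len: int
    round: int
    kind: str  # extend | bridge
    bin_id: str
    overlap_bp: int
    identity: float


def n50(lengths) -> int:
    lengths = sorted(lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for ln in lengths:
        acc += ln
        if acc >= half:
            return ln
    return 0


def collect_donors(archive: BinSet, refined: BinSet, groups: list[list[str]],
                   pool: ContigPool, unbinned: list[str] | None = None,
                   k: float = OPERATIVE_K) -> dict[str, list[str]]:
    """Donor contig ids per refined bin.

    Archived redundant bins are re-filtered by multidimensional outlier
    removal at the operative k; their surviving inliers are offered
    only to bins in the same ANI group as the archived source bin.
    Un-binned pool contigs are offered to every bin.
    """
    group_of: dict[str, int] = {}
    for gi, grp in enumerate(groups):
        for bid in grp:
            group_of[bid] = gi
    donors: dict[str, list[str]] = {b.bin_id: [] for b in refined}
    for ab in archive:
        verdicts = multidim_iqr_outliers(ab, pool, operative_k=k)
        survivors = [v.contig_id for v in verdicts if not v.is_outlier]
        gi = group_of.get(ab.bin_id)
        if gi is None:
            continue
        for b in refined:
            if group_of.get(b.bin_id) == gi:
                donors[b.bin_id].extend(survivors)
    for b in refined:
        donors[b.bin_id].extend(unbinned or [])
        # a bin's own contigs are targets, never donors to themselves
        own = set(b.contig_ids)
        seen: set[str] = set()
        uniq = []
        for d in donors[b.bin_id]:
            if d not in own and d not in seen:
                seen.add(d)
                uniq.append(d)
        donors[b.bin_id] = uniq
    return donors


def _oriented(seq: str, orientation: str) -> str:
    return seq if orientation == "forward" else revcomp(seq)


def _extension_event(c: OverlapCandidate, lt: int, ld: int):
    """Geometry check for a single-end extension; returns merged length
    pieces or None if the candidate cannot extend."""
    left, right = c.donor_protrudes_left, c.donor_protrudes_right
    if left and right:
        return None  # restriction: donor longer than the target at both ends
    if not left and not right:
        return None  # containment: nothing to add
    merged_len = (lt - c.offset) if left else (c.offset + ld)
    if merged_len < MAX_LENGTH_RATIO * lt and merged_len > lt:
        return merged_len
    return None


def _find_events(index: OverlapIndex, donor_ids, consumed: set[str],
                 pool: ContigPool, min_overlap: int, min_identity: float):
    """Enumerate admissible extend/bridge events for one bin."""
    tlens = {tid: len(s) for tid, s in index.targets.items()}
    events = []
    for did in donor_ids:
        if did in consumed:
            continue
        dseq = pool[did].seq
        ld = len(dseq)
        cands = index.query(did, dseq, min_overlap, min_identity)
        by_orient: dict[str, list[OverlapCandidate]] = {}
        for c in cands:
            by_orient.setdefault(c.orientation, []).append(c)
        for orientation, ocands in by_orient.items():
            # extensions
            for c in ocands:
                mlen = _extension_event(c, tlens[c.target_id], ld)
                if mlen is not None:
                    score = (c.overlap_len, c.identity)
                    events.append(("extend", score, did, orientation, (c,), mlen))
            # bridges: donor prefix leaves T1's tail, suffix enters T2's head
            rights = [c for c in ocands if c.donor_protrudes_right and not c.donor_protrudes_left]
            lefts = [c for c in ocands if c.donor_protrudes_left and not c.donor_protrudes_right]
            for c1 in rights:
                for c2 in lefts:
                    if c1.target_id == c2.target_id:
                        continue
                    lt1 = tlens[c1.target_id]
                    e1 = lt1 - c1.offset          # donor coord where T1 ends
                    s2 = -c2.offset               # donor coord where T2 starts
                    if s2 < e1:
                        continue
                    gap = s2 - e1
                    mlen = lt1 + tlens[c2.target_id] + gap
                    if mlen >= MAX_LENGTH_RATIO * (lt1 + tlens[c2.target_id]):
                        continue
                    score = (c1.overlap_len + c2.overlap_len,
                             min(c1.identity, c2.identity))
                    events.append(("bridge", score, did, orientation, (c1, c2), mlen))
    events.sort(key=lambda e: (-e[1][0], -e[1][1], e[2],
                               tuple(c.target_id for c in e[4])))
    return events


def rolc_round(binset: BinSet, donors: dict[str, list[str]], pool: ContigPool,
               min_overlap: int, min_identity: float = MIN_IDENTITY,
               round_no: int = 1,
               consumed: set[str] | None = None) -> tuple[BinSet, list[MergeEvent]]:
    """One rOLC round: greedily apply the best admissible merge events.

    Events are ranked by total overlap length (ties: identity, donor
    id, target ids); a donor is consumed at most once per round; after
    each applied event overlaps are recomputed so a fresh merge product
    can immediately serve as a target.
    """
    consumed = consumed if consumed is not None else set()
    out_bins = []
    log: list[MergeEvent] = []
    for b in sorted(binset, key=lambda b: b.bin_id):
        ids = list(b.contig_ids)
        counter = 0
        while True:
            index = OverlapIndex({tid: pool[tid].seq for tid in ids})
            events = _find_events(index, donors.get(b.bin_id, []),
                                  consumed, pool, min_overlap, min_identity)
            applied = False
            taken: set[str] = set()
            deferred: set[str] = set()
            for kind, score, did, orientation, cands, mlen in events:
                if did in consumed or did in deferred:
                    continue
                if any(c.target_id in taken for c in cands):
                    # this donor's best use touches a fresh merge product;
                    # retry next pass instead of settling for a worse event
                    deferred.add(did)
                    continue
                dseq = _oriented(pool[did].seq, orientation)
                counter += 1
                merged_id = f"{b.bin_id}_m{round_no}_{counter}"
                if kind == "extend":
                    c = cands[0]
                    tseq = pool[c.target_id].seq
                    if c.donor_protrudes_left:
                        seq = dseq[: -c.offset] + tseq
                    else:
                        seq = tseq + dseq[len(tseq) - c.offset:]
                    tids = (c.target_id,)
                else:
                    c1, c2 = cands
                    t1, t2 = pool[c1.target_id].seq, pool[c2.target_id].seq
                    e1 = len(t1) - c1.offset
                    s2 = -c2.offset
                    seq = t1 + dseq[e1:s2] + t2
                    tids = (c1.target_id, c2.target_id)
                depths = None
                if all(pool[t].depths is not None for t in tids):
                    lens = np.array([pool[t].length for t in tids], dtype=float)
                    mat = np.stack([pool[t].depths for t in tids])
                    depths = (mat * lens[:, None]).sum(axis=0) / lens.sum()
                pool.add(Contig(merged_id, seq, depths))
                pos = min(ids.index(t) for t in tids)
                ids = [i for i in ids if i not in tids]
                ids.insert(pos, merged_id)
                consumed.add(did)
                taken.update(tids)
                applied = True
                log.append(MergeEvent(tids, did, merged_id, len(seq), round_no,
                                      kind, b.bin_id, score[0], score[1]))
            if not applied:
                break
        out_bins.append(Bin(b.bin_id, ids, source="gapfilled"))
    return BinSet(binset.name, out_bins, stage="gapfilled"), log


def gap_fill(refined: BinSet, archive: BinSet, groups: list[list[str]],
             pool: ContigPool, unbinned: list[str] | None = None,
             round1_overlap: int = ROUND1_MIN_OVERLAP,
             round2_overlap: int = ROUND2_MIN_OVERLAP,
             min_identity: float = MIN_IDENTITY):
    """Two rOLC rounds of increasing stringency plus contiguity stats.

    Donors consumed in round 1 are not offered again in round 2.
    Returns (gap-filled BinSet, events, stats) where stats maps bin id
    to {n_contigs,N50} before/after.
    """
    donors = collect_donors(archive, refined, groups, pool, unbinned)
    before = {b.bin_id: _contiguity(b, pool) for b in refined}
    consumed: set[str] = set()
    r1, ev1 = rolc_round(refined, donors, pool, round1_overlap, min_identity,
                         round_no=1, consumed=consumed)
    r2, ev2 = rolc_round(r1, donors, pool, round2_overlap, min_identity,
                         round_no=2, consumed=consumed)
    events = ev1 + ev2
    stats = {bid: {"before": before[bid], "after": _contiguity(r2.get(bid), pool)}
             for bid in before}
    return r2.with_stage("gapfilled"), events, stats


def _contiguity(b: Bin, pool: ContigPool) -> dict[str, int]:
    lens = [pool[c].length for c in b.contig_ids]
    return {"n_contigs": len(lens), "total_bp": sum(lens), "n50": n50(lens)}
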