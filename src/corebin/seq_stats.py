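"""Sequence-level primitives: tetranucleotide frequency, fragment ANI/AF,
and suffix-prefix overlap detection.

TNF uses the strand-canonical 136-dimension convention standard in
composition-based binning (reverse-complement 4-mer pairs collapsed).
ANI is computed by fragment mapping: the query is chopped into fixed
fragments, each seeded against a k-mer index of the target and aligned
with banded edit distance (edlib). Identity counts gaps as mismatches
(matches / alignment columns), the strictest common convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

__all__ = [
    "TNF_DIM",
    "ANI_UNDEFINED",
    "revcomp",
    "compute_tnf",
    "tnf_distance",
    "AniResult",
    "SequenceIndex",
    "compute_ani",
    "best_fragment_hits",
    "OverlapCandidate",
    "OverlapIndex",
    "find_overlaps",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASE_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

ANI_UNDEFINED = float("nan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Bases as 0..3, anything else (N) as -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[arr]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-window; windows containing N get -1."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        out = (out << 2) | np.where(c < 0, 0, c).astype(np.int64)
        valid &= c >= 0
    out[~valid] = -1
    return out


# ---------------------------------------------------------------------------
# Tetranucleotide frequency

def _build_canonical_map() -> tuple[np.ndarray, int]:
    rc = np.zeros(256, dtype=np.int64)
    for code in range(256):
        r = 0
        c = code
        for _ in range(4):
            r = (r << 2) | (3 - (c & 3))
            c >>= 2
        rc[code] = r
    canon = np.minimum(np.arange(256), rc)
    uniq = np.unique(canon)
    lookup = np.zeros(256, dtype=np.int64)
    for idx, code in enumerate(uniq):
        lookup[canon == code] = idx
    return lookup, len(uniq)


_CANON_LOOKUP, TNF_DIM = _build_canonical_map()
assert TNF_DIM == 136


def compute_tnf(*seqs: str) -> np.ndarray:
    """Canonical tetranucleotide frequency vector (136 dims).

    Several sequences may be passed to obtain a pooled (bin-level)
    vector; windows never span sequence boundaries, and windows
    containing N are skipped. Returns the all-zero vector when no
    valid 4-mer exists.
    """
    counts = np.zeros(TNF_DIM, dtype=np.int64)
    for seq in seqs:
        km = _kmer_codes(_encode(seq), 4)
        km = km[km >= 0]
        if km.size:
            counts += np.bincount(_CANON_LOOKUP[km], minlength=TNF_DIM)
    total = counts.sum()
    if total == 0:
        return np.zeros(TNF_DIM, dtype=float)
    return counts / total


def tnf_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# Fragment-mapping ANI

FRAGMENT_LEN = 1000
MIN_TERMINAL_FRAGMENT = 500
SEED_K = 16
SEED_STRIDE = 4
BAND_FRACTION = 0.05  # band width relative to fragment length
MIN_FRAGMENT_COVERAGE = 0.8
MAX_EDIT_FRACTION = 0.3


@dataclass
class AniResult:
    """Fragment-mapping ANI of a query sequence set against a target set.

    ``ani`` is NaN (undefined) when no fragment aligned; it is never
    reported as a fake 0% identity.
    """

    ani: float
    af: float
    n_fragments_aligned: int


@dataclass
class FragmentHit:
    query_id: str
    target_id: str
    identity: float
    qlen: int
    target_start: int
    target_end: int


class SequenceIndex:
    """Exact k-mer index over a set of named sequences."""

    def __init__(self, seqs: dict[str, str], k: int = SEED_K):
        self.k = k
        self.names = list(seqs)
        self.seqs = seqs
        self._index: dict[int, list[tuple[int, int]]] = {}
        for si, name in enumerate(self.names):
            codes = _kmer_codes(_encode(seqs[name]), k)
            for pos in np.flatnonzero(codes >= 0):
                self._index.setdefault(int(codes[pos]), []).append((si, int(pos)))

    def lookup(self, code: int):
        return self._index.get(code, ())


def _fragments(seq: str):
    """Yield (offset, fragment) pieces of ~FRAGMENT_LEN.

    A trailing piece shorter than MIN_TERMINAL_FRAGMENT is merged into
    the previous fragment so no query bases are dropped; a sequence
    shorter than one fragment is emitted whole.
    """
    n = len(seq)
    starts = list(range(0, n, FRAGMENT_LEN))
    if len(starts) > 1 and n - starts[-1] < MIN_TERMINAL_FRAGMENT:
        starts.pop()
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else n
        yield s, seq[s:e]


def _align_fragment(frag: str, index: SequenceIndex) -> tuple[float, str, int, int] | None:
    """Best (identity, target, t_start, t_end) for one fragment, or None."""
    best = None
    for oriented, flip in ((frag, False), (revcomp(frag), True)):
        codes = _kmer_codes(_encode(oriented), index.k)
        votes: dict[tuple[int, int], int] = {}
        band = max(int(BAND_FRACTION * len(frag)), 20)
        for qpos in range(0, codes.size, SEED_STRIDE):
            code = int(codes[qpos])
            if code < 0:
                continue
            for si, tpos in index.lookup(code):
                diag = (tpos - qpos) // band
                key = (si, diag)
                votes[key] = votes.get(key, 0) + 1
        if not votes:
            continue
        (si, diag), _ = max(votes.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
        tname = index.names[si]
        tseq = index.seqs[tname]
        w0 = max(0, diag * band - band)
        w1 = min(len(tseq), (diag + 1) * band + len(frag) + band)
        window = tseq[w0:w1]
        res = edlib.align(oriented, window, mode="HW", task="path",
                          k=int(MAX_EDIT_FRACTION * len(frag)))
        if res["editDistance"] < 0:
            continue
        matches, cols, qcov = _cigar_stats(res["cigar"], len(frag),
                                           trim_terminal_gaps=True)
        if cols == 0 or qcov < MIN_FRAGMENT_COVERAGE:
            continue
        identity = 100.0 * matches / cols
        loc = res["locations"][0]
        t_start, t_end = w0 + loc[0], w0 + loc[1] + 1
        cand = (identity, tname, t_start, t_end)
        if best is None or cand[0] > best[0]:
            best = cand
    return best


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            ops.append((num, ch))
            num = 0
    return ops


def _cigar_stats(cigar: str, qlen: int, trim_terminal_gaps: bool = False
                 ) -> tuple[int, int, float]:
    """(matches, alignment columns, aligned-query fraction) from an
    edlib extended cigar (=, X, I, D).

    With ``trim_terminal_gaps`` leading/trailing indel runs are
    excluded (local-alignment semantics): a query fragment hanging
    over the end of the target is then scored only on the part that
    truly aligns, and the coverage fraction reflects that part.
    Internal gaps always count as mismatch columns.
    """
    ops = _parse_cigar(cigar)
    if trim_terminal_gaps:
        while ops and ops[0][1] in "ID":
            ops.pop(0)
        while ops and ops[-1][1] in "ID":
            ops.pop()
    matches = cols = qaligned = 0
    for num, ch in ops:
        cols += num
        if ch == "=":
            matches += num
            qaligned += num
        elif ch == "X":
            qaligned += num
    return matches, cols, qaligned / qlen if qlen else 0.0


def best_fragment_hits(query_seqs: dict[str, str], index: SequenceIndex) -> list[FragmentHit]:
    """Map every fragment of every query sequence onto the index."""
    hits = []
    for qid, seq in query_seqs.items():
        for _, frag in _fragments(seq):
            res = _align_fragment(frag, index)
            if res is not None:
                identity, tname, t0, t1 = res
                hits.append(FragmentHit(qid, tname, identity, len(frag), t0, t1))
    return hits


def compute_ani(query_seqs: dict[str, str] | str,
                target: dict[str, str] | str | SequenceIndex) -> AniResult:
    """Fragment-mapping ANI/AF of a query sequence set against a target set.

    ani = mean identity over aligned fragments, af = percent of query
    bases in aligned fragments (denominator: total query bases).
    """
    if isinstance(query_seqs, str):
        query_seqs = {"query": query_seqs}
    if not isinstance(target, SequenceIndex):
        if isinstance(target, str):
            target = {"target": target}
        target = SequenceIndex(target)
    total_bp = sum(len(s) for s in query_seqs.values())
    hits = best_fragment_hits(query_seqs, target)
    if not hits or total_bp == 0:
        return AniResult(ANI_UNDEFINED, 0.0, 0)
    aligned_bp = sum(h.qlen for h in hits)
    ani = float(np.mean([h.identity for h in hits]))
    return AniResult(ani, 100.0 * aligned_bp / total_bp, len(hits))


# ---------------------------------------------------------------------------
# Suffix-prefix / containment overlap detection

OVERLAP_K = 21


@dataclass
class OverlapCandidate:
    donor_id: str
    target_id: str
    overlap_len: int
    identity: float
    orientation: str  # forward | revcomp
    donor_protrudes_left: bool
    donor_protrudes_right: bool
    offset: int  # donor coordinate x maps to target coordinate x + offset


def _overlap_for_offset(donor_seq: str, target_seq: str, offset: int) -> tuple[int, float] | None:
    """Exact-offset overlap geometry: align the implied donor/target
    segments and return (overlap_len, identity)."""
    ld, lt = len(donor_seq), len(target_seq)
    t0, t1 = max(0, offset), min(lt, offset + ld)
    if t1 <= t0:
        return None
    d0, d1 = t0 - offset, t1 - offset
    dseg, tseg = donor_seq[d0:d1], target_seq[t0:t1]
    res = edlib.align(dseg, tseg, mode="NW", task="path",
                      k=max(16, int(0.1 * len(dseg))))
    if res["editDistance"] < 0:
        return None
    matches, cols, _ = _cigar_stats(res["cigar"], len(dseg))
    if cols == 0:
        return None
    return t1 - t0, 100.0 * matches / cols


class OverlapIndex:
    """Exact 21-mer index over target sequences, reusable across many
    donor queries (the Layout step queries every donor against the
    same bin)."""

    def __init__(self, targets: dict[str, str], k: int = OVERLAP_K):
        self.k = k
        self.targets = dict(targets)
        self._index: dict[int, list[tuple[str, int]]] = {}
        for tid in sorted(targets):
            codes = _kmer_codes(_encode(targets[tid]), k)
            for pos in np.flatnonzero(codes >= 0):
                self._index.setdefault(int(codes[pos]), []).append((tid, int(pos)))

    def query(self, donor_id: str, donor_seq: str, min_len: int,
              min_identity: float) -> list[OverlapCandidate]:
        out: list[OverlapCandidate] = []
        for orientation, dseq in (("forward", donor_seq), ("revcomp", revcomp(donor_seq))):
            dcodes = _kmer_codes(_encode(dseq), self.k)
            votes: dict[tuple[str, int], int] = {}
            for qpos in range(dcodes.size):
                code = int(dcodes[qpos])
                if code < 0:
                    continue
                for tid, tpos in self._index.get(code, ()):
                    key = (tid, tpos - qpos)
                    votes[key] = votes.get(key, 0) + 1
            by_target: dict[str, list[int]] = {}
            for (tid, off) in sorted(votes, key=lambda k: (-votes[k], k[0], k[1])):
                if len(by_target.setdefault(tid, [])) < 5:
                    by_target[tid].append(off)
            for tid, offsets in by_target.items():
                tseq = self.targets[tid]
                best_cand = None
                for off in offsets:
                    geom = _overlap_for_offset(dseq, tseq, off)
                    if geom is None:
                        continue
                    ovl, ident = geom
                    if ovl < min_len or ident < min_identity:
                        continue
                    cand = OverlapCandidate(
                        donor_id, tid, ovl, ident, orientation,
                        donor_protrudes_left=off < 0,
                        donor_protrudes_right=off + len(dseq) > len(tseq),
                        offset=off,
                    )
                    if best_cand is None or (cand.overlap_len, cand.identity) > \
                            (best_cand.overlap_len, best_cand.identity):
                        best_cand = cand
                if best_cand is not None:
                    out.append(best_cand)
        out.sort(key=lambda c: (-c.overlap_len, -c.identity, c.target_id, c.orientation))
        return out


def find_overlaps(donor_id: str, donor_seq: str, targets: dict[str, str],
                  min_len: int, min_identity: float) -> list[OverlapCandidate]:
    """Detect suffix-prefix and containment overlaps of a donor against
    each target, in both donor orientations.

    Overlaps are anchored by exact 21-mers shared at a consistent
    offset, verified by global alignment of the implied segments.
    One candidate (the best offset) is emitted per target and
    orientation; ties between equal-length overlaps break by higher
    identity, then lexicographic target id.
    """
    assert min_len >= 1
    return OverlapIndex(targets).query(donor_id, donor_seq, min_len, min_identity)
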