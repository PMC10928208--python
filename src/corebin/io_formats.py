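"""On-disk artifacts: contig pools, bin sets, depth tables, link tables.

All readers validate against a shared contig pool and all writers emit
deterministic, diff-friendly output (sorted records, 80-column FASTA).
Contig identifiers are compared as exact strings; no prefix munging is
ever applied.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "ContigPool",
    "Bin",
    "BinSet",
    "LinkTable",
    "read_contig_pool",
    "write_contig_pool",
    "read_depth_table",
    "write_depth_table",
    "read_binset",
    "write_binset",
    "read_link_table",
    "write_link_table",
]

_VALID = set("ACGTN")
_FASTA_WIDTH = 80


class FormatError(ValueError):
    """A data-contract violation in an on-disk artifact."""


@dataclass
class Contig:
    """A nucleotide sequence with optional per-sample mean read depths."""

    id: str
    seq: str
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise FormatError(f"contig id {self.id!r} is empty or contains whitespace")
        if not self.seq:
            raise FormatError(f"contig {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def mean_depth(self) -> float:
        """Across-sample mean depth; the coverage scalar of the CSI equations."""
        if self.depths is None:
            raise ValueError(f"contig {self.id!r} has no depth vector loaded")
        return float(np.mean(self.depths))


class ContigPool(dict):
    """Ordered mapping id -> Contig; iteration order is load order.

    ``samples`` holds the global sample ordering shared by every depth
    vector once a depth table has been attached.
    """

    def __init__(self, contigs=(), samples: list[str] | None = None):
        super().__init__()
        self.samples: list[str] | None = samples
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self:
            raise FormatError(f"duplicate contig id {contig.id!r}")
        self[contig.id] = contig

    def total_bp(self, ids=None) -> int:
        ids = self.keys() if ids is None else ids
        return sum(self[i].length for i in ids)


@dataclass
class Bin:
    """A named, ordered, duplicate-free collection of contig ids."""

    bin_id: str
    contig_ids: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.contig_ids:
            raise FormatError(f"bin {self.bin_id!r} has no contigs")
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise FormatError(f"bin {self.bin_id!r} contains duplicate contig ids")

    def total_bp(self, pool: ContigPool) -> int:
        return pool.total_bp(self.contig_ids)

    def seqs(self, pool: ContigPool) -> list[str]:
        return [pool[i].seq for i in self.contig_ids]


@dataclass
class BinSet:
    name: str
    bins: list[Bin] = field(default_factory=list)
    stage: str = "initial"  # initial | hybrid | selected | refined | gapfilled

    def __post_init__(self) -> None:
        ids = [b.bin_id for b in self.bins]
        if len(set(ids)) != len(ids):
            raise FormatError(f"binset {self.name!r} has duplicate bin ids")

    def __iter__(self):
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    def get(self, bin_id: str) -> Bin:
        for b in self.bins:
            if b.bin_id == bin_id:
                return b
        raise KeyError(bin_id)

    def with_stage(self, stage: str) -> "BinSet":
        return replace(self, stage=stage)


class LinkTable:
    """Symmetric contig-contig link support (read pairs / long reads)."""

    def __init__(self, records=()):
        self._support: dict[tuple[str, str], int] = {}
        for a, b, s in records:
            self.add(a, b, s)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, support: int) -> None:
        if a == b:
            raise FormatError(f"self-link on contig {a!r}")
        if support < 1:
            raise FormatError(f"link {a!r}-{b!r} has support {support} < 1")
        self._support[self._key(a, b)] = self._support.get(self._key(a, b), 0) + int(support)

    def support(self, a: str, b: str) -> int:
        return self._support.get(self._key(a, b), 0)

    def neighbours(self, contig_id: str):
        """Yield (other_contig, support) for every link touching contig_id."""
        for (a, b), s in self._support.items():
            if a == contig_id:
                yield b, s
            elif b == contig_id:
                yield a, s

    def __len__(self) -> int:
        return len(self._support)

    def records(self):
        for (a, b), s in sorted(self._support.items()):
            yield a, b, s


# ---------------------------------------------------------------------------
# FASTA


def _clean_seq(raw: str, where: str, permissive: bool) -> str:
    seq = raw.upper()
    bad = set(seq) - _VALID
    if bad:
        if not permissive:
            raise FormatError(
                f"{where}: characters {sorted(bad)} are not in ACGTN "
                "(pass permissive=True to map them to N)"
            )
        seq = "".join(ch if ch in _VALID else "N" for ch in seq)
    return seq


def read_contig_pool(path, permissive: bool = False) -> ContigPool:
    """Load an assembled contig pool from FASTA, preserving file order.

    Sequences are uppercased; characters outside ACGTN are a hard error
    unless ``permissive`` maps them to N. Duplicate ids and empty
    sequences are always hard errors.
    """
    pool = ContigPool()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"contig {rec.id!r} has an empty sequence")
        pool.add(Contig(rec.id, _clean_seq(str(rec.seq), f"contig {rec.id!r}", permissive)))
    if not pool:
        raise FormatError(f"no FASTA records in {path}")
    return pool


def _write_fasta(records, path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WIDTH)
        writer.write_file(recs)


def write_contig_pool(pool: ContigPool, path) -> None:
    _write_fasta(((c.id, c.seq) for c in pool.values()), path)


# ---------------------------------------------------------------------------
# Depth tables


def read_depth_table(path, pool: ContigPool) -> ContigPool:
    """Attach per-sample depth vectors from a TSV to an existing pool.

    Two dialects are auto-detected from the header: the plain dialect
    (contigName, then one mean-depth column per sample) and the
    MetaBAT2 / jgi_summarize_bam_contig_depths dialect (contigName,
    contigLen, totalAvgDepth, then alternating depth and variance
    columns; variance columns are ignored). Every pool contig must
    appear in the table; table rows for unknown contigs are skipped
    with a warning.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: depth table needs a contig column and >=1 sample")
        metabat = "contigLen" in header and "totalAvgDepth" in header
        if metabat:
            sample_cols = list(range(3, len(header), 2))
        else:
            sample_cols = list(range(1, len(header)))
        samples = [header[i] for i in sample_cols]
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            cid = parts[0]
            if cid not in pool:
                warnings.warn(f"{path}:{lineno}: contig {cid!r} not in pool; skipped")
                continue
            try:
                vals = np.array([float(parts[i]) for i in sample_cols], dtype=float)
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric or missing depth") from exc
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise FormatError(f"{path}:{lineno}: negative or non-finite depth")
            pool[cid].depths = vals
            seen.add(cid)
    missing = [cid for cid in pool if cid not in seen]
    if missing:
        raise FormatError(
            f"{path}: no depth row for contig(s) {missing[:5]!r}"
            f"{' ...' if len(missing) > 5 else ''} (coverage is mandatory)"
        )
    pool.samples = samples
    return pool


def write_depth_table(pool: ContigPool, path, dialect: str = "plain") -> None:
    """Write the pool's depth matrix as TSV in either accepted dialect."""
    if pool.samples is None:
        raise ValueError("pool has no sample names; attach a depth table first")
    with open(path, "w") as fh:
        if dialect == "plain":
            fh.write("contigName\t" + "\t".join(pool.samples) + "\n")
            for c in pool.values():
                fh.write(c.id + "\t" + "\t".join(_fmt(v) for v in c.depths) + "\n")
        elif dialect == "metabat":
            cols = ["contigName", "contigLen", "totalAvgDepth"]
            for s in pool.samples:
                cols += [s, s + "-var"]
            fh.write("\t".join(cols) + "\n")
            for c in pool.values():
                row = [c.id, str(c.length), _fmt(float(np.sum(c.depths)))]
                for v in c.depths:
                    row += [_fmt(v), _fmt(0.0)]
                fh.write("\t".join(row) + "\n")
        else:
            raise ValueError(f"unknown depth-table dialect {dialect!r}")


def _fmt(v: float) -> str:
    return format(float(v), ".6g")


# ---------------------------------------------------------------------------
# Bin sets


_FASTA_EXT = (".fa", ".fasta", ".fna")


def read_binset(directory, pool: ContigPool, name: str | None = None, stage: str = "initial") -> BinSet:
    """One Bin per FASTA file in ``directory``; bin_id is the file stem.

    Record ids must resolve in the shared pool — bins are views on the
    assembly, never independent sequence stores. Empty files are
    skipped with a warning.
    """
    directory = str(directory)
    files = sorted(f for f in os.listdir(directory) if f.endswith(_FASTA_EXT))
    if not files:
        raise FormatError(f"no FASTA files in {directory}")
    bins = []
    for fname in files:
        ids = []
        for rec in SeqIO.parse(os.path.join(directory, fname), "fasta"):
            if rec.id not in pool:
                raise FormatError(f"{fname}: contig {rec.id!r} not in the contig pool")
            ids.append(rec.id)
        if not ids:
            warnings.warn(f"{fname}: empty FASTA, skipped")
            continue
        stem = fname.rsplit(".", 1)[0]
        bins.append(Bin(stem, ids, source=stage))
    return BinSet(name or os.path.basename(directory.rstrip("/")), bins, stage=stage)


def write_binset(binset: BinSet, directory, pool: ContigPool, overwrite: bool = False) -> None:
    """One FASTA per bin (records in sorted id order) plus a manifest TSV."""
    directory = str(directory)
    if os.path.isdir(directory) and os.listdir(directory) and not overwrite:
        raise FormatError(f"output directory {directory} is not empty (use overwrite=True)")
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "manifest.tsv"), "w") as mf:
        mf.write("bin_id\tn_contigs\ttotal_bp\tstage\n")
        for b in sorted(binset.bins, key=lambda b: b.bin_id):
            ids = sorted(b.contig_ids)
            _write_fasta(((i, pool[i].seq) for i in ids), os.path.join(directory, b.bin_id + ".fa"))
            mf.write(f"{b.bin_id}\t{len(ids)}\t{b.total_bp(pool)}\t{binset.stage}\n")


# ---------------------------------------------------------------------------
# Link tables

_LINK_HEADER = "contig_a\tcontig_b\tsupport"


def read_link_table(path, pool: ContigPool | None = None) -> LinkTable:
    table = LinkTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _LINK_HEADER:
            raise FormatError(f"{path}: expected header {_LINK_HEADER!r}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            a, b, s = line.rstrip("\n").split("\t")
            if pool is not None and (a not in pool or b not in pool):
                warnings.warn(f"{path}:{lineno}: link references unknown contig; skipped")
                continue
            table.add(a, b, int(s))
    return table


def write_link_table(table: LinkTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_LINK_HEADER + "\n")
        for a, b, s in table.records():
            fh.write(f"{a}\t{b}\t{s}\n")
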