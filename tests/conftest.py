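"""Shared fixtures: small hand-built communities plus the standard
seeded benchmarks, generated once per session."""

import numpy as np
import pytest

from corebin import synthetic as syn
from corebin.io_formats import Bin, BinSet, Contig, ContigPool


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1)


def random_dna(rng, n):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def small_pool():
    """Six contigs over two 'genomes' with simple depth vectors."""
    rng = np.random.default_rng(7)
    pool = ContigPool()
    pool.samples = ["s0", "s1"]
    for i in range(6):
        pool.add(Contig(f"c{i}", random_dna(rng, 1500),
                        np.array([10.0 + i, 20.0 + i])))
    return pool


@pytest.fixture(scope="session")
def redundancy40():
    return syn.make_benchmark("redundancy40", seed=1)


@pytest.fixture(scope="session")
def contamination10x5():
    return syn.make_benchmark("contamination10x5", seed=1)


@pytest.fixture(scope="session")
def retrieval10():
    return syn.make_benchmark("retrieval10", seed=1)


@pytest.fixture()  # function-scoped: gap filling adds merge products to the pool
def gapfill5():
    return syn.make_benchmark("gapfill5", seed=1)


@pytest.fixture(scope="session")
def defect_run(tmp_path_factory):
    """One full pipeline run on the standard defect community."""
    from corebin.pipeline import run_pipeline

    base = tmp_path_factory.mktemp("defect")
    planted = syn.standard_defect_community(seed=1)
    syn.write_bundle(planted, base)
    cfg = {
        "inputs": {"bins": [str(base / "bins")], "contigs": str(base / "contigs.fa"),
                   "depth": str(base / "depth.tsv"), "links": str(base / "links.tsv"),
                   "references": str(base / "references.fa")},
        "out": str(base / "out"),
    }
    results = run_pipeline(cfg)
    return {"base": base, "cfg": cfg, "planted": planted, "results": results}
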