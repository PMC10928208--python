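"""Generate a synthetic metagenome community and inspect its parts.

Ten genomes are sampled from perturbed order-3 Markov chains, cut into
contigs, and given negative-binomial read depths over three samples.
"""

import numpy as np

from corebin.synthetic import CommunitySpec, simulate_community

com = simulate_community(CommunitySpec(seed=1))

print(f"genomes:        {len(com.references)}")
print(f"contigs:        {len(com.pool)}")
print(f"samples:        {len(com.pool.samples)}")
lengths = [c.length for c in com.pool.values()]
print(f"contig length:  median {int(np.median(lengths))} bp "
      f"(min {min(lengths)}, max {max(lengths)})")
depths = [c.mean_depth for c in com.pool.values()]
print(f"mean depth:     {np.mean(depths):.1f}x across contigs")

# Every contig is labeled with its source genome — the ground truth that
# downstream benchmarks score against.
gid = com.truth[next(iter(com.pool))]
print(f"first contig comes from genome {gid!r} "
      f"({len(com.references[gid])} bp)")
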