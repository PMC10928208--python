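"""Detect a planted redundant bin with core-sequence coverage statistics.

A duplicate of one genome's bin is planted at half coverage. Inlier
contigs of the two bins are paired at ANI >= 99%; the mean pairwise
depth ratio X recovers the planted coverage scale, and the delta
coverage statistic (|mu_A - X*mu_B| over all inliers) stays near zero,
which is the signature of a redundant pair.
"""

from corebin.bin_selection import classify_redundancy, evaluate_pair
from corebin.synthetic import CommunitySpec, plant_defects, simulate_community

com = simulate_community(CommunitySpec(n_genomes=4, seed=1))
planted = plant_defects(com, redundancy_rate=0.25, coverage_scale_range=(0.5, 0.5))
(orig, dup, scale), = planted.labels.redundant_pairs
print(f"planted duplicate {dup!r} of {orig!r} at coverage scale {scale:.2f}")

decision = evaluate_pair(planted.binset.get(dup), planted.binset.get(orig),
                         planted.pool)
decision = classify_redundancy(decision, mode="threshold")
print(f"inlier pairs (ANI>=99%, >=1 kb): {decision.n_pairs}")
print(f"depth normalization ratio X:     {decision.x_bar:.3f}  "
      f"(planted scale {scale:.2f})")
print(f"delta coverage:                  {decision.delta:.3f}  "
      f"(< w = {decision.w} means the bins sample the same genome)")
print(f"verdict: {decision.verdict}")
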