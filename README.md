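# corebin

Core-sequence-based **selection, refinement and gap filling of
metagenomic bins**, with a deterministic synthetic-community generator
so every stage can be exercised and scored without external data.

Metagenomic binning tools — especially when several binners are run at
several thresholds over multiple assemblies — produce bin sets that are
redundant (the same genome recovered repeatedly at different coverage),
contaminated (foreign contigs), and incomplete (native contigs left
un-binned). `corebin` implements the post-binning chain that turns such
bin sets into non-redundant, cleaned, gap-filled genome bins:

1. **Bin selection.** Bins comprising the same contigs merge into
   hybrid bins; hybrid bins group at ANI ≥ 99% and aligned fraction
   ≥ 50%. Within a group, each bin's *core* (inlier) contigs are those
   whose mean depth x_i satisfies the interquartile band

   ```
   Q1 − k·IQR  ≤  x_i  ≤  Q3 + k·IQR        (k = 0 for core identification)
   ```

   Inliers of a bin pair are matched by sequence identity (ANI ≥ 99%,
   both ≥ 1000 bp), giving the depth-normalization ratio
   `X̄ = (1/n) Σ cov(a_i)/cov(b_i)` and the delta coverage
   `Δ = |μ_A − X̄·μ_B|` over *all* inliers. `Δ < w` marks the pair
   redundant; the smaller bin is archived (not discarded). The decision
   threshold is either a fixed calibrated `w` or a small fully
   connected classifier trained on labeled synthetic pairs.

2. **Refinement.** Each contig of each bin is tested on several
   dimensions — Euclidean distance of its 136-dimension canonical
   tetranucleotide frequency (TNF) vector to the bin's length-weighted
   centroid, every pairwise coverage ratio `CCC_ab = cov_a / cov_b`
   across samples, and mean depth — with the same IQR band at
   k ∈ {0, 0.5, 1, 2} (removal at the conservative k = 2). Flagged
   contigs are pooled, not destroyed; iterative read-pair link tracking
   then re-homes un-binned contigs into the bin they are most strongly
   linked to, gated by the same composition+coverage test.

3. **Gap filling (rOLC).** Inliers of archived redundant bins and
   remaining un-binned contigs act as donors that extend bin contigs or
   bridge two of them, under restrained overlap–layout–consensus rules:
   overlap ≥ 300 bp (round 1) / ≥ 500 bp (round 2) at ≥ 99% identity,
   no donor protruding beyond its target at both ends, merged length
   < 105% of the summed target lengths, target base kept at every
   disagreement.

4. **Evaluation.** Against reference genomes, completeness = % of the
   majority reference covered, contamination = % of aligned bp on
   other references, quality = completeness − 5·contamination, with
   tiers *baseline* (≥35% / ≤20%), *MAG* (quality ≥ 50) and *high*
   (≥90% / ≤5%).

## Worked example

`examples/` holds one short script per capability. Detecting a planted
redundant bin (`examples/02_bin_selection.py`):

```
planted duplicate 'bin_g01_dup' of 'bin_g01' at coverage scale 0.50
inlier pairs (ANI>=99%, >=1 kb): 8
depth normalization ratio X:     0.476  (planted scale 0.50)
delta coverage:                  0.267  (< w = 2.0 means the bins sample the same genome)
verdict: redundant
```

The pairwise depth ratio recovers the planted coverage scale (0.476 vs
0.50), and the near-zero delta says the two bins' coverage structures
agree up to that scale — a redundant pair. The full pipeline on a
community with planted duplicates, contaminants and withheld contigs
(`examples/05_full_pipeline.py`):

```
10 bins selected (3 archived as redundant)
  selected: quality  59.43  completeness  85.68  contamination  5.25  (9 MAG-grade bins)
   refined: quality  87.60  completeness  88.22  contamination  0.12  (10 MAG-grade bins)
 gapfilled: quality  87.65  completeness  88.27  contamination  0.12  (10 MAG-grade bins)
```

Mean true quality rises monotonically through the stages: refinement
removes essentially all planted contamination and recovers withheld
contigs; gap filling adds contiguity without ever lowering quality.

A thin CLI mirrors the library (`corebin select|refine|gapfill|eval|
simulate|fixture|run`); `corebin run --config run.yaml` executes the
whole chain with content-hash checkpoints, so a killed run resumes
byte-identically and configuration drift is refused unless `--force`d.

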