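# Methods

## The redundancy decision (core sequence identification)

Bins are compared only within groups pre-screened by sequence: an edge
joins two bins when fragment-mapping ANI ≥ 99% and aligned fraction
≥ 50% in at least one direction (AF is query-relative, so a partial bin
inside a fuller one still groups); groups are single-linkage connected
components.

Within a bin, the coverage scalar of every contig is its across-sample
mean depth. The core (inlier) band is `Q1 − k·IQR ≤ x ≤ Q3 + k·IQR`
with quartiles by linear interpolation between order statistics.
Bounds are *inclusive* with a 1e-9 relative tolerance: with tied
quartiles (IQR = 0, the normal case for a uniformly covered bin at
k = 0) a literal strict inequality would classify every contig as an
outlier; the tolerance also keeps classification independent of the
floating-point path that produced the quartiles. A strict mode is
retained for fidelity experiments. Core identification uses k = 0,
i.e. the central half of the coverage distribution — deliberately
conservative, because the paired-inlier statistics below assume the
core is free of contaminating coverage levels.

For a grouped pair, inlier contigs ≥ 1000 bp are matched greedily by
contig-level ANI (descending ANI, ties by aligned length then ids; one
partner each). The depth-normalization ratio is the mean of paired
coverage ratios, and the delta coverage `Δ = |μ_A − X̄·μ_B|` is taken
over **all** inliers, paired or not. This asymmetry is the point: a
chimeric bin that shares one genome with its partner pairs only on the
shared content, so X̄ reflects the shared part while μ_B includes the
foreign part, and Δ grows. A genuine duplicate is proportional
everywhere and Δ stays at the noise floor. Zero qualifying pairs is a
distinct *no-evidence* verdict and both bins are always retained.

Two decision modes stand in for a learned threshold:

* **threshold** (default): redundant iff Δ < w. The shipped default
  w = 2.0 comes from `calibrate_threshold` (geometric midpoint between
  the labeled Δ populations) on the standard redundancy benchmark;
  on that data the redundant class sits below ≈ 0.9 and the distinct
  class above ≈ 2.6.
* **model**: a small fully connected network (16×8 ReLU, logistic
  output) over signed-log features (Δ, Δ/μ, X̄, pair count, inlier bp,
  coverage dispersions), trained with scikit-learn on labeled synthetic
  pairs and persisted as plain JSON (standardisation parameters plus
  layer weights), evaluated by an explicit forward pass.

An absolute Δ compared against one global w is only meaningful when
the abundance range across compared pairs is moderate — Δ's noise floor
scales with μ. The redundancy benchmark therefore uses a moderately
even community (abundance σ = 0.35 on the log scale); the feature-based
model mode is the instrument for wider abundance ranges.

When a pair is redundant, the bin with less total inlier bp is archived
(ties: the lexicographically larger id), strongest evidence (smallest
Δ) first; archived bins later serve as gap-filling donors.

## Sequence primitives

* **TNF**: 136-dimension canonical tetranucleotide frequencies
  (reverse-complement 4-mer pairs collapsed), windows never spanning
  contig boundaries, N-containing windows skipped. Bin composition is
  the length-weighted mean vector, so long, reliable contigs anchor the
  centroid.
* **Fragment ANI**: the query is chopped into 1000-bp fragments
  (a trailing piece < 500 bp merges into its predecessor, so nothing is
  dropped); each fragment is seeded by exact 16-mers (stride 4) against
  an index of the target, the best diagonal is verified by banded edit
  distance (edlib, band ≈ 5% of the fragment, edit cap 30%), and
  identity is matches / alignment columns with *terminal* indel runs
  trimmed — local-alignment semantics, so a fragment hanging over a
  contig end is scored on the part that truly aligns. A fragment counts
  as aligned when ≥ 80% of it aligns; ANI is the mean identity of
  aligned fragments and AF the percent of query bases they carry. ANI
  is reported as NaN, never a fake 0, when nothing aligns.
* **Overlap detection**: exact 21-mer anchors at a consistent offset,
  verified by global alignment of the implied segments (gaps count as
  mismatches there — the strictest convention); both donor orientations
  tested; ties break by overlap length, identity, then target id.

## Refinement

Outlier dimensions per bin: TNF distance to centroid (one scalar
dimension — per-component testing over 136 dimensions would flag nearly
every contig), one dimension per unordered sample pair of coverage
ratios (pseudocount 0.01 on denominators), and mean depth. Bands are
computed at k ∈ {0, 0.5, 1, 2} for diagnostics; removal uses the most
conservative listed value, k = 2, and a contig is removed when outside
*any* dimension's band. Bins with fewer than 4 contigs are never pruned
(no quartile support), and a bin whose survivors total < 50 kb
dissolves entirely into the un-binned pool — below any plausible genome
size, fragments serve retrieval better than a stub bin. Removed contigs
are pooled, not destroyed, which is what lets mis-homed multi-copy
sequence be re-assigned rather than lost.

Retrieval iterates to a fix point (guard: 20 iterations): an un-binned
contig joins a bin when its summed link support there is ≥ 3 (enough to
suppress sporadic chimeric pairs at typical simulated link rates), that
bin is the unique support maximizer (strict tie: never guess), and the
contig passes the bin's k = 2 composition+coverage band test. Each
iteration is computed against the membership at its start, so a chain
c1–c2–bin resolves over exactly two iterations. A final redundancy
re-check (same machinery as selection) runs after retrieval and again
after gap filling.

## Gap filling

Donors are the archived bins' contigs re-filtered by outlier removal at
k = 2, offered only to bins in the archived bin's ANI group, plus all
remaining un-binned contigs, offered to every bin. Layout accepts an
extension when the donor protrudes past exactly one target end, and a
bridge when the donor leaves one contig's tail and enters another's
head, each flank meeting the round's overlap/identity thresholds
(≥ 300 bp round 1, ≥ 500 bp round 2, ≥ 99% identity). Both event kinds
must satisfy merged length < 105% of the summed target lengths, and a
donor protruding at both ends of a target is rejected outright — both
restrictions exist to keep contamination from being stitched into a
bin. Consensus keeps the target base at every disagreement (targets
passed refinement QC; donors did not), so on exact-overlap fixtures the
arithmetic is exact: `l1 + l2 − overlap` for extensions,
`l1 + l2 + gap` for bridges. Events apply greedily by total overlap
length; a donor is consumed at most once per round and never reused in
round 2; a donor whose best event is blocked by a fresh merge product
waits for the next pass rather than settling for a worse event. N in a
donor never matches, so low-quality masked bases cannot seed a merge.
Reassembly between the two rounds is out of scope; an external
assembler can be slotted between them by rerunning the stage on its
output.

## Evaluation

Each bin contig is fragment-aligned against the closed reference set
and assigned to the reference receiving most of its aligned bp.
Completeness counts each covered majority-reference position once;
contamination's denominator is aligned bp, so novel unaligned sequence
is not punished. Quality = completeness − 5·contamination. Tiers:
high (completeness ≥ 90 ∧ contamination ≤ 5), MAG (quality ≥ 50),
baseline (completeness ≥ 35 ∧ contamination ≤ 20), reported with that
precedence. ORF-level contamination screening would need a gene caller
and is not implemented.

## The synthetic generator

Genomes are order-3 Markov chains perturbed from one shared base model;
the `divergence` parameter (default 0.1) scales a per-genome Gaussian
perturbation of the transition logits and controls how separable
genomes are compositionally. Genomes default to 100–160 kb — a
deliberate scale-down that preserves what the statistics consume:
dozens of ≥ 1 kb contigs per bin (lognormal lengths, median ≈ 3 kb,
matching a typical short-read metagenome assembly regime), per-sample
abundances lognormal(3.0, 0.7) (median ≈ 20×), and per-contig depths
drawn as negative-binomial read counts at dispersion r = 50 (≈ 14%
coverage CV per contig — moderate overdispersion). Links join
genome-adjacent contigs with depth-proportional Poisson support
(min 1) plus 2% false cross-genome links; link simulation is
adjacency-based, not read-level, because retrieval consumes link
tables, not reads.

Planted defects are labeled exhaustively. Redundant duplicates are
*re-fragmented* from the genome with fresh contig boundaries, 10–30% of
contigs dropped, and depths re-drawn at one rescaled mean — a bin of
the same genome from a second assembly, which also makes archived
duplicates genuinely useful rOLC donors. Distinct (negative) pairs are
chimeras: half the bin re-fragmented from the host genome, half from
another genome at its own abundance, balanced by contig count and with
a guaranteed abundance contrast — a minority component would be
stripped by the k = 0 core filter (leaving a genuinely redundant core),
and a contrast-free chimera is informationally indistinguishable from a
rescaled duplicate by any coverage-based method.

What the generator does **not** emulate: real k-mer composition (Markov
chains are smoother than real genomes, so TNF separation at default
divergence is weaker than between real taxa — coverage dimensions carry
most of the contaminant signal here), read-level artifacts (chimeric
contigs, strain microdiversity, mapping bias), assembly errors, and
genome-scale repeat structure. Passing benchmarks therefore demonstrate
the statistics behave as designed under their stated assumptions, not
field performance on real communities.

## Known limitations and degenerate cases

* IQR outlier removal has a statistical false-positive floor: with
  ~5 tested dimensions and unbounded coverage noise, ≈ 2% of clean
  native contigs fall outside the k = 2 band. They are parked in the
  un-binned pool (and usually re-homed by retrieval when link evidence
  exists), never silently deleted — but a defect-free community is not
  reproduced exactly.
* The fixed-w threshold mode assumes comparable coverage magnitudes
  across pairs; use model mode for communities spanning large abundance
  ranges.
* Single-sample data leaves no CCC dimensions; only TNF and depth are
  tested.
* Evaluation is nucleotide-level against a closed reference set;
  reference-free (marker-gene) quality estimation is out of scope.
* All stages are deterministic given their inputs; the only randomness
  in the package lives in the generator and classifier training, both
  seeded.
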