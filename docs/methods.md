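# Methods

## Data model

A genome is an ordered list of chromosomes; a chromosome is an ordered
sequence of signed integer gene labels plus a linear/circular flag.
Signs carry orientation (+g: tail→head).  Duplications are allowed
everywhere, so adjacency and content are multisets, and distinct
genomes can share the same multiset — the profile, not the genome, is
the object the encodings consume.

Adjacency identity: the pair (a, b) of consecutive signed genes equals
its reverse-complement (−b, −a); the canonical key is the
lexicographically smaller ordered pair, while the display form records
the first-encountered orientation.  Telomeres are recorded as signed
free extremities (positive = head).  A circular chromosome of length L
contributes L adjacencies — the closing adjacency (last, first) is
enumerated *first*, then the scan-order pairs; a linear chromosome
contributes its left telomere, L−1 internal adjacencies, and its right
telomere.  The closing-first rule is the deterministic convention that
fixes column order in the encodings (columns appear in first-appearance
order while scanning genomes in input order); any fixed convention
would do statistically, but this one is frozen and tested.

## Encodings

For each adjacency key with maximum copy number t across the dataset, a
genome with k copies contributes (t−k) zeros then k ones.  vlbe2/vlbe3
append gene-content columns (presence/absence, respectively
multiplicity blocks), genes in ascending label order; mlwd is the
presence/absence baseline.  Widths are therefore Σ_a t_a (+ gene terms)
and the number of ones per row equals the number of adjacencies +
telomeres (+ gene copies) of that genome — both conservation laws are
property-tested.

Invariant-column reduction (dropping columns where every genome agrees)
defaults **off**, reproducing the reference tables exactly — note the
three-genome example retains constant gene-presence columns even in the
reduced-looking tables, so both behaviours are exposed and the pipeline
presets turn reduction on.

## Substitution model

Two states (0 = absent, 1 = present), asymmetric rates.  The bias ratio
B = loss/gain defaults to 1000: adjacencies and gene copies are easily
destroyed by rearrangement and essentially never independently
recreated.  Stationary frequencies π₀ = B/(B+1), π₁ = 1/(B+1);

    P01(t) = π1 (1 − e^(−λt)),   P10(t) = π0 (1 − e^(−λt)).

λ is fixed by normalizing the stationary flip flux to one expected flip
per site per unit branch length, λ = 1/(2π₀π₁), making branch lengths
comparable across bias ratios.  The root prior is the stationary
distribution, so the model is time-reversible and the likelihood is
root-placement invariant (tested to 10⁻⁸).  No ascertainment-bias
correction is applied: all-absent columns are unobservable in
principle, and with π₁ ≈ 10⁻³ the uncorrected likelihood already treats
gains as rare; the omission is a known deviation risk for branch-length
interpretation (topology is far less sensitive).

Numerical notes that matter in practice:

* With B = 1000, λ ≈ 500, so the *informative* branch-length range is
  roughly [10⁻⁸, 10⁻²] inside the admissible bracket [10⁻⁸, 20]
  (lengths beyond ~5/λ are numerically stationary).  Per-branch
  optimization therefore runs bounded Brent in **log-length space**;
  linear-space search essentially never probes the informative sliver.
* A tree whose branches are all saturated is a fixed point of
  round-robin per-branch optimization (no signal crosses a saturated
  neighborhood), so hill-climbing initializes every branch at the
  relaxation scale 1/λ rather than at distance-based lengths.
* Column patterns are deduplicated with multiplicity weights before
  pruning; per-node partials are rescaled to avoid underflow.
* Round-robin branch optimization exits when a full round improves the
  log-likelihood by less than `tol` (default 10⁻⁶) or after 25 rounds
  (warning, best-so-far returned).  NNI accepts the first strictly
  improving move in a fixed node-index scan order — deterministic under
  the seed; after each accepted move all branch lengths are re-optimized.

## Tree search

Starting trees: neighbor-joining (scikit-bio) on normalized per-pair
Hamming distances of the encoded rows; additional starts use
random-permutation stepwise addition.  Search is NNI hill-climbing;
with ≤ 3 taxa the unique topology is returned directly.  Bootstrap
resamples columns with replacement and reports the percentage of
replicate trees containing each bipartition of the best tree.

The `BinaryTreeML`/`TreeMLResults` pair is the modelling front end:
construct from an encoding matrix (or genomes), `fit()`, inspect
`summary()`, `branch_lengths()`, `newick`.

## Simulator

One replicate: a Yule topology on n_leaves (the pure-birth intensity
cancels out of the conditioned topology, so only the split order is
random), then per-branch event budgets L = r·n·(1/K)·e^s with
s ~ U(−1,1), where K is the edge count of the longest leaf-to-leaf path
and r ∈ {1..4} scales the expected tree diameter to d = r·n events.
Budgets are round(L) — branch "length" is an event count.  The root is
the identity genome (one linear chromosome 1..n by default).

Event semantics: inversion reverses and sign-flips a segment;
transposition moves a segment (weight 0 in all presets); translocation
exchanges suffixes of two linear chromosomes; fusion concatenates two
chromosomes (circulars are opened at a random point); fission splits a
chromosome (a circle opens into one linear); insertion adds fresh,
never-seen labels; deletion removes a segment (emptying the genome
aborts the replicate); segmental duplication copies a segment to a
random position; WGD appends a copy of every chromosome.  Inapplicable
draws are resampled.  Segment lengths are Uniform{1..10} genes by
default.  Every event is logged with its exact parameters, and each
leaf genome is reproducible by replaying its root-to-leaf log prefix
(tested).

Preset event mixes (this package's calibration, exposed in config):
`no_dup` (inversion .70, translocation .10, fusion .05, fission .05,
insertion .04, deletion .06), `segmental_dup` (shifts .15 from
inversion to segmental duplication), `segmental_wgd` (adds WGD .005).

What the simulator emulates — and what it does not: it produces
realistic *event regimes* (rates, mixes, duplication pressure) over
random trees, but genes are exchangeable integer labels with no
lengths, no intergenic distances, no hotspots, no gene-family birth
process, and no ortholog-assignment noise.  Passing recovery tests
therefore demonstrates correctness of the encode→infer pipeline under
the stated stochastic model, not performance on real annotated genomes,
where homology assignment errors dominate.

## Benchmark scales and an honest negative result

The built-in experiments run at desk scale (10 leaves, 200 genes,
replicates in the tens) so the full suite completes quickly; the same
harness accepts larger scenarios.

At this scale the recovery experiment (rearrangement-only, r = 1)
attains mean RF error ≈ 0.07 for vlbe1 over 10 replicates.  In the
`segmental_wgd` regime at r = 2, however, the multiplicity encodings
**do not** beat the presence/absence baseline here: measured means are
mlwd ≈ 0.00, vlbe1 ≈ 0.21, vlbe3 ≈ 0.31 over 20 replicates.  Two
compounding reasons, both structural:

1. *Floor effect.*  WGD is invisible to presence/absence characters, so
   mlwd sees an effectively duplication-free dataset, which it already
   solves perfectly at 10 leaves / 200 genes.  There is no error left
   for copy-number information to remove.
2. *Ploidy homoplasy.*  At .005 WGD weight and ~10³ events per
   replicate, every replicate contains several WGDs on *independent*
   branches.  A WGD flips thousands of multiplicity-slot columns
   ([count ≥ 2] and deeper) simultaneously for everything below it, so
   unrelated doubled lineages share massive, correlated "rare gain"
   signatures, and the independent-columns likelihood groups leaves by
   ploidy rather than ancestry.  Per-replicate vlbe3 error correlates
   strongly with the number of WGD branches.  With at most one WGD per
   dataset the same signature *reinforces* a true clade instead — the
   regime in which multiplicity encoding is expected to shine.

The corresponding ordering test in `tests/test_acceptance.py` asserts
the favourable ordering and currently fails; it is kept as an explicit,
honest record of this limitation rather than weakened.

## Other limitations

* No rate heterogeneity across sites and no partitioned models; the
  engine targets desk-scale correctness, with PHYLIP/FASTA export for
  scaling out to external ML programs.
* Binary alphabet only.
* The RF error rate uses 2(n−3) for binary trees; search never emits
  polytomies, and the fallback normalization (larger internal-edge
  count) exists only for user-supplied trees.
* CLI provenance: TSV/newick outputs carry '#' headers; PHYLIP/FASTA
  formats cannot carry comments, so every run also writes a
  `*.provenance.json` sidecar with version, config hash and seed.
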