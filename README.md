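# vlwd — gene-order phylogenies with massive duplications

`vlwd` reconstructs phylogenies from whole-genome **gene-order** data:
signed, possibly duplicated gene sequences partitioned into linear and
circular chromosomes.  Gene-order changes (inversions, translocations,
fusions, fissions, indels, segmental duplications and whole-genome
duplications) are rare relative to point mutations, so they carry
phylogenetic signal much deeper in time — but classical encodings break
down when genomes contain many duplicated genes.

The package is aimed at comparative genomicists who already have gene
orders (integer gene-family labels, orientation in the sign) and want a
maximum-likelihood tree, and at methods developers who want a controlled
simulator and benchmark harness for duplication-heavy regimes.

## The method

A genome is summarized by its multiset of **adjacencies** — unordered
pairs of gene extremities that are consecutive on a chromosome, with
(a, b) ≡ (−b, −a) — plus **telomeres** (free extremities of linear
chromosomes) and its **gene content** (copy number per gene family).

These multisets are turned into aligned binary characters by
variable-length binary encodings.  For each adjacency a with maximum
copy number t = max_i k_i across the genomes D_1..D_n, a genome with k
copies contributes a block of *t − k* zeros followed by *k* ones:

* **vlbe1** — adjacency multiplicity blocks only (rearrangement-only model);
* **vlbe2** — vlbe1 plus one presence/absence column per gene;
* **vlbe3** — vlbe1 plus per-gene multiplicity blocks, encoded the same way;
* **mlwd** — the presence/absence baseline (one column per adjacency and
  per gene; no copy-number information).

Trees are fitted under a two-state asymmetric-rate Markov model.  The
**bias ratio** B (default 1000) is the loss rate (1 → 0) over the gain
rate (0 → 1): an adjacency or gene copy is easily destroyed and very
unlikely to be recreated.  Stationary frequencies are
π₀ = B/(B+1), π₁ = 1/(B+1); transition probabilities have the closed
form P₀₁(t) = π₁(1−e^(−λt)), P₁₀(t) = π₀(1−e^(−λt)), with λ normalized
so a unit branch length is one expected flip per site at stationarity.
Likelihoods use Felsenstein pruning with a stationary root prior;
search is NNI hill-climbing from a neighbor-joining start, with column
bootstrap for supports.  Alignments can also be exported in relaxed
PHYLIP/FASTA for an external ML program.

A genome-evolution simulator (Yule topologies, per-branch event budgets
L = r·n·(1/K)·e^s with s ~ U(−1,1), configurable event mixes including
segmental and whole-genome duplication) and a Robinson-Foulds benchmark
loop close the validation circle.

## Worked example

Simulate six genomes of 100 genes under rearrangements + segmental
duplications, encode with vlbe3, fit, and compare to the truth:

```python
from vlwd import (SimScenario, simulate, build_profile, gene_content,
                  encode, BinaryTreeML, rf_error)
from vlwd.likelihood import to_newick

scenario = SimScenario.from_preset("segmental_dup", n_leaves=6,
                                   n_genes=100, rate=1, seed=42)
result = simulate(scenario)
profile = build_profile(result.leaf_genomes)
content = {g.name: gene_content(g) for g in result.leaf_genomes}
matrix = encode(profile, content, scheme="vlbe3",
                reduce_invariant_columns=True)

res = BinaryTreeML(matrix, bias_ratio=1000).fit(seed=1)
print(res.summary())
print(rf_error(to_newick(result.tree), res.tree))
```

prints

```
Binary-encoding ML phylogeny
============================================
taxa:             6
sites:            785 (vlbe3)
bias ratio:       1000
stationary pi:    (0.999001, 0.000999001)
log-likelihood:   -6570.8504
tree length:      0.0107 expected flips/site
starts / seed:    1 / 1
tree:
  (T2:0.0004643761735927942,(((T4:0.000687616353166824,T5:0.0002721807585256637):0.0010326370038638015,T1:0.0013267686550508817):0.002654423385005811,T6:0.001261868008034802):0.0012301537910852731,T3:0.0017349049173730608);
RFReport(rf_distance=0, rf_error_rate=0.0, n_internal_edges=6)
```

785 binary sites come out of ~600 adjacencies/telomeres and ~120 gene
families after dropping invariant columns; the fitted tree matches the
simulated truth exactly (RF distance 0), and the tiny branch lengths
(≈10⁻³ expected flips per site) reflect how strongly the B = 1000 bias
compresses the time axis.

The same pipeline is available from the shell:

```sh
vlwd encode genomes.txt --scheme vlbe3 -o aln.phy      # GRIMM-like input
vlwd infer aln.phy --bias-ratio 1000 --seed 1 -o tree.nwk
vlwd simulate scenario.yaml -o simdir/
vlwd benchmark sweep.yaml -o results.tsv
vlwd rf simdir/true_tree.nwk tree.nwk
```

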