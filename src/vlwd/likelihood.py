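"""Maximum-likelihood tree inference on binary encodings.

The substitution model is a two-state (0/1) continuous-time Markov chain
with asymmetric rates.  The *bias ratio* B is the loss rate (1 -> 0)
divided by the gain rate (0 -> 1); adjacencies and gene copies are far
more easily destroyed than re-created, so B defaults to 1000.  The chain
has stationary frequencies pi0 = B/(B+1), pi1 = 1/(B+1) and closed-form
transition probabilities

    P01(t) = pi1 (1 - exp(-lam t)),   P10(t) = pi0 (1 - exp(-lam t)),

where lam is fixed by normalizing the expected number of state flips per
unit branch length at stationarity to 1 (lam = 1 / (2 pi0 pi1)), making
branch lengths comparable across bias ratios.

Likelihoods are computed by Felsenstein pruning with a stationary root
prior; the model is time-reversible, so the likelihood is invariant to
root placement.  Tree search is NNI hill-climbing from a neighbor-joining
start (per-pair Hamming distances), with optional extra random stepwise-
addition starts; branch lengths are optimized per-branch by bounded
scalar minimization in round-robin passes.

Trees are carried as :class:`dendropy.Tree` objects ("PhyloTree" in this
package's vocabulary); newick strings are accepted anywhere a tree is.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .encodings import EncodingMatrix

__all__ = [
    "TwoStateModel",
    "PhyloTree",
    "read_newick",
    "to_newick",
    "transition_matrix",
    "log_likelihood",
    "optimize_branch_lengths",
    "search_tree",
    "bootstrap",
    "BinaryTreeML",
    "TreeMLResults",
]

PhyloTree = dendropy.Tree

_MIN_BRANCH = 1e-8
_MAX_BRANCH = 20.0


class TwoStateModel:
    """Asymmetric two-state substitution model parameterized by the bias ratio."""

    def __init__(self, bias_ratio: float = 1000.0):
        if not bias_ratio > 0:
            raise ValueError("bias ratio must be positive")
        self.bias_ratio = float(bias_ratio)
        B = self.bias_ratio
        self.pi = np.array([B / (B + 1.0), 1.0 / (B + 1.0)])
        # expected flips per unit branch length at stationarity:
        # pi0*gain + pi1*loss = 2*pi0*pi1*lam  ==  1
        self.rate = 1.0 / (2.0 * self.pi[0] * self.pi[1])

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        f = -np.expm1(-self.rate * t)  # 1 - exp(-lam t), accurate near 0
        p0, p1 = self.pi
        return np.array([[1.0 - p1 * f, p1 * f], [p0 * f, 1.0 - p0 * f]])

    def __repr__(self) -> str:
        return f"TwoStateModel(bias_ratio={self.bias_ratio:g})"


def transition_matrix(model: TwoStateModel, t: float) -> np.ndarray:
    """2x2 stochastic matrix P(t) for the model (rows: from-state 0, 1)."""
    return model.transition_matrix(t)


# ---------------------------------------------------------------------------
# newick / tree plumbing


def read_newick(source: str | Path, taxon_namespace: dendropy.TaxonNamespace | None = None) -> PhyloTree:
    """Parse a newick tree from a string or a file path (underscores preserved)."""
    kwargs = dict(schema="newick", preserve_underscores=True)
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    text = str(source)
    if "(" in text:
        return dendropy.Tree.get(data=text, **kwargs)
    return dendropy.Tree.get(path=text, **kwargs)


def to_newick(tree: PhyloTree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def _as_tree(tree: PhyloTree | str) -> PhyloTree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return read_newick(tree)


def _leaf_labels(tree: PhyloTree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _clamp_branch_lengths(tree: PhyloTree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length < _MIN_BRANCH:
            edge.length = _MIN_BRANCH


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a degree-2 root into a trifurcation (in place; returns tree)."""
    root = tree.seed_node
    if len(root.child_nodes()) == 2:
        internal = [c for c in root.child_nodes() if not c.is_leaf()]
        if internal:
            tree.collapse_basal_bifurcation()
    return tree


# ---------------------------------------------------------------------------
# pruning engine


class _SiteData:
    """Unique column patterns + multiplicities of an encoding matrix."""

    def __init__(self, matrix: EncodingMatrix):
        if matrix.width == 0:
            raise ValueError("cannot compute likelihoods on an empty matrix")
        self.taxa = list(matrix.taxa)
        self.row_of = {name: i for i, name in enumerate(self.taxa)}
        patterns, weights = np.unique(matrix.bits, axis=1, return_counts=True)
        self.patterns = patterns  # (n_taxa, n_patterns)
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]
        # leaf partials: one-hot of the observed state per pattern
        self._leaf_partials = {}
        for name, i in self.row_of.items():
            states = patterns[i]
            part = np.zeros((self.n_patterns, 2))
            part[np.arange(self.n_patterns), states] = 1.0
            self._leaf_partials[name] = part

    def leaf_partial(self, label: str) -> np.ndarray:
        try:
            return self._leaf_partials[label]
        except KeyError:
            raise ValueError(f"tree leaf '{label}' not present in the matrix taxa") from None


def _pruned_loglik(tree: PhyloTree, data: _SiteData, model: TwoStateModel) -> float:
    npat = data.n_patterns
    logscale = np.zeros(npat)
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[id(node)] = data.leaf_partial(node.taxon.label)
            continue
        part = np.ones((npat, 2))
        for child in node.child_nodes():
            t = child.edge.length
            if t is None:
                raise ValueError("tree has a missing branch length")
            P = model.transition_matrix(t)
            part = part * (partials.pop(id(child)) @ P.T)
        m = part.max(axis=1)
        nz = m > 0
        safe = np.where(nz, m, 1.0)
        part = part / safe[:, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(nz, np.log(safe), -np.inf)
        partials[id(node)] = part
    root_part = partials[id(tree.seed_node)]
    site = root_part @ model.pi
    with np.errstate(divide="ignore"):
        return float(np.dot(data.weights, np.log(site) + logscale))


def log_likelihood(
    tree: PhyloTree | str, matrix: EncodingMatrix, model: TwoStateModel
) -> float:
    """Log-likelihood of the matrix on the tree (stationary root prior).

    Leaf labels must match the matrix taxa exactly; the result does not
    depend on where the tree is rooted (the model is reversible).
    """
    tree = _as_tree(tree)
    if set(_leaf_labels(tree)) != set(matrix.taxa):
        raise ValueError("tree leaf set does not match matrix taxa")
    return _pruned_loglik(tree, _SiteData(matrix), model)


# ---------------------------------------------------------------------------
# branch-length optimization


def _edges(tree: PhyloTree) -> list:
    return [
        nd.edge
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node
    ]


def _optimize_edge(tree, edge, data, model, current_ll: float) -> float:
    # Optimize in log-length space: with large bias ratios the normalized
    # rate is huge and the informative region spans only the smallest few
    # decades of the bracket, which a linear-space search never probes.
    def neg_ll(u: float) -> float:
        edge.length = float(np.exp(u))
        return -_pruned_loglik(tree, data, model)

    res = minimize_scalar(
        neg_ll, bounds=(np.log(_MIN_BRANCH), np.log(_MAX_BRANCH)), method="bounded",
        options={"xatol": 1e-7},
    )
    if -res.fun >= current_ll:
        edge.length = float(np.exp(res.x))
        return float(-res.fun)
    # optimizer failed to improve (flat likelihood); keep previous length
    edge.length = float(edge.length)
    return current_ll


def _optimize_branch_lengths(
    tree: PhyloTree, data: _SiteData, model: TwoStateModel,
    tol: float = 1e-6, max_rounds: int = 25,
) -> tuple[float, list[float]]:
    _clamp_branch_lengths(tree)
    ll = _pruned_loglik(tree, data, model)
    trace = [ll]
    for _ in range(max_rounds):
        before = ll
        for edge in _edges(tree):
            ll = _optimize_edge(tree, edge, data, model, ll)
        trace.append(ll)
        if ll - before < tol:
            return ll, trace
    warnings.warn("branch-length optimization did not converge; returning best so far")
    return ll, trace


def optimize_branch_lengths(
    tree: PhyloTree | str,
    matrix: EncodingMatrix,
    model: TwoStateModel,
    tol: float = 1e-6,
    max_rounds: int = 25,
) -> PhyloTree:
    """Round-robin per-branch optimization until the round gain drops below tol.

    Operates on (and returns) a clone of the input tree; the result carries
    ``log_likelihood`` and the per-round ``optimization_trace`` attributes.
    The returned likelihood is never below the input tree's likelihood.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    tree = _as_tree(tree).clone(depth=1)
    data = _SiteData(matrix)
    ll, trace = _optimize_branch_lengths(tree, data, model, tol, max_rounds)
    tree.log_likelihood = ll
    tree.optimization_trace = trace
    return tree


# ---------------------------------------------------------------------------
# starting trees


def _hamming_distance_matrix(matrix: EncodingMatrix) -> np.ndarray:
    bits = matrix.bits.astype(np.int16)
    diff = (bits[:, None, :] != bits[None, :, :]).mean(axis=2)
    return diff


def nj_start_tree(matrix: EncodingMatrix) -> PhyloTree:
    """Neighbor-joining on normalized per-pair Hamming distances of the rows."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(_hamming_distance_matrix(matrix), ids=matrix.taxa)
    newick = str(nj(dm))
    tree = read_newick(newick)
    _clamp_branch_lengths(tree)
    return unroot(tree)


def _random_stepwise_tree(matrix: EncodingMatrix, rng: np.random.Generator) -> PhyloTree:
    """Random-permutation stepwise addition (random attachment edge)."""
    order = [matrix.taxa[i] for i in rng.permutation(len(matrix.taxa))]
    tns = dendropy.TaxonNamespace(matrix.taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    for label in order[:3]:
        child = root.new_child(edge_length=0.1)
        child.taxon = tns.get_taxon(label)
    for label in order[3:]:
        edges = _edges(tree)
        edge = edges[rng.integers(len(edges))]
        parent, child = edge.tail_node, edge.head_node
        parent.remove_child(child)
        mid = parent.new_child(edge_length=0.1)
        mid.add_child(child)
        child.edge.length = 0.1
        leaf = mid.new_child(edge_length=0.1)
        leaf.taxon = tns.get_taxon(label)
    return tree


# ---------------------------------------------------------------------------
# NNI hill-climbing search


def _internal_edges(tree: PhyloTree) -> list:
    return [
        nd.edge
        for nd in tree.postorder_node_iter()
        if (not nd.is_leaf()) and nd is not tree.seed_node
    ]


def _nni_swap(a, b) -> None:
    """Exchange subtrees a and b between their (distinct) parents."""
    pa, pb = a.parent_node, b.parent_node
    pa.remove_child(a)
    pb.remove_child(b)
    pa.add_child(b)
    pb.add_child(a)


def _hill_climb(
    tree: PhyloTree, data: _SiteData, model: TwoStateModel, tol: float
) -> tuple[PhyloTree, float]:
    # Start every branch at the model's relaxation scale 1/lam.  Distance-based
    # starting lengths are typically far beyond saturation for large bias
    # ratios, and a fully saturated tree is a fixed point of per-branch
    # optimization (no signal passes a saturated neighborhood).
    for edge in _edges(tree):
        edge.length = 1.0 / model.rate
    ll, _ = _optimize_branch_lengths(tree, data, model, tol)
    improved = True
    while improved:
        improved = False
        for edge in _internal_edges(tree):
            v = edge.head_node
            u = edge.tail_node
            a = next(c for c in u.child_nodes() if c is not v)
            for b in list(v.child_nodes()):
                _nni_swap(a, b)
                saved = edge.length
                ll_new = _optimize_edge(tree, edge, data, model, -np.inf)
                if ll_new > ll + 1e-9:
                    ll, _ = _optimize_branch_lengths(tree, data, model, tol)
                    improved = True
                    break
                _nni_swap(b, a)  # revert (swap is an involution)
                edge.length = saved
            if improved:
                break
    return tree, ll


def search_tree(
    matrix: EncodingMatrix,
    model: TwoStateModel | None = None,
    seed: int = 0,
    n_starts: int = 1,
    tol: float = 1e-6,
) -> PhyloTree:
    """Best ML tree over ``n_starts`` NNI hill-climbs.

    The first start is neighbor-joining on Hamming distances; additional
    starts use random stepwise addition.  Deterministic given ``seed``.
    The returned tree carries a ``log_likelihood`` attribute.
    """
    model = model or TwoStateModel()
    n = len(matrix.taxa)
    if n < 2:
        raise ValueError("tree search requires at least 2 taxa")
    data = _SiteData(matrix)
    rng = np.random.default_rng(seed)
    if n <= 3:
        # unique unrooted topology: a single edge or a star
        tns = dendropy.TaxonNamespace(matrix.taxa)
        tree = dendropy.Tree(taxon_namespace=tns)
        for label in matrix.taxa:
            child = tree.seed_node.new_child(edge_length=0.1)
            child.taxon = tns.get_taxon(label)
        ll, _ = _optimize_branch_lengths(tree, data, model, tol)
        tree.log_likelihood = ll
        return tree
    best_tree, best_ll = None, -np.inf
    for s in range(int(n_starts)):
        start = nj_start_tree(matrix) if s == 0 else _random_stepwise_tree(matrix, rng)
        tree, ll = _hill_climb(start, data, model, tol)
        if ll > best_ll:
            best_tree, best_ll = tree, ll
    best_tree.log_likelihood = best_ll
    return best_tree


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: PhyloTree, all_taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalized to the side without the reference taxon."""
    ref = min(all_taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            splits.add(side)
    return splits


def _resample_columns(matrix: EncodingMatrix, rng: np.random.Generator) -> EncodingMatrix:
    idx = rng.integers(matrix.width, size=matrix.width)
    return EncodingMatrix(
        list(matrix.taxa),
        [matrix.columns[j] for j in idx],
        np.ascontiguousarray(matrix.bits[:, idx]),
        matrix.scheme,
    )


def bootstrap(
    matrix: EncodingMatrix,
    model: TwoStateModel | None = None,
    replicates: int = 100,
    seed: int = 0,
    n_starts: int = 1,
) -> PhyloTree:
    """Column-resampling bootstrap; supports annotate the best tree's internal nodes.

    Support values are percentages (0-100) of replicate trees containing
    each non-trivial bipartition of the best tree, stored as internal
    node labels.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    model = model or TwoStateModel()
    rng = np.random.default_rng(seed)
    best = search_tree(matrix, model, seed=seed, n_starts=n_starts)
    all_taxa = frozenset(matrix.taxa)
    counts: dict[frozenset[str], int] = {}
    for _ in range(replicates):
        rep_matrix = _resample_columns(matrix, rng)
        rep_seed = int(rng.integers(2**31))
        rep_tree = search_tree(rep_matrix, model, seed=rep_seed, n_starts=n_starts)
        for split in _bipartitions(rep_tree, all_taxa):
            counts[split] = counts.get(split, 0) + 1
    ref = min(all_taxa)
    for node in best.postorder_node_iter():
        if node.is_leaf() or node is best.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            support = 100.0 * counts.get(side, 0) / replicates
            node.label = f"{support:g}"
    return best


# ---------------------------------------------------------------------------
# model/results front end


class BinaryTreeML:
    """ML phylogeny model over a binary encoding matrix.

    Statsmodels-style front end: construct from data, call :meth:`fit`,
    inspect the returned :class:`TreeMLResults`.

    Examples
    --------
    >>> model = BinaryTreeML(matrix, bias_ratio=1000)   # doctest: +SKIP
    >>> res = model.fit(seed=1)                          # doctest: +SKIP
    >>> print(res.summary())                             # doctest: +SKIP
    """

    def __init__(self, matrix: EncodingMatrix, bias_ratio: float = 1000.0):
        self.matrix = matrix
        self.model = TwoStateModel(bias_ratio)

    @classmethod
    def from_genomes(
        cls,
        genomes: Sequence,
        scheme: str = "vlbe3",
        reduce_invariant_columns: bool = False,
        bias_ratio: float = 1000.0,
    ) -> "BinaryTreeML":
        from .adjacencies import build_profile
        from .encodings import encode
        from .genomes import gene_content

        profile = build_profile(genomes)
        content = {g.name: gene_content(g) for g in genomes}
        return cls(encode(profile, content, scheme, reduce_invariant_columns), bias_ratio)

    def loglike(self, tree: PhyloTree | str) -> float:
        return log_likelihood(tree, self.matrix, self.model)

    def fit(
        self,
        seed: int = 0,
        n_starts: int = 1,
        bootstrap_replicates: int = 0,
        tol: float = 1e-6,
    ) -> "TreeMLResults":
        if bootstrap_replicates:
            tree = bootstrap(
                self.matrix, self.model, replicates=bootstrap_replicates,
                seed=seed, n_starts=n_starts,
            )
        else:
            tree = search_tree(self.matrix, self.model, seed=seed, n_starts=n_starts, tol=tol)
        return TreeMLResults(self, tree, tree.log_likelihood, seed=seed, n_starts=n_starts)


class TreeMLResults:
    """Fitted tree, its log-likelihood and diagnostics."""

    def __init__(self, model: BinaryTreeML, tree: PhyloTree, loglik: float,
                 seed: int, n_starts: int):
        self.model = model
        self.tree = tree
        self.log_likelihood = float(loglik)
        self.seed = seed
        self.n_starts = n_starts

    @property
    def newick(self) -> str:
        return to_newick(self.tree)

    def branch_lengths(self):
        """DataFrame of branch lengths keyed by the child-side clade."""
        import pandas as pd

        rows = []
        for nd in self.tree.preorder_node_iter():
            if nd is self.tree.seed_node:
                continue
            clade = sorted(lf.taxon.label for lf in nd.leaf_iter())
            rows.append({"clade": ",".join(clade), "length": nd.edge.length})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        tree_len = sum(
            nd.edge.length or 0.0
            for nd in self.tree.preorder_node_iter()
            if nd is not self.tree.seed_node
        )
        lines = [
            "Binary-encoding ML phylogeny",
            "=" * 44,
            f"taxa:             {m.matrix.n_taxa}",
            f"sites:            {m.matrix.width} ({m.matrix.scheme})",
            f"bias ratio:       {m.model.bias_ratio:g}",
            f"stationary pi:    ({m.model.pi[0]:.6g}, {m.model.pi[1]:.6g})",
            f"log-likelihood:   {self.log_likelihood:.4f}",
            f"tree length:      {tree_len:.4f} expected flips/site",
            f"starts / seed:    {self.n_starts} / {self.seed}",
            "tree:",
            f"  {self.newick}",
        ]
        return "\n".join(lines)
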