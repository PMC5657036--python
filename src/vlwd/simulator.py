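"""Genome evolution simulator for benchmarking gene-order phylogenies.

A replicate draws a Yule (pure-birth) topology on ``n_leaves`` taxa,
assigns each branch an event budget

    L = r * n * (1/K) * exp(s),    s ~ Uniform(-1, 1),

where n is the root genome size, r in {1,2,3,4} scales the tree diameter
to d = r*n expected events, and K is the number of edges on the longest
leaf-to-leaf path — so the realized diameter fluctuates around d by the
per-branch factor exp(s).  Starting from the identity genome (one linear
chromosome 1..n), round(L) events are applied along each branch, drawn
from a configurable mix of inversions, transpositions, translocations,
fusions, fissions, insertions, deletions, segmental duplications and
whole-genome duplications.  Events that are inapplicable to the current
genome (e.g. a translocation with a single chromosome) are resampled.

Three named presets mirror the benchmark regimes: ``no_dup`` (pure
rearrangement + indels), ``segmental_dup`` (adds segmental duplications)
and ``segmental_wgd`` (adds whole-genome duplications on top).  Every
applied event is logged with its exact parameters, so any leaf genome
can be reproduced by replaying its root-to-leaf event-log prefix.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Any

import dendropy
import numpy as np

from .genomes import Chromosome, Genome

__all__ = [
    "EVENT_TYPES",
    "EVENT_PRESETS",
    "SimScenario",
    "SimResult",
    "SimulationError",
    "sample_tree",
    "assign_branch_lengths",
    "apply_event",
    "replay_events",
    "simulate",
]

EVENT_TYPES = (
    "inversion",
    "transposition",
    "translocation",
    "fusion",
    "fission",
    "insertion",
    "deletion",
    "segmental_duplication",
    "wgd",
)

# Benchmark regime presets.  The relative weights are this package's own
# calibration (config-exposed); the regimes themselves are pure
# rearrangement+indels, + segmental duplications, + whole-genome duplications.
EVENT_PRESETS: dict[str, dict[str, float]] = {
    "no_dup": {
        "inversion": 0.70, "translocation": 0.10, "fusion": 0.05,
        "fission": 0.05, "insertion": 0.04, "deletion": 0.06,
    },
    "segmental_dup": {
        "inversion": 0.55, "translocation": 0.10, "fusion": 0.05,
        "fission": 0.05, "insertion": 0.04, "deletion": 0.06,
        "segmental_duplication": 0.15,
    },
    "segmental_wgd": {
        "inversion": 0.545, "translocation": 0.10, "fusion": 0.05,
        "fission": 0.05, "insertion": 0.04, "deletion": 0.06,
        "segmental_duplication": 0.15, "wgd": 0.005,
    },
}


class SimulationError(RuntimeError):
    """A replicate became degenerate (e.g. deletions annihilated a genome)."""


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of one simulation replicate."""

    n_leaves: int = 10
    n_genes: int = 200
    rate: int = 1  # r: tree diameter = rate * n_genes expected events
    event_mix: dict[str, float] = field(
        default_factory=lambda: dict(EVENT_PRESETS["no_dup"])
    )
    seg_len_max: int = 10  # segment lengths ~ Uniform{1..seg_len_max}
    seed: int = 0
    n_root_chromosomes: int = 1
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("n_leaves must be >= 3")
        if self.rate not in (1, 2, 3, 4):
            raise ValueError("rate r must be in {1, 2, 3, 4}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        unknown = set(self.event_mix) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types in mix: {sorted(unknown)}")
        probs = np.array(list(self.event_mix.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("event probabilities must be non-negative and sum to 1")

    @classmethod
    def from_preset(cls, preset: str, **kwargs) -> "SimScenario":
        return cls(event_mix=dict(EVENT_PRESETS[preset]), **kwargs)

    def with_seed(self, seed: int) -> "SimScenario":
        return replace(self, seed=seed)


@dataclass
class SimResult:
    scenario: SimScenario
    tree: dendropy.Tree  # true tree; edge lengths = event budgets L (float)
    root_genome: Genome
    leaf_genomes: list[Genome]
    event_log: list[dict[str, Any]]  # one record per applied event


# ---------------------------------------------------------------------------
# model trees


def sample_tree(n_leaves: int, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) topology on leaves T1..Tn, deterministic under seed.

    The speciation intensity cancels out of the conditioned topology
    distribution, so only the split order is random.
    """
    if n_leaves < 3:
        raise ValueError("n_leaves must be >= 3")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = [tree.seed_node]
    while len(leaves) < n_leaves:
        node = leaves.pop(int(rng.integers(len(leaves))))
        leaves.append(node.new_child())
        leaves.append(node.new_child())
    # random label assignment: traversal order would constrain which
    # labelled topologies can occur
    order = rng.permutation(n_leaves)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.get_taxon(f"T{int(order[i]) + 1}")
    return tree


def _edge_diameter(tree: dendropy.Tree) -> int:
    """Number of edges on the longest leaf-to-leaf path."""
    best = 0
    down: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            down[id(node)] = 0
            continue
        depths = sorted((down[id(c)] + 1 for c in kids), reverse=True)
        down[id(node)] = depths[0]
        if len(depths) >= 2:
            best = max(best, depths[0] + depths[1])
        else:
            best = max(best, depths[0])
    return best


def assign_branch_lengths(
    tree: dendropy.Tree, r: int, n: int, seed: int = 0, variation: bool = True
) -> dendropy.Tree:
    """Set each edge length to L = r*n/K * exp(s), s ~ Uniform(-1,1).

    K is the edge count of the longest leaf-to-leaf path; with
    ``variation=False`` every edge gets exactly r*n/K.  Event budgets are
    ``round(L)``.
    """
    rng = np.random.default_rng(seed)
    K = _edge_diameter(tree)
    base = r * n / K
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = rng.uniform(-1.0, 1.0) if variation else 0.0
        node.edge.length = base * float(np.exp(s))
    return tree


def branch_event_budget(length: float) -> int:
    return max(0, int(round(length)))


# ---------------------------------------------------------------------------
# events
#
# Working representation during evolution: list of [list_of_signed_ints,
# circular_flag] pairs.  Each event is split into a parameter sampler (draws
# from the rng, returns None if inapplicable) and a pure applier (mutates the
# working genome given explicit parameters) so that logged parameters replay
# exactly.


def _total_genes(chroms) -> int:
    return sum(len(c[0]) for c in chroms)


def _pick_position(chroms, rng) -> tuple[int, int]:
    """(chromosome index, gene offset), uniform over gene copies."""
    total = _total_genes(chroms)
    p = int(rng.integers(total))
    for ci, (genes, _) in enumerate(chroms):
        if p < len(genes):
            return ci, p
        p -= len(genes)
    raise AssertionError("unreachable")


def _seg_len(rng, cap: int, seg_len_max: int) -> int:
    return int(rng.integers(1, min(seg_len_max, cap) + 1))


def _sample_inversion(chroms, rng, seg_len_max, next_label):
    ci, start = _pick_position(chroms, rng)
    genes = chroms[ci][0]
    length = _seg_len(rng, len(genes) - start, seg_len_max)
    return {"chrom": ci, "start": start, "len": length}


def _apply_inversion(chroms, p):
    genes = chroms[p["chrom"]][0]
    i, j = p["start"], p["start"] + p["len"]
    genes[i:j] = [-g for g in reversed(genes[i:j])]


def _sample_transposition(chroms, rng, seg_len_max, next_label):
    ci, start = _pick_position(chroms, rng)
    genes = chroms[ci][0]
    if len(genes) < 2:
        return None
    length = _seg_len(rng, len(genes) - start, seg_len_max)
    if length == len(genes):
        return None
    dest = int(rng.integers(len(genes) - length + 1))
    return {"chrom": ci, "start": start, "len": length, "dest": dest}


def _apply_transposition(chroms, p):
    genes = chroms[p["chrom"]][0]
    i, j = p["start"], p["start"] + p["len"]
    seg = genes[i:j]
    del genes[i:j]
    genes[p["dest"]:p["dest"]] = seg


def _sample_translocation(chroms, rng, seg_len_max, next_label):
    linear = [ci for ci, (_, circ) in enumerate(chroms) if not circ]
    if len(linear) < 2:
        return None
    a, b = rng.choice(len(linear), size=2, replace=False)
    ca, cb = linear[int(a)], linear[int(b)]
    i = int(rng.integers(0, len(chroms[ca][0]) + 1))
    j = int(rng.integers(0, len(chroms[cb][0]) + 1))
    return {"chrom_a": ca, "chrom_b": cb, "cut_a": i, "cut_b": j}


def _apply_translocation(chroms, p):
    ga, gb = chroms[p["chrom_a"]][0], chroms[p["chrom_b"]][0]
    i, j = p["cut_a"], p["cut_b"]
    new_a, new_b = ga[:i] + gb[j:], gb[:j] + ga[i:]
    chroms[p["chrom_a"]][0] = new_a
    chroms[p["chrom_b"]][0] = new_b
    _drop_empty(chroms)


def _sample_fusion(chroms, rng, seg_len_max, next_label):
    if len(chroms) < 2:
        return None
    a, b = rng.choice(len(chroms), size=2, replace=False)
    a, b = int(a), int(b)
    rot_a = int(rng.integers(len(chroms[a][0]))) if chroms[a][1] else 0
    rot_b = int(rng.integers(len(chroms[b][0]))) if chroms[b][1] else 0
    flip_b = bool(rng.integers(2))
    return {"chrom_a": a, "chrom_b": b, "rot_a": rot_a, "rot_b": rot_b, "flip_b": flip_b}


def _apply_fusion(chroms, p):
    a, b = p["chrom_a"], p["chrom_b"]
    ga = chroms[a][0][p["rot_a"]:] + chroms[a][0][: p["rot_a"]]  # open circular at rot
    gb = chroms[b][0][p["rot_b"]:] + chroms[b][0][: p["rot_b"]]
    if p["flip_b"]:
        gb = [-g for g in reversed(gb)]
    fused = [ga + gb, False]
    for ci in sorted((a, b), reverse=True):
        del chroms[ci]
    chroms.append(fused)


def _sample_fission(chroms, rng, seg_len_max, next_label):
    eligible = [ci for ci, (genes, _) in enumerate(chroms) if len(genes) >= 2]
    if not eligible:
        return None
    ci = int(eligible[int(rng.integers(len(eligible)))])
    cut = int(rng.integers(1, len(chroms[ci][0])))
    return {"chrom": ci, "cut": cut}


def _apply_fission(chroms, p):
    genes, circ = chroms[p["chrom"]]
    if circ:
        # cutting a circle yields one linear chromosome
        chroms[p["chrom"]] = [genes[p["cut"]:] + genes[: p["cut"]], False]
    else:
        chroms[p["chrom"]] = [genes[: p["cut"]], False]
        chroms.append([genes[p["cut"]:], False])


def _sample_insertion(chroms, rng, seg_len_max, next_label):
    ci, pos = _pick_position(chroms, rng)
    length = _seg_len(rng, seg_len_max, seg_len_max)
    labels = list(range(next_label[0], next_label[0] + length))
    signs = [int(s) for s in rng.choice([-1, 1], size=length)]
    next_label[0] += length
    return {"chrom": ci, "pos": pos, "genes": [l * s for l, s in zip(labels, signs)]}


def _apply_insertion(chroms, p):
    genes = chroms[p["chrom"]][0]
    genes[p["pos"]:p["pos"]] = list(p["genes"])


def _sample_deletion(chroms, rng, seg_len_max, next_label):
    ci, start = _pick_position(chroms, rng)
    genes = chroms[ci][0]
    length = _seg_len(rng, len(genes) - start, seg_len_max)
    return {"chrom": ci, "start": start, "len": length}


def _apply_deletion(chroms, p):
    genes = chroms[p["chrom"]][0]
    del genes[p["start"]:p["start"] + p["len"]]
    _drop_empty(chroms)
    if not chroms:
        raise SimulationError("genome annihilated by deletion (all genes lost)")


def _sample_segmental_duplication(chroms, rng, seg_len_max, next_label):
    ci, start = _pick_position(chroms, rng)
    genes = chroms[ci][0]
    length = _seg_len(rng, len(genes) - start, seg_len_max)
    di, dpos = _pick_position(chroms, rng)
    return {"chrom": ci, "start": start, "len": length, "dest_chrom": di, "dest_pos": dpos}


def _apply_segmental_duplication(chroms, p):
    seg = list(chroms[p["chrom"]][0][p["start"]:p["start"] + p["len"]])
    dest = chroms[p["dest_chrom"]][0]
    dest[p["dest_pos"]:p["dest_pos"]] = seg


def _sample_wgd(chroms, rng, seg_len_max, next_label):
    return {}


def _apply_wgd(chroms, p):
    chroms.extend([list(genes), circ] for genes, circ in list(chroms))


def _drop_empty(chroms) -> None:
    chroms[:] = [c for c in chroms if c[0]]


_SAMPLERS = {
    "inversion": _sample_inversion,
    "transposition": _sample_transposition,
    "translocation": _sample_translocation,
    "fusion": _sample_fusion,
    "fission": _sample_fission,
    "insertion": _sample_insertion,
    "deletion": _sample_deletion,
    "segmental_duplication": _sample_segmental_duplication,
    "wgd": _sample_wgd,
}
_APPLIERS = {
    "inversion": _apply_inversion,
    "transposition": _apply_transposition,
    "translocation": _apply_translocation,
    "fusion": _apply_fusion,
    "fission": _apply_fission,
    "insertion": _apply_insertion,
    "deletion": _apply_deletion,
    "segmental_duplication": _apply_segmental_duplication,
    "wgd": _apply_wgd,
}


def _to_working(genome: Genome):
    return [[list(c.genes), c.circular] for c in genome.chromosomes]


def _from_working(chroms, name: str) -> Genome:
    return Genome(name, tuple(Chromosome(tuple(g), circ) for g, circ in chroms))


def apply_event(
    genome: Genome,
    event_type: str,
    rng: np.random.Generator,
    seg_len_max: int = 10,
    next_label: list[int] | None = None,
) -> Genome:
    """Apply one event of the given type; inapplicable events raise.

    ``next_label`` is a 1-element mutable list holding the next fresh gene
    label for insertions (defaults to one past the current maximum).
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type '{event_type}'")
    chroms = _to_working(genome)
    if next_label is None:
        next_label = [max(abs(g) for c, _ in chroms for g in c) + 1]
    params = _SAMPLERS[event_type](chroms, rng, seg_len_max, next_label)
    if params is None:
        raise SimulationError(f"event '{event_type}' not applicable to this genome")
    _APPLIERS[event_type](chroms, params)
    return _from_working(chroms, genome.name)


def replay_events(root: Genome, events, name: str | None = None) -> Genome:
    """Re-apply logged events (type + parameters) to the root genome."""
    chroms = _to_working(root)
    for ev in events:
        _APPLIERS[ev["event"]](chroms, ev["params"])
    return _from_working(chroms, name or root.name)


# ---------------------------------------------------------------------------
# full replicate


def _root_genome(scenario: SimScenario) -> Genome:
    n, k = scenario.n_genes, scenario.n_root_chromosomes
    labels = list(range(1, n + 1))
    bounds = [round(i * n / k) for i in range(k + 1)]
    chroms = tuple(
        Chromosome(tuple(labels[bounds[i]:bounds[i + 1]]), False)
        for i in range(k)
        if bounds[i + 1] > bounds[i]
    )
    return Genome("root", chroms)


def simulate(scenario: SimScenario) -> SimResult:
    """Run one replicate: tree, branch budgets, event draws, leaf genomes.

    Fully reproducible from ``scenario.seed``; a deletion that empties a
    genome aborts the replicate with :class:`SimulationError`.
    """
    rng = np.random.default_rng(scenario.seed)
    tree = sample_tree(scenario.n_leaves, seed=int(rng.integers(2**31)))
    assign_branch_lengths(
        tree, scenario.rate, scenario.n_genes, seed=int(rng.integers(2**31))
    )
    types = list(scenario.event_mix.keys())
    probs = np.array([scenario.event_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()

    root = _root_genome(scenario)
    next_label = [scenario.n_genes + 1]
    event_log: list[dict[str, Any]] = []
    genome_at: dict[int, list] = {id(tree.seed_node): _to_working(root)}
    leaf_genomes: list[Genome] = []

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        chroms = copy.deepcopy(genome_at[id(node.parent_node)])
        budget = branch_event_budget(node.edge.length)
        branch_id = _branch_label(node)
        for step in range(budget):
            for _attempt in range(1000):
                etype = types[int(rng.choice(len(types), p=probs))]
                params = _SAMPLERS[etype](chroms, rng, scenario.seg_len_max, next_label)
                if params is not None:
                    break
            else:
                raise SimulationError("no applicable event found after 1000 draws")
            _APPLIERS[etype](chroms, params)
            event_log.append(
                {"branch": branch_id, "step": step, "event": etype, "params": params}
            )
        genome_at[id(node)] = chroms
        if node.is_leaf():
            leaf_genomes.append(_from_working(chroms, node.taxon.label))
    # free internal states; keep only what the result needs
    return SimResult(scenario, tree, root, leaf_genomes, event_log)


def _branch_label(node) -> str:
    """Stable branch identifier: the sorted leaf set below the branch."""
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def events_for_leaf(result: SimResult, leaf_label: str) -> list[dict[str, Any]]:
    """The root-to-leaf prefix of the event log, in applied order."""
    tree = result.tree
    leaf = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == leaf_label
    )
    path_ids = []
    node = leaf
    while node is not tree.seed_node:
        path_ids.append(_branch_label(node))
        node = node.parent_node
    path_ids = set(path_ids)
    # preorder logging guarantees ancestors precede descendants in the log
    return [ev for ev in result.event_log if ev["branch"] in path_ids]
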