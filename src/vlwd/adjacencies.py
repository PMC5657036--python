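"""Adjacency/telomere multisets of genomes and the cross-genome profile.

An adjacency is the unordered pairing of two gene extremities that are
consecutive on a chromosome.  Reading a chromosome in the opposite
direction produces the reverse-complement pair, so ``(a, b)`` and
``(-b, -a)`` denote the same adjacency; the canonical key is the
lexicographically smaller of the two ordered integer pairs.  A telomere
is the free extremity of a gene at an end of a linear chromosome,
recorded as a signed label (positive = head, negative = tail).

The :class:`AdjacencyProfile` collects, over a set of genomes, every key
that occurs in at least one genome, in deterministic first-appearance
order, together with the per-genome copy counts and the per-key maximum
count ``t`` that drives the variable-length encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genomes import Chromosome, Genome

__all__ = ["AdjacencyKey", "AdjacencyProfile", "enumerate_adjacencies", "build_profile"]


@dataclass(frozen=True)
class AdjacencyKey:
    """Canonical identity of an adjacency or telomere.

    ``left``/``right`` hold the canonical orientation; ``display`` the
    orientation in which the key was first encountered (excluded from
    equality/hashing).  For telomeres ``right`` is None and ``left`` is
    the signed free extremity.
    """

    kind: str  # "adjacency" | "telomere"
    left: int
    right: int | None = None
    display: tuple[int, ...] = field(default=(), compare=False, repr=False)

    @classmethod
    def adjacency(cls, a: int, b: int) -> "AdjacencyKey":
        canon = min((a, b), (-b, -a))
        return cls("adjacency", canon[0], canon[1], display=(a, b))

    @classmethod
    def telomere(cls, extremity: int) -> "AdjacencyKey":
        return cls("telomere", extremity, None, display=(extremity,))

    def display_str(self) -> str:
        if self.kind == "telomere":
            g = self.display[0]
            return f"({abs(g)}{'h' if g > 0 else 't'})"
        return f"({self.display[0]},{self.display[1]})"


def _chromosome_keys(chrom: Chromosome) -> list[AdjacencyKey]:
    g = chrom.genes
    if chrom.circular:
        # closing adjacency (last, first) first, then the scan-order pairs
        keys = [AdjacencyKey.adjacency(g[-1], g[0])]
        keys += [AdjacencyKey.adjacency(g[i], g[i + 1]) for i in range(len(g) - 1)]
        return keys
    # linear: left telomere, internal adjacencies, right telomere.
    # Signed extremity convention: +x = head of x, -x = tail of x.  The left
    # end of a chromosome starting with signed gene x exposes -x, the right
    # end after last gene y exposes +y.
    keys = [AdjacencyKey.telomere(-g[0])]
    keys += [AdjacencyKey.adjacency(g[i], g[i + 1]) for i in range(len(g) - 1)]
    keys.append(AdjacencyKey.telomere(g[-1]))
    return keys


def enumerate_adjacencies(genome: Genome) -> list[AdjacencyKey]:
    """The ordered multiset of adjacency/telomere keys of a genome.

    A circular chromosome of length L contributes L adjacencies, with the
    closing adjacency (last gene, first gene) emitted first; a linear
    chromosome of length L contributes its left telomere, L-1 internal
    adjacencies in scan order, and its right telomere.  Multiplicities
    are preserved (the result is a list, not a set).
    """
    keys: list[AdjacencyKey] = []
    for chrom in genome.chromosomes:
        keys.extend(_chromosome_keys(chrom))
    return keys


@dataclass
class AdjacencyProfile:
    """Taxa-by-key copy-count table over every key present in >= 1 genome."""

    genome_names: list[str]
    keys: list[AdjacencyKey]
    counts: np.ndarray  # shape (n_genomes, n_keys), non-negative ints

    @property
    def max_counts(self) -> np.ndarray:
        """Per-key maximum copy number t across genomes (t >= 1 by construction)."""
        return self.counts.max(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tkind\t" + "\t".join(self.genome_names) + "\tt\n")
            t = self.max_counts
            for j, key in enumerate(self.keys):
                row = "\t".join(str(int(c)) for c in self.counts[:, j])
                fh.write(f"{key.display_str()}\t{key.kind}\t{row}\t{int(t[j])}\n")


def build_profile(genomes: Sequence[Genome] | Iterable[Genome]) -> AdjacencyProfile:
    """Scan genomes in input order, collecting keys in first-appearance order."""
    genomes = list(genomes)
    if not genomes:
        raise ValueError("build_profile requires at least one genome")
    index: dict[AdjacencyKey, int] = {}
    keys: list[AdjacencyKey] = []
    per_genome: list[dict[int, int]] = []
    for genome in genomes:
        row: dict[int, int] = {}
        for key in enumerate_adjacencies(genome):
            j = index.get(key)
            if j is None:
                j = len(keys)
                index[key] = j
                keys.append(key)  # keeps first-encountered display orientation
            row[j] = row.get(j, 0) + 1
        per_genome.append(row)
    counts = np.zeros((len(genomes), len(keys)), dtype=np.int64)
    for i, row in enumerate(per_genome):
        for j, c in row.items():
            counts[i, j] = c
    return AdjacencyProfile([g.name for g in genomes], keys, counts)
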