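"""Multichromosomal signed gene orders and GRIMM-style file I/O.

A genome is an ordered list of chromosomes; a chromosome is an ordered
sequence of signed integer gene labels (``+g``: tail-to-head orientation,
``-g``: head-to-tail) plus a topology flag (linear or circular).  Gene
labels may repeat within and across chromosomes — duplications are
first-class citizens of this data model.

The file dialect is GRIMM-like::

    # comment
    >genome_name
    1 -2 3 $       # linear chromosome, '$' terminator
    4 -5 @         # circular chromosome, '@' terminator

Chromosome tokens may span several lines; a chromosome ends at its
terminator.  Lines are LF/CRLF tolerant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "Gene",
    "Chromosome",
    "Genome",
    "GenomeParseError",
    "read_genomes",
    "write_genomes",
    "gene_content",
]


class Gene(NamedTuple):
    """An oriented gene: positive ``label`` plus ``sign`` (+1 tail→head, -1 head→tail)."""

    label: int
    sign: int

    @classmethod
    def from_signed(cls, value: int) -> "Gene":
        if value == 0:
            raise ValueError("gene labels are nonzero signed integers")
        return cls(abs(value), 1 if value > 0 else -1)

    @property
    def signed(self) -> int:
        return self.label * self.sign


@dataclass(frozen=True)
class Chromosome:
    """An ordered run of signed gene labels with linear or circular topology."""

    genes: tuple[int, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError("chromosome must contain at least one gene")
        for g in self.genes:
            if g == 0:
                raise ValueError("gene label 0 is not allowed (labels are >= 1, sign carries orientation)")

    def __len__(self) -> int:
        return len(self.genes)

    def reversed(self) -> "Chromosome":
        """The same chromosome read in the opposite direction."""
        return Chromosome(tuple(-g for g in reversed(self.genes)), self.circular)


@dataclass(frozen=True)
class Genome:
    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("genome name must be non-empty")
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")

    @property
    def n_genes(self) -> int:
        """Total gene copies across all chromosomes."""
        return sum(len(c) for c in self.chromosomes)


class GenomeParseError(ValueError):
    """Malformed gene-order file; message carries the 1-based line number."""


def gene_content(genome: Genome) -> Counter:
    """Copy count per gene label, ignoring orientation.

    The counts sum to ``genome.n_genes`` and are invariant under reversing
    or reordering chromosomes.
    """
    counts: Counter = Counter()
    for chrom in genome.chromosomes:
        for g in chrom.genes:
            counts[abs(g)] += 1
    return counts


def read_genomes(
    path: str | Path,
    name_map: Mapping[str, int] | None = None,
) -> list[Genome]:
    """Parse a GRIMM-like gene-order file.

    Parameters
    ----------
    path
        Text file with ``>name`` headers and ``$``/``@``-terminated
        chromosome lines of signed integers.
    name_map
        Optional mapping from string gene tokens to positive integer
        labels, applied before validation.  Lets files carry gene names
        instead of the integer labels the encodings require; a leading
        ``-`` on a token still flips orientation.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    genomes: list[Genome] = []
    seen_names: set[str] = set()
    current_name: str | None = None
    current_header_line = 0
    chroms: list[Chromosome] = []
    pending: list[int] = []  # tokens of a chromosome awaiting its terminator

    def err(lineno: int, msg: str) -> GenomeParseError:
        return GenomeParseError(f"{path.name}:{lineno}: {msg}")

    def flush_genome(lineno: int) -> None:
        nonlocal current_name, chroms, pending
        if current_name is None:
            return
        if pending:
            raise err(lineno, f"chromosome of genome '{current_name}' missing '$' or '@' terminator")
        if not chroms:
            raise err(current_header_line, f"genome '{current_name}' has no chromosomes")
        genomes.append(Genome(current_name, tuple(chroms)))
        current_name, chroms, pending = None, [], []

    def parse_token(tok: str, lineno: int) -> int:
        sign = 1
        body = tok
        if body.startswith("-"):
            sign, body = -1, body[1:]
        elif body.startswith("+"):
            body = body[1:]
        if name_map is not None and body in name_map:
            label = name_map[body]
        else:
            try:
                label = int(body)
            except ValueError:
                raise err(lineno, f"unrecognized gene token '{tok}'") from None
        if label < 1:
            raise err(lineno, f"gene label must be >= 1, got '{tok}'")
        return sign * label

    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush_genome(lineno)
            name = line[1:].strip()
            if not name:
                raise err(lineno, "malformed header: empty genome name")
            if name in seen_names:
                raise err(lineno, f"duplicate genome name '{name}'")
            seen_names.add(name)
            current_name = name
            current_header_line = lineno
            continue
        if current_name is None:
            raise err(lineno, "chromosome data before any '>' header")
        for tok in line.split():
            if tok in ("$", "@"):
                if not pending:
                    raise err(lineno, "empty chromosome before terminator")
                chroms.append(Chromosome(tuple(pending), circular=(tok == "@")))
                pending = []
            else:
                pending.append(parse_token(tok, lineno))

    flush_genome(len(lines) + 1)
    if not genomes:
        raise GenomeParseError(f"{path.name}: no genome records found")
    return genomes


def write_genomes(genomes: Sequence[Genome] | Iterable[Genome], path: str | Path) -> None:
    """Write genomes in the GRIMM-like dialect; re-readable by :func:`read_genomes`."""
    genomes = list(genomes)
    if not genomes:
        raise ValueError("cannot write an empty genome sequence")
    names = [g.name for g in genomes]
    if len(set(names)) != len(names):
        raise ValueError("genome names must be unique within a dataset")
    out = []
    for g in genomes:
        out.append(f">{g.name}")
        for chrom in g.chromosomes:
            term = "@" if chrom.circular else "$"
            out.append(" ".join(str(x) for x in chrom.genes) + f" {term}")
    Path(path).write_text("\n".join(out) + "\n")
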