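"""Binary character matrices from adjacency profiles and gene content.

Four schemes are supported:

``vlbe1``
    Per adjacency/telomere key with maximum copy number t: a block of t
    columns per taxon written as (t - k) zeros then k ones, where k is
    that taxon's copy count.
``vlbe2``
    The vlbe1 block followed by one presence/absence column per distinct
    gene, genes in ascending label order.
``vlbe3``
    The vlbe1 block followed by a per-gene multiplicity block encoded
    exactly like the adjacencies ((t_g - k_g) zeros then k_g ones).
``mlwd``
    The presence/absence baseline: one column per adjacency key and one
    per gene (1 = present, 0 = absent).

Invariant-column reduction (dropping columns where every taxon has the
same state) is off by default and enabled in the benchmark pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .adjacencies import AdjacencyKey, AdjacencyProfile

__all__ = ["SCHEMES", "ColumnInfo", "EncodingMatrix", "encode", "write_alignment", "read_alignment"]

SCHEMES = ("vlbe1", "vlbe2", "vlbe3", "mlwd")


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one binary column: its source key/gene and multiplicity slot."""

    source_kind: str  # "adjacency" | "telomere" | "gene"
    source: str  # display string of the key, or the gene label
    slot: int  # 0-based index within the multiplicity block


@dataclass
class EncodingMatrix:
    taxa: list[str]
    columns: list[ColumnInfo]
    bits: np.ndarray  # shape (n_taxa, n_cols), dtype uint8, values {0,1}
    scheme: str

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def width(self) -> int:
        return self.bits.shape[1]

    def row_strings(self) -> list[str]:
        return ["".join("1" if b else "0" for b in row) for row in self.bits]

    def columns_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tsource_kind\tsource\tslot\n")
            for j, col in enumerate(self.columns):
                fh.write(f"{j}\t{col.source_kind}\t{col.source}\t{col.slot}\n")


def _multiplicity_block(counts: np.ndarray, t: int) -> np.ndarray:
    """(t - k) zeros then k ones per taxon, for one key with max count t."""
    block = np.zeros((counts.shape[0], t), dtype=np.uint8)
    for i, k in enumerate(counts):
        if k:
            block[i, t - int(k):] = 1
    return block


def _gene_count_table(
    taxa: Sequence[str], content: Mapping[str, Mapping[int, int]]
) -> tuple[list[int], np.ndarray]:
    labels = sorted({g for name in taxa for g in content[name]})
    table = np.zeros((len(taxa), len(labels)), dtype=np.int64)
    for i, name in enumerate(taxa):
        for j, g in enumerate(labels):
            table[i, j] = content[name].get(g, 0)
    return labels, table


def encode(
    profile: AdjacencyProfile,
    content: Mapping[str, Mapping[int, int]] | None = None,
    scheme: str = "vlbe3",
    reduce_invariant_columns: bool = False,
) -> EncodingMatrix:
    """Build the binary character matrix for one encoding scheme.

    Parameters
    ----------
    profile
        Adjacency profile of the genome set (column universe + counts).
    content
        Per-genome gene copy counts keyed by genome name (as returned by
        :func:`vlwd.genomes.gene_content`).  Required for vlbe2, vlbe3
        and mlwd; ignored by vlbe1.
    scheme
        One of ``vlbe1``, ``vlbe2``, ``vlbe3``, ``mlwd``.
    reduce_invariant_columns
        Drop columns constant across all taxa.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown encoding scheme '{scheme}' (expected one of {SCHEMES})")
    if not profile.keys:
        raise ValueError("empty adjacency profile")
    if scheme != "vlbe1" and content is None:
        raise ValueError(f"scheme '{scheme}' requires gene content")

    taxa = list(profile.genome_names)
    blocks: list[np.ndarray] = []
    columns: list[ColumnInfo] = []
    t_vec = profile.max_counts

    if scheme == "mlwd":
        blocks.append((profile.counts > 0).astype(np.uint8))
        columns += [ColumnInfo(k.kind, k.display_str(), 0) for k in profile.keys]
    else:
        for j, key in enumerate(profile.keys):
            t = int(t_vec[j])
            blocks.append(_multiplicity_block(profile.counts[:, j], t))
            columns += [ColumnInfo(key.kind, key.display_str(), s) for s in range(t)]

    if scheme in ("vlbe2", "mlwd"):
        labels, table = _gene_count_table(taxa, content)
        blocks.append((table > 0).astype(np.uint8))
        columns += [ColumnInfo("gene", str(g), 0) for g in labels]
    elif scheme == "vlbe3":
        labels, table = _gene_count_table(taxa, content)
        tg = table.max(axis=0)
        for j, g in enumerate(labels):
            t = int(tg[j])
            blocks.append(_multiplicity_block(table[:, j], t))
            columns += [ColumnInfo("gene", str(g), s) for s in range(t)]

    bits = np.concatenate(blocks, axis=1) if blocks else np.zeros((len(taxa), 0), np.uint8)
    if reduce_invariant_columns:
        keep = (bits != bits[0]).any(axis=0)
        bits = bits[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]
    return EncodingMatrix(taxa, columns, np.ascontiguousarray(bits, dtype=np.uint8), scheme)


def _sanitize(name: str) -> str:
    safe = "".join(ch if ch.isalnum() or ch in "._-" else "_" for ch in name)
    return safe or "_"


def write_alignment(
    matrix: EncodingMatrix, path: str | Path, fmt: str = "phylip"
) -> dict[str, str]:
    """Write the matrix as relaxed PHYLIP or FASTA.

    Taxon names are sanitized to external-tool-safe tokens; the returned
    dict maps sanitized -> original names.  If sanitization changed any
    name a ``<path>.names.tsv`` sidecar records the mapping.  Raises on
    a name collision after sanitization.
    """
    if matrix.n_taxa == 0 or matrix.width == 0:
        raise ValueError("cannot write an empty alignment")
    safe = [_sanitize(t) for t in matrix.taxa]
    if len(set(safe)) != len(safe):
        raise ValueError("taxon name collision after sanitization")
    rows = matrix.row_strings()
    path = Path(path)
    if fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{matrix.n_taxa} {matrix.width}\n")
            for name, row in zip(safe, rows):
                fh.write(f"{name}  {row}\n")
    elif fmt == "fasta":
        records = [
            SeqRecord(Seq(row), id=name, description="") for name, row in zip(safe, rows)
        ]
        SeqIO.write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown alignment format '{fmt}' (expected 'phylip' or 'fasta')")
    name_map = dict(zip(safe, matrix.taxa))
    if any(s != o for s, o in name_map.items()):
        with open(str(path) + ".names.tsv", "w") as fh:
            fh.write("sanitized\toriginal\n")
            for s, o in name_map.items():
                fh.write(f"{s}\t{o}\n")
    return name_map


def read_alignment(path: str | Path, fmt: str | None = None) -> EncodingMatrix:
    """Read a binary alignment (relaxed PHYLIP or FASTA) back into a matrix.

    Column provenance is not recoverable from alignment files; columns
    are tagged as opaque ``site`` descriptors.
    """
    path = Path(path)
    if fmt is None:
        first = path.read_text().lstrip()[:1]
        fmt = "fasta" if first == ">" else "phylip"
    taxa: list[str] = []
    rows: list[str] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq))
    elif fmt == "phylip":
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        try:
            ntax, ncols = map(int, lines[0].split())
        except (ValueError, IndexError):
            raise ValueError(f"{path.name}: malformed PHYLIP header") from None
        if len(lines) - 1 != ntax:
            raise ValueError(f"{path.name}: expected {ntax} sequence lines (interleaved PHYLIP unsupported)")
        for ln in lines[1:]:
            name, seq = ln.split(None, 1)
            seq = seq.replace(" ", "")
            if len(seq) != ncols:
                raise ValueError(f"{path.name}: sequence for '{name}' has {len(seq)} != {ncols} sites")
            taxa.append(name)
            rows.append(seq)
    else:
        raise ValueError(f"unknown alignment format '{fmt}'")
    if not rows:
        raise ValueError(f"{path.name}: no sequences found")
    if any(set(r) - {"0", "1"} for r in rows):
        raise ValueError(f"{path.name}: alignment contains non-binary characters")
    if len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path.name}: unequal sequence lengths")
    bits = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
    columns = [ColumnInfo("site", str(j), 0) for j in range(bits.shape[1])]
    return EncodingMatrix(taxa, columns, bits, scheme="unknown")
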