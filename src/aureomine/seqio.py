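"""Readers and writers for the formats the mining pipeline touches.

FASTA holds peptides and database proteins, a nine-column GFF3 subset
(CDS rows only) holds gene neighborhoods, a headered TSV holds taxonomy,
and Newick holds peptide trees.  Every parser validates strictly and
raises :class:`SeqIOError` on malformed input rather than repairing it:
the downstream property calculations are poisoned by silently accepted
ambiguity, so rejection is the only safe default.

Coordinates are 1-based inclusive throughout, the GFF3 convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from skbio import TreeNode

#: The 20 canonical amino acids; X is additionally tolerated as "unknown".
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
VALID_AA = set(CANONICAL_AA) | {"X"}

#: Phyla accepted in taxonomy tables when the phylum field is non-empty.
KNOWN_PHYLA = frozenset(
    {
        "Actinomycetota",
        "Bacillota",
        "Bacteroidota",
        "Pseudomonadota",
        "Cyanobacteriota",
    }
)


class SeqIOError(ValueError):
    """Raised for any malformed record in any supported format."""


@dataclass(frozen=True)
class SeqRecord:
    """A named amino-acid sequence.

    ``sequence`` is upper case over the 20 canonical letters plus X and
    never contains whitespace or gaps.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record with empty id")
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_AA:
                raise SeqIOError(
                    f"record {self.id!r}: invalid amino-acid character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """One CDS on a contig; start/end are 1-based inclusive."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise SeqIOError(f"feature {self.gene_id!r}: start {self.start} < 1")
        if self.end < self.start:
            raise SeqIOError(
                f"feature {self.gene_id!r}: end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-"}:
            raise SeqIOError(
                f"feature {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TaxonomyRow:
    sequence_or_assembly_id: str
    phylum: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence_or_assembly_id:
            raise SeqIOError("taxonomy row with empty id")
        if self.phylum and self.phylum not in KNOWN_PHYLA:
            raise SeqIOError(f"unknown phylum {self.phylum!r}")


# ---------------------------------------------------------------------------
# FASTA


def _clean_sequence(rec_id: str, raw: str) -> str:
    seq = raw.upper()
    # stop characters are stripped from the end only; an internal '*' is an error
    while seq.endswith("*"):
        seq = seq[:-1]
    return seq


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into validated records, preserving order.

    Duplicate ids, empty sequences and non-amino-acid characters
    (anything outside the 20 canonical letters plus X) are hard errors.
    Trailing ``*`` stop characters are stripped; case is folded to upper.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for bio_rec in _BioSeqIO.parse(handle, "fasta"):
            if bio_rec.id in seen:
                raise SeqIOError(f"{path}: duplicate sequence id {bio_rec.id!r}")
            seen.add(bio_rec.id)
            desc = bio_rec.description
            if desc.startswith(bio_rec.id):
                desc = desc[len(bio_rec.id) :].strip()
            seq = _clean_sequence(bio_rec.id, str(bio_rec.seq))
            if not seq:
                raise SeqIOError(f"{path}: record {bio_rec.id!r} has empty sequence")
            records.append(SeqRecord(id=bio_rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with 60-column wrapped sequence lines."""
    with open(path, "w") as handle:
        handle.write(format_fasta(records, width=width))


def format_fasta(records: Sequence[SeqRecord], width: int = 60) -> str:
    out = io.StringIO()
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        out.write(header + "\n")
        for i in range(0, len(rec.sequence), width):
            out.write(rec.sequence[i : i + width] + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Aligned FASTA (rows may contain '-')


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA as ``(id, row)`` pairs; rows may contain gaps."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for bio_rec in _BioSeqIO.parse(handle, "fasta"):
            if bio_rec.id in seen:
                raise SeqIOError(f"{path}: duplicate sequence id {bio_rec.id!r}")
            seen.add(bio_rec.id)
            row = str(bio_rec.seq).upper().replace(".", "-")
            bad = set(row) - VALID_AA - {"-"}
            if bad:
                raise SeqIOError(f"{path}: invalid characters {bad!r} in {bio_rec.id!r}")
            rows.append((bio_rec.id, row))
    lengths = {len(r) for _, r in rows}
    if len(lengths) > 1:
        raise SeqIOError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    return rows


def write_alignment_fasta(
    rows: Sequence[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as handle:
        for rec_id, row in rows:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(row), width):
                handle.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 subset (CDS rows only)


def read_features(path: str | Path) -> list[GeneFeature]:
    """Read the nine-column GFF3 subset, keeping CDS rows only.

    ``product`` comes from the ``product=`` attribute (empty if absent),
    ``gene_id`` from ``ID=``.  Unknown strand symbols and end < start are
    hard errors; non-CDS rows are skipped.
    """
    path = Path(path)
    features: list[GeneFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SeqIOError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            attr_map: dict[str, str] = {}
            for chunk in attrs.split(";"):
                if "=" in chunk:
                    key, _, value = chunk.partition("=")
                    attr_map[key.strip()] = value.strip()
            features.append(
                GeneFeature(
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    gene_id=attr_map.get("ID", f"{contig}:{start}-{end}"),
                    product=attr_map.get("product", ""),
                )
            )
    return features


def write_features(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as the GFF3 subset read by :func:`read_features`."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            handle.write(
                "\t".join(
                    [f.contig, "aureomine", "CDS", str(f.start), str(f.end), ".",
                     f.strand, "0", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Taxonomy TSV

_TAX_HEADER = ["id", "phylum", "genus", "species"]


def read_taxonomy(path: str | Path) -> list[TaxonomyRow]:
    path = Path(path)
    rows: list[TaxonomyRow] = []
    seen: set[str] = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _TAX_HEADER:
            raise SeqIOError(f"{path}: expected header {_TAX_HEADER}, got {header}")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise SeqIOError(f"{path}:{lineno}: expected 4 columns")
            if cols[0] in seen:
                raise SeqIOError(f"{path}:{lineno}: duplicate id {cols[0]!r}")
            seen.add(cols[0])
            rows.append(TaxonomyRow(*cols))
    return rows


def write_taxonomy(rows: Iterable[TaxonomyRow], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_TAX_HEADER) + "\n")
        for row in rows:
            handle.write(
                "\t".join(
                    [row.sequence_or_assembly_id, row.phylum, row.genus, row.species]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick (written for the phylogeny module)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
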