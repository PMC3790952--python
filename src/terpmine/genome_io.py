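"""Sequence and feature I/O, and the coordinate contract for the whole pipeline.

All in-memory coordinates are 0-based half-open intervals on the forward
strand.  The only place 1-based inclusive coordinates appear is inside a
serialized GFF3 file; the conversion happens here and nowhere else.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "ContigRecord",
    "FeatureRow",
    "read_fasta",
    "write_fasta",
    "read_protein_fasta",
    "read_genbank",
    "read_gff3",
    "write_gff3",
]

_DNA_ALPHABET = frozenset("ACGTN")

FEATURE_TYPES = ("anchor", "cyclase_candidate", "decoy")


@dataclass(frozen=True)
class ContigRecord:
    """One genomic sequence: uppercase DNA over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: non-ACGTN characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureRow:
    """A located feature on a contig, 0-based half-open, strand '+'/'-'."""

    contig_id: str
    start: int
    end: int
    strand: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read a FASTA file into ContigRecords, order preserved.

    Sequences are uppercased; gap characters and whitespace are stripped.
    Raises on an empty file and on duplicate record ids.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        records.append(ContigRecord(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered {id: sequence} map.

    Sequences are uppercased; duplicate ids and empty files raise.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        out[rec.id] = "".join(str(rec.seq).upper().split())
    if not out:
        raise ValueError(f"no records in {path}")
    return out


def write_fasta(records: list[ContigRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genbank(path: str | Path) -> list[ContigRecord]:
    """Reduce a GenBank file to plain ContigRecords (annotations ignored).

    The pipeline computes its own ORFs, so existing feature tables are
    deliberately discarded.
    """
    records = [
        ContigRecord(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "genbank")
    ]
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def _esc(value: str) -> str:
    return urllib.parse.quote(value, safe=" :/.-_|()[]{}'")


def write_gff3(
    features: list[FeatureRow],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Serialize features as GFF3 (1-based inclusive on disk).

    If ``contig_lengths`` is given, every feature is bounds-checked against
    its contig before anything is written.
    """
    if contig_lengths is not None:
        for f in features:
            length = contig_lengths.get(f.contig_id)
            if length is not None and f.end > length:
                raise ValueError(
                    f"feature [{f.start},{f.end}) exceeds contig "
                    f"{f.contig_id!r} length {length}"
                )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{_esc(k)}={_esc(v)}" for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "terpmine",
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[FeatureRow]:
    """Parse a GFF3 file written by :func:`write_gff3` back into FeatureRows."""
    features: list[FeatureRow] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs: dict[str, str] = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    k, _, v = pair.partition("=")
                    attrs[urllib.parse.unquote(k)] = urllib.parse.unquote(v)
            features.append(
                FeatureRow(
                    contig_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    type=cols[2],
                    attributes=attrs,
                )
            )
    return features
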