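"""Six-frame ORF enumeration with bacterial (table 11) translation.

An ORF is a maximal start->stop interval: within one stop-bounded frame
segment, alternative in-frame starts collapse to the longest ORF (the most
5' start).  ORFs running off a contig end are discarded because their
translation would be unreliable.  Reverse-strand ORFs are reported in
forward-strand coordinates with strand '-'.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .genome_io import ContigRecord

__all__ = ["OrfRecord", "translate", "find_orfs", "reverse_complement"]

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
DEFAULT_MIN_LEN_AA = 100  # targets are 343-371 aa; decoy load stays manageable


@dataclass(frozen=True)
class OrfRecord:
    """A predicted coding interval; [start, end) includes the stop codon."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def length_aa(self) -> int:
        return (self.end - self.start) // 3 - 1

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"


def translate(dna: str, table_id: int = 11) -> str:
    """Translate a codon-aligned DNA string; stops are '*', N-codons are 'X'."""
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate(table=table_id))


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _scan_frame(
    seq: str,
    frame: int,
    min_len_aa: int,
    start_codons: frozenset[str],
    stop_codons: frozenset[str],
) -> list[tuple[int, int]]:
    """Maximal ORFs [start, end) in one forward frame of ``seq``.

    Walks codons once, remembering the first start codon since the last
    stop; ORFs not closed by a stop before the sequence end are dropped.
    """
    orfs: list[tuple[int, int]] = []
    first_start: int | None = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in stop_codons:
            if first_start is not None:
                n_aa = (pos - first_start) // 3
                if n_aa >= min_len_aa:
                    orfs.append((first_start, pos + 3))
                first_start = None
        elif first_start is None and codon in start_codons:
            first_start = pos
    return orfs


def find_orfs(
    contig: ContigRecord,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS,
    table_id: int = 11,
) -> list[OrfRecord]:
    """Enumerate ORFs with >= min_len_aa residues on all six frames.

    Alternative starts (GTG/TTG) translate as M, the bacterial convention.
    Results are sorted by (start, end, strand).
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    starts = frozenset(start_codons)
    stops = frozenset(("TAA", "TAG", "TGA"))
    records: list[OrfRecord] = []
    n = contig.length
    for strand, seq in (("+", contig.seq), ("-", reverse_complement(contig.seq))):
        for frame in range(3):
            for s, e in _scan_frame(seq, frame, min_len_aa, starts, stops):
                protein = "M" + translate(seq[s + 3 : e - 3], table_id)
                if strand == "+":
                    fwd_s, fwd_e = s, e
                else:
                    fwd_s, fwd_e = n - e, n - s
                records.append(
                    OrfRecord(
                        contig_id=contig.id,
                        start=fwd_s,
                        end=fwd_e,
                        strand=strand,
                        frame=frame,
                        protein=protein,
                    )
                )
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records
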