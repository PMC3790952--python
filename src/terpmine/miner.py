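"""Neighborhood mining: motif-positive ORFs flanking GGDP-synthase anchors.

The headline stage.  Diterpene biosynthesis needs a GGDP synthase, and in
actinomycete genomes the cyclase usually sits near it, so the miner first
recognizes anchor ORFs by local-alignment identity to query GGDP synthases
and then nominates every motif-classified ORF within a genomic window of an
anchor as a diterpene-cyclase candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import ContigRecord, FeatureRow, write_gff3
from .homology import Anchor, find_anchors
from .motifs import DEFAULT_MOTIFS, ClassCall, MotifDef, classify
from .orf_finder import DEFAULT_MIN_LEN_AA, OrfRecord, find_orfs

__all__ = ["MineParams", "CandidateLocus", "mine", "write_report", "REPORT_COLUMNS"]

DEFAULT_WINDOW_BP = 10_000  # spans typical actinomycete cluster gene spacing


@dataclass(frozen=True)
class MineParams:
    min_len_aa: int = DEFAULT_MIN_LEN_AA
    min_identity_pct: float = 30.0
    min_aligned_frac: float = 0.5
    window_bp: int = DEFAULT_WINDOW_BP
    motif_defs: tuple[MotifDef, ...] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0 < self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in (0, 100]")


@dataclass(frozen=True)
class CandidateLocus:
    anchor: Anchor
    candidate_orf: OrfRecord
    class_call: ClassCall
    distance_bp: int
    same_strand: bool

    @property
    def rank_score(self) -> float:
        # anchor identity dominates; distance is a mild penalty
        return self.anchor.alignment.percent_identity - 0.1 * (self.distance_bp / 1000.0)


def _gap_bp(a: OrfRecord, b: OrfRecord) -> int:
    """Gap between two intervals on the same contig; 0 if they touch/overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def mine(
    contigs: list[ContigRecord],
    queries: dict[str, str],
    params: MineParams = MineParams(),
) -> list[CandidateLocus]:
    """Run the full anchor + neighborhood + motif screen over a genome.

    For each anchor, every ORF on the same contig whose interval lies
    within ``window_bp`` of the anchor interval (either side, either
    strand) and that carries at least one class motif becomes a
    candidate.  An ORF that itself qualifies as an anchor is never
    reported as a candidate, which avoids self-pairing artifacts.
    Results are sorted by descending rank_score.
    """
    candidates: list[CandidateLocus] = []
    for contig in contigs:
        orfs = find_orfs(contig, min_len_aa=params.min_len_aa)
        anchors = find_anchors(
            orfs,
            queries,
            min_identity_pct=params.min_identity_pct,
            min_aligned_frac=params.min_aligned_frac,
        )
        anchor_ids = {a.orf.id for a in anchors}
        calls = {
            orf.id: classify(orf.protein, params.motif_defs, orf_id=orf.id)
            for orf in orfs
            if orf.id not in anchor_ids
        }
        for anchor in anchors:
            for orf in orfs:
                if orf.id in anchor_ids:
                    continue
                call = calls[orf.id]
                if call.call == "none":
                    continue
                gap = _gap_bp(anchor.orf, orf)
                if gap > params.window_bp:
                    continue
                candidates.append(
                    CandidateLocus(
                        anchor=anchor,
                        candidate_orf=orf,
                        class_call=call,
                        distance_bp=gap,
                        same_strand=anchor.orf.strand == orf.strand,
                    )
                )
    candidates.sort(
        key=lambda c: (
            -c.rank_score,
            -c.candidate_orf.length_aa,
            c.candidate_orf.contig_id,
            c.candidate_orf.start,
        )
    )
    return candidates


REPORT_COLUMNS = (
    "contig",
    "anchor_start",
    "anchor_end",
    "anchor_strand",
    "anchor_query",
    "anchor_pct_identity",
    "anchor_aligned_length",
    "candidate_start",
    "candidate_end",
    "candidate_strand",
    "candidate_length_aa",
    "motifs",
    "class_call",
    "distance_bp",
    "same_strand",
    "rank_score",
)


def write_report(
    candidates: list[CandidateLocus],
    tsv_path: str | Path,
    gff_path: str | Path | None = None,
) -> None:
    """Write the candidate table as TSV plus a parallel GFF3 of features.

    The TSV has a fixed column order; identical inputs give byte-identical
    files.  ``gff_path`` defaults to the TSV path with a .gff3 suffix.
    """
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in candidates:
            aln = c.anchor.alignment
            fh.write(
                "\t".join(
                    [
                        c.candidate_orf.contig_id,
                        str(c.anchor.orf.start),
                        str(c.anchor.orf.end),
                        c.anchor.orf.strand,
                        aln.query_id,
                        f"{aln.percent_identity:.2f}",
                        str(aln.aligned_length),
                        str(c.candidate_orf.start),
                        str(c.candidate_orf.end),
                        c.candidate_orf.strand,
                        str(c.candidate_orf.length_aa),
                        ",".join(sorted({h.motif_name for h in c.class_call.hits})),
                        c.class_call.call,
                        str(c.distance_bp),
                        str(c.same_strand),
                        f"{c.rank_score:.4f}",
                    ]
                )
                + "\n"
            )
    if gff_path is None:
        gff_path = tsv_path.with_suffix(".gff3")
    features = [
        FeatureRow(
            contig_id=c.candidate_orf.contig_id,
            start=c.candidate_orf.start,
            end=c.candidate_orf.end,
            strand=c.candidate_orf.strand,
            type="cyclase_candidate",
            attributes={
                "class_call": c.class_call.call,
                "distance_bp": str(c.distance_bp),
                "anchor": c.anchor.orf.id,
            },
        )
        for c in candidates
    ]
    write_gff3(features, gff_path)
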