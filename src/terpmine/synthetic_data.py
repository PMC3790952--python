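"""Synthetic genomes with planted truth sets, and simulated assay datasets.

Everything the pipeline consumes can be generated here deterministically:
high-GC background contigs carrying a planted GGDP-synthase-like anchor
gene (mutated to a chosen percent identity against the shipped synthetic
query), a planted motif-bearing cyclase gene at a controlled distance,
motif-free decoy genes, and replicated coupled-assay absorbance traces
whose initial rates follow Michaelis-Menten kinetics.

All seed proteins are fully synthetic sequences generated from fixed
internal seeds (no database sequences are shipped); they reproduce the
*statistical* situation of the real screen — a remote anchor homologue
(~30-35 % identity) next to an NSE-motif cyclase — not its residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import ContigRecord, FeatureRow
from .kinetics import AssayTrace, simulate_trace
from .motifs import DEFAULT_MOTIFS, MotifDef, scan_motifs
from .orf_finder import find_orfs, reverse_complement

__all__ = [
    "PlantSpec",
    "GenomeSpec",
    "anchor_query_protein",
    "classI_cyclase_protein",
    "mutate_to_identity",
    "reverse_translate",
    "random_protein",
    "plant_genome",
    "two_cluster_spec",
    "simulate_assay_dataset",
    "ASSAY_S_GRID_UM",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

# table 11 back-translation map (M handled by the start codon on emission)
_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

# the assay's substrate grid, uM
ASSAY_S_GRID_UM = (10.0, 20.0, 40.0, 80.0, 100.0, 160.0, 200.0)

DEFAULT_GC = 0.72  # Streptomyces-like background

_NSE_MOTIF = "NDLFSLTAE"  # matches [ND]Dxx[ST]xxx[ED]


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _motif_free_protein(
    length: int,
    rng: np.random.Generator,
    motif_defs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
    max_tries: int = 200,
) -> str:
    for _ in range(max_tries):
        p = random_protein(length, rng)
        if not scan_motifs(p, motif_defs):
            return p
    raise RuntimeError(f"could not sample a motif-free protein of length {length}")


def anchor_query_protein(length: int = 350) -> str:
    """The shipped synthetic GGDP-synthase-like query (motif-free, fixed)."""
    rng = np.random.default_rng(20130206)
    return "M" + _motif_free_protein(length - 1, rng)


def classI_cyclase_protein(length: int = 350, motif_at: int = 220) -> str:
    """A synthetic class-I cyclase seed with one NSE/DTE motif embedded."""
    rng = np.random.default_rng(20130207)
    body = _motif_free_protein(length - 1, rng)
    p = "M" + body[:motif_at] + _NSE_MOTIF + body[motif_at + len(_NSE_MOTIF) :]
    p = p[:length]
    hits = scan_motifs(p)
    assert hits and all(h.motif_name == "NSE/DTE" for h in hits)
    return p


def motif_span(protein: str, motif_defs: tuple[MotifDef, ...] = DEFAULT_MOTIFS) -> set[int]:
    """Residue indices covered by any motif hit (for freezing during mutation)."""
    frozen: set[int] = set()
    for h in scan_motifs(protein, motif_defs):
        frozen.update(range(h.start, h.start + len(h.matched_subsequence)))
    return frozen


def mutate_to_identity(
    seed_protein: str,
    target_identity_pct: float,
    rng_seed: int | np.random.Generator,
    frozen_positions: set[int] | None = None,
) -> str:
    """Substitute residues until exact-match identity hits the target +/-2 pts.

    Substitutions are uniform over the 19 other residues at positions
    sampled without replacement; ``frozen_positions`` (e.g. a motif span)
    are never touched.  Raises if the target is unreachable with the
    frozen set.
    """
    if not 0 < target_identity_pct <= 100:
        raise ValueError("target identity must be in (0, 100]")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = len(seed_protein)
    frozen = frozen_positions or set()
    n_mut = round(n * (1 - target_identity_pct / 100.0))
    mutable = [i for i in range(n) if i not in frozen]
    if n_mut > len(mutable):
        raise ValueError(
            f"target {target_identity_pct}% needs {n_mut} substitutions but only "
            f"{len(mutable)} positions are mutable"
        )
    positions = rng.choice(len(mutable), size=n_mut, replace=False)
    out = list(seed_protein)
    for idx in positions:
        i = mutable[idx]
        choices = [a for a in _AA if a != seed_protein[i]]
        out[i] = rng.choice(choices)
    mutant = "".join(out)
    realized = 100.0 * sum(a == b for a, b in zip(seed_protein, mutant)) / n
    if abs(realized - target_identity_pct) > 2.0:
        raise AssertionError(
            f"realized identity {realized:.1f}% outside +/-2 of target"
        )
    return mutant


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Protein -> CDS with uniform synonymous codons, ATG start, random stop.

    The leading residue is emitted as ATG regardless of amino acid so the
    gene is re-callable by a start-codon ORF finder.
    """
    codons = ["ATG"]
    for aa in protein[1:]:
        codons.append(str(rng.choice(_CODONS[aa])))
    codons.append(str(rng.choice(_STOPS)))
    return "".join(codons)


@dataclass(frozen=True)
class PlantSpec:
    """One element to plant: an anchor/cyclase/decoy gene at a fixed locus."""

    kind: str  # anchor | cyclase | decoy
    contig_index: int
    position: int
    strand: str = "+"
    seed_protein: str | None = None  # defaults per kind
    target_identity_pct: float | None = None  # None = plant the seed verbatim
    length_aa: int = 120  # decoys only

    def __post_init__(self) -> None:
        if self.kind not in ("anchor", "cyclase", "decoy"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class GenomeSpec:
    n_contigs: int
    contig_length_bp: int
    planted: tuple[PlantSpec, ...] = ()
    gc_fraction: float = DEFAULT_GC
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        for p in self.planted:
            if not 0 <= p.contig_index < self.n_contigs:
                raise ValueError(f"contig_index {p.contig_index} out of range")


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(list("ACGT"), size=length, p=probs)


def _planted_protein(plant: PlantSpec, rng: np.random.Generator) -> str:
    """Protein to plant; mutants are re-drawn until their motif content is
    clean (anchors stay motif-free, cyclases stay pure class I)."""
    if plant.kind == "anchor":
        seed = plant.seed_protein or anchor_query_protein()
        frozen: set[int] = set()

        def accept(p: str) -> bool:
            return not scan_motifs(p)

    elif plant.kind == "cyclase":
        seed = plant.seed_protein or classI_cyclase_protein()
        frozen = motif_span(seed)
        seed_calls = {h.motif_name for h in scan_motifs(seed)}

        def accept(p: str) -> bool:
            return {h.motif_name for h in scan_motifs(p)} == seed_calls

    else:
        return "M" + _motif_free_protein(plant.length_aa - 1, rng)
    if plant.target_identity_pct is None or plant.target_identity_pct == 100:
        return seed
    for _ in range(100):
        mutant = mutate_to_identity(seed, plant.target_identity_pct, rng, frozen)
        if accept(mutant):
            return mutant
    raise RuntimeError(f"could not draw a motif-clean {plant.kind} mutant")


@dataclass
class _PlantedGene:
    start: int
    end: int
    strand: str
    protein: str
    kind: str


def _insert_gene(seq: np.ndarray, gene: _PlantedGene, rng: np.random.Generator) -> None:
    """(Re-)emit a planted gene's CDS, plus an upstream in-frame stop so
    the ORF finder calls exactly [start, end)."""
    cds = reverse_translate(gene.protein, rng)
    insert = cds if gene.strand == "+" else reverse_complement(cds)
    seq[gene.start : gene.end] = list(insert)
    if gene.strand == "+" and gene.start >= 3:
        seq[gene.start - 3 : gene.start] = list("TAA")
    elif gene.strand == "-" and gene.end + 3 <= len(seq):
        seq[gene.end : gene.end + 3] = list("TTA")


def _scrub_contig(
    seq: np.ndarray,
    contig_id: str,
    planted: list[_PlantedGene],
    motif_defs: tuple[MotifDef, ...],
    rng: np.random.Generator,
    min_len_aa: int = 100,
    max_rounds: int = 50,
) -> None:
    """Remove chance motif-positive ORFs so the truth set is complete.

    High-GC random DNA is stop-poor enough to produce long spurious ORFs,
    a few of which carry class motifs by chance; left alone they would be
    genuine unlabeled positives.  An offending ORF in pure background gets
    an in-frame stop written over its middle codon; one that overlaps a
    planted gene (e.g. an antisense ORF inside its CDS) is removed by
    re-drawing that gene's synonymous codons.  The planted genes
    themselves (exact start/end/strand matches) are expected and kept.
    """
    for _ in range(max_rounds):
        contig = ContigRecord(id=contig_id, seq="".join(seq))
        offending = []
        for orf in find_orfs(contig, min_len_aa=min_len_aa):
            if any(
                orf.start == g.start and orf.end == g.end and orf.strand == g.strand
                for g in planted
            ):
                continue
            if scan_motifs(orf.protein, motif_defs):
                offending.append(orf)
        if not offending:
            return
        for orf in offending:
            overlapped = [
                g for g in planted if orf.start < g.end and g.start < orf.end
            ]
            if overlapped:
                for g in overlapped:
                    _insert_gene(seq, g, rng)
            else:
                k = orf.length_aa // 2
                if orf.strand == "+":
                    pos = orf.start + 3 * k
                    seq[pos : pos + 3] = list("TAA")
                else:
                    pos = orf.end - 3 * (k + 1)
                    seq[pos : pos + 3] = list("TTA")
    raise RuntimeError(f"{contig_id}: background scrub did not converge")


def plant_genome(spec: GenomeSpec) -> tuple[list[ContigRecord], list[FeatureRow]]:
    """Generate contigs with planted genes and the matching truth features.

    Background bases are i.i.d. at ``gc_fraction``; each planted protein
    is reverse-translated and written over the background at its
    position (reverse-complemented for '-' strand genes), with an
    in-frame stop placed immediately upstream so the gene's called
    boundaries equal the planted ones.  Chance motif-positive background
    ORFs are disrupted so the truth set is complete.  Overlapping
    plantings raise.  Byte-identical output for identical spec + seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seqs = [
        _background(spec.contig_length_bp, spec.gc_fraction, rng)
        for _ in range(spec.n_contigs)
    ]
    genes: dict[int, list[_PlantedGene]] = {i: [] for i in range(spec.n_contigs)}
    truth: list[FeatureRow] = []
    for plant in spec.planted:
        protein = _planted_protein(plant, rng)
        start = plant.position
        end = start + 3 * (len(protein) + 1)
        if end > spec.contig_length_bp:
            raise ValueError(f"planting [{start},{end}) exceeds contig length")
        for g in genes[plant.contig_index]:
            if start < g.end and g.start < end:
                raise ValueError(
                    f"planting [{start},{end}) overlaps existing [{g.start},{g.end})"
                )
        gene = _PlantedGene(start, end, plant.strand, protein, plant.kind)
        genes[plant.contig_index].append(gene)
        _insert_gene(seqs[plant.contig_index], gene, rng)
        truth.append(
            FeatureRow(
                contig_id=f"contig{plant.contig_index + 1}",
                start=start,
                end=end,
                strand=plant.strand,
                type="cyclase_candidate" if plant.kind == "cyclase" else plant.kind,
                attributes={
                    "kind": plant.kind,
                    "length_aa": str(len(protein)),
                    **(
                        {"target_identity_pct": str(plant.target_identity_pct)}
                        if plant.target_identity_pct is not None
                        else {}
                    ),
                },
            )
        )
    for i, seq in enumerate(seqs):
        _scrub_contig(seq, f"contig{i + 1}", genes[i], DEFAULT_MOTIFS, rng)
    contigs = [
        ContigRecord(id=f"contig{i + 1}", seq="".join(seq))
        for i, seq in enumerate(seqs)
    ]
    return contigs, truth


def two_cluster_spec(
    rng_seed: int,
    identity_pct: float = 35.0,
    distance_bp: int = 3000,
    n_decoys: int = 20,
    contig_length_bp: int = 20_000,
) -> GenomeSpec:
    """A genome emulating the discovery scenario: two contigs, each with an
    anchor + class-I cyclase pair at a controlled gap, plus motif-free
    decoys on separate contigs (no class-II gene anywhere)."""
    anchor_len_bp = 3 * (350 + 1)
    planted = []
    for ci in (0, 1):
        planted.append(
            PlantSpec(
                kind="anchor",
                contig_index=ci,
                position=2000,
                strand="+",
                target_identity_pct=identity_pct,
            )
        )
        planted.append(
            PlantSpec(
                kind="cyclase",
                contig_index=ci,
                position=2000 + anchor_len_bp + distance_bp,
                strand="+" if ci == 0 else "-",
            )
        )
    decoy_contigs = max(2, (n_decoys + 9) // 10)
    for d in range(n_decoys):
        ci = 2 + d % decoy_contigs
        slot = d // decoy_contigs
        planted.append(
            PlantSpec(
                kind="decoy",
                contig_index=ci,
                position=500 + slot * 800,
                strand="+" if d % 2 == 0 else "-",
                length_aa=120,
            )
        )
    return GenomeSpec(
        n_contigs=2 + decoy_contigs,
        contig_length_bp=contig_length_bp,
        planted=tuple(planted),
        rng_seed=rng_seed,
    )


def simulate_assay_dataset(
    truth: dict[str, float],
    s_grid: tuple[float, ...] = ASSAY_S_GRID_UM,
    replicates: int = 3,
    noise_sd: float = 0.002,
    rng_seed: int = 0,
    **trace_kwargs,
) -> list[AssayTrace]:
    """One seeded AssayTrace per (substrate concentration, replicate).

    ``truth`` must carry Km (uM), kcat (min^-1) and enzyme_conc (uM).
    """
    if not s_grid:
        raise ValueError("substrate grid is empty")
    seeds = np.random.SeedSequence(rng_seed).generate_state(len(s_grid) * replicates)
    traces: list[AssayTrace] = []
    k = 0
    for s in s_grid:
        for rep in range(replicates):
            traces.append(
                simulate_trace(
                    Km=truth["Km"],
                    kcat=truth["kcat"],
                    enzyme_conc=truth["enzyme_conc"],
                    substrate_conc=s,
                    noise_sd=noise_sd,
                    seed=int(seeds[k]),
                    replicate_id=rep,
                    **trace_kwargs,
                )
            )
            k += 1
    return traces
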