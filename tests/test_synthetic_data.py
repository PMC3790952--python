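"""Generators: identity control, determinism, truth-set completeness."""

import numpy as np
import pytest

from oracles import revcomp, translate_lookup
from terpmine.motifs import scan_motifs
from terpmine.orf_finder import find_orfs
from terpmine.synthetic_data import (
    GenomeSpec,
    PlantSpec,
    anchor_query_protein,
    classI_cyclase_protein,
    mutate_to_identity,
    plant_genome,
    random_protein,
    reverse_translate,
    simulate_assay_dataset,
    two_cluster_spec,
)


def identity_pct(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


class TestSeedProteins:
    def test_anchor_query_is_motif_free_and_stable(self):
        p = anchor_query_protein()
        assert p == anchor_query_protein()
        assert scan_motifs(p) == []

    def test_cyclase_seed_is_pure_class_I(self):
        p = classI_cyclase_protein()
        hits = scan_motifs(p)
        assert hits and {h.motif_name for h in hits} == {"NSE/DTE"}


class TestMutateToIdentity:
    def test_target_100_returns_seed(self):
        seed = anchor_query_protein()
        assert mutate_to_identity(seed, 100, rng_seed=1) == seed

    @pytest.mark.parametrize("target", [80, 50, 30])
    def test_realized_identity_in_band(self, target):
        seed = anchor_query_protein(300)
        mut = mutate_to_identity(seed, target, rng_seed=3)
        assert abs(identity_pct(seed, mut) - target) <= 2

    def test_different_seeds_differ_same_band(self):
        seed = anchor_query_protein(300)
        a = mutate_to_identity(seed, 50, rng_seed=1)
        b = mutate_to_identity(seed, 50, rng_seed=2)
        assert a != b
        assert abs(identity_pct(seed, a) - identity_pct(seed, b)) <= 4

    def test_frozen_positions_untouched(self):
        seed = classI_cyclase_protein()
        frozen = {h.start + k for h in scan_motifs(seed)
                  for k in range(len(h.matched_subsequence))}
        mut = mutate_to_identity(seed, 40, rng_seed=5, frozen_positions=frozen)
        assert all(mut[i] == seed[i] for i in frozen)

    def test_unreachable_target_with_frozen_rejected(self):
        seed = "MDDDDDDDDD"
        with pytest.raises(ValueError, match="mutable"):
            mutate_to_identity(seed, 10, rng_seed=1,
                               frozen_positions=set(range(9)))


class TestReverseTranslate:
    def test_cds_translates_back_to_protein(self):
        rng = np.random.default_rng(2)
        protein = "M" + random_protein(120, rng)
        cds = reverse_translate(protein, rng)
        assert len(cds) == 3 * (len(protein) + 1)
        assert cds.startswith("ATG")
        back = translate_lookup(cds)
        assert back[:-1] == protein
        assert back[-1] == "*"


class TestPlantGenome:
    def test_empty_spec_is_pure_background(self):
        contigs, truth = plant_genome(GenomeSpec(1, 5000, rng_seed=4))
        assert truth == []
        assert len(contigs) == 1 and contigs[0].length == 5000

    def test_fixed_seed_byte_identical(self):
        spec = two_cluster_spec(rng_seed=42, n_decoys=4)
        a, _ = plant_genome(spec)
        b, _ = plant_genome(spec)
        assert [c.seq for c in a] == [c.seq for c in b]

    def test_overlapping_plantings_rejected(self):
        spec = GenomeSpec(
            1, 10_000,
            planted=(PlantSpec("cyclase", 0, 1000, "+"),
                     PlantSpec("cyclase", 0, 1500, "+")),
        )
        with pytest.raises(ValueError, match="overlaps"):
            plant_genome(spec)

    def test_planted_gene_called_at_exact_coordinates(self):
        spec = GenomeSpec(
            1, 8000, planted=(PlantSpec("cyclase", 0, 2000, "-"),), rng_seed=8
        )
        contigs, truth = plant_genome(spec)
        orfs = find_orfs(contigs[0], min_len_aa=300)
        # background may contribute extra motif-free ORFs; the planted gene
        # must be called at exactly its truth coordinates
        assert (truth[0].start, truth[0].end, "-") in [
            (o.start, o.end, o.strand) for o in orfs
        ]

    def test_decoys_carry_no_motifs(self):
        spec = GenomeSpec(
            1, 20_000,
            planted=tuple(PlantSpec("decoy", 0, 500 + i * 900, "+", length_aa=150)
                          for i in range(8)),
            rng_seed=12,
        )
        contigs, truth = plant_genome(spec)
        for t in truth:
            cds = contigs[0].seq[t.start : t.end]
            if t.strand == "-":
                cds = revcomp(cds)
            protein = "M" + translate_lookup(cds[3:-3])
            assert scan_motifs(protein) == []

    def test_background_free_of_motif_positive_orfs(self):
        contigs, _ = plant_genome(GenomeSpec(2, 20_000, rng_seed=77))
        for contig in contigs:
            for orf in find_orfs(contig, min_len_aa=100):
                assert scan_motifs(orf.protein) == []


class TestAssayDataset:
    def test_trace_count(self):
        truth = {"Km": 50.0, "kcat": 1.0, "enzyme_conc": 5.0}
        assert len(simulate_assay_dataset(truth, replicates=3)) == 21

    def test_seeded_and_deterministic(self):
        truth = {"Km": 50.0, "kcat": 1.0, "enzyme_conc": 5.0}
        a = simulate_assay_dataset(truth, rng_seed=5)
        b = simulate_assay_dataset(truth, rng_seed=5)
        c = simulate_assay_dataset(truth, rng_seed=6)
        assert all(np.array_equal(x.absorbance340, y.absorbance340)
                   for x, y in zip(a, b))
        assert any(not np.array_equal(x.absorbance340, y.absorbance340)
                   for x, y in zip(a, c))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_assay_dataset({"Km": 1, "kcat": 1, "enzyme_conc": 1}, s_grid=())
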