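"""Mass arithmetic, formula search, unsaturation counting, Mosher calls."""

import numpy as np
import pytest
from pyteomics.mass import calculate_mass

from terpmine.chem import (
    Formula,
    MosherProton,
    count_unsaturations_from_table,
    dbe,
    formula_search,
    load_diterpene4_table,
    monoisotopic_mass,
    mosher_call,
    parse_formula,
)


def random_cho(rng) -> Formula:
    c = int(rng.integers(1, 40))
    h = int(rng.integers(0, min(2 * c + 2, 80) + 1))
    o = int(rng.integers(0, 8))
    if h == 0 and o == 0:
        h = 4
    return Formula.from_dict({"C": c, "H": h, "O": o})


class TestMass:
    def test_carbon_is_exactly_twelve(self):
        assert monoisotopic_mass("C") == 12.0

    def test_protonated_diterpene_alcohol(self):
        assert f"{monoisotopic_mass('C20H35O'):.4f}" == "291.2688"

    def test_additivity(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            a, b = random_cho(rng), random_cho(rng)
            da, db = a.as_dict(), b.as_dict()
            union = Formula.from_dict(
                {el: da.get(el, 0) + db.get(el, 0) for el in set(da) | set(db)}
            )
            assert monoisotopic_mass(a) + monoisotopic_mass(b) == pytest.approx(
                monoisotopic_mass(union), abs=1e-9
            )

    def test_agrees_with_pyteomics(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            f = random_cho(rng)
            assert monoisotopic_mass(f) == pytest.approx(
                calculate_mass(formula=str(f)), abs=1e-6
            )

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            Formula.from_dict({"Zz": 1})

    @pytest.mark.parametrize("bad", ["", "20C", "c20", "C20H35O!"])
    def test_unparseable_formula_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestFormulaSearch:
    def test_measured_ion_retrieves_neutral_diterpene_formula(self):
        hits = formula_search(291.2690, tol_ppm=5.0, adduct="[M+H]+")
        assert hits, "no formulas within tolerance"
        assert str(hits[0].neutral) == "C20H34O"
        assert str(hits[0].ion) == "C20H35O"

    def test_self_retrieval_at_tight_tolerance(self):
        target = monoisotopic_mass("C10H16O2")
        hits = formula_search(target, tol_ppm=0.01, adduct="none")
        assert [str(h.neutral) for h in hits] == ["C10H16O2"]

    def test_matches_triple_loop_enumeration(self):
        bounds = {"C": (0, 12), "H": (0, 26), "O": (0, 7)}
        mz, tol = 180.0634, 10.0  # glucose-sized target
        got = {str(h.neutral) for h in formula_search(mz, tol, bounds, adduct="none")}
        expected = set()
        for c in range(13):
            for h in range(27):
                for o in range(8):
                    if c + h + o == 0:
                        continue
                    m = monoisotopic_mass(Formula.from_dict({"C": c, "H": h, "O": o}))
                    if abs(m - mz) <= mz * tol * 1e-6:
                        expected.add(str(Formula.from_dict({"C": c, "H": h, "O": o})))
        assert got == expected and "C6H12O6" in got

    def test_roundtrip_contains_generating_formula(self):
        rng = np.random.default_rng(41)
        for _ in range(200):
            f = random_cho(rng)
            hits = formula_search(monoisotopic_mass(f), tol_ppm=1.0, adduct="none")
            assert str(f) in {str(h.neutral) for h in hits}

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            formula_search(291.0, tol_ppm=0)


class TestDbe:
    @pytest.mark.parametrize(
        "formula,expected", [("CH4", 0), ("C6H6", 4), ("C20H34O", 4), ("C20H32", 5)]
    )
    def test_values(self, formula, expected):
        assert dbe(formula) == expected

    def test_adding_two_hydrogens_lowers_dbe_by_one(self):
        assert dbe("C20H32O") - dbe("C20H34O") == 1

    def test_impossible_formula_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            dbe("CH6")


class TestUnsaturationTable:
    def test_packaged_diterpene_table_gives_monocycle_with_three_olefins(self):
        result = count_unsaturations_from_table(load_diterpene4_table(), "C20H34O")
        assert result == {"double_bonds": 3, "rings": 1}

    def test_fully_saturated_table(self):
        from terpmine.chem import ShiftRow

        rows = [ShiftRow(str(i), "CH2", 20.0 + i) for i in range(6)]
        result = count_unsaturations_from_table(rows, "C6H14")
        assert result == {"double_bonds": 0, "rings": 0}

    def test_constructed_four_olefin_monocycle(self):
        from terpmine.chem import ShiftRow

        rows = [ShiftRow(str(i), "CH=", 120.0 + i) for i in range(4)]
        rows += [ShiftRow(str(4 + i), "C=", 130.0 + i) for i in range(4)]
        rows += [ShiftRow(str(8 + i), "CH2", 25.0 + i) for i in range(2)]
        # C10H12: DBE 5 -> 4 double bonds + 1 ring
        result = count_unsaturations_from_table(rows, "C10H12")
        assert result == {"double_bonds": 4, "rings": 1}

    def test_odd_olefinic_count_rejected(self):
        from terpmine.chem import ShiftRow

        rows = [ShiftRow("1", "CH=", 120.0)] + [
            ShiftRow(str(i + 2), "CH2", 20.0) for i in range(5)
        ]
        with pytest.raises(ValueError, match="unpairable"):
            count_unsaturations_from_table(rows, "C6H8")

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="carbons"):
            count_unsaturations_from_table(load_diterpene4_table()[:-1], "C20H34O")


def proton(label, side, dd):
    return MosherProton(label, side, delta_s=1.0 + dd, delta_r=1.0)


class TestMosher:
    def test_uniform_opposite_signs_call_s(self):
        protons = [proton("H14a", "A", +0.05), proton("H14b", "A", +0.02),
                   proton("H15", "B", -0.04), proton("H16", "B", -0.01)]
        assert mosher_call(protons) == "S"

    def test_side_swap_flips_call(self):
        protons = [proton("a", "A", +0.05), proton("b", "B", -0.04)]
        swapped = [MosherProton(p.label, "B" if p.side == "A" else "A",
                                p.delta_s, p.delta_r) for p in protons]
        assert mosher_call(protons) == "S"
        assert mosher_call(swapped) == "R"

    def test_all_zero_is_indeterminate(self):
        protons = [proton("a", "A", 0.0), proton("b", "B", 0.0)]
        assert mosher_call(protons) == "indeterminate"

    def test_mixed_signs_within_side_is_indeterminate(self):
        protons = [proton("a", "A", +0.05), proton("b", "A", -0.05),
                   proton("c", "B", -0.04)]
        assert mosher_call(protons) == "indeterminate"

    def test_uniform_reference_shift_invariance(self):
        protons = [proton("a", "A", +0.05), proton("b", "B", -0.04)]
        shifted = [MosherProton(p.label, p.side, p.delta_s + 0.3, p.delta_r + 0.3)
                   for p in protons]
        assert mosher_call(protons) == mosher_call(shifted)

    def test_missing_side_rejected(self):
        with pytest.raises(ValueError, match="both sides"):
            mosher_call([proton("a", "A", 0.05)])
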