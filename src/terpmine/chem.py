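"""Small-molecule arithmetic for product characterization.

Covers the desk computations used to pin down a new diterpene alcohol:
monoisotopic mass and CHO formula search against a measured m/z, degrees
of unsaturation (DBE), double-bond/ring counting from a 13C shift table,
and the modified-Mosher sign analysis for secondary-alcohol configuration.

Mass convention: sums of most-abundant-isotope atomic masses for the
*neutral* formula, with no electron-mass correction — for an [M+H]+ ion
the "calculated" value is the neutral mass of the protonated composition.
This matches how HRMS values are conventionally printed in natural-product
papers; users of ion-mass conventions should subtract one electron mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "Formula",
    "ShiftRow",
    "MosherProton",
    "parse_formula",
    "monoisotopic_mass",
    "formula_search",
    "FormulaMatch",
    "dbe",
    "count_unsaturations_from_table",
    "load_diterpene4_table",
    "mosher_call",
    "PROTON_MASS",
]

# most-abundant-isotope masses, u (CODATA/AME)
ISOTOPE_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}
PROTON_MASS = ISOTOPE_MASS["H"]  # neutral-H convention for adduct arithmetic

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 50),
    "H": (0, 100),
    "O": (0, 10),
}


@dataclass(frozen=True)
class Formula:
    """Elemental composition; counts over {C,H,N,O,S,P}, neutral by default."""

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for _, n in self.counts):
            raise ValueError("element counts must be >= 0")
        if all(n == 0 for _, n in self.counts):
            raise ValueError("formula must contain at least one atom")
        unknown = [el for el, _ in self.counts if el not in ISOTOPE_MASS]
        if unknown:
            raise ValueError(f"unknown element(s) {unknown}")

    @staticmethod
    def from_dict(counts: dict[str, int], charge: int = 0) -> "Formula":
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        return Formula(counts=items, charge=charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:  # Hill notation
        d = self.as_dict()
        parts = []
        for el in ["C", "H"] + sorted(set(d) - {"C", "H"}):
            n = d.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """'C20H35O' -> Formula; raises on unparseable text."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise ValueError(f"cannot parse formula {text!r}")
    return Formula.from_dict(counts)


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(ISOTOPE_MASS[el] * n for el, n in formula.counts)


@dataclass(frozen=True)
class FormulaMatch:
    neutral: Formula
    ion: Formula | None  # protonated composition for [M+H]+, else None
    calc_mz: float
    ppm_error: float


def formula_search(
    measured_mz: float,
    tol_ppm: float = 5.0,
    element_bounds: dict[str, tuple[int, int]] | None = None,
    adduct: str = "[M+H]+",
) -> list[FormulaMatch]:
    """All formulas within tol_ppm of a measured m/z, ranked by |ppm error|.

    ``adduct`` is "[M+H]+" (calc m/z = neutral mass + H) or "none"
    (neutral mass compared directly).  H counts are solved analytically
    for each combination of the heavier elements, so wide H bounds are
    cheap.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if adduct not in ("[M+H]+", "none"):
        raise ValueError(f"unsupported adduct {adduct!r}")
    bounds = dict(DEFAULT_BOUNDS if element_bounds is None else element_bounds)
    h_lo, h_hi = bounds.pop("H", (0, 0))
    heavy = sorted(bounds)
    offset = PROTON_MASS if adduct == "[M+H]+" else 0.0
    tol_da = measured_mz * tol_ppm * 1e-6
    matches: list[FormulaMatch] = []

    def recurse(idx: int, counts: dict[str, int], mass: float) -> None:
        if idx == len(heavy):
            # remaining mass budget is filled with H
            target_h = (measured_mz - offset - mass) / ISOTOPE_MASS["H"]
            for n_h in {int(target_h), int(target_h) + 1}:
                if not h_lo <= n_h <= h_hi:
                    continue
                full = dict(counts, H=n_h)
                if all(v == 0 for v in full.values()):
                    continue
                neutral = Formula.from_dict(full) if any(full.values()) else None
                calc = mass + n_h * ISOTOPE_MASS["H"] + offset
                if abs(calc - measured_mz) <= tol_da:
                    ion = None
                    if adduct == "[M+H]+":
                        ion = Formula.from_dict(
                            {**full, "H": full.get("H", 0) + 1}, charge=1
                        )
                    matches.append(
                        FormulaMatch(
                            neutral=neutral,
                            ion=ion,
                            calc_mz=calc,
                            ppm_error=(calc - measured_mz) / measured_mz * 1e6,
                        )
                    )
            return
        el = heavy[idx]
        lo, hi = bounds[el]
        for n in range(lo, hi + 1):
            new_mass = mass + n * ISOTOPE_MASS[el]
            if new_mass > measured_mz + tol_da:
                break
            recurse(idx + 1, {**counts, el: n} if n else counts, new_mass)

    recurse(0, {}, 0.0)
    matches.sort(key=lambda m: (abs(m.ppm_error), str(m.neutral)))
    return matches


def dbe(formula: Formula | str) -> float:
    """Degrees of unsaturation (rings + pi bonds): (2C + 2 + N + P - H)/2."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    d = formula.as_dict()
    value = (2 * d.get("C", 0) + 2 + d.get("N", 0) + d.get("P", 0) - d.get("H", 0)) / 2
    if value < 0:
        raise ValueError(f"negative DBE ({value}) — impossible formula {formula}")
    return value


@dataclass(frozen=True)
class ShiftRow:
    """One carbon of a 1H/13C NMR assignment table."""

    position: str
    carbon_type: str  # CH3, CH2, CH, C, CH=, C=, CH-O
    delta_c: float
    delta_h: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_c <= 250.0:
            raise ValueError(f"delta_C {self.delta_c} outside [0, 250] ppm")


OLEFINIC_WINDOW = (100.0, 160.0)  # 13C ppm window for alkene carbons


def count_unsaturations_from_table(
    rows: list[ShiftRow],
    formula: Formula | str,
    olefinic_window: tuple[float, float] = OLEFINIC_WINDOW,
) -> dict[str, int]:
    """Partition DBE into C=C double bonds and rings from 13C shifts.

    Carbons resonating inside the olefinic window pair up into double
    bonds; whatever DBE remains is carried by rings.  The shift table
    must list every carbon of the formula exactly once.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    n_c = formula.as_dict().get("C", 0)
    if len(rows) != n_c:
        raise ValueError(f"table lists {len(rows)} carbons but formula has {n_c}")
    lo, hi = olefinic_window
    olefinic = sum(1 for r in rows if lo <= r.delta_c <= hi)
    if olefinic % 2:
        raise ValueError(f"odd number of olefinic carbons ({olefinic}) — unpairable")
    double_bonds = olefinic // 2
    total = dbe(formula)
    if total != int(total):
        raise ValueError(f"non-integer DBE {total} for a neutral molecule")
    rings = int(total) - double_bonds
    if rings < 0:
        raise ValueError(
            f"{double_bonds} double bonds exceed total DBE {int(total)}"
        )
    return {"double_bonds": double_bonds, "rings": rings}


def load_diterpene4_table() -> list[ShiftRow]:
    """The packaged 1H/13C assignment table for the novel C20H34O diterpene."""
    rows: list[ShiftRow] = []
    text = (resources.files("terpmine.data") / "diterpene4_nmr.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        pos, ctype, dc = parts[0], parts[1], float(parts[2])
        dh: tuple[float, ...] = ()
        if len(parts) > 3 and parts[3]:
            dh = tuple(float(x) for x in parts[3].split(";"))
        rows.append(ShiftRow(position=pos, carbon_type=ctype, delta_c=dc, delta_h=dh))
    return rows


@dataclass(frozen=True)
class MosherProton:
    """One proton used in the modified-Mosher analysis.

    ``side`` places the proton relative to the MTPA ester plane in the
    standard model (carbinol H toward the viewer, MTPA group at the
    rear): "A" is the substituent side that, when its protons carry
    positive delta-delta = d(S) - d(R), indicates an S carbinol center;
    "B" is the opposite side.
    """

    label: str
    side: str  # "A" or "B"
    delta_s: float
    delta_r: float

    def __post_init__(self) -> None:
        if self.side not in ("A", "B"):
            raise ValueError(f"side must be 'A' or 'B', got {self.side!r}")

    @property
    def delta_delta(self) -> float:
        return self.delta_s - self.delta_r


def _side_sign(protons: list[MosherProton]) -> int:
    """Consensus sign of a side's nonzero delta-deltas: +1, -1, or 0 (mixed/none)."""
    signs = {1 if p.delta_delta > 0 else -1 for p in protons if p.delta_delta != 0.0}
    if len(signs) != 1:
        return 0
    return signs.pop()


def mosher_call(protons: list[MosherProton]) -> str:
    """Absolute configuration of a secondary alcohol: 'R', 'S', or 'indeterminate'.

    Requires at least one proton on each side of the carbinol.  The call
    is made only when the two sides show uniform, opposite delta-delta
    signs; anything else (mixed signs within a side, or all zeros)
    returns 'indeterminate'.
    """
    side_a = [p for p in protons if p.side == "A"]
    side_b = [p for p in protons if p.side == "B"]
    if not side_a or not side_b:
        raise ValueError("need protons on both sides of the carbinol")
    sa, sb = _side_sign(side_a), _side_sign(side_b)
    if sa == 1 and sb == -1:
        return "S"
    if sa == -1 and sb == 1:
        return "R"
    return "indeterminate"
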