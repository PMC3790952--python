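"""Independent brute-force oracles used by the property tests.

Each oracle re-derives a result from first principles by a method
deliberately different from the implementation under test: positionwise
scans, exhaustive enumeration, and a hand-entered codon table.
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# The standard genetic code written out by hand (TCAG order); the bacterial
# table shares all codon->aa assignments, differing only in start codons.
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_BASES = "TCAG"
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AAS[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
STOPS = {c for c, aa in CODON_TABLE.items() if aa == "*"}


def translate_lookup(dna: str) -> str:
    """Codon-by-codon dictionary translation; N-containing codons -> X."""
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def orfs_bruteforce(
    seq: str,
    min_len_aa: int,
    start_codons: tuple[str, ...] = ("ATG", "GTG", "TTG"),
) -> set[tuple[str, int, int]]:
    """Every maximal ORF as (strand, fwd_start, fwd_end), by position scan.

    For each start-codon occurrence, walk to the next in-frame stop;
    ORFs sharing a stop collapse to the earliest (longest) start.
    """
    n = len(seq)
    collapsed: dict[tuple[str, int], int] = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for pos in range(n - 2):
            if s[pos : pos + 3] not in start_codons:
                continue
            p = pos
            while p + 3 <= n and s[p : p + 3] not in STOPS:
                p += 3
            if p + 3 > n:
                continue  # runs off the contig: discarded
            key = (strand, p + 3)
            if key not in collapsed or pos < collapsed[key]:
                collapsed[key] = pos
    out = set()
    for (strand, stop_end), start in collapsed.items():
        if (stop_end - start) // 3 - 1 < min_len_aa:
            continue
        if strand == "+":
            out.add((strand, start, stop_end))
        else:
            out.add((strand, n - stop_end, n - start))
    return out


def motif_hits_regex(protein: str, pattern: tuple[frozenset[str], ...]) -> list[tuple[int, str]]:
    """Overlap-tolerant motif scan via a lookahead regex."""
    rx = re.compile(
        "(?=(" + "".join("[" + "".join(sorted(s)) + "]" for s in pattern) + "))"
    )
    return [(m.start(), m.group(1)) for m in rx.finditer(protein)]


def enumerate_global_score(
    a: str,
    b: str,
    matrix,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best affine-gap global alignment score by exhaustive enumeration.

    A gap of length k costs gap_open + k * gap_extend; a gap in one
    sequence immediately followed by a gap in the other opens a new gap.
    """
    best = float("-inf")

    def rec(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):
            step = gap_extend if prev == "D" else gap_open + gap_extend
            rec(i + 1, j, "D", score - step)
        if j < len(b):
            step = gap_extend if prev == "I" else gap_open + gap_extend
            rec(i, j + 1, "I", score - step)

    rec(0, 0, "M", 0.0)
    return best


def enumerate_local_score(
    a: str,
    b: str,
    matrix,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best local score: exhaustive max over all nonempty substring pairs."""
    best = float("-inf")
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(
                        best,
                        enumerate_global_score(
                            a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend
                        ),
                    )
    return best
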