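"""Terpene-synthase class motifs: scanning and class I/II calling.

Class I terpene synthases ionize the prenyl diphosphate with Mg2+ bound by
an aspartate-rich DDXXD/E motif and/or an NSE/DTE triad; class II cyclases
protonate the terminal olefin via a DXDD motif.  The screen is
presence-based: any hit of a class-tagged motif contributes to the call.

Patterns are ordered lists of allowed-residue sets, written compactly as
e.g. ``DDxx[DE]`` ('x' = any residue, brackets = alternatives).  The
defaults encode the canonical published consensus for each motif and can
be overridden from a plain-text config (see :func:`parse_motif_config`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MotifDef",
    "MotifHit",
    "ClassCall",
    "DEFAULT_MOTIFS",
    "parse_pattern",
    "parse_motif_config",
    "scan_motifs",
    "classify",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: tuple[frozenset[str], ...]
    class_tag: str  # "I" or "II"

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise ValueError(f"motif {self.name!r}: pattern shorter than 4")
        if any(not pos for pos in self.pattern):
            raise ValueError(f"motif {self.name!r}: empty position set")
        if self.class_tag not in ("I", "II"):
            raise ValueError(f"motif {self.name!r}: class_tag must be I or II")


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 0-based residue offset
    matched_subsequence: str


@dataclass(frozen=True)
class ClassCall:
    orf_id: str
    hits: tuple[MotifHit, ...]
    call: str  # classI | classII | both | none


def parse_pattern(text: str) -> tuple[frozenset[str], ...]:
    """Parse compact pattern notation: 'DDxx[DE]' -> position sets."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "[":
            j = text.index("]", i)
            alts = text[i + 1 : j]
            if not alts:
                raise ValueError(f"empty alternative set in pattern {text!r}")
            positions.append(frozenset(alts.upper()))
            i = j + 1
        elif c in "xX.":
            positions.append(frozenset(_AA))
            i += 1
        elif c.upper() in _AA:
            positions.append(frozenset(c.upper()))
            i += 1
        else:
            raise ValueError(f"bad character {c!r} in pattern {text!r}")
    return tuple(positions)


def _motif(name: str, pattern: str, tag: str) -> MotifDef:
    return MotifDef(name=name, pattern=parse_pattern(pattern), class_tag=tag)


# Canonical consensus encodings.  NSE/DTE uses the (N/D)Dxx(S/T)xxxE/D form.
DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    _motif("DDXXD/E", "DDxx[DE]", "I"),
    _motif("NSE/DTE", "[ND]Dxx[ST]xxx[ED]", "I"),
    _motif("DXDD", "DxDD", "II"),
)


def parse_motif_config(text: str) -> tuple[MotifDef, ...]:
    """Read motif definitions from plain text.

    One motif per line: ``name <whitespace> class_tag <whitespace> pattern``;
    blank lines and '#' comments are ignored.
    """
    defs: list[MotifDef] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"motif config line {lineno}: expected 3 fields, got {raw!r}")
        name, tag, pattern = parts
        defs.append(_motif(name, pattern, tag))
    if not defs:
        raise ValueError("motif config defines no motifs")
    return tuple(defs)


def scan_motifs(
    protein: str, motif_defs: tuple[MotifDef, ...] = DEFAULT_MOTIFS
) -> list[MotifHit]:
    """All motif occurrences in a protein, overlaps allowed, sorted by start."""
    if not protein:
        raise ValueError("empty protein")
    hits: list[MotifHit] = []
    for mdef in motif_defs:
        k = len(mdef.pattern)
        for i in range(len(protein) - k + 1):
            window = protein[i : i + k]
            if all(res in pos for res, pos in zip(window, mdef.pattern)):
                hits.append(MotifHit(mdef.name, i, window))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def classify(
    protein: str,
    motif_defs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
    orf_id: str = "",
) -> ClassCall:
    """Class I/II/both/none call from motif presence."""
    hits = tuple(scan_motifs(protein, motif_defs))
    tags = {next(m.class_tag for m in motif_defs if m.name == h.motif_name) for h in hits}
    if tags == {"I"}:
        call = "classI"
    elif tags == {"II"}:
        call = "classII"
    elif tags == {"I", "II"}:
        call = "both"
    else:
        call = "none"
    return ClassCall(orf_id=orf_id, hits=hits, call=call)
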