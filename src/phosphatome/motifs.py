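"""Signature-motif patterns and kinase catalytic-loop specificity rules.

Bacterial PPP-family phosphatases are recognized by three classical motifs
(GDXHG, GDXXDRG, GNHE) plus the later-described (I/L/V)D(S/T)G motif, which
separates genuine PPP-like phosphatases from ApaH-like diadenosine
tetraphosphatases that share the same calcineurin-like domain.  Cdc25-type
tyrosine phosphatases carry the active-site motif CE[F/Y]SXXR on a
rhodanese fold.  Eukaryotic-like protein kinases (ELKs) signal their
substrate specificity through the catalytic-loop hexapeptide: DLKPEN for
Ser/Thr kinases, DLRAAN or DLAARN for Tyr kinases, and DLKPDN is known from
one experimentally dual-specific kinase.

Pattern grammar
---------------
Uppercase letters are fixed residues, ``X`` is a wildcard matching any
residue (including the ambiguity character X), and ``(A/B/...)`` or
``[A/B/...]`` is an alternation over the listed residues.  A fixed residue
or alternation member never matches the ambiguity character X in a target
sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genome_io import AMINO_ACIDS

#: sentinel element matching any residue
WILDCARD = None

Element = frozenset | None  # a fixed residue is a 1-element frozenset


class PatternSyntaxError(ValueError):
    """Motif pattern text violates the grammar; carries the column index."""

    def __init__(self, message: str, column: int):
        super().__init__(f"column {column}: {message}")
        self.column = column


@dataclass(frozen=True)
class MotifPattern:
    """A compiled signature motif: an ordered tuple of match elements."""

    name: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError(f"{self.name}: pattern needs at least 2 elements")
        for el in self.elements:
            if el is WILDCARD:
                continue
            if not el or not el <= frozenset(AMINO_ACIDS):
                raise ValueError(f"{self.name}: invalid element {el!r}")

    def __len__(self) -> int:
        return len(self.elements)

    def render(self) -> str:
        """Render back to pattern text (canonical ``(A/B)`` alternations)."""
        parts = []
        for el in self.elements:
            if el is WILDCARD:
                parts.append("X")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("(" + "/".join(sorted(el)) + ")")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """One match of a motif in a protein sequence (1-based start)."""

    motif: str
    position: int
    match: str


def compile_pattern(text: str, name: str | None = None) -> MotifPattern:
    """Compile pattern text into a :class:`MotifPattern`.

    Both alternation bracket styles are accepted: ``(I/L/V)`` and ``[F/Y]``.
    """
    elements: list[Element] = []
    i = 0
    n = len(text)
    closers = {"(": ")", "[": "]"}
    while i < n:
        ch = text[i]
        if ch in closers:
            close = closers[ch]
            j = text.find(close, i + 1)
            if j < 0:
                raise PatternSyntaxError(f"unbalanced {ch!r}", i + 1)
            body = text[i + 1 : j]
            members = [m for m in body.split("/") if m]
            if not members:
                raise PatternSyntaxError("empty alternation", i + 1)
            residues = set()
            for m in members:
                if len(m) != 1 or m not in AMINO_ACIDS:
                    raise PatternSyntaxError(
                        f"invalid alternation member {m!r}", i + 1
                    )
                residues.add(m)
            elements.append(frozenset(residues))
            i = j + 1
        elif ch in (")", "]"):
            raise PatternSyntaxError(f"unbalanced {ch!r}", i + 1)
        elif ch == "X":
            elements.append(WILDCARD)
            i += 1
        elif ch in AMINO_ACIDS:
            elements.append(frozenset(ch))
            i += 1
        else:
            raise PatternSyntaxError(f"invalid character {ch!r}", i + 1)
    return MotifPattern(name=name or text, elements=tuple(elements))


def scan(sequence: str, pattern: MotifPattern) -> list[MotifHit]:
    """All (possibly overlapping) motif hits, in ascending position order."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    k = len(pattern)
    hits: list[MotifHit] = []
    for start in range(len(sequence) - k + 1):
        window = sequence[start : start + k]
        ok = True
        for res, el in zip(window, pattern.elements):
            if el is WILDCARD:
                continue
            if res not in el:
                ok = False
                break
        if ok:
            hits.append(MotifHit(motif=pattern.name, position=start + 1, match=window))
    return hits


def contains(sequence: str, pattern: MotifPattern) -> bool:
    return bool(sequence) and bool(scan(sequence, pattern))


# ---------------------------------------------------------------------------
# Shipped motif library

PPP_MOTIF_TEXTS = {
    "GDXHG": "GDXHG",
    "GDXXDRG": "GDXXDRG",
    "GNHE": "GNHE",
    "ILV_DST_G": "(I/L/V)D(S/T)G",
}

CDC25_MOTIF_TEXT = "CE[F/Y]SXXR"

PPP_MOTIFS = {name: compile_pattern(t, name) for name, t in PPP_MOTIF_TEXTS.items()}
CDC25_MOTIF = compile_pattern(CDC25_MOTIF_TEXT, "CDC25")


@dataclass(frozen=True)
class PppMotifFlags:
    """Presence of the four PPP signature motifs in one protein."""

    GDXHG: bool
    GDXXDRG: bool
    GNHE: bool
    ILV_DST_G: bool

    @property
    def consensus_complete(self) -> bool:
        """True when all four motifs are present (a fully consensus PPP)."""
        return self.GDXHG and self.GDXXDRG and self.GNHE and self.ILV_DST_G

    def as_dict(self) -> dict[str, bool]:
        return {
            "GDXHG": self.GDXHG,
            "GDXXDRG": self.GDXXDRG,
            "GNHE": self.GNHE,
            "ILV_DST_G": self.ILV_DST_G,
        }


def check_ppp_motifs(sequence: str) -> PppMotifFlags:
    """Test a protein for the PPP signature motifs (anywhere in sequence)."""
    if not sequence:
        return PppMotifFlags(False, False, False, False)
    return PppMotifFlags(
        **{name: contains(sequence, pat) for name, pat in PPP_MOTIFS.items()}
    )


# ---------------------------------------------------------------------------
# Kinase catalytic loop


class CatalyticLoopLabel(enum.Enum):
    SER_THR = "SER_THR"
    TYR = "TYR"
    SER_THR_DUAL_CANDIDATE = "SER_THR_DUAL_CANDIDATE"
    UNCLASSIFIED = "UNCLASSIFIED"


_SER_THR_LOOP = "DLKPEN"
_TYR_LOOPS = frozenset({"DLRAAN", "DLAARN"})
_DUAL_LOOP = "DLKPDN"


def classify_catalytic_loop(
    hexapeptide: str, relaxed: bool = False
) -> CatalyticLoopLabel:
    """Classify an ePK catalytic-loop hexapeptide (subdomain VIb).

    Strict (default) rules are exact consensus matches: DLKPEN -> Ser/Thr,
    DLRAAN / DLAARN -> Tyr, DLKPDN -> Ser/Thr dual-specificity candidate.
    With ``relaxed=True`` any DLKxxN loop (lysine at position 3 being the
    Ser/Thr indicator) maps to Ser/Thr unless it is the known dual loop.
    """
    if len(hexapeptide) != 6:
        raise ValueError(f"catalytic loop must be 6 residues, got {len(hexapeptide)}")
    hexapeptide = hexapeptide.upper()
    if hexapeptide == _DUAL_LOOP:
        return CatalyticLoopLabel.SER_THR_DUAL_CANDIDATE
    if hexapeptide == _SER_THR_LOOP:
        return CatalyticLoopLabel.SER_THR
    if hexapeptide in _TYR_LOOPS:
        return CatalyticLoopLabel.TYR
    if relaxed and hexapeptide.startswith("DLK") and hexapeptide.endswith("N"):
        return CatalyticLoopLabel.SER_THR
    return CatalyticLoopLabel.UNCLASSIFIED


# ---------------------------------------------------------------------------
# Motif library file support (name, pattern, family, source)


def load_motif_library(path: str | Path) -> dict[str, MotifPattern]:
    """Load a user-extensible motif library TSV: name, pattern, family, source."""
    motifs: dict[str, MotifPattern] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["name", "pattern"]:
            raise ValueError(f"{path}: expected columns name, pattern, ...")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name, pattern_text = fields[0], fields[1]
            motifs[name] = compile_pattern(pattern_text, name)
    return motifs


def default_motif_library_path() -> Path:
    return Path(__file__).parent / "data" / "motifs.tsv"


def scan_many(
    sequences: Iterable[tuple[str, str]], motifs: dict[str, MotifPattern]
) -> list[tuple[str, MotifHit]]:
    """Scan multiple (id, sequence) records with a motif library."""
    out: list[tuple[str, MotifHit]] = []
    for sid, seq in sequences:
        for pat in motifs.values():
            for hit in scan(seq, pat):
                out.append((sid, hit))
    return out
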