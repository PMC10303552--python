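"""PROSITE-style motif compilation and matching, and the ESI-motif modes.

The motif dialect is the minimal PROSITE subset the triage heuristics need:
fixed residues (``E``), residue classes (``[ED]``), the wildcard ``X``, and
wildcard repeats ``X(n)`` / bounded ``X(n,m)``, joined by ``-``.  Exclusion
classes, anchors and repeats of non-wildcard elements are deliberately not
supported; keeping the dialect small keeps the matcher fully checkable
against brute force.

The ESI motif is the conserved tripeptide in the first β-strand of
Ugi/SAUGI-type Ung inhibitors — the strand that docks into the Ung
DNA-binding cleft.  Position 1 is an invariant glutamate.  Position 2
tolerates [ASVFHTNI] across natural variants; position 3 tolerates [LVIFMT]
naturally, extended to [LVIFMTPWC] once functionally verified synthetic
variants are admitted.  Four scanning modes arise from crossing
strict/lenient position-2 with natural/synthetic position-3.

An ``X`` in the *sequence* (an ambiguous residue) matches only wildcard
pattern elements — it cannot be asserted to belong to any residue class.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ProsPattern",
    "PatternElement",
    "MotifHit",
    "EsiMode",
    "PatternSyntaxError",
    "compile_prosite",
    "find_matches",
    "has_esi_motif",
    "find_esi_motifs",
    "derive_position_classes",
    "ESI_POS1",
    "ESI_POS2_STRICT",
    "ESI_POS3_NATURAL",
    "ESI_POS3_SYNTHETIC",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ESI_POS1 = frozenset("E")
ESI_POS2_STRICT = frozenset("ASVFHTNI")
ESI_POS2_LENIENT = frozenset(AMINO_ACIDS)
ESI_POS3_NATURAL = frozenset("LVIFMT")
ESI_POS3_SYNTHETIC = frozenset("LVIFMTPWC")


class PatternSyntaxError(ValueError):
    """Raised for a malformed PROSITE-style pattern, with position info."""


@dataclass(frozen=True)
class PatternElement:
    """One element: a residue class (possibly singleton) or an X repeat."""

    residues: frozenset[str] | None  # None for wildcard
    min_rep: int = 1
    max_rep: int = 1

    @property
    def is_wildcard(self) -> bool:
        return self.residues is None

    def serialize(self) -> str:
        if self.is_wildcard:
            if (self.min_rep, self.max_rep) == (1, 1):
                return "X"
            if self.min_rep == self.max_rep:
                return f"X({self.min_rep})"
            return f"X({self.min_rep},{self.max_rep})"
        res = "".join(sorted(self.residues))
        return res if len(res) == 1 else f"[{res}]"

    def admits(self, aa: str) -> bool:
        if self.is_wildcard:
            return True
        # an ambiguous sequence residue never satisfies a class or fixed element
        return aa in self.residues


@dataclass(frozen=True)
class ProsPattern:
    """A compiled PROSITE-style pattern."""

    source: str
    elements: tuple[PatternElement, ...]

    def serialize(self) -> str:
        return "-".join(e.serialize() for e in self.elements)

    @property
    def min_length(self) -> int:
        return sum(e.min_rep for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_rep for e in self.elements)


@dataclass(frozen=True)
class MotifHit:
    """A pattern match: 1-based inclusive residue coordinates."""

    start: int
    end: int
    matched: str


_TOKEN = re.compile(
    r"""
    \[(?P<cls>[A-WYZ]*)\]            |   # residue class (no X inside)
    (?P<x>[Xx])(\((?P<n>\d+)(,(?P<m>\d+))?\))?  |   # wildcard w/ repeat
    (?P<fix>[A-WYZa-wyz])                # fixed residue
    """,
    re.VERBOSE,
)


def compile_prosite(pattern: str) -> ProsPattern:
    """Compile a PROSITE-style pattern string.

    Supported: fixed residues, ``[classes]``, ``X``, ``X(n)``, ``X(n,m)``,
    ``-`` separators, optional whitespace, an optional trailing ``.``.
    """
    stripped = pattern.strip().rstrip(".")
    if not stripped:
        raise PatternSyntaxError("empty pattern")
    elements: list[PatternElement] = []
    for pos, token in enumerate(t.strip() for t in stripped.split("-")):
        if not token:
            raise PatternSyntaxError(f"empty element at position {pos + 1}")
        m = _TOKEN.fullmatch(token)
        if m is None:
            raise PatternSyntaxError(
                f"unrecognised token {token!r} at element {pos + 1}"
            )
        if m.group("cls") is not None:
            cls = m.group("cls").upper()
            if not cls:
                raise PatternSyntaxError(f"empty class at element {pos + 1}")
            bad = set(cls) - set(AMINO_ACIDS)
            if bad:
                raise PatternSyntaxError(
                    f"invalid residue(s) {sorted(bad)!r} in class at element {pos + 1}"
                )
            elements.append(PatternElement(residues=frozenset(cls)))
        elif m.group("x") is not None:
            n = int(m.group("n")) if m.group("n") else 1
            mm = int(m.group("m")) if m.group("m") else n
            if mm < n:
                raise PatternSyntaxError(
                    f"bad repeat bounds ({n},{mm}) at element {pos + 1}: max < min"
                )
            elements.append(PatternElement(residues=None, min_rep=n, max_rep=mm))
        else:
            fix = m.group("fix").upper()
            if fix not in AMINO_ACIDS:
                raise PatternSyntaxError(
                    f"invalid residue {fix!r} at element {pos + 1}"
                )
            elements.append(PatternElement(residues=frozenset(fix)))
    return ProsPattern(source=pattern, elements=tuple(elements))


def _match_lengths(elements: Sequence[PatternElement], seq: str, i: int) -> set[int]:
    """All total lengths with which elements match seq starting at index i."""
    if not elements:
        return {0}
    head, rest = elements[0], elements[1:]
    lengths: set[int] = set()
    if head.is_wildcard:
        for k in range(head.min_rep, head.max_rep + 1):
            if i + k > len(seq):
                break
            for tail in _match_lengths(rest, seq, i + k):
                lengths.add(k + tail)
    else:
        if i < len(seq) and head.admits(seq[i]):
            for tail in _match_lengths(rest, seq, i + 1):
                lengths.add(1 + tail)
    return lengths


def find_matches(pattern: ProsPattern, seq: str) -> list[MotifHit]:
    """All matches of a compiled pattern at all start positions.

    For variable-length patterns every (start, length) combination that
    matches is reported.  Hits are ordered by start, then end.
    """
    hits: list[MotifHit] = []
    n = len(seq)
    min_len = pattern.min_length
    for i in range(n - min_len + 1):
        for total in sorted(_match_lengths(pattern.elements, seq, i)):
            if total == 0:
                continue  # a fully-optional pattern matching nothing is noise
            hits.append(MotifHit(start=i + 1, end=i + total, matched=seq[i : i + total]))
    return hits


class EsiMode(enum.Enum):
    """ESI-motif leniency modes: (position-2 class, position-3 class)."""

    STRICT_NATURAL = "strict_natural"
    LENIENT_NATURAL = "lenient_natural"
    STRICT_SYNTHETIC = "strict_synthetic"
    LENIENT_SYNTHETIC = "lenient_synthetic"

    @property
    def pos2_class(self) -> frozenset[str]:
        return ESI_POS2_STRICT if self.value.startswith("strict") else ESI_POS2_LENIENT

    @property
    def pos3_class(self) -> frozenset[str]:
        return (
            ESI_POS3_NATURAL if self.value.endswith("natural") else ESI_POS3_SYNTHETIC
        )

    def pattern(self) -> ProsPattern:
        """The mode rendered as a compiled three-element pattern."""
        p2 = "X" if self.pos2_class == ESI_POS2_LENIENT else f"[{''.join(sorted(self.pos2_class))}]"
        p3 = f"[{''.join(sorted(self.pos3_class))}]"
        return compile_prosite(f"E-{p2}-{p3}")

    def implies(self, other: "EsiMode") -> bool:
        """True if a hit under self is necessarily a hit under other."""
        return self.pos2_class <= other.pos2_class and self.pos3_class <= other.pos3_class


def find_esi_motifs(seq: str, mode: EsiMode = EsiMode.STRICT_NATURAL) -> list[MotifHit]:
    """All ESI-motif occurrences in a sequence under the given mode."""
    return find_matches(mode.pattern(), seq)


def has_esi_motif(seq: str, mode: EsiMode = EsiMode.STRICT_NATURAL) -> bool:
    """Whether any position carries an ESI motif under the given mode."""
    pos2, pos3 = mode.pos2_class, mode.pos3_class
    # lenient position 2 is a true wildcard: it admits even an ambiguous X
    wild2 = pos2 == ESI_POS2_LENIENT
    for i in range(len(seq) - 2):
        if seq[i] == "E" and (wild2 or seq[i + 1] in pos2) and seq[i + 2] in pos3:
            return True
    return False


def derive_position_classes(motifs: Iterable[str]) -> ProsPattern:
    """Union the residues observed at each position of equal-length motifs
    into a PROSITE-style pattern (singleton sets render as fixed residues)."""
    motifs = list(motifs)
    if not motifs:
        raise ValueError("need at least one motif")
    length = len(motifs[0])
    if any(len(m) != length for m in motifs):
        raise ValueError("motifs must all have the same length")
    elements = tuple(
        PatternElement(residues=frozenset(m[i] for m in motifs)) for i in range(length)
    )
    pattern = ProsPattern(source="<derived>", elements=elements)
    return pattern
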