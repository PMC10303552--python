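"""Comparative statistics on pre-aligned sequence pairs.

Ung-inhibitor homologs conserve their fold and Ung-binding chemistry at
very low sequence identity, so the interesting quantities are small counts
over aligned columns: how many positions are literally identical, and how
many carry an acidic residue (D or E) in both sequences — the class-level
conservation behind the DNA-phosphate mimicry.

Alignments are consumed, never computed.  The reference alignments for
these proteins are structure-based (derived from crystal complexes), and
recomputing them with a sequence aligner would silently change every
count; supply the alignment you mean.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AlignedPair",
    "identical_positions",
    "shared_acidic_positions",
    "percent_identity",
]

_GAP = "-"
_ACIDIC = frozenset("DE")


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length aligned protein strings ('-' marks gaps)."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if not self.a or len(self.a) != len(self.b):
            raise ValueError(
                f"aligned sequences must be equal non-zero length "
                f"(got {len(self.a)} and {len(self.b)})"
            )


def _as_pair(pair_or_a, b=None) -> AlignedPair:
    if b is not None:
        return AlignedPair(pair_or_a, b)
    return pair_or_a


def identical_positions(pair_or_a, b: str | None = None) -> int:
    """Count columns where both sequences carry the same residue (gaps never
    count as identical)."""
    pair = _as_pair(pair_or_a, b)
    return sum(
        1 for x, y in zip(pair.a, pair.b) if x == y and x != _GAP
    )


def shared_acidic_positions(pair_or_a, b: str | None = None) -> int:
    """Count columns where both sequences carry an acidic residue (D or E),
    not necessarily the same one."""
    pair = _as_pair(pair_or_a, b)
    return sum(1 for x, y in zip(pair.a, pair.b) if x in _ACIDIC and y in _ACIDIC)


def percent_identity(pair_or_a, b: str | None = None) -> float:
    """Identical positions over columns ungapped in both sequences."""
    pair = _as_pair(pair_or_a, b)
    comparable = sum(1 for x, y in zip(pair.a, pair.b) if x != _GAP and y != _GAP)
    if comparable == 0:
        raise ValueError("no comparable (ungapped-in-both) columns")
    return identical_positions(pair) / comparable
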