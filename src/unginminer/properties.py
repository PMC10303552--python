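"""Physicochemical attributes used by the triage heuristics.

The filter cascade scores each putative protein on composition-level
attributes that characterise DNA-mimicking Ung inhibitors: they are small
(~9.5-13 kDa), strongly acidic (high D+E content, few K/R), hydrophilic
(negative GRAVY), and carry a characteristic glycine/proline content.
All attributes are composition-based, hence invariant under residue
permutation.

Conventions:

* acidic = {D, E}; basic = {K, R}.  Histidine is excluded from both: it is
  mostly uncharged at cytoplasmic pH and the published acidic-residue
  counts for the reference inhibitors are consistent with D+E only.
* GRAVY is the mean Kyte-Doolittle hydropathy; ``X`` residues are excluded
  from the mean (an ambiguous residue has no defensible hydropathy).
* Molecular mass uses average isotopic residue masses plus one water;
  ``X`` contributes the mean residue mass, 110 Da.
* ``acid_base_ratio`` returns ``inf`` when there are no basic residues:
  the filters select strongly acidic proteins with a "ratio >= r" test,
  which a basic-residue-free protein must pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from Bio.Data.IUPACData import protein_weights

__all__ = [
    "PropertyVector",
    "gc_content",
    "gravy",
    "molecular_mass",
    "count_acidic",
    "count_basic",
    "property_vector",
    "KYTE_DOOLITTLE",
]

_WATER = 18.0153
#: Average residue masses (free amino acid minus one water).
_RESIDUE_MASS = {aa: w - _WATER for aa, w in protein_weights.items()}
_X_MASS = 110.0

_ACIDIC = frozenset("DE")
_BASIC = frozenset("KR")


@dataclass(frozen=True)
class PropertyVector:
    """The heuristic attributes of one protein."""

    length: int
    gravy: float
    acidic_count: int
    basic_count: int
    acid_base_ratio: float  # inf when basic_count == 0
    de_fraction: float
    glypro_fraction: float
    mass_da: float

    def as_dict(self) -> dict[str, float]:
        return {
            "length": self.length,
            "gravy": self.gravy,
            "acidic_count": self.acidic_count,
            "basic_count": self.basic_count,
            "acid_base_ratio": self.acid_base_ratio,
            "de_fraction": self.de_fraction,
            "glypro_fraction": self.glypro_fraction,
            "mass_da": self.mass_da,
        }


def gc_content(seq: str) -> float:
    """G+C fraction among unambiguous A/C/G/T positions.

    Ambiguity codes are excluded from both numerator and denominator;
    an empty or all-ambiguous sequence is an error.
    """
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T positions")
    return gc / (gc + at)


def count_acidic(seq: str) -> int:
    """Number of aspartate + glutamate residues."""
    return sum(1 for aa in seq if aa in _ACIDIC)


def count_basic(seq: str) -> int:
    """Number of lysine + arginine residues (histidine excluded)."""
    return sum(1 for aa in seq if aa in _BASIC)


def gravy(seq: str) -> float:
    """Grand average of hydropathy (Kyte-Doolittle), X residues excluded."""
    values = [KYTE_DOOLITTLE[aa] for aa in seq if aa != "X"]
    if not values:
        raise ValueError("cannot compute GRAVY: no unambiguous residues")
    # fsum: exactly-rounded, hence invariant under residue permutation
    return math.fsum(values) / len(values)


def molecular_mass(seq: str) -> float:
    """Average-isotopic molecular mass in Daltons (chain + one water)."""
    if not seq:
        raise ValueError("mass of an empty sequence is undefined")
    return math.fsum(_X_MASS if aa == "X" else _RESIDUE_MASS[aa] for aa in seq) + _WATER


def property_vector(seq: str) -> PropertyVector:
    """Compute all heuristic attributes for one protein sequence."""
    if not seq:
        raise ValueError("cannot compute properties of an empty sequence")
    if "*" in seq:
        raise ValueError("sequence contains a stop marker '*'")
    acidic = count_acidic(seq)
    basic = count_basic(seq)
    n = len(seq)
    return PropertyVector(
        length=n,
        gravy=gravy(seq),
        acidic_count=acidic,
        basic_count=basic,
        acid_base_ratio=(acidic / basic) if basic else math.inf,
        de_fraction=acidic / n,
        glypro_fraction=sum(1 for aa in seq if aa in "GP") / n,
        mass_da=molecular_mass(seq),
    )
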