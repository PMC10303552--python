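"""Seeded synthetic phage-like genomes for end-to-end testing.

Verified Ugi-type inhibitors come from AT-rich (25-30% GC) uracil-DNA
phage genomes, so the generator emulates that regime: i.i.d. nucleotide
background at a controlled GC fraction, with protein-coding cassettes
spliced in.  Each cassette is stop-flanked — stop codon, coding sequence,
stop codon — so the extraction stage recovers the embedded protein
exactly, making recovery assertions exact rather than probabilistic.

Reverse translation picks, per residue, the synonymous codon whose GC
fraction is closest to the genome's target (ties broken lexicographically).
Codon-usage realism is irrelevant here; what matters is GC control and
exact re-translation.

Decoy proteins come in three violation profiles, checked on emission:

* ``motif-less`` — no ESI motif under any mode;
* ``lenient-only`` — an ESI motif under the lenient modes but none under
  the strict modes;
* ``property-violating`` — a strict-natural ESI motif, but basic and
  hydrophobic composition that the calibrated property filters reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from Bio.Data.CodonTable import standard_dna_table

from .io import GenomeRecord
from .motifs import EsiMode, has_esi_motif
from .orfs import reverse_complement
from .properties import count_acidic

__all__ = [
    "EmbedSpec",
    "SyntheticSpec",
    "random_genome",
    "reverse_translate",
    "embed_orf",
    "make_decoys",
    "synthesize",
]

_BASES = np.array(list("ACGT"))

_STOPS = tuple(sorted(standard_dna_table.stop_codons))  # TAA, TAG, TGA


def _gc_frac(codon: str) -> float:
    return sum(1 for b in codon if b in "GC") / 3.0


def _codon_choices() -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for codons in by_aa.values():
        codons.sort()
    return by_aa


_SYNONYMS = _codon_choices()


def random_genome(length: int, gc_target: float, seed: int) -> GenomeRecord:
    """An i.i.d. random genome with P(G)=P(C)=gc_target/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc_target < 1.0:
        raise ValueError(f"gc_target must be in (0, 1), got {gc_target}")
    rng = np.random.default_rng(seed)
    p_gc = gc_target / 2.0
    p_at = (1.0 - gc_target) / 2.0
    seq = "".join(rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at]))
    return GenomeRecord(id=f"synth_{seed}", seq=seq,
                        description=f"synthetic genome gc_target={gc_target}")


def _nearest_gc(codons: Sequence[str], gc_target: float) -> str:
    return min(codons, key=lambda c: (abs(_gc_frac(c) - gc_target), c))


def reverse_translate(protein: str, gc_target: float) -> str:
    """Encode a protein choosing, per residue, the GC-nearest synonymous codon."""
    bad = set(protein) - set(_SYNONYMS)
    if bad:
        raise ValueError(
            f"cannot reverse-translate residue(s) {sorted(bad)!r} "
            "(only the 20 standard residues are encodable)"
        )
    return "".join(_nearest_gc(_SYNONYMS[aa], gc_target) for aa in protein)


def _cassette(protein: str, strand: str, gc_target: float) -> str:
    stop = _nearest_gc(_STOPS, gc_target)
    nt = stop + reverse_translate(protein, gc_target) + stop
    return nt if strand == "+" else reverse_complement(nt)


def embed_orf(
    genome: GenomeRecord,
    protein: str,
    position: int,
    strand: Literal["+", "-"] = "+",
    gc_target: float = 0.3,
    occupied: list[tuple[int, int]] | None = None,
) -> GenomeRecord:
    """Splice a stop-flanked coding cassette into a genome, overwriting.

    ``position`` is the 0-based offset of the cassette (stop codon
    included).  ``occupied`` is an optional caller-held registry of
    (start, end) half-open intervals; overlap with a registered interval
    is an error, and the new interval is appended.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    cassette = _cassette(protein, strand, gc_target)
    end = position + len(cassette)
    if position < 0 or end > len(genome.seq):
        raise ValueError(
            f"cassette [{position}, {end}) does not fit in a {len(genome.seq)} nt genome"
        )
    if occupied is not None:
        for lo, hi in occupied:
            if position < hi and lo < end:
                raise ValueError(
                    f"cassette [{position}, {end}) overlaps embedded ORF [{lo}, {hi})"
                )
        occupied.append((position, end))
    seq = genome.seq[:position] + cassette + genome.seq[end:]
    return GenomeRecord(id=genome.id, seq=seq, description=genome.description)


def _cds_coords(position: int, aa_len: int, strand: str, genome_len: int):
    """Forward-strand 1-based CDS coordinates and frame label for a cassette
    embedded at ``position``."""
    nt_start = position + 4  # skip the leading stop codon
    nt_end = position + 3 + 3 * aa_len
    if strand == "+":
        frame = f"+{(nt_start - 1) % 3 + 1}"
    else:
        frame = f"-{(genome_len - nt_end) % 3 + 1}"
    return nt_start, nt_end, frame


_DECOY_PROFILES = ("motif-less", "lenient-only", "property-violating")

# residues that can never be part of an ESI motif at any position except pos2
_NEUTRAL = "K"


def _scrub_lenient_synthetic(seq: list[str]) -> None:
    """Remove every lenient-synthetic ESI hit by overwriting position 3 with
    a residue outside all position-3 classes (K, which also cannot seed a
    new motif as position 1)."""
    pos3 = EsiMode.LENIENT_SYNTHETIC.pos3_class
    for i in range(len(seq) - 2):
        if seq[i] == "E" and seq[i + 2] in pos3:
            seq[i + 2] = _NEUTRAL


def make_decoys(
    n: int,
    seed: int,
    profile: Literal["motif-less", "lenient-only", "property-violating"] = "motif-less",
) -> list[str]:
    """Generate decoy proteins of 40-200 residues in a violation profile.

    Profile compliance is asserted on emission.
    """
    if profile not in _DECOY_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {_DECOY_PROFILES}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    pool = np.array(list("ADEFGHIKLMNPQRSTVWYC"))
    basic_pool = np.array(list("KRLIVSTGAW"))
    decoys: list[str] = []
    for _ in range(n):
        length = int(rng.integers(40, 201))
        if profile == "property-violating":
            seq = ["M"] + list(rng.choice(basic_pool, size=length - 1))
            j = int(rng.integers(1, length - 3))
            seq[j : j + 3] = list("ESI")
            # the single motif glutamate is the only acidic residue
            s = "".join(seq)
            assert has_esi_motif(s, EsiMode.STRICT_NATURAL)
            assert count_acidic(s) / length < 0.05
        else:
            # start with an M so decoys survive start-trimming intact
            seq = ["M"] + list(rng.choice(pool, size=length - 1))
            _scrub_lenient_synthetic(seq)
            if profile == "lenient-only":
                j = int(rng.integers(1, length - 3))
                pos2 = str(rng.choice(list("GKRDQYWCPML")))
                pos3 = str(rng.choice(sorted(EsiMode.LENIENT_NATURAL.pos3_class)))
                seq[j : j + 3] = ["E", pos2, pos3]
            s = "".join(seq)
            if profile == "motif-less":
                assert not has_esi_motif(s, EsiMode.LENIENT_SYNTHETIC)
            else:
                assert has_esi_motif(s, EsiMode.LENIENT_NATURAL)
                assert not has_esi_motif(s, EsiMode.STRICT_SYNTHETIC)
        decoys.append(s)
    return decoys


@dataclass(frozen=True)
class EmbedSpec:
    """One protein to embed: strand and position may be left for auto-placement."""

    protein_id: str
    seq: str
    strand: Literal["+", "-"] = "+"
    position: int | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    """A complete synthetic-genome recipe."""

    genome_length: int = 50_000
    gc_target: float = 0.28
    seed: int = 0
    embeds: tuple[EmbedSpec, ...] = ()
    decoy_count: int = 0
    decoy_profile: str = "motif-less"

    def __post_init__(self) -> None:
        need = sum(3 * len(e.seq) + 6 for e in self.embeds)
        if self.genome_length < need + 100:
            raise ValueError(
                f"genome_length {self.genome_length} too short for "
                f"{need} nt of embedded cassettes plus flanks"
            )


def synthesize(spec: SyntheticSpec) -> tuple[GenomeRecord, pd.DataFrame]:
    """Build the genome a spec describes and its ground-truth table.

    Embedded positives come first, then ``decoy_count`` decoys of the
    requested profile, all spliced in at evenly spaced non-overlapping
    positions (explicit positions in an :class:`EmbedSpec` are honoured).
    Returns the genome and a truth table with one row per embedded ORF
    (id, kind, strand, frame, nt_start, nt_end, aa sequence).
    """
    rng = np.random.default_rng(spec.seed)
    genome = random_genome(spec.genome_length, spec.gc_target, spec.seed)
    decoys = make_decoys(spec.decoy_count, seed=spec.seed + 1, profile=spec.decoy_profile)
    items: list[tuple[str, str, str, str, int | None]] = [
        (e.protein_id, "positive", e.seq, e.strand, e.position) for e in spec.embeds
    ] + [
        (f"decoy_{spec.decoy_profile}_{i}", "decoy", seq, "+" if i % 2 == 0 else "-", None)
        for i, seq in enumerate(decoys)
    ]
    occupied: list[tuple[int, int]] = []
    rows = []
    n_auto = sum(1 for it in items if it[4] is None)
    slot = spec.genome_length // max(n_auto + 1, 1)
    auto_i = 0
    for pid, kind, seq, strand, position in items:
        if position is None:
            auto_i += 1
            position = auto_i * slot - (3 * len(seq) + 6) // 2
        genome = embed_orf(
            genome, seq, position, strand=strand, gc_target=spec.gc_target,
            occupied=occupied,
        )
        nt_start, nt_end, frame = _cds_coords(position, len(seq), strand, spec.genome_length)
        rows.append(
            {
                "protein_id": pid,
                "kind": kind,
                "strand": strand,
                "frame": frame,
                "nt_start": nt_start,
                "nt_end": nt_end,
                "aa_seq": seq,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["protein_id", "kind", "strand", "frame", "nt_start", "nt_end", "aa_seq"],
    )
    return genome, truth
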