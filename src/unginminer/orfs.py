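"""Six-frame translation and putative-polypeptide extraction.

A phage genome is translated in all six reading frames with the standard
genetic code, every stop-delimited segment is taken as a putative
polypeptide, its N-terminus is trimmed to the first valid start residue
(M, I, V or L — the residues encoded by the common bacterial initiation
codons), and segments shorter than a minimum length (default 40 residues)
are discarded.  No ribosome-binding-site or gene-model evidence is used:
the point is an exhaustive, annotation-free sweep of everything a genome
could express.

Coordinates on emitted proteins are 1-based inclusive forward-strand
nucleotide positions spanning the codons of the reported amino-acid
sequence, so that re-translating ``genome[nt_start..nt_end]`` (reverse
complemented first for minus frames) reproduces the protein exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values

from .io import DNA_ALPHABET, GenomeRecord

__all__ = [
    "Frame",
    "FRAMES",
    "START_RESIDUES",
    "TranslatedFrame",
    "PutativeProtein",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
    "extract_putative_proteins",
    "count_putative_proteins",
]

Frame = Literal["+1", "+2", "+3", "-1", "-2", "-3"]
FRAMES: tuple[Frame, ...] = ("+1", "+2", "+3", "-1", "-2", "-3")

#: Valid start residues: M (ATG), plus I/V/L for the alternative initiation
#: codons ATT/ATC/ATA, GTG and TTG/CTG used by bacteria and their phages.
START_RESIDUES = frozenset("MIVL")

_COMPLEMENT = str.maketrans(
    {k: v for k, v in ambiguous_dna_complement.items()}
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (ambiguity-code aware)."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def _build_codon_map() -> dict[str, str]:
    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_CODONS = _build_codon_map()


@lru_cache(maxsize=4096)
def _translate_codon(codon: str) -> str:
    """Translate one codon; ambiguity codes are expanded and the codon is
    emitted as the shared residue when every expansion agrees, else 'X'."""
    aa = _CODONS.get(codon)
    if aa is not None:
        return aa
    residues = set()
    for b1 in ambiguous_dna_values[codon[0]]:
        for b2 in ambiguous_dna_values[codon[1]]:
            for b3 in ambiguous_dna_values[codon[2]]:
                residues.add(_CODONS[b1 + b2 + b3])
                if len(residues) > 1:
                    return "X"
    return residues.pop()


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading frame of a genome, translated ('*' marks stops)."""

    genome_id: str
    frame: Frame
    peptide: str


@dataclass(frozen=True)
class PutativeProtein:
    """A stop-delimited, start-trimmed translated segment with provenance."""

    genome_id: str
    frame: Frame
    aa_seq: str
    nt_start: int  # 1-based inclusive, forward strand
    nt_end: int  # 1-based inclusive, forward strand
    trimmed_prefix_len: int = 0

    @property
    def id(self) -> str:
        return f"{self.genome_id}|{self.frame}|{self.nt_start}-{self.nt_end}"

    def __len__(self) -> int:
        return len(self.aa_seq)


def translate_frame(nt: str) -> str:
    """Translate a nucleotide string in frame +1, dropping trailing 1-2 nt."""
    n = len(nt) - len(nt) % 3
    return "".join(_translate_codon(nt[i : i + 3]) for i in range(0, n, 3))


def six_frame_translate(genome: GenomeRecord) -> list[TranslatedFrame]:
    """Translate a genome in all six reading frames.

    Frames +1..+3 are the forward strand at offsets 0..2; frames -1..-3 are
    the reverse complement at offsets 0..2.
    """
    if len(genome.seq) < 3:
        raise ValueError(
            f"genome {genome.id!r} is shorter than one codon ({len(genome.seq)} nt)"
        )
    fwd, rev = genome.seq, reverse_complement(genome.seq)
    frames = []
    for label, strand_seq in (("+", fwd), ("-", rev)):
        for offset in range(3):
            frames.append(
                TranslatedFrame(
                    genome_id=genome.id,
                    frame=f"{label}{offset + 1}",  # type: ignore[arg-type]
                    peptide=translate_frame(strand_seq[offset:]),
                )
            )
    return frames


def _segments(peptide: str) -> Iterable[tuple[int, str]]:
    """Yield (start index in peptide, segment) for stop-delimited segments.

    The leading segment (before the first stop) and trailing segment (after
    the last stop) are included: a gene running off the edge of a linear
    genome record is still a gene.
    """
    start = 0
    for i, aa in enumerate(peptide):
        if aa == "*":
            if i > start:
                yield start, peptide[start:i]
            start = i + 1
    if len(peptide) > start:
        yield start, peptide[start:]


def _map_coords(frame: Frame, pep_start: int, aa_len: int, genome_len: int) -> tuple[int, int]:
    """Map a peptide slice [pep_start, pep_start+aa_len) to 1-based inclusive
    forward-strand nucleotide coordinates."""
    offset = int(frame[1]) - 1
    if frame[0] == "+":
        nt_start = offset + 3 * pep_start + 1
        nt_end = offset + 3 * (pep_start + aa_len)
    else:
        nt_start = genome_len - offset - 3 * (pep_start + aa_len) + 1
        nt_end = genome_len - offset - 3 * pep_start
    return nt_start, nt_end


def extract_putative_proteins(
    frames: Iterable[TranslatedFrame],
    genome: GenomeRecord,
    min_len: int = 40,
    length_check: Literal["post_trim", "pre_trim"] = "post_trim",
) -> list[PutativeProtein]:
    """Extract putative polypeptides from six translated frames.

    Each stop-delimited segment is trimmed to its first residue in
    ``START_RESIDUES``; segments with no start residue are dropped.  With
    ``length_check="post_trim"`` (default, the stricter reading) the minimum
    length applies to the trimmed protein; with ``"pre_trim"`` it applies to
    the raw stop-to-stop segment and the trimmed protein is kept whatever
    its remaining length.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if length_check not in ("post_trim", "pre_trim"):
        raise ValueError(f"unknown length_check mode {length_check!r}")
    by_frame = {f.frame: f for f in frames}
    out: list[PutativeProtein] = []
    for frame in FRAMES:
        tf = by_frame.get(frame)
        if tf is None:
            continue
        if tf.genome_id != genome.id:
            raise ValueError(
                f"frame {frame} belongs to genome {tf.genome_id!r}, not {genome.id!r}"
            )
        hits: list[PutativeProtein] = []
        for seg_start, segment in _segments(tf.peptide):
            if length_check == "pre_trim" and len(segment) < min_len:
                continue
            trim = next(
                (i for i, aa in enumerate(segment) if aa in START_RESIDUES), None
            )
            if trim is None:
                continue
            aa_seq = segment[trim:]
            if length_check == "post_trim" and len(aa_seq) < min_len:
                continue
            nt_start, nt_end = _map_coords(
                frame, seg_start + trim, len(aa_seq), len(genome.seq)
            )
            hits.append(
                PutativeProtein(
                    genome_id=genome.id,
                    frame=frame,
                    aa_seq=aa_seq,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    trimmed_prefix_len=trim,
                )
            )
        hits.sort(key=lambda p: p.nt_start)
        out.extend(hits)
    return out


def count_putative_proteins(
    genome: GenomeRecord,
    min_len: int = 40,
    length_check: Literal["post_trim", "pre_trim"] = "post_trim",
) -> int:
    """Number of putative polypeptides a genome yields — the denominator of
    any 'k candidates out of N possible protein-coding sequences' statement."""
    return len(
        extract_putative_proteins(
            six_frame_translate(genome), genome, min_len=min_len, length_check=length_check
        )
    )
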