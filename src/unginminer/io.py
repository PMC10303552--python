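"""FASTA input/output with strict alphabet validation.

Genomes and proteins are plain records (id, description, seq). The id is the
first whitespace-delimited token of the FASTA header, following NCBI
convention, and must be unique within a file so that provenance strings built
from it stay unambiguous. Aligned FASTA (gap characters) is rejected here:
alignment handling lives in :mod:`unginminer.plasticity` and expects its own
inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "GenomeRecord",
    "ProteinRecord",
    "FastaError",
    "read_fasta_nt",
    "read_fasta_aa",
    "write_fasta",
    "DNA_ALPHABET",
    "PROTEIN_ALPHABET",
]

#: IUPAC nucleotide codes: the four bases plus ambiguity codes.
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: The 20 standard residues plus X (ambiguous) and '*' (stop, internal only).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}


class FastaError(ValueError):
    """Malformed FASTA content or an alphabet violation."""


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence with stable identity.

    ``seq`` is stored uppercase over the IUPAC DNA alphabet; RNA-style ``U``
    is normalised to ``T`` on load.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("genome record requires a non-empty id")
        if not self.seq:
            raise FastaError(f"genome record {self.id!r} has an empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq, 1) if c in bad)
            raise FastaError(
                f"record {self.id!r}: invalid nucleotide {self.seq[pos - 1]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence (20 standard residues plus X)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("protein record requires a non-empty id")
        if not self.seq:
            raise FastaError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq, 1) if c in bad)
            raise FastaError(
                f"record {self.id!r}: invalid residue {self.seq[pos - 1]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _split_header(header: str) -> tuple[str, str]:
    parts = header.split(None, 1)
    return parts[0], (parts[1] if len(parts) > 1 else "")


def _parse(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        text_started = False
        for line in handle:
            if line.strip():
                text_started = True
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: sequence data before the first '>' header"
                    )
                break
        handle.seek(0)
        if not text_started:
            raise FastaError(f"{path}: empty FASTA file")
        for header, seq in SimpleFastaParser(handle):
            rid, desc = _split_header(header)
            if rid in seen:
                raise FastaError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            out.append((rid, desc, seq))
    if not out:
        raise FastaError(f"{path}: no records found")
    return out


def read_fasta_nt(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a nucleotide FASTA file.

    Sequences are uppercased and ``U`` is converted to ``T``.  Raises
    :class:`FastaError` for malformed files, duplicate ids, or characters
    outside the IUPAC DNA alphabet.
    """
    records = []
    for rid, desc, seq in _parse(path):
        records.append(GenomeRecord(id=rid, description=desc, seq=seq.upper().replace("U", "T")))
    return records


def read_fasta_aa(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA file (uppercased; '*' is rejected)."""
    return [
        ProteinRecord(id=rid, description=desc, seq=seq.upper())
        for rid, desc, seq in _parse(path)
    ]


def write_fasta(
    records: Sequence[Union[GenomeRecord, ProteinRecord]],
    path: str | os.PathLike,
    width: int = 60,
) -> None:
    """Write records as FASTA with LF line endings.

    ``read(write(x))`` is the identity on (id, description, seq).  Records
    containing ``'*'`` are refused: stop markers must be stripped upstream.
    """
    if width < 1:
        raise ValueError("width must be a positive integer")
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    lines: list[str] = []
    for rec in records:
        if "*" in rec.seq:
            raise FastaError(
                f"record {rec.id!r} contains a stop marker '*'; strip stops "
                "before writing FASTA"
            )
        header = f">{rec.id} {rec.description}".rstrip()
        lines.append(header)
        for i in range(0, len(rec.seq), width):
            lines.append(rec.seq[i : i + width])
    with open(path, "w", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")


def records_from_strings(pairs: Iterable[tuple[str, str]], kind: str = "protein"):
    """Convenience: build records from (id, seq) pairs (mostly for tests)."""
    cls = ProteinRecord if kind == "protein" else GenomeRecord
    return [cls(id=i, seq=s) for i, s in pairs]
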