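"""Six-frame translation and putative-protein extraction, checked against a
brute-force oracle built directly on Bio.Seq translation."""

import re

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from unginminer.io import GenomeRecord
from unginminer.orfs import (
    FRAMES,
    START_RESIDUES,
    count_putative_proteins,
    extract_putative_proteins,
    reverse_complement,
    six_frame_translate,
    translate_frame,
)


# --- independent oracle -----------------------------------------------------

def oracle_proteins(seq: str, min_len: int) -> list[str]:
    """Enumerate putative proteins via Biopython translation + regex split."""
    out = []
    rc = str(Seq(seq).reverse_complement())
    for strand in (seq, rc):
        for off in range(3):
            sub = strand[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate())
            for segment in re.split(r"\*", pep):
                m = next((i for i, aa in enumerate(segment) if aa in "MIVL"), None)
                if m is None:
                    continue
                trimmed = segment[m:]
                if len(trimmed) >= min_len:
                    out.append(trimmed)
    return sorted(out)


# --- unit behaviour ---------------------------------------------------------

def test_reverse_complement_basics():
    assert reverse_complement("ATGC") == "GCAT"
    assert reverse_complement("AN") == "NT"
    with pytest.raises(ValueError):
        reverse_complement("AZ")


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=100))
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_translate_standard_code():
    assert translate_frame("ATGAAA") == "MK"
    assert translate_frame("ATGTAAATG") == "M*M"
    # frame -1 of ATGAAA is the translation of its reverse complement TTTCAT
    assert translate_frame(reverse_complement("ATGAAA")) == "FH"


def test_ambiguous_codons():
    assert translate_frame("GGN") == "G"  # all GGx encode glycine
    assert translate_frame("ANA") == "X"  # unresolvable
    assert translate_frame("TAR") == "*"  # TAA/TAG both stop


def test_six_frames_have_expected_lengths_and_labels(tiny_genome):
    frames = six_frame_translate(tiny_genome)
    assert [f.frame for f in frames] == list(FRAMES)
    n = len(tiny_genome.seq)
    for f in frames:
        offset = int(f.frame[1]) - 1
        assert len(f.peptide) == (n - offset) // 3


def test_too_short_genome_errors():
    with pytest.raises(ValueError):
        six_frame_translate(GenomeRecord(id="g", seq="AT"))


def test_trimming_and_provenance():
    # frame +1 peptide of this genome is GGMKLV; trimmed to MKLV
    genome = GenomeRecord(id="g", seq="GGTGGAATGAAACTTGTT")
    frames = six_frame_translate(genome)
    prots = extract_putative_proteins(frames, genome, min_len=3)
    p = next(p for p in prots if p.frame == "+1")
    assert p.aa_seq == "MKLV"
    assert p.trimmed_prefix_len == 2
    assert p.id == "g|+1|7-18"
    assert (p.nt_end - p.nt_start + 1) == 3 * len(p.aa_seq)


def test_segment_without_start_residue_discarded():
    # frame +1 translates to GGGG: no M/I/V/L anywhere
    genome = GenomeRecord(id="g", seq="GGAGGAGGAGGA")
    prots = extract_putative_proteins(six_frame_translate(genome), genome, min_len=1)
    assert all(p.frame != "+1" for p in prots)


def test_minimum_length_post_trim_discards():
    # 2-aa protein below min_len=3 is dropped, kept at min_len=2
    genome = GenomeRecord(id="g", seq="ATGAAATAA")
    assert count_putative_proteins(genome, min_len=3) < count_putative_proteins(
        genome, min_len=2
    )


def test_pre_trim_vs_post_trim_length_check():
    # frame +1: peptide GGGGGMK -> segment len 7, trimmed 'MK' len 2
    genome = GenomeRecord(id="g", seq="GGAGGAGGAGGAGGAATGAAA")
    frames = six_frame_translate(genome)
    post = extract_putative_proteins(frames, genome, min_len=5, length_check="post_trim")
    pre = extract_putative_proteins(frames, genome, min_len=5, length_check="pre_trim")
    assert all(p.frame != "+1" for p in post)
    assert any(p.frame == "+1" and p.aa_seq == "MK" for p in pre)


def test_tiny_genome_count_frozen(tiny_genome):
    # hand enumeration: +1 gives MK; -1 gives LFH; -3 gives IS; others none
    prots = extract_putative_proteins(
        six_frame_translate(tiny_genome), tiny_genome, min_len=2
    )
    assert sorted((p.frame, p.aa_seq) for p in prots) == [
        ("+1", "MK"),
        ("-1", "LFH"),
        ("-3", "IS"),
    ]
    assert count_putative_proteins(tiny_genome, min_len=2) == 3


# --- properties -------------------------------------------------------------

genomes = st.text(alphabet="ACGT", min_size=3, max_size=300)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(genomes, st.integers(min_value=1, max_value=8))
def test_equivalence_with_bruteforce_oracle(seq, min_len):
    genome = GenomeRecord(id="g", seq=seq)
    prots = extract_putative_proteins(six_frame_translate(genome), genome, min_len=min_len)
    assert sorted(p.aa_seq for p in prots) == oracle_proteins(seq, min_len)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(genomes)
def test_strand_symmetry(seq):
    g = GenomeRecord(id="g", seq=seq)
    rc = GenomeRecord(id="g", seq=reverse_complement(seq))
    fwd = extract_putative_proteins(six_frame_translate(g), g, min_len=1)
    rev = extract_putative_proteins(six_frame_translate(rc), rc, min_len=1)
    minus = sorted(p.aa_seq for p in fwd if p.frame.startswith("-"))
    plus = sorted(p.aa_seq for p in rev if p.frame.startswith("+"))
    assert minus == plus


@settings(derandomize=True, max_examples=40, deadline=None)
@given(genomes)
def test_emitted_proteins_satisfy_invariants(seq):
    g = GenomeRecord(id="g", seq=seq)
    for p in extract_putative_proteins(six_frame_translate(g), g, min_len=1):
        assert p.aa_seq[0] in START_RESIDUES
        assert "*" not in p.aa_seq
        assert (p.nt_end - p.nt_start + 1) == 3 * len(p.aa_seq)
        sub = g.seq[p.nt_start - 1 : p.nt_end]
        if p.frame.startswith("-"):
            sub = reverse_complement(sub)
        assert translate_frame(sub) == p.aa_seq


@settings(derandomize=True, max_examples=30, deadline=None)
@given(genomes, st.integers(min_value=1, max_value=10))
def test_min_len_monotonicity(seq, min_len):
    g = GenomeRecord(id="g", seq=seq)
    assert count_putative_proteins(g, min_len=min_len + 1) <= count_putative_proteins(
        g, min_len=min_len
    )
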