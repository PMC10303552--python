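"""Motif engine: parser contracts, matcher equivalence against an
independent regex oracle, and the ESI leniency lattice."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unginminer.motifs import (
    EsiMode,
    PatternElement,
    PatternSyntaxError,
    ProsPattern,
    compile_prosite,
    derive_position_classes,
    find_esi_motifs,
    find_matches,
    has_esi_motif,
)
from unginminer.reference import BETA1_LIBRARY_VARIANTS, LIBRARY1_CLONES


# --- parsing ----------------------------------------------------------------

def test_compile_p56_pattern():
    p = compile_prosite("E-X(2)-Y-X(0,2)-G")
    assert p.serialize() == "E-X(2)-Y-X(0,2)-G"
    assert (p.min_length, p.max_length) == (5, 7)


def test_compile_class_pattern_normalises():
    p = compile_prosite("E-X(6)-[ED]-[ED]")
    assert p.serialize() == "E-X(6)-[DE]-[DE]"


@pytest.mark.parametrize(
    "bad", ["E-X(1,0)", "", "E--G", "E-[∅]", "[]", "E-J", "E-[EJ]", "E-X(2", "1-2"]
)
def test_parse_errors(bad):
    with pytest.raises(PatternSyntaxError):
        compile_prosite(bad)


def test_compile_serialize_roundtrip_is_identity():
    for src in ("E-X(2)-Y-X(0,2)-G", "E-X(6)-[DE]-[DE]", "E-[AST]-[CIM]", "X(0,3)-E"):
        p = compile_prosite(src)
        assert compile_prosite(p.serialize()).serialize() == p.serialize() == src


# --- matching ---------------------------------------------------------------

def test_fixed_pattern_single_hit():
    p = compile_prosite("E-X(2)-Y-X(0,2)-G")
    hits = find_matches(p, "EAAYG")
    assert [(h.start, h.end, h.matched) for h in hits] == [(1, 5, "EAAYG")]


def test_acidic_pattern_hit():
    p = compile_prosite("E-X(6)-[ED]-[ED]")
    assert [(h.start, h.end) for h in find_matches(p, "EAAAAAADE")] == [(1, 9)]


def test_no_hits_without_leading_glutamate():
    p = compile_prosite("E-X(2)-Y-X(0,2)-G")
    assert find_matches(p, "AAAA") == []


def test_variable_length_reports_all_lengths():
    p = compile_prosite("E-X(0,2)-G")
    hits = find_matches(p, "EGG")
    assert [(h.start, h.end) for h in hits] == [(1, 2), (1, 3)]


def test_sequence_x_matches_only_wildcards():
    assert find_matches(compile_prosite("E-X-G"), "EXG")  # wildcard admits X
    assert not find_matches(compile_prosite("E-[GA]-G"), "EXG")  # class never
    assert not find_matches(compile_prosite("E-G-G"), "EXG")  # fixed never
    # X is the wildcard, not a residue: it cannot appear inside a class
    with pytest.raises(PatternSyntaxError):
        compile_prosite("E-[GX]-G")


# --- oracle equivalence -----------------------------------------------------

def regex_oracle(pattern: ProsPattern, seq: str):
    """Translate to a Python regex and enumerate all (start, length) pairs."""
    parts = []
    for e in pattern.elements:
        if e.is_wildcard:
            parts.append(f".{{{e.min_rep},{e.max_rep}}}")
        else:
            residues = "".join(sorted(e.residues))
            parts.append(f"[{residues}]" if len(residues) > 1 else residues)
    rx = re.compile("".join(parts))
    out = []
    for i in range(len(seq)):
        for L in range(max(pattern.min_length, 1), pattern.max_length + 1):
            if i + L <= len(seq) and rx.fullmatch(seq, i, i + L):
                out.append((i + 1, i + L))
    return sorted(out)


elements = st.one_of(
    st.sampled_from("ACDEFGHIKLMNPQRSTVWY").map(lambda r: r),
    st.sets(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=1, max_size=4).map(
        lambda s: "[" + "".join(sorted(s)) + "]"
    ),
    st.tuples(st.integers(0, 3), st.integers(0, 3)).map(
        lambda t: f"X({min(t)},{max(t)})"
    ),
)
patterns = st.lists(elements, min_size=1, max_size=6).map("-".join)


@settings(derandomize=True, max_examples=120, deadline=None)
@given(patterns, st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=50))
def test_matcher_equivalent_to_regex_oracle(src, seq):
    p = compile_prosite(src)
    mine = sorted((h.start, h.end) for h in find_matches(p, seq))
    assert mine == regex_oracle(p, seq)


# --- ESI modes --------------------------------------------------------------

def test_esi_mode_classes():
    assert EsiMode.STRICT_NATURAL.pos2_class == frozenset("ASVFHTNI")
    assert EsiMode.STRICT_NATURAL.pos3_class == frozenset("LVIFMT")
    assert EsiMode.LENIENT_SYNTHETIC.pos3_class == frozenset("LVIFMTPWC")


def test_known_heptapeptide_mode_membership():
    assert has_esi_motif("QEAMLML", EsiMode.STRICT_NATURAL)
    assert not has_esi_motif("QETCLML", EsiMode.STRICT_NATURAL)
    assert has_esi_motif("QETCLML", EsiMode.STRICT_SYNTHETIC)
    assert not has_esi_motif("PTRSIVK", EsiMode.LENIENT_SYNTHETIC)


def test_all_library_variants_pass_strict_synthetic():
    assert len(set(BETA1_LIBRARY_VARIANTS)) == 12
    for hepta in BETA1_LIBRARY_VARIANTS:
        assert has_esi_motif(hepta, EsiMode.STRICT_SYNTHETIC), hepta


def test_randomised_library_clones_fail_every_mode():
    for clone in LIBRARY1_CLONES:
        for mode in EsiMode:
            assert not has_esi_motif(clone, mode), (clone, mode)


@settings(derandomize=True, max_examples=150)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=0, max_size=60))
def test_mode_lattice_monotonicity(seq):
    # any hit implies a hit under every more lenient mode
    for mode in EsiMode:
        if has_esi_motif(seq, mode):
            assert has_esi_motif(seq, EsiMode.LENIENT_SYNTHETIC)
    if has_esi_motif(seq, EsiMode.STRICT_NATURAL):
        assert has_esi_motif(seq, EsiMode.LENIENT_NATURAL)
        assert has_esi_motif(seq, EsiMode.STRICT_SYNTHETIC)


@settings(derandomize=True, max_examples=80)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=60),
       st.sampled_from(list(EsiMode)))
def test_has_esi_agrees_with_pattern_matcher(seq, mode):
    assert has_esi_motif(seq, mode) == bool(find_esi_motifs(seq, mode))


# --- class derivation -------------------------------------------------------

def test_derive_position_classes():
    p = derive_position_classes(["ESI", "EAM", "ETC"])
    assert p.serialize() == "E-[AST]-[CIM]"
    assert derive_position_classes(["ESI"]).serialize() == "E-S-I"


def test_derive_errors():
    with pytest.raises(ValueError):
        derive_position_classes([])
    with pytest.raises(ValueError):
        derive_position_classes(["ESI", "ES"])


def test_natural_esi_classes_recovered_from_library():
    # the motif positions 2-4 of the shuffling-library heptapeptides all fall
    # inside the strict-synthetic position classes
    tripeptides = {h[1:4] for h in BETA1_LIBRARY_VARIANTS}
    derived = derive_position_classes(sorted(tripeptides))
    assert derived.elements[0].residues == frozenset("E")
    assert derived.elements[1].residues <= EsiMode.STRICT_SYNTHETIC.pos2_class
    assert derived.elements[2].residues <= EsiMode.STRICT_SYNTHETIC.pos3_class
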