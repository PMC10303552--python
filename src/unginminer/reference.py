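"""Bundled reference material: verified inhibitor sequences and the
published worked sequences used throughout tests and examples.

The PBS1/PBS2/AR9 Ugi protein (``ugi_pbs1.fasta``) is the genuine,
well-established 84-residue sequence.  The remaining reference inhibitors
ship as *synthetic stand-ins* (``*.synthetic.fasta``): constructed
sequences that reproduce each protein's published length class, acidic
residue count, printed β-strand fragments at their printed positions and
motif content, but are not the native sequences.  They exist so that
calibration and the full pipeline run self-contained; any conclusion that
depends on the exact native residues should be re-run with user-supplied
FASTA of the true accessions.
"""

from __future__ import annotations

from importlib import resources

from .io import ProteinRecord, read_fasta_aa

__all__ = [
    "load_ugi",
    "load_ugi_saugi_positives",
    "load_p56_references",
    "BETA1_UGI",
    "BETA1_LIBRARY_VARIANTS",
    "LIBRARY1_CLONES",
    "BETA1_SAUGI",
    "BETA1_MCUGI1",
    "BETA2_UGI",
    "BETA2_UGI2",
    "P56_PROSITE",
    "ACIDIC_PROSITE_UGI",
    "ACIDIC_PROSITE_SHARED",
]

#: The Ung-binding first β-strand of Ugi; residues 2-4 carry the ESI-type
#: motif (here E-S-I itself).
BETA1_UGI = "QESILML"

#: Functionally verified heptapeptide variants of the Ugi first β-strand
#: recovered from the two motif-shuffling mutagenesis libraries (one of the
#: twelve restores the prototypical sequence).
BETA1_LIBRARY_VARIANTS = (
    # library shuffling the motif within observed natural variation
    "QESILML",
    "QEAMLML",
    # library randomising motif positions 2-3
    "QEALLML",
    "QESTLML",
    "QESVLML",
    "QETCLML",
    "QESWLML",
    "QEAPLML",
    "QETVLML",
    "QEVTLML",
    "QETMLML",
    "QETILML",
)

#: Soluble but non-functional clones from the fully randomised β-strand
#: library; neither carries any ESI-type motif.
LIBRARY1_CLONES = ("PTRSIVK", "KSNKSLP")

#: Printed Ung-binding β-strand octapeptides (residues 24-31) of SAUGI and
#: its distant homolog MCUGI1 — only one glutamate is common to the two.
BETA1_SAUGI = "ECESIEEI"
BETA1_MCUGI1 = "LTEFVQLG"

#: Printed second-β-strand octapeptides of Ugi (41-48) and Ugi-2 (45-52) —
#: only the histidine is common.
BETA2_UGI = "ILVHTAYD"
BETA2_UGI2 = "KICHSTSL"

#: PROSITE pattern recognising p56-type inhibitors.
P56_PROSITE = "E-X(2)-Y-X(0,2)-G"

#: Acidic-residue pattern shared by the Ugi variants (β1/α2 span) ...
ACIDIC_PROSITE_UGI = "E-X(6)-[ED]-[ED]-X-[ED]-[ED]"
#: ... and its shorter form additionally common to the SAUGI family.
ACIDIC_PROSITE_SHARED = "E-X(6)-[ED]-[ED]"


def _load(name: str) -> list[ProteinRecord]:
    ref = resources.files("unginminer.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_fasta_aa(path)


def load_ugi() -> ProteinRecord:
    """The genuine PBS1/PBS2/AR9 Ugi protein (84 aa)."""
    return _load("ugi_pbs1.fasta")[0]


def load_ugi_saugi_positives(include_standins: bool = True) -> list[ProteinRecord]:
    """The Ugi/SAUGI-type calibration positives.

    Always includes the genuine Ugi; with ``include_standins`` (default)
    also the synthetic stand-ins for Ugi-2, SAUGI, MCUGI1/2, MBUGI, SYUGI
    and JMUGI.
    """
    records = [load_ugi()]
    if include_standins:
        records += _load("ungin_positives.synthetic.fasta")
    return records


def load_p56_references() -> list[ProteinRecord]:
    """Synthetic stand-ins for the p56-type inhibitors (PZA and VMY22)."""
    return _load("p56_references.synthetic.fasta")


def load_default_config():
    """The committed filter configuration: the zero-margin strict-natural
    envelope calibrated on the bundled Ugi/SAUGI-type positives."""
    from .pipeline import FilterConfig

    ref = resources.files("unginminer.data").joinpath("default_config.yaml")
    with resources.as_file(ref) as path:
        return FilterConfig.from_yaml(path)
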