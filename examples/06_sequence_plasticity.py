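"""Position-wise comparisons of the Ung-binding β-strands.

Distant inhibitor homologs conserve their fold at very low sequence
identity; position-wise counts over printed β-strand octapeptides make the
point concrete: each divergent pair conserves exactly one residue.
"""

from unginminer import identical_positions, percent_identity, shared_acidic_positions
from unginminer.reference import BETA1_MCUGI1, BETA1_SAUGI, BETA2_UGI, BETA2_UGI2

pairs = [
    ("SAUGI b1 vs MCUGI1 b1", BETA1_SAUGI, BETA1_MCUGI1),
    ("Ugi b2   vs Ugi-2 b2 ", BETA2_UGI, BETA2_UGI2),
]
for name, a, b in pairs:
    print(f"{name}: {a} / {b}")
    print(f"  identical positions : {identical_positions(a, b)}")
    print(f"  shared acidic sites : {shared_acidic_positions(a, b)}")
    print(f"  percent identity    : {percent_identity(a, b):.2f}")
# One conserved residue out of eight in each pair — the glutamate for the
# SAUGI pair, the histidine for the Ugi pair — is why plain homology search
# fails and composition/motif heuristics are needed.
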