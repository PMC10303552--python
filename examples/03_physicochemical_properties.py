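"""The heuristic attribute vector of the reference inhibitors.

Ung inhibitors are small, strongly acidic DNA mimics: high D+E fraction,
few basic residues, negative GRAVY, ~9.5-13 kDa.  These attributes drive
the interval filters.
"""

from unginminer import property_vector
from unginminer.reference import load_ugi_saugi_positives

print(f"{'protein':16s} {'len':>4s} {'GRAVY':>7s} {'D+E':>4s} {'K+R':>4s} "
      f"{'D+E frac':>9s} {'mass (Da)':>10s}")
for rec in load_ugi_saugi_positives():
    v = property_vector(rec.seq)
    print(f"{rec.id:16s} {v.length:4d} {v.gravy:7.3f} {v.acidic_count:4d} "
          f"{v.basic_count:4d} {v.de_fraction:9.3f} {v.mass_da:10.1f}")
# The min-to-max envelope of these columns IS the calibrated filter
# configuration: any protein outside it cannot be retained alongside the
# known positives.
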