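# Methods

## The screening model

Uracil-DNA glycosylase inhibitors (UngIns) are protein mimics of DNA: they
occupy the Ung DNA-binding cleft and sequester the minor-groove
intercalating residue.  Mimicry constrains chemistry, not sequence —
distant homologs keep the fold and the surface charge while sharing almost
no residues — so the screen operates on composition-level attributes and a
minimal motif, not on alignment.

The pipeline treats a genome as an unannotated bag of potential proteins.
Every stop-to-stop segment in all six reading frames is a candidate
("putative protein") after N-terminal trimming to the first valid start
residue.  Start residues are M, I, V and L, the amino acids encoded by the
initiation codons ATG, ATT/ATC/ATA, GTG and TTG/CTG used by bacteria and
their phages; rarer alternatives are deliberately excluded for stringency.
The default minimum length is 40 residues, applied **after** trimming (the
stricter of the two possible readings; the `length_check="pre_trim"`
switch applies it to the raw stop-to-stop segment instead, for users who
want the other convention).  Leading and trailing genome-edge segments are
eligible: excluding them would silently drop genes running off the edge of
a linear record.  Genomes are treated as linear by default; a `circular`
flag appends one minimum-ORF of sequence and de-duplicates proteins whose
wrapped coordinates coincide.

Translation uses the standard genetic code.  Segmentation only depends on
the stop set TAA/TAG/TGA, which the bacterial table shares, so the choice
of table is immaterial here.  A codon containing ambiguity codes is
translated to its shared residue when every expansion agrees (including
all-stop codons, which count as stops) and to `X` otherwise.  `X` is never
a valid start, never matches a motif class, is excluded from the GRAVY
mean, and contributes the mean residue mass (110 Da) to the chain mass.

## Attributes and filters

Per-protein attributes (all composition-based, hence permutation
invariant):

| attribute | definition | default band (calibrated) |
|---|---|---|
| length | residue count | 84–113 aa |
| de_fraction | (D+E)/length | 0.152–0.239 |
| gravy | mean Kyte–Doolittle hydropathy, X excluded | −0.50 – +0.29 |
| glypro_fraction | (G+P)/length | 0.023–0.083 |
| acid_base_ratio | (D+E)/(K+R); `inf` when K+R = 0 | ≥ 3.0 |
| mass_da | average-isotopic chain mass + one water | 9.48–12.63 kDa |

Acidic means D+E and basic means K+R; histidine is excluded because it is
mostly uncharged at cytoplasmic pH and the published acidic counts of the
reference inhibitors are consistent with D+E only.  The `inf` sentinel for
basic-free proteins is intentional: strongly acidic DNA mimics must pass a
"ratio ≥ r" test even with zero basic residues.  "Molecular mass bounds"
are interpreted as whole-chain mass (UngIns are single small domains); a
sliding-window mass is not implemented.  Floating-point sums use `fsum` so
attribute values are exactly permutation invariant.

The cascade order is length → acidity → hydrophobicity → Gly/Pro →
acid:base → mass → ESI (→ optional extra patterns).  The filters are
independent predicates, so order affects only the per-stage report, never
the final candidate set; the narrative order is kept for report
comparability.  `relax_serially` disables one stage at a time to surface
near-miss candidates that fail exactly one filter.

## The ESI motif and the PROSITE dialect

The ESI motif is the glutamate-led tripeptide in the Ung-docking β-strand.
Position 1 is invariant E.  Position 2 tolerates [ASVFHTNI] across natural
variants; position 3 tolerates [LVIFMT], extended to [LVIFMTPWC] when
functionally verified synthetic variants are admitted.  Crossing
strict/lenient position 2 with natural/synthetic position 3 gives four
modes forming a lattice (strict ⇒ lenient, natural ⇒ synthetic); scanning
is sequence-wide because the inputs are unannotated translations with no
known strand topology.  Under the lenient modes position 2 is a true
wildcard and also admits an ambiguous `X`.

The motif engine supports the minimal PROSITE subset the heuristics need:
fixed residues, `[classes]`, `X`, `X(n)`, `X(n,m)`, `-` separators and an
optional trailing period.  Exclusion classes, anchors and repeats of
non-wildcard elements are unsupported on purpose — the dialect stays small
enough that the matcher is fully checkable against a brute-force oracle
(the test suite cross-checks it against an independent translation to
Python regular expressions over all start/length pairs).  All overlapping
matches and all lengths of variable patterns are reported;
fully-optional patterns never report zero-length hits.

## Calibration

The tuning rule "retain every known positive with as few false positives
as possible" has a closed-form solution for independent interval filters:
the min-to-max envelope of each attribute over the positives.  `calibrate`
computes that envelope (optionally widened outward by a relative margin,
`bound ∓ margin·|bound|`), fixes the requested ESI mode after verifying
every positive carries the motif under it, and, when background genomes
are supplied, counts surviving non-positive sequences as false positives.
No stochastic search is involved; results are reproducible by
construction.  Envelope minimality is a tested property: shrinking any
bound by any ε rejects at least one positive.

Ugi/SAUGI-type and p56-type references are separate profiles: the ESI
heuristic targets the Ugi/SAUGI fold, while p56-type inhibitors are
recognised by the pattern `E-X(2)-Y-X(0,2)-G` only.

## Bundled reference sequences

The genuine PBS1/PBS2/AR9 Ugi (84 aa) is bundled and is verified in-tests
against four independent published facts: its length, the `QESILML`
β-strand at 19–25, the `ILVHTAYD` octapeptide at 41–48, and its 18 acidic
residues.  The other reference inhibitors ship as **synthetic stand-ins**,
labelled `synthetic` in filename and FASTA headers.  Each stand-in is a
constructed sequence satisfying every published constraint for its
protein — length class, acidic-residue count (21 for the Ugi-2 stand-in,
17 for SAUGI, 18 for MCUGI1), the printed β-strand octapeptides at their
printed positions, the acidic PROSITE patterns
(`E-X(6)-[ED]-[ED]-X-[ED]-[ED]` for the Ugi pair, `E-X(6)-[ED]-[ED]` for
the SAUGI family), ESI-motif class membership, and the p56 recognition
pattern — over a seeded background composition.  Stand-ins make
calibration and the end-to-end pipeline self-contained and exercise every
code path, but they are not evidence about the native residues; analyses
sensitive to exact sequence should be re-run with the true accession
records supplied as FASTA.

## The synthetic-data generator

`random_genome` draws i.i.d. nucleotides with P(G)=P(C)=gc/2 at a default
target of 28% GC — the AT-rich regime of uracil-DNA phage genomes where
all verified Ugi variants occur.  Default screen size is 50 kb (phage
scale, large enough for a few hundred putative proteins per genome).
Embedded ORFs are stop-flanked cassettes, so extraction recovers the
embedded protein exactly when it begins with a valid start residue; truth
tables carry exact forward-strand coordinates and frames for both strands.
Reverse translation picks the GC-nearest synonymous codon
(lexicographic tie-break) — GC control and exact re-translation are what
matter; codon-usage realism is not modelled.  Decoys (40–200 aa, ten per
profile in the standard screen) are constructed, and checked on emission,
to sit in one of three violation profiles: no ESI motif under any mode;
motif under lenient modes only; or a genuine strict-natural motif inside
basic/hydrophobic composition that the property filters reject.

What the generator does **not** emulate: real gene architecture (operons,
RBS spacing, tRNAs, repeats), codon usage, compositional heterogeneity
along the genome, and homology between decoys and positives.  Passing the
synthetic end-to-end tests therefore demonstrates correctness of the
machinery (extraction, calibration, filtering, accounting) under
controlled conditions, not field performance on real phage genomes, where
near-boundary proteins and envelope tightness dominate the false-positive
and false-negative rates.

## Numerical and convention choices

* Coordinates: 1-based inclusive forward-strand in all outputs; 0-based
  half-open internally.  Provenance ids are
  `{genome_id}|{frame}|{nt_start}-{nt_end}`.
* GC content excludes ambiguity codes from numerator and denominator;
  GC bins are half-open `[k·w, (k+1)·w)` percent with w = 5, resolving the
  25–35% priority range into two bins.
* Outputs are deterministic: stable frame-then-coordinate ordering,
  byte-identical FASTA for identical inputs, seeded generators everywhere.
* Bulk runs record per-genome failures and continue; bulk inputs are
  routinely contaminated with malformed records.
* Calibration attribute envelopes round length bounds outward to integers;
  all other bounds are kept at full float precision.

## Known limitations

* The exact numeric filter bands published for the original screens are
  not reproducible here; the committed defaults are the zero-margin
  strict-natural envelope over the bundled positives and will differ from
  any envelope fitted over the native sequences wherever a stand-in's
  background composition differs from the native one.
* Whole-genome screens of real phages (e.g. the ~262 kb Yersinia phage
  phiR1-37) require user-downloaded FASTA; no network access is attempted.
* Windowed ("local") mass, PSSM/HMM motif models, MSA construction and any
  BLAST-based confirmation of candidates are out of scope.
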