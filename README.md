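# unginminer

Heuristic genomic triage for **uracil-DNA glycosylase inhibitors (UngIns)**
— small phage- and mobile-element-encoded proteins that mimic DNA and shut
down Ung-type uracil-DNA glycosylase.

## The problem

UngIns such as Ugi (Bacillus phages PBS1/PBS2/AR9), SAUGI (*Staphylococcus
aureus* SCC*mec*) and p56 (*Salasmaviridae* phages) diverge so fast that
homology search misses functional family members: distant homologs share
the fold at 12–32% identity, and divergent Ung-binding β-strands can
conserve a single residue.  What does survive divergence is a
*physicochemical signature*: UngIns are small (~9.5–13 kDa), strongly
acidic (high Asp+Glu content, few Lys/Arg — the electrostatic mimicry of
DNA phosphates), hydrophilic, and carry a conserved glutamate-led
tripeptide (the **ESI motif**) in the β-strand that docks the Ung
DNA-binding cleft.

`unginminer` turns that signature into a screening pipeline:

1. **Six-frame translation** of a genome; every stop-delimited segment,
   N-trimmed to the first start residue (M/I/V/L) and at least 40 aa, is a
   *putative protein*.
2. **Interval filters** on length, D+E fraction, GRAVY (mean
   Kyte–Doolittle hydropathy), Gly+Pro fraction, acidic:basic ratio
   (D+E)/(K+R), and molecular mass.
3. **Motif filter**: require an ESI motif `E-[ASVFHTNI]-[LVIFMT]`
   (strict/natural), with lenient position-2 (`E-X-[LVIFMT]`) and
   synthetic position-3 (`[LVIFMTPWC]`) variants — four leniency modes
   forming a lattice.
4. **Calibration**: thresholds are the min-to-max envelope of the
   attributes over known positives — the tightest configuration retaining
   every known UngIn, solved in closed form rather than searched.
5. **GC binning** for bulk screens: verified Ugi variants all come from
   AT-rich (25–30% GC) uracil-DNA phage genomes, so 25–35% GC bins are
   flagged as priority space.

A seeded synthetic-genome generator (controlled GC, stop-flanked embedded
ORFs, decoys in three violation profiles) makes every stage testable
without downloads.

## Worked example

```python
from unginminer import EsiMode, calibrate, run_pipeline
from unginminer.reference import load_ugi_saugi_positives
from unginminer.synth import EmbedSpec, SyntheticSpec, synthesize

positives = load_ugi_saugi_positives()
genome, truth = synthesize(SyntheticSpec(
    genome_length=50_000, gc_target=0.28, seed=7,
    embeds=tuple(EmbedSpec(p.id, p.seq) for p in positives),
    decoy_count=10, decoy_profile="property-violating",
))
result = calibrate(positives, [genome], esi_mode=EsiMode.STRICT_NATURAL)
candidates, report = run_pipeline(genome, result.config)
print(report.to_frame())
```

prints the per-stage survivor counts

```
          stage  input  surviving
         length    252         24
        acidity     24          8
 hydrophobicity      8          8
        gly_pro      8          8
acid_base_ratio      8          8
           mass      8          8
            esi      8          8
```

reading: the 50 kb genome yields 252 putative proteins; the length filter
leaves 24, the acidity filter leaves the 8 embedded positives, and every
later stage (including the strict-natural ESI filter) retains exactly
those 8 — all ten decoys die despite carrying a genuine ESI motif, and
`result.false_positive_count` is 0.

The same workflow is available from the shell:

```bash
unginminer simulate --length 50000 --gc 0.28 --seed 7 --decoys 10 \
    --decoy-profile property-violating --out genome.fasta --truth truth.tsv
unginminer calibrate --out-config config.yaml
unginminer filter --genome genome.fasta --config config.yaml --out results/
```

See `examples/` for one short script per capability (extraction, motif
scanning, properties, calibration+screening, bulk GC binning, β-strand
plasticity).

## Bundled reference material

`unginminer.reference` ships the genuine 84-residue Ugi protein and the
functionally verified β-strand heptapeptide variants, plus **synthetic
stand-ins** (so labelled in filenames and headers) for the other reference
inhibitors; the stand-ins reproduce each protein's published length class,
acidic-residue count, printed β-strand fragments and motif content but are
not the native sequences.  Re-run any accession-sensitive analysis with
user-supplied FASTA of the true records.

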