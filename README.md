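# ngpd — next-generation phage display enrichment analysis

`ngpd` analyses deep-sequenced phage-display biopanning experiments in which
a random peptide library (nonapeptides fused to the N terminus of the M13
major coat protein gpVIII) is selected against a target protein and, in
parallel, an unrelated control protein. Instead of picking clones, the
insert-coding amplicon of the round-3 output phage is sequenced, and peptide
enrichment is quantified statistically. The package is aimed at protein
biochemists running biopanning + amplicon sequencing ("NGPD") screens, and it
ships a full synthetic-data generator so every stage can be validated against
known ground truth without any external data.

## What it computes

**Read processing.** Barcoded single-end reads are demultiplexed by exact 5′
barcode match, translated in the three forward reading frames, and the
insert peptide is taken strictly between the conserved gpVIII flanks
(`AEGEF` upstream, `DPAKAA` downstream). Inserts containing stops or
ambiguous residues are discarded; fixed-length mode (9 aa) is the default.

**Enrichment ranking.** For a peptide seen x₁ times among n₁ extracted
target-arm peptides and x₂ among n₂ control-arm peptides, the pooled
two-proportion Z statistic

    Z = (p₁ − p₂) / √( p̂(1−p̂)(1/n₁ + 1/n₂) ),   p̂ = (x₁+x₂)/(n₁+n₂)

ranks peptides by both frequency ratio and absolute abundance (Z² equals the
1-df χ² of the 2×2 table). The top-50 set feeds motif discovery.

**Motif discovery.** A zero-or-one-occurrence-per-sequence (ZOOPS)
expectation–maximization algorithm fits an ungapped position weight matrix,
an occurrence prior λ, and a background composition; multiple motifs are
found sequentially by erasing each motif's member sequences. Degenerate
consensus patterns such as `(YNHC)-(±)-L-(±)-φ-R` (φ nonpolar, ± charged,
X any residue) are executable for membership checks.

**ITC fitting.** One-site isothermal titration calorimetry isotherms are
modelled via the mass-action quadratic for the complex concentration with
the exponential displaced-volume correction for an overfilled perfusion
cell, and fitted by multi-start nonlinear least squares over
(N, ln K_a, ΔH, q_dil) with Jacobian standard errors.

## Worked example

```sh
ngpd simulate --out-dir sim --n-clones 2000 --n-binders 3 --n-reads 10000 --seed 42
ngpd rank --fastq sim/reads.fastq --sheet sim/barcodes.tsv --out-dir rank
ngpd motif --fasta rank/top_peptides.fasta --out-dir motifs --n-motifs 2 --seed 0
ngpd itcfit fylir_heats.csv --out-dir itcout
```

prints

```
wrote 10000 reads/arm; binders: CMYRSRSMD, CSQKKVCQF, TLMIEWSPK
reads 20000 (assigned 20000), extracted target/control 8785/8662, unique peptides 3384, top-N 50
motif 1: width 8, consensus CSQKSVSQ, lambda 0.62, members 31
motif 2: width 7, consensus TLMIDWS, lambda 0.37, members 7
fylir_heats.csv: N=0.985 K_D=9.96 uM dH=-10.80 kcal/mol (c=3.0)
```

All three spiked binder peptides head the Z ranking (`rank/ranked.tsv`; the
top entry `CSQKKVCQF` has Z ≈ 46.2 with 1938/8785 target vs 5/8662 control
counts), the two discovered motifs are noisy copies of two of the binders,
and the one-site fit of a simulated 30 µM protein / 300 µM peptide titration
(`fylir_heats.csv`, generated with K_D = 8.86 µM, ΔH = −10 kcal/mol, 2%
noise) recovers K_D ≈ 10.0 µM at c ≈ 3 — within the precision the shallow
isotherm supports.

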