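# Methods

This note documents the models implemented in `ngpd`, the choices made where
the published procedure leaves details open, and what the synthetic-data
validation does and does not demonstrate.

## Synthetic library and panning model

`ngpd.library` emulates a PC89VIII-style display library: random inserts
(default 9 residues, uniform over the 20 standard amino acids) fused between
the conserved gpVIII protein flanks AEGEF and DPAKAA. Back-translation picks
uniformly among synonymous codons of the standard code (the physical
library's codon scheme is unknown and immaterial at the protein level);
inserts therefore contain no stop codons by construction.

Panning is modelled as multiplicative per-round selection. Both arms start
from the same clone frequencies. Each round, every clone's abundance is
multiplied by independent lognormal amplification noise with mean 1 and a
configurable coefficient of variation (default 0.3, a moderate level of
round-to-round clone jackpotting); in the target arm, binder clones gain an
additional enrichment factor (default 10 per round). Frequencies are
renormalized each round. With zero noise the binder odds grow exactly as
factor^rounds, which the tests assert in closed form. The default conditions
of the end-to-end validation — 10⁴ clones, 5 binders, 3 rounds, 4×10⁴
reads per arm — mirror the scale of a real screen's "meaningful reads" per
barcode; per-round enrichment dynamics of real screens are not calibrated
(only the final round is sequenced in practice), so the factor is
illustrative.

Reads are sampled multinomially from clone frequencies. Each read is
`barcode + 0–2 random pad bases (frame offset) + flank DNA + insert DNA +
flank DNA + 6 random trailing bases`, with i.i.d. substitution errors
(default 0.5% per base) applied downstream of the barcode (the two-step PCR
barcode design makes barcodes effectively error-protected). An optional
indel mode (default off) exercises frame-breaking errors. Quality strings
are constant Q30 placeholders: the analysis never consumes qualities.
Identical seeds give byte-identical FASTQ.

## Read processing

Demultiplexing requires an exact 5′ barcode prefix by default
(`--barcode-mismatch` relaxes this to unique-within-budget Hamming
matching); unassigned reads are counted, never dropped silently. Reads are
translated in the three forward frames only (a six-frame option exists);
codons containing N become `X`, stops become `*`. Extraction takes the
substring strictly between the first AEGEF and the subsequent first DPAKAA
in any frame (first frame wins), rejecting inserts with `*` or `X` and — in
the default fixed-length mode — any insert that is not 9 residues. The
count-table totals n₁/n₂ are the numbers of successfully extracted peptides
per sample, the natural reading of "meaningful reads". Extraction is
validated read-by-read against an independent brute-force oracle (per-codon
Biopython translation plus a regex scan) on 10⁴ mixed structured/random
reads.

## Two-proportion Z ranking

The pooled-variance statistic without continuity correction is the default:
it is the textbook two-proportion Z test and satisfies the identity
Z² = χ²(1 df) of the 2×2 contingency table, which serves as the test oracle
(an unpooled option exists). No pseudo-counts are added: a peptide absent
from the control arm legitimately gets a large finite Z. Ranking uses the
statistic alone — no p-values or multiple-testing correction, matching the
screening use of the ranking — with ties broken by target count then
lexicographically. Peptides seen only in the control arm keep their negative
Z in the full table but are excluded from the top-N motif input. Under a
shared-null simulation, ≈5% of well-populated peptides exceed |Z| > 1.96,
confirming calibration.

## ZOOPS EM motif discovery

The motif model is the classic ZOOPS mixture: a sequence either contains
exactly one occurrence of a width-w motif (prior λ, offset uniform over the
feasible positions) drawn column-wise from a PWM, or is pure background.
EM computes per-sequence, per-offset occurrence posteriors (E-step) and
re-estimates the PWM (Dirichlet pseudo-count 0.01), λ (clipped to
(10⁻⁶, 1−10⁻⁶)), and the background from expected non-motif residues
(M-step); the log-likelihood is asserted non-decreasing to 10⁻⁹ relative
tolerance. Each of the multi-starts is seeded from one observed
width-length subsequence smoothed toward the empirical background; starts
are drawn from the sorted peptide list so the fit is invariant to input
order. Because starts seeded one column off the true register converge to a
shifted local optimum, the best model is polished by re-running EM from its
±1-column-shifted PWM until no shift improves the likelihood (MEME-style
column shifting); this reliably snaps to the maximum-likelihood register.
Convergence: relative log-likelihood change < 10⁻⁶ or 500 iterations.
Sequences with total occurrence posterior > 0.5 are members, at their
posterior-mode offset.

Width selection scans 6–8 by default and keeps the width maximizing the
per-motif-column likelihood ratio against a background-only model (wider
motifs otherwise always win). Multiple motifs are found sequentially; after
each fit the member sequences are removed (the simplest faithful variant of
probabilistic erasure). Degenerate consensus patterns use the documented
residue classes φ = {A,V,L,I,M,F,W,P,G,C} (nonpolar, including G/C/P, which
the graphical motif legend does not enumerate) and ± = {D,E,K,R,H}
(charged). Per-position information content is the relative entropy
Σ_a p log₂(p/bg) in bits.

## One-site ITC model and fitting

After cumulative injected volume ΔV into an overfilled cell of volume V₀,
effective concentrations follow the continuous displacement correction
M = M₀e^(−ΔV/V₀), X = Xs(1−e^(−ΔV/V₀)); a discrete per-injection
(1−v/V₀) mode is retained and matches an independent from-scratch stepwise
implementation to 10⁻⁸ relative (the two conventions agree on
concentrations to ~0.5% for a typical titration, but pointwise heats can
differ at very sharp transitions, so the exact-equivalence oracle uses the
matching convention). The complex concentration is the physical root of
c² − c(N·M + X + K_D) + N·M·X = 0, evaluated in the cancellation-free form
2NMX/(b+√(b²−4NMX)). Per-injection heats apply the displaced-volume
correction δQᵢ = Qᵢ − Qᵢ₋₁ + (dvᵢ/V₀)(Qᵢ+Qᵢ₋₁)/2 with Q = V₀·ΔH·c, and are
reported normalized per mole of injectant plus a constant dilution offset.
Internal units are calories, litres, molar (MicroCal convention).

Fitting minimizes uniform-weight squared residuals of normalized heats over
(N, ln K_a, ΔH, q_dil), multi-started over a log-spaced K_a grid
(10³–10⁹ M⁻¹); N can be fixed at 1. The first injection is excluded by
default (standard practice against syringe-tip diffusion; the published
policy is not stated). Standard errors come from the Jacobian at the
optimum; parameters lying in the Jacobian's null space (e.g. K_a when
ΔH ≈ 0) get infinite error and are flagged unidentifiable, and the K_D error
bar is withheld when the Wiseman c-value N·M₀/K_D falls outside [0.1, 1000].
Peak integration of raw power traces is out of scope (instrument software's
job); a trapezoid integrator exists only for synthetic traces.

### Information limits at the published design

The validation titrations use the published protocol — 30 µM cell protein,
300 µM peptide syringe, 8-µl injections (35 per run, reaching a molar ratio
of ≈2), 25 °C — with generating K_D 8.86 µM (FYLIR) or 6.92 µM (LXLL),
N = 1, and typical exothermic enthalpies (−10 / −8 kcal/mol; the published
isotherms constrain K_D, not ΔH, at this level of description). At these
conditions c ≈ 3–4 and the isotherm is a shallow sigmoid, so with 2%
peak-scale noise the Fisher-information (Jacobian) limit puts the relative
standard error of a single-run K_D near 20–25% and of ΔH near 8%. The
recovery tests therefore assert unbiasedness (median estimates within the
published uncertainties) and consistency of the observed spread with the
reported standard errors, rather than an arbitrarily tighter accuracy no
unbiased estimator could achieve at this design. Noise-free refits recover
all parameters to 0.1%.

Total-heat conservation (Σ raw heats = N·M₀·V₀·ΔH) holds exactly only for
instantaneous saturation; with a slowly saturating titration a physically
real fraction of titrant is displaced before binding, so the conservation
check uses a strongly saturating protocol (3 mM syringe, 1 nM K_D), where
the law holds within 2%.

## Pipeline, reproducibility, problem sizes

Each CLI stage writes a JSON manifest with the configuration, its hash, the
seed, and per-stage counts (reads in/assigned/unassigned, extractions,
unique peptides); identical configurations reproduce byte-identical
non-log outputs. All randomness flows through seeded NumPy generators.
The test suite validates the full pipeline at the screen's nominal scale
(10⁴ clones, 4×10⁴ reads/arm, 20 seeds for the spike-recovery property) and
module behaviour at smaller sizes chosen to keep each test deep but quick;
the acceptance script uses 50 simulate-and-refit replicates per titration.

## Limitations

The generator does not model phage propagation biology, PCR chimeras,
barcode hopping, flow-space (homopolymer) error structure, or
quality-dependent errors; substitution errors are i.i.d. Passing the
ground-truth recovery tests shows the statistical machinery is correct under
the stated generative model, not that real libraries are free of the
amplification biases these simplifications ignore. Real published
sequencing-derived numbers (specific top-50 lists and motif membership
counts) depend on unreleased raw data and are not reproduced. Two-site and
competitive ITC models, global multi-experiment fitting, and baseline
estimation from thermograms are out of scope.
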