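"""Synthetic phage-display libraries, panning simulation, and FASTQ emission.

This module generates the ground-truth data the rest of the pipeline is tested
against: a random peptide library displayed on the phage major coat protein
gpVIII (inserts flanked by the conserved AEGEF/DPAKAA protein sequence),
multi-round biopanning in which a known set of binder clones is enriched
multiplicatively against a control arm, and barcoded single-end amplicon reads
with per-base substitution noise in the style of an Ion Torrent run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import AA_TO_CODONS, AMINO_ACIDS

# Conserved gpVIII protein flanks around the displayed insert and one fixed
# DNA encoding used by the read simulator. The extractor works at the protein
# level, so the particular synonymous codons here are arbitrary but frozen.
UP_FLANK_AA = "AEGEF"
DOWN_FLANK_AA = "DPAKAA"
UP_FLANK_DNA = "GCTGAAGGTGAATTT"
DOWN_FLANK_DNA = "GATCCTGCTAAAGCTGCT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of a random insert library (nonapeptide by default)."""

    n_clones: int
    insert_length: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.insert_length < 1:
            raise ValueError("insert_length must be >= 1")


@dataclass(frozen=True)
class EnrichmentTruth:
    """Ground-truth enrichment model: which clones bind and how strongly.

    ``per_round_enrichment_factor`` is the multiplicative fold-change a binder
    clone gains per panning round in the target arm, on top of the clone
    amplification noise that both arms experience.
    """

    binder_peptides: frozenset[str]
    per_round_enrichment_factor: float = 10.0
    amplification_noise_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.per_round_enrichment_factor <= 0:
            raise ValueError("enrichment factor must be > 0")
        if self.amplification_noise_cv < 0:
            raise ValueError("noise CV must be >= 0")


@dataclass(frozen=True)
class ReadModel:
    """How clone abundances become sequencing reads.

    Each read is ``barcode + pad + AEGEF-DNA + insert-DNA + DPAKAA-DNA +
    trailing context``; the pad length (0/1/2 nt, drawn from
    ``frame_offset_weights``) sets the reading frame the insert lands in.
    Errors are i.i.d. substitutions; an optional indel mode emulates the
    frame-breaking indels of Ion Torrent homopolymer miscalls.
    """

    barcode: str
    n_reads: int
    per_base_error_rate: float = 0.005
    frame_offset_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    indel_rate: float = 0.0
    trailing_length: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.per_base_error_rate < 1):
            raise ValueError("per_base_error_rate must be in [0, 1)")
        if abs(sum(self.frame_offset_weights) - 1.0) > 1e-9:
            raise ValueError("frame offset weights must sum to 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass
class PanningResult:
    """Per-round clone frequency trajectories for the target and control arms.

    Row 0 of each array is the pre-selection (round 0) library; row r is the
    frequency vector after round r.
    """

    target_freqs: np.ndarray
    control_freqs: np.ndarray
    binder_mask: np.ndarray


def build_library(spec: LibrarySpec) -> list[tuple[str, str]]:
    """Sample a random peptide library and back-translate it.

    Returns ``[(insert_peptide, insert_dna), ...]`` with residues uniform over
    the 20 standard amino acids and codons uniform over the synonymous codons
    of each residue (the physical library's codon scheme is not modelled).
    Inserts contain no stop codons by construction.
    """
    rng = np.random.default_rng(spec.seed)
    residue_idx = rng.integers(0, 20, size=(spec.n_clones, spec.insert_length))
    clones: list[tuple[str, str]] = []
    for row in residue_idx:
        peptide = "".join(AMINO_ACIDS[i] for i in row)
        codons = []
        for aa in peptide:
            choices = AA_TO_CODONS[aa]
            codons.append(choices[rng.integers(0, len(choices))])
        clones.append((peptide, "".join(codons)))
    return clones


def _amplification_noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-1 lognormal multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def simulate_panning(
    library: list[tuple[str, str]],
    truth: EnrichmentTruth,
    rounds: int = 3,
    seed: int = 0,
    initial_freqs: np.ndarray | None = None,
) -> PanningResult:
    """Simulate multi-round biopanning of target and control arms.

    Both arms start from the same library frequencies. Every round, every
    clone's abundance is multiplied by independent lognormal amplification
    noise; in the target arm, binder clones are additionally multiplied by the
    enrichment factor. Frequencies are renormalized after each round.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    peptides = [p for p, _ in library]
    unknown = truth.binder_peptides - set(peptides)
    if unknown:
        raise ValueError(f"binder peptides not in library: {sorted(unknown)[:3]}")
    n = len(library)
    binder_mask = np.array([p in truth.binder_peptides for p in peptides])

    if initial_freqs is None:
        freqs0 = np.full(n, 1.0 / n)
    else:
        freqs0 = np.asarray(initial_freqs, dtype=float)
        freqs0 = freqs0 / freqs0.sum()

    rng = np.random.default_rng(seed)
    target = np.empty((rounds + 1, n))
    control = np.empty((rounds + 1, n))
    target[0] = freqs0
    control[0] = freqs0
    gain = np.where(binder_mask, truth.per_round_enrichment_factor, 1.0)
    for r in range(1, rounds + 1):
        t = target[r - 1] * _amplification_noise(rng, n, truth.amplification_noise_cv) * gain
        c = control[r - 1] * _amplification_noise(rng, n, truth.amplification_noise_cv)
        target[r] = t / t.sum()
        control[r] = c / c.sum()
    return PanningResult(target_freqs=target, control_freqs=control, binder_mask=binder_mask)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return b"".join(_BASES[rng.integers(0, 4, size=n)]).decode()


def _apply_substitutions(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        # substitute with one of the three other bases
        others = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([others[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def _apply_indels(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate == 0:
        return seq
    out = []
    for ch in seq:
        u = rng.random()
        if u < rate / 2:
            continue  # deletion
        out.append(ch)
        if rate / 2 <= u < rate:
            out.append("ACGT"[rng.integers(0, 4)])  # insertion
    return "".join(out)


@dataclass
class EmitResult:
    """Bookkeeping from FASTQ emission: reads drawn per clone."""

    clone_read_counts: np.ndarray
    n_reads: int


def emit_fastq(
    library: list[tuple[str, str]],
    frequencies: np.ndarray,
    model: ReadModel,
    path: str | Path,
    seed: int = 0,
    read_prefix: str = "read",
    append: bool = False,
) -> EmitResult:
    """Sample reads multinomially from clone frequencies and write FASTQ.

    Quality strings are constant Q30 placeholders ('?'): the published
    procedure never consumes base qualities. Read headers record the source
    clone index so noise-free round trips can be asserted exactly.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if abs(frequencies.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must be normalized")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(model.n_reads, frequencies)
    clone_ids = np.repeat(np.arange(len(library)), counts)
    rng.shuffle(clone_ids)
    offsets = rng.choice(3, size=model.n_reads, p=np.asarray(model.frame_offset_weights))

    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for i, (clone, off) in enumerate(zip(clone_ids, offsets)):
            insert_dna = library[clone][1]
            seq = (
                model.barcode
                + _random_bases(rng, int(off))
                + UP_FLANK_DNA
                + insert_dna
                + DOWN_FLANK_DNA
                + _random_bases(rng, model.trailing_length)
            )
            # errors hit everything downstream of the barcode (the two-step
            # PCR design protects the barcode itself)
            payload = _apply_substitutions(seq[len(model.barcode):], rng, model.per_base_error_rate)
            payload = _apply_indels(payload, rng, model.indel_rate)
            seq = model.barcode + payload
            fh.write(f"@{read_prefix}{i:06d} clone={clone}\n{seq}\n+\n{'?' * len(seq)}\n")
    return EmitResult(clone_read_counts=counts, n_reads=model.n_reads)


def write_truth_tsv(
    library: list[tuple[str, str]], result: PanningResult, path: str | Path
) -> None:
    """Write the ground-truth sidecar: clone, peptide, binder flag, per-round frequencies."""
    rounds = result.target_freqs.shape[0] - 1
    data = {
        "clone": np.arange(len(library)),
        "peptide": [p for p, _ in library],
        "insert_dna": [d for _, d in library],
        "is_binder": result.binder_mask.astype(int),
    }
    for r in range(rounds + 1):
        data[f"freq_target_r{r}"] = result.target_freqs[r]
        data[f"freq_control_r{r}"] = result.control_freqs[r]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
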