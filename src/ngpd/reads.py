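"""FASTQ to per-sample peptide count tables.

The processing chain mirrors the published amplicon workflow: demultiplex by
exact 5' barcode, translate each read in the three forward frames, keep the
peptide strictly between the conserved gpVIII flanks (AEGEF upstream, DPAKAA
downstream), and tabulate paired target/control counts for the Z test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._codons import CODON_TO_AA
from .library import DOWN_FLANK_AA, UP_FLANK_AA

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BarcodeRow:
    sample_id: str
    barcode: str
    panning_round: int
    condition: str  # "target" or "control"


@dataclass
class BarcodeSheet:
    """Sample sheet mapping barcodes to (round, condition) samples."""

    rows: list[BarcodeRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("barcode sheet is empty")
        barcodes = [r.barcode for r in self.rows]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in sheet")
        keys = [(r.panning_round, r.condition) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (round, condition) pair in sheet")
        for r in self.rows:
            if r.condition not in ("target", "control"):
                raise ValueError(f"condition must be target/control, got {r.condition!r}")
            if set(r.barcode) - set("ACGT"):
                raise ValueError(f"barcode {r.barcode!r} contains non-ACGT characters")

    def sample(self, panning_round: int, condition: str) -> BarcodeRow:
        for r in self.rows:
            if r.panning_round == panning_round and r.condition == condition:
                return r
        raise KeyError(f"no sample for round {panning_round}, condition {condition}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeSheet":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "barcode": str})
        return cls(
            [
                BarcodeRow(r.sample_id, r.barcode, int(r.panning_round), r.condition)
                for r in df.itertuples()
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "barcode": r.barcode,
                    "panning_round": r.panning_round,
                    "condition": r.condition,
                }
                for r in self.rows
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PeptideExtract:
    """One successfully extracted insert peptide and its provenance."""

    insert_peptide: str
    source_read_id: str
    frame: int


@dataclass
class DemuxResult:
    """Reads per sample after barcode trimming, plus conservation bookkeeping."""

    assignments: dict[str, list[tuple[str, str]]]
    n_total: int
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return self.n_total - self.n_unassigned


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    fastq_path: str | Path, sheet: BarcodeSheet, max_mismatch: int = 0
) -> DemuxResult:
    """Assign reads to samples by 5' barcode prefix and trim the barcode.

    Default policy is exact matching (0 mismatches). With ``max_mismatch`` > 0
    a read is assigned only when exactly one barcode is within the budget.
    Unassigned reads are counted, never silently dropped.
    """
    assignments: dict[str, list[tuple[str, str]]] = {r.sample_id: [] for r in sheet.rows}
    by_barcode = {r.barcode: r.sample_id for r in sheet.rows}
    n_total = 0
    n_unassigned = 0
    with open(fastq_path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            n_total += 1
            read_id = title.split(None, 1)[0]
            seq = seq.upper()
            hit = None
            if max_mismatch == 0:
                for bc, sid in by_barcode.items():
                    if seq.startswith(bc):
                        hit = (bc, sid)
                        break
            else:
                candidates = [
                    (bc, sid)
                    for bc, sid in by_barcode.items()
                    if len(seq) >= len(bc) and _hamming(seq[: len(bc)], bc) <= max_mismatch
                ]
                if len(candidates) == 1:
                    hit = candidates[0]
            if hit is None:
                n_unassigned += 1
            else:
                bc, sid = hit
                assignments[sid].append((read_id, seq[len(bc):]))
    if n_total == 0:
        logger.warning("empty FASTQ: %s", fastq_path)
    return DemuxResult(assignments=assignments, n_total=n_total, n_unassigned=n_unassigned)


def translate_three_frames(dna: str) -> tuple[str, str, str]:
    """Translate the forward strand in frames 0, 1, 2 with the standard code.

    Codons containing N (or any non-ACGT base) give 'X'; stops give '*';
    trailing 1-2 nt of each frame are dropped.
    """
    dna = dna.upper()
    frames = []
    for off in range(3):
        aa = [
            CODON_TO_AA.get(dna[i : i + 3], "X")
            for i in range(off, len(dna) - 2, 3)
        ]
        frames.append("".join(aa))
    return tuple(frames)  # type: ignore[return-value]


def extract_insert(
    protein: str,
    up_flank: str = UP_FLANK_AA,
    down_flank: str = DOWN_FLANK_AA,
    insert_length: int | None = 9,
) -> str | None:
    """Return the peptide strictly between the first flank pair, or None.

    Inserts containing '*' (internal stop) or 'X' (ambiguous base) are
    rejected, as is any insert whose length differs from ``insert_length``
    when fixed-length mode is on (pass None for variable-length libraries).
    """
    if not up_flank or not down_flank:
        raise ValueError("flanks must be non-empty")
    start = protein.find(up_flank)
    if start < 0:
        return None
    start += len(up_flank)
    end = protein.find(down_flank, start)
    if end < 0:
        return None
    insert = protein[start:end]
    if "*" in insert or "X" in insert:
        return None
    if insert_length is not None and len(insert) != insert_length:
        return None
    return insert


def extract_from_read(
    read_id: str,
    dna: str,
    up_flank: str = UP_FLANK_AA,
    down_flank: str = DOWN_FLANK_AA,
    insert_length: int | None = 9,
) -> PeptideExtract | None:
    """Translate a read in three frames and take the first frame that yields an insert."""
    for frame, protein in enumerate(translate_three_frames(dna)):
        insert = extract_insert(protein, up_flank, down_flank, insert_length)
        if insert is not None:
            return PeptideExtract(insert_peptide=insert, source_read_id=read_id, frame=frame)
    return None


def extract_sample(
    reads: list[tuple[str, str]],
    up_flank: str = UP_FLANK_AA,
    down_flank: str = DOWN_FLANK_AA,
    insert_length: int | None = 9,
) -> list[PeptideExtract]:
    """Run insert extraction over all reads of one demultiplexed sample."""
    out = []
    for read_id, dna in reads:
        ex = extract_from_read(read_id, dna, up_flank, down_flank, insert_length)
        if ex is not None:
            out.append(ex)
    return out


@dataclass
class PeptideCountTable:
    """Paired target/control peptide counts — the input of the Z test.

    ``df`` has columns peptide, x_target, x_control; totals are the number of
    successfully extracted peptides per sample (the 'meaningful reads'), not
    raw read counts.
    """

    df: pd.DataFrame
    n_target: int
    n_control: int

    def __post_init__(self) -> None:
        if int(self.df["x_target"].sum()) != self.n_target:
            raise ValueError("x_target does not sum to n_target")
        if int(self.df["x_control"].sum()) != self.n_control:
            raise ValueError("x_control does not sum to n_control")
        if (self.df[["x_target", "x_control"]] < 0).any().any():
            raise ValueError("negative counts")

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["freq_target"] = out["x_target"] / max(self.n_target, 1)
        out["freq_control"] = out["x_control"] / max(self.n_control, 1)
        with open(path, "w") as fh:
            fh.write(f"# n_target={self.n_target}\tn_control={self.n_control}\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PeptideCountTable":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
            df = pd.read_csv(fh, sep="\t")
        df = df[["peptide", "x_target", "x_control"]]
        return cls(df=df, n_target=int(meta["n_target"]), n_control=int(meta["n_control"]))


def count_peptides(
    target_extracts: list[PeptideExtract],
    control_extracts: list[PeptideExtract],
    target_round: int | None = None,
    control_round: int | None = None,
) -> PeptideCountTable:
    """Tabulate paired counts over the union of peptides of both samples.

    Rows are ordered by descending target count, then lexicographically, so
    serialized tables are deterministic.
    """
    if target_round is not None and control_round is not None and target_round != control_round:
        raise ValueError(
            f"paired samples come from different rounds: {target_round} vs {control_round}"
        )
    t = pd.Series([e.insert_peptide for e in target_extracts], dtype=str).value_counts()
    c = pd.Series([e.insert_peptide for e in control_extracts], dtype=str).value_counts()
    df = pd.DataFrame({"x_target": t, "x_control": c}).fillna(0).astype(int)
    df.index.name = "peptide"
    df = df.reset_index()
    df = df.sort_values(
        ["x_target", "peptide"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return PeptideCountTable(
        df=df, n_target=len(target_extracts), n_control=len(control_extracts)
    )


def write_fasta(peptides: list[str], path: str | Path, prefix: str = "pep") -> None:
    """Write unique-peptide FASTA (one record per input peptide, in order)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peptides):
            fh.write(f">{prefix}{i:04d}\n{p}\n")


def read_fasta(path: str | Path) -> list[str]:
    """Read peptide sequences from a FASTA file."""
    seqs: list[str] = []
    cur: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                    cur = []
            else:
                cur.append(line)
    if cur:
        seqs.append("".join(cur))
    return seqs
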