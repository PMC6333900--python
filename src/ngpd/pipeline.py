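"""End-to-end orchestration of the phage-display enrichment workflow.

Stages mirror the experimental flow: simulate (or receive) barcoded amplicon
reads; demultiplex/translate/extract into paired count tables; rank by the
two-proportion Z statistic; discover motifs in the top-ranked set; and fit
ITC heat tables with the one-site model. Each stage writes a small JSON
manifest recording the configuration hash, the seed, and per-stage counts so
that identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, itc, library, motif, reads

logger = logging.getLogger(__name__)

TARGET_BARCODE = "AGTCTGTACA"
CONTROL_BARCODE = "TCAGCAGTGT"


@dataclass
class SimulateConfig:
    out_dir: str
    n_clones: int = 10_000
    insert_length: int = 9
    n_binders: int = 5
    enrichment_factor: float = 10.0
    noise_cv: float = 0.3
    rounds: int = 3
    n_reads: int = 40_000
    error_rate: float = 0.005
    seed: int = 0


@dataclass
class RankConfig:
    fastq: str
    sheet: str
    out_dir: str
    panning_round: int = 3
    insert_length: int = 9
    top_n: int = 50
    barcode_mismatch: int = 0
    pooled: bool = True


def _config_hash(cfg) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_manifest(out_dir: Path, stage: str, cfg, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "config": asdict(cfg) if not isinstance(cfg, dict) else cfg,
        "config_hash": _config_hash(cfg) if not isinstance(cfg, dict) else None,
        **extra,
    }
    (out_dir / f"{stage}_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_simulate(cfg: SimulateConfig) -> dict:
    """Simulate a 3-round panning experiment and emit a multiplexed FASTQ.

    Binder clones are the first ``n_binders`` clones of the seeded library
    (the library itself is random, so this is an unbiased choice). The FASTQ
    holds both round-``rounds`` arms, distinguished by barcode; a barcode
    sheet and a ground-truth sidecar are written next to it.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib = library.build_library(
        library.LibrarySpec(cfg.n_clones, cfg.insert_length, seed=cfg.seed)
    )
    binders = frozenset(p for p, _ in lib[: cfg.n_binders])
    truth = library.EnrichmentTruth(
        binder_peptides=binders,
        per_round_enrichment_factor=cfg.enrichment_factor,
        amplification_noise_cv=cfg.noise_cv,
    )
    panning = library.simulate_panning(lib, truth, rounds=cfg.rounds, seed=cfg.seed + 1)

    sheet = reads.BarcodeSheet(
        [
            reads.BarcodeRow(f"target_r{cfg.rounds}", TARGET_BARCODE, cfg.rounds, "target"),
            reads.BarcodeRow(f"control_r{cfg.rounds}", CONTROL_BARCODE, cfg.rounds, "control"),
        ]
    )
    fastq = out / "reads.fastq"
    t_model = library.ReadModel(TARGET_BARCODE, cfg.n_reads, cfg.error_rate)
    c_model = library.ReadModel(CONTROL_BARCODE, cfg.n_reads, cfg.error_rate)
    library.emit_fastq(lib, panning.target_freqs[-1], t_model, fastq, seed=cfg.seed + 2,
                       read_prefix="t")
    library.emit_fastq(lib, panning.control_freqs[-1], c_model, fastq, seed=cfg.seed + 3,
                       read_prefix="c", append=True)
    sheet.to_tsv(out / "barcodes.tsv")
    library.write_truth_tsv(lib, panning, out / "truth.tsv")
    info = {
        "seed": cfg.seed,
        "n_binders": len(binders),
        "binders": sorted(binders),
        "n_reads_per_arm": cfg.n_reads,
        "files": ["reads.fastq", "barcodes.tsv", "truth.tsv"],
    }
    _write_manifest(out, "simulate", cfg, info)
    logger.info("simulate: %d clones, %d binders, %d reads/arm", cfg.n_clones, len(binders), cfg.n_reads)
    return info


def run_rank(cfg: RankConfig) -> dict:
    """Demultiplex -> translate -> extract -> count -> Z-rank.

    Writes the full ranked table (``ranked.tsv``), the top-N peptide FASTA for
    motif discovery, and the paired count table; logs per-stage counts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = reads.BarcodeSheet.from_tsv(cfg.sheet)
    demux = reads.demultiplex(cfg.fastq, sheet, max_mismatch=cfg.barcode_mismatch)

    t_row = sheet.sample(cfg.panning_round, "target")
    c_row = sheet.sample(cfg.panning_round, "control")
    t_ex = reads.extract_sample(demux.assignments[t_row.sample_id], insert_length=cfg.insert_length)
    c_ex = reads.extract_sample(demux.assignments[c_row.sample_id], insert_length=cfg.insert_length)
    table = reads.count_peptides(t_ex, c_ex, t_row.panning_round, c_row.panning_round)
    table.to_tsv(out / "counts.tsv")

    ranked = enrichment.rank_peptides(table, pooled=cfg.pooled)
    enrichment.enrichment_report(ranked, out / "ranked.tsv")
    top = enrichment.select_top(ranked, cfg.top_n)
    reads.write_fasta(list(top["peptide"]), out / "top_peptides.fasta")

    stats = {
        "reads_total": demux.n_total,
        "reads_assigned": demux.n_assigned,
        "reads_unassigned": demux.n_unassigned,
        "extracted_target": len(t_ex),
        "extracted_control": len(c_ex),
        "unique_peptides": int(len(table.df)),
        "top_n": int(len(top)),
    }
    _write_manifest(out, "rank", cfg, stats)
    logger.info("rank: %s", stats)
    return stats


def run_motif(
    fasta: str,
    out_dir: str,
    n_motifs: int = 2,
    widths: tuple[int, ...] = (6, 7, 8),
    n_starts: int = 10,
    seed: int = 0,
) -> list[motif.MotifModel]:
    """Sequential motif discovery with erasure, plus degenerate-pattern report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peptides = reads.read_fasta(fasta)
    if not peptides:
        raise ValueError(f"no peptides in {fasta}")
    models = motif.discover_motifs(
        peptides, n_motifs=n_motifs, widths=widths, n_starts=n_starts, seed=seed
    )
    rows = []
    for k, model in enumerate(models, start=1):
        motif.write_pwm_tsv(model, out / f"motif{k}_pwm.tsv")
        if model.degenerate:
            logger.warning("motif %d is degenerate (trivial input)", k)
    # pattern-match report against the two published consensus patterns
    for p in peptides:
        m1, o1 = motif.match_degenerate(p, motif.MOTIF_1)
        m2, o2 = motif.match_degenerate(p, motif.MOTIF_2)
        rows.append(
            {"peptide": p, "matches_motif1": int(m1), "offset_motif1": o1,
             "matches_motif2": int(m2), "offset_motif2": o2}
        )
    pd.DataFrame(rows).to_csv(out / "pattern_matches.tsv", sep="\t", index=False)
    cfg = {"fasta": str(fasta), "n_motifs": n_motifs, "widths": list(widths),
           "n_starts": n_starts, "seed": seed}
    _write_manifest(out, "motif", cfg, {
        "n_input": len(peptides),
        "motifs": [
            {"width": m.width, "consensus": m.consensus(), "lambda": m.lam,
             "log_likelihood": m.log_likelihood, "n_members": len(m.members)}
            for m in models
        ],
    })
    return models


def run_itcfit(
    heat_files: list[str],
    out_dir: str,
    cell_volume_ml: float = 1.4,
    cell_um: float = 30.0,
    syringe_um: float = 300.0,
    exclude_first: bool = True,
) -> pd.DataFrame:
    """Fit one or more heat tables with the one-site model; batch-tolerant."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in heat_files:
        row: dict = {"file": str(f)}
        try:
            heats = itc.InjectionHeats.from_csv(f, cell_volume_ml, cell_um, syringe_um)
            fit = itc.fit_one_site(heats, exclude_first=exclude_first)
            row.update(
                n_sites=fit.n_sites, n_sites_se=fit.n_sites_se,
                kd_um=fit.kd_m * 1e6, kd_se_um=fit.kd_se_m * 1e6,
                dh_kcal_per_mol=fit.dh_kcal_per_mol, dh_se=fit.dh_se,
                q_dil_kcal_per_mol=fit.q_dil_kcal_per_mol,
                c_value=fit.c_value, rss=fit.rss, converged=fit.converged,
            )
        except Exception as exc:  # keep the batch alive
            logger.error("fit failed for %s: %s", f, exc)
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "itc_fits.tsv", sep="\t", index=False)
    return df


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
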