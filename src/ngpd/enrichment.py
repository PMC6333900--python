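"""Two-proportion Z-test ranking of target-vs-control peptide enrichment.

For a peptide seen x1 times among n1 extracted target-arm peptides and x2
times among n2 control-arm peptides, the pooled two-proportion statistic is

    Z = (p1 - p2) / sqrt( p*(1-p*) (1/n1 + 1/n2) ),   p* = (x1+x2)/(n1+n2)

with p1 = x1/n1, p2 = x2/n2. Positive Z means target-enriched; the statistic
rewards both the frequency ratio and the absolute abundance, which is what
makes it a useful ranking score for biopanning output. No continuity
correction is applied, so Z^2 equals the 1-df chi-square statistic of the
corresponding 2x2 table.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .reads import PeptideCountTable

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["peptide", "z", "x1", "n1", "x2", "n2", "p1", "p2"]


def two_proportion_z(
    x1: int, n1: int, x2: int, n2: int, pooled: bool = True, pseudocount: float = 0.0
) -> float:
    """Two-proportion Z statistic; NaN sentinel when the statistic is undefined.

    Undefined cases are x1+x2 = 0 and pooled proportion 1 (all observations
    are this peptide), where the pooled variance vanishes. With
    ``pooled=False`` the unpooled (Welch-style) variance p1(1-p1)/n1 +
    p2(1-p2)/n2 is used instead.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample totals must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    x1 = x1 + pseudocount
    x2 = x2 + pseudocount
    n1 = n1 + 2 * pseudocount
    n2 = n2 + 2 * pseudocount
    p1 = x1 / n1
    p2 = x2 / n2
    if pooled:
        p = (x1 + x2) / (n1 + n2)
        var = p * (1 - p) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var <= 0:
        return math.nan
    return (p1 - p2) / math.sqrt(var)


def z_scores(
    x1: np.ndarray, n1: int, x2: np.ndarray, n2: int, pooled: bool = True
) -> np.ndarray:
    """Vectorized pooled/unpooled Z over arrays of paired counts."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    p1 = x1 / n1
    p2 = x2 / n2
    if pooled:
        p = (x1 + x2) / (n1 + n2)
        var = p * (1 - p) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(var), np.nan)
    return z


def rank_peptides(
    table: PeptideCountTable, pooled: bool = True
) -> pd.DataFrame:
    """Rank all peptides by Z score, descending.

    Ties are broken by target count (descending) then peptide lexicographic
    order; rows with an undefined statistic sort last. Returns the full ranked
    table with columns peptide, z, x1, n1, x2, n2, p1, p2.
    """
    if len(table.df) == 0:
        logger.warning("empty count table: nothing to rank")
        return pd.DataFrame(columns=REPORT_COLUMNS)
    df = pd.DataFrame(
        {
            "peptide": table.df["peptide"],
            "x1": table.df["x_target"].astype(int),
            "x2": table.df["x_control"].astype(int),
        }
    )
    df["n1"] = table.n_target
    df["n2"] = table.n_control
    df["p1"] = df["x1"] / table.n_target
    df["p2"] = df["x2"] / table.n_control
    df["z"] = z_scores(df["x1"].to_numpy(), table.n_target, df["x2"].to_numpy(), table.n_control, pooled)
    if df["z"].isna().all():
        logger.warning("all Z statistics undefined")
    df = df.sort_values(
        ["z", "x1", "peptide"], ascending=[False, False, True], na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return df[REPORT_COLUMNS]


def select_top(ranked: pd.DataFrame, top_n: int = 50) -> pd.DataFrame:
    """The top-N peptides used for motif discovery.

    Drops rows with undefined Z and peptides never seen in the target arm
    (x1 = 0: these can only be control-enriched and carry no motif signal for
    the target).
    """
    if ranked.empty:
        return ranked.copy()
    z = ranked["z"].astype(float)
    valid = ranked[np.isfinite(z) & (ranked["x1"] > 0)]
    return valid.head(top_n).reset_index(drop=True)


def enrichment_report(records: pd.DataFrame, path: str | Path) -> None:
    """Serialize ranked records as TSV with the fixed column order."""
    out = records.reindex(columns=REPORT_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back an enrichment report written by :func:`enrichment_report`."""
    return pd.read_csv(path, sep="\t")
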