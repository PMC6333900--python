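"""Ungapped motif discovery in peptide sets by ZOOPS expectation-maximization.

The model is the classic zero-or-one-occurrence-per-sequence (ZOOPS) mixture
used by MEME-style motif elicitation: each peptide either contains one
occurrence of a width-w motif (prior probability lambda, offset uniform over
the feasible positions) emitted from a position weight matrix, or is pure
background. EM alternates computing per-sequence, per-offset occurrence
posteriors with re-estimating the PWM, lambda, and the background residue
frequencies; the data log-likelihood is non-decreasing across iterations.

The module also makes the field's degenerate-consensus notation executable:
patterns over fixed residues, wildcard X, the nonpolar class phi, the charged
class (+/-), and explicit alternative sets such as (YNHC) or (RP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._codons import AA_INDEX, AMINO_ACIDS

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.01
_LAMBDA_MIN, _LAMBDA_MAX = 1e-6, 1.0 - 1e-6

#: residue classes of the degenerate-consensus notation
NONPOLAR = frozenset("AVLIMFWPGC")  # phi
CHARGED = frozenset("DEKRH")  # (+/-)
ANY = frozenset(AMINO_ACIDS)  # X


@dataclass
class MotifModel:
    """A fitted ZOOPS motif: PWM, background, occurrence prior, membership."""

    width: int
    pwm: np.ndarray  # (width, 20) row-stochastic
    background: np.ndarray  # (20,)
    lam: float  # ZOOPS per-sequence occurrence prior
    log_likelihood: float
    members: list[tuple[int, int]]  # (sequence index, best offset), posterior > 0.5
    ll_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.pwm.argmax(axis=1))


def _encode(peptides: list[str]) -> list[np.ndarray]:
    enc = []
    for p in peptides:
        try:
            enc.append(np.array([AA_INDEX[a] for a in p], dtype=np.intp))
        except KeyError as e:
            raise ValueError(f"non-standard residue {e} in peptide {p!r}") from None
    return enc


def _zoops_ll_and_posteriors(
    seqs: list[np.ndarray],
    log_pwm: np.ndarray,
    log_bg: np.ndarray,
    lam: float,
) -> tuple[float, list[np.ndarray]]:
    """E-step: total log-likelihood and per-sequence offset posteriors z_ij.

    For sequence i with m_i feasible offsets,
      P(seq_i) = (1-lam) P_bg(seq_i) + (lam/m_i) sum_j P_motif(seq_i | j)
    and z_ij is the posterior of an occurrence at offset j.
    """
    w = log_pwm.shape[0]
    total_ll = 0.0
    posteriors = []
    for s in seqs:
        m = s.size - w + 1
        bg_ll = float(log_bg[s].sum())
        # log-ratio of motif window vs background for each offset
        ratios = np.empty(m)
        for j in range(m):
            win = s[j : j + w]
            ratios[j] = float(log_pwm[np.arange(w), win].sum() - log_bg[win].sum())
        a = np.log1p(-lam)
        b = np.log(lam / m) + ratios
        mx = max(a, b.max())
        mix = mx + np.log(np.exp(a - mx) + np.exp(b - mx).sum())
        total_ll += bg_ll + mix
        posteriors.append(np.exp(b - mix))
    return total_ll, posteriors


def _m_step(
    seqs: list[np.ndarray], posteriors: list[np.ndarray], width: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Re-estimate PWM, background, and lambda from expected counts."""
    counts = np.full((width, 20), PSEUDOCOUNT)
    bg_counts = np.full(20, PSEUDOCOUNT)
    q_sum = 0.0
    for s, z in zip(seqs, posteriors):
        np.add.at(bg_counts, s, 1.0)
        for j, zj in enumerate(z):
            if zj > 0:
                win = s[j : j + width]
                np.add.at(counts, (np.arange(width), win), zj)
                np.add.at(bg_counts, win, -zj)
        q_sum += z.sum()
    bg_counts = np.clip(bg_counts, PSEUDOCOUNT, None)
    pwm = counts / counts.sum(axis=1, keepdims=True)
    background = bg_counts / bg_counts.sum()
    lam = float(np.clip(q_sum / len(seqs), _LAMBDA_MIN, _LAMBDA_MAX))
    return pwm, background, lam


def em_fit(
    peptides: list[str],
    width: int,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = 0,
) -> MotifModel:
    """Fit a single ZOOPS motif, keeping the best of ``n_starts`` seeded runs.

    Each start is seeded from one observed width-length subsequence smoothed
    toward the empirical background, the standard MEME-style initialization.
    Start subsequences are drawn from the lexicographically sorted peptide
    list, so the fit is invariant to input order. Convergence is declared
    when the relative log-likelihood change drops below ``tol``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    seqs = _encode(peptides)
    if not seqs:
        raise ValueError("no peptides given")
    if min(s.size for s in seqs) < width:
        raise ValueError("width exceeds shortest peptide length")
    seed_pool = [seqs[i] for i in np.argsort(np.asarray(peptides, dtype=object))]
    rng = np.random.default_rng(seed)

    all_res = np.concatenate(seqs)
    emp_bg = np.bincount(all_res, minlength=20).astype(float)
    emp_bg = (emp_bg + PSEUDOCOUNT) / (emp_bg + PSEUDOCOUNT).sum()
    degenerate = len(np.unique(all_res)) == 1
    if degenerate:
        logger.warning("degenerate input: all residues identical; motif is trivial")

    best: MotifModel | None = None
    for _ in range(n_starts):
        i = rng.integers(0, len(seed_pool))
        j = rng.integers(0, seed_pool[i].size - width + 1)
        seed_win = seed_pool[i][j : j + width]
        pwm = 0.4 * emp_bg[None, :].repeat(width, axis=0)
        pwm[np.arange(width), seed_win] += 0.6
        model = _run_em(seqs, pwm, emp_bg.copy(), 0.5, width, max_iter, tol)
        model.degenerate = degenerate
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    best = _shift_polish(seqs, best, emp_bg, max_iter, tol)
    return best


def _run_em(
    seqs: list[np.ndarray],
    pwm: np.ndarray,
    background: np.ndarray,
    lam: float,
    width: int,
    max_iter: int,
    tol: float,
) -> MotifModel:
    """EM to convergence from a given initialization."""
    trace: list[float] = []
    prev_ll = -np.inf
    posteriors: list[np.ndarray] = []
    for _ in range(max_iter):
        ll, posteriors = _zoops_ll_and_posteriors(seqs, np.log(pwm), np.log(background), lam)
        trace.append(ll)
        if np.isfinite(prev_ll) and ll - prev_ll < tol * abs(prev_ll):
            break
        prev_ll = ll
        pwm, background, lam = _m_step(seqs, posteriors, width)
    members = [
        (i, int(z.argmax())) for i, z in enumerate(posteriors) if z.sum() > 0.5
    ]
    return MotifModel(
        width=width, pwm=pwm, background=background, lam=lam,
        log_likelihood=trace[-1], members=members, ll_trace=trace,
    )


def _shift_polish(
    seqs: list[np.ndarray],
    best: MotifModel,
    emp_bg: np.ndarray,
    max_iter: int,
    tol: float,
) -> MotifModel:
    """Escape register-shifted local optima (MEME-style column shifting).

    Multi-start EM frequently converges to the planted motif displaced by one
    column; re-running EM from the +/-1-shifted PWM finds the neighbouring
    basin, and the higher-likelihood register wins.
    """
    w = best.width
    improved = True
    rounds = 0
    while improved and rounds < w:
        improved = False
        rounds += 1
        for shift in (-1, 1):
            pwm = np.tile(emp_bg, (w, 1)).astype(float)
            if shift == 1:
                pwm[:-1] = best.pwm[1:]
            else:
                pwm[1:] = best.pwm[:-1]
            cand = _run_em(seqs, pwm, best.background.copy(), best.lam, w, max_iter, tol)
            if cand.log_likelihood > best.log_likelihood + 1e-9 * abs(best.log_likelihood):
                cand.degenerate = best.degenerate
                best = cand
                improved = True
    return best


def background_log_likelihood(peptides: list[str]) -> float:
    """Log-likelihood of a motif-free model with the ML (empirical) background."""
    seqs = _encode(peptides)
    all_res = np.concatenate(seqs)
    counts = np.bincount(all_res, minlength=20).astype(float)
    freqs = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.where(counts > 0, counts * np.log(freqs), 0.0).sum())
    return ll


def fit_best_width(
    peptides: list[str],
    widths: tuple[int, ...] = (6, 7, 8),
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = 0,
) -> MotifModel:
    """Scan candidate widths; keep the model with the largest per-motif-column
    likelihood ratio versus the background-only model (a likelihood comparison
    across widths needs the per-column normalization because wider motifs
    always fit at least as well)."""
    ll0 = background_log_likelihood(peptides)
    best = None
    best_score = -np.inf
    for k, w in enumerate(widths):
        sub = None if seed is None else seed + k
        model = em_fit(peptides, w, n_starts=n_starts, max_iter=max_iter, tol=tol, seed=sub)
        score = (model.log_likelihood - ll0) / w
        if score > best_score:
            best, best_score = model, score
    assert best is not None
    return best


def discover_motifs(
    peptides: list[str],
    n_motifs: int = 2,
    widths: tuple[int, ...] = (6, 7, 8),
    n_starts: int = 10,
    seed: int | None = 0,
) -> list[MotifModel]:
    """Sequential multi-motif discovery with erasure.

    After each motif is fitted, its member sequences are removed and the
    search repeats on the remainder (the simplest faithful variant of
    MEME's probabilistic erasure). Member indices in the returned models
    refer to the peptide list each round was fitted on.
    """
    remaining = list(peptides)
    models = []
    for k in range(n_motifs):
        if len(remaining) < 2 or min(len(p) for p in remaining) < min(widths):
            logger.warning("too few sequences left for motif %d", k + 1)
            break
        sub = None if seed is None else seed + 1000 * k
        model = fit_best_width(remaining, widths=widths, n_starts=n_starts, seed=sub)
        models.append(model)
        member_idx = {i for i, _ in model.members}
        remaining = [p for i, p in enumerate(remaining) if i not in member_idx]
    return models


def information_content(model: MotifModel) -> np.ndarray:
    """Per-position relative entropy (bits) of the PWM versus the background.

    IC_i = sum_a pwm[i,a] log2(pwm[i,a]/bg[a]); zero iff the row equals the
    background, log2(20) for a point mass against a uniform background.
    """
    pwm = model.pwm
    bg = model.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pwm > 0, pwm * np.log2(pwm / bg), 0.0)
    return terms.sum(axis=1)


# ---------------------------------------------------------------------------
# degenerate consensus patterns


@dataclass(frozen=True)
class DegeneratePattern:
    """Residue-class consensus pattern, e.g. ``(YNHC)-(±)-L-(±)-φ-R``."""

    positions: tuple[frozenset[str], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("empty pattern")
        if all(p == ANY for p in self.positions):
            raise ValueError("pattern must have at least one non-wildcard position")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def parse(cls, text: str, label: str = "") -> "DegeneratePattern":
        """Parse dash-separated notation.

        Tokens: a single residue letter; ``X`` (any); ``φ``/``phi`` (nonpolar);
        ``±``/``+-``/``(±)`` (charged); ``(ABC)`` or ``[ABC]`` (alternatives).
        """
        import re

        # tokens are parenthesized groups or runs without dashes, so a dash
        # inside (+-) does not split the token
        tokens = re.findall(r"\([^)]*\)|\[[^\]]*\]|[^-\s]+", text)
        positions = []
        for tok in tokens:
            core = tok.strip("()[]")
            if core in ("±", "+-", "+/−", "+/-"):
                positions.append(CHARGED)
            elif core in ("φ", "phi"):
                positions.append(NONPOLAR)
            elif core == "X":
                positions.append(ANY)
            else:
                if set(core) - set(AMINO_ACIDS):
                    raise ValueError(f"unknown token {tok!r}")
                positions.append(frozenset(core))
        return cls(tuple(positions), label=label or text)


#: the two consensus motifs recovered from the top-50 USP11 binders
MOTIF_1 = DegeneratePattern.parse("(YNHC)-(±)-L-(±)-φ-R", label="motif1")
MOTIF_2 = DegeneratePattern.parse("L-X-L-φ-X-X-S-(RP)", label="motif2")


def match_degenerate(
    peptide: str, pattern: DegeneratePattern
) -> tuple[bool, int | None]:
    """Slide the pattern along the peptide; return (matches, first offset)."""
    w = len(pattern)
    for off in range(len(peptide) - w + 1):
        if all(peptide[off + k] in pattern.positions[k] for k in range(w)):
            return True, off
    return False, None


def write_pwm_tsv(model: MotifModel, path) -> None:
    """Motif matrix as TSV: rows = positions, columns = residues, plus IC."""
    import pandas as pd

    df = pd.DataFrame(model.pwm, columns=list(AMINO_ACIDS))
    df.insert(0, "position", np.arange(1, model.width + 1))
    df["information_bits"] = information_content(model)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_logo(model: MotifModel, path) -> None:
    """Render a simple information-content-scaled sequence logo (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = information_content(model)
    fig, ax = plt.subplots(figsize=(0.6 * model.width + 1, 3))
    for i in range(model.width):
        heights = model.pwm[i] * ic[i]
        order = np.argsort(heights)
        y = 0.0
        for a in order:
            h = heights[a]
            if h < 0.01:
                continue
            ax.text(
                i + 0.5, y + h / 2, AMINO_ACIDS[a],
                ha="center", va="center", fontsize=6 + 14 * h / max(ic.max(), 1e-9),
                family="monospace",
            )
            y += h
    ax.set_xlim(0, model.width)
    ax.set_ylim(0, max(ic.max(), 1.0) * 1.05)
    ax.set_xticks(np.arange(model.width) + 0.5, np.arange(1, model.width + 1))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
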