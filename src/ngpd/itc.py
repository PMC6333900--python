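"""One-site isothermal titration calorimetry: forward model, simulation, fitting.

The forward model is the standard single-class-of-sites isotherm for an
overfilled perfusion cell. After cumulative injected volume dV the effective
cell concentrations are

    M = M0 exp(-dV/V0)          (titrand, protein)
    X = Xs (1 - exp(-dV/V0))    (titrant, peptide)

and the complex concentration is the physical root of the mass-action
quadratic  c^2 - c (N M + X + Kd) + N M X = 0.  The cumulative heat is
Q = V0 dH c; the per-injection heat applies the displaced-volume correction

    dq_i = Q_i - Q_{i-1} + (dv_i / V0) (Q_i + Q_{i-1}) / 2

and is reported normalized per mole of injectant (kcal/mol) plus a constant
dilution-heat offset. Fitting is multi-start weighted nonlinear least squares
over (N, ln Ka, dH, q_dil) with standard errors from the Jacobian. Internal
units are calories (MicroCal convention), litres, and molar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument protocol: cell volume/concentration, syringe, injection schedule."""

    cell_volume_l: float
    cell_conc_m: float
    syringe_conc_m: float
    injection_volumes_l: tuple[float, ...]
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_volume_l <= 0 or self.cell_conc_m <= 0 or self.syringe_conc_m <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if not self.injection_volumes_l or any(v <= 0 for v in self.injection_volumes_l):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_l)

    @property
    def cumulative_volumes_l(self) -> np.ndarray:
        return np.cumsum(self.injection_volumes_l)


def vp_itc_protocol(
    n_injections: int = 35,
    injection_ul: float = 8.0,
    cell_um: float = 30.0,
    syringe_um: float = 300.0,
    cell_volume_ml: float = 1.4,
    temperature_c: float = 25.0,
) -> TitrationProtocol:
    """A VP-ITC style protocol; defaults reproduce the peptide/USP11_DU setup
    (30 uM protein in the cell, 300 uM peptide in the syringe, 8-ul
    injections at 25 C)."""
    return TitrationProtocol(
        cell_volume_l=cell_volume_ml * 1e-3,
        cell_conc_m=cell_um * 1e-6,
        syringe_conc_m=syringe_um * 1e-6,
        injection_volumes_l=tuple([injection_ul * 1e-6] * n_injections),
        temperature_k=273.15 + temperature_c,
    )


@dataclass
class InjectionHeats:
    """Integrated per-injection heats, raw (cal) and normalized (kcal/mol injectant)."""

    raw_heats_cal: np.ndarray
    normalized_kcal_per_mol: np.ndarray
    protocol: TitrationProtocol

    def __post_init__(self) -> None:
        n = self.protocol.n_injections
        if len(self.raw_heats_cal) != n or len(self.normalized_kcal_per_mol) != n:
            raise ValueError("heat array lengths must match the protocol")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "injection_index": np.arange(1, self.protocol.n_injections + 1),
                "volume_ul": np.asarray(self.protocol.injection_volumes_l) * 1e6,
                "heat_ucal": self.raw_heats_cal * 1e6,
                "normalized_kcal_per_mol": self.normalized_kcal_per_mol,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, cell_volume_ml: float, cell_um: float, syringe_um: float,
        temperature_c: float = 25.0,
    ) -> "InjectionHeats":
        df = pd.read_csv(path)
        protocol = TitrationProtocol(
            cell_volume_l=cell_volume_ml * 1e-3,
            cell_conc_m=cell_um * 1e-6,
            syringe_conc_m=syringe_um * 1e-6,
            injection_volumes_l=tuple(df["volume_ul"].to_numpy() * 1e-6),
            temperature_k=273.15 + temperature_c,
        )
        return cls(
            raw_heats_cal=df["heat_ucal"].to_numpy() * 1e-6,
            normalized_kcal_per_mol=df["normalized_kcal_per_mol"].to_numpy(),
            protocol=protocol,
        )


@dataclass
class OneSiteFit:
    """Fitted one-site parameters with asymptotic standard errors."""

    n_sites: float
    kd_m: float
    dh_kcal_per_mol: float
    q_dil_kcal_per_mol: float
    n_sites_se: float
    kd_se_m: float
    dh_se: float
    q_dil_se: float
    rss: float
    c_value: float
    converged: bool

    @property
    def ka_m(self) -> float:
        return 1.0 / self.kd_m

    @property
    def kd_identifiable(self) -> bool:
        """False when the data do not constrain K_D (SE exceeds the estimate)."""
        return bool(np.isfinite(self.kd_se_m) and self.kd_se_m < self.kd_m)


def effective_concentrations(
    protocol: TitrationProtocol, i: int, dilution: str = "continuous"
) -> tuple[float, float]:
    """Cell concentrations (M_i, X_i) after injection i (1-based; i=0 gives the start).

    ``dilution="continuous"`` uses the exponential displacement correction for
    an overfilled perfusion cell (the default); ``"discrete"`` applies the
    per-injection (1 - v/V0) dilution products instead. The two agree to
    first order in v/V0.
    """
    if not (0 <= i <= protocol.n_injections):
        raise ValueError(f"injection index {i} out of range")
    if dilution == "continuous":
        dv = 0.0 if i == 0 else float(protocol.cumulative_volumes_l[i - 1])
        decay = np.exp(-dv / protocol.cell_volume_l)
        return protocol.cell_conc_m * decay, protocol.syringe_conc_m * (1.0 - decay)
    if dilution == "discrete":
        m, x = protocol.cell_conc_m, 0.0
        for dv in protocol.injection_volumes_l[:i]:
            f = 1.0 - dv / protocol.cell_volume_l
            m *= f
            x = x * f + protocol.syringe_conc_m * dv / protocol.cell_volume_l
        return m, x
    raise ValueError(f"unknown dilution mode {dilution!r}")


def bound_fraction(m_t: float, x_t: float, kd: float, n_sites: float = 1.0) -> float:
    """Complex concentration from the mass-action quadratic (physical root).

    Written in the numerically stable form c = 2 N M X / (b + sqrt(b^2 - 4 N M X))
    with b = N M + X + Kd, which avoids cancellation in the tight-binding limit.
    """
    if m_t <= 0 or kd <= 0 or n_sites <= 0 or x_t < 0:
        raise ValueError("concentrations, Kd and N must be positive (X_t >= 0)")
    sites = n_sites * m_t
    b = sites + x_t + kd
    disc = b * b - 4.0 * sites * x_t
    return 2.0 * sites * x_t / (b + np.sqrt(max(disc, 0.0)))


def _complex_trajectory(
    protocol: TitrationProtocol, n_sites: float, kd: float, dilution: str = "continuous"
) -> np.ndarray:
    """Complex concentration after injections 0..n (index 0 = before any injection)."""
    out = np.empty(protocol.n_injections + 1)
    for i in range(protocol.n_injections + 1):
        m, x = effective_concentrations(protocol, i, dilution)
        out[i] = bound_fraction(m, x, kd, n_sites) if x > 0 else 0.0
    return out


def predict_heats(
    protocol: TitrationProtocol,
    n_sites: float,
    kd: float,
    dh_kcal_per_mol: float,
    q_dil_kcal_per_mol: float = 0.0,
    dilution: str = "continuous",
) -> InjectionHeats:
    """Model per-injection heats for one-site binding.

    Raw heats are in calories; normalized heats divide by the moles of
    injectant delivered per injection and add the dilution offset.
    """
    dh_cal = dh_kcal_per_mol * 1e3
    complex_conc = _complex_trajectory(protocol, n_sites, kd, dilution)
    q_cum = protocol.cell_volume_l * dh_cal * complex_conc  # cal
    dv = np.asarray(protocol.injection_volumes_l)
    raw = (
        q_cum[1:]
        - q_cum[:-1]
        + (dv / protocol.cell_volume_l) * (q_cum[1:] + q_cum[:-1]) / 2.0
    )
    moles = protocol.syringe_conc_m * dv
    normalized = raw / moles / 1e3 + q_dil_kcal_per_mol  # kcal/mol
    raw_with_dil = raw + q_dil_kcal_per_mol * 1e3 * moles
    return InjectionHeats(
        raw_heats_cal=raw_with_dil, normalized_kcal_per_mol=normalized, protocol=protocol
    )


def peak_noise_sd(
    protocol: TitrationProtocol,
    n_sites: float,
    kd: float,
    dh_kcal_per_mol: float,
    frac: float = 0.02,
) -> float:
    """Noise SD (kcal/mol) equal to ``frac`` of the peak normalized model heat."""
    model = predict_heats(protocol, n_sites, kd, dh_kcal_per_mol, 0.0)
    return frac * float(np.abs(model.normalized_kcal_per_mol).max())


def simulate_titration(
    protocol: TitrationProtocol,
    n_sites: float,
    kd: float,
    dh_kcal_per_mol: float,
    q_dil_kcal_per_mol: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> InjectionHeats:
    """Model heats plus i.i.d. Gaussian noise on the normalized heats."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = predict_heats(protocol, n_sites, kd, dh_kcal_per_mol, q_dil_kcal_per_mol)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=protocol.n_injections)
    normalized = clean.normalized_kcal_per_mol + noise
    moles = protocol.syringe_conc_m * np.asarray(protocol.injection_volumes_l)
    raw = clean.raw_heats_cal + noise * 1e3 * moles
    return InjectionHeats(raw_heats_cal=raw, normalized_kcal_per_mol=normalized, protocol=protocol)


def fit_one_site(
    heats: InjectionHeats,
    protocol: TitrationProtocol | None = None,
    exclude_first: bool = True,
    float_n: bool = True,
    ka_grid: np.ndarray | None = None,
    allow_extreme_c: bool = False,
) -> OneSiteFit:
    """Fit (N, K_D, dH, q_dil) to normalized heats by least squares.

    Multi-start over a log-spaced K_a grid; the first injection is excluded by
    default (syringe-tip diffusion makes it unreliable in practice). Standard
    errors come from the Jacobian at the optimum; the K_D error bar is
    withheld (NaN, with a warning) when the c-value N*M0/K_D falls outside
    [0.1, 1000], where the isotherm shape no longer constrains K_D, unless
    ``allow_extreme_c`` is set.
    """
    protocol = protocol or heats.protocol
    y = np.asarray(heats.normalized_kcal_per_mol, dtype=float)
    use = np.ones(len(y), dtype=bool)
    if exclude_first:
        use[0] = False
    if use.sum() < 6:
        raise ValueError("need at least 6 usable injections")
    y_use = y[use]

    dh0 = y_use[np.argmax(np.abs(y_use))] - y_use[-1]
    if dh0 == 0:
        dh0 = -1.0
    q0 = float(np.mean(y_use[-3:]))
    if ka_grid is None:
        ka_grid = np.logspace(3, 9, 7)

    def residuals(theta: np.ndarray) -> np.ndarray:
        if float_n:
            n_sites, ln_ka, dh, q_dil = theta
        else:
            ln_ka, dh, q_dil = theta
            n_sites = 1.0
        model = predict_heats(protocol, n_sites, np.exp(-ln_ka), dh, q_dil)
        return model.normalized_kcal_per_mol[use] - y_use

    best = None
    for ka0 in ka_grid:
        theta0 = (
            np.array([1.0, np.log(ka0), dh0, q0])
            if float_n
            else np.array([np.log(ka0), dh0, q0])
        )
        lower = [1e-3, np.log(1.0), -np.inf, -np.inf] if float_n else [np.log(1.0), -np.inf, -np.inf]
        upper = [100.0, np.log(1e15), np.inf, np.inf] if float_n else [np.log(1e15), np.inf, np.inf]
        try:
            res = least_squares(residuals, theta0, bounds=(lower, upper), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("one-site fit failed from every start")
    if not best.success:
        logger.warning("fit did not report convergence; returning best partial result")

    theta = best.x
    if float_n:
        n_sites, ln_ka, dh, q_dil = theta
    else:
        ln_ka, dh, q_dil = theta
        n_sites = 1.0
    kd = float(np.exp(-ln_ka))
    rss = float(2 * best.cost)
    dof = max(int(use.sum()) - len(theta), 1)
    s2 = rss / dof
    jac = best.jac
    # pseudo-inverse guards the unidentifiable (flat-heat) case
    cov = s2 * np.linalg.pinv(jac.T @ jac)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    # parameters lying in the Jacobian's null space are unconstrained by the
    # data (e.g. K_a when dH ~ 0): report infinite error, not a spurious 0
    _, sv, vt = np.linalg.svd(jac, full_matrices=False)
    null_dirs = vt[sv < sv.max() * 1e-8]
    if null_dirs.size:
        se[(np.abs(null_dirs) > 1e-6).any(axis=0)] = np.inf
    if float_n:
        n_se, ln_ka_se, dh_se, q_se = se
    else:
        ln_ka_se, dh_se, q_se = se
        n_se = 0.0
    kd_se = kd * ln_ka_se  # delta method on ln Ka

    c_value = n_sites * protocol.cell_conc_m / kd
    if not allow_extreme_c and not (0.1 <= c_value <= 1000.0):
        warnings.warn(
            f"c-value {c_value:.3g} outside [0.1, 1000]: K_D error bar withheld",
            stacklevel=2,
        )
        kd_se = float("nan")

    return OneSiteFit(
        n_sites=float(n_sites),
        kd_m=kd,
        dh_kcal_per_mol=float(dh),
        q_dil_kcal_per_mol=float(q_dil),
        n_sites_se=float(n_se),
        kd_se_m=float(kd_se),
        dh_se=float(dh_se),
        q_dil_se=float(q_se),
        rss=rss,
        c_value=float(c_value),
        converged=bool(best.success),
    )


def trapezoid_integrate_power(
    time_s: np.ndarray, power_ucal_per_s: np.ndarray, boundaries_s: np.ndarray
) -> np.ndarray:
    """Integrate a synthetic power trace into per-injection heats (ucal).

    Only intended for synthetic traces: real thermogram baseline estimation
    and peak integration belong to dedicated instrument software.
    """
    heats = []
    for lo, hi in zip(boundaries_s[:-1], boundaries_s[1:]):
        m = (time_s >= lo) & (time_s <= hi)
        heats.append(np.trapezoid(power_ucal_per_s[m], time_s[m]))
    return np.asarray(heats)


# Reference one-site parameters for the two USP11_DU peptide ligands, used by
# the worked examples and validation simulations: dissociation constants as
# measured for the FYLIR (AEGEFYKLKIRTPQ) and LXLL (AEGEFLELLKASRW) peptides.
# Enthalpies are typical exothermic values for peptide-domain binding; the
# published isotherms constrain K_D, not dH, at this level of description.
FYLIR_PARAMS = {"n_sites": 1.0, "kd": 8.86e-6, "dh_kcal_per_mol": -10.0}
LXLL_PARAMS = {"n_sites": 1.0, "kd": 6.92e-6, "dh_kcal_per_mol": -8.0}
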