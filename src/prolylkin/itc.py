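"""Isothermal titration calorimetry: simulation and fitting of one- and
two-independent-site binding isotherms.

A peptide titrant is injected stepwise into a cell containing the protein;
each injection releases the heat of the newly formed complexes.  For a set
of independent site classes j (stoichiometry n_j, dissociation constant
K_D,j, enthalpy dH_j) the cumulative heat content after injection i is

    Q_i = V0 * M_t,i * sum_j n_j * dH_j * [X]_i / (K_D,j + [X]_i),

where [X]_i is the free titrant concentration solving the mass balance

    X_t = [X] + M_t * sum_j n_j * [X] / (K_D,j + [X]).

Differential per-injection heats carry the standard displaced-volume
correction and are normalized per mole of injectant, matching how
instrument software reports isotherms.  Full-length SlyD shows two site
classes (high-affinity chaperone/IF site, weaker catalytic/FKBP site); the
IF-deleted construct shows one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "InjectionProtocol",
    "BindingSite",
    "BindingModel",
    "Isotherm",
    "IsothermFit",
    "free_ligand_solve",
    "simulate_isotherm",
    "fit_isotherm",
]


@dataclass(frozen=True)
class InjectionProtocol:
    """Cell and syringe protocol of a titration experiment (volumes in ul,
    concentrations in uM)."""

    cell_volume_ul: float
    cell_conc_uM: float
    syringe_conc_uM: float
    injection_volumes_ul: tuple[float, ...]
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        vols = tuple(float(v) for v in self.injection_volumes_ul)
        object.__setattr__(self, "injection_volumes_ul", vols)
        if self.cell_volume_ul <= 0 or any(v <= 0 for v in vols):
            raise ValueError("volumes must be > 0")
        if self.cell_conc_uM < 0 or self.syringe_conc_uM < 0:
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def slyd_default(cls) -> "InjectionProtocol":
        """Default peptide-into-SlyD protocol: one 3 ul pre-injection then
        42 x 6.5 ul of 1.2 mM peptide into 50 uM protein at 25 C (VP-ITC
        style 1400 ul cell)."""
        return cls(
            cell_volume_ul=1400.0,
            cell_conc_uM=50.0,
            syringe_conc_uM=1200.0,
            injection_volumes_ul=(3.0,) + (6.5,) * 42,
            temperature_C=25.0,
        )

    def cell_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Total macromolecule and titrant concentrations in the cell after
        each injection (perfusion-cell dilution convention).

        With cumulative injected volume dV, the macromolecule dilutes as
        M_t = M0 * (1 - dV/2V0) / (1 + dV/2V0) and the titrant accumulates
        as X_t = X_syr * (dV/V0) / (1 + dV/2V0).
        """
        dv = np.cumsum(self.injection_volumes_ul)
        v0 = self.cell_volume_ul
        m = self.cell_conc_uM * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        x = self.syringe_conc_uM * (dv / v0) / (1 + dv / (2 * v0))
        return m, x


@dataclass(frozen=True)
class BindingSite:
    """One independent class of binding sites."""

    n: float          # stoichiometry (sites per macromolecule)
    kd_uM: float      # dissociation constant
    dh_kcal_mol: float  # binding enthalpy

    def __post_init__(self) -> None:
        if self.kd_uM <= 0:
            raise ValueError("kd_uM must be > 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")


@dataclass(frozen=True)
class BindingModel:
    """One or two independent site classes, ordered by K_D ascending."""

    sites: tuple[BindingSite, ...]

    def __post_init__(self) -> None:
        sites = tuple(self.sites)
        if not 1 <= len(sites) <= 2:
            raise ValueError("model supports 1 or 2 site classes")
        object.__setattr__(self, "sites", tuple(sorted(sites, key=lambda s: s.kd_uM)))


@dataclass(frozen=True)
class Isotherm:
    """Per-injection heats in kcal per mole of injectant."""

    heats_kcal_mol: np.ndarray
    protocol: InjectionProtocol

    def __post_init__(self) -> None:
        h = np.asarray(self.heats_kcal_mol, dtype=float)
        object.__setattr__(self, "heats_kcal_mol", h)
        if h.shape != (len(self.protocol.injection_volumes_ul),):
            raise ValueError("heats length must match the number of injections")

    def molar_ratios(self) -> np.ndarray:
        """Titrant/macromolecule molar ratio in the cell after each injection."""
        m, x = self.protocol.cell_concentrations()
        return x / m


def free_ligand_solve(x_total_uM: float, m_total_uM: float, model: BindingModel) -> float:
    """Free titrant concentration from the multi-site mass balance.

    Solved by bracketed root-finding on [0, X_t]; the mass-balance function
    is monotone in [X], so the bracket always exists for valid inputs.
    """
    if x_total_uM < 0 or m_total_uM < 0:
        raise ValueError("totals must be >= 0")
    if x_total_uM == 0:
        return 0.0
    if m_total_uM == 0:
        return float(x_total_uM)

    def balance(x_free: float) -> float:
        bound = sum(
            s.n * x_free / (s.kd_uM + x_free) for s in model.sites
        )
        return x_total_uM - x_free - m_total_uM * bound

    if balance(x_total_uM) >= 0:  # binding negligible at the upper bracket
        return float(x_total_uM)
    x = brentq(balance, 0.0, x_total_uM, xtol=1e-12 * max(x_total_uM, 1.0), rtol=1e-14)
    assert abs(balance(x)) < 1e-8 * max(x_total_uM, 1.0)
    return float(x)


def _cumulative_heats(model: BindingModel, protocol: InjectionProtocol) -> np.ndarray:
    """Cumulative heat content Q_i (kcal per liter-free units absorbed into
    the per-mole normalization downstream; see simulate_isotherm)."""
    m_tot, x_tot = protocol.cell_concentrations()
    v0 = protocol.cell_volume_ul
    q = np.empty_like(m_tot)
    for i, (m, x) in enumerate(zip(m_tot, x_tot)):
        x_free = free_ligand_solve(x, m, model)
        q[i] = v0 * m * sum(
            s.n * s.dh_kcal_mol * x_free / (s.kd_uM + x_free) for s in model.sites
        )
    return q  # ul * uM * kcal/mol = 1e-12 kcal


def simulate_isotherm(
    model: BindingModel,
    protocol: InjectionProtocol,
    noise_sd_kcal_mol: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    """Differential per-injection heats for a binding model and protocol.

    Applies the displaced-volume correction dQ_i = Q_i - Q_{i-1} +
    (dV_i/V0) * (Q_i + Q_{i-1})/2 and normalizes by the moles injected;
    optional Gaussian noise (kcal/mol) is seeded.
    """
    q = _cumulative_heats(model, protocol)
    v0 = protocol.cell_volume_ul
    dv = np.asarray(protocol.injection_volumes_ul)
    q_prev = np.concatenate(([0.0], q[:-1]))
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    moles_injected = dv * protocol.syringe_conc_uM  # ul * uM = 1e-12 mol
    heats = dq / moles_injected  # kcal per mole injectant
    if noise_sd_kcal_mol > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd_kcal_mol, heats.size)
    return Isotherm(heats_kcal_mol=heats, protocol=protocol)


@dataclass(frozen=True)
class IsothermFit:
    """Fitted binding model with per-parameter standard errors and flags."""

    model: BindingModel
    standard_errors: dict
    c_values: tuple[float, ...]
    residual_rms: float
    converged: bool
    message: str = ""


def _default_init(data: Isotherm, n_sites: int) -> list[BindingSite]:
    """Crude but serviceable starting values from the isotherm itself."""
    m0 = data.protocol.cell_conc_uM
    h = data.heats_kcal_mol
    dh0 = float(h[1] if h.size > 1 else h[0])
    if dh0 == 0:
        dh0 = -1.0
    if n_sites == 1:
        return [BindingSite(n=1.0, kd_uM=max(m0 / 5.0, 1e-3), dh_kcal_mol=dh0)]
    return [
        BindingSite(n=1.0, kd_uM=max(m0 / 100.0, 1e-4), dh_kcal_mol=dh0),
        BindingSite(n=1.0, kd_uM=max(m0 / 5.0, 1e-3), dh_kcal_mol=0.5 * dh0),
    ]


def fit_isotherm(
    data: Isotherm,
    n_sites: int,
    init: list[BindingSite] | None = None,
    skip_first: bool = True,
    fix_n: float | None = None,
) -> IsothermFit:
    """Least-squares fit of (n_j, K_D,j, dH_j) to an isotherm.

    The first injection (typically a small pre-injection whose syringe tip
    diffusion corrupts the heat) is excluded by default.  K_D is fitted in
    log10 space.  Site classes in the result are ordered by K_D ascending.
    ``fix_n`` pins all stoichiometries at the given value.  A c-value
    (M_t * n / K_D) outside [1, 1000] triggers a warning, as K_D is then
    weakly determined.
    """
    if n_sites not in (1, 2):
        raise ValueError("n_sites must be 1 or 2")
    heats = data.heats_kcal_mol
    mask = np.ones(heats.size, dtype=bool)
    if skip_first:
        mask[0] = False
    if mask.sum() < 10:
        raise ValueError("need at least 10 informative injections")
    if np.max(np.abs(heats[mask])) < 1e-9:
        return IsothermFit(
            model=BindingModel((BindingSite(1.0, 1.0, 0.0),) * 1),
            standard_errors={},
            c_values=(np.nan,) * n_sites,
            residual_rms=0.0,
            converged=False,
            message="all-zero heats: no binding signal to fit",
        )
    sites0 = init if init is not None else _default_init(data, n_sites)
    if len(sites0) != n_sites:
        raise ValueError("init must supply one BindingSite per site class")

    free_n = fix_n is None

    def pack(sites: list[BindingSite]) -> np.ndarray:
        theta = []
        for s in sites:
            if free_n:
                theta.append(s.n)
            theta.extend([np.log10(s.kd_uM), s.dh_kcal_mol])
        return np.array(theta)

    def unpack(theta: np.ndarray) -> list[BindingSite]:
        sites = []
        i = 0
        for _ in range(n_sites):
            if free_n:
                n = theta[i]
                i += 1
            else:
                n = fix_n
            logkd, dh = theta[i], theta[i + 1]
            i += 2
            sites.append(BindingSite(n=max(n, 1e-6), kd_uM=10.0**logkd, dh_kcal_mol=dh))
        return sites

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = BindingModel(tuple(unpack(theta)))
        sim = simulate_isotherm(model, data.protocol)
        return sim.heats_kcal_mol[mask] - heats[mask]

    x0 = pack(sites0)
    lower, upper = [], []
    for _ in range(n_sites):
        if free_n:
            lower.append(0.05)
            upper.append(10.0)
        lower.extend([-6.0, -200.0])
        upper.extend([6.0, 200.0])
    sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
    fitted_sites = unpack(sol.x)

    # covariance from the Jacobian at the optimum
    dof = max(mask.sum() - sol.x.size, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(sol.x.size, np.nan)

    per_site_err = []
    i = 0
    for j in range(n_sites):
        e: dict = {}
        if free_n:
            e["n"] = float(perr[i])
            i += 1
        # log10(Kd) error propagated to Kd: d(Kd) = Kd * ln10 * d(log10 Kd)
        e["kd_uM"] = float(fitted_sites[j].kd_uM * np.log(10.0) * perr[i])
        e["dh_kcal_mol"] = float(perr[i + 1])
        i += 2
        per_site_err.append(e)

    # report site classes ordered by K_D ascending, errors kept in sync
    order = np.argsort([s.kd_uM for s in fitted_sites])
    model = BindingModel(tuple(fitted_sites[j] for j in order))
    errs = {
        f"site{rank}_{key}": val
        for rank, j in enumerate(order)
        for key, val in per_site_err[j].items()
    }

    c_values = tuple(
        data.protocol.cell_conc_uM * s.n / s.kd_uM for s in model.sites
    )
    for c in c_values:
        if not 1.0 <= c <= 1000.0:
            warnings.warn(
                f"c-value {c:.3g} outside [1, 1000]: K_D weakly determined",
                stacklevel=2,
            )
    return IsothermFit(
        model=model,
        standard_errors=errs,
        c_values=c_values,
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
        converged=bool(sol.success),
        message=str(sol.message),
    )
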