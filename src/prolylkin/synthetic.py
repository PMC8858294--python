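"""Seeded synthetic fixtures for every analysis stage.

The generators emulate the statistical structure of the real measurements
so that the full pipeline (spectra -> exchange rates -> activity slope;
isotherm -> binding constants; coordinates -> geometry metrics) can be
exercised and its recovery accuracy quantified without any external data.
Every generator returns a machine-readable truth manifest alongside the
fixture, and the same seed yields bit-identical output.

Default conditions mirror the assay design: 100 uM substrate titrated with
0-6 uM enzyme for the NMR series; one 3 ul then 42 x 6.5 ul injections of
1.2 mM peptide into 50 uM protein for ITC.  The spectral defaults
(p_cis = 0.25, line separation 20 Hz, intrinsic r2 = 8 s^-1) are plausible
values for a leucine methyl doublet of a cis/trans peptide mixture; the
cis population of the real pseudo-wild-type peptide is not published, so
0.25 is an arbitrary but fixed choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .itc import BindingModel, BindingSite, InjectionProtocol, Isotherm, simulate_isotherm
from .lineshape import ExchangeParameters, Spectrum1D, simulate_two_site_spectrum
from .structure import StructureModel

__all__ = [
    "FixtureConfig",
    "generate_titration_spectra",
    "generate_isotherm_data",
    "generate_toy_structures",
    "build_toy_structure",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Ground-truth parameters for all synthetic fixtures."""

    seed: int = 0
    # NMR titration
    substrate_conc_uM: float = 100.0
    enzyme_concs_uM: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0)
    kcat_over_km: float = 3.0        # uM^-1 s^-1
    baseline_rate: float = 0.5       # uncatalysed exchange, s^-1
    p_cis: float = 0.25
    delta_nu_hz: float = 20.0        # cis-trans line separation
    r2: float = 8.0                  # intrinsic relaxation rate, s^-1
    snr: float = 100.0               # peak height / noise sigma
    axis_hz: tuple[float, float, int] = (-60.0, 80.0, 2801)
    # ITC (psWT-like two-site truth: tight chaperone site, weaker FKBP site)
    itc_sites: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.22, -15.4),
        (1.0, 3.5, -6.4),
    )  # (n, K_D uM, dH kcal/mol)
    itc_noise_kcal_mol: float = 0.1
    # toy structures
    structure_states: tuple[tuple[str, float, float], ...] = (
        ("closed", 10.8, 93.5),
        ("tight", 14.2, 83.5),
        ("loose", 19.5, 100.5),
        ("open", 26.8, 120.0),
    )  # (label, d A, delta deg)
    peptide_core_scatter_A: float = 0.3
    peptide_termini_scatter_A: float = 3.0

    def __post_init__(self) -> None:
        if self.substrate_conc_uM <= 0 or self.snr <= 0:
            raise ValueError("substrate_conc_uM and snr must be > 0")
        if self.kcat_over_km < 0 or self.baseline_rate < 0:
            raise ValueError("rates must be >= 0")

    def frequency_axis(self) -> np.ndarray:
        lo, hi, n = self.axis_hz
        return np.linspace(lo, hi, int(n))

    def exchange_params(self, k_ex: float) -> ExchangeParameters:
        return ExchangeParameters(
            p_cis=self.p_cis,
            nu_cis=self.delta_nu_hz,
            nu_trans=0.0,
            r2_cis=self.r2,
            r2_trans=self.r2,
            k_ex=k_ex,
        )


def generate_titration_spectra(
    config: FixtureConfig,
) -> tuple[list[Spectrum1D], dict]:
    """Noisy two-site spectra across the enzyme titration.

    The true exchange rate at each enzyme concentration is
    k_ex = baseline_rate + kcat_over_km * [E]; Gaussian noise is scaled so
    the tallest noiseless peak sits at the configured SNR.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.frequency_axis()
    spectra: list[Spectrum1D] = []
    true_k: list[float] = []
    sigmas: list[float] = []
    for conc in config.enzyme_concs_uM:
        k_ex = config.baseline_rate + config.kcat_over_km * conc
        clean = simulate_two_site_spectrum(config.exchange_params(k_ex), axis)
        sigma = float(np.max(clean.intensity)) / config.snr
        noisy = clean.intensity + rng.normal(0.0, sigma, axis.size)
        spectra.append(Spectrum1D(axis, noisy, noise_sigma=sigma))
        true_k.append(k_ex)
        sigmas.append(sigma)
    manifest = {
        "seed": config.seed,
        "enzyme_concs_uM": list(config.enzyme_concs_uM),
        "true_k_ex": true_k,
        "noise_sigma": sigmas,
        "kcat_over_km": config.kcat_over_km,
        "baseline_rate": config.baseline_rate,
        "p_cis": config.p_cis,
        "nu_cis_hz": config.delta_nu_hz,
        "nu_trans_hz": 0.0,
        "r2": config.r2,
        "snr": config.snr,
    }
    return spectra, manifest


def generate_isotherm_data(config: FixtureConfig) -> tuple[Isotherm, dict]:
    """A noisy isotherm under the default injection protocol."""
    model = BindingModel(
        tuple(BindingSite(n=n, kd_uM=kd, dh_kcal_mol=dh) for n, kd, dh in config.itc_sites)
    )
    protocol = InjectionProtocol.slyd_default()
    iso = simulate_isotherm(
        model, protocol, noise_sd_kcal_mol=config.itc_noise_kcal_mol, seed=config.seed
    )
    manifest = {
        "seed": config.seed,
        "sites": [
            {"n": s.n, "kd_uM": s.kd_uM, "dh_kcal_mol": s.dh_kcal_mol} for s in model.sites
        ],
        "noise_sd_kcal_mol": config.itc_noise_kcal_mol,
        "protocol": {
            "cell_volume_ul": protocol.cell_volume_ul,
            "cell_conc_uM": protocol.cell_conc_uM,
            "syringe_conc_uM": protocol.syringe_conc_uM,
            "n_injections": len(protocol.injection_volumes_ul),
        },
    }
    return iso, manifest


# ---------------------------------------------------------------------------
# toy structures


def _base_protein_coords() -> dict[int, np.ndarray]:
    """Deterministic C-alpha curve for residues 1-150 (anchors overridden)."""
    coords = {}
    for i in range(1, 151):
        coords[i] = np.array(
            [1.4 * i, 9.0 * np.sin(i / 6.0), 9.0 * np.cos(i / 8.0)]
        )
    return coords


def build_toy_structure(
    identifier: str,
    d: float,
    delta_deg: float,
    peptide_coords: dict[int, np.ndarray] | None = None,
    rigid_motion: tuple[np.ndarray, np.ndarray] | None = None,
    site_occupancy: str = "none",
) -> StructureModel:
    """A synthetic two-domain C-alpha model with prescribed (d, delta).

    Anchor residues are placed exactly: CA19 at the origin, CA145 and CA146
    on the x axis, CA95 at the prescribed angle from residue 19, CA99 at
    distance d from CA146.  All other residues follow an arbitrary smooth
    curve.  An optional rigid motion (R, t) is applied to everything, which
    leaves d and delta invariant.
    """
    coords = _base_protein_coords()
    delta = np.radians(delta_deg)
    coords[19] = np.array([0.0, 0.0, 0.0])
    coords[145] = np.array([12.0, 0.0, 0.0])
    coords[146] = np.array([15.0, 0.0, 0.0])
    coords[95] = 14.0 * np.array([np.cos(delta), np.sin(delta), 0.0])
    coords[99] = coords[146] + np.array([0.0, d, 0.0])
    ca: dict[tuple[str, int, str], np.ndarray] = {
        ("A", i, " "): xyz for i, xyz in coords.items()
    }
    if peptide_coords:
        for pos, xyz in peptide_coords.items():
            ca[("B", pos, " ")] = np.asarray(xyz, dtype=float)
    model = StructureModel(
        identifier=identifier,
        ca=ca,
        peptide_chain="B" if peptide_coords else None,
        site_occupancy=site_occupancy,
    )
    if rigid_motion is not None:
        R, t = rigid_motion
        model = model.transformed(np.asarray(R, float), np.asarray(t, float))
    return model


def _base_peptide_coords() -> dict[int, np.ndarray]:
    """Extended 15-residue substrate trace near the catalytic site."""
    return {p: np.array([3.5 * (p - 8) + 6.0, 16.0, 4.0]) for p in range(1, 16)}


#: substrate positions treated as the conformationally conserved core
PEPTIDE_CORE_POSITIONS = tuple(range(5, 12))


def generate_toy_structures(
    config: FixtureConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[StructureModel], dict]:
    """Synthetic structure ensemble: one model per conformational state.

    Every model carries a 15-residue peptide whose core positions (5-11)
    scatter with a small amplitude and whose termini scatter broadly,
    mimicking a substrate that is conformationally conserved around the
    proline and disordered at the ends.  Each model receives a random
    global rigid motion (seeded), which the geometry metrics must ignore.
    If ``out_dir`` is given, each model is also written as a PDB file.
    """
    rng = np.random.default_rng(config.seed)
    models: list[StructureModel] = []
    truth = []
    for label, d, delta in config.structure_states:
        pep = {}
        for pos, base in _base_peptide_coords().items():
            sd = (
                config.peptide_core_scatter_A
                if pos in PEPTIDE_CORE_POSITIONS
                else config.peptide_termini_scatter_A
            )
            pep[pos] = base + rng.normal(0.0, sd, 3)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20.0, 20.0, 3)
        model = build_toy_structure(
            identifier=f"synthetic_{label}",
            d=d,
            delta_deg=delta,
            peptide_coords=pep,
            rigid_motion=(R, t),
            site_occupancy="FKBP_only",
        )
        models.append(model)
        truth.append({"id": model.identifier, "label": label, "d": d, "delta_deg": delta})
    manifest = {
        "seed": config.seed,
        "models": truth,
        "peptide_core_positions": list(PEPTIDE_CORE_POSITIONS),
        "core_scatter_A": config.peptide_core_scatter_A,
        "termini_scatter_A": config.peptide_termini_scatter_A,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for model in models:
            write_ca_pdb(model, out / f"{model.identifier}.pdb")
    return models, manifest


def write_ca_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a C-alpha-only PDB rendering of a StructureModel (ALA/GLY
    placeholders; one CA atom per residue)."""
    st = gemmi.Structure()
    st.name = model.identifier
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    keys = sorted(model.ca.keys())
    for chain_name, resnum, icode in keys:
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(resnum, icode if icode.strip() else " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        x, y, z = model.ca[(chain_name, resnum, icode)]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        res.add_atom(atom)
        chains[chain_name].add_residue(res)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
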