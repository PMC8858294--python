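"""Inter-domain geometry and superposition analysis of two-domain
isomerase structures.

SlyD consists of a catalytic FKBP domain (residues 1-66 + 125-150) and a
chaperone IF domain inserted in its flap (residues 70-117).  The relative
placement of the two domains is summarized by two coarse metrics measured
on C-alpha atoms: the distance d between residues 99 (IF) and 146 (FKBP)
and the angle delta at residue 19 subtended by residues 145 and 95.
Structures cluster into closed / tight / loose / open conformational
states in the (d, delta) plane; classification here is nearest-centroid in
standardized coordinates against a labelled reference set, with a cutoff
beyond which a structure is called "intermediate".

Coordinate I/O is handled by gemmi (PDB and mmCIF); superpositions use the
Kabsch SVD algorithm on C-alpha atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "DomainDefinition",
    "ConformationMetrics",
    "SuperpositionResult",
    "FKBP_DOMAIN",
    "IF_DOMAIN",
    "FKBP_CORE",
    "load_coordinates",
    "kabsch_superpose",
    "core_rmsd",
    "per_residue_peptide_rmsd",
    "interdomain_metrics",
    "classify_conformation",
]


@dataclass(frozen=True)
class DomainDefinition:
    """A named set of author-numbered residue ranges (inclusive)."""

    name: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ranges = tuple((int(a), int(b)) for a, b in self.ranges)
        object.__setattr__(self, "ranges", ranges)
        if not ranges or any(a > b for a, b in ranges):
            raise ValueError("ranges must be non-empty (start, stop) pairs with start <= stop")

    def __contains__(self, resnum: int) -> bool:
        return any(a <= resnum <= b for a, b in self.ranges)

    def residue_numbers(self) -> list[int]:
        out: list[int] = []
        for a, b in self.ranges:
            out.extend(range(a, b + 1))
        return out


FKBP_DOMAIN = DomainDefinition("FKBP", ((1, 66), (125, 150)))
IF_DOMAIN = DomainDefinition("IF", ((70, 117),))
#: core FKBP selection used for cross-construct backbone comparisons
FKBP_CORE = DomainDefinition("FKBP_core", ((1, 57), (126, 150)))


@dataclass
class StructureModel:
    """C-alpha trace of one structure, keyed by (chain, resnum, icode).

    ``ca`` maps (chain_name, residue_number, insertion_code) to a length-3
    coordinate array in Angstrom.  ``peptide_chain`` annotates which chain
    holds the substrate peptide, if any; ``site_occupancy`` is a free-form
    label such as "none", "IF_only", "FKBP_only", "both" or "partial_IF".
    """

    identifier: str
    ca: dict[tuple[str, int, str], np.ndarray]
    peptide_chain: str | None = None
    site_occupancy: str = "none"

    def __post_init__(self) -> None:
        for key, xyz in self.ca.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite or malformed coordinates at {key}")
            self.ca[key] = xyz

    def chains(self) -> list[str]:
        return sorted({c for c, _, _ in self.ca})

    def first_protein_chain(self) -> str:
        chains = self.chains()
        if not chains:
            raise ValueError(f"{self.identifier}: empty model")
        for c in chains:
            if c != self.peptide_chain:
                return c
        return chains[0]

    def ca_coord(self, chain: str, resnum: int, icode: str = " ") -> np.ndarray:
        try:
            return self.ca[(chain, resnum, icode)]
        except KeyError:
            raise KeyError(
                f"{self.identifier}: no C-alpha for residue {resnum}{icode.strip()} "
                f"in chain {chain}"
            ) from None

    def residues_in(self, selection: DomainDefinition, chain: str) -> list[int]:
        """Residue numbers of the selection present in the given chain."""
        present = {r for c, r, i in self.ca if c == chain and i == " "}
        return [r for r in selection.residue_numbers() if r in present]

    def coords_for(self, chain: str, resnums: list[int]) -> np.ndarray:
        return np.array([self.ca_coord(chain, r) for r in resnums])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with all coordinates rigidly moved: x -> R x + t."""
        moved = {k: rotation @ v + translation for k, v in self.ca.items()}
        return StructureModel(
            identifier=self.identifier,
            ca=moved,
            peptide_chain=self.peptide_chain,
            site_occupancy=self.site_occupancy,
        )


def load_coordinates(
    path: str | Path,
    chains: list[str] | None = None,
    peptide_chain: str | None = None,
    identifier: str | None = None,
    site_occupancy: str = "none",
) -> StructureModel:
    """Read C-alpha coordinates from a PDB or mmCIF file.

    Only the first model is used.  Alternate locations are resolved to the
    highest-occupancy conformer; insertion codes are preserved in the keys.
    Missing residues are simply absent (never fabricated).  Requesting a
    chain that does not exist raises a ValueError.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    available = [ch.name for ch in model]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise ValueError(
                f"{path}: chain(s) {missing} not present (available: {available})"
            )
    wanted = set(chains) if chains is not None else None
    ca: dict[tuple[str, int, str], np.ndarray] = {}
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        for residue in chain:
            best = None
            for atom in residue:
                if atom.name != "CA" or atom.element == gemmi.Element("Ca"):
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is None:
                continue
            icode = residue.seqid.icode if residue.seqid.icode.strip() else " "
            key = (chain.name, residue.seqid.num, icode)
            ca[key] = np.array([best.pos.x, best.pos.y, best.pos.z])
    return StructureModel(
        identifier=identifier or Path(path).stem,
        ca=ca,
        peptide_chain=peptide_chain,
        site_occupancy=site_occupancy,
    )


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (proper rotation, det = +1)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - mc, target - tc
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    t = tc - R @ mc
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(mobile))


def kabsch_superpose(
    mobile: StructureModel,
    target: StructureModel,
    selection: DomainDefinition,
    mobile_chain: str | None = None,
    target_chain: str | None = None,
) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``target`` over the
    C-alpha atoms of ``selection`` present in both structures."""
    mc = mobile_chain or mobile.first_protein_chain()
    tc = target_chain or target.first_protein_chain()
    common = sorted(
        set(mobile.residues_in(selection, mc)) & set(target.residues_in(selection, tc))
    )
    if len(common) < 3:
        raise ValueError(
            f"superposition needs >= 3 common C-alpha atoms in {selection.name}; "
            f"found {len(common)}"
        )
    return _kabsch(mobile.coords_for(mc, common), target.coords_for(tc, common))


def core_rmsd(
    a: StructureModel,
    b: StructureModel,
    core: DomainDefinition = FKBP_CORE,
    a_chain: str | None = None,
    b_chain: str | None = None,
) -> float:
    """C-alpha RMSD over ``core`` after superposing on that same selection."""
    return kabsch_superpose(a, b, core, a_chain, b_chain).rmsd


def per_residue_peptide_rmsd(
    models: list[StructureModel],
    positions: list[int] | None = None,
    align_on: DomainDefinition = FKBP_DOMAIN,
) -> pd.DataFrame:
    """Positional conservation of a bound peptide across structures.

    All models are first superposed onto the first one over ``align_on``
    (the receptor frame); then, for every substrate position, the C-alpha
    distances between all unordered model pairs in which the position is
    resolved are collected.  Positions resolved in fewer than two models
    get NaN mean/sd and n_pairs = 0 (undefined, not zero).

    Returns a DataFrame with columns position, mean_rmsd, sd_rmsd, n_pairs.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    if positions is None:
        positions = list(range(1, 16))
    target = models[0]
    aligned: list[StructureModel] = [target]
    for m in models[1:]:
        sup = kabsch_superpose(m, target, align_on)
        aligned.append(m.transformed(sup.rotation, sup.translation))
    rows = []
    for pos in positions:
        coords = []
        for m in aligned:
            if m.peptide_chain is None:
                continue
            key = (m.peptide_chain, pos, " ")
            if key in m.ca:
                coords.append(m.ca[key])
        dists = [
            float(np.linalg.norm(coords[i] - coords[j]))
            for i in range(len(coords))
            for j in range(i + 1, len(coords))
        ]
        if dists:
            rows.append((pos, float(np.mean(dists)), float(np.std(dists, ddof=0)), len(dists)))
        else:
            rows.append((pos, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["position", "mean_rmsd", "sd_rmsd", "n_pairs"])


@dataclass(frozen=True)
class ConformationMetrics:
    """Inter-domain distance d (A) and angle delta (deg), plus state label."""

    d: float
    delta: float
    state: str | None = None

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if not 0.0 <= self.delta <= 180.0:
            raise ValueError("delta must be in [0, 180] degrees")


# residue anchors of the inter-domain metrics
_DIST_PAIR = (99, 146)      # IF residue 99 to FKBP residue 146
_ANGLE_TRIPLE = (145, 19, 95)  # angle at 19 between vectors to 145 and 95


def interdomain_metrics(model: StructureModel, chain: str | None = None) -> ConformationMetrics:
    """Distance d (C-alpha 99 to 146) and angle delta (at C-alpha 19,
    between the vectors to residues 145 and 95)."""
    ch = chain or model.first_protein_chain()
    p99 = model.ca_coord(ch, _DIST_PAIR[0])
    p146 = model.ca_coord(ch, _DIST_PAIR[1])
    p145 = model.ca_coord(ch, _ANGLE_TRIPLE[0])
    p19 = model.ca_coord(ch, _ANGLE_TRIPLE[1])
    p95 = model.ca_coord(ch, _ANGLE_TRIPLE[2])
    d = float(np.linalg.norm(p99 - p146))
    v1, v2 = p145 - p19, p95 - p19
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    delta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return ConformationMetrics(d=d, delta=delta)


def classify_conformation(
    metrics: ConformationMetrics,
    references: pd.DataFrame,
    cutoff: float = 2.0,
) -> tuple[str, float]:
    """Nearest-centroid state assignment in standardized (d, delta) space.

    ``references`` needs columns label, d_angstrom, delta_deg.  Coordinates
    are standardized by the reference mean and SD (so the two axes, which
    live on different scales, weigh equally); the per-label centroids are
    computed in that space.  If the nearest centroid lies farther than
    ``cutoff`` standardized units, the state is "intermediate".

    Returns (label, distance_to_assigned_centroid).
    """
    if references.empty:
        raise ValueError("reference set is empty")
    ref = references[["d_angstrom", "delta_deg"]].to_numpy(dtype=float)
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z_ref = (ref - mean) / sd
    z_pt = (np.array([metrics.d, metrics.delta]) - mean) / sd
    labels = references["label"].to_numpy()
    best_label, best_dist = "intermediate", np.inf
    for label in pd.unique(labels):
        centroid = z_ref[labels == label].mean(axis=0)
        dist = float(np.linalg.norm(z_pt - centroid))
        if dist < best_dist:
            best_label, best_dist = label, dist
    if best_dist > cutoff:
        return "intermediate", best_dist
    return best_label, best_dist
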