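"""Per-residue torsional entropy from structural ensembles.

Each residue is described by the joint distribution of its rotatable
torsion angles: backbone phi and psi plus the sidechain torsions among
heavy atoms, and those terminating in a polar hydrogen (the hydroxyl
torsions of Ser, Thr and Tyr, the thiol of Cys, the indole N-H of Trp).
Proline rings, aromatic rings, amide and guanidinium planes are rigid
and contribute no torsion; methyl and amino rotors have threefold
symmetry and are taken as freely rotating, so their contribution to any
entropy *change* vanishes and they are excluded.  With these rules the
internal torsion counts are 2 (Ala, Gly, Pro), 3 (Val), 4 (Ile), 5 (Trp)
and 6 (Lys, Arg).

Entropies are computed residue by residue (torsions of different
residues are treated as independent) with the nearest-neighbor estimator
on the residue's torus, relative to the uniform angle distribution
(sum of log 2 pi).  Subtracting packaged unfolded-state reference
entropies yields the conformational entropy of folding per residue;
summing folding entropies over a residue's contact cluster approximates
the entropy of the local opening reaction probed by hydrogen exchange.
The neglected phi_i / psi_{i-1} correlation across the peptide bond can
be quantified through the mutual-information helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import EntropyEstimate, SampleSet, entropy_knn, mutual_information, relative_to_uniform
from .reference import unfolded_reference_entropy, vdw_radius
from .spaces import MetricSpace

__all__ = [
    "TORSION_DEFINITIONS",
    "torsion_names",
    "compute_dihedral",
    "ResidueTorsions",
    "TorsionTrajectory",
    "extract_torsion_trajectory",
    "residue_entropy",
    "folding_entropy",
    "contact_map",
    "contact_cluster_entropy",
    "phi_psi_mutual_information",
]

# atom references are (residue offset, atom name)
_PHI = (("phi", ((-1, "C"), (0, "N"), (0, "CA"), (0, "C"))),)
_PSI = (("psi", ((0, "N"), (0, "CA"), (0, "C"), (1, "N"))),)


def _chi(name: str, a: str, b: str, c: str, d: str):
    return (name, ((0, a), (0, b), (0, c), (0, d)))


# Sidechain torsion inventories.  Heavy-atom chi angles, plus torsions
# ending in a polar hydrogen; rigid moieties (rings, amide and
# guanidinium planes) and threefold rotors (methyl, amino) are excluded.
_SIDECHAINS: dict[str, tuple] = {
    "ALA": (),
    "GLY": (),
    "SER": (_chi("chi1", "N", "CA", "CB", "OG"), _chi("chi2", "CA", "CB", "OG", "HG")),
    "THR": (_chi("chi1", "N", "CA", "CB", "OG1"), _chi("chi2", "CA", "CB", "OG1", "HG1")),
    "CYS": (_chi("chi1", "N", "CA", "CB", "SG"), _chi("chi2", "CA", "CB", "SG", "HG")),
    "CYS_SS": (_chi("chi1", "N", "CA", "CB", "SG"),),
    "VAL": (_chi("chi1", "N", "CA", "CB", "CG1"),),
    "LEU": (_chi("chi1", "N", "CA", "CB", "CG"), _chi("chi2", "CA", "CB", "CG", "CD1")),
    "ILE": (_chi("chi1", "N", "CA", "CB", "CG1"), _chi("chi2", "CA", "CB", "CG1", "CD1")),
    "MET": (
        _chi("chi1", "N", "CA", "CB", "CG"),
        _chi("chi2", "CA", "CB", "CG", "SD"),
        _chi("chi3", "CB", "CG", "SD", "CE"),
    ),
    "ASP": (_chi("chi1", "N", "CA", "CB", "CG"), _chi("chi2", "CA", "CB", "CG", "OD1")),
    "ASN": (_chi("chi1", "N", "CA", "CB", "CG"), _chi("chi2", "CA", "CB", "CG", "OD1")),
    "GLU": (
        _chi("chi1", "N", "CA", "CB", "CG"),
        _chi("chi2", "CA", "CB", "CG", "CD"),
        _chi("chi3", "CB", "CG", "CD", "OE1"),
    ),
    "GLN": (
        _chi("chi1", "N", "CA", "CB", "CG"),
        _chi("chi2", "CA", "CB", "CG", "CD"),
        _chi("chi3", "CB", "CG", "CD", "OE1"),
    ),
    "LYS": (
        _chi("chi1", "N", "CA", "CB", "CG"),
        _chi("chi2", "CA", "CB", "CG", "CD"),
        _chi("chi3", "CB", "CG", "CD", "CE"),
        _chi("chi4", "CG", "CD", "CE", "NZ"),
    ),
    "ARG": (
        _chi("chi1", "N", "CA", "CB", "CG"),
        _chi("chi2", "CA", "CB", "CG", "CD"),
        _chi("chi3", "CB", "CG", "CD", "NE"),
        _chi("chi4", "CG", "CD", "NE", "CZ"),
    ),
    "HIS": (_chi("chi1", "N", "CA", "CB", "CG"), _chi("chi2", "CA", "CB", "CG", "ND1")),
    "PHE": (_chi("chi1", "N", "CA", "CB", "CG"), _chi("chi2", "CA", "CB", "CG", "CD1")),
    "TYR": (
        _chi("chi1", "N", "CA", "CB", "CG"),
        _chi("chi2", "CA", "CB", "CG", "CD1"),
        _chi("chi_oh", "CE1", "CZ", "OH", "HH"),
    ),
    "TRP": (
        _chi("chi1", "N", "CA", "CB", "CG"),
        _chi("chi2", "CA", "CB", "CG", "CD1"),
        _chi("chi_nh", "CG", "CD1", "NE1", "HE1"),
    ),
    "PRO": (),  # ring rigid: phi and psi only
}

#: Full torsion inventory per residue type (backbone phi, psi first).
TORSION_DEFINITIONS: dict[str, tuple] = {
    res: _PHI + _PSI + chis for res, chis in _SIDECHAINS.items()
}


def torsion_names(residue_type: str, variant: str = "internal") -> tuple[str, ...]:
    """Ordered torsion names for a residue type and terminal variant."""
    defs = TORSION_DEFINITIONS[residue_type.upper()]
    names = [name for name, _ in defs]
    if variant == "nterm":
        names = [n for n in names if n != "phi"]
    elif variant == "cterm":
        names = [n for n in names if n != "psi"]
    elif variant != "internal":
        raise ValueError(f"unknown variant {variant!r}")
    return tuple(names)


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral about the p2--p3 bond, in (-pi, pi] (IUPAC sign)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    norm_b1 = np.linalg.norm(b1)
    if norm_b1 < 1e-12:
        raise ValueError("coincident central atoms")
    b1 = b1 / norm_b1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise ValueError("collinear atoms leave the dihedral undefined")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    angle = math.atan2(y, x)
    return math.pi if angle == -math.pi else angle


@dataclass
class ResidueTorsions:
    """Angle matrix (snapshots x torsions, radians) for one residue."""

    residue_index: int
    chain_id: str
    residue_type: str
    variant: str
    angle_names: tuple[str, ...]
    angles: np.ndarray
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_snapshots(self) -> int:
        return self.angles.shape[0]

    @property
    def n_torsions(self) -> int:
        return self.angles.shape[1]


@dataclass
class TorsionTrajectory:
    """Per-residue torsion-angle matrices extracted from an ensemble."""

    residues: dict[tuple[str, int], ResidueTorsions]

    def __iter__(self):
        return iter(self.residues.values())

    def __len__(self) -> int:
        return len(self.residues)

    def get(self, chain_id: str, residue_index: int) -> ResidueTorsions | None:
        return self.residues.get((chain_id, residue_index))

    @classmethod
    def from_angle_table(cls, table: pd.DataFrame) -> "TorsionTrajectory":
        """Build from a long-format angle table.

        Expected columns: residue_index, residue_type, variant,
        angle_name, degrees, model (and optionally chain_id).
        """
        required = {"residue_index", "residue_type", "variant", "angle_name", "degrees", "model"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"angle table lacks columns: {sorted(missing)}")
        table = table.copy()
        if "chain_id" not in table.columns:
            table["chain_id"] = "A"
        residues: dict[tuple[str, int], ResidueTorsions] = {}
        for (chain, idx), group in table.groupby(["chain_id", "residue_index"], sort=True):
            wide = group.pivot_table(
                index="model", columns="angle_name", values="degrees", sort=False
            )
            # preserve first-appearance ordering of angle names
            order = list(dict.fromkeys(group["angle_name"]))
            wide = wide[order]
            if wide.isna().any().any():
                raise ValueError(f"residue {idx}: missing angle entries for some models")
            residues[(chain, int(idx))] = ResidueTorsions(
                residue_index=int(idx),
                chain_id=str(chain),
                residue_type=str(group["residue_type"].iloc[0]),
                variant=str(group["variant"].iloc[0]),
                angle_names=tuple(order),
                angles=np.deg2rad(wide.to_numpy(dtype=float)),
            )
        return cls(residues)


def _atom_index_map(atoms) -> dict[tuple[str, int, str], int]:
    return {
        (str(c), int(r), str(a)): i
        for i, (c, r, a) in enumerate(zip(atoms.chain_id, atoms.res_id, atoms.atom_name))
    }


def _detect_disulfides(atoms, cutoff: float = 2.5) -> set[tuple[str, int]]:
    mask = (atoms.res_name == "CYS") & (atoms.atom_name == "SG")
    idx = np.where(mask)[0]
    bridged: set[tuple[str, int]] = set()
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            d = np.linalg.norm(atoms.coord[idx[i]] - atoms.coord[idx[j]])
            if d < cutoff:
                for a in (idx[i], idx[j]):
                    bridged.add((str(atoms.chain_id[a]), int(atoms.res_id[a])))
    return bridged


def extract_torsion_trajectory(models, definitions=None) -> TorsionTrajectory:
    """Extract per-residue torsion-angle matrices from a model ensemble.

    ``models`` is a biotite ``AtomArrayStack`` (models = snapshots) with
    shared topology.  Residues at chain termini lose phi (N-terminal) or
    psi (C-terminal); disulfide-bridged cysteines (SG-SG < 2.5 A in the
    first model) switch to the reduced phi/psi/chi1 torsion set.
    Torsions whose atoms are absent are skipped with a per-residue
    warning; residues with no computable torsion are dropped.
    """
    if definitions is None:
        definitions = TORSION_DEFINITIONS
    template = models[0]
    index = _atom_index_map(template)
    bridged = _detect_disulfides(template)
    coords = models.coord  # (n_models, n_atoms, 3)
    n_models = coords.shape[0]

    residues: dict[tuple[str, int], ResidueTorsions] = {}
    seen: list[tuple[str, int, str]] = []
    for chain, res_id, res_name in zip(template.chain_id, template.res_id, template.res_name):
        key = (str(chain), int(res_id), str(res_name))
        if key not in seen:
            seen.append(key)
    present = {(c, r) for c, r, _ in seen}
    if not any(str(n).upper() in definitions for _, _, n in seen):
        raise ValueError("no residues resolvable to torsion definitions")

    for chain, res_id, res_name in seen:
        res_type = res_name.upper()
        if (chain, res_id) in bridged and res_type == "CYS":
            res_type = "CYS_SS"
        if res_type not in definitions:
            continue
        variant = "internal"
        if (chain, res_id - 1) not in present:
            variant = "nterm"
        elif (chain, res_id + 1) not in present:
            variant = "cterm"
        wanted = [
            (name, atom_refs)
            for name, atom_refs in definitions[res_type]
            if name in torsion_names(res_type, variant)
        ]
        names: list[str] = []
        columns: list[np.ndarray] = []
        warn: list[str] = []
        for name, atom_refs in wanted:
            try:
                atom_idx = [index[(chain, res_id + off, atom)] for off, atom in atom_refs]
            except KeyError:
                warn.append(f"missing-atoms-for-{name}")
                continue
            p = coords[:, atom_idx, :]
            angles = np.empty(n_models)
            try:
                for m in range(n_models):
                    angles[m] = compute_dihedral(p[m, 0], p[m, 1], p[m, 2], p[m, 3])
            except ValueError:
                warn.append(f"degenerate-geometry-for-{name}")
                continue
            names.append(name)
            columns.append(angles)
        if not names:
            continue
        residues[(chain, res_id)] = ResidueTorsions(
            residue_index=res_id,
            chain_id=chain,
            residue_type=res_type,
            variant=variant,
            angle_names=tuple(names),
            angles=np.column_stack(columns),
            warnings=tuple(warn),
        )
    if not residues:
        raise ValueError("no residues with computable torsions")
    return TorsionTrajectory(residues)


def residue_entropy(residue: ResidueTorsions, k: int = 1) -> EntropyEstimate:
    """Joint torsional entropy of one residue, relative to uniform angles."""
    if residue.n_snapshots < 2:
        raise ValueError("need at least two snapshots")
    space = MetricSpace.torus([2.0 * math.pi] * residue.n_torsions)
    absolute = entropy_knn(SampleSet(residue.angles, space), k)
    return relative_to_uniform(absolute, space)


def folding_entropy(
    per_residue: dict[tuple[str, int], EntropyEstimate],
    traj: TorsionTrajectory,
) -> dict[tuple[str, int], float]:
    """Conformational entropy of folding: computed minus unfolded reference.

    The unfolded-state reference for the residue's type and terminal
    variant is subtracted from each relative entropy; the difference (kB)
    is the residue's contribution to the folding entropy.
    """
    out: dict[tuple[str, int], float] = {}
    for key, est in per_residue.items():
        res = traj.residues[key]
        ref = unfolded_reference_entropy(res.residue_type, res.variant)
        out[key] = est.value - ref
    return out


def contact_map(atoms, margin: float = 1.0) -> dict[tuple[str, int], set]:
    """Residue contact sets from one representative structure.

    Two residues are in contact when any interatomic distance is below
    ``margin`` (1 A) plus the sum of the two van der Waals radii.  The
    map is symmetric and every residue contacts itself.
    """
    keys = np.array([f"{c}|{r}" for c, r in zip(atoms.chain_id, atoms.res_id)])
    radii = np.array([vdw_radius(e) for e in atoms.element])
    coords = np.asarray(atoms.coord, dtype=float)
    unique_keys = list(dict.fromkeys(keys.tolist()))
    contacts: dict[tuple[str, int], set] = {}

    def parse(k: str) -> tuple[str, int]:
        c, r = k.rsplit("|", 1)
        return (c, int(r))

    for k in unique_keys:
        contacts[parse(k)] = {parse(k)}
    from scipy.spatial.distance import cdist

    dist = cdist(coords, coords)
    threshold = radii[:, None] + radii[None, :] + margin
    close = dist < threshold
    ii, jj = np.where(close)
    for i, j in zip(ii, jj):
        if keys[i] != keys[j]:
            contacts[parse(keys[i])].add(parse(keys[j]))
    return contacts


def contact_cluster_entropy(
    contacts: dict[tuple[str, int], set],
    folding: dict[tuple[str, int], float],
) -> dict[tuple[str, int], float]:
    """Sum of folding entropies over each residue's contact cluster.

    Approximates the conformational entropy released by a local opening
    reaction centred on the residue.  Contacting residues without a
    folding entropy (e.g. skipped residues) contribute zero.
    """
    return {
        key: sum(folding.get(member, 0.0) for member in members)
        for key, members in contacts.items()
        if key in folding
    }


def phi_psi_mutual_information(
    traj: TorsionTrajectory, chain_id: str, residue_index: int, k: int = 1
) -> float:
    """Mutual information (kB) of phi_i with psi_{i-1} across the peptide bond."""
    res_i = traj.get(chain_id, residue_index)
    res_prev = traj.get(chain_id, residue_index - 1)
    if res_i is None or res_prev is None:
        raise ValueError(f"residues {residue_index - 1} and {residue_index} must both be present")
    if "phi" not in res_i.angle_names or "psi" not in res_prev.angle_names:
        raise ValueError("terminal residues lack the phi/psi pair")
    circle = MetricSpace.torus([2.0 * math.pi])
    phi_i = res_i.angles[:, res_i.angle_names.index("phi")]
    psi_prev = res_prev.angles[:, res_prev.angle_names.index("psi")]
    return mutual_information(
        SampleSet(phi_i[:, None], circle), SampleSet(psi_prev[:, None], circle), k
    )
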