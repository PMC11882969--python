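"""Geometric pose filters and symmetry-aware ligand RMSD.

Two operations from the docking campaign live here.  The polar-contact
filter keeps docked poses that place at least one polar ligand atom (N or O
by default) within a cutoff of a binding-site anchor atom — for CB1R the
side-chain oxygens/nitrogens of Ser383(7.39), Thr201(3.37) and His178(2.65).
The symmetry-corrected RMSD compares two poses of the same molecule in a
common coordinate frame, minimizing over one-to-one atom assignments within
each element class (a linear assignment on squared distances, i.e. the
Hungarian algorithm), so that chemically equivalent atom relabelings do not
inflate the RMSD.  Hydrogens are ignored throughout: experimental models
rarely place them reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "BindingSiteSpec",
    "ContactResult",
    "LigandPose",
    "PoseError",
    "hungarian_rmsd",
    "polar_contact_filter",
    "read_receptor_anchors",
    "read_sdf_poses",
    "write_sdf_poses",
]

#: ligand atoms counted as polar in the contact filter
DEFAULT_POLAR_ELEMENTS = frozenset({"N", "O"})
DEFAULT_CONTACT_CUTOFF = 3.5  # Å, heavy atom to heavy atom

#: side-chain polar atoms harvested per residue type
SIDECHAIN_POLAR_ATOMS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "HIS": ("ND1", "NE2"),
    "TYR": ("OH",),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
}

_ONE_LETTER = {"S": "SER", "T": "THR", "H": "HIS", "Y": "TYR", "N": "ASN", "Q": "GLN"}


class PoseError(ValueError):
    pass


@dataclass
class LigandPose:
    """Heavy-atom 3D pose of one ligand.

    ``polar_mask`` defaults to flagging N and O atoms.
    """

    molecule_id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) Å
    polar_mask: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) == 0:
            raise PoseError(f"pose {self.molecule_id}: no atoms")
        if self.coords.shape != (len(self.elements), 3):
            raise PoseError(
                f"pose {self.molecule_id}: coords shape {self.coords.shape} "
                f"does not match {len(self.elements)} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise PoseError(f"pose {self.molecule_id}: non-finite coordinates")
        if self.polar_mask is None:
            self.polar_mask = np.array(
                [e in DEFAULT_POLAR_ELEMENTS for e in self.elements]
            )
        else:
            self.polar_mask = np.asarray(self.polar_mask, dtype=bool)
            if self.polar_mask.shape[0] != len(self.elements):
                raise PoseError(
                    f"pose {self.molecule_id}: polar_mask length mismatch"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class Anchor:
    label: str  # e.g. "S383^7.39:OG"
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class BindingSiteSpec:
    """Anchor atoms and the heavy-atom contact cutoff (Å)."""

    anchors: tuple[Anchor, ...]
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF

    def __post_init__(self):
        if len(self.anchors) == 0:
            raise PoseError("binding site has no anchor atoms")
        if self.contact_cutoff <= 0:
            raise PoseError(f"contact cutoff must be > 0, got {self.contact_cutoff}")

    @property
    def anchor_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.anchors], dtype=float)


@dataclass(frozen=True)
class Contact:
    ligand_atom: int
    anchor: str
    distance: float


@dataclass
class ContactResult:
    passed: bool
    contacts: list[Contact] = field(default_factory=list)
    reason: str = ""


def polar_contact_filter(pose: LigandPose, site: BindingSiteSpec) -> ContactResult:
    """Pass iff >= 1 polar ligand atom lies within the cutoff of an anchor.

    Every (ligand atom, anchor, distance) pair within the cutoff is
    reported.  A ligand without polar atoms fails with reason "apolar
    ligand" rather than raising: that is a legitimate triage outcome.
    """
    idx = np.flatnonzero(pose.polar_mask)
    if idx.size == 0:
        return ContactResult(passed=False, reason="apolar ligand")
    d = cdist(pose.coords[idx], site.anchor_coords)
    contacts = [
        Contact(int(idx[i]), site.anchors[j].label, float(d[i, j]))
        for i, j in zip(*np.nonzero(d <= site.contact_cutoff))
    ]
    contacts.sort(key=lambda c: c.distance)
    if contacts:
        return ContactResult(passed=True, contacts=contacts)
    return ContactResult(passed=False, reason="no polar contact within cutoff")


def hungarian_rmsd(a: LigandPose, b: LigandPose) -> float:
    """Symmetry-corrected heavy-atom RMSD between two poses of one molecule.

    For each element class the optimal one-to-one atom assignment is found
    by solving a linear assignment problem with squared-distance costs; the
    RMSD is then taken over the union of assigned pairs.  No superposition
    is performed — both poses must already sit in a common frame (compare
    after overlaying receptors, not ligands).
    """
    if sorted(a.elements) != sorted(b.elements):
        raise PoseError(
            f"element multiset mismatch between {a.molecule_id} and {b.molecule_id}"
        )
    sq_sum, n = 0.0, 0
    for elem in sorted(set(a.elements)):
        ia = [i for i, e in enumerate(a.elements) if e == elem]
        ib = [i for i, e in enumerate(b.elements) if e == elem]
        cost = cdist(a.coords[ia], b.coords[ib], "sqeuclidean")
        rows, cols = linear_sum_assignment(cost)
        sq_sum += cost[rows, cols].sum()
        n += len(ia)
    return float(np.sqrt(sq_sum / n))


def identity_rmsd(a: LigandPose, b: LigandPose) -> float:
    """RMSD with atoms paired by input order (no assignment)."""
    if len(a.elements) != len(b.elements):
        raise PoseError("atom count mismatch")
    return float(np.sqrt(((a.coords - b.coords) ** 2).sum(axis=1).mean()))


def kabsch_transform(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rotation+translation mapping mobile onto target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def align_pose(pose: LigandPose, mobile_ref: np.ndarray, target_ref: np.ndarray) -> LigandPose:
    """Move a pose by the transform that maps one receptor frame onto another.

    ``mobile_ref``/``target_ref`` are matched reference coordinates (for
    example Calpha atoms of selected residues) in the pose's frame and the
    target frame.  Used when comparing a docked pose against an experimental
    one solved in a different coordinate system.
    """
    rot, trans = kabsch_transform(np.asarray(mobile_ref), np.asarray(target_ref))
    return LigandPose(
        molecule_id=pose.molecule_id,
        elements=list(pose.elements),
        coords=pose.coords @ rot.T + trans,
        polar_mask=pose.polar_mask.copy(),
    )


def read_receptor_anchors(
    pdb_path: str | Path,
    residue_selectors: list[str],
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> BindingSiteSpec:
    """Harvest side-chain polar anchor atoms from a receptor structure.

    Selectors are one-letter residue codes plus author residue numbers, e.g.
    ``"S383"``, ``"T201"``, ``"H178"``.  Serine yields its OG atom,
    threonine OG1, histidine both ND1 and NE2.  A missing residue or
    side-chain atom raises naming the offender.
    """
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("receptor", str(pdb_path))
    by_number: dict[int, list] = {}
    for res in structure.get_residues():
        by_number.setdefault(res.get_id()[1], []).append(res)

    anchors: list[Anchor] = []
    for sel in residue_selectors:
        one, num = sel[0].upper(), int(sel[1:])
        resname = _ONE_LETTER.get(one)
        if resname is None:
            raise PoseError(f"selector {sel!r}: unsupported residue type {one!r}")
        matches = [r for r in by_number.get(num, []) if r.get_resname() == resname]
        if not matches:
            raise PoseError(f"residue {sel} ({resname}{num}) not found in {pdb_path}")
        res = matches[0]
        for atom_name in SIDECHAIN_POLAR_ATOMS[resname]:
            if atom_name not in res:
                raise PoseError(f"residue {sel}: atom {atom_name} missing")
            anchors.append(
                Anchor(f"{sel}:{atom_name}", tuple(map(float, res[atom_name].coord)))
            )
    return BindingSiteSpec(anchors=tuple(anchors), contact_cutoff=contact_cutoff)


def write_sdf_poses(poses: list[LigandPose], path: str | Path) -> None:
    """Write poses as a multi-record SDF (heavy atoms, no bonds)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    with Chem.SDWriter(str(path)) as writer:
        for pose in poses:
            rw = Chem.RWMol()
            for e in pose.elements:
                rw.AddAtom(Chem.Atom(e))
            conf = Chem.Conformer(pose.n_atoms)
            for i, (x, y, z) in enumerate(pose.coords):
                conf.SetAtomPosition(i, Point3D(x, y, z))
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", pose.molecule_id)
            for atom in mol.GetAtoms():
                atom.SetNoImplicit(True)
            writer.write(mol)


def _pose_from_mol(mol) -> LigandPose:
    conf = mol.GetConformer()
    elements, coords = [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        elements.append(atom.GetSymbol())
        p = conf.GetAtomPosition(atom.GetIdx())
        coords.append((p.x, p.y, p.z))
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else "ligand"
    return LigandPose(molecule_id=name, elements=elements, coords=np.array(coords))


def read_sdf_poses(path: str | Path) -> list[LigandPose]:
    """Read heavy-atom poses from an SDF file."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    poses = []
    for mol in supplier:
        if mol is None:
            continue
        poses.append(_pose_from_mol(mol))
    if not poses:
        raise PoseError(f"no readable poses in {path}")
    return poses


def read_mol2_pose(path: str | Path) -> LigandPose:
    """Read a single heavy-atom pose from a mol2 file."""
    from rdkit import Chem

    mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    if mol is None:
        raise PoseError(f"unreadable mol2 file: {path}")
    return _pose_from_mol(mol)
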