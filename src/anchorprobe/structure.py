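"""Protein structures: loading, preparation, superposition and metrics.

Structures are flat, typed atom arrays (not a hierarchy): every atom carries
coordinates, a partial charge, LJ parameters, a vdW radius and a solvation
parameter from the configured :class:`~anchorprobe.params.ParameterSet`.
Preparation follows the mapping engine's conventions: hetero/solvent records
are excluded, hydrogens are ignored (united-atom treatment), alternate
locations resolve to the highest occupancy, and only the first model of a
multi-model file is read.

Residues are always addressed by ``(chain id, residue number, insertion
code)`` triples, never bare integers.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.transform import Rotation

from .params import AtomParams, ParameterSet, default_parameter_set

__all__ = [
    "Atom", "ProteinStructure", "RigidTransform", "SiteValidation",
    "load_structure", "write_pdb", "validate_site_resolved",
    "superpose_calpha", "sidechain_rmsd", "czeta_distance",
    "read_residue_map",
]

ResidueId = tuple[str, int, str]

STANDARD_RESIDUES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: ResidueId
    position: np.ndarray        # (3,) A
    partial_charge: float       # e
    vdw_radius: float           # A
    eps: float                  # kcal/mol
    sigma: float                # A
    solvation_param: float      # kcal/(mol*A^2)
    is_polar: bool

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")


class ProteinStructure:
    """An ordered list of parameterized atoms plus a residue index."""

    def __init__(self, atoms: list[Atom], source_id: str = ""):
        self.atoms = list(atoms)
        self.source_id = source_id
        self.residue_index: dict[ResidueId, list[int]] = {}
        for i, a in enumerate(self.atoms):
            self.residue_index.setdefault(a.residue_id, []).append(i)
        #: residues lacking a CA atom (e.g. pseudo-atom scaffolds)
        self.missing_calpha: list[ResidueId] = [
            rid for rid, idx in self.residue_index.items()
            if not any(self.atoms[i].name == "CA" for i in idx)]

    # -- array views -------------------------------------------------------
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def lj(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([a.eps for a in self.atoms]),
                np.array([a.sigma for a in self.atoms]))

    def asp(self) -> np.ndarray:
        return np.array([a.solvation_param for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    def residue_atoms(self, residue_id: ResidueId) -> list[Atom]:
        return [self.atoms[i] for i in self.residue_index.get(residue_id, [])]

    def atom(self, residue_id: ResidueId, name: str) -> Atom:
        for a in self.residue_atoms(residue_id):
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in residue {residue_id}")

    def transformed(self, t: "RigidTransform") -> "ProteinStructure":
        atoms = []
        for a in self.atoms:
            b = Atom(a.serial, a.name, a.element, a.residue_name,
                     a.residue_id, t.apply(a.position), a.partial_charge,
                     a.vdw_radius, a.eps, a.sigma, a.solvation_param,
                     a.is_polar)
            atoms.append(b)
        return ProteinStructure(atoms, self.source_id)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray      # (3,3), det = +1
    translation: np.ndarray   # (3,)

    def __post_init__(self):
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation matrix determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)


# ---------------------------------------------------------------------------
# loading / writing


def _pick_altloc(residue) -> list:
    """Highest-occupancy alternate location; ties break by altLoc id order."""
    chosen = {}
    for atom in residue.get_atoms():
        if atom.element == "H" or atom.get_name().startswith("H"):
            continue
        name = atom.get_name()
        if atom.is_disordered():
            best = None
            for alt in sorted(atom.disordered_get_id_list()):
                cand = atom.disordered_get(alt)
                if best is None or cand.get_occupancy() > best.get_occupancy():
                    best = cand
            atom = best
        prev = chosen.get(name)
        if prev is None or (atom.get_occupancy() or 1.0) > (prev.get_occupancy() or 1.0):
            chosen[name] = atom
    return list(chosen.values())


def load_structure(path: str | Path, keep_hetero: bool = False,
                   parameter_set: ParameterSet | None = None,
                   ) -> ProteinStructure:
    """Read a PDB file into a parameterized :class:`ProteinStructure`.

    Hetero/solvent records are dropped unless ``keep_hetero`` (and even then
    only residues the parameter table knows can be kept). Hydrogens are
    ignored; alternate locations resolve to the highest occupancy; the first
    model wins in multi-model files.

    Raises ``ValueError`` for unparsable/empty files and ``KeyError`` (with
    the residue id) for an unknown residue that cannot be parameterized.
    """
    ps = parameter_set or default_parameter_set()
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = next(parser.get_structure("s", str(path)).get_models(),
                         None)
    except Exception as exc:
        raise ValueError(f"unparsable PDB file {path}: {exc}") from exc
    if model is None:
        raise ValueError(f"no model found in {path}")
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            is_het = hetflag.strip() != ""
            resname = residue.get_resname().strip()
            if is_het or resname not in STANDARD_RESIDUES:
                continue   # hetero atoms are excluded before mapping
            rid: ResidueId = (chain.id, resseq, icode.strip())
            for atom in _pick_altloc(residue):
                name = atom.get_name()
                try:
                    p: AtomParams = ps.lookup(resname, name)
                except KeyError:
                    if name == "OXT":
                        continue
                    raise KeyError(
                        f"unparameterized atom {name!r} in residue "
                        f"{resname} {rid}") from None
                serial += 1
                atoms.append(Atom(
                    serial=serial, name=name, element=p.element,
                    residue_name=resname, residue_id=rid,
                    position=np.array(atom.get_coord(), dtype=float),
                    partial_charge=p.charge, vdw_radius=p.radius,
                    eps=p.eps, sigma=p.sigma, solvation_param=p.asp,
                    is_polar=p.polar))
    if not atoms:
        raise ValueError(f"no standard amino-acid atoms in {path}")
    return ProteinStructure(atoms, source_id=Path(path).stem)


def write_pdb(structure: ProteinStructure, path: str | Path | None = None,
              ) -> str:
    """Serialize to fixed-width PDB ATOM records; returns the text."""
    buf = io.StringIO()
    last_chain = None
    for i, a in enumerate(structure.atoms, start=1):
        chain, resseq, icode = a.residue_id
        if last_chain is not None and chain != last_chain:
            buf.write("TER\n")
        last_chain = chain
        x, y, z = a.position
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        buf.write(
            f"ATOM  {i:5d} {name:4.4s} {a.residue_name:>3.3s} "
            f"{chain:1.1s}{resseq:4d}{icode or ' ':1.1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2.2s}\n")
    buf.write("TER\nEND\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# site validation


@dataclass
class SiteValidation:
    """Truthy iff every site residue is present with all expected atoms."""

    ok: bool
    missing_residues: list[ResidueId] = field(default_factory=list)
    missing_atoms: dict[ResidueId, list[str]] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.ok


def validate_site_resolved(structure: ProteinStructure,
                           site_residues: list[ResidueId],
                           parameter_set: ParameterSet | None = None,
                           ) -> SiteValidation:
    """Check that all residues lining a site are fully resolved.

    Mapping runs require every residue surrounding the site of interest to
    be present with its complete set of heavy atoms.
    """
    if not site_residues:
        raise ValueError("site_residues must be non-empty")
    ps = parameter_set or default_parameter_set()
    missing_res: list[ResidueId] = []
    missing_atoms: dict[ResidueId, list[str]] = {}
    for rid in site_residues:
        atoms = structure.residue_atoms(rid)
        if not atoms:
            missing_res.append(rid)
            continue
        expected = set(ps.expected_atoms(atoms[0].residue_name))
        present = {a.name for a in atoms}
        gone = sorted(expected - present)
        if gone:
            missing_atoms[rid] = gone
    ok = not missing_res and not missing_atoms
    return SiteValidation(ok, missing_res, missing_atoms)


def read_residue_map(path: str | Path) -> list[tuple[ResidueId, ResidueId]]:
    """Two-column residue-pair table: ``mobile_residue<TAB>reference_residue``.

    Each residue is ``chain:resseq[:icode]`` (e.g. ``A:170``). Used to map a
    kinase's own numbering onto the reference (PKA) numbering for site
    superposition when no alignment-derived mapping is available.
    """
    def parse(tok: str) -> ResidueId:
        parts = tok.split(":")
        if len(parts) < 2:
            raise ValueError(f"bad residue token {tok!r}; want chain:resseq")
        return (parts[0], int(parts[1]), parts[2] if len(parts) > 2 else "")

    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mob, ref = line.split("\t")[:2]
        pairs.append((parse(mob), parse(ref)))
    return pairs


# ---------------------------------------------------------------------------
# superposition and distance metrics


def superpose_calpha(mobile: ProteinStructure, reference: ProteinStructure,
                     residue_map: list[tuple[ResidueId, ResidueId]],
                     ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition over paired CA atoms (Kabsch).

    ``residue_map`` pairs mobile residues with reference residues; the
    transform maps mobile coordinates into the reference frame. The RMSD is
    computed over the paired CA set only.
    """
    if len(residue_map) < 3:
        raise ValueError("need at least 3 residue pairs for superposition")
    mob = np.array([mobile.atom(m, "CA").position for m, _ in residue_map])
    ref = np.array([reference.atom(r, "CA").position for _, r in residue_map])
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    mob0, ref0 = mob - mc, ref - rc
    # collinearity check: rank of the centered point set
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) CA point set")
    rot, _ = Rotation.align_vectors(ref0, mob0)
    R = rot.as_matrix()
    t = rc - R @ mc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum(
        (transform.apply(mob) - ref) ** 2, axis=1))))
    return transform, rmsd


def _paired_coords(pose_a, pose_b, names: list[str]) -> tuple[np.ndarray,
                                                              np.ndarray]:
    a = {n: p for n, p in zip(pose_a.atom_names, pose_a.coords)}
    b = {n: p for n, p in zip(pose_b.atom_names, pose_b.coords)}
    return (np.array([a[n] for n in names]), np.array([b[n] for n in names]))


def sidechain_rmsd(pose_a, pose_b) -> float:
    """RMSD over probe heavy atoms excluding CB, in a common frame.

    No re-superposition is applied: the poses are assumed already expressed
    in the same coordinate frame. CB is the attachment pseudo-atom and is
    excluded from the metric.
    """
    if pose_a.aa_type != pose_b.aa_type:
        raise ValueError("poses are of different amino-acid types")
    names = [n for n in pose_a.atom_names if n != "CB"]
    if set(pose_a.atom_names) != set(pose_b.atom_names):
        raise ValueError("mismatched atom-name sets")
    a, b = _paired_coords(pose_a, pose_b, names)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def czeta_distance(pose_a, pose_b) -> float:
    """Distance between the guanidino CZ atoms of two Arg poses."""
    for p in (pose_a, pose_b):
        if p.aa_type != "ARG":
            raise ValueError("CZ distance is defined for Arg poses only")
    (a,), (b,) = _paired_coords(pose_a, pose_b, ["CZ"])
    return float(np.linalg.norm(a - b))
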