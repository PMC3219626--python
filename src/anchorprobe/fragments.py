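"""Side-chain fragments: ideal templates, torsions, probes and rotamers.

A probe is a single amino-acid side chain from CB outward, with CB acting as
an uncharged attachment pseudo-atom. Fragments are built from ideal internal
coordinates (bond lengths, angles, chi torsions) by natural-extension
(NeRF) placement, so any rotamer of any supported residue can be constructed
either free in space (for surface mapping) or onto an existing backbone (for
in-silico mutagenesis).

The compact backbone-independent rotamer library ships as
``data/rotamers_v1.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .params import ParameterSet, default_parameter_set

__all__ = ["ProbePose", "make_probe", "build_sidechain", "rotamer_library",
           "rotate_torsion", "compute_torsion", "TERMINAL_ATOM",
           "SUPPORTED_FRAGMENTS"]


def _d(name, parent, aref, tref, r, theta, tspec):
    return (name, parent, aref, tref, r, theta, tspec)


def _chi(k, offset=0.0):
    return ("chi", k, offset)


# z-matrix per residue: side-chain atoms beyond CB, built in order.
# tspec is either a fixed torsion (deg) or ("chi", k, offset).
_ZMAT: dict[str, list[tuple]] = {
    "ALA": [],
    "SER": [_d("OG", "CB", "CA", "N", 1.42, 110.5, _chi(1))],
    "THR": [_d("OG1", "CB", "CA", "N", 1.43, 109.6, _chi(1)),
            _d("CG2", "CB", "CA", "N", 1.53, 110.7, _chi(1, -120.0))],
    "CYS": [_d("SG", "CB", "CA", "N", 1.81, 114.0, _chi(1))],
    "VAL": [_d("CG1", "CB", "CA", "N", 1.53, 110.5, _chi(1)),
            _d("CG2", "CB", "CA", "N", 1.53, 110.5, _chi(1, 120.0))],
    "LEU": [_d("CG", "CB", "CA", "N", 1.53, 116.3, _chi(1)),
            _d("CD1", "CG", "CB", "CA", 1.53, 110.7, _chi(2)),
            _d("CD2", "CG", "CB", "CA", 1.53, 110.7, _chi(2, 120.0))],
    "ILE": [_d("CG1", "CB", "CA", "N", 1.53, 110.4, _chi(1)),
            _d("CG2", "CB", "CA", "N", 1.53, 110.5, _chi(1, -120.0)),
            _d("CD1", "CG1", "CB", "CA", 1.53, 113.8, _chi(2))],
    "MET": [_d("CG", "CB", "CA", "N", 1.53, 114.0, _chi(1)),
            _d("SD", "CG", "CB", "CA", 1.81, 112.7, _chi(2)),
            _d("CE", "SD", "CG", "CB", 1.79, 100.9, _chi(3))],
    "ASP": [_d("CG", "CB", "CA", "N", 1.53, 112.6, _chi(1)),
            _d("OD1", "CG", "CB", "CA", 1.25, 118.4, _chi(2)),
            _d("OD2", "CG", "CB", "CA", 1.25, 118.4, _chi(2, 180.0))],
    "ASN": [_d("CG", "CB", "CA", "N", 1.53, 112.6, _chi(1)),
            _d("OD1", "CG", "CB", "CA", 1.23, 120.8, _chi(2)),
            _d("ND2", "CG", "CB", "CA", 1.33, 116.4, _chi(2, 180.0))],
    "GLU": [_d("CG", "CB", "CA", "N", 1.53, 114.1, _chi(1)),
            _d("CD", "CG", "CB", "CA", 1.53, 112.6, _chi(2)),
            _d("OE1", "CD", "CG", "CB", 1.25, 118.4, _chi(3)),
            _d("OE2", "CD", "CG", "CB", 1.25, 118.4, _chi(3, 180.0))],
    "GLN": [_d("CG", "CB", "CA", "N", 1.53, 114.1, _chi(1)),
            _d("CD", "CG", "CB", "CA", 1.53, 112.6, _chi(2)),
            _d("OE1", "CD", "CG", "CB", 1.23, 120.8, _chi(3)),
            _d("NE2", "CD", "CG", "CB", 1.33, 116.4, _chi(3, 180.0))],
    "LYS": [_d("CG", "CB", "CA", "N", 1.53, 114.1, _chi(1)),
            _d("CD", "CG", "CB", "CA", 1.53, 111.3, _chi(2)),
            _d("CE", "CD", "CG", "CB", 1.53, 111.3, _chi(3)),
            _d("NZ", "CE", "CD", "CG", 1.47, 110.6, _chi(4))],
    "ARG": [_d("CG", "CB", "CA", "N", 1.53, 114.1, _chi(1)),
            _d("CD", "CG", "CB", "CA", 1.53, 111.3, _chi(2)),
            _d("NE", "CD", "CG", "CB", 1.47, 112.0, _chi(3)),
            _d("CZ", "NE", "CD", "CG", 1.33, 124.2, _chi(4)),
            _d("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
            _d("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0)],
    "PHE": [_d("CG", "CB", "CA", "N", 1.51, 113.8, _chi(1)),
            _d("CD1", "CG", "CB", "CA", 1.39, 120.7, _chi(2)),
            _d("CD2", "CG", "CB", "CA", 1.39, 120.7, _chi(2, 180.0)),
            _d("CE1", "CD1", "CG", "CB", 1.39, 120.7, 180.0),
            _d("CE2", "CD2", "CG", "CB", 1.39, 120.7, 180.0),
            _d("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0)],
}

SUPPORTED_FRAGMENTS = frozenset(_ZMAT)

#: position-proxy atom of each probe type (guanidino CZ for Arg,
#: carboxylate CD for Glu, last-built atom otherwise)
TERMINAL_ATOM = {res: ("CZ" if res == "ARG" else
                       "CD" if res == "GLU" else
                       (zm[-1][0] if zm else "CB"))
                 for res, zm in _ZMAT.items()}

def n_chis(aa_type: str) -> int:
    ks = [e[6][1] for e in _ZMAT[aa_type] if isinstance(e[6], tuple)]
    return max(ks) if ks else 0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place atom D bonded to c with angle D-c-b and torsion D-c-b-a."""
    theta = np.deg2rad(theta_deg)
    phi = -np.deg2rad(phi_deg)     # sign matches the IUPAC convention
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-r * np.cos(theta),
                   r * np.sin(theta) * np.cos(phi),
                   r * np.sin(theta) * np.sin(phi)])
    return c + np.column_stack([bc, m, n]) @ d2


def compute_torsion(p1, p2, p3, p4) -> float:
    """Dihedral angle p1-p2-p3-p4 in degrees, IUPAC sign convention."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))


def build_sidechain(aa_type: str, chis: tuple[float, ...],
                    n_pos: np.ndarray, ca_pos: np.ndarray,
                    cb_pos: np.ndarray) -> dict[str, np.ndarray]:
    """Build side-chain atoms beyond CB onto an existing N/CA/CB frame."""
    if aa_type not in _ZMAT:
        raise KeyError(f"unsupported fragment type {aa_type!r}")
    pos = {"N": np.asarray(n_pos, float), "CA": np.asarray(ca_pos, float),
           "CB": np.asarray(cb_pos, float)}
    for name, parent, aref, tref, r, theta, tspec in _ZMAT[aa_type]:
        if isinstance(tspec, tuple):
            _, k, offset = tspec
            phi = chis[k - 1] + offset
        else:
            phi = tspec
        pos[name] = _nerf(pos[tref], pos[aref], pos[parent], r, theta, phi)
    return {k: v for k, v in pos.items() if k not in ("N", "CA")}


def _chi_axes(aa_type: str) -> list[tuple[str, str, list[str]]]:
    """For each chi: (axis proximal, axis distal, moved atom names)."""
    zm = _ZMAT[aa_type]
    children: dict[str, list[str]] = {}
    for name, parent, *_ in zm:
        children.setdefault(parent, []).append(name)

    def descendants(atom: str) -> list[str]:
        out = []
        for c in children.get(atom, []):
            out.append(c)
            out.extend(descendants(c))
        return out

    axes = []
    for k in range(1, n_chis(aa_type) + 1):
        first = next(e for e in zm
                     if isinstance(e[6], tuple) and e[6][1] == k)
        name, parent, aref = first[0], first[1], first[2]
        axes.append((aref, parent, descendants(parent)))
    return axes


@dataclass
class ProbePose:
    """One side-chain fragment placed in space.

    ``atom_names``/``coords`` are parallel; CB is the uncharged attachment
    pseudo-atom. Parameter arrays come from the configured parameter set at
    creation and travel with the pose.
    """

    aa_type: str
    atom_names: list[str]
    coords: np.ndarray           # (n, 3) A
    origin: str = ""             # scatter seed id
    charges: np.ndarray = field(default=None, repr=False)
    eps: np.ndarray = field(default=None, repr=False)
    sigma: np.ndarray = field(default=None, repr=False)
    radii: np.ndarray = field(default=None, repr=False)
    asps: np.ndarray = field(default=None, repr=False)
    polar: np.ndarray = field(default=None, repr=False)

    @property
    def n_heavy(self) -> int:
        return len(self.atom_names)

    @property
    def terminal_index(self) -> int:
        return self.atom_names.index(TERMINAL_ATOM[self.aa_type])

    @property
    def terminal_pos(self) -> np.ndarray:
        return self.coords[self.terminal_index]

    def copy(self) -> "ProbePose":
        return ProbePose(self.aa_type, list(self.atom_names),
                         self.coords.copy(), self.origin, self.charges,
                         self.eps, self.sigma, self.radii, self.asps,
                         self.polar)

    def with_coords(self, coords: np.ndarray) -> "ProbePose":
        p = self.copy()
        p.coords = np.asarray(coords, float)
        return p


def make_probe(aa_type: str, parameter_set: ParameterSet | None = None,
               chis: tuple[float, ...] | None = None,
               origin: str = "template") -> ProbePose:
    """Ideal free fragment with CB at the origin.

    A virtual backbone (N, CA) anchors chi1; chi1 of a free fragment is a
    rigid rotation and defaults to 180.
    """
    ps = parameter_set or default_parameter_set()
    if aa_type not in _ZMAT:
        raise KeyError(f"unsupported fragment type {aa_type!r}")
    k = n_chis(aa_type)
    if chis is None:
        chis = tuple([180.0] * k)
    if len(chis) != k:
        raise ValueError(f"{aa_type} takes {k} chi angles, got {len(chis)}")
    n_pos = np.array([-2.40, 1.36, 0.0])
    ca_pos = np.array([-1.53, 0.0, 0.0])
    cb_pos = np.zeros(3)
    built = build_sidechain(aa_type, chis, n_pos, ca_pos, cb_pos)
    names = ["CB"] + [e[0] for e in _ZMAT[aa_type]]
    coords = np.array([built[n] for n in names])
    p = {n: ps.lookup(aa_type, n) for n in names}
    charges = np.array([p[n].charge for n in names])
    charges[0] = 0.0    # CB is an uncharged attachment pseudo-atom
    return ProbePose(
        aa_type=aa_type, atom_names=names, coords=coords, origin=origin,
        charges=charges,
        eps=np.array([p[n].eps for n in names]),
        sigma=np.array([p[n].sigma for n in names]),
        radii=np.array([p[n].radius for n in names]),
        asps=np.array([p[n].asp for n in names]),
        polar=np.array([p[n].polar for n in names], dtype=bool))


def rotate_torsion(pose: ProbePose, chi_index: int, delta_deg: float,
                   ) -> ProbePose:
    """Rotate chi ``chi_index`` (1-based) by ``delta_deg`` about its bond."""
    axes = _chi_axes(pose.aa_type)
    prox, dist, moved = axes[chi_index - 1]
    name_to_i = {n: i for i, n in enumerate(pose.atom_names)}
    if prox not in name_to_i:   # chi1 axis starts at CA, absent in fragments
        raise ValueError(
            f"chi{chi_index} axis atom {prox!r} not part of the fragment")
    a = pose.coords[name_to_i[prox]]
    b = pose.coords[name_to_i[dist]]
    axis = b - a
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(delta_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    coords = pose.coords.copy()
    idx = [name_to_i[n] for n in moved if n in name_to_i]
    coords[idx] = (coords[idx] - b) @ R.T + b
    return pose.with_coords(coords)


_ROTLIB: dict[str, list[tuple[float, ...]]] | None = None


def rotamer_library(path: str | Path | None = None,
                    ) -> dict[str, list[tuple[float, ...]]]:
    """Chi-angle combinations per residue type (compact, backbone-free)."""
    global _ROTLIB
    if path is None and _ROTLIB is not None:
        return _ROTLIB
    if path is None:
        ctx = resources.as_file(
            resources.files("anchorprobe.data") / "rotamers_v1.tsv")
        with ctx as p:
            lib = _parse_rotlib(p)
        _ROTLIB = lib
        return lib
    return _parse_rotlib(Path(path))


def _parse_rotlib(path: Path) -> dict[str, list[tuple[float, ...]]]:
    lib: dict[str, list[tuple[float, ...]]] = {}
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        lib.setdefault(parts[0], []).append(
            tuple(float(x) for x in parts[1:] if x != ""))
    lib.setdefault("ALA", [()])
    lib.setdefault("GLY", [()])
    return lib
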