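"""Synthetic desk-scale fixtures with known ground truth.

These generators build small rigid pseudo-proteins -- slabs, hemispherical
pockets, grooves and convex decoy blobs -- as valid PDB-writable
structures, lined with chosen chemical groups (carboxylate, guanidinium,
hydroxyl, methyl) at analytically known positions. They let every stage of
the mapping engine be exercised and verified without any external
structure: a pocket lined with two carboxylates has a computable optimal
arginine salt-bridge position, a groove lined with acids must classify as
basophilic, convex decoys provide a weak-binding background.

Scaffold pseudo-atoms reuse standard residue/atom names (ALA CB united
methyl carbons) so the normal parameter table applies; no parallel
parameterization path exists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragments import ProbePose, make_probe
from .params import COULOMB_KCAL, ParameterSet, default_parameter_set
from .scoring import EnergyBreakdown, ScoringParameters, compose_breakdown
from .structure import Atom, ProteinStructure

__all__ = ["LiningGroup", "FixtureSpec", "make_pocket_fixture",
           "pocket_with_carboxylates", "make_groove_fixture",
           "make_background_decoys", "golden_breakdown_case",
           "negate_charges"]

_SPACING = 2.6          # scaffold lattice constant, A
_GROUP_GEOMETRY = {"carboxylate", "guanidinium", "hydroxyl", "methyl"}


@dataclass(frozen=True)
class LiningGroup:
    group: str                 # carboxylate | guanidinium | hydroxyl | methyl
    position: tuple            # anchor-atom position, A
    direction: tuple           # unit-ish vector pointing into the cavity

    def __post_init__(self):
        if self.group not in _GROUP_GEOMETRY:
            raise ValueError(f"unknown lining group {self.group!r}")


@dataclass(frozen=True)
class FixtureSpec:
    geometry: str = "hemisphere"        # slab | hemisphere | groove
    lining: tuple = ()                  # LiningGroup instances
    cavity_radius: float = 4.5          # A
    extent: float = 10.0                # half-width of the slab, A
    depth: float = 10.4                 # slab thickness, A
    groove_halfwidth: float = 3.2      # A
    groove_depth: float = 4.5          # A
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in ("slab", "hemisphere", "groove"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        pos = [np.asarray(g.position, float) for g in self.lining]
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if np.linalg.norm(pos[i] - pos[j]) < 3.0:
                    raise ValueError("lining groups overlap")


def _build_structure(records, source_id: str,
                     ps: ParameterSet | None = None) -> ProteinStructure:
    """records: (chain, resseq, resname, atomname, xyz) -> structure."""
    ps = ps or default_parameter_set()
    atoms = []
    for i, (chain, resseq, resname, name, xyz) in enumerate(records, 1):
        p = ps.lookup(resname, name)
        atoms.append(Atom(
            serial=i, name=name, element=p.element, residue_name=resname,
            residue_id=(chain, resseq, ""), position=np.asarray(xyz, float),
            partial_charge=p.charge, vdw_radius=p.radius, eps=p.eps,
            sigma=p.sigma, solvation_param=p.asp, is_polar=p.polar))
    return ProteinStructure(atoms, source_id=source_id)


def _perp(d: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    return u / np.linalg.norm(u)


def _group_atoms(group: str, pos: np.ndarray, d: np.ndarray):
    """Atom records (resname, atomname, xyz) for one lining group."""
    d = np.asarray(d, float)
    d = d / np.linalg.norm(d)
    u = _perp(d)
    c, s = math.cos(math.radians(30)), math.sin(math.radians(30))
    if group == "carboxylate":
        # full mutable ASP: N-CA-CB frame buried behind, CG plate at pos
        cb = pos - 1.53 * d
        w = 0.5 * d + (math.sqrt(3) / 2) * u
        ca = cb - 1.53 * w
        nn = ca - 1.47 * (0.5 * d - (math.sqrt(3) / 2) * u)
        return [("ASP", "N", nn),
                ("ASP", "CA", ca),
                ("ASP", "CB", cb),
                ("ASP", "CG", pos),
                ("ASP", "OD1", pos + 1.25 * (c * d + s * u)),
                ("ASP", "OD2", pos + 1.25 * (c * d - s * u))]
    if group == "guanidinium":       # ARG head group, CZ at pos
        return [("ARG", "CD", pos - 1.33 * d - 1.47 * (c * d + s * u)),
                ("ARG", "NE", pos - 1.33 * d),
                ("ARG", "CZ", pos),
                ("ARG", "NH1", pos + 1.33 * (c * d + s * u)),
                ("ARG", "NH2", pos + 1.33 * (c * d - s * u))]
    if group == "hydroxyl":          # SER tip, OG at pos
        return [("SER", "CB", pos - 1.42 * d),
                ("SER", "OG", pos)]
    return [("ALA", "CB", pos)]      # methyl


def _slab_lattice(spec: FixtureSpec) -> np.ndarray:
    xs = np.arange(-spec.extent, spec.extent + 1e-9, _SPACING)
    zs = np.arange(-spec.depth, 1e-9, _SPACING)
    pts = np.array([[x, y, z] for x in xs for y in xs for z in zs])
    return pts


def make_pocket_fixture(spec: FixtureSpec,
                        out_prefix: str | Path | None = None,
                        ) -> tuple[ProteinStructure, dict]:
    """Rigid pseudo-protein with the requested cavity and lining.

    Returns the structure and a ground-truth record: the analytically
    placed optimal probe position (for an Arg probe against carboxylate
    lining) and the expected sign of each energy term. With
    ``out_prefix``, writes ``<prefix>.pdb`` and ``<prefix>.json``.
    """
    pts = _slab_lattice(spec)
    if spec.geometry == "hemisphere":
        keep = np.linalg.norm(pts, axis=1) > spec.cavity_radius + 0.8
        pts = pts[keep]
    elif spec.geometry == "groove":
        keep = ~((np.abs(pts[:, 0]) < spec.groove_halfwidth)
                 & (pts[:, 2] > -spec.groove_depth))
        pts = pts[keep]

    lining_records = []
    for g in spec.lining:
        for resname, name, xyz in _group_atoms(
                g.group, np.asarray(g.position, float),
                np.asarray(g.direction, float)):
            lining_records.append((resname, name, xyz))
    if lining_records:
        lin_xyz = np.array([xyz for *_, xyz in lining_records])
        keep = np.ones(len(pts), dtype=bool)
        for q in lin_xyz:
            keep &= np.linalg.norm(pts - q, axis=1) > 2.4
        pts = pts[keep]

    records = [("A", i + 1, "ALA", "CB", p) for i, p in enumerate(pts)]
    by_res: list = []
    resseq = 0
    i = 0
    while i < len(lining_records):
        resname = lining_records[i][0]
        n = {"ASP": 6, "ARG": 5, "SER": 2, "ALA": 1}[resname]
        resseq += 1
        for resname_, name, xyz in lining_records[i:i + n]:
            by_res.append(("B", resseq, resname_, name, xyz))
        i += n
    structure = _build_structure(records + by_res, source_id="pocket")

    truth = _ground_truth(spec)
    if out_prefix is not None:
        from .structure import write_pdb
        out_prefix = Path(out_prefix)
        write_pdb(structure, out_prefix.with_suffix(".pdb"))
        out_prefix.with_suffix(".json").write_text(
            json.dumps(truth, indent=2, default=_json_default))
    return structure, truth


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _ground_truth(spec: FixtureSpec) -> dict:
    charged = [g for g in spec.lining if g.group == "carboxylate"]
    truth: dict = {
        "geometry": spec.geometry,
        "cavity_center": [0.0, 0.0, 0.0],
        "cavity_radius": spec.cavity_radius,
        "n_carboxylates": len(charged),
        "expected_term_signs": {"V": -1, "E": -1 if charged else 0},
    }
    if len(charged) >= 2:
        pos = np.array([g.position for g in charged], float)
        dirs = np.array([g.direction for g in charged], float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        dm = dirs.mean(axis=0)
        nd = np.linalg.norm(dm)
        mid = pos.mean(axis=0)
        opt = mid + (1.5 * dm / nd if nd > 1e-9 else 0.0)
        truth["optimal_position"] = opt.tolist()
    elif len(charged) == 1:
        g = charged[0]
        d = np.asarray(g.direction, float)
        d /= np.linalg.norm(d)
        truth["optimal_position"] = (
            np.asarray(g.position, float) + 3.2 * d).tolist()
    return truth


def pocket_with_carboxylates(n_carboxylates: int = 2,
                             cavity_radius: float = 4.5) -> FixtureSpec:
    """Hemispherical pocket with 0, 1 or 2 carboxylates on its walls.

    Two groups sit on opposite walls with their CG atoms ~8 A apart and
    their planes facing the pocket mouth, so an Arg guanidinium bridging
    both defines the planted optimum near the mouth center.
    """
    if not 0 <= n_carboxylates <= 2:
        raise ValueError("supported: 0, 1 or 2 carboxylates")
    r = cavity_radius - 0.2
    theta = math.radians(68.0)
    p1 = np.array([r * math.sin(theta), 0.0, -r * math.cos(theta)])
    p2 = np.array([-p1[0], 0.0, p1[2]])
    groups = [LiningGroup("carboxylate", tuple(p1), tuple(-p1 / np.linalg.norm(p1))),
              LiningGroup("carboxylate", tuple(p2), tuple(-p2 / np.linalg.norm(p2)))]
    return FixtureSpec(geometry="hemisphere", cavity_radius=cavity_radius,
                       lining=tuple(groups[:n_carboxylates]))


def make_groove_fixture(lining: str = "carboxylate",
                        ) -> tuple[ProteinStructure, np.ndarray]:
    """Slab with a linear groove lined on one wall; returns the structure
    and reference points along the groove floor (the substrate path)."""
    spec = FixtureSpec(geometry="groove")
    half, depth = spec.groove_halfwidth, spec.groove_depth
    groups = []
    if lining != "methyl":
        for y in (-5.2, 0.0, 5.2):
            pos = (half + 0.6, y, -depth / 2)
            groups.append(LiningGroup(lining, pos, (-1.0, 0.0, 0.3)))
    spec = FixtureSpec(geometry="groove", lining=tuple(groups))
    structure, _ = make_pocket_fixture(spec)
    path = np.array([[0.0, y, -depth + 1.5]
                     for y in np.arange(-6.0, 6.1, 1.5)])
    return structure, path


def make_background_decoys(n: int, seed: int = 0,
                           out_dir: str | Path | None = None,
                           ) -> list[ProteinStructure]:
    """Convex-dominated decoy blobs with sparse shallow dimples.

    Solid lattice balls (no internal voids) with 2-3 carved surface
    dimples, one of which carries a weak polar group (hydroxyl), so each
    decoy yields only weak anchoring spots -- the background a random
    protein surface would give.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    rng = np.random.default_rng(seed)
    decoys = []
    for k in range(n):
        extent, depth = 8.0, 7.8
        xs = np.arange(-extent, extent + 1e-9, _SPACING)
        zs = np.arange(-depth, 1e-9, _SPACING)
        pts = np.array([[x, y, z] for x in xs for y in xs for z in zs])
        pts += rng.normal(scale=0.12, size=pts.shape)
        records = []
        n_dents = 1 + int(rng.integers(0, 3))
        dent_centers = []
        for _ in range(n_dents):
            for _try in range(20):
                c = np.array([rng.uniform(-4.0, 4.0),
                              rng.uniform(-4.0, 4.0), 0.0])
                if all(np.linalg.norm(c - q) > 6.5 for q in dent_centers):
                    break
            else:
                continue
            r_dent = rng.uniform(2.9, 3.6)
            pts = pts[np.linalg.norm(pts - c, axis=1) > r_dent + 0.8]
            dent_centers.append(c)
        # one weak polar group on the first dent wall
        if dent_centers:
            c = dent_centers[0]
            u = np.array([rng.normal(), rng.normal(), -0.4])
            u /= np.linalg.norm(u)
            og = c + 2.2 * u
            records += [("B", 1, "SER", "CB", og + 1.42 * u),
                        ("B", 1, "SER", "OG", og)]
            pts = pts[np.linalg.norm(pts - og, axis=1) > 2.4]
        records = [("A", i + 1, "ALA", "CB", p)
                   for i, p in enumerate(pts)] + records
        s = _build_structure(records, source_id=f"decoy{k:02d}")
        decoys.append(s)
        if out_dir is not None:
            from .structure import write_pdb
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_pdb(s, out_dir / f"decoy{k:02d}.pdb")
    return decoys


def negate_charges(structure: ProteinStructure) -> ProteinStructure:
    """Flip every partial charge; geometry, radii and LJ terms unchanged."""
    atoms = []
    for a in structure.atoms:
        atoms.append(Atom(a.serial, a.name, a.element, a.residue_name,
                          a.residue_id, a.position.copy(),
                          -a.partial_charge, a.vdw_radius, a.eps, a.sigma,
                          a.solvation_param, a.is_polar))
    return ProteinStructure(atoms, structure.source_id + "_negated")


# ---------------------------------------------------------------------------
# golden scoring case


def _naive_sasa(coords, radii, n_points, probe_radius):
    """Independent brute-force Shrake-Rupley (explicit loops)."""
    from .surface import _sphere_points
    pts = _sphere_points(n_points)
    out = []
    for i in range(len(coords)):
        ri = radii[i] + probe_radius
        free = 0
        for p in pts:
            x = coords[i] + ri * p
            buried = False
            for j in range(len(coords)):
                if j == i:
                    continue
                if np.linalg.norm(x - coords[j]) < radii[j] + probe_radius:
                    buried = True
                    break
            if not buried:
                free += 1
        out.append(4.0 * math.pi * ri * ri * free / n_points)
    return np.array(out)


def golden_breakdown_case(n_points: int = 96,
                          ) -> tuple[ProteinStructure, ProbePose,
                                     ScoringParameters, EnergyBreakdown]:
    """A <=10-atom configuration whose full breakdown is recomputed here by
    explicit term-by-term arithmetic, independent of the engine code path.

    A glutamate probe sits 5.5 A from an aspartate carboxylate plate; every
    quantity (V and E by naive pair loops, areas by a brute-force sphere
    sampler, the composition by the literal formulas) is evaluated with
    plain Python loops and frozen into the returned expected breakdown.
    """
    d = np.array([0.0, 0.0, 1.0])
    records = [("ASP", "CB", np.array([0.0, 0.0, -1.53])),
               ("ASP", "CG", np.array([0.0, 0.0, 0.0])),
               ("ASP", "OD1", np.array([0.625, 0.0, 1.083])),
               ("ASP", "OD2", np.array([-0.625, 0.0, 1.083])),
               ("ALA", "CB", np.array([3.2, 0.0, -1.0]))]
    structure = _build_structure(
        [("A", i + 1, rn, an, xyz) for i, (rn, an, xyz) in
         enumerate(records)], source_id="golden")
    pose = make_probe("GLU")
    pose = pose.with_coords(pose.coords + (np.array([0.0, 0.0, 5.5])
                                           - pose.terminal_pos))
    params = ScoringParameters()

    # --- independent recomputation, explicit loops ---
    V = 0.0
    E = 0.0
    for i in range(len(pose.coords)):
        for j, a in enumerate(structure.atoms):
            r = np.linalg.norm(pose.coords[i] - a.position)
            r = max(r, 0.4)
            eps = math.sqrt(pose.eps[i] * a.eps)
            sig = 0.5 * (pose.sigma[i] + a.sigma)
            sr6 = (sig / r) ** 6
            V += 4.0 * eps * (sr6 * sr6 - sr6)
            E += (COULOMB_KCAL / params.eps
                  * pose.charges[i] * a.partial_charge / r)
    pr = 1.4
    iso = _naive_sasa(pose.coords, pose.radii, n_points, pr)
    all_c = np.vstack([pose.coords, structure.coords()])
    all_r = np.concatenate([pose.radii, structure.radii()])
    bound = _naive_sasa(all_c, all_r, n_points, pr)
    prot_alone = _naive_sasa(structure.coords(), structure.radii(),
                             n_points, pr)
    np_probe = len(pose.coords)
    s_p = float(np.sum(pose.asps * (iso - bound[:np_probe])))
    s_cav = float(np.sum(structure.asp() * (prot_alone
                                            - bound[np_probe:])))
    A = float(bound[:np_probe].sum())
    pol = pose.polar
    fa_pol = float(bound[:np_probe][pol].sum() / iso[pol].sum())
    expected = compose_breakdown(V, E, pose.n_heavy, A, fa_pol, s_p,
                                 s_cav, params)
    return structure, pose, params, expected
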