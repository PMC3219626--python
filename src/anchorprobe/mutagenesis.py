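"""In-silico mutagenesis: shape-mimicking side-chain replacement and
subsite ddG by re-mapping.

Mutations probe which residues drive Arg binding at a subsite while
perturbing the pocket shape as little as possible: the canonical menu
replaces Thr by Val, Asp/Asn by Leu and Glu by Met -- hydrophobic residues
of comparable size. The replacement rotamer is chosen automatically as the
clash-free rotamer with maximal heavy-atom volume overlap with the native
side chain (a deterministic surrogate for choosing the rotamer that best
mimics the native surface shape by eye), then relaxed by exactly 20
steepest-descent steps of its chi torsions against the fixed remainder of
the structure. The energetic effect is read out by re-mapping: ddG is the
change in best subsite dG between mutant and wild-type maps, reported NC
(no significant change) within +/-1 kcal/mol and absent when the wild
type has no spot at the subsite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .fragments import build_sidechain, n_chis, rotamer_library
from .groove import SiteDefinition, subsite_energies
from .params import ParameterSet, default_parameter_set
from .scoring import ScoringParameters
from .structure import Atom, ProteinStructure, ResidueId
from .surface import MapConfig, map_surface, pair_energy

log = logging.getLogger("anchorprobe")

__all__ = ["MutationSpec", "DdgResult", "mutate_residue", "ddg_at_subsite",
           "mutation_scan", "NC_THRESHOLD"]

#: |ddG| at or below this is "no significant change" (kcal/mol)
NC_THRESHOLD = 1.0

#: shape-preserving replacement menu (charged/polar -> apolar of like size)
ALLOWED_MUTATIONS = {
    ("THR", "VAL"), ("ASP", "LEU"), ("ASN", "LEU"), ("GLU", "MET"),
    ("PHE", "SER"),
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class MutationSpec:
    residue_id: ResidueId
    from_aa: str
    to_aa: str
    label: str = ""                       # e.g. PKA-numbering tag "D169L"
    policy: str = "mimic-shape"           # or "explicit"
    chis: tuple = ()                      # used when policy == "explicit"
    force: bool = False                   # allow off-menu replacements

    def __post_init__(self):
        menu_ok = ((self.from_aa, self.to_aa) in ALLOWED_MUTATIONS
                   or self.from_aa == self.to_aa)
        if not menu_ok and not self.force:
            raise ValueError(
                f"{self.from_aa}->{self.to_aa} is outside the "
                "shape-preserving menu; pass force=True to override")


def _sphere_overlap_volume(r1: float, r2: float, d: float) -> float:
    """Lens volume of two intersecting spheres."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r ** 3
    return (np.pi * (r1 + r2 - d) ** 2
            * (d ** 2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
            / (12 * d))


def _shape_overlap(new_xyz, new_r, old_xyz, old_r) -> float:
    total = 0.0
    for i in range(len(new_xyz)):
        for j in range(len(old_xyz)):
            total += _sphere_overlap_volume(
                new_r[i], old_r[j],
                float(np.linalg.norm(new_xyz[i] - old_xyz[j])))
    return total


def mutate_residue(structure: ProteinStructure, spec: MutationSpec,
                   rotlib: dict | None = None,
                   parameter_set: ParameterSet | None = None,
                   clash_factor: float = 0.5,
                   relax_steps: int = 20) -> ProteinStructure:
    """Replace one side chain, mimicking the native shape, and relax it.

    The backbone (and CB) stay fixed; candidate rotamers that hard-clash
    with the environment are rejected, the remaining rotamer with the
    largest heavy-atom volume overlap with the wild-type side chain wins,
    and exactly ``relax_steps`` steepest-descent torsion steps remove
    residual strain against the fixed environment. No atom outside the
    mutated residue ever moves.
    """
    ps = parameter_set or default_parameter_set()
    rotlib = rotlib or rotamer_library()
    rid = spec.residue_id
    old_atoms = structure.residue_atoms(rid)
    if not old_atoms:
        raise KeyError(f"residue {rid} not found")
    if old_atoms[0].residue_name != spec.from_aa:
        raise ValueError(
            f"residue {rid} is {old_atoms[0].residue_name}, "
            f"not {spec.from_aa}")

    by_name = {a.name: a for a in old_atoms}
    n_pos = by_name["N"].position if "N" in by_name else None
    ca_pos = by_name["CA"].position if "CA" in by_name else None
    cb_pos = by_name["CB"].position if "CB" in by_name else None
    if ca_pos is None or n_pos is None:
        raise ValueError(f"residue {rid} lacks backbone atoms N/CA")
    if cb_pos is None:      # rebuild CB from the backbone frame
        c_pos = by_name["C"].position
        u = ca_pos - n_pos
        v = ca_pos - c_pos
        bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        nrm = np.cross(u, v)
        d = (bis / np.linalg.norm(bis) * np.cos(np.deg2rad(54.75))
             + nrm / np.linalg.norm(nrm) * np.sin(np.deg2rad(54.75)))
        cb_pos = ca_pos + 1.53 * d

    old_sc = [a for a in old_atoms if a.name not in BACKBONE_ATOMS
              and a.name != "CB"]
    old_xyz = np.array([a.position for a in old_sc]).reshape(-1, 3)
    old_r = np.array([a.vdw_radius for a in old_sc])

    env = [a for a in structure.atoms if a.residue_id != rid]
    env_xyz = np.array([a.position for a in env])
    env_r = np.array([a.vdw_radius for a in env])

    if spec.policy == "explicit":
        candidates = [tuple(spec.chis)]
    else:
        candidates = [c[:n_chis(spec.to_aa)] for c in rotlib[spec.to_aa]]
        candidates = sorted(set(candidates))
    best = None
    for chis in candidates:
        built = build_sidechain(spec.to_aa, chis, n_pos, ca_pos, cb_pos)
        names = [n for n in built if n != "CB"]
        xyz = np.array([built[n] for n in names]).reshape(-1, 3)
        radii = np.array([ps.lookup(spec.to_aa, n).radius for n in names])
        if len(xyz) and len(env_xyz):
            lim = clash_factor * (radii[:, None] + env_r[None, :])
            if np.any(cdist(xyz, env_xyz) < lim):
                continue
        score = _shape_overlap(xyz, radii, old_xyz, old_r) if len(old_xyz) \
            else 0.0
        if best is None or score > best[0]:
            best = (score, chis)
    if best is None:
        raise RuntimeError(
            f"no clash-free rotamer for {spec.from_aa}->{spec.to_aa} "
            f"at {rid}")
    chis = list(best[1])

    # exactly `relax_steps` steepest-descent steps on the chi torsions
    def side_energy(chi_values):
        built = build_sidechain(spec.to_aa, tuple(chi_values), n_pos,
                                ca_pos, cb_pos)
        names = [n for n in built if n != "CB"]
        if not names or not len(env_xyz):
            return 0.0
        xyz = np.array([built[n] for n in names])
        p = [ps.lookup(spec.to_aa, n) for n in names]
        V, E = pair_energy(
            xyz, [x.charge for x in p], [x.eps for x in p],
            [x.sigma for x in p], env_xyz,
            [a.partial_charge for a in env], [a.eps for a in env],
            [a.sigma for a in env], 1.5)
        return V + E

    if chis:
        f0 = side_energy(chis)
        h = 0.5    # deg
        for _ in range(relax_steps):
            g = np.zeros(len(chis))
            for k in range(len(chis)):
                up = list(chis); up[k] += h
                dn = list(chis); dn[k] -= h
                g[k] = (side_energy(up) - side_energy(dn)) / (2 * h)
            if np.abs(g).max() < 1e-9:
                break
            d = -g / np.linalg.norm(g)
            step = 10.0   # deg
            while step > 1e-3:
                trial = [c + step * dk for c, dk in zip(chis, d)]
                ft = side_energy(trial)
                if ft < f0 - 1e-9:
                    chis, f0 = trial, ft
                    break
                step *= 0.5
            else:
                break

    built = build_sidechain(spec.to_aa, tuple(chis), n_pos, ca_pos, cb_pos)
    new_atoms: list[Atom] = []
    serial = 0
    for a in structure.atoms:
        if a.residue_id != rid:
            serial += 1
            new_atoms.append(Atom(serial, a.name, a.element, a.residue_name,
                                  a.residue_id, a.position.copy(),
                                  a.partial_charge, a.vdw_radius, a.eps,
                                  a.sigma, a.solvation_param, a.is_polar))
            continue
        if a.name in BACKBONE_ATOMS:
            p = ps.lookup(spec.to_aa, a.name)
            serial += 1
            new_atoms.append(Atom(serial, a.name, p.element, spec.to_aa,
                                  rid, a.position.copy(), p.charge,
                                  p.radius, p.eps, p.sigma, p.asp, p.polar))
        elif a.name == "CA":    # unreachable; CA is backbone
            pass
    # insert the new side chain right after the residue's backbone: simplest
    # is to append in canonical build order at the residue position
    rebuilt: list[Atom] = []
    inserted = False
    for a in new_atoms:
        rebuilt.append(a)
        if a.residue_id == rid and a.name == "O" and not inserted:
            for name, xyz in built.items():
                p = ps.lookup(spec.to_aa, name)
                rebuilt.append(Atom(0, name, p.element, spec.to_aa, rid,
                                    np.asarray(xyz, float), p.charge,
                                    p.radius, p.eps, p.sigma, p.asp,
                                    p.polar))
            inserted = True
    if not inserted:    # residue had no O (pseudo-residue); append at end
        for name, xyz in built.items():
            p = ps.lookup(spec.to_aa, name)
            rebuilt.append(Atom(0, name, p.element, spec.to_aa, rid,
                                np.asarray(xyz, float), p.charge, p.radius,
                                p.eps, p.sigma, p.asp, p.polar))
    for i, a in enumerate(rebuilt, 1):
        a.serial = i
    out = ProteinStructure(rebuilt, structure.source_id
                           + f"_{spec.label or spec.to_aa}")
    return out


@dataclass(frozen=True)
class DdgResult:
    """ddG at one subsite: a value, NC, or absent (no wild-type spot)."""

    kind: str                     # "value" | "nc" | "absent"
    ddg: float | None
    wt_dg: float | None
    mut_dg: float | None

    def __str__(self) -> str:
        if self.kind == "absent":
            return "-"
        if self.kind == "nc":
            return "NC"
        return f"{self.ddg:+.1f}"


def ddg_at_subsite(wild_report, mutant_report, subsite: str,
                   ) -> DdgResult:
    """Best-subsite-dG difference (mutant - wild), NC within +/-1.

    Both reports must come from maps computed with identical parameters;
    ``subsite`` is "-2" or "-5". When the wild type has no spot at the
    subsite the result is absent; when the mutant loses the spot entirely
    the penalty is reported against the reporting threshold of the map.
    """
    wt = wild_report.best_dg.get(subsite)
    mut = mutant_report.best_dg.get(subsite)
    if wt is None:
        return DdgResult("absent", None, None, mut)
    if mut is None:
        # spot vanished: at least the distance from wt to the threshold
        ddg = -2.0 - wt
        kind = "nc" if abs(ddg) <= NC_THRESHOLD else "value"
        return DdgResult(kind, ddg, wt, None)
    ddg = mut - wt
    kind = "nc" if abs(ddg) <= NC_THRESHOLD else "value"
    return DdgResult(kind, ddg, wt, mut)


def mutation_scan(structure: ProteinStructure, specs: list[MutationSpec],
                  site: SiteDefinition, subsites: tuple = ("-2", "-5"),
                  probe: str = "ARG",
                  params: ScoringParameters | None = None,
                  config: MapConfig | None = None,
                  parameter_set: ParameterSet | None = None,
                  ) -> pd.DataFrame:
    """Map the wild type and every mutant; tabulate per-subsite ddG.

    Returns a tidy table with one row per (variant, subsite): the wild-type
    rows carry absolute dG, mutant rows carry ddG/NC/absent strings plus
    numeric columns.
    """
    wt_map = map_surface(structure, params=params, config=config,
                         aa_type=probe, parameter_set=parameter_set)
    wt_rep = subsite_energies(wt_map.mean_spots, site)
    rows = []
    for sub in subsites:
        dg = wt_rep.best_dg.get(sub)
        rows.append({"variant": "WT", "subsite": sub,
                     "dG": dg, "ddG": None,
                     "call": "-" if dg is None else f"{dg:.1f}"})
    for spec in specs:
        mutant = mutate_residue(structure, spec,
                                parameter_set=parameter_set)
        mut_map = map_surface(mutant, params=params, config=config,
                              aa_type=probe, parameter_set=parameter_set)
        mut_rep = subsite_energies(mut_map.mean_spots, site)
        for sub in subsites:
            res = ddg_at_subsite(wt_rep, mut_rep, sub)
            rows.append({"variant": spec.label or
                         f"{spec.from_aa}->{spec.to_aa}@{spec.residue_id}",
                         "subsite": sub, "dG": res.mut_dg,
                         "ddG": res.ddg, "call": str(res)})
    return pd.DataFrame(rows)


def read_mutation_specs(path: str | Path) -> list[MutationSpec]:
    """Mutation spec TSV: chain, resseq, from_aa, to_aa[, label, policy]."""
    specs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        chain, resseq, from_aa, to_aa = parts[:4]
        label = parts[4] if len(parts) > 4 else ""
        policy = parts[5] if len(parts) > 5 else "mimic-shape"
        specs.append(MutationSpec((chain, int(resseq), ""), from_aa, to_aa,
                                  label=label, policy=policy))
    return specs
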