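"""Surface mapping: SASA, subpocket seeds, probe scattering, minimization
and clustering into mean anchoring spots.

The engine runs in two stages. A geometry stage detects subpockets --
concave surface loci with enough free volume to hold a single side-chain
fragment -- and scatters ideal fragments over them in many discrete
orientations, giving a non-random yet exhaustive coverage of the surface.
An energy stage then alternates local energy minimization (Lennard-Jones
plus Coulomb at a low dielectric, over rigid-body and side-chain torsional
degrees of freedom) with intermediate clustering, scores the surviving
poses with the empirical dG function, and finally merges adjacent scored
spots (fragment RMSD below ``rms_min``, default 3 A) into mean anchoring
spots whose coordinates are dG-weighted averages and whose energy is the
cluster minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .fragments import (ProbePose, _chi_axes, make_probe, n_chis,
                        rotate_torsion)
from .params import COULOMB_KCAL, ParameterSet, default_parameter_set
from .scoring import EnergyBreakdown, ScoringParameters, score_pose
from .structure import ProteinStructure, sidechain_rmsd

log = logging.getLogger("anchorprobe")

__all__ = ["SasaCalculator", "SubpocketSeed", "AnchoringSpot",
           "MeanAnchoringSpot", "MapConfig", "MapResult", "compute_sasa",
           "detect_subpockets", "scatter_probes", "minimize_pose",
           "cluster_spots", "map_surface", "pair_energy"]


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere sampling."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class SasaCalculator:
    """Shrake-Rupley sphere-sampling SASA with a fixed point set.

    Deterministic for a given ``n_points``; the default 1.4 A probe radius
    models a water molecule.
    """

    def __init__(self, n_points: int = 240, probe_radius: float = 1.4):
        if n_points < 32:
            raise ValueError("n_points must be at least 32")
        self.n_points = n_points
        self.probe_radius = probe_radius
        self._points = _sphere_points(n_points)

    def compute(self, coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
        return self.compute_subset(coords, radii,
                                   np.arange(len(np.atleast_2d(coords))))

    def compute_subset(self, coords: np.ndarray, radii: np.ndarray,
                       subset: np.ndarray) -> np.ndarray:
        """Areas of ``subset`` atoms with *all* atoms as occluders."""
        coords = np.atleast_2d(np.asarray(coords, float))
        radii = np.asarray(radii, float)
        if np.any(radii <= 0):
            raise ValueError("all radii must be positive")
        rs = radii + self.probe_radius
        areas = np.empty(len(subset), dtype=float)
        d = cdist(coords[subset], coords)
        for k, i in enumerate(subset):
            touch = (d[k] < rs[i] + rs).nonzero()[0]
            touch = touch[touch != i]
            pts = coords[i] + rs[i] * self._points
            if len(touch):
                dd = cdist(pts, coords[touch])
                buried = (dd < rs[touch]).any(axis=1)
                n_free = int((~buried).sum())
            else:
                n_free = self.n_points
            areas[k] = 4.0 * np.pi * rs[i] ** 2 * n_free / self.n_points
        return areas


def compute_sasa(structure: ProteinStructure,
                 pose: ProbePose | None = None,
                 probe_radius: float = 1.4,
                 n_points: int = 240) -> np.ndarray:
    """Per-atom solvent-accessible areas (protein atoms first, then pose)."""
    engine = SasaCalculator(n_points=n_points, probe_radius=probe_radius)
    coords = structure.coords()
    radii = structure.radii()
    if pose is not None:
        coords = np.vstack([coords, pose.coords])
        radii = np.concatenate([radii, pose.radii])
    return engine.compute(coords, radii)


# ---------------------------------------------------------------------------
# subpocket detection


@dataclass(eq=False)
class SubpocketSeed:
    position: np.ndarray
    depth_score: float            # buried-direction fraction, [0, 1]
    lining_atoms: np.ndarray      # indices into structure.atoms


def detect_subpockets(structure: ProteinStructure,
                      grid_spacing: float = 1.0,
                      burial_threshold: float = 0.55,
                      n_directions: int = 42,
                      min_gap: float = 1.4,
                      max_gap: float = 3.5,
                      ray_length: float = 8.0,
                      ray_step: float = 1.0,
                      suppress_radius: float = 2.0) -> list[SubpocketSeed]:
    """Grid-based concavity scan for side-chain-sized subpockets.

    Exterior grid nodes close to the molecular surface (solvent gap between
    ``min_gap`` and ``max_gap``, so a water/fragment atom fits) are scored
    by the fraction of directions blocked by protein within ``ray_length``,
    ray-marching through a vdW occupancy grid; nodes above
    ``burial_threshold`` survive a non-maximum suppression and become
    scatter seeds. A convex surface never reaches the threshold, so a lone
    residue yields no seeds.
    """
    coords = structure.coords()
    radii = structure.radii()
    pad = max_gap + 1.5
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    h = grid_spacing
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    cell_centers = lo + h * np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
        axis=-1).reshape(-1, 3)
    # chunked nearest-surface gap (keeps intermediates cache-sized)
    gap = np.empty(len(cell_centers))
    chunk = max(1, 2_000_000 // max(len(coords), 1))
    for s in range(0, len(cell_centers), chunk):
        d = cdist(cell_centers[s:s + chunk], coords)
        d -= radii
        gap[s:s + chunk] = d.min(axis=1)
    occupied = (gap < 0.0).reshape(shape)
    band = (gap >= min_gap) & (gap <= max_gap)
    cand = cell_centers[band]
    if len(cand) == 0:
        return []
    dirs = _sphere_points(n_directions)
    steps = np.arange(ray_step, ray_length + 1e-9, ray_step)
    burial = np.empty(len(cand))
    shape_m1 = np.array(shape) - 1
    for s in range(0, len(cand), 512):
        block = cand[s:s + 512]
        # (b, n_dir, n_step, 3) occupancy lookups along each ray
        samples = (block[:, None, None, :]
                   + dirs[None, :, None, :] * steps[None, None, :, None])
        idx = np.rint((samples - lo) / h).astype(int)
        np.clip(idx, 0, shape_m1, out=idx)
        blocked = occupied[idx[..., 0], idx[..., 1], idx[..., 2]]
        burial[s:s + 512] = blocked.any(axis=2).mean(axis=1)
    keep = burial >= burial_threshold
    cand, burial = cand[keep], burial[keep]
    order = np.argsort(-burial)
    seeds: list[SubpocketSeed] = []
    taken: list[np.ndarray] = []
    for i in order:
        p = cand[i]
        if any(np.linalg.norm(p - q) < suppress_radius for q in taken):
            continue
        taken.append(p)
        lining = (cdist(coords, p[None, :])[:, 0] - radii < 5.0).nonzero()[0]
        seeds.append(SubpocketSeed(position=p, depth_score=float(burial[i]),
                                   lining_atoms=lining))
    return seeds


# ---------------------------------------------------------------------------
# probe scattering


def _orientation_set(n: int) -> list[np.ndarray]:
    """n deterministic rotation matrices spreading axis and roll."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    dirs = _sphere_points(n)
    out = []
    for k in range(n):
        z = dirs[k]
        a = np.array([1.0, 0.0, 0.0])
        if abs(z @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        x = np.cross(a, z)
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        roll = k * golden
        xr = np.cos(roll) * x + np.sin(roll) * y
        yr = np.cross(z, xr)
        out.append(np.column_stack([xr, yr, z]))
    return out


def scatter_probes(structure: ProteinStructure, aa_type: str,
                   seeds: list[SubpocketSeed], orientations: int = 24,
                   parameter_set: ParameterSet | None = None,
                   clash_factor: float = 0.5) -> list[ProbePose]:
    """Ideal fragments at discrete orientations around each seed.

    The fragment's terminal group sits on the seed point; orientations
    rotate the whole fragment about it. Poses with a hard clash (pair
    distance below ``clash_factor`` times the radius sum) are rejected.
    """
    template = make_probe(aa_type, parameter_set)
    coords = structure.coords()
    radii = structure.radii()
    rots = _orientation_set(orientations)
    axis = template.terminal_pos - template.coords[0]
    axis = axis / np.linalg.norm(axis)
    poses: list[ProbePose] = []
    for si, seed in enumerate(seeds):
        near = (cdist(coords, seed.position[None, :])[:, 0] < 14.0
                ).nonzero()[0]
        for k, R in enumerate(rots):
            c = (template.coords - template.terminal_pos) @ R.T \
                + seed.position
            pose = template.with_coords(c)
            pose.origin = f"seed{si:04d}:o{k:03d}"
            if len(near):
                dmin = cdist(c, coords[near])
                lim = clash_factor * (pose.radii[:, None] + radii[near][None, :])
                if np.any(dmin < lim):
                    continue
            poses.append(pose)
    return poses


# ---------------------------------------------------------------------------
# interaction energy and pose minimization


def pair_energy(ca, qa, ea, sa, cb, qb, eb, sb,
                dielectric: float = 1.5) -> tuple[float, float]:
    """Lennard-Jones and Coulomb energy between two atom sets (kcal/mol)."""
    d = cdist(np.atleast_2d(ca), np.atleast_2d(cb))
    d = np.maximum(d, 0.4)      # guard against overflow at pathological overlap
    eps = np.sqrt(np.outer(ea, eb))
    sig = 0.5 * (np.asarray(sa)[:, None] + np.asarray(sb)[None, :])
    sr6 = (sig / d) ** 6
    V = float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    E = float(COULOMB_KCAL / dielectric * np.sum(np.outer(qa, qb) / d))
    return V, E


def _intra_pairs(pose: ProbePose) -> list[tuple[int, int]]:
    """Index pairs of fragment atoms >= 4 bonds apart (self-clash guard)."""
    from .fragments import _ZMAT
    parents = {e[0]: e[1] for e in _ZMAT[pose.aa_type]}
    names = pose.atom_names
    idx = {n: i for i, n in enumerate(names)}
    # graph distance via parent chains rooted at CB
    def path_to_root(n):
        out = [n]
        while n in parents:
            n = parents[n]
            out.append(n)
        return out
    pairs = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            pa, pb = path_to_root(a), path_to_root(b)
            common = next(x for x in pa if x in pb)
            dist = pa.index(common) + pb.index(common)
            if dist >= 4:
                pairs.append((idx[a], idx[b]))
    return pairs


class _EnergyContext:
    """Probe-protein (+ probe self LJ) energy against a fixed neighborhood."""

    def __init__(self, structure: ProteinStructure, pose: ProbePose,
                 dielectric: float, cutoff: float = 16.0):
        coords = structure.coords()
        center = pose.coords.mean(axis=0)
        near = (cdist(coords, center[None, :])[:, 0] < cutoff).nonzero()[0]
        self.pc = coords[near]
        self.pq = structure.charges()[near]
        eps, sig = structure.lj()
        self.pe, self.ps = eps[near], sig[near]
        self.dielectric = dielectric
        self.intra = _intra_pairs(pose)

    def energy(self, pose: ProbePose) -> tuple[float, float]:
        if len(self.pc) == 0:
            V = E = 0.0
        else:
            V, E = pair_energy(pose.coords, pose.charges, pose.eps,
                               pose.sigma, self.pc, self.pq, self.pe,
                               self.ps, self.dielectric)
        for i, j in self.intra:
            d = max(float(np.linalg.norm(pose.coords[i] - pose.coords[j])),
                    0.4)
            e = np.sqrt(pose.eps[i] * pose.eps[j])
            s = 0.5 * (pose.sigma[i] + pose.sigma[j])
            sr6 = (s / d) ** 6
            V += 4.0 * e * (sr6 ** 2 - sr6)
        return V, E

    def total(self, pose: ProbePose) -> float:
        V, E = self.energy(pose)
        return V + E

    def total_grad(self, pose: ProbePose) -> tuple[float, np.ndarray]:
        """Energy and its analytic Cartesian gradient per probe atom."""
        x = pose.coords
        G = np.zeros_like(x)
        f = 0.0
        if len(self.pc):
            rel = x[:, None, :] - self.pc[None, :, :]
            r = np.sqrt(np.einsum("ijk,ijk->ij", rel, rel))
            np.maximum(r, 0.4, out=r)
            eps = np.sqrt(np.outer(pose.eps, self.pe))
            sig = 0.5 * (pose.sigma[:, None] + self.ps[None, :])
            sr6 = (sig / r) ** 6
            qq = (COULOMB_KCAL / self.dielectric
                  * np.outer(pose.charges, self.pq))
            f += float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)) + np.sum(qq / r))
            # dU/dr: LJ + Coulomb
            dudr = (4.0 * eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r
                    - qq / r ** 2)
            G += np.einsum("ij,ijk->ik", dudr / r, rel)
        for i, j in self.intra:
            rel = x[i] - x[j]
            d = max(float(np.linalg.norm(rel)), 0.4)
            e = np.sqrt(pose.eps[i] * pose.eps[j])
            s = 0.5 * (pose.sigma[i] + pose.sigma[j])
            sr6 = (s / d) ** 6
            f += 4.0 * e * (sr6 ** 2 - sr6)
            dudr = 4.0 * e * (-12.0 * sr6 ** 2 + 6.0 * sr6) / d
            G[i] += dudr * rel / d
            G[j] -= dudr * rel / d
        return f, G


def _apply_dofs(pose: ProbePose, x: np.ndarray,
                torsion_ids: list[int]) -> ProbePose:
    """Torsions (deg), then rotation about the centroid, then translation."""
    p = pose
    for k, chi in enumerate(torsion_ids):
        if x[6 + k] != 0.0:
            p = rotate_torsion(p, chi, np.degrees(x[6 + k]))
    w = x[3:6]
    ang = np.linalg.norm(w)
    c = p.coords.mean(axis=0)
    if ang > 0:
        axis = w / ang
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        coords = (p.coords - c) @ R.T + c
    else:
        coords = p.coords.copy()
    return p.with_coords(coords + x[:3])


def minimize_pose(structure: ProteinStructure, pose: ProbePose,
                  cycles: int = 150, dielectric: float = 1.5,
                  gtol: float = 0.1, cutoff: float = 16.0,
                  ) -> tuple[ProbePose, float, float]:
    """Steepest-descent local optimization of a rigid pose plus torsions.

    Degrees of freedom: 3 translations, 3 rotations (about the fragment
    centroid) and the fragment chi torsions beyond chi1 (chi1 of a free
    fragment is redundant with rigid rotation). Backtracking line search
    guarantees a monotone energy; convergence at max-gradient < ``gtol``
    kcal/(mol*A) or the cycle budget. Returns the pose with its raw LJ (V)
    and Coulomb (E) energies against the full protein.
    """
    ctx = _EnergyContext(structure, pose, dielectric, cutoff)
    torsion_ids = list(range(2, n_chis(pose.aa_type) + 1))
    ndof = 6 + len(torsion_ids)
    current = pose.copy()
    f0, G = ctx.total_grad(current)
    axes = _chi_axes(current.aa_type)
    name_to_i = {n: i for i, n in enumerate(current.atom_names)}
    for _ in range(cycles):
        # project the Cartesian gradient onto the pose degrees of freedom
        g = np.zeros(ndof)
        g[:3] = G.sum(axis=0)
        c = current.coords.mean(axis=0)
        g[3:6] = np.sum(np.cross(current.coords - c, G), axis=0)
        for k, chi in enumerate(torsion_ids):
            prox, dist, moved = axes[chi - 1]
            a = current.coords[name_to_i[prox]]
            b = current.coords[name_to_i[dist]]
            u = b - a
            u /= np.linalg.norm(u)
            idx = [name_to_i[n] for n in moved if n in name_to_i]
            g[6 + k] = float(u @ np.sum(
                np.cross(current.coords[idx] - b, G[idx]), axis=0))
        gmax = np.abs(g).max()
        if gmax < gtol:
            break
        direction = -g / np.linalg.norm(g)
        step = 0.25
        accepted = False
        while step > 1e-5:
            trial = _apply_dofs(current, step * direction, torsion_ids)
            ft = ctx.total(trial)
            if ft < f0 - 1e-6:
                current = trial
                f0, G = ctx.total_grad(current)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    V, E = _full_energy(structure, current, dielectric)
    return current, V, E


def _full_energy(structure: ProteinStructure, pose: ProbePose,
                 dielectric: float) -> tuple[float, float]:
    eps, sig = structure.lj()
    return pair_energy(pose.coords, pose.charges, pose.eps, pose.sigma,
                       structure.coords(), structure.charges(), eps, sig,
                       dielectric)


# ---------------------------------------------------------------------------
# clustering


@dataclass(eq=False)
class AnchoringSpot:
    pose: ProbePose
    energy: EnergyBreakdown
    rank: int = 0

    @property
    def dG(self) -> float:
        return self.energy.dG


@dataclass(eq=False)
class MeanAnchoringSpot:
    pose: ProbePose                    # dG-weighted average coordinates
    members: list[AnchoringSpot]
    dG: float                          # minimum member dG
    rank: int = 0


def _rank_key(spot: AnchoringSpot):
    # deterministic ranking: dG, then raw E, then scatter seed id
    return (round(spot.dG, 6), round(spot.energy.E, 6), spot.pose.origin)


def cluster_spots(spots: list[AnchoringSpot], rms_min: float = 3.0,
                  ) -> list[MeanAnchoringSpot]:
    """Greedy merge of adjacent spots into mean anchoring spots.

    The lowest-dG unassigned spot seeds a cluster and gathers every
    unassigned spot whose fragment RMSD (heavy atoms, CB excluded) to it is
    at most ``rms_min``. Representative coordinates are dG-weighted
    averages -- lower dG weighs more, via w = exp(min_dG - dG) -- and the
    cluster energy is the minimum member dG.
    """
    remaining = sorted(spots, key=_rank_key)
    out: list[MeanAnchoringSpot] = []
    while remaining:
        seed = remaining[0]
        members = [s for s in remaining
                   if sidechain_rmsd(seed.pose, s.pose) <= rms_min]
        remaining = [s for s in remaining if s not in members]
        dgs = np.array([m.dG for m in members])
        w = np.exp(dgs.min() - dgs)
        coords = np.einsum("m,mij->ij",
                           w / w.sum(),
                           np.stack([m.pose.coords for m in members]))
        rep = members[0].pose.with_coords(coords)
        out.append(MeanAnchoringSpot(pose=rep, members=members,
                                     dG=float(dgs.min())))
    out.sort(key=lambda c: (round(c.dG, 6),
                            _rank_key(c.members[0])))
    for r, c in enumerate(out, start=1):
        c.rank = r
    return out


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class MapConfig:
    probe: str = "ARG"
    grid_spacing: float = 1.0
    burial_threshold: float = 0.55
    orientations: int = 24
    cycles: int = 3                       # minimize/cluster rounds
    cycle_budgets: tuple = (40, 40, 150)  # SD iterations per round
    intermediate_rms: float = 1.5         # A, dedup between rounds
    rms_min: float = 3.0                  # A, final mean-spot clustering
    report_threshold: float = -2.0        # kcal/mol, drop weaker spots
    sasa_points: int = 120
    dielectric: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.rms_min <= 0:
            raise ValueError("rms_min must be > 0")
        if len(self.cycle_budgets) < self.cycles:
            raise ValueError("need one cycle budget per cycle")


@dataclass
class MapResult:
    mean_spots: list[MeanAnchoringSpot]
    detailed_spots: list[AnchoringSpot]
    seeds: list[SubpocketSeed]
    n_scattered: int
    config: MapConfig
    scoring: ScoringParameters


def _dedup_poses(scored: list[tuple[ProbePose, float]], rms: float,
                 ) -> list[ProbePose]:
    """Keep the lowest-energy pose of each RMSD-adjacent group."""
    order = sorted(scored, key=lambda t: t[1])
    kept: list[tuple[ProbePose, float]] = []
    for pose, e in order:
        if any(sidechain_rmsd(pose, kp) <= rms for kp, _ in kept):
            continue
        kept.append((pose, e))
    return [p for p, _ in kept]


def map_surface(structure: ProteinStructure, aa_type: str | None = None,
                params: ScoringParameters | None = None,
                config: MapConfig | None = None,
                parameter_set: ParameterSet | None = None) -> MapResult:
    """Run the full mapping pipeline on a prepared structure.

    seeds -> scatter -> (minimize, cluster) cycles -> score -> cluster at
    ``rms_min`` -> rank. Deterministic for a fixed config.
    """
    config = config or MapConfig()
    if aa_type is not None and aa_type != config.probe:
        config = replace(config, probe=aa_type)
    params = params or ScoringParameters()
    ps = parameter_set or default_parameter_set()
    log.info("mapping %s with %s probe", structure.source_id, config.probe)
    seeds = detect_subpockets(structure, grid_spacing=config.grid_spacing,
                              burial_threshold=config.burial_threshold)
    poses = scatter_probes(structure, config.probe, seeds,
                           orientations=config.orientations,
                           parameter_set=ps)
    log.info("%d seeds, %d scattered poses", len(seeds), len(poses))
    n_scattered = len(poses)

    minimized: list[tuple[ProbePose, float, float]] = []
    current = poses
    for cycle in range(config.cycles):
        budget = config.cycle_budgets[cycle]
        minimized = []
        for pose in current:
            try:
                p, V, E = minimize_pose(structure, pose, cycles=budget,
                                        dielectric=config.dielectric)
            except FloatingPointError:      # divergence: drop with a record
                log.warning("pose %s discarded (diverged)", pose.origin)
                continue
            minimized.append((p, V, E))
        if cycle < config.cycles - 1:
            current = _dedup_poses([(p, V + E) for p, V, E in minimized],
                                   config.intermediate_rms)
            log.info("cycle %d: %d poses after clustering", cycle + 1,
                     len(current))

    sasa = SasaCalculator(n_points=config.sasa_points)
    protein_areas = sasa.compute(structure.coords(), structure.radii())
    spots: list[AnchoringSpot] = []
    for pose, V, E in minimized:
        bd = score_pose(structure, pose, V, E, params, sasa, protein_areas)
        if bd.dG <= config.report_threshold:
            spots.append(AnchoringSpot(pose=pose, energy=bd))
    spots.sort(key=_rank_key)
    for r, s in enumerate(spots, start=1):
        s.rank = r
    mean_spots = cluster_spots(spots, rms_min=config.rms_min)
    log.info("%d detailed spots, %d mean spots", len(spots),
             len(mean_spots))
    return MapResult(mean_spots=mean_spots, detailed_spots=spots,
                     seeds=seeds, n_scattered=n_scattered, config=config,
                     scoring=params)
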