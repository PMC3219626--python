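"""Empirical binding free-energy scoring of side-chain probes.

The score of a bound probe combines a size-normalized van der Waals term, a
dielectric-corrected electrostatic term and desolvation of both the probe
and the anchoring cavity:

    dG = V' + lambda_e * E' - lambda_s * (S_p + S_cav)

with

    V'       = V / N**alpha            (N = probe non-hydrogen atom count)
    E'       = E * eps / eps_eff
    eps_eff  = eps + (eps_max - eps) * fA_pol * p
    p        = min(1, C1 * exp(C2 * A))      C1 = 0.0024, C2 = 0.167

V and E are the raw Lennard-Jones and Coulomb interaction energies of the
minimized probe, the latter computed at the minimization dielectric
eps = 1.5. ``A`` is the solvent-exposed area of the bound probe, ``fA_pol``
the fraction of its polar area that remains accessible, and ``p`` the
probability that this area would be buried by a hypothetical protein
partner: a probe deeply buried in a surface pocket keeps eps_eff close to
eps, while a partially exposed probe feels higher dielectric shielding.
Desolvation terms are conventional sums of atomic solvation parameter times
buried area, so hydrophobic burial lowers dG and charged-group burial
penalizes it.

The weights alpha, lambda_e, lambda_s and eps_max are free parameters of
the model; the shipped defaults are package choices and can be refit from
(context, ddG) data via :func:`calibrate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

__all__ = ["ScoringParameters", "EnergyBreakdown", "vdw_corrected",
           "burial_probability", "effective_dielectric",
           "compose_breakdown", "solvation_terms", "score_pose",
           "calibrate", "CalibrationResult"]


@dataclass(frozen=True)
class ScoringParameters:
    alpha: float = 0.5        # vdW size-normalization exponent
    lambda_e: float = 0.5     # electrostatic weight
    lambda_s: float = 1.0     # desolvation weight
    eps: float = 1.5          # minimization dielectric
    eps_max: float = 20.0     # fully shielded dielectric
    c1: float = 0.0024        # burial-probability prefactor
    c2: float = 0.167         # burial-probability exponent, 1/A^2

    def __post_init__(self):
        if not (self.eps_max >= self.eps > 0):
            raise ValueError("require eps_max >= eps > 0")
        if self.lambda_e < 0 or self.lambda_s < 0:
            raise ValueError("lambda_e and lambda_s must be >= 0")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("C1 and C2 must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    """All terms of the score for one pose; dG is exactly recomputable."""

    V: float          # raw LJ, kcal/mol
    V_corr: float     # V / N^alpha
    E: float          # raw Coulomb at eps, kcal/mol
    E_corr: float     # E * eps / eps_eff
    S_p: float        # probe desolvation, kcal/mol
    S_cav: float      # cavity desolvation, kcal/mol
    A: float          # exposed area of the bound probe, A^2
    fA_pol: float     # accessible fraction of probe polar area, [0, 1]
    p: float          # interface-burial probability, [0, 1]
    eps_eff: float    # effective dielectric
    dG: float         # total, kcal/mol


def vdw_corrected(V: float, n_heavy: int, alpha: float) -> float:
    """Size-normalized vdW term V / N**alpha."""
    if n_heavy < 1:
        raise ValueError("probe must contain at least one heavy atom")
    return V / n_heavy ** alpha


def burial_probability(A: float, params: ScoringParameters) -> float:
    """p = min(1, C1 * exp(C2 * A)); monotone non-decreasing in A."""
    if A < 0:
        raise ValueError("exposed area must be non-negative")
    return min(1.0, params.c1 * math.exp(params.c2 * A))


def effective_dielectric(fA_pol: float, p: float,
                         params: ScoringParameters) -> float:
    """Interpolate eps_eff = eps + (eps_max - eps) * fA_pol * p."""
    if not (0.0 <= fA_pol <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError("fA_pol and p must lie in [0, 1]")
    return params.eps + (params.eps_max - params.eps) * fA_pol * p


def compose_breakdown(V: float, E: float, n_heavy: int, A: float,
                      fA_pol: float, S_p: float, S_cav: float,
                      params: ScoringParameters) -> EnergyBreakdown:
    """Pure arithmetic composition of all terms into a breakdown."""
    v_corr = vdw_corrected(V, n_heavy, params.alpha)
    p = burial_probability(A, params)
    eps_eff = effective_dielectric(fA_pol, p, params)
    e_corr = E * params.eps / eps_eff
    dg = v_corr + params.lambda_e * e_corr - params.lambda_s * (S_p + S_cav)
    return EnergyBreakdown(V=V, V_corr=v_corr, E=E, E_corr=e_corr,
                           S_p=S_p, S_cav=S_cav, A=A, fA_pol=fA_pol,
                           p=p, eps_eff=eps_eff, dG=dg)


def solvation_terms(structure, pose, sasa, protein_areas=None,
                    ) -> tuple[float, float, float, float]:
    """Desolvation terms and exposure descriptors for a bound pose.

    Returns ``(S_p, S_cav, A, fA_pol)``:

    * ``S_p``  -- sum over probe atoms of asp_i * (isolated - bound area)
    * ``S_cav`` -- same sum over the protein atoms whose area changes
    * ``A``    -- total exposed area of the bound probe
    * ``fA_pol`` -- bound polar area / isolated polar area of the probe

    ``sasa`` is a Shrake-Rupley engine with ``compute``/``compute_subset``;
    ``protein_areas`` may carry precomputed unbound per-atom areas of the
    protein to avoid recomputation across a map run.
    """
    pc = structure.coords()
    pr = structure.radii()
    iso = sasa.compute(pose.coords, pose.radii)
    # protein atoms close enough for their accessible area to change
    reach = pose.radii.max() + pr.max() + 2.0 * sasa.probe_radius
    near = (cdist(pc, pose.coords).min(axis=1) < reach).nonzero()[0]
    if protein_areas is None:
        unbound = sasa.compute_subset(pc, pr, near)
    else:
        unbound = np.asarray(protein_areas)[near]
    n_probe = len(pose.coords)
    all_coords = np.vstack([pose.coords, pc[near]])
    all_radii = np.concatenate([pose.radii, pr[near]])
    # occluders: the rest of the protein barely matters beyond `near`, but
    # include a second shell for correctness of the near atoms' areas
    shell = (cdist(pc, pose.coords).min(axis=1)
             < reach + 2 * pr.max() + 2 * sasa.probe_radius).nonzero()[0]
    extra = np.setdiff1d(shell, near, assume_unique=True)
    occl_coords = np.vstack([all_coords, pc[extra]])
    occl_radii = np.concatenate([all_radii, pr[extra]])
    bound = sasa.compute_subset(occl_coords, occl_radii,
                                np.arange(len(all_coords)))
    probe_bound = bound[:n_probe]
    prot_bound = bound[n_probe:]
    s_p = float(np.sum(pose.asps * (iso - probe_bound)))
    asp_near = structure.asp()[near]
    s_cav = float(np.sum(asp_near * (unbound - prot_bound)))
    A = float(probe_bound.sum())
    pol = pose.polar
    iso_pol = float(iso[pol].sum())
    fa_pol = float(probe_bound[pol].sum() / iso_pol) if iso_pol > 0 else 0.0
    fa_pol = min(max(fa_pol, 0.0), 1.0)
    return s_p, s_cav, A, fa_pol


def score_pose(structure, pose, raw_V: float, raw_E: float,
               params: ScoringParameters, sasa, protein_areas=None,
               ) -> EnergyBreakdown:
    """Full breakdown for a minimized pose given its raw V and E."""
    s_p, s_cav, A, fa_pol = solvation_terms(structure, pose, sasa,
                                            protein_areas)
    return compose_breakdown(raw_V, raw_E, pose.n_heavy, A, fa_pol,
                             s_p, s_cav, params)


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationResult:
    params: ScoringParameters
    residuals: np.ndarray
    correlation: float
    free: tuple[str, ...] = field(default_factory=tuple)


_FREE_BOUNDS = {"alpha": (0.01, 3.0), "lambda_e": (0.0, 10.0),
                "lambda_s": (0.0, 10.0), "eps_max": (1.5, 200.0)}


def _ctx_dg(ctx: Mapping[str, float], params: ScoringParameters) -> float:
    return compose_breakdown(ctx["V"], ctx["E"], int(ctx["n_heavy"]),
                             ctx["A"], ctx["fA_pol"], ctx["S_p"],
                             ctx["S_cav"], params).dG


def calibrate(training: Sequence[tuple[Mapping, Mapping, float]],
              free: tuple[str, ...] = ("alpha", "lambda_e", "lambda_s",
                                       "eps_max"),
              start: ScoringParameters | None = None) -> CalibrationResult:
    """Least-squares fit of the free score weights to target ddG data.

    Each training point is ``(context_mut, context_ref, target_ddg)`` where
    a context holds the raw quantities (V, E, n_heavy, A, fA_pol, S_p,
    S_cav) of one pose and the model prediction is
    ``dG(context_mut) - dG(context_ref)``.
    """
    if len(training) < len(free):
        raise ValueError(
            f"{len(training)} training points cannot constrain "
            f"{len(free)} free parameters")
    unknown = set(free) - set(_FREE_BOUNDS)
    if unknown:
        raise ValueError(f"not fittable: {sorted(unknown)}")
    p0 = start or ScoringParameters()

    def with_values(x: np.ndarray) -> ScoringParameters:
        return replace(p0, **dict(zip(free, x)))

    def resid(x: np.ndarray) -> np.ndarray:
        ps = with_values(x)
        return np.array([_ctx_dg(a, ps) - _ctx_dg(b, ps) - t
                         for a, b, t in training])

    x0 = np.array([getattr(p0, f) for f in free])
    lo = np.array([_FREE_BOUNDS[f][0] for f in free])
    hi = np.array([_FREE_BOUNDS[f][1] for f in free])
    sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    fitted = with_values(sol.x)
    pred = np.array([_ctx_dg(a, fitted) - _ctx_dg(b, fitted)
                     for a, b, _ in training])
    target = np.array([t for _, _, t in training])
    if np.std(pred) > 0 and np.std(target) > 0:
        corr = float(np.corrcoef(pred, target)[0, 1])
    else:
        corr = float("nan")
    return CalibrationResult(fitted, sol.fun, corr, tuple(free))
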