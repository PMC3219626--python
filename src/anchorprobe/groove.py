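"""Substrate-groove analysis: the -2/5 site, subsites, background and
basophilic/acidophilic classification.

Ser/Thr kinases bind substrate arginines N-terminal to the phosphoacceptor
(P0) at a conserved C-lobe surface region, the -2/5 site, which splits
into a -2 and a -5 subsite. Subsite centers are defined from the
crystallographic guanidino (CZ) positions of peptide arginines bound in
reference complexes, after superposing all structures over the CA atoms of
the residues lining the site (PKA numbering 128-136, 168-170, 201-204,
230, 234-236). A predicted anchoring spot is assigned to the subsite whose
center is nearest (ties go to -2; beyond the site radius it is "outside"),
and per-subsite best dG values are compared against a background
distribution pooled from full-surface maps of unrelated proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scoring import ScoringParameters
from .structure import ProteinStructure
from .surface import MapConfig, MeanAnchoringSpot, map_surface

__all__ = ["PKA_SITE_RESIDUE_NUMBERS", "SiteDefinition",
           "BackgroundDistribution", "PreferenceReport",
           "build_site_definition", "assign_subsite", "subsite_energies",
           "background_distribution", "background_percentile",
           "classify_basophilic"]

#: CA residues (PKA numbering) used for -2/5-site superposition
PKA_SITE_RESIDUE_NUMBERS = tuple(
    list(range(128, 137)) + list(range(168, 171)) + list(range(201, 205))
    + [230] + list(range(234, 237)))


@dataclass
class SiteDefinition:
    """The -2/5 site frame: superposition residues and subsite centers."""

    subsite_centers: dict            # {"-2": (3,), "-5": (3,)}
    superposition_residues: tuple = PKA_SITE_RESIDUE_NUMBERS
    reference_id: str = ""
    site_radius: float = 8.0         # A; farther spots are "outside"

    def __post_init__(self):
        self.subsite_centers = {k: np.asarray(v, float)
                                for k, v in self.subsite_centers.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "subsite_centers": {k: v.tolist()
                                for k, v in self.subsite_centers.items()},
            "superposition_residues": list(self.superposition_residues),
            "reference_id": self.reference_id,
            "site_radius": self.site_radius}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SiteDefinition":
        d = json.loads(Path(path).read_text())
        return cls(subsite_centers=d["subsite_centers"],
                   superposition_residues=tuple(
                       d.get("superposition_residues",
                             PKA_SITE_RESIDUE_NUMBERS)),
                   reference_id=d.get("reference_id", ""),
                   site_radius=float(d.get("site_radius", 8.0)))


def build_site_definition(reference_complexes, site_radius: float = 8.0,
                          reference_id: str = "") -> SiteDefinition:
    """Subsite centers from reference-bound Arg positions.

    ``reference_complexes`` is a list of ``(pose, subsite_label)`` pairs --
    crystallographic Arg side chains already superposed into a common
    frame, labelled "-2" or "-5". The -2 center averages the CZ positions
    of its references (three in the canonical construction); the -5 center
    likewise (a single reference canonically).
    """
    groups: dict[str, list[np.ndarray]] = {}
    for pose, label in reference_complexes:
        if label not in ("-2", "-5"):
            raise ValueError(f"subsite label must be -2 or -5, got {label}")
        if "CZ" not in pose.atom_names:
            raise ValueError("reference Arg pose lacks a CZ atom")
        groups.setdefault(label, []).append(
            pose.coords[pose.atom_names.index("CZ")])
    centers = {k: np.mean(v, axis=0) for k, v in groups.items()}
    return SiteDefinition(subsite_centers=centers, site_radius=site_radius,
                          reference_id=reference_id)


def assign_subsite(spot: MeanAnchoringSpot, site: SiteDefinition) -> str:
    """"-2", "-5" or "outside" by shortest distance to the subsite centers.

    Distances are measured from the spot's position proxy (CZ for Arg,
    terminal-group atom otherwise). An exact tie goes to -2.
    """
    pos = spot.pose.terminal_pos
    best_label, best_d = "outside", np.inf
    for label in ("-2", "-5"):         # fixed order makes ties go to -2
        if label not in site.subsite_centers:
            continue
        d = float(np.linalg.norm(pos - site.subsite_centers[label]))
        if d < best_d - 1e-12:
            best_label, best_d = label, d
    if best_d > site.site_radius:
        return "outside"
    return best_label


@dataclass
class PreferenceReport:
    """Per-subsite best dG, spot assignments and classification."""

    best_dg: dict                       # {"-2": float|None, "-5": ...}
    assignments: list = field(default_factory=list)  # (rank, subsite, dG)
    percentiles: dict = field(default_factory=dict)
    classification: str = "unclassified"


def subsite_energies(mean_spots: list[MeanAnchoringSpot],
                     site: SiteDefinition) -> PreferenceReport:
    """Best (lowest) dG per subsite among assigned spots; None if empty."""
    best: dict[str, float | None] = {"-2": None, "-5": None}
    rows = []
    for spot in mean_spots:
        label = assign_subsite(spot, site)
        rows.append((spot.rank, label, spot.dG))
        if label in best and (best[label] is None or spot.dG < best[label]):
            best[label] = spot.dG
    return PreferenceReport(best_dg=best, assignments=rows)


@dataclass
class BackgroundDistribution:
    """Pooled mean-spot dG samples from full-surface maps of a decoy set."""

    samples: np.ndarray
    source_ids: tuple = ()

    def __post_init__(self):
        self.samples = np.sort(np.asarray(self.samples, float))
        if self.samples.size == 0:
            raise ValueError("background distribution is empty")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# dG_kcal_mol\tsource"]
        srcs = (self.source_ids if len(self.source_ids) == len(self.samples)
                else [""] * len(self.samples))
        for s, src in zip(self.samples, srcs):
            lines.append(f"{s:.4f}\t{src}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BackgroundDistribution":
        samples, srcs = [], []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            samples.append(float(parts[0]))
            srcs.append(parts[1] if len(parts) > 1 else "")
        return cls(np.array(samples), tuple(srcs))


def background_distribution(structures: list[ProteinStructure],
                            probe: str = "ARG",
                            params: ScoringParameters | None = None,
                            config: MapConfig | None = None,
                            ) -> BackgroundDistribution:
    """Pool mean-spot dG values over the surfaces of a background set."""
    if not structures:
        raise ValueError("background set is empty")
    samples, srcs = [], []
    for s in structures:
        result = map_surface(s, params=params, config=config,
                             aa_type=probe)
        for spot in result.mean_spots:
            samples.append(spot.dG)
            srcs.append(s.source_id)
    return BackgroundDistribution(np.array(samples), tuple(srcs))


def background_percentile(dg: float,
                          distribution: BackgroundDistribution) -> float:
    """Lower-tail fraction of background samples at or below ``dg``."""
    return float(np.searchsorted(distribution.samples, dg, side="right")
                 / distribution.samples.size)


def classify_basophilic(structure: ProteinStructure,
                        region_points: np.ndarray,
                        params: ScoringParameters | None = None,
                        config: MapConfig | None = None,
                        margin: float = 1.5,
                        region_radius: float = 10.0,
                        maps: dict | None = None) -> tuple[str, dict]:
    """Compare Arg vs Glu maps near the substrate-binding region.

    ``region_points`` trace the superposed reference-peptide backbone
    (P-3..P+3); a spot counts if its position proxy lies within
    ``region_radius`` (default 10 A) of any of them. "basophilic" when the
    best Arg dG beats the best Glu dG by at least ``margin`` kcal/mol,
    "acidophilic" for the converse, else "neither".
    """
    region_points = np.atleast_2d(np.asarray(region_points, float))
    best: dict[str, float | None] = {}
    for probe in ("ARG", "GLU"):
        if maps is not None and probe in maps:
            result = maps[probe]
        else:
            result = map_surface(structure, params=params, config=config,
                                 aa_type=probe)
        near = [s.dG for s in result.mean_spots
                if np.linalg.norm(s.pose.terminal_pos - region_points,
                                  axis=1).min() <= region_radius]
        best[probe] = min(near) if near else None
    arg, glu = best["ARG"], best["GLU"]
    if arg is None and glu is None:
        label = "neither"
    elif glu is None:
        label = "basophilic" if arg <= -abs(margin) else "neither"
    elif arg is None:
        label = "acidophilic" if glu <= -abs(margin) else "neither"
    elif arg <= glu - margin:
        label = "basophilic"
    elif glu <= arg - margin:
        label = "acidophilic"
    else:
        label = "neither"
    return label, {"best_arg_dg": arg, "best_glu_dg": glu}
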