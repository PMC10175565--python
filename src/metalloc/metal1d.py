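"""Geometric zinc-location prediction from a coordination probability map.

The predictor scores every potentially coordinating residue by how
compatible its neighborhood is with the environments in the probability
map, clusters the high scorers, places a candidate metal at the
score-weighted average of the cluster's reference points, and finally
rescores each candidate site from its own surroundings to discard
implausible placements.

A residue's *reference point* approximates where a bound metal would
sit relative to it: the donor atom for single-donor residues, the donor
midpoint for residues with two equivalent donors (in which case the
search radius is enlarged by the midpoint-to-donor distance).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .pdbio import MissingAtomError, ProteinStructure, Residue, THREE_TO_ONE
from .probmap import ProbabilityMap
from .sites import PredictedSite

__all__ = [
    "Metal1DConfig",
    "ReferencePoint",
    "ResidueScore",
    "REFERENCE_ATOMS",
    "reference_point",
    "compatibility_score",
    "score_residues",
    "cluster_and_place",
    "score_sites",
    "predict",
]

logger = logging.getLogger(__name__)

#: Donor atoms defining each residue's reference point.  Two entries
#: mean the reference point is the donor midpoint and the search radius
#: is enlarged by the midpoint-donor distance.
REFERENCE_ATOMS: dict[str, tuple[str, ...]] = {
    "CYS": ("SG",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
    "LYS": ("NZ",),
}


@dataclass
class Metal1DConfig:
    """Tunable parameters of the geometric predictor.

    ``search_radius`` is roughly twice the typical metal-donor distance
    (2.2 +/- 0.2 A from LINK records); candidate sites are rescored
    within ``site_radius_fraction`` of it, and high scorers closer than
    ``cluster_distance`` (default twice the search radius) are grouped
    into one site.
    """

    search_radius: float = 5.5
    threshold_t: float = 0.5
    site_radius_fraction: float = 0.6
    cluster_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.search_radius <= 0:
            raise ValueError("search_radius must be positive")
        if not 0.0 < self.threshold_t <= 1.0:
            raise ValueError("threshold_t must be in (0, 1]")
        if not 0.0 < self.site_radius_fraction <= 1.0:
            raise ValueError("site_radius_fraction must be in (0, 1]")
        if self.cluster_distance is None:
            self.cluster_distance = 2.0 * self.search_radius

    @property
    def site_radius(self) -> float:
        return self.site_radius_fraction * self.search_radius


@dataclass
class ReferencePoint:
    residue_key: tuple[str, int, str]
    position: np.ndarray
    radius_increment: float
    letter: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.radius_increment < 0:
            raise ValueError("radius increment must be >= 0")


@dataclass
class ResidueScore:
    residue_key: tuple[str, int, str]
    score: float
    reference: ReferencePoint


def reference_point(residue: Residue) -> ReferencePoint:
    """Reference point of a supported coordinating residue.

    Raises :class:`MissingAtomError` for unsupported residue types or
    residues missing their donor atoms.
    """
    parent = residue.standard_parent
    if parent is None or parent not in REFERENCE_ATOMS:
        raise MissingAtomError(
            f"{residue.residue_name} {residue.key} has no coordinating side chain")
    donor_names = REFERENCE_ATOMS[parent]
    donors = [residue.get_atom(name).position for name in donor_names]
    if len(donors) == 1:
        position = donors[0]
        increment = 0.0
    else:
        position = (donors[0] + donors[1]) / 2.0
        increment = float(np.linalg.norm(position - donors[0]))
    return ReferencePoint(
        residue_key=residue.key,
        position=position,
        radius_increment=increment,
        letter=THREE_TO_ONE[parent],
    )


def compatibility_score(observed: Iterable[str], pmap: ProbabilityMap) -> float:
    """Sum of map probabilities over environments compatible with ``observed``.

    An environment is compatible when it is a sub-multiset of the
    observed letters; a residue surrounded by every environment in the
    map therefore scores exactly 1.
    """
    obs = Counter(l.upper() for l in observed)
    total = 0.0
    for env, entry in pmap.entries.items():
        env_counts = Counter(env)
        if all(obs[l] >= c for l, c in env_counts.items()):
            total += entry.probability
    return total


def _reference_points(structure: ProteinStructure) -> list[ReferencePoint]:
    points = []
    for residue in structure.amino_residues():
        if (residue.standard_parent or "") not in REFERENCE_ATOMS:
            continue
        try:
            points.append(reference_point(residue))
        except MissingAtomError as exc:
            logger.info("skipping residue: %s", exc)
    return points


def score_residues(structure: ProteinStructure, pmap: ProbabilityMap,
                   config: Metal1DConfig | None = None) -> list[ResidueScore]:
    """Score every supported residue against the probability map.

    The observed multiset for residue *r* is its own letter plus the
    letters of all other reference points within
    ``search_radius + increment_r``.
    """
    config = config or Metal1DConfig()
    points = _reference_points(structure)
    if not points:
        warnings.warn(f"{structure.id}: no supported coordinating residues")
        return []
    positions = np.array([p.position for p in points])
    dists = cdist(positions, positions)
    scores = []
    for i, point in enumerate(points):
        radius = config.search_radius + point.radius_increment
        neighbor_idx = [j for j in range(len(points))
                        if j != i and dists[i, j] <= radius]
        observed = [point.letter] + [points[j].letter for j in neighbor_idx]
        scores.append(ResidueScore(
            residue_key=point.residue_key,
            score=compatibility_score(observed, pmap),
            reference=point,
        ))
    return scores


def _weighted_site(points: Sequence[np.ndarray], weights: Sequence[float],
                   members: list[tuple[str, int, str]]) -> PredictedSite:
    w = np.asarray(weights, dtype=float)
    pts = np.asarray(points, dtype=float)
    position = (w[:, None] * pts).sum(axis=0) / w.sum()
    return PredictedSite(position=position, score=float(w.max()),
                         member_residues=members)


def cluster_and_place(scores: list[ResidueScore],
                      config: Metal1DConfig | None = None) -> list[PredictedSite]:
    """Group high-scoring residues and place one candidate site per group.

    High scorers are residues scoring at least ``threshold_t`` times the
    maximum; groups are connected components of the closer-than-
    ``cluster_distance`` graph; the site is the score-weighted average
    of the group's reference points.  An isolated high scorer borrows
    its own score for the nearest other reference point, which places
    the site at their midpoint.
    """
    config = config or Metal1DConfig()
    max_score = max((s.score for s in scores), default=0.0)
    if max_score <= 0.0:
        return []
    high = [s for s in scores if s.score >= config.threshold_t * max_score
            and s.score > 0.0]
    positions = np.array([s.reference.position for s in high])
    n = len(high)
    dists = cdist(positions, positions)
    adjacency = csr_matrix((dists < config.cluster_distance) & ~np.eye(n, dtype=bool))
    n_comp, labels = connected_components(adjacency, directed=False)

    all_points = [s.reference for s in scores]
    sites = []
    for comp in range(n_comp):
        members = [high[i] for i in range(n) if labels[i] == comp]
        if len(members) == 1:
            lone = members[0]
            others = [p for p in all_points if p.residue_key != lone.residue_key]
            if others:
                nearest = min(
                    others,
                    key=lambda p: (float(np.linalg.norm(p.position -
                                                        lone.reference.position)),
                                   p.residue_key),
                )
                # fictitious copy of the lone score -> midpoint placement
                sites.append(_weighted_site(
                    [lone.reference.position, nearest.position],
                    [lone.score, lone.score],
                    [lone.residue_key, nearest.residue_key],
                ))
                continue
            sites.append(PredictedSite(position=lone.reference.position.copy(),
                                       score=lone.score,
                                       member_residues=[lone.residue_key]))
            continue
        sites.append(_weighted_site(
            [m.reference.position for m in members],
            [m.score for m in members],
            [m.residue_key for m in members],
        ))
    return sites


def score_sites(sites: list[PredictedSite], structure: ProteinStructure,
                pmap: ProbabilityMap,
                config: Metal1DConfig | None = None) -> list[PredictedSite]:
    """Rescore candidate sites from their surroundings and filter.

    Each site's final score is the compatibility of the residues whose
    reference points fall within 60% of the search radius (enlarged by
    each residue's own increment); sites below ``threshold_t`` times the
    best final score are discarded.  This removes candidates stranded in
    empty space by the weighted averaging.
    """
    config = config or Metal1DConfig()
    if not sites:
        return []
    points = _reference_points(structure)
    rescored = []
    for site in sites:
        observed = []
        members = []
        for point in points:
            radius = config.site_radius + point.radius_increment
            if np.linalg.norm(point.position - site.position) <= radius:
                observed.append(point.letter)
                members.append(point.residue_key)
        final = compatibility_score(observed, pmap) if observed else 0.0
        rescored.append(PredictedSite(position=site.position, score=final,
                                      member_residues=members or site.member_residues))
    max_final = max(s.score for s in rescored)
    if max_final <= 0.0:
        return []
    return [s for s in rescored if s.score >= config.threshold_t * max_final]


def predict(structure: ProteinStructure, pmap: ProbabilityMap,
            config: Metal1DConfig | None = None) -> list[PredictedSite]:
    """Full geometric prediction: score, cluster, place, rescore, sort."""
    config = config or Metal1DConfig()
    scores = score_residues(structure, pmap, config)
    if not scores:
        return []
    sites = cluster_and_place(scores, config)
    sites = score_sites(sites, structure, pmap, config)
    return sorted(sites, key=lambda s: (-s.score, tuple(s.position)))
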