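"""Coordination-environment probability maps mined from LINK records.

Every zinc ion that LINK records connect to two or more distinct amino
acids defines a coordination environment: the multiset of the residues'
one-letter codes, written in alphabetical order so that e.g. CCH and CHC
are the same environment.  Counting environments over a corpus and
normalizing yields the probability map that drives the geometric
predictor.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .pdbio import (
    ProteinStructure,
    THREE_TO_ONE,
    WATER_NAMES,
    PARENT_RESIDUE,
)

__all__ = [
    "CoordinationEnvironment",
    "MapEntry",
    "ProbabilityMap",
    "LinkDistanceStats",
    "EmptyMapError",
    "canonical_environment",
    "extract_environments",
    "build_probability_map",
    "link_distance_stats",
    "save_map",
    "load_map",
]


class EmptyMapError(ValueError):
    """Raised when no coordination environments could be mined."""


def canonical_environment(letters: Iterable[str]) -> str:
    """Canonical environment code: one-letter codes sorted ascending."""
    letters = [l.upper() for l in letters]
    bad = [l for l in letters if l not in THREE_TO_ONE.values()]
    if bad:
        raise ValueError(f"invalid one-letter codes: {bad}")
    return "".join(sorted(letters))


#: An environment is just its canonical code string (e.g. "CCHH").
CoordinationEnvironment = str


@dataclass
class MapEntry:
    count: int
    probability: float
    n_structures: int


@dataclass
class ProbabilityMap:
    entries: dict[str, MapEntry] = field(default_factory=dict)
    total_count: int = 0
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.entries:
            total_p = sum(e.probability for e in self.entries.values())
            if abs(total_p - 1.0) > 1e-9:
                raise ValueError(f"probabilities sum to {total_p}, not 1")

    def probability(self, code: str) -> float:
        entry = self.entries.get(code)
        return entry.probability if entry is not None else 0.0

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LinkDistanceStats:
    mean: float
    std: float
    n: int


def _residue_letter(residue_name: str) -> Optional[str]:
    """One-letter code for a linked residue; modified residues map to
    their standard parent, anything else is None."""
    name = residue_name.upper()
    if name in PARENT_RESIDUE:
        name = PARENT_RESIDUE[name]
    return THREE_TO_ONE.get(name)


def _zinc_link_groups(structure: ProteinStructure, metal: str = "ZN",
                      collect_distances: bool = False):
    """Group retained LINK records by metal instance.

    Returns ``{metal_residue_key: {partner_residue_key: (letter, [distances])}}``.
    Applies the mining exclusions: water partners dropped, unresolvable
    partners skipped with a warning, non-amino partners without a
    standard parent skipped with a warning.
    """
    metal = metal.upper()
    groups: dict[tuple, dict[tuple, tuple[str, list[float]]]] = {}
    for link in structure.links:
        p1, p2 = link.partners()
        if p1.residue_name.upper() == metal:
            metal_p, other = p1, p2
        elif p2.residue_name.upper() == metal:
            metal_p, other = p2, p1
        else:
            continue
        if other.residue_name.upper() in WATER_NAMES:
            continue  # water links excluded
        metal_atom = structure.resolve_link_partner(metal_p)
        other_atom = structure.resolve_link_partner(other)
        if metal_atom is None or other_atom is None:
            warnings.warn(
                f"{structure.id}: unresolvable LINK partner "
                f"{other.residue_name} {other.chain_id}{other.residue_seq}; record skipped")
            continue
        letter = _residue_letter(other.residue_name)
        if letter is None:
            warnings.warn(
                f"{structure.id}: linked residue {other.residue_name} has no "
                f"standard parent; record skipped")
            continue
        metal_key = (metal_p.chain_id, metal_p.residue_seq, metal_p.insertion_code)
        res_key = (other.chain_id, other.residue_seq, other.insertion_code)
        per_metal = groups.setdefault(metal_key, {})
        dist = float(np.linalg.norm(metal_atom.position - other_atom.position))
        if res_key in per_metal:
            per_metal[res_key][1].append(dist)
        else:
            per_metal[res_key] = (letter, [dist])
    return groups


def extract_environments(structure: ProteinStructure, metal: str = "ZN") -> list[str]:
    """Coordination environments of every zinc in a structure.

    One letter per distinct amino-acid residue linked to the zinc
    (bidentate carboxylates count once); water links are dropped; zincs
    left with fewer than 2 distinct amino-acid partners (weak sites)
    emit nothing.
    """
    groups = _zinc_link_groups(structure, metal)
    envs = []
    for per_metal in groups.values():
        letters = [letter for letter, _ in per_metal.values()]
        if len(letters) >= 2:
            envs.append(canonical_environment(letters))
    return envs


def build_probability_map(structures: Iterable[ProteinStructure],
                          metal: str = "ZN") -> ProbabilityMap:
    """Aggregate environment counts over a corpus into a normalized map."""
    counts: Counter[str] = Counter()
    per_env_structures: dict[str, set[str]] = {}
    source_ids: list[str] = []
    for structure in structures:
        source_ids.append(structure.id)
        for env in extract_environments(structure, metal):
            counts[env] += 1
            per_env_structures.setdefault(env, set()).add(structure.id)
    if not counts:
        raise EmptyMapError("no coordination environments found in corpus")
    total = sum(counts.values())
    entries = {
        env: MapEntry(count=c, probability=c / total,
                      n_structures=len(per_env_structures[env]))
        for env, c in sorted(counts.items())
    }
    return ProbabilityMap(entries=entries, total_count=total, source_ids=source_ids)


def link_distance_stats(structures: Iterable[ProteinStructure],
                        metal: str = "ZN") -> LinkDistanceStats:
    """Metal-donor distance statistics over retained links.

    Distances are recomputed from coordinates (the optional LINK
    distance column is ignored) over exactly the links that survive the
    environment-mining exclusions.  The spread is the population
    standard deviation.
    """
    distances: list[float] = []
    for structure in structures:
        groups = _zinc_link_groups(structure, metal, collect_distances=True)
        for per_metal in groups.values():
            if len(per_metal) < 2:
                continue  # same retention rule as extract_environments
            for _, dists in per_metal.values():
                distances.extend(dists)
    if not distances:
        raise EmptyMapError("no retained metal-amino-acid links")
    arr = np.asarray(distances)
    return LinkDistanceStats(mean=float(arr.mean()),
                             std=float(arr.std(ddof=0)),
                             n=len(arr))


def save_map(pmap: ProbabilityMap, path: str | Path) -> None:
    """Write a map as TSV (environment, count, probability, n_structures)
    with a JSON provenance sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        [(env, e.count, e.probability, e.n_structures)
         for env, e in pmap.entries.items()],
        columns=["environment", "count", "probability", "n_structures"],
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "total_count": pmap.total_count,
        "source_ids": pmap.source_ids,
    }, indent=1))


def load_map(path: str | Path) -> ProbabilityMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"environment": str})
    entries = {
        str(env): MapEntry(int(cnt), float(prob), int(n_st))
        for env, cnt, prob, n_st in zip(df["environment"], df["count"],
                                        df["probability"], df["n_structures"])
    }
    if not entries:
        raise EmptyMapError(f"{path}: empty probability map")
    sidecar = path.with_suffix(path.suffix + ".json")
    total = int(df["count"].sum())
    source_ids: list[str] = []
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        total = int(meta.get("total_count", total))
        source_ids = list(meta.get("source_ids", []))
    return ProbabilityMap(entries=entries, total_count=total, source_ids=source_ids)
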