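"""Predicted metal sites and their PDB/TSV serialization.

A predicted site is a 3-D position with a confidence score — a
probability-map compatibility score for the geometric predictor, or the
cluster's maximum voxel probability for the density predictor.  Sites
are written as zinc HETATM records with the score in the B-factor
column so any molecular viewer can display them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PredictedSite", "write_sites_pdb", "read_sites_pdb", "write_sites_tsv"]


@dataclass
class PredictedSite:
    position: np.ndarray
    score: float
    member_residues: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("site position must be a finite 3-vector")
        if self.score < 0:
            raise ValueError(f"site score {self.score} is negative")


def write_sites_pdb(sites: list[PredictedSite], path: str | Path,
                    element: str = "ZN") -> None:
    """HETATM record per site, score in the B-factor column."""
    lines = []
    for i, site in enumerate(sites, start=1):
        x, y, z = site.position
        lines.append(
            f"HETATM{i:5d} {element:>2s}   {element:>3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{site.score:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sites_pdb(path: str | Path) -> list[PredictedSite]:
    """Read sites back from a HETATM file (score from the B-factor column)."""
    sites = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(("HETATM", "ATOM  ")):
            pos = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            score = float(line[60:66]) if line[60:66].strip() else 0.0
            sites.append(PredictedSite(position=np.array(pos), score=score))
    return sites


def write_sites_tsv(sites: list[PredictedSite], path: str | Path) -> None:
    rows = []
    for rank, site in enumerate(sites, start=1):
        members = ";".join(f"{c}{s}{i}" for c, s, i in site.member_residues)
        rows.append((rank, *np.round(site.position, 4), round(site.score, 6), members))
    pd.DataFrame(rows, columns=["rank", "x", "y", "z", "score", "member_residues"]) \
        .to_csv(path, sep="\t", index=False)
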