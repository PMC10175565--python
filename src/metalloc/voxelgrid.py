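"""Voxelization of residue environments and density post-processing.

Residue-centered 16 A boxes at 0.5 A resolution are painted into eight
boolean-masked channels (aromatic, hydrophobic, positive ionizable,
negative ionizable, h-bond donor, h-bond acceptor, occupancy, metal
chain) using an atom-centered pair-correlation function

    v(d) = 1 - exp(-(r_vdw / d)^12),   v(0) = 1,

combined across atoms with a per-voxel maximum so values stay in [0,1].
Per-residue probability boxes predicted by the network are averaged on
a global bounding-box grid, and ions are placed at probability-weighted
centroids of agglomerative clusters of high-probability voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import AgglomerativeClustering

from .pdbio import Atom, MetalSite, MissingAtomError, ProteinStructure, Residue, WATER_NAMES
from .sites import PredictedSite

__all__ = [
    "CHANNELS",
    "VDW_RADII",
    "VoxelGrid",
    "DensityMap",
    "PostConfig",
    "assign_channels",
    "voxelize_environment",
    "voxelize_target",
    "sample_training_residues",
    "predict_density",
    "place_ions",
    "write_cube",
    "read_cube",
    "save_environments",
    "load_environments",
]

#: Fixed channel order of the input tensor.
CHANNELS = (
    "aromatic",
    "hydrophobic",
    "positive_ionizable",
    "negative_ionizable",
    "hbond_donor",
    "hbond_acceptor",
    "occupancy",
    "metal_chain",
)

#: Van der Waals radii (A) used by the pair-correlation function.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90,
             "P": 1.80, "ZN": 1.39}
_DEFAULT_VDW = 1.70

_METAL_CHANNEL_ELEMENTS = frozenset({
    "ZN", "FE", "CU", "MN", "CO", "NI", "MG", "CA", "NA", "K", "CD", "HG",
})

_AROMATIC = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
# carbons bonded only to carbon/hydrogen
_HYDROPHOBIC = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG"},
    "ASN": {"CB"},
    "ASP": {"CB"},
    "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "HIS": {"CB"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD"},
    "MET": {"CB"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG"},
    "THR": {"CG2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "VAL": {"CB", "CG1", "CG2"},
}
_POSITIVE = {"LYS": {"NZ"}, "ARG": {"NE", "CZ", "NH1", "NH2"}}
_NEGATIVE = {"ASP": {"OD1", "OD2", "CG"}, "GLU": {"OE1", "OE2", "CD"}}
_DONOR_SIDECHAIN = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "HIS": {"ND1", "NE2"}, "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"},
}
_ACCEPTOR_SIDECHAIN = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_KNOWN_SIDECHAIN_ATOMS: dict[str, set[str]] = {}
for table in (_AROMATIC, _HYDROPHOBIC, _POSITIVE, _NEGATIVE,
              _DONOR_SIDECHAIN, _ACCEPTOR_SIDECHAIN):
    for resname, names in table.items():
        _KNOWN_SIDECHAIN_ATOMS.setdefault(resname, set()).update(names)
# remaining plain side-chain atoms that carry no pharmacophore flag
for resname, names in {
    "CYS": {"CB"}, "SER": {"CB"}, "MET": {"CG", "CE", "SD"},
    "LYS": {"CE"}, "ARG": {"CD"}, "ASN": {"CG"}, "GLN": {"CD"},
    "THR": {"CB"}, "TRP": {"CD1", "NE1", "CE2"}, "GLY": set(),
}.items():
    _KNOWN_SIDECHAIN_ATOMS.setdefault(resname, set()).update(names)


def assign_channels(atom: Atom) -> np.ndarray:
    """Boolean channel vector of one heavy atom (order of :data:`CHANNELS`)."""
    flags = np.zeros(len(CHANNELS), dtype=bool)
    name = atom.name
    res = atom.residue_name.upper()
    element = atom.element.upper()
    if atom.is_hetero and element in _METAL_CHANNEL_ELEMENTS and res not in WATER_NAMES:
        flags[CHANNELS.index("metal_chain")] = True
        flags[CHANNELS.index("occupancy")] = True
        return flags
    flags[CHANNELS.index("occupancy")] = True
    known = (name in _BACKBONE) or (name in _KNOWN_SIDECHAIN_ATOMS.get(res, set()))
    if not known:
        warnings.warn(f"untyped atom {res}.{name}; occupancy channel only")
        return flags
    flags[0] = name in _AROMATIC.get(res, set())
    flags[1] = name in _HYDROPHOBIC.get(res, set())
    flags[2] = name in _POSITIVE.get(res, set())
    flags[3] = name in _NEGATIVE.get(res, set())
    flags[4] = (name == "N") or name in _DONOR_SIDECHAIN.get(res, set())
    flags[5] = (name in {"O", "OXT"}) or name in _ACCEPTOR_SIDECHAIN.get(res, set())
    return flags


@dataclass
class VoxelGrid:
    """Regular cubic grid; ``origin`` is the center of voxel (0,0,0)."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # (channels, n, n, n)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 4 or len(set(self.values.shape[1:])) != 1:
            raise ValueError("values must be (channels, n, n, n)")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def voxel_centers(self) -> np.ndarray:
        """(n^3, 3) array of voxel center coordinates (C-order)."""
        idx = np.indices((self.n,) * 3).reshape(3, -1).T
        return self.origin + idx * self.spacing


@dataclass
class DensityMap:
    origin: np.ndarray
    spacing: float
    values: np.ndarray  # (nx, ny, nz)
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D")
        if self.counts is None:
            self.counts = np.zeros(self.values.shape, dtype=int)

    def voxel_centers(self) -> np.ndarray:
        idx = np.indices(self.values.shape).reshape(3, -1).T
        return self.origin + idx * self.spacing


@dataclass
class PostConfig:
    """Density post-processing parameters.

    ``residue_selection`` are the residues voxelized at inference (the
    vast majority of zinc sites have at least one nearby);
    ``merge_radius`` is the KD-search radius of the grid averaging;
    voxels above ``cluster_probability_threshold`` are clustered with
    ``cluster_distance_threshold`` agglomerative linkage.
    """

    residue_selection: tuple[str, ...] = ("CYS", "HIS", "ASP", "GLU")
    merge_radius: float = 0.25
    cluster_probability_threshold: float = 0.15
    cluster_distance_threshold: float = 7.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_probability_threshold < 1.0:
            raise ValueError("cluster_probability_threshold must be in (0,1)")
        if self.merge_radius <= 0 or self.cluster_distance_threshold <= 0:
            raise ValueError("distances must be positive")


def pair_correlation(distance: np.ndarray | float, r_vdw: float) -> np.ndarray:
    """Occupancy value of an atom at ``distance`` from a voxel center."""
    d = np.asarray(distance, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, r_vdw / np.maximum(d, 1e-300), np.inf)
        v = 1.0 - np.exp(-np.minimum(ratio ** 12, 700.0))
    return np.where(d <= 0, 1.0, np.clip(v, 0.0, 1.0))


def _paint_max(values: np.ndarray, origin: np.ndarray, spacing: float,
               position: np.ndarray, r_vdw: float, reach_factor: float = 2.5) -> None:
    """In-place channel update: per-voxel max with one atom's contribution."""
    n = np.array(values.shape)
    reach = reach_factor * r_vdw
    lo = np.maximum(np.ceil((position - origin - reach) / spacing).astype(int), 0)
    hi = np.minimum(np.floor((position - origin + reach) / spacing).astype(int), n - 1)
    if np.any(lo > hi):
        return
    axes = [origin[k] + spacing * np.arange(lo[k], hi[k] + 1) for k in range(3)]
    dx2 = (axes[0] - position[0]) ** 2
    dy2 = (axes[1] - position[1]) ** 2
    dz2 = (axes[2] - position[2]) ** 2
    d = np.sqrt(dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :])
    block = values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    np.maximum(block, pair_correlation(d, r_vdw), out=block)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _grid_frame(center: np.ndarray, box: float, spacing: float):
    n = int(round(box / spacing))
    origin = center - (n - 1) / 2.0 * spacing
    return origin, n


def voxelize_environment(structure: ProteinStructure, center_residue: Residue,
                         box: float = 16.0, spacing: float = 0.5,
                         rotation_rng: Optional[np.random.Generator] = None,
                         ) -> VoxelGrid:
    """8-channel voxel grid of the environment around a residue's C-alpha.

    The box center falls midway between the two central voxels on each
    axis; an optional uniform random rotation about the center is
    applied to the atoms before painting.  Hydrogens and waters are
    excluded.
    """
    try:
        center = center_residue.get_atom("CA").position
    except MissingAtomError:
        raise MissingAtomError(
            f"{center_residue.residue_name} {center_residue.key} has no CA atom")
    origin, n = _grid_frame(center, box, spacing)
    values = np.zeros((len(CHANNELS), n, n, n))
    rotation = _random_rotation(rotation_rng) if rotation_rng is not None else None
    reach = 2.5 * max(VDW_RADII.values())
    for atom in structure.heavy_atoms():
        if atom.residue_name.upper() in WATER_NAMES:
            continue
        pos = atom.position
        if rotation is not None:
            pos = center + rotation @ (pos - center)
        if np.any(pos < origin - reach) or np.any(pos > origin + (n - 1) * spacing + reach):
            continue
        flags = assign_channels(atom)
        r_vdw = VDW_RADII.get(atom.element.upper(), _DEFAULT_VDW)
        for c in np.flatnonzero(flags):
            _paint_max(values[c], origin, spacing, pos, r_vdw)
    return VoxelGrid(origin=origin, spacing=spacing, values=values)


def voxelize_target(metal_positions: Sequence[np.ndarray] | np.ndarray,
                    frame: VoxelGrid | tuple[np.ndarray, float, int],
                    threshold: float = 0.05) -> VoxelGrid:
    """Binary 1-channel target grid of metal locations.

    The metal density is painted with the same pair-correlation function
    (zinc van der Waals radius) and binarized above ``threshold``.
    """
    if isinstance(frame, VoxelGrid):
        origin, spacing, n = frame.origin, frame.spacing, frame.n
    else:
        origin, spacing, n = frame
    values = np.zeros((1, n, n, n))
    for pos in np.atleast_2d(np.asarray(metal_positions, dtype=float).reshape(-1, 3)):
        _paint_max(values[0], origin, spacing, pos, VDW_RADII["ZN"])
    values = (values > threshold).astype(float)
    return VoxelGrid(origin=origin, spacing=spacing, values=values)


def sample_training_residues(structure: ProteinStructure,
                             zinc_sites: Sequence[MetalSite],
                             seed: int | np.random.Generator = 0,
                             cutoff: float = 12.0,
                             ) -> list[tuple[Residue, int]]:
    """Balanced (residue, label) sample for training.

    Positives are residues whose C-alpha lies within ``cutoff`` of any
    zinc; negatives are an equal-sized seeded random draw from the rest
    (all of them if fewer).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    metal_pos = np.array([s.position for s in zinc_sites]).reshape(-1, 3)
    positives, others = [], []
    for res in structure.amino_residues():
        if not res.has_atom("CA"):
            continue
        ca = res.get_atom("CA").position
        if len(metal_pos) and np.min(np.linalg.norm(metal_pos - ca, axis=1)) <= cutoff:
            positives.append(res)
        else:
            others.append(res)
    n_neg = min(len(positives), len(others))
    neg_idx = rng.choice(len(others), size=n_neg, replace=False) if n_neg else []
    sample = [(r, 1) for r in positives]
    sample.extend((others[int(i)], 0) for i in sorted(neg_idx))
    return sample


Predictor = Callable[[VoxelGrid], np.ndarray]


def predict_density(predictor: Predictor, structure: ProteinStructure,
                    post: PostConfig | None = None,
                    box: float = 16.0, spacing: float = 0.5) -> DensityMap:
    """Whole-protein probability density by per-residue prediction.

    Each selected residue's environment is voxelized (no rotation at
    inference), run through ``predictor`` (any callable mapping a
    :class:`VoxelGrid` to an (n,n,n) probability array), and the boxes
    are averaged on a global bounding-box grid: every global voxel takes
    the mean of predicted values within ``merge_radius`` of it.
    """
    post = post or PostConfig()
    selected = [r for r in structure.amino_residues()
                if (r.standard_parent or "") in post.residue_selection
                and r.has_atom("CA")]
    if not selected:
        raise ValueError(
            f"{structure.id}: no residues of {post.residue_selection} to voxelize")

    boxes = []
    for res in selected:
        grid = voxelize_environment(structure, res, box=box, spacing=spacing)
        probs = np.asarray(predictor(grid), dtype=float)
        probs = probs.reshape(grid.n, grid.n, grid.n)
        boxes.append((grid, probs))

    mins = np.min([g.origin for g, _ in boxes], axis=0)
    maxs = np.max([g.origin + (g.n - 1) * g.spacing for g, _ in boxes], axis=0)
    shape = np.floor((maxs - mins) / spacing).astype(int) + 1
    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)

    snap_exact = post.merge_radius <= spacing / 2.0 + 1e-12
    if snap_exact:
        for grid, probs in boxes:
            centers = grid.voxel_centers()
            rel = (centers - mins) / spacing
            idx = np.rint(rel).astype(int)
            dist = np.linalg.norm((rel - idx) * spacing, axis=1)
            ok = (dist <= post.merge_radius) & np.all(idx >= 0, axis=1) \
                & np.all(idx < shape, axis=1)
            flat = np.ravel_multi_index(idx[ok].T, tuple(shape))
            np.add.at(sums.ravel(), flat, probs.ravel()[ok])
            np.add.at(counts.ravel(), flat, 1)
    else:
        pts = np.concatenate([g.voxel_centers() for g, _ in boxes])
        vals = np.concatenate([p.ravel() for _, p in boxes])
        tree = cKDTree(pts)
        grid_idx = np.indices(tuple(shape)).reshape(3, -1).T
        grid_pts = mins + grid_idx * spacing
        for flat_i, neighbors in enumerate(tree.query_ball_point(
                grid_pts, post.merge_radius)):
            if neighbors:
                sums.ravel()[flat_i] = vals[neighbors].sum()
                counts.ravel()[flat_i] = len(neighbors)

    values = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return DensityMap(origin=mins, spacing=spacing, values=values, counts=counts)


def place_ions(density: DensityMap, post: PostConfig | None = None) -> list[PredictedSite]:
    """Place one ion per cluster of high-probability voxels.

    Voxels above the probability threshold are clustered by average-
    linkage agglomerative clustering with the distance cutoff; each
    cluster yields a site at the probability-weighted centroid whose
    score is the cluster's maximum voxel probability.
    """
    post = post or PostConfig()
    if not np.all(np.isfinite(density.values)):
        raise ValueError("density contains non-finite values")
    mask = density.values > post.cluster_probability_threshold
    if not mask.any():
        return []
    idx = np.argwhere(mask)
    coords = density.origin + idx * density.spacing
    probs = density.values[mask]
    if len(coords) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        labels = AgglomerativeClustering(
            n_clusters=None,
            distance_threshold=post.cluster_distance_threshold,
            linkage="average",
        ).fit_predict(coords)
    sites = []
    for lab in np.unique(labels):
        sel = labels == lab
        w = probs[sel]
        center = (w[:, None] * coords[sel]).sum(axis=0) / w.sum()
        sites.append(PredictedSite(position=center, score=float(w.max())))
    return sorted(sites, key=lambda s: (-s.score, tuple(s.position)))


_BOHR_PER_ANGSTROM = 1.8897259886


def write_cube(density: DensityMap, path: str | Path,
               comment: str = "zinc probability density") -> None:
    """Write a density as a Gaussian cube file (coordinates in Bohr)."""
    o = density.origin * _BOHR_PER_ANGSTROM
    step = density.spacing * _BOHR_PER_ANGSTROM
    nx, ny, nz = density.values.shape
    lines = [comment, "generated by metalloc"]
    lines.append(f"{1:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
    lines.append(f"{nx:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}")
    lines.append(f"{ny:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}")
    lines.append(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}")
    lines.append(f"{30:5d}{0.0:12.6f}" + "".join(f"{v:12.6f}" for v in o))
    flat = density.values.reshape(nx * ny, nz)
    for row in flat:
        for start in range(0, nz, 6):
            lines.append("".join(f"{v:13.5E}" for v in row[start:start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> DensityMap:
    """Read back a cube file written by :func:`write_cube`."""
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = np.array([float(x) for x in lines[2].split()[1:4]]) / _BOHR_PER_ANGSTROM
    nx, sx = int(lines[3].split()[0]), float(lines[3].split()[1])
    ny = int(lines[4].split()[0])
    nz = int(lines[5].split()[0])
    spacing = sx / _BOHR_PER_ANGSTROM
    data = []
    for line in lines[6 + natoms:]:
        data.extend(float(x) for x in line.split())
    values = np.array(data).reshape(nx, ny, nz)
    return DensityMap(origin=origin, spacing=spacing, values=values)


def save_environments(path: str | Path, structure_id: str,
                      examples: Iterable[tuple[tuple, VoxelGrid, VoxelGrid | None]],
                      ) -> None:
    """Store voxelized environments in HDF5 (one group per structure)."""
    import h5py

    with h5py.File(path, "a") as fh:
        grp = fh.require_group(structure_id)
        for key, grid, target in examples:
            name = "_".join(str(k) for k in key)
            if name in grp:
                del grp[name]
            sub = grp.create_group(name)
            sub.create_dataset("input", data=grid.values, compression="gzip")
            sub.attrs["origin"] = grid.origin
            sub.attrs["spacing"] = grid.spacing
            if target is not None:
                sub.create_dataset("target", data=target.values, compression="gzip")


def load_environments(path: str | Path, structure_id: str,
                      ) -> list[tuple[str, VoxelGrid, VoxelGrid | None]]:
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        grp = fh[structure_id]
        for name in sorted(grp):
            sub = grp[name]
            grid = VoxelGrid(origin=np.array(sub.attrs["origin"]),
                             spacing=float(sub.attrs["spacing"]),
                             values=np.array(sub["input"]))
            target = None
            if "target" in sub:
                target = VoxelGrid(origin=grid.origin, spacing=grid.spacing,
                                   values=np.array(sub["target"]))
            out.append((name, grid, target))
    return out
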