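"""Synthetic metalloprotein generator.

Builds small zinc proteins with controlled geometry: donor atoms of the
requested coordination motif sit at ideal tetrahedral or octahedral
vertices at 2.2 A from the metal (the mean LINK-record coordination
distance, optionally perturbed by Gaussian noise), full heavy-atom
residues are grown outward from each donor using internal-geometry
templates, matching LINK records are emitted, and decoy residues are
scattered away from the planted sites.  Templates carry ideal local
geometry only — no attempt at a Ramachandran-valid backbone is made,
since the predictors consume side-chain geometry, not stereochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pdbio import Atom, LinkPartner, LinkRecord, MetalSite, ProteinStructure, Residue
from .voxelgrid import DensityMap

__all__ = [
    "SiteSpec",
    "SynthProtein",
    "SUPPORTED_LETTERS",
    "make_zinc_site",
    "make_protein",
    "make_corpus",
    "make_density",
]

_LETTER_TO_RESIDUE = {
    "C": "CYS", "H": "HIS", "D": "ASP", "E": "GLU", "N": "ASN", "Q": "GLN",
    "S": "SER", "T": "THR", "Y": "TYR", "M": "MET", "K": "LYS",
}
SUPPORTED_LETTERS = tuple(sorted(_LETTER_TO_RESIDUE))

#: LINK donor atom per coordinating residue type.
_DONOR_ATOM = {
    "CYS": "SG", "HIS": "NE2", "ASP": "OD1", "GLU": "OE1", "ASN": "OD1",
    "GLN": "OE1", "SER": "OG", "THR": "OG1", "TYR": "OH", "MET": "SD",
    "LYS": "NZ",
}

_TETRAHEDRAL = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]) / np.sqrt(3)
_OCTAHEDRAL = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                        (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=float)
_GEOMETRIES = {"tetrahedral": _TETRAHEDRAL, "octahedral": _OCTAHEDRAL}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p = _unit(np.cross(u, helper))
    return p, np.cross(u, p)


def _backbone(cb: np.ndarray, anchor: np.ndarray) -> dict[str, np.ndarray]:
    """Grow CA/N/C/O off a CB, pointing away from the side-chain anchor."""
    u = _unit(cb - anchor)
    p, q = _frame(u)
    ca = cb + 1.53 * _unit(u + 0.6 * p)
    return {
        "CA": ca,
        "N": ca + 1.46 * _unit(u - 0.8 * p + 0.4 * q),
        "C": ca + 1.53 * _unit(u + 0.2 * p - 0.9 * q),
        "O": ca + 1.53 * _unit(u + 0.2 * p - 0.9 * q) + 1.23 * q,
    }


def _hexagon(cg: np.ndarray, d: np.ndarray, p: np.ndarray,
             names=("CD1", "CE1", "CZ", "CE2", "CD2")) -> dict[str, np.ndarray]:
    """Aromatic ring vertices following CG along direction d."""
    side = 1.39
    out = {
        names[0]: cg + side * (0.5 * d + 0.866 * p),
        names[1]: cg + side * (0.5 * d + 0.866 * p) + side * d,
        names[2]: cg + 2 * side * d,
        names[3]: cg + side * (0.5 * d - 0.866 * p) + side * d,
        names[4]: cg + side * (0.5 * d - 0.866 * p),
    }
    return out


def _build_templates() -> dict[str, dict[str, np.ndarray]]:
    """Heavy-atom residue templates.

    Coordinating residues have their LINK donor atom at the origin with
    the body in the -x half-space (so an aligned template extends away
    from the metal); decoy-only residues are anchored at CA.
    """
    t: dict[str, dict[str, np.ndarray]] = {}

    def A(**kwargs):
        return {k: np.asarray(v, dtype=float) for k, v in kwargs.items()}

    # -- coordinating residues (donor at origin) --
    cys = A(SG=(0, 0, 0), CB=(-1.30, 1.20, 0.00))
    cys.update(_backbone(cys["CB"], cys["SG"]))
    t["CYS"] = cys

    # imidazole: regular pentagon of side 1.37, NE2 at the origin
    ring_r = 1.37 / (2 * np.sin(np.pi / 5))
    center = np.array([-ring_r, 0.0, 0.0])
    ang = {"NE2": 0.0, "CE1": 72.0, "ND1": 144.0, "CG": 216.0, "CD2": 288.0}
    his = {name: center + ring_r * np.array(
        [np.cos(np.radians(a)), np.sin(np.radians(a)), 0.0])
        for name, a in ang.items()}
    his["CB"] = his["CG"] + 1.50 * _unit(his["CG"] - center)
    his.update(_backbone(his["CB"], his["CG"]))
    t["HIS"] = his

    asp = A(OD1=(0, 0, 0), OD2=(0, -2.20, 0), CG=(-0.593, -1.10, 0))
    asp["CB"] = asp["CG"] + 1.52 * np.array([-1.0, 0.0, 0.0])
    asp.update(_backbone(asp["CB"], asp["CG"]))
    t["ASP"] = asp

    glu = A(OE1=(0, 0, 0), OE2=(0, -2.20, 0), CD=(-0.593, -1.10, 0))
    glu["CG"] = glu["CD"] + 1.52 * np.array([-1.0, 0.0, 0.0])
    glu["CB"] = glu["CG"] + 1.53 * _unit(np.array([-0.5, 0.8, 0.3]))
    glu.update(_backbone(glu["CB"], glu["CG"]))
    t["GLU"] = glu

    asn = A(OD1=(0, 0, 0), CG=(-1.23, 0, 0))
    asn["ND2"] = asn["CG"] + 1.33 * _unit(np.array([-0.5, 1.0, 0.0]))
    asn["CB"] = asn["CG"] + 1.52 * _unit(np.array([-0.6, -1.0, 0.2]))
    asn.update(_backbone(asn["CB"], asn["CG"]))
    t["ASN"] = asn

    gln = A(OE1=(0, 0, 0), CD=(-1.23, 0, 0))
    gln["NE2"] = gln["CD"] + 1.33 * _unit(np.array([-0.5, 1.0, 0.0]))
    gln["CG"] = gln["CD"] + 1.52 * _unit(np.array([-0.6, -1.0, 0.2]))
    gln["CB"] = gln["CG"] + 1.53 * _unit(np.array([-0.8, 0.5, 0.3]))
    gln.update(_backbone(gln["CB"], gln["CG"]))
    t["GLN"] = gln

    ser = A(OG=(0, 0, 0), CB=(-1.42, 0, 0))
    ser.update(_backbone(ser["CB"], ser["OG"]))
    t["SER"] = ser

    thr = A(OG1=(0, 0, 0), CB=(-1.43, 0, 0))
    thr["CG2"] = thr["CB"] + 1.53 * _unit(np.array([-0.3, -1.2, 0.4]))
    thr.update(_backbone(thr["CB"], thr["OG1"]))
    t["THR"] = thr

    tyr = A(OH=(0, 0, 0), CZ=(-1.38, 0, 0))
    d = np.array([-1.0, 0.0, 0.0])
    p = np.array([0.0, 1.0, 0.0])
    ring = _hexagon(tyr["CZ"], d, p, names=("CE1", "CD1", "CG", "CD2", "CE2"))
    tyr.update(ring)
    tyr["CB"] = tyr["CG"] + 1.51 * _unit(np.array([-1.0, 0.0, 0.15]))
    tyr.update(_backbone(tyr["CB"], tyr["CG"]))
    t["TYR"] = tyr

    met = A(SD=(0, 0, 0), CG=(-1.80, 0, 0))
    met["CE"] = met["SD"] + 1.79 * _unit(np.array([0.4, 1.0, 0.3]))
    met["CB"] = met["CG"] + 1.53 * _unit(np.array([-0.7, 0.9, 0.3]))
    met.update(_backbone(met["CB"], met["CG"]))
    t["MET"] = met

    lys = A(NZ=(0, 0, 0), CE=(-1.49, 0, 0))
    lys["CD"] = lys["CE"] + 1.53 * _unit(np.array([-0.6, 1.0, 0.2]))
    lys["CG"] = lys["CD"] + 1.53 * _unit(np.array([-1.0, -0.4, 0.3]))
    lys["CB"] = lys["CG"] + 1.53 * _unit(np.array([-0.7, 1.0, 0.2]))
    lys.update(_backbone(lys["CB"], lys["CG"]))
    t["LYS"] = lys

    # -- decoy-only residues (CA at origin) --
    gly = A(CA=(0, 0, 0), N=(-0.70, 1.28, 0), C=(1.23, 0.88, 0), O=(1.23, 2.11, 0))
    t["GLY"] = gly
    ala = dict(gly)
    ala["CB"] = 1.53 * _unit(np.array([0.3, -0.9, -0.8]))
    t["ALA"] = ala
    val = dict(ala)
    val["CG1"] = val["CB"] + 1.53 * _unit(np.array([1.0, -0.5, 0.0]))
    val["CG2"] = val["CB"] + 1.53 * _unit(np.array([-0.9, -0.6, -0.4]))
    t["VAL"] = val
    leu = dict(ala)
    leu["CG"] = leu["CB"] + 1.53 * _unit(np.array([0.3, -1.0, 0.2]))
    leu["CD1"] = leu["CG"] + 1.53 * _unit(np.array([1.0, -0.4, -0.3]))
    leu["CD2"] = leu["CG"] + 1.53 * _unit(np.array([-0.8, -0.7, 0.6]))
    t["LEU"] = leu
    phe = dict(ala)
    phe["CG"] = phe["CB"] + 1.50 * _unit(np.array([0.2, -1.0, -0.2]))
    d = _unit(phe["CG"] - phe["CB"])
    p, _ = _frame(d)
    phe.update(_hexagon(phe["CG"], d, p))
    t["PHE"] = phe
    return t


_TEMPLATES = _build_templates()

_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S", "C": "C"}


def _atom_element(name: str) -> str:
    return _ELEMENT_FROM_NAME.get(name[0], "C")


@dataclass
class SiteSpec:
    """One planted zinc site.

    ``motif`` is a coordination-environment code (e.g. "CCHH"); its
    residues occupy the first vertices of the chosen polyhedron, so
    motifs shorter than the coordination number leave open vertices
    (as water-completed sites do).
    """

    motif: str
    geometry: str = "tetrahedral"
    bond_length: float = 2.2
    noise_sigma: float = 0.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.motif = "".join(sorted(self.motif.upper()))
        self.center = np.asarray(self.center, dtype=float)
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {sorted(_GEOMETRIES)}")
        bad = [l for l in self.motif if l not in _LETTER_TO_RESIDUE]
        if bad:
            raise ValueError(
                f"unsupported motif letters {bad}; supported: {SUPPORTED_LETTERS}")
        n_vertices = len(_GEOMETRIES[self.geometry])
        if not 2 <= len(self.motif) <= n_vertices:
            raise ValueError(
                f"motif length {len(self.motif)} does not fit {self.geometry} "
                f"coordination (2..{n_vertices})")
        if self.bond_length <= 0 or self.noise_sigma < 0:
            raise ValueError("bond_length must be > 0 and noise_sigma >= 0")


@dataclass
class SynthProtein:
    structure: ProteinStructure
    planted_sites: list[MetalSite]
    site_specs: list[SiteSpec]
    seed: int


def _rotation_aligning(target: np.ndarray, roll: float) -> np.ndarray:
    """Rotation mapping +x to ``target`` (unit), composed with a roll
    about ``target``."""
    a = np.array([1.0, 0.0, 0.0])
    b = _unit(target)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        align = np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        align = np.eye(3) + vx + vx @ vx / (1.0 + c)
    K = np.array([[0, -b[2], b[1]], [b[2], 0, -b[0]], [-b[1], b[0], 0]])
    roll_m = np.eye(3) + np.sin(roll) * K + (1 - np.cos(roll)) * (K @ K)
    return roll_m @ align


def make_zinc_site(spec: SiteSpec, seed: int | np.random.Generator = 0,
                   chain_id: str = "A", start_seq: int = 1,
                   metal_seq: int = 901,
                   ) -> tuple[list[Residue], MetalSite, list[LinkRecord]]:
    """Realize one zinc site: residues, the metal, and its LINK records."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vertices = _GEOMETRIES[spec.geometry]
    residues: list[Residue] = []
    links: list[LinkRecord] = []
    for i, letter in enumerate(spec.motif):
        res_name = _LETTER_TO_RESIDUE[letter]
        donor_name = _DONOR_ATOM[res_name]
        direction = vertices[i]
        donor_pos = spec.center + spec.bond_length * direction \
            + rng.normal(0.0, spec.noise_sigma, size=3)
        outward = _unit(donor_pos - spec.center)
        # template body lives at -x; map +x onto -outward so it points away
        rot = _rotation_aligning(-outward, roll=rng.uniform(0.0, 2 * np.pi))
        seq = start_seq + i
        atoms = [
            Atom(serial=0, name=name, element=_atom_element(name),
                 residue_name=res_name, chain_id=chain_id, residue_seq=seq,
                 insertion_code="", position=donor_pos + rot @ offset)
            for name, offset in _TEMPLATES[res_name].items()
        ]
        residues.append(Residue(chain_id=chain_id, residue_seq=seq,
                                insertion_code="", residue_name=res_name,
                                atoms=atoms))
        links.append(LinkRecord(
            partner1=LinkPartner(donor_name, res_name, chain_id, seq),
            partner2=LinkPartner("ZN", "ZN", chain_id, metal_seq),
            distance=float(np.linalg.norm(donor_pos - spec.center)),
        ))
    site = MetalSite(element="ZN", position=spec.center.copy(), occupancy=1.0,
                     source_residue=(chain_id, metal_seq, ""))
    return residues, site, links


_DECOY_POOL = ("GLY", "ALA", "VAL", "LEU", "PHE", "SER", "THR",
               "CYS", "HIS", "ASP", "ASN", "LYS")


def make_protein(specs: Sequence[SiteSpec], n_decoys: int = 20,
                 box: float = 40.0, seed: int = 0,
                 min_separation: float = 18.0,
                 decoy_exclusion: float = 6.0,
                 structure_id: Optional[str] = None) -> SynthProtein:
    """Assemble a synthetic protein with planted sites and decoys.

    Site centers are drawn uniformly inside the box with pairwise
    separation of at least ``min_separation`` (>= 10 A; the default
    18 A keeps the reference-point clusters of distinct sites disjoint
    at the geometric predictor's default 11 A grouping distance).
    Decoy residues are scattered so that none of their heavy atoms comes
    within ``decoy_exclusion`` of a planted metal.
    """
    if min_separation < 10.0:
        raise ValueError("min_separation must be >= 10 A")
    rng = np.random.default_rng(seed)
    margin = 8.0
    if box <= 2 * margin:
        raise ValueError("box too small for site placement margins")

    centers: list[np.ndarray] = []
    for _ in specs:
        for _attempt in range(1000):
            candidate = rng.uniform(margin, box - margin, size=3)
            if all(np.linalg.norm(candidate - c) >= min_separation for c in centers):
                centers.append(candidate)
                break
        else:
            raise RuntimeError(
                f"could not place {len(specs)} sites {min_separation} A apart "
                f"in a {box} A box")

    structure = ProteinStructure(id=structure_id or f"SYNTH{seed}")
    planted: list[MetalSite] = []
    placed_specs: list[SiteSpec] = []
    seq = 1
    for i, (spec, center) in enumerate(zip(specs, centers)):
        placed = SiteSpec(motif=spec.motif, geometry=spec.geometry,
                          bond_length=spec.bond_length,
                          noise_sigma=spec.noise_sigma, center=center)
        residues, site, links = make_zinc_site(
            placed, rng, chain_id="A", start_seq=seq, metal_seq=901 + i)
        structure.residues.extend(residues)
        structure.links.extend(links)
        planted.append(site)
        placed_specs.append(placed)
        seq += len(residues)

    metal_pos = np.array([s.position for s in planted]).reshape(-1, 3)
    existing_ca = [r.get_atom("CA").position for r in structure.residues]
    for _ in range(n_decoys):
        res_name = _DECOY_POOL[int(rng.integers(len(_DECOY_POOL)))]
        template = _TEMPLATES[res_name]
        anchor_name = "CA" if "CA" in template else next(iter(template))
        for _attempt in range(300):
            anchor = rng.uniform(1.0, box - 1.0, size=3)
            rot = _rotation_aligning(_unit(rng.normal(size=3)),
                                     roll=rng.uniform(0, 2 * np.pi))
            coords = {name: anchor + rot @ (pos - template[anchor_name])
                      for name, pos in template.items()}
            positions = np.array(list(coords.values()))
            if len(metal_pos) and np.min(
                    np.linalg.norm(positions[:, None] - metal_pos[None], axis=2)
            ) < decoy_exclusion:
                continue
            if existing_ca and min(np.linalg.norm(coords["CA"] - ca)
                                   for ca in existing_ca) < 4.0:
                continue
            atoms = [Atom(serial=0, name=name, element=_atom_element(name),
                          residue_name=res_name, chain_id="A", residue_seq=seq,
                          insertion_code="", position=pos)
                     for name, pos in coords.items()]
            structure.residues.append(Residue(
                chain_id="A", residue_seq=seq, insertion_code="",
                residue_name=res_name, atoms=atoms))
            existing_ca.append(coords["CA"])
            seq += 1
            break
        else:
            raise RuntimeError("could not place decoy residue after 300 tries")

    for i, site in enumerate(planted):
        structure.hetero_atoms.append(Atom(
            serial=0, name="ZN", element="ZN", residue_name="ZN",
            chain_id="A", residue_seq=901 + i, insertion_code="",
            position=site.position.copy(), occupancy=site.occupancy,
            is_hetero=True))
    for serial, atom in enumerate(structure.all_atoms(), start=1):
        atom.serial = serial
    return SynthProtein(structure=structure, planted_sites=planted,
                        site_specs=placed_specs, seed=seed)


def make_corpus(n_proteins: int, motifs: Sequence[str] | dict[str, float],
                seed: int = 0, noise_sigma: float = 0.1,
                sites_per_protein: tuple[int, int] = (1, 2),
                n_decoys: int = 12, box: float = 40.0) -> list[SynthProtein]:
    """A corpus of synthetic proteins.

    ``motifs`` given as a sequence are assigned on a balanced
    round-robin schedule (every motif equally represented); given as a
    ``{motif: weight}`` mapping they are drawn with those frequencies.
    """
    rng = np.random.default_rng(seed)
    weighted = isinstance(motifs, dict)
    if weighted:
        names = sorted(motifs)
        weights = np.array([motifs[m] for m in names], dtype=float)
        weights = weights / weights.sum()
    else:
        names = list(motifs)
    lo, hi = sites_per_protein
    corpus = []
    rr = 0
    for i in range(n_proteins):
        n_sites = int(rng.integers(lo, hi + 1))
        chosen = []
        for _ in range(n_sites):
            if weighted:
                chosen.append(names[int(rng.choice(len(names), p=weights))])
            else:
                chosen.append(names[rr % len(names)])
                rr += 1
        specs = [SiteSpec(motif=m, geometry="octahedral" if len(m) > 4
                          else "tetrahedral", noise_sigma=noise_sigma)
                 for m in chosen]
        sub_seed = int(rng.integers(2 ** 31 - 1))
        corpus.append(make_protein(specs, n_decoys=n_decoys, box=box,
                                   seed=sub_seed,
                                   structure_id=f"SYNTH{seed}_{i}"))
    return corpus


def make_density(peaks: Sequence[tuple[np.ndarray, float, float]],
                 origin: np.ndarray, spacing: float,
                 shape: tuple[int, int, int]) -> DensityMap:
    """Gaussian test density: value = max over peaks of
    ``peak * exp(-|x-c|^2 / (2 sigma^2))``."""
    origin = np.asarray(origin, dtype=float)
    values = np.zeros(shape)
    idx = np.indices(shape).reshape(3, -1).T
    coords = origin + idx * spacing
    for center, peak, sigma in peaks:
        if not 0.0 < peak <= 1.0:
            raise ValueError("peak values must be in (0, 1]")
        d2 = np.sum((coords - np.asarray(center, dtype=float)) ** 2, axis=1)
        values = np.maximum(values, peak * np.exp(-d2 / (2.0 * sigma ** 2))
                            .reshape(shape))
    return DensityMap(origin=origin, spacing=spacing, values=values)
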