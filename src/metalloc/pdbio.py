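"""PDB-format structure I/O for metal-site analysis.

Reading and writing go through :mod:`gemmi`; on top of it this module
applies the conventions the predictors rely on: only the first MODEL is
kept, alternative conformations are collapsed to the highest-occupancy
conformer, hydrogens are dropped, and LINK records are retained verbatim
so coordination environments can be mined from them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "LinkPartner",
    "LinkRecord",
    "ProteinStructure",
    "MetalSite",
    "PDBFormatError",
    "EmptyStructureError",
    "MissingAtomError",
    "read_pdb",
    "write_pdb",
    "extract_metal_sites",
    "count_unique_protein_ligands",
    "classify_site_quality",
    "STANDARD_AA",
    "THREE_TO_ONE",
    "PARENT_RESIDUE",
    "WATER_NAMES",
]


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a file contains no ATOM/HETATM records."""


class MissingAtomError(KeyError):
    """Raised when a residue lacks an atom an operation requires."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA = frozenset(THREE_TO_ONE)

#: Modified residues mapped to their standard parent (PDB chemical
#: component heritage); used when counting coordination partners.
PARENT_RESIDUE = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (closest standard analogue for S/Se donor)
    "CSO": "CYS",
    "CSD": "CYS",
    "CME": "CYS",
    "HIC": "HIS",
    "MLY": "LYS",
    "PTR": "TYR",
    "SEP": "SER",
    "TPO": "THR",
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Elements commonly deposited as monoatomic metal HETATMs.
METAL_ELEMENTS = frozenset({
    "ZN", "FE", "CU", "MN", "CO", "NI", "MG", "CA", "NA", "K",
    "CD", "HG", "PB", "PT", "AU", "AG", "MO", "W", "V", "CR",
})


def infer_element(atom_name: str, residue_name: str) -> str:
    """Infer an element symbol from an atom name (PDB v3.3 justification).

    Used as a fallback when the element column is blank and gemmi could
    not assign one.  Monoatomic ions are named after their element; for
    amino-acid atoms the element is the first alphabetic character after
    stripping leading digits.
    """
    name = atom_name.strip()
    if residue_name.strip().upper() == name.upper() and name.upper() in METAL_ELEMENTS:
        return name.upper()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in {"CL", "BR", "SE", "FE", "ZN", "MG", "MN", "NA"} and len(name) >= 2:
        # two-letter element only when the raw name is left-justified at col 13
        return stripped[:2].upper()
    return stripped[0].upper()


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if not self.element:
            self.element = infer_element(self.name, self.residue_name)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in {"H", "D"}


@dataclass
class Residue:
    chain_id: str
    residue_seq: int
    insertion_code: str
    residue_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_amino(self) -> bool:
        return self.residue_name in STANDARD_AA

    @property
    def standard_parent(self) -> Optional[str]:
        """Standard residue name, mapping modified residues to their parent."""
        if self.residue_name in STANDARD_AA:
            return self.residue_name
        return PARENT_RESIDUE.get(self.residue_name)

    def get_atom(self, name: str) -> Atom:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        raise MissingAtomError(f"{self.residue_name} {self.key}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


class LinkPartner(NamedTuple):
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str = ""


@dataclass
class LinkRecord:
    """One LINK record: a declared linkage between two atoms."""

    partner1: LinkPartner
    partner2: LinkPartner
    distance: Optional[float] = None

    def partners(self) -> tuple[LinkPartner, LinkPartner]:
        return (self.partner1, self.partner2)


@dataclass
class MetalSite:
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    source_residue: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        self.element = self.element.upper()
        self.position = np.asarray(self.position, dtype=float)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"metal occupancy {self.occupancy} outside [0,1]")


@dataclass
class ProteinStructure:
    """One model's worth of coordinates plus LINK records.

    ``residues`` holds polymer residues (standard amino acids and
    modified residues with a standard parent); every other HETATM atom
    (metals, ligands, retained waters) lives in ``hetero_atoms``.
    """

    id: str
    residues: list[Residue] = field(default_factory=list)
    links: list[LinkRecord] = field(default_factory=list)
    hetero_atoms: list[Atom] = field(default_factory=list)

    def amino_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.standard_parent is not None]

    def find_residue(self, chain_id: str, residue_seq: int,
                     insertion_code: str = "") -> Optional[Residue]:
        for res in self.residues:
            if res.key == (chain_id, residue_seq, insertion_code):
                return res
        return None

    def resolve_link_partner(self, partner: LinkPartner) -> Optional[Atom]:
        """Find the atom a LINK partner refers to, or None."""
        res = self.find_residue(partner.chain_id, partner.residue_seq,
                                partner.insertion_code)
        if res is not None:
            for atom in res.atoms:
                if atom.name == partner.atom_name:
                    return atom
        for atom in self.hetero_atoms:
            if (atom.residue_key == (partner.chain_id, partner.residue_seq,
                                     partner.insertion_code)
                    and atom.name == partner.atom_name):
                return atom
        return None

    def all_atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms
        yield from self.hetero_atoms

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.all_atoms() if a.is_heavy]


def _resolve_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Collapse altLoc groups: keep the highest occupancy, ties broken by
    altLoc identifier ascending."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = []
            order.append(a.name)
        by_name[a.name].append(a)
    kept = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            kept.append(group[0])
        else:
            kept.append(min(group, key=lambda a: (-a.occ, a.altloc or "\x7f")))
    return kept


def _altloc_str(altloc: str) -> str:
    return "" if altloc in ("\x00", "", " ") else altloc


def read_pdb(path: str | Path, keep_water: bool = False) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Only the first MODEL is retained; for atoms with alternative
    conformations only the highest-occupancy conformer is kept (ties by
    altLoc identifier); hydrogens are dropped; waters are dropped unless
    ``keep_water``; LINK records are parsed verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")

    model = st[0]  # first-model rule
    structure = ProteinStructure(id=st.name or path.stem)
    serial = 0
    for chain in model:
        for gres in chain:
            res_name = gres.name.strip()
            is_water = res_name in WATER_NAMES
            if is_water and not keep_water:
                continue
            atoms: list[Atom] = []
            for gatom in _resolve_altlocs(list(gres)):
                element = gatom.element.name.upper()
                if not element or element == "X":
                    element = infer_element(gatom.name, res_name)
                if element in {"H", "D"}:
                    continue
                serial += 1
                atoms.append(Atom(
                    serial=serial,
                    name=gatom.name,
                    element=element,
                    residue_name=res_name,
                    chain_id=chain.name,
                    residue_seq=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=min(1.0, max(0.0, float(gatom.occ))),
                    alt_loc=_altloc_str(gatom.altloc),
                    is_hetero=(gres.het_flag == "H"),
                ))
            if not atoms:
                continue
            is_polymer = (res_name in STANDARD_AA or res_name in PARENT_RESIDUE
                          ) and not is_water
            if is_polymer:
                structure.residues.append(Residue(
                    chain_id=chain.name,
                    residue_seq=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    residue_name=res_name,
                    atoms=atoms,
                ))
            else:
                for a in atoms:
                    a.is_hetero = True
                structure.hetero_atoms.extend(atoms)

    if not structure.residues and not structure.hetero_atoms:
        raise EmptyStructureError(f"{path}: structure has zero atoms after filtering")

    for con in st.connections:
        if con.type == gemmi.ConnectionType.Disulf:
            continue  # SSBOND, not a LINK
        p1, p2 = con.partner1, con.partner2
        dist = con.reported_distance if con.reported_distance > 0 else None
        structure.links.append(LinkRecord(
            partner1=LinkPartner(p1.atom_name, p1.res_id.name, p1.chain_name,
                                 p1.res_id.seqid.num,
                                 (p1.res_id.seqid.icode or "").strip()),
            partner2=LinkPartner(p2.atom_name, p2.res_id.name, p2.chain_name,
                                 p2.res_id.seqid.num,
                                 (p2.res_id.seqid.icode or "").strip()),
            distance=dist,
        ))
    return structure


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure back to PDB format (fixed columns, 3 decimals).

    LINK records are emitted for every :class:`LinkRecord`; coordinates
    round-trip at PDB precision.
    """
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def _chain(chain_id: str) -> gemmi.Chain:
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        return chains[chain_id]

    def _add_residue(chain_id: str, seq: int, icode: str, name: str,
                     atoms: Sequence[Atom], het: bool) -> None:
        gres = gemmi.Residue()
        gres.name = name
        gres.seqid = gemmi.SeqId(seq, icode or " ")
        gres.het_flag = "H" if het else "A"
        for atom in atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element.capitalize())
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = atom.occupancy
            ga.b_iso = 0.0
            gres.add_atom(ga)
        _chain(chain_id).add_residue(gres)

    for res in structure.residues:
        het = any(a.is_hetero for a in res.atoms)
        _add_residue(res.chain_id, res.residue_seq, res.insertion_code,
                     res.residue_name, res.atoms, het)
    het_groups: dict[tuple, list[Atom]] = {}
    for atom in structure.hetero_atoms:
        het_groups.setdefault(
            (atom.chain_id, atom.residue_seq, atom.insertion_code,
             atom.residue_name), []).append(atom)
    for (chain_id, seq, icode, name), atoms in het_groups.items():
        _add_residue(chain_id, seq, icode, name, atoms, het=True)

    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)

    for link in structure.links:
        con = gemmi.Connection()
        con.type = gemmi.ConnectionType.Covale
        for attr, partner in (("partner1", link.partner1), ("partner2", link.partner2)):
            addr = gemmi.AtomAddress()
            addr.chain_name = partner.chain_id
            addr.res_id = gemmi.ResidueId()
            addr.res_id.name = partner.residue_name
            addr.res_id.seqid = gemmi.SeqId(partner.residue_seq,
                                            partner.insertion_code or " ")
            addr.atom_name = partner.atom_name
            setattr(con, attr, addr)
        st.connections.append(con)

    Path(path).write_text(st.make_pdb_string())


def extract_metal_sites(structure: ProteinStructure, element: str = "ZN") -> list[MetalSite]:
    """One :class:`MetalSite` per HETATM of the requested element, in file order."""
    element = element.upper()
    sites = []
    for atom in structure.hetero_atoms:
        if atom.element.upper() == element or (
                atom.residue_name.upper() == element and len(atom.residue_name) <= 2):
            sites.append(MetalSite(
                element=element,
                position=atom.position.copy(),
                occupancy=atom.occupancy,
                source_residue=atom.residue_key,
            ))
    return sites


def count_unique_protein_ligands(site: MetalSite, structure: ProteinStructure,
                                 radius: float = 2.8) -> int:
    """Number of distinct protein residues with >=1 heavy atom within ``radius``.

    Counts standard amino-acid residues only (waters and hetero ligands
    are never protein ligands); a bidentate residue counts once.  Any
    heavy atom qualifies, backbone carbonyls included.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    count = 0
    for res in structure.residues:
        if not res.is_amino:
            continue
        for atom in res.heavy_atoms():
            if np.linalg.norm(atom.position - site.position) <= radius:
                count += 1
                break
    return count


def classify_site_quality(site: MetalSite, structure: ProteinStructure,
                          radius: float = 2.8) -> str:
    """Label a metal site by its coordination support.

    ``artifact_like``: fewer than 2 unique protein ligands within 2.8 A
    or occupancy <= 0.5 — the signature of a crystallization artifact.
    ``preorganized_3plus``: >=3 unique ligands and occupancy > 0.5 — a
    well-defined, biologically significant site.  Everything else is
    ``coordinated_2plus``.
    """
    n_ligands = count_unique_protein_ligands(site, structure, radius)
    if n_ligands < 2 or site.occupancy <= 0.5:
        return "artifact_like"
    if n_ligands >= 3:
        return "preorganized_3plus"
    return "coordinated_2plus"
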