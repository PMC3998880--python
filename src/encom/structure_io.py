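"""Coarse-grained protein structure input/output.

Parses PDB files into the light-weight structure representation used by the
elastic-network modules, assigns Sobolev-style atom types to heavy atoms and
reads/writes normal-mode files in a plain-text NMD-style format.

Only heavy atoms of standard amino-acid residues are retained: waters,
ligands, hydrogens and all but the highest-occupancy alternate location are
dropped on reading.  Every residue that enters a network must have exactly
one C-alpha atom; residues without one are dropped with a warning.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("encom")

__all__ = [
    "AtomType",
    "Atom",
    "Residue",
    "ProteinStructure",
    "read_pdb",
    "write_pdb",
    "assign_atom_types",
    "classify_atom",
    "write_modes",
    "read_modes",
    "InputError",
    "EmptyStructureError",
    "DimensionError",
    "ELEMENT_RADII",
]


class InputError(ValueError):
    """Unreadable or malformed input file."""


class EmptyStructureError(InputError):
    """No usable residues remain after filtering."""


class DimensionError(ValueError):
    """Mismatched sizes between related objects."""


class AtomType(enum.Enum):
    """Eight-class atom typing in the style of Sobolev et al.

    Classes: hydrophilic atoms can both donate and accept hydrogen bonds,
    acceptor/donor atoms do only one, hydrophobic carbons have no polar
    neighbour, aromatic carbons belong to a ring system, neutral carbons are
    bonded to a polar atom, and the neutral-donor/neutral-acceptor classes
    hold weakly polar atoms (thiol sulfur, thioether sulfur, proline's
    backbone nitrogen).  Atoms outside the bundled table get UNASSIGNED and
    are treated as NEUTRAL in interaction-weight computations.
    """

    HYDROPHILIC = 1
    ACCEPTOR = 2
    DONOR = 3
    HYDROPHOBIC = 4
    AROMATIC = 5
    NEUTRAL = 6
    NEUTRAL_DONOR = 7
    NEUTRAL_ACCEPTOR = 8
    UNASSIGNED = 0


#: Fixed per-element van der Waals radii (Angstrom) used by the contact module.
ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
DEFAULT_RADIUS = 1.7

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Crystallographic substitutions mapped onto their parent residue.
RESIDUE_ALIASES = {"MSE": "MET"}

_T = AtomType

# Side-chain atom classes per residue.  The table is a reconstruction of the
# Sobolev scheme from its published rules: hydroxyl oxygens and histidine ring
# nitrogens are hydrophilic (donor+acceptor), carbonyl/carboxyl oxygens are
# acceptors, amine/amide/guanidinium nitrogens are donors, carbons bonded to
# N/O are neutral, ring carbons are aromatic and all remaining carbons are
# hydrophobic.  Sulfurs are placed in the weakly polar classes.
_SIDE_CHAIN_TYPES: dict[str, dict[str, AtomType]] = {
    "ALA": {"CB": _T.HYDROPHOBIC},
    "ARG": {"CB": _T.HYDROPHOBIC, "CG": _T.HYDROPHOBIC, "CD": _T.NEUTRAL,
            "NE": _T.DONOR, "CZ": _T.NEUTRAL, "NH1": _T.DONOR, "NH2": _T.DONOR},
    "ASN": {"CB": _T.HYDROPHOBIC, "CG": _T.NEUTRAL, "OD1": _T.ACCEPTOR,
            "ND2": _T.DONOR},
    "ASP": {"CB": _T.HYDROPHOBIC, "CG": _T.NEUTRAL, "OD1": _T.ACCEPTOR,
            "OD2": _T.ACCEPTOR},
    "CYS": {"CB": _T.HYDROPHOBIC, "SG": _T.NEUTRAL_DONOR},
    "GLN": {"CB": _T.HYDROPHOBIC, "CG": _T.HYDROPHOBIC, "CD": _T.NEUTRAL,
            "OE1": _T.ACCEPTOR, "NE2": _T.DONOR},
    "GLU": {"CB": _T.HYDROPHOBIC, "CG": _T.HYDROPHOBIC, "CD": _T.NEUTRAL,
            "OE1": _T.ACCEPTOR, "OE2": _T.ACCEPTOR},
    "GLY": {},
    "HIS": {"CB": _T.HYDROPHOBIC, "CG": _T.AROMATIC, "ND1": _T.HYDROPHILIC,
            "CD2": _T.AROMATIC, "CE1": _T.AROMATIC, "NE2": _T.HYDROPHILIC},
    "ILE": {"CB": _T.HYDROPHOBIC, "CG1": _T.HYDROPHOBIC, "CG2": _T.HYDROPHOBIC,
            "CD1": _T.HYDROPHOBIC},
    "LEU": {"CB": _T.HYDROPHOBIC, "CG": _T.HYDROPHOBIC, "CD1": _T.HYDROPHOBIC,
            "CD2": _T.HYDROPHOBIC},
    "LYS": {"CB": _T.HYDROPHOBIC, "CG": _T.HYDROPHOBIC, "CD": _T.HYDROPHOBIC,
            "CE": _T.NEUTRAL, "NZ": _T.DONOR},
    "MET": {"CB": _T.HYDROPHOBIC, "CG": _T.HYDROPHOBIC,
            "SD": _T.NEUTRAL_ACCEPTOR, "CE": _T.HYDROPHOBIC},
    "PHE": {"CB": _T.HYDROPHOBIC, "CG": _T.AROMATIC, "CD1": _T.AROMATIC,
            "CD2": _T.AROMATIC, "CE1": _T.AROMATIC, "CE2": _T.AROMATIC,
            "CZ": _T.AROMATIC},
    "PRO": {"CB": _T.HYDROPHOBIC, "CG": _T.HYDROPHOBIC, "CD": _T.NEUTRAL},
    "SER": {"CB": _T.NEUTRAL, "OG": _T.HYDROPHILIC},
    "THR": {"CB": _T.NEUTRAL, "OG1": _T.HYDROPHILIC, "CG2": _T.HYDROPHOBIC},
    "TRP": {"CB": _T.HYDROPHOBIC, "CG": _T.AROMATIC, "CD1": _T.AROMATIC,
            "CD2": _T.AROMATIC, "NE1": _T.DONOR, "CE2": _T.AROMATIC,
            "CE3": _T.AROMATIC, "CZ2": _T.AROMATIC, "CZ3": _T.AROMATIC,
            "CH2": _T.AROMATIC},
    "TYR": {"CB": _T.HYDROPHOBIC, "CG": _T.AROMATIC, "CD1": _T.AROMATIC,
            "CD2": _T.AROMATIC, "CE1": _T.AROMATIC, "CE2": _T.AROMATIC,
            "CZ": _T.AROMATIC, "OH": _T.HYDROPHILIC},
    "VAL": {"CB": _T.HYDROPHOBIC, "CG1": _T.HYDROPHOBIC, "CG2": _T.HYDROPHOBIC},
}

# Backbone atoms share types across residues, except proline's nitrogen
# which carries no amide hydrogen and is only a weak acceptor.
_BACKBONE_TYPES = {
    "N": _T.DONOR,
    "CA": _T.NEUTRAL,
    "C": _T.NEUTRAL,
    "O": _T.ACCEPTOR,
    "OXT": _T.ACCEPTOR,
}


def classify_atom(residue_name: str, atom_name: str) -> AtomType:
    """Return the atom-type class for a (residue, atom-name) pair.

    Unknown pairs yield :attr:`AtomType.UNASSIGNED` with a warning.
    """
    res = RESIDUE_ALIASES.get(residue_name, residue_name)
    if res in STANDARD_RESIDUES:
        if atom_name in _BACKBONE_TYPES:
            if res == "PRO" and atom_name == "N":
                return _T.NEUTRAL_ACCEPTOR
            return _BACKBONE_TYPES[atom_name]
        side = _SIDE_CHAIN_TYPES[res]
        if atom_name in side:
            return side[atom_name]
    logger.warning("unknown atom type for (%s, %s); using UNASSIGNED",
                   residue_name, atom_name)
    return _T.UNASSIGNED


@dataclass
class Atom:
    """A heavy atom of the coarse-grained structure."""

    serial: int
    name: str
    element: str
    residue_index: int
    coords: np.ndarray
    atom_type: AtomType = AtomType.UNASSIGNED
    radius: float = DEFAULT_RADIUS
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise InputError(f"atom {self.serial} ({self.name}): bad coords")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def calpha(self) -> Atom:
        for a in self.atoms:
            if a.name == "CA":
                return a
        raise InputError(f"residue {self.label} has no CA atom")

    @property
    def side_chain(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seq_number}{self.insertion_code}"


@dataclass
class ProteinStructure:
    """Ordered residue list with one C-alpha node per residue."""

    residues: list[Residue]
    source_id: str = ""
    model_number: int = 1

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def calpha_coords(self) -> np.ndarray:
        """(N, 3) array of C-alpha coordinates in residue order."""
        return np.array([r.calpha.coords for r in self.residues], dtype=float)

    def iter_atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Identity keys (chain, seq number, insertion code) per residue."""
        return [(r.chain_id, r.seq_number, r.insertion_code)
                for r in self.residues]

    def copy(self) -> "ProteinStructure":
        residues = [
            Residue(r.chain_id, r.seq_number, r.name,
                    [replace(a, coords=a.coords.copy()) for a in r.atoms],
                    r.insertion_code)
            for r in self.residues
        ]
        return ProteinStructure(residues, self.source_id, self.model_number)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "ProteinStructure":
        """Rigid-body transformed copy (coords -> R @ coords + t)."""
        out = self.copy()
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        for a in out.iter_atoms():
            a.coords = R @ a.coords + t
        return out

    def subset(self, indices: Sequence[int]) -> "ProteinStructure":
        """New structure restricted to the given residue indices (reindexed)."""
        residues = []
        for new_idx, i in enumerate(indices):
            r = self.residues[i]
            atoms = [replace(a, coords=a.coords.copy(), residue_index=new_idx)
                     for a in r.atoms]
            residues.append(Residue(r.chain_id, r.seq_number, r.name, atoms,
                                    r.insertion_code))
        return ProteinStructure(residues, self.source_id, self.model_number)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _pick_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one atom per name: the highest-occupancy alternate location."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or a.occ > prev.occ:
            by_name[a.name] = a
    return list(by_name.values())


def read_pdb(path: str | Path, model: int = 1,
             chains: Optional[Iterable[str]] = None,
             assign_types: bool = True) -> ProteinStructure:
    """Parse a PDB file into a heavy-atom :class:`ProteinStructure`.

    Parameters
    ----------
    path : PDB file path.
    model : model number to use (NMR multi-model files default to model 1).
    chains : optional set of chain identifiers to keep.
    assign_types : assign Sobolev-style atom types after parsing.

    Waters, ligands, hydrogens and lower-occupancy alternate locations are
    dropped.  Residues without a C-alpha are dropped with a warning.  MSE is
    mapped to MET; other non-standard amino acids are dropped with a warning.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise InputError(f"cannot read PDB file {path}: {exc}") from exc

    gmodel = None
    for m in st:
        if m.num == model:
            gmodel = m
            break
    if gmodel is None:
        raise InputError(f"model {model} not found in {path}")

    chain_filter = set(chains) if chains is not None else None
    residues: list[Residue] = []
    for chain in gmodel:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for gres in chain:
            name = gres.name
            if name == "HOH":
                continue
            mapped = RESIDUE_ALIASES.get(name, name)
            has_ca = any(a.name == "CA" and a.element.name != "H"
                         for a in gres)
            if mapped not in STANDARD_RESIDUES:
                if has_ca:
                    logger.warning("dropping non-standard residue %s %s%s",
                                   name, chain.name, gres.seqid.num)
                continue
            if not has_ca:
                logger.warning("dropping residue %s %s%s: no CA record",
                               name, chain.name, gres.seqid.num)
                continue
            heavy = [a for a in gres if not a.is_hydrogen()]
            picked = _pick_altlocs(heavy)
            atoms = []
            for ga in picked:
                elem = ga.element.name.upper()
                if name == "MSE" and ga.name == "SE":
                    # selenomethionine: treat selenium as the sulfur it replaces
                    atom_name, elem = "SD", "S"
                else:
                    atom_name = ga.name
                atoms.append(Atom(
                    serial=ga.serial,
                    name=atom_name,
                    element=elem,
                    residue_index=len(residues),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    radius=ELEMENT_RADII.get(elem, DEFAULT_RADIUS),
                    bfactor=float(ga.b_iso),
                    occupancy=float(ga.occ),
                ))
            icode = gres.seqid.icode.strip()
            residues.append(Residue(chain.name, gres.seqid.num, mapped,
                                    atoms, icode))

    if not residues:
        raise EmptyStructureError(f"no usable residues in {path}")
    structure = ProteinStructure(residues, source_id=path.stem,
                                 model_number=model)
    if assign_types:
        assign_atom_types(structure)
    return structure


def assign_atom_types(structure: ProteinStructure) -> ProteinStructure:
    """Assign one of the 8 Sobolev-style classes to every heavy atom.

    Modifies the structure in place and returns it.  Unknown (residue, atom)
    pairs get :attr:`AtomType.UNASSIGNED` (handled as NEUTRAL downstream).
    """
    for res in structure.residues:
        for atom in res.atoms:
            atom.atom_type = classify_atom(res.name, atom.name)
    return structure


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write the structure as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = structure.source_id or "encom"
    model = gemmi.Model(structure.model_number)
    chain_map: dict[str, gemmi.Chain] = {}
    serial = 0
    for res in structure.residues:
        chain = chain_map.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id)
            chain_map[res.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        for atom in res.atoms:
            serial += 1
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.serial = serial
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            ga.b_iso = atom.bfactor
            gres.add_atom(ga)
        chain.add_residue(gres)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Normal-mode file I/O (plain-text, NMD-style)
# ---------------------------------------------------------------------------

def write_modes(decomposition, structure: ProteinStructure,
                path: str | Path) -> None:
    """Write eigenvalues/eigenvectors in a plain-text NMD-style format.

    Format: header lines (``name``, ``model``, ``n_residues``), one
    ``coordinates`` line with the C-alpha coordinates, then one ``mode``
    line per mode: ``mode <index> <eigenvalue> <component ...>``.  The file
    round-trips losslessly at double precision.
    """
    n = decomposition.n_residues
    if n != structure.n_residues:
        raise DimensionError(
            f"decomposition has {n} residues, structure has "
            f"{structure.n_residues}")
    vecs = decomposition.eigenvectors
    vals = decomposition.eigenvalues
    if vecs.size == 0 or len(vals) == 0:
        raise DimensionError("empty mode set")
    coords = structure.calpha_coords().ravel()
    with open(path, "w") as fh:
        fh.write("nmd encom 1\n")
        fh.write(f"name {structure.source_id or 'structure'}\n")
        fh.write(f"model {decomposition.model_kind.name.lower()}\n")
        fh.write(f"n_residues {n}\n")
        fh.write("coordinates " + " ".join(f"{x:.17g}" for x in coords) + "\n")
        for k in range(len(vals)):
            comp = " ".join(f"{x:.17g}" for x in vecs[:, k])
            fh.write(f"mode {k + 1} {vals[k]:.17g} {comp}\n")


def read_modes(path: str | Path) -> dict:
    """Read a mode file written by :func:`write_modes`.

    Returns a dict with ``eigenvalues`` (ascending, as written),
    ``eigenvectors`` (columns), ``coordinates``, ``n_residues`` and
    ``model`` keys.
    """
    eigenvalues: list[float] = []
    columns: list[np.ndarray] = []
    coords = None
    n_res = None
    model = None
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "n_residues":
                n_res = int(parts[1])
            elif parts[0] == "model":
                model = parts[1]
            elif parts[0] == "coordinates":
                coords = np.array([float(x) for x in parts[1:]])
            elif parts[0] == "mode":
                eigenvalues.append(float(parts[2]))
                columns.append(np.array([float(x) for x in parts[3:]]))
    if not columns:
        raise InputError(f"no modes found in {path}")
    return {
        "eigenvalues": np.array(eigenvalues),
        "eigenvectors": np.column_stack(columns),
        "coordinates": coords,
        "n_residues": n_res,
        "model": model,
    }
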