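"""Protein structure model: parsing PDB files into an ordered residue list.

The rest of the pipeline works on a deliberately small model of a protein:
an ordered list of residues, each carrying its atoms' coordinates and a
representative coordinate (the alpha-carbon when present, else the centroid).
Residue identity is the author key ``(chain_id, author_number, insertion_code)``
exactly as printed in the source file, because all reported residue numbers in
allostery work follow crystal-structure author numbering (e.g. the PDZ domain
of 1BE9 runs 301..415).  Internal graph nodes are 0-based indices in file
order; the ``Structure`` keeps the bijection between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import EmptyStructureError, InputError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueKey",
    "STANDARD_AMINO_ACIDS",
    "DEFAULT_NONSTANDARD_MAP",
    "read_structure",
    "structure_from_atom_array",
    "filter_protein",
]

#: The 20 standard amino-acid 3-letter codes.
STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Non-standard residues mapped to their standard parent and retained by
#: :func:`filter_protein`.  Extend or override via the ``nonstandard_map``
#: argument.
DEFAULT_NONSTANDARD_MAP = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "PYL": "LYS",  # pyrrolysine
}

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """A single atom: label, element symbol and Cartesian coordinates in A."""

    name: str
    element: str
    xyz: np.ndarray  # shape (3,), float64

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=np.float64)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise InputError(f"atom {self.name!r}: coordinates must be 3 finite numbers")
        object.__setattr__(self, "xyz", xyz)


@dataclass(frozen=True)
class Residue:
    """An amino-acid residue with author identity and its atoms.

    ``rep_xyz`` is the alpha-carbon coordinate when a CA atom is present,
    otherwise the centroid of all atoms.
    """

    chain_id: str
    author_number: int
    insertion_code: str
    name: str
    atoms: tuple[Atom, ...]
    rep_xyz: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise InputError("residue must contain at least one atom")
        rep = None
        for atom in self.atoms:
            if atom.name == "CA" and atom.element != "CA":  # exclude calcium ions
                rep = atom.xyz
                break
        if rep is None:
            rep = np.mean([a.xyz for a in self.atoms], axis=0)
        object.__setattr__(self, "rep_xyz", np.asarray(rep, dtype=np.float64))

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.author_number, self.insertion_code)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.stack([a.xyz for a in self.atoms])


class Structure:
    """An ordered collection of residues with an author-key index.

    Internal indices are 0..n-1 in file order; ``index_of`` maps the author
    key back to the internal index and ``key_of`` inverts it.
    """

    def __init__(self, source_id: str, residues: list[Residue]):
        self.source_id = source_id
        self.residues: list[Residue] = list(residues)
        self._index: dict[ResidueKey, int] = {}
        for i, res in enumerate(self.residues):
            if res.key in self._index:
                raise InputError(f"duplicate residue key {res.key!r} in {source_id!r}")
            self._index[res.key] = i

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def index_of(self, key: ResidueKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise InputError(f"residue key {key!r} not found in {self.source_id!r}") from None

    def key_of(self, index: int) -> ResidueKey:
        return self.residues[index].key

    def resolve(self, chain_id: str, author_number: int, insertion_code: str = "") -> int:
        """Internal index of the residue with the given author identity."""
        return self.index_of((chain_id, author_number, insertion_code))

    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def rep_coords(self) -> np.ndarray:
        """(n, 3) array of representative coordinates, file order."""
        return np.stack([r.rep_xyz for r in self.residues])


def structure_from_atom_array(atoms: struc.AtomArray, source_id: str) -> Structure:
    """Group a biotite ``AtomArray`` into the package's residue model."""
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{source_id!r}: no atoms")
    residues: list[Residue] = []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for lo, hi in zip(starts[:-1], starts[1:]):
        sub = atoms[lo:hi]
        atom_objs = tuple(
            Atom(name=str(sub.atom_name[j]), element=str(sub.element[j]), xyz=sub.coord[j])
            for j in range(sub.array_length())
        )
        residues.append(
            Residue(
                chain_id=str(sub.chain_id[0]),
                author_number=int(sub.res_id[0]),
                insertion_code=str(sub.ins_code[0]).strip(),
                name=str(sub.res_name[0]),
                atoms=atom_objs,
            )
        )
    return Structure(source_id, residues)


def read_structure(path, keep_hydrogens: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first model is used.  For alternate locations the
    highest-occupancy conformer is kept (ties: first occurrence).  Hydrogens
    (and deuterium) are dropped unless ``keep_hydrogens``.

    Raises
    ------
    InputError
        If the file is missing or unparseable.
    EmptyStructureError
        If no atoms survive parsing.
    """
    try:
        pdb = PDBFile.read(str(path))
        n_records = sum(
            line.startswith(("ATOM", "HETATM")) for line in pdb.lines
        )
        if n_records == 0:
            raise EmptyStructureError(f"{path!r}: no ATOM/HETATM records")
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except EmptyStructureError:
        raise
    except (OSError, struc.BadStructureError, ValueError) as exc:
        raise InputError(f"cannot read structure from {path!r}: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path!r}: no ATOM/HETATM records")
    if not keep_hydrogens:
        atoms = atoms[~np.isin(atoms.element, ("H", "D"))]
        if atoms.array_length() == 0:
            raise EmptyStructureError(f"{path!r}: no heavy atoms")
    return structure_from_atom_array(atoms, source_id=str(path))


def filter_protein(
    structure: Structure,
    chains: list[str] | None = None,
    nonstandard_map: dict[str, str] | None = None,
) -> Structure:
    """Restrict a structure to amino-acid residues (optionally: given chains).

    Waters, nucleic acids, ions and other hetero groups are dropped.
    Non-standard amino acids in ``nonstandard_map`` (default:
    :data:`DEFAULT_NONSTANDARD_MAP`) are renamed to their standard parent and
    retained.  Internal indices are recomputed; author keys are untouched, so
    the operation is idempotent.
    """
    if len(structure) == 0:
        raise EmptyStructureError("cannot filter an empty structure")
    mapping = DEFAULT_NONSTANDARD_MAP if nonstandard_map is None else nonstandard_map
    chain_set = set(chains) if chains is not None else None
    kept: list[Residue] = []
    for res in structure:
        if chain_set is not None and res.chain_id not in chain_set:
            continue
        name = res.name
        if name in mapping:
            name = mapping[name]
        if name not in STANDARD_AMINO_ACIDS:
            continue
        if name == res.name:
            kept.append(res)
        else:
            kept.append(
                Residue(
                    chain_id=res.chain_id,
                    author_number=res.author_number,
                    insertion_code=res.insertion_code,
                    name=name,
                    atoms=res.atoms,
                )
            )
    if not kept:
        raise EmptyStructureError(
            f"{structure.source_id!r}: no amino-acid residues after filtering"
        )
    return Structure(structure.source_id, kept)
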