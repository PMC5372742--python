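"""Minimal coordinate model for protein structures.

Wraps gemmi's PDB reader into a flat, deterministic model holding exactly
what disulfide geometry analysis needs: per-residue atom coordinates with
author numbering, alternate locations resolved to a single conformer.

Conventions:

* Only the first MODEL of a multi-model file is read (crystal structures
  are single-model; a warning is emitted otherwise).
* Alternate locations: the highest-occupancy conformer wins; on a tie the
  alphabetically first altloc tag wins. This yields one deterministic
  conformer per atom, which dihedral math requires.
* Residue numbering is author numbering (PDB columns 23-26); no
  renumbering is performed, so Cys55/Cys99 labels match the literature.
* HETATM records with residue name CYS are kept, so chemically modified
  cysteines still participate in bridge detection.
* SSBOND records are parsed into advisory pairs only; detection is always
  recomputed from coordinates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "StructureError",
    "PDBParseError",
    "EmptyStructureError",
    "ResidueLookupError",
    "read_pdb",
    "get_residue",
]


class StructureError(Exception):
    """Base class for structure-model errors."""


class PDBParseError(StructureError):
    """Malformed PDB content (names the offending line where possible)."""


class EmptyStructureError(StructureError):
    """File contained no ATOM/HETATM coordinate records."""


class ResidueLookupError(StructureError, KeyError):
    """Requested (chain, residue number) not present in the model."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: label, element, Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        object.__setattr__(self, "coords", coords)


@dataclass
class ResidueRecord:
    """One residue: chain label, author number, 3-letter code, atoms by name."""

    chain_id: str
    res_num: int
    res_name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    def atom_coords(self, name: str) -> np.ndarray:
        try:
            return self.atoms[name].coords
        except KeyError:
            raise StructureError(
                f"residue {self.chain_id}/{self.res_name}{self.res_num} "
                f"is missing atom {name!r}"
            ) from None

    def has_atoms(self, *names: str) -> bool:
        return all(n in self.atoms for n in names)


@dataclass
class StructureModel:
    """Ordered residue collection for one structure (first model only)."""

    structure_id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    source_path: str = ""
    ssbond_pairs: list[tuple[tuple[str, int], tuple[str, int]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        keys = [(r.chain_id, r.res_num) for r in self.residues]
        if len(keys) != len(set(keys)):
            raise StructureError("duplicate (chain_id, res_num) in structure model")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def cysteines(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.res_name == "CYS"]


# PDB fixed columns: record name 1-6, x/y/z in 31-38, 39-46, 47-54.
_COORD_FIELD = re.compile(r"^\s*[-+]?(\d+\.?\d*|\.\d+)\s*$")


def _validate_coordinate_columns(path: str) -> None:
    """gemmi coerces malformed floats silently; enforce strict columns here."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}: line {lineno}: coordinate record shorter than 54 columns"
                )
            for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                if not _COORD_FIELD.match(line[lo:hi]):
                    raise PDBParseError(
                        f"{path}: line {lineno}: malformed {label} coordinate "
                        f"field {line[lo:hi]!r}"
                    )


def _resolve_altlocs(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; occupancy tie broken by altloc tag, A before B."""
    def key(a: gemmi.Atom) -> tuple[float, str]:
        tag = a.altloc if a.altloc != "\0" else ""
        return (-a.occ, tag)

    return sorted(atoms, key=key)[0]


def read_pdb(path: str, structure_id: str | None = None) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        PDB file in fixed-column format. Must contain at least one
        ATOM/HETATM record.
    structure_id
        Identifier for the model; defaults to the file's HEADER id or the
        file stem.

    Raises
    ------
    OSError
        Unreadable file.
    PDBParseError
        Malformed coordinate columns (the message names the line number).
    EmptyStructureError
        No coordinate records.
    """
    _validate_coordinate_columns(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise PDBParseError(f"{path}: {exc}") from exc

    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records found")
    if len(st) > 1:
        warnings.warn(
            f"{path}: {len(st)} models present; reading the first model only",
            stacklevel=2,
        )

    residues: list[ResidueRecord] = []
    for chain in st[0]:
        for res in chain:
            rec = ResidueRecord(
                chain_id=chain.name, res_num=res.seqid.num, res_name=res.name.strip()
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                chosen = _resolve_altlocs(group)
                tag = chosen.altloc if chosen.altloc != "\0" else ""
                rec.atoms[name] = AtomRecord(
                    name=name,
                    element=chosen.element.name,
                    coords=np.array(
                        [chosen.pos.x, chosen.pos.y, chosen.pos.z], dtype=float
                    ),
                    altloc=tag,
                    occupancy=chosen.occ,
                )
            residues.append(rec)

    ssbonds = []
    for conn in st.connections:
        if conn.type == gemmi.ConnectionType.Disulf:
            p1 = (conn.partner1.chain_name, conn.partner1.res_id.seqid.num)
            p2 = (conn.partner2.chain_name, conn.partner2.res_id.seqid.num)
            ssbonds.append((p1, p2))

    sid = structure_id or (st.name.strip() if st.name.strip() else None)
    if sid is None:
        sid = re.sub(r"\.(pdb|ent)$", "", str(path).rsplit("/", 1)[-1], flags=re.I)
    return StructureModel(
        structure_id=sid, residues=residues, source_path=str(path),
        ssbond_pairs=ssbonds,
    )


def get_residue(model: StructureModel, chain_id: str, res_num: int) -> ResidueRecord:
    """Look up a residue by chain label and author number.

    Raises :class:`ResidueLookupError` listing the residue numbers available
    on that chain if nothing matches.
    """
    for res in model.residues:
        if res.chain_id == chain_id and res.res_num == res_num:
            return res
    available = [r.res_num for r in model.residues if r.chain_id == chain_id]
    raise ResidueLookupError(
        f"no residue {chain_id}/{res_num} in {model.structure_id}; "
        f"chain {chain_id!r} has residues {available if available else '(none)'}"
    )
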