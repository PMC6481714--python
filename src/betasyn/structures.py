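"""Atomic structure handling built on biotite's AtomArray.

``StructureModel`` is a thin wrapper that fixes the conventions the rest of
the package relies on: one model (first NMR model by default), alternate
locations resolved to highest occupancy, finite coordinates, and unique
residue numbers within a chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_1TO3 = {v: k for k, v in _3TO1.items()}


class StructureError(ValueError):
    pass


@dataclass
class StructureModel:
    """Parsed atomic coordinates (biotite AtomArray) with validation."""

    atoms: "object"  # biotite.structure.AtomArray

    def __post_init__(self) -> None:
        if self.atoms.array_length() == 0:
            raise StructureError("structure contains no atoms")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError("structure contains non-finite coordinates")
        for chain in np.unique(self.atoms.chain_id):
            mask = self.atoms.chain_id == chain
            rids = self.atoms.res_id[mask]
            names = self.atoms.res_name[mask]
            first_name: dict[int, str] = {}
            for rid, name in zip(rids, names):
                if rid in first_name and first_name[rid] != name:
                    raise StructureError(
                        f"chain {chain}: residue number {rid} used by "
                        f"{first_name[rid]} and {name}"
                    )
                first_name[int(rid)] = name

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        res_ids: np.ndarray,
        res_names: list[str],
        atom_names: list[str],
        coords: np.ndarray,
        chain_id: str = "A",
        elements: list[str] | None = None,
    ) -> "StructureModel":
        import biotite.structure as struc

        n = len(atom_names)
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(coords, dtype=float)
        arr.res_id = np.asarray(res_ids, dtype=int)
        arr.res_name = np.asarray(res_names, dtype="U5")
        arr.atom_name = np.asarray(atom_names, dtype="U6")
        arr.chain_id = np.full(n, chain_id, dtype="U4")
        if elements is None:
            elements = [name.strip()[0] for name in atom_names]
        arr.element = np.asarray(elements, dtype="U2")
        arr.hetero = np.zeros(n, dtype=bool)
        return cls(arr)

    # -- basic queries ----------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    def chains(self) -> list[str]:
        return [str(c) for c in np.unique(self.atoms.chain_id)]

    def residue_numbers(self, chain: str | None = None) -> np.ndarray:
        mask = np.ones(self.atoms.array_length(), dtype=bool)
        if chain is not None:
            mask = self.atoms.chain_id == chain
        return np.unique(self.atoms.res_id[mask])

    def residue_letters(self) -> dict[int, str]:
        """Map residue number -> one-letter code (first chain wins)."""
        out: dict[int, str] = {}
        for rid, name in zip(self.atoms.res_id, self.atoms.res_name):
            rid = int(rid)
            if rid not in out:
                out[rid] = _3TO1.get(str(name), "X")
        return out

    def ca_trace(self, warn_missing: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(residue numbers, CA coordinates) of the first chain."""
        chain = self.chains()[0]
        mask = (self.atoms.chain_id == chain) & (self.atoms.atom_name == "CA")
        res_ids = self.atoms.res_id[mask].astype(int)
        if warn_missing:
            all_res = set(self.residue_numbers(chain).tolist())
            missing = all_res - set(res_ids.tolist())
            if missing:
                warnings.warn(
                    f"{len(missing)} residue(s) without CA skipped", stacklevel=2
                )
        return res_ids, self.atoms.coord[mask]

    def atom_selection(
        self, res_id: int, atom_mode: str = "heavy", chain: str | None = None
    ) -> np.ndarray:
        """Coordinates of one residue's atoms in the requested mode.

        Modes: ``heavy`` (all non-H), ``CA``, ``CB`` (glycine falls back to
        CA with a warning), ``sidechain`` (non-backbone heavy atoms; glycine
        falls back to CA).
        """
        mask = self.atoms.res_id == res_id
        if chain is not None:
            mask &= self.atoms.chain_id == chain
        if not mask.any():
            raise StructureError(f"residue {res_id} absent"
                                 + (f" from chain {chain}" if chain else ""))
        names = self.atoms.atom_name[mask]
        elements = self.atoms.element[mask]
        coords = self.atoms.coord[mask]
        if atom_mode == "heavy":
            sel = elements != "H"
        elif atom_mode == "CA":
            sel = names == "CA"
        elif atom_mode == "CB":
            sel = names == "CB"
            if not sel.any():
                warnings.warn(
                    f"residue {res_id}: no CB (glycine?); falling back to CA",
                    stacklevel=2,
                )
                sel = names == "CA"
        elif atom_mode == "sidechain":
            sel = np.array(
                [n not in BACKBONE_ATOMS and e != "H" for n, e in zip(names, elements)]
            )
            if not sel.any():
                sel = names == "CA"
        else:
            raise StructureError(f"unknown atom_mode {atom_mode!r}")
        if not sel.any():
            raise StructureError(f"residue {res_id}: no atoms in mode {atom_mode!r}")
        return coords[sel]

    # -- geometry ---------------------------------------------------------
    def centroid(self) -> np.ndarray:
        return self.atoms.coord.astype(np.float64).mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Apply a rigid transform x -> R x + t, returning a new model."""
        new_atoms = self.atoms.copy()
        new_atoms.coord = self.atoms.coord @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(new_atoms)

    def with_chain_id(self, chain_id: str) -> "StructureModel":
        new_atoms = self.atoms.copy()
        new_atoms.chain_id = np.full(new_atoms.array_length(), chain_id, dtype="U4")
        return StructureModel(new_atoms)

    # -- I/O --------------------------------------------------------------
    def write_pdb(self, path: str | Path) -> None:
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile()
        f.set_structure(self.atoms)
        f.write(str(path))

    def write_cif(self, path: str | Path) -> None:
        import biotite.structure.io.pdbx as pdbx

        f = pdbx.CIFFile()
        pdbx.set_structure(f, self.atoms)
        f.write(str(path))


def read_structure(
    path: str | Path, format: str | None = None, model: int = 1
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    The first NMR model is used unless ``model`` says otherwise; alternate
    locations are resolved to the highest-occupancy conformer.  The format
    is inferred from the suffix when not given.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "pdb" if suffix in (".pdb", ".ent") else (
            "cif" if suffix in (".cif", ".mmcif") else None
        )
        if format is None:
            raise StructureError(f"cannot infer format of {path}; pass format=")
    format = format.lower()
    if format == "pdb":
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile.read(str(path))
        atoms = f.get_structure(model=model, altloc="occupancy")
    elif format in ("cif", "mmcif"):
        import biotite.structure.io.pdbx as pdbx

        f = pdbx.CIFFile.read(str(path))
        atoms = pdbx.get_structure(f, model=model, altloc="occupancy")
    else:
        raise StructureError(f"unknown structure format {format!r}")
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise StructureError(f"no (non-hetero) atoms in {path}")
    return StructureModel(atoms)


def one_to_three(letter: str) -> str:
    return _1TO3[letter]


def three_to_one(name: str) -> str:
    return _3TO1.get(name, "X")
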