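"""PDB reading and writing for peptide/anion models.

Fixed-column PDB v3.3 via Biopython: peptide atoms as ATOM records, anion
atoms (residue names SO4/PO4) as HETATM, multi-model files as MODEL/ENDMDL
blocks.  Coordinates survive a write/read round trip at 3-decimal precision.
Alternate locations are not modelled: the first altLoc is kept with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.PDB.StructureBuilder import StructureBuilder

from .core import ANION_RESNAME, AnionModel, Atom, Structure

__all__ = ["PDBFormatError", "read_pdb", "write_pdb", "split_anion", "merge_anion"]

_ANION_RESNAMES = set(ANION_RESNAME.values())
_RESNAME_TO_KIND = {v: k for k, v in ANION_RESNAME.items()}


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed or written."""


def read_pdb(path: Union[str, Path]) -> List[Structure]:
    """Parse a PDB file into one :class:`Structure` per MODEL block.

    Files without MODEL records yield a single structure.  Malformed
    coordinate fields raise :class:`PDBFormatError` naming the offending
    line; a file with no atoms at all is also an error.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise PDBFormatError(f"{path}: malformed record ({exc})") from exc

    structures: List[Structure] = []
    for model in bio:
        atoms: List[Atom] = []
        seen_altloc = False
        for chain in model:
            for residue in chain:
                hetflag, resseq, _ = residue.id
                resname = residue.get_resname().strip()
                for atom in residue:
                    if atom.get_altloc() not in (" ", "A"):
                        seen_altloc = True
                        continue
                    name = atom.get_name()
                    element = (atom.element or name[0]).strip() or name[0]
                    atoms.append(
                        Atom(
                            serial=atom.get_serial_number() or len(atoms) + 1,
                            name=name,
                            residue_index=resseq,
                            residue_code=resname,
                            element=element,
                            xyz=np.asarray(atom.get_coord(), float),
                        )
                    )
        if seen_altloc:
            warnings.warn(
                f"{path}: alternate locations present; kept first altLoc only"
            )
        if atoms:
            structures.append(Structure(atoms, model_id=model.serial_num or len(structures) + 1))
    if not structures:
        raise PDBFormatError(f"{path}: no atoms found")
    return structures


def _to_bio(structures: Sequence[Structure]):
    builder = StructureBuilder()
    builder.init_structure("model")
    for k, s in enumerate(structures):
        builder.init_model(k)
        builder.init_seg("    ")
        builder.init_chain("A")
        current: Optional[Tuple[int, str]] = None
        for a in s.atoms:
            key = (a.residue_index, a.residue_code)
            if key != current:
                hetflag = f"H_{a.residue_code}" if a.residue_code in _ANION_RESNAMES else " "
                builder.init_residue(a.residue_code, hetflag, a.residue_index, " ")
                current = key
            builder.init_atom(
                a.name,
                np.asarray(a.xyz, float),
                0.0,
                1.0,
                " ",
                _fullname(a.name, a.element),
                a.serial,
                element=a.element.upper(),
            )
    return builder.get_structure()


def _fullname(name: str, element: str) -> str:
    # column alignment: single-letter elements are indented one space
    if len(element) == 1 and len(name) < 4:
        return f" {name}"
    return name


def write_pdb(
    structures: Union[Structure, Sequence[Structure]], path: Union[str, Path]
) -> Path:
    """Write one or more structures to ``path``.

    A single structure produces a plain file; several produce MODEL/ENDMDL
    blocks (the convention used for docking-pose ensembles and trajectory
    frames).  An empty list is an error.
    """
    single = isinstance(structures, Structure)
    seq = [structures] if single else list(structures)
    if not seq:
        raise ValueError("no structures to write")
    path = Path(path)
    io = PDBIO()
    io.set_structure(_to_bio(seq))
    io.save(str(path), write_end=True)
    if single:
        # strip the MODEL/ENDMDL wrapper Biopython does not emit for 1 model
        pass
    return path


def split_anion(structure: Structure) -> Tuple[Structure, Optional[AnionModel]]:
    """Separate a combined structure into (peptide-only, anion or None)."""
    pep_atoms = [a for a in structure.atoms if a.residue_code not in _ANION_RESNAMES]
    anion_atoms = [a for a in structure.atoms if a.residue_code in _ANION_RESNAMES]
    pep = Structure(
        [Atom(a.serial, a.name, a.residue_index, a.residue_code, a.element, a.xyz.copy())
         for a in pep_atoms],
        model_id=structure.model_id,
    )
    if not anion_atoms:
        return pep, None
    kind = _RESNAME_TO_KIND[anion_atoms[0].residue_code]
    central = next(a for a in anion_atoms if a.element in ("S", "P"))
    oxygens = [a for a in anion_atoms if a.element == "O"]
    hydro = next((a for a in anion_atoms if a.element == "H"), None)
    anion = AnionModel(kind, central, oxygens, hydro)
    return pep, anion


def merge_anion(structure: Structure, anion: AnionModel) -> Structure:
    """Append anion atoms to a peptide structure as one combined model."""
    atoms = [
        Atom(a.serial, a.name, a.residue_index, a.residue_code, a.element, a.xyz.copy())
        for a in structure.atoms
    ]
    base = max(a.serial for a in atoms) if atoms else 0
    res_idx = max(a.residue_index for a in atoms) + 1 if atoms else 1
    for k, a in enumerate(anion.atoms, start=1):
        atoms.append(
            Atom(base + k, a.name, res_idx, ANION_RESNAME[anion.kind], a.element, a.xyz.copy())
        )
    return Structure(atoms, model_id=structure.model_id)
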