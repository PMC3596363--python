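"""Peptide backbone construction from sequence plus per-residue torsions.

Chains are grown by sequential internal-coordinate extension (NeRF-style)
using fixed ideal bond lengths and angles, so re-measuring torsions from the
built coordinates recovers the inputs essentially exactly.  Only backbone
atoms plus amide H, alpha-H and C-beta are placed: every interaction this
package analyses involves main-chain atoms of the recognition motif only.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .core import (
    ANION_BOND,
    ANION_CENTRAL,
    ANION_RESNAME,
    AnionModel,
    Atom,
    BackboneDihedrals,
    PeptideModel,
    ResidueSpec,
    Structure,
    place_atom,
)

__all__ = [
    "IDEAL_GEOMETRY",
    "peptide_catalog",
    "get_peptide",
    "motif_residues_for",
    "native_dihedrals",
    "model_dihedrals",
    "build_backbone",
    "make_model",
    "truncate_to_short",
    "build_anion",
]

#: Ideal backbone geometry (Engh-Huber-style): bond lengths in A, angles in deg.
IDEAL_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C=O": 1.231,
    "N-H": 1.01,
    "CA-HA": 1.09,
    "CA-CB": 1.53,
    "CH3-C": 1.508,  # acetyl methyl to carbonyl carbon
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "C-N-H": 119.5,
    "N-CA-CB": 109.47,
    "N-CA-HA": 109.47,
}

# Improper torsion C(i)-N(i)-CA(i)-X fixing the tetrahedral substituents of
# C-alpha.  -120 deg places C-beta for an L-residue; +120 the alpha hydrogen
# (values match CCD ideal residue templates).
_CB_IMPROPER = -120.0
_HA_IMPROPER = 120.0

_HELIX_PHI_PSI = (-57.0, -47.0)
_EXTENDED_PHI_PSI = (180.0, 180.0)


# ---------------------------------------------------------------------------
# packaged peptide catalog
# ---------------------------------------------------------------------------


def _load_catalog() -> dict:
    text = (
        importlib.resources.files("cannmotif")
        .joinpath("data/peptides.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


_CATALOG = _load_catalog()


def peptide_catalog() -> List[str]:
    """Ids of all shipped peptide designs (long and short)."""
    return list(_CATALOG["peptides"]) + list(_CATALOG["short_peptides"])


def _parent_id(peptide_id: str) -> Tuple[str, bool]:
    """(long-form id, is_short) for any catalog id."""
    if peptide_id in _CATALOG["peptides"]:
        return peptide_id, False
    if peptide_id in _CATALOG["short_peptides"]:
        return _CATALOG["short_peptides"][peptide_id], True
    raise KeyError(
        f"unknown peptide id {peptide_id!r}; known: {', '.join(peptide_catalog())}"
    )


def get_peptide(peptide_id: str) -> PeptideModel:
    """Look up a shipped design and return its :class:`PeptideModel`."""
    parent, short = _parent_id(peptide_id)
    entry = _CATALOG["peptides"][parent]
    seq = list(entry["motif_sequence"])
    if short:
        seq = seq + [_CATALOG["anchor_helix"]["sequence"][0]]  # Ala5
    else:
        seq = seq + list(_CATALOG["anchor_helix"]["sequence"])
    return PeptideModel(
        id=peptide_id,
        residues=[ResidueSpec(c) for c in seq],
        n_cap="acetyl",
        c_cap="amide",
    )


def motif_residues_for(peptide_id: str) -> Tuple[int, int, int]:
    """1-based (Calpha(-1), N(0), N(+1)) residue indices of the motif."""
    _parent_id(peptide_id)  # validate
    return tuple(_CATALOG["motif_residues"])  # type: ignore[return-value]


def native_dihedrals(peptide_id: str) -> List[Tuple[float, float]]:
    """Crystal-derived (phi, psi) of the four motif-segment residues."""
    parent, _ = _parent_id(peptide_id)
    return [tuple(pair) for pair in _CATALOG["peptides"][parent]["native"]]


def model_dihedrals(
    peptide_id: str,
    variant: str,
    experimental: Optional[List[Tuple[float, float]]] = None,
) -> BackboneDihedrals:
    """Torsion recipe for a catalog design.

    ``native`` uses the crystal-derived motif torsions, ``extended`` sets the
    first four residues to (180, 180), and ``experimental_like`` takes
    user-supplied motif torsions (e.g. NMR-derived values).  Residues after
    the motif segment are right-handed alpha-helical at (-57, -47).
    """
    peptide = get_peptide(peptide_id)
    n = len(peptide)
    if variant == "native":
        head = native_dihedrals(peptide_id)
    elif variant == "extended":
        head = [_EXTENDED_PHI_PSI] * 4
    elif variant == "experimental_like":
        if experimental is None or len(experimental) != 4:
            raise ValueError(
                "experimental_like requires four user-supplied (phi, psi) pairs"
            )
        head = [tuple(p) for p in experimental]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    pairs = head + [_HELIX_PHI_PSI] * (n - 4)
    return BackboneDihedrals(
        phi=[p for p, _ in pairs], psi=[s for _, s in pairs]
    )


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------


def _tetrahedral_substituents(
    n_xyz: np.ndarray, ca_xyz: np.ndarray, c_xyz: np.ndarray
) -> Dict[str, np.ndarray]:
    """Positions for CB-like and HA-like substituents on C-alpha."""
    g = IDEAL_GEOMETRY
    cb = place_atom(c_xyz, n_xyz, ca_xyz, g["CA-CB"], g["N-CA-CB"], _CB_IMPROPER)
    ha = place_atom(c_xyz, n_xyz, ca_xyz, g["CA-HA"], g["N-CA-HA"], _HA_IMPROPER)
    return {"cb_site": cb, "ha_site": ha}


def build_backbone(peptide: PeptideModel, dihedrals: BackboneDihedrals) -> Structure:
    """Build a 3-D model of ``peptide`` at the given backbone torsions.

    The acetyl cap (residue index 0) defines phi of residue 1 and the
    C-terminal amide cap (index n+1) defines psi of residue n; for free
    termini those torsions must be ``None``.  Amide H is placed on every
    non-proline backbone N, alpha hydrogens on C-alpha (two for Gly, none
    for Aib, which gets its two methyl carbons instead), and C-beta for all
    non-glycine residues.  Side chains beyond C-beta are not built.
    """
    n = len(peptide)
    if len(dihedrals) != n:
        raise ValueError("dihedral table length does not match peptide length")
    g = IDEAL_GEOMETRY

    for i in range(1, n + 1):
        phi, psi, omega = dihedrals.residue(i)
        if phi is None and not (i == 1 and peptide.n_cap == "free"):
            raise ValueError(f"phi undefined for residue {i}")
        if psi is None and not (i == n and peptide.c_cap == "free"):
            raise ValueError(f"psi undefined for residue {i}")
        if omega is None:
            raise ValueError(f"omega undefined for residue {i}")

    atoms: List[Atom] = []
    serial = [0]

    def add(name: str, res_idx: int, res_code: str, xyz: np.ndarray) -> Atom:
        serial[0] += 1
        element = "C" if name.startswith("C") else name[0]
        a = Atom(serial[0], name, res_idx, res_code, element, np.asarray(xyz, float))
        atoms.append(a)
        return a

    # --- seed the chain ---------------------------------------------------
    if peptide.n_cap == "acetyl":
        ch3 = np.zeros(3)
        c_prev = np.array([g["CH3-C"], 0.0, 0.0])
        th = math.radians(g["CA-C-N"])
        n1 = c_prev + g["C-N"] * np.array([math.cos(th), math.sin(th), 0.0])
        add("CH3", 0, "ACE", ch3)
        cap_c = add("C", 0, "ACE", c_prev)
        prev_c, prev_ca_like = c_prev, ch3
        cap_o_pending = ("ACE", 0, n1)
    else:
        # free N-terminus: seed with N1, CA1 and grow from there
        n1 = np.zeros(3)
        prev_c = None
        prev_ca_like = None
        cap_o_pending = None

    prev_o_ref: Optional[Tuple[int, str, np.ndarray, np.ndarray]] = None
    n_pos = n1
    prev_n = None

    for i in range(1, n + 1):
        code = peptide.residues[i - 1].code
        phi, psi, omega = dihedrals.residue(i)

        if i == 1:
            if peptide.n_cap == "acetyl":
                n_i = n_pos
            else:
                n_i = np.zeros(3)
        else:
            # N(i) from psi(i-1): torsion N(i-1)-CA(i-1)-C(i-1)-N(i)
            n_i = place_atom(prev_n, prev_ca, prev_c, g["C-N"], g["CA-C-N"], psi_prev)

        if i == 1 and peptide.n_cap == "free":
            th = math.radians(g["C-N-CA"])
            ca_i = n_i + g["N-CA"] * np.array([1.0, 0.0, 0.0])
        else:
            # CA(i) from omega(i): torsion CA(i-1)/CH3 - C(i-1) - N(i) - CA(i)
            ca_i = place_atom(prev_ca_like, prev_c, n_i, g["N-CA"], g["C-N-CA"], omega)

        if i == 1 and peptide.n_cap == "free":
            # phi undefined: place C in an arbitrary plane
            th = math.radians(g["N-CA-C"])
            c_i = ca_i + g["CA-C"] * np.array([math.cos(math.pi - th), math.sin(math.pi - th), 0.0])
        else:
            # C(i) from phi(i): torsion C(i-1)-N(i)-CA(i)-C(i)
            c_i = place_atom(prev_c, n_i, ca_i, g["CA-C"], g["N-CA-C"], phi)

        na = add("N", i, code, n_i)
        # amide H: planar, anti to CA(i) across the C(i-1)-N(i) bond
        if code != "PRO" and not (i == 1 and peptide.n_cap == "free"):
            h = place_atom(ca_i, prev_c, n_i, g["N-H"], g["C-N-H"], 180.0)
            add("H", i, code, h)
        add("CA", i, code, ca_i)

        sub = _tetrahedral_substituents(n_i, ca_i, c_i)
        if code == "GLY":
            ha2 = place_atom(c_i, n_i, ca_i, g["CA-HA"], g["N-CA-HA"], _CB_IMPROPER)
            add("HA2", i, code, ha2)
            add("HA3", i, code, sub["ha_site"])
        elif code == "AIB":
            add("CB1", i, code, sub["cb_site"])
            # second methyl at the HA site, carbon bond length
            cb2 = place_atom(c_i, n_i, ca_i, g["CA-CB"], g["N-CA-CB"], _HA_IMPROPER)
            add("CB2", i, code, cb2)
        else:
            add("CB", i, code, sub["cb_site"])
            add("HA", i, code, sub["ha_site"])

        add("C", i, code, c_i)

        # carbonyl O of the acetyl cap: planar, anti to N1 (placeable now)
        if cap_o_pending is not None:
            _, _, n_ref = cap_o_pending
            o_cap = place_atom(n_ref, ch3, prev_c, g["C=O"], g["CA-C-O"], 180.0)
            # insert right after the cap C so atom order stays chain-like
            serial_o = cap_c.serial + 1
            for a in atoms:
                if a.serial >= serial_o:
                    a.serial += 1
            atoms.insert(
                atoms.index(cap_c) + 1,
                Atom(serial_o, "O", 0, "ACE", "O", o_cap),
            )
            serial[0] += 1
            cap_o_pending = None

        # carbonyl O of residue i-1: planar, anti to N(i)
        if prev_o_ref is not None:
            idx_prev, code_prev, ca_p, c_p = prev_o_ref
            o_prev = place_atom(n_i, ca_p, c_p, g["C=O"], g["CA-C-O"], 180.0)
            add("O", idx_prev, code_prev, o_prev)
        prev_o_ref = (i, code, ca_i, c_i)

        prev_n, prev_ca, prev_c = n_i, ca_i, c_i
        prev_ca_like = ca_i
        psi_prev = psi

    # --- C-terminus -------------------------------------------------------
    psi_last = dihedrals.psi[n - 1]
    if peptide.c_cap == "amide":
        nt = place_atom(prev_n, prev_ca, prev_c, g["C-N"], g["CA-C-N"], psi_last)
        o_last = place_atom(nt, prev_ca, prev_c, g["C=O"], g["CA-C-O"], 180.0)
        add("O", n, peptide.residues[-1].code, o_last)
        add("N", n + 1, "NH2", nt)
        h1 = place_atom(prev_ca, prev_c, nt, g["N-H"], g["C-N-H"], 180.0)
        h2 = place_atom(prev_ca, prev_c, nt, g["N-H"], g["C-N-H"], 0.0)
        add("HN1", n + 1, "NH2", h1)
        add("HN2", n + 1, "NH2", h2)
    else:
        # free acid: place O anti to N of the (absent) next residue using psi
        # if defined, else in the N-CA-C plane
        ref_tor = (psi_last + 180.0) if psi_last is not None else 0.0
        o_last = place_atom(prev_n, prev_ca, prev_c, g["C=O"], g["CA-C-O"], ref_tor)
        add("O", n, peptide.residues[-1].code, o_last)

    # order atoms per residue in conventional order, serials sequential
    atoms.sort(key=lambda a: (a.residue_index, a.serial))
    for k, a in enumerate(atoms, start=1):
        a.serial = k
    return Structure(atoms)


def make_model(
    peptide_id: str,
    variant: str,
    experimental: Optional[List[Tuple[float, float]]] = None,
) -> Structure:
    """Build one of the shipped designs at a named torsion recipe.

    Short designs (SCPS*) are built by constructing the 18-residue parent
    and truncating its anchor helix, mirroring how they were designed.
    """
    _, short = _parent_id(peptide_id)
    if short:
        parent, _ = _parent_id(peptide_id)
        parent_structure = make_model(parent, variant, experimental)
        parent_peptide = get_peptide(parent)
        structure, _pep = truncate_to_short(parent_structure, parent_peptide)
        return structure
    peptide = get_peptide(peptide_id)
    dihedrals = model_dihedrals(peptide_id, variant, experimental)
    return build_backbone(peptide, dihedrals)


def truncate_to_short(
    structure: Structure, peptide: PeptideModel, keep: int = 5
) -> Tuple[Structure, PeptideModel]:
    """Cut a built model down to its first ``keep`` residues plus caps.

    Coordinates of kept atoms are unchanged; the backbone N of residue
    ``keep + 1`` becomes the C-terminal amide nitrogen (so psi of the last
    kept residue is preserved exactly) and two amide hydrogens are added.
    """
    n = len(peptide)
    if n < keep:
        raise ValueError(f"peptide has {n} residues; need at least {keep}")
    if n == keep:
        return structure.copy(), peptide

    g = IDEAL_GEOMETRY
    kept = [
        a
        for a in structure.atoms
        if a.residue_index <= keep and a.residue_code != "NH2"
    ]
    atoms = [
        Atom(a.serial, a.name, a.residue_index, a.residue_code, a.element, a.xyz.copy())
        for a in kept
    ]
    nt_xyz = structure.atom(keep + 1, "N").xyz.copy()
    ca = structure.atom(keep, "CA").xyz
    c = structure.atom(keep, "C").xyz
    h1 = place_atom(ca, c, nt_xyz, g["N-H"], g["C-N-H"], 180.0)
    h2 = place_atom(ca, c, nt_xyz, g["N-H"], g["C-N-H"], 0.0)
    code = "NH2"
    last = max(a.serial for a in atoms)
    atoms.append(Atom(last + 1, "N", keep + 1, code, "N", nt_xyz))
    atoms.append(Atom(last + 2, "HN1", keep + 1, code, "H", h1))
    atoms.append(Atom(last + 3, "HN2", keep + 1, code, "H", h2))
    short_id = peptide.id if peptide.id.startswith("S") else "S" + peptide.id
    short_pep = PeptideModel(
        id=short_id,
        residues=peptide.residues[:keep],
        n_cap=peptide.n_cap,
        c_cap="amide",
    )
    return Structure(atoms), short_pep


# ---------------------------------------------------------------------------
# anion construction
# ---------------------------------------------------------------------------

#: Unit tetrahedron vertex directions.
_TET = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / math.sqrt(3.0)

_OH_BOND = 0.96


def build_anion(kind: str, residue_index: int = 9001) -> AnionModel:
    """Ideal tetrahedral sulfate or hydrogen-phosphate centred at the origin.

    Sulfate: S-O 1.49 A; phosphate: P-O 1.54 A with one hydroxyl hydrogen
    (O-H 0.96 A) pointing radially outward on O4.
    """
    if kind not in ANION_BOND:
        raise ValueError(f"unknown anion kind {kind!r}; use sulfate or phosphate")
    bond = ANION_BOND[kind]
    central_el = ANION_CENTRAL[kind]
    resname = ANION_RESNAME[kind]
    central = Atom(1, central_el, residue_index, resname, central_el, np.zeros(3))
    oxygens = [
        Atom(k + 2, f"O{k + 1}", residue_index, resname, "O", bond * _TET[k])
        for k in range(4)
    ]
    hydroxyl = None
    if kind == "phosphate":
        o4 = oxygens[3].xyz
        h_xyz = o4 + _OH_BOND * (o4 / np.linalg.norm(o4))
        hydroxyl = Atom(6, "HO4", residue_index, resname, "H", h_xyz)
    return AnionModel(kind, central, oxygens, hydroxyl)
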