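"""Domain types and 3-D geometry primitives shared by all analysis stages.

The package models short designed peptides (standard residues plus the
helix-promoting Aib, alpha-aminoisobutyric acid) interacting with tetrahedral
oxyanions (sulfate SO4^2-, hydrogen phosphate HPO4^2-).  Everything downstream
consumes the lightweight :class:`Structure` container defined here; distances
are in angstroms, angles and torsions in degrees on (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "ALLOWED_RESIDUES",
    "CAP_CODES",
    "ResidueSpec",
    "PeptideModel",
    "BackboneDihedrals",
    "Atom",
    "Structure",
    "AnionModel",
    "HBondContact",
    "PointChargeSet",
    "GeometryError",
    "dihedral_angle",
    "bond_angle",
    "place_atom",
    "wrap_angle",
    "angle_close",
]

#: Twenty standard three-letter codes.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)

#: Residues a peptide may contain: the 20 standard ones plus Aib.
ALLOWED_RESIDUES = STANDARD_RESIDUES | {"AIB"}

#: Pseudo-residue codes used for terminal blocking groups.
CAP_CODES = frozenset({"ACE", "NH2"})


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear points, coincident atoms)."""


# ---------------------------------------------------------------------------
# peptide description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueSpec:
    """One residue of a peptide: three-letter code plus alpha-H bookkeeping.

    Aib carries two methyl groups on C-alpha and therefore no alpha hydrogen;
    every other allowed residue has at least one.
    """

    code: str

    def __post_init__(self) -> None:
        if self.code not in ALLOWED_RESIDUES:
            raise ValueError(f"unknown residue code {self.code!r}")

    @property
    def has_alpha_hydrogen(self) -> bool:
        return self.code != "AIB"


@dataclass
class PeptideModel:
    """A designed peptide: id, ordered residues, and terminal capping state."""

    id: str
    residues: List[ResidueSpec]
    n_cap: str = "acetyl"  # {acetyl, free}
    c_cap: str = "amide"  # {amide, free}

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")
        if self.n_cap not in ("acetyl", "free"):
            raise ValueError(f"unknown n_cap {self.n_cap!r}")
        if self.c_cap not in ("amide", "free"):
            raise ValueError(f"unknown c_cap {self.c_cap!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> List[str]:
        return [r.code for r in self.residues]


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees onto (-180, 180]."""
    wrapped = math.fmod(angle, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


def angle_close(a: float, b: float, tol: float) -> bool:
    """Circular closeness test: 180 and -180 compare equal."""
    d = abs(wrap_angle(a - b))
    return min(d, 360.0 - d) <= tol


@dataclass
class BackboneDihedrals:
    """Per-residue backbone torsions (phi, psi, omega) in degrees.

    Entries are ``None`` where a torsion is undefined (phi of the first
    residue of an uncapped chain, psi of the last).  All defined values
    live on (-180, 180].
    """

    phi: List[Optional[float]]
    psi: List[Optional[float]]
    omega: List[Optional[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.phi)
        if len(self.psi) != n:
            raise ValueError("phi and psi lists must have equal length")
        if not self.omega:
            self.omega = [180.0] * n
        if len(self.omega) != n:
            raise ValueError("omega list length mismatch")
        for name in ("phi", "psi", "omega"):
            vals = getattr(self, name)
            setattr(
                self,
                name,
                [None if v is None else wrap_angle(float(v)) for v in vals],
            )

    def __len__(self) -> int:
        return len(self.phi)

    def residue(self, i: int) -> Tuple[Optional[float], Optional[float], Optional[float]]:
        """(phi, psi, omega) of 1-based residue ``i``."""
        return self.phi[i - 1], self.psi[i - 1], self.omega[i - 1]

    def close_to(self, other: "BackboneDihedrals", tol: float = 0.5) -> bool:
        if len(self) != len(other):
            return False
        for a, b in zip(self.phi + self.psi, other.phi + other.psi):
            if a is None or b is None:
                continue
            if not angle_close(a, b, tol):
                return False
        return True


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One atom record: serial, name, residue assignment, element, position (A)."""

    serial: int
    name: str
    residue_index: int
    residue_code: str
    element: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError("xyz must be a 3-vector")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Structure:
    """Ordered atom records for one model (peptide, optionally with an anion).

    ``residue_index`` 0 denotes the N-acetyl cap (ACE) and ``n_residues + 1``
    the C-terminal amide cap (NH2); anion atoms carry residue codes SO4/PO4.
    """

    atoms: List[Atom]
    model_id: int = 1

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.residue_index, a.residue_code, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in model {self.model_id}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure(
            [
                Atom(a.serial, a.name, a.residue_index, a.residue_code, a.element, a.xyz.copy())
                for a in self.atoms
            ],
            model_id=self.model_id,
        )

    # -- lookup helpers ----------------------------------------------------

    def atom(self, residue_index: int, name: str) -> Atom:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in residue {residue_index}")

    def has_atom(self, residue_index: int, name: str) -> bool:
        try:
            self.atom(residue_index, name)
            return True
        except KeyError:
            return False

    def residue_indices(self) -> List[int]:
        out: List[int] = []
        for a in self.atoms:
            if a.residue_index not in out:
                out.append(a.residue_index)
        return out

    def residue_code(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_code
        raise KeyError(f"no residue {residue_index}")

    def peptide_residue_indices(self) -> List[int]:
        """Indices of real residues (caps and hetero groups excluded)."""
        return [
            i
            for i in self.residue_indices()
            if self.residue_code(i) in ALLOWED_RESIDUES
        ]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid transform: x -> R x + t applied to every atom."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for a in out.atoms:
            a.xyz = R @ a.xyz + t
        return out


# ideal central-atom-to-oxygen bond lengths for generated anions (A)
ANION_BOND = {"sulfate": 1.49, "phosphate": 1.54}
ANION_CENTRAL = {"sulfate": "S", "phosphate": "P"}
ANION_RESNAME = {"sulfate": "SO4", "phosphate": "PO4"}


@dataclass
class AnionModel:
    """A tetrahedral oxyanion: central S/P atom, four oxygens, optional O-H.

    Hydrogen phosphate carries one hydroxyl hydrogen; sulfate none.
    """

    kind: str
    central: Atom
    oxygens: List[Atom]
    hydroxyl_h: Optional[Atom] = None

    def __post_init__(self) -> None:
        if self.kind not in ("sulfate", "phosphate"):
            raise ValueError(f"unknown anion kind {self.kind!r}")
        if len(self.oxygens) != 4:
            raise ValueError("anion must have exactly 4 oxygens")
        if self.kind == "sulfate" and self.hydroxyl_h is not None:
            raise ValueError("sulfate carries no hydroxyl hydrogen")

    @property
    def atoms(self) -> List[Atom]:
        out = [self.central] + list(self.oxygens)
        if self.hydroxyl_h is not None:
            out.append(self.hydroxyl_h)
        return out

    def copy(self) -> "AnionModel":
        def cp(a: Atom) -> Atom:
            return Atom(a.serial, a.name, a.residue_index, a.residue_code, a.element, a.xyz.copy())

        return AnionModel(
            self.kind,
            cp(self.central),
            [cp(o) for o in self.oxygens],
            None if self.hydroxyl_h is None else cp(self.hydroxyl_h),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnionModel":
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for a in out.atoms:
            a.xyz[:] = R @ a.xyz + t
        return out


@dataclass
class HBondContact:
    """One donor-H...acceptor-O contact with its geometry and optional energy."""

    donor_kind: str  # {"Calpha", "N"}
    donor_residue: int
    donor_heavy: str  # atom name of X (CA or N)
    hydrogen: str  # atom name of H
    acceptor_o: str  # anion oxygen atom name
    d_ho: float
    angle_xho: float
    energy: Optional[float] = None
    hclass: str = "geometric_only"  # {"weak", "strong", "geometric_only"}

    def __post_init__(self) -> None:
        if self.donor_kind not in ("Calpha", "N"):
            raise ValueError(f"unknown donor kind {self.donor_kind!r}")
        if self.d_ho <= 0:
            raise ValueError("H...O distance must be positive")
        if not (0.0 <= self.angle_xho <= 180.0):
            raise ValueError("X-H...O angle must lie in [0, 180]")

    @property
    def donor_id(self) -> str:
        return f"{self.donor_kind}:{self.donor_residue}"


@dataclass(frozen=True)
class PointChargeSet:
    """Partial charges (e) and scale factor for the Coulomb H-bond energy.

    The four-term sum couples the anion's central atom and acceptor oxygen
    with the donor hydrogen and donor heavy atom; amide and alpha-carbon
    donors carry different charges.
    """

    scale: float = 332.0  # kcal*A/(mol*e^2)
    q_s: float = 1.6
    q_o: float = -0.9
    q_h_amide: float = 0.3
    q_n: float = -0.5
    q_h_alpha: float = 0.06
    q_calpha: float = -0.1

    def donor_charges(self, donor_kind: str) -> Tuple[float, float]:
        """(q_H, q_X) for the given donor kind."""
        if donor_kind == "N":
            return self.q_h_amide, self.q_n
        if donor_kind == "Calpha":
            return self.q_h_alpha, self.q_calpha
        raise ValueError(f"unknown donor kind {donor_kind!r}")


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

_COLLINEAR_TOL = 1e-8


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees on (-180, 180].

    IUPAC sign convention: right-handed, cis (eclipsed) = 0.  Raises
    :class:`GeometryError` when three consecutive points are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.dot(n1, n1) < _COLLINEAR_TOL or np.dot(n2, n2) < _COLLINEAR_TOL:
        raise GeometryError("collinear points: torsion undefined")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return wrap_angle(math.degrees(math.atan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 at the middle point, in degrees [0, 180]."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("coincident points: angle undefined")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to points a-b-c.

    D sits at ``bond`` angstroms from ``c``, making bond angle
    ``angle`` (degrees) at c with b, and torsion a-b-c-D equal to
    ``torsion`` (degrees, IUPAC sign).  This is the elementary step of
    sequential natural-extension chain construction.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_u)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        raise GeometryError("reference points collinear: cannot place atom")
    n_u = n / norm_n
    m_u = np.cross(n_u, bc_u)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc_u + d_local[1] * m_u + d_local[2] * n_u
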