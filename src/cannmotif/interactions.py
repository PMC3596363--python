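"""Hydrogen-bond detection and scoring of anion-peptide contacts.

The recognition motif offers three backbone donors to a bound oxyanion:
the C-alpha H of the residue preceding the helix (Calpha(-1)) and the amide
N-H of the following two residues (N(0), N(+1)).  A contact is accepted
geometrically when the H...O distance is within the donor-specific cutoff
(3.0 A for C-alpha donors, 2.7 A for amide donors, both inclusive) and the
X-H...O angle is at least 90 degrees.

Each accepted contact can additionally be scored with a four-term Coulomb
point-charge energy (kcal/mol) coupling the anion's central atom and the
acceptor oxygen with the donor hydrogen and heavy atom; energies at or below
-1.0 kcal/mol count as strong hydrogen bonds, those between -0.5 and -1.0 as
weak.

The canonical recognition pattern has exactly two anion oxygens engaged: one
bridging Calpha(-1)-H and N(0)-H simultaneously, the other contacting
N(+1)-H alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import (
    AnionModel,
    Atom,
    GeometryError,
    HBondContact,
    PointChargeSet,
    Structure,
    bond_angle,
)

__all__ = [
    "HBondCriteria",
    "MotifInteraction",
    "detect_hbond",
    "hbond_energy",
    "classify_energy",
    "map_anion_contacts",
    "is_canonical_pattern",
    "contacts_to_frame",
]

#: Maximum covalent X-H bond length accepted for a donor pair (A).
_COVALENT_XH_MAX = 1.2


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance thresholds, inclusive at the boundaries.

    The amide-donor distance cutoff is configurable because published
    conventions vary between 2.7 A and the 3.0 A used for survey work on
    crystal structures; 2.7 A is the default here.
    """

    d_max_calpha: float = 3.0
    d_max_amide: float = 2.7
    angle_min: float = 90.0
    weak_energy: float = -0.5
    strong_energy: float = -1.0

    def d_max(self, donor_kind: str) -> float:
        return self.d_max_calpha if donor_kind == "Calpha" else self.d_max_amide


DEFAULT_CRITERIA = HBondCriteria()


@dataclass
class MotifInteraction:
    """All motif-donor contacts of one pose, with the canonical-pattern flag."""

    contacts: List[HBondContact]
    oxygen_map: Dict[str, Set[str]]
    canonical: bool

    @property
    def n_interacting_oxygens(self) -> int:
        return len(self.oxygen_map)

    def donor_contact(self, donor_kind: str, donor_residue: int) -> Optional[HBondContact]:
        """Best (shortest) contact of the given donor, or None."""
        best = None
        for c in self.contacts:
            if c.donor_kind == donor_kind and c.donor_residue == donor_residue:
                if best is None or c.d_ho < best.d_ho:
                    best = c
        return best

    def to_dict(self) -> dict:
        return {
            "canonical": self.canonical,
            "n_interacting_oxygens": self.n_interacting_oxygens,
            "oxygen_map": {k: sorted(v) for k, v in self.oxygen_map.items()},
            "contacts": [
                {
                    "donor_kind": c.donor_kind,
                    "donor_residue": c.donor_residue,
                    "hydrogen": c.hydrogen,
                    "acceptor_o": c.acceptor_o,
                    "d_ho": round(c.d_ho, 4),
                    "angle_xho": round(c.angle_xho, 3),
                    "energy": None if c.energy is None else round(c.energy, 4),
                    "hclass": c.hclass,
                }
                for c in self.contacts
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def detect_hbond(
    donor_heavy: Atom,
    hydrogen: Atom,
    acceptor_o: Atom,
    donor_kind: str,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> Optional[HBondContact]:
    """Geometric H-bond test for one donor/acceptor pair.

    Returns a :class:`HBondContact` when the H...O distance and X-H...O
    angle criteria are met (inclusive), else ``None``.  The hydrogen must be
    covalently bonded to the donor heavy atom (< 1.2 A).
    """
    if donor_kind not in ("Calpha", "N"):
        raise ValueError(f"unknown donor kind {donor_kind!r}")
    d_xh = float(np.linalg.norm(hydrogen.xyz - donor_heavy.xyz))
    if d_xh >= _COVALENT_XH_MAX:
        raise ValueError(
            f"hydrogen {hydrogen.name} is {d_xh:.2f} A from donor "
            f"{donor_heavy.name}: not covalently bonded"
        )
    d_ho = float(np.linalg.norm(acceptor_o.xyz - hydrogen.xyz))
    # thresholds are inclusive; the epsilon keeps exact-boundary geometries
    # from flipping on floating-point noise
    if d_ho > criteria.d_max(donor_kind) + 1e-9:
        return None
    angle = bond_angle(donor_heavy.xyz, hydrogen.xyz, acceptor_o.xyz)
    if angle < criteria.angle_min - 1e-9:
        return None
    return HBondContact(
        donor_kind=donor_kind,
        donor_residue=donor_heavy.residue_index,
        donor_heavy=donor_heavy.name,
        hydrogen=hydrogen.name,
        acceptor_o=acceptor_o.name,
        d_ho=d_ho,
        angle_xho=angle,
    )


def hbond_energy(
    donor_kind: str,
    central_xyz,
    acceptor_xyz,
    hydrogen_xyz,
    heavy_xyz,
    charges: PointChargeSet = PointChargeSet(),
) -> float:
    """Four-term Coulomb energy of an S/P=O...H-X contact, kcal/mol.

    E = scale * (qS qH / r_SH + qS qX / r_SX + qO qH / r_OH + qO qX / r_OX)
    with X = N (amide donor) or C-alpha, using the donor-appropriate partial
    charges.  Coincident atoms raise :class:`GeometryError`.
    """
    q_h, q_x = charges.donor_charges(donor_kind)
    s, o, h, x = (np.asarray(p, float) for p in (central_xyz, acceptor_xyz, hydrogen_xyz, heavy_xyz))
    pairs = [
        (charges.q_s * q_h, np.linalg.norm(s - h)),
        (charges.q_s * q_x, np.linalg.norm(s - x)),
        (charges.q_o * q_h, np.linalg.norm(o - h)),
        (charges.q_o * q_x, np.linalg.norm(o - x)),
    ]
    total = 0.0
    for qq, r in pairs:
        if r <= 0.0 or r < 1e-6:
            raise GeometryError("coincident atoms in energy evaluation")
        total += qq / r
    return charges.scale * total


def classify_energy(
    energy: float, criteria: HBondCriteria = DEFAULT_CRITERIA
) -> str:
    """Label an H-bond energy: strong (E <= -1.0), weak (-1.0 < E <= -0.5), none."""
    if not np.isfinite(energy):
        raise ValueError("energy must be finite")
    if energy <= criteria.strong_energy:
        return "strong"
    if energy <= criteria.weak_energy:
        return "weak"
    return "none"


def _motif_donors(
    structure: Structure, motif_residues: Sequence[int]
) -> List[Tuple[str, Atom, List[Atom]]]:
    """(donor_kind, heavy atom, candidate hydrogens) for the three motif donors."""
    ca_res, n0_res, n1_res = motif_residues
    donors: List[Tuple[str, Atom, List[Atom]]] = []

    ca = structure.atom(ca_res, "CA")
    ha_names = [
        n for n in ("HA", "HA2", "HA3") if structure.has_atom(ca_res, n)
    ]
    if ha_names:
        donors.append(("Calpha", ca, [structure.atom(ca_res, n) for n in ha_names]))
    # Aib has no alpha hydrogen: the C-alpha donor is simply absent then.

    for res in (n0_res, n1_res):
        n_atom = structure.atom(res, "N")
        if not structure.has_atom(res, "H"):
            raise ValueError(
                f"residue {res} has no amide hydrogen; build hydrogens first"
            )
        donors.append(("N", n_atom, [structure.atom(res, "H")]))
    return donors


def is_canonical_pattern(
    oxygen_map: Dict[str, Set[str]], motif_residues: Sequence[int]
) -> bool:
    """Canonical two-oxygen recognition pattern predicate.

    Exactly two oxygens carry contacts; one of them contacts BOTH the
    Calpha(-1)-H and N(0)-H donors, while the other contacts ONLY N(+1)-H.
    """
    if len(oxygen_map) != 2:
        return False
    ca_res, n0_res, n1_res = motif_residues
    bridge = {f"Calpha:{ca_res}", f"N:{n0_res}"}
    lone = {f"N:{n1_res}"}
    donor_sets = list(oxygen_map.values())
    for bridging, single in (donor_sets, donor_sets[::-1]):
        if bridge <= bridging and single == lone:
            return True
    return False


def map_anion_contacts(
    structure: Structure,
    anion: AnionModel,
    motif_residues: Sequence[int],
    criteria: HBondCriteria = DEFAULT_CRITERIA,
    charges: PointChargeSet = PointChargeSet(),
) -> MotifInteraction:
    """Evaluate all motif-donor/anion-oxygen pairs of one pose.

    Donors are Calpha(-1)-H (the nearer alpha hydrogen for glycine),
    N(0)-H and N(+1)-H; every one of the four anion oxygens is tried as an
    acceptor (the phosphate hydroxyl oxygen included).  Accepted contacts
    get the Coulomb energy and weak/strong label attached.
    """
    if len(motif_residues) != 3:
        raise ValueError("motif_residues must give three residue indices")
    donors = _motif_donors(structure, motif_residues)
    contacts: List[HBondContact] = []
    oxygen_map: Dict[str, Set[str]] = {}
    for oxy in anion.oxygens:
        for kind, heavy, hydrogens in donors:
            # glycine offers two alpha hydrogens: use the nearer one
            hyd = min(hydrogens, key=lambda h: np.linalg.norm(h.xyz - oxy.xyz))
            contact = detect_hbond(heavy, hyd, oxy, kind, criteria)
            if contact is None:
                continue
            energy = hbond_energy(
                kind, anion.central.xyz, oxy.xyz, hyd.xyz, heavy.xyz, charges
            )
            label = classify_energy(energy, criteria)
            contact.energy = energy
            contact.hclass = label if label != "none" else "geometric_only"
            contacts.append(contact)
            oxygen_map.setdefault(oxy.name, set()).add(contact.donor_id)
    canonical = is_canonical_pattern(oxygen_map, motif_residues)
    return MotifInteraction(contacts=contacts, oxygen_map=oxygen_map, canonical=canonical)


def contacts_to_frame(
    interactions: Sequence[MotifInteraction], model_ids: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """One row per contact over an ensemble, for TSV export."""
    rows = []
    if model_ids is None:
        model_ids = range(1, len(interactions) + 1)
    for mid, inter in zip(model_ids, interactions):
        for c in inter.contacts:
            rows.append(
                {
                    "model": mid,
                    "donor": c.donor_id,
                    "hydrogen": c.hydrogen,
                    "oxygen": c.acceptor_o,
                    "d_ho": c.d_ho,
                    "angle_xho": c.angle_xho,
                    "energy": c.energy,
                    "hclass": c.hclass,
                    "canonical": inter.canonical,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "model", "donor", "hydrogen", "oxygen",
            "d_ho", "angle_xho", "energy", "hclass", "canonical",
        ],
    )
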