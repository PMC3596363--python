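"""Backbone conformation analysis: torsions, Ramachandran states, helicity.

Two simple criteria track the helical state of the recognition segment over
conformer series: per-residue (phi, psi) windows around the right-handed
helical and polyproline-II regions of the Ramachandran map, and the distance
between consecutive amide protons, which stays below 4 A in a helix.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    AnionModel,
    BackboneDihedrals,
    Structure,
    dihedral_angle,
)
from .interactions import (
    DEFAULT_CRITERIA,
    HBondCriteria,
    MotifInteraction,
    map_anion_contacts,
)

__all__ = [
    "RamaState",
    "RamaWindows",
    "TrajectoryRecord",
    "TransitionReport",
    "backbone_dihedrals",
    "classify_state",
    "nh_nh_distances",
    "analyze_trajectory",
    "NH_NH_HELICAL_MAX",
]

#: Consecutive amide-H distance below which a residue pair reads as helical (A).
NH_NH_HELICAL_MAX = 4.0


class RamaState(str, Enum):
    """Backbone conformational state of one residue."""

    helical_R = "helical_R"
    ppII = "ppII"
    noncanonical_helical = "noncanonical_helical"
    other = "other"


@dataclass(frozen=True)
class RamaWindows:
    """Inclusive (phi, psi) boxes for state classification, degrees.

    The strict right-handed helical window is phi = -70 +/- 15,
    psi = -57 +/- 12; polyproline II is phi = -70 +/- 15, psi = 150 +/- 20.
    "Non-canonical helical" is the broad right-handed helical basin minus
    the strict window.  Ties at the borders resolve to the more specific
    state (helical_R > ppII > noncanonical_helical > other).
    """

    helical_phi: Tuple[float, float] = (-85.0, -55.0)
    helical_psi: Tuple[float, float] = (-69.0, -45.0)
    ppii_phi: Tuple[float, float] = (-85.0, -55.0)
    ppii_psi: Tuple[float, float] = (130.0, 170.0)
    broad_phi: Tuple[float, float] = (-110.0, -40.0)
    broad_psi: Tuple[float, float] = (-80.0, -5.0)


DEFAULT_WINDOWS = RamaWindows()


def _in_box(v: float, box: Tuple[float, float]) -> bool:
    return box[0] <= v <= box[1]


def classify_state(
    phi: float, psi: float, windows: RamaWindows = DEFAULT_WINDOWS
) -> RamaState:
    """Classify one residue's (phi, psi) pair; total over the torus."""
    if _in_box(phi, windows.helical_phi) and _in_box(psi, windows.helical_psi):
        return RamaState.helical_R
    if _in_box(phi, windows.ppii_phi) and _in_box(psi, windows.ppii_psi):
        return RamaState.ppII
    if _in_box(phi, windows.broad_phi) and _in_box(psi, windows.broad_psi):
        return RamaState.noncanonical_helical
    return RamaState.other


def backbone_dihedrals(structure: Structure) -> BackboneDihedrals:
    """Measure per-residue (phi, psi, omega) from coordinates.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Cap atoms (acetyl C, amide N) supply the terminal torsions; without a
    cap the first phi / last psi are ``None``.  A missing backbone atom
    raises an error naming the residue.
    """
    res_ids = structure.peptide_residue_indices()
    if not res_ids:
        raise ValueError("structure contains no peptide residues")
    phi: List[Optional[float]] = []
    psi: List[Optional[float]] = []
    omega: List[Optional[float]] = []
    for pos, i in enumerate(res_ids):
        for name in ("N", "CA", "C"):
            if not structure.has_atom(i, name):
                raise ValueError(
                    f"residue {i} ({structure.residue_code(i)}) missing backbone atom {name}"
                )
        n_i = structure.atom(i, "N").xyz
        ca_i = structure.atom(i, "CA").xyz
        c_i = structure.atom(i, "C").xyz

        prev_idx = res_ids[pos - 1] if pos > 0 else i - 1
        if pos > 0 or structure.has_atom(prev_idx, "C"):
            c_prev = structure.atom(prev_idx, "C").xyz
            phi.append(dihedral_angle(c_prev, n_i, ca_i, c_i))
            if structure.has_atom(prev_idx, "CA") or structure.has_atom(prev_idx, "CH3"):
                ca_like = (
                    structure.atom(prev_idx, "CA").xyz
                    if structure.has_atom(prev_idx, "CA")
                    else structure.atom(prev_idx, "CH3").xyz
                )
                omega.append(dihedral_angle(ca_like, c_prev, n_i, ca_i))
            else:
                omega.append(None)
        else:
            phi.append(None)
            omega.append(None)

        next_idx = res_ids[pos + 1] if pos + 1 < len(res_ids) else i + 1
        if pos + 1 < len(res_ids) or structure.has_atom(next_idx, "N"):
            n_next = structure.atom(next_idx, "N").xyz
            psi.append(dihedral_angle(n_i, ca_i, c_i, n_next))
        else:
            psi.append(None)
    return BackboneDihedrals(phi=phi, psi=psi, omega=omega)


def nh_nh_distances(structure: Structure) -> List[Tuple[int, int, float]]:
    """Distances between consecutive amide protons, (i, i+1, distance A).

    Pairs where either residue lacks an amide hydrogen (Pro, missing H)
    are omitted.  A pair reads as helical when the distance is < 4 A.
    """
    res_ids = structure.peptide_residue_indices()
    out: List[Tuple[int, int, float]] = []
    for a, b in zip(res_ids, res_ids[1:]):
        if not (structure.has_atom(a, "H") and structure.has_atom(b, "H")):
            continue
        d = float(
            np.linalg.norm(structure.atom(a, "H").xyz - structure.atom(b, "H").xyz)
        )
        out.append((a, b, d))
    return out


@dataclass
class TrajectoryRecord:
    """Per-frame analysis results."""

    frame_index: int
    time: float
    phi: List[Optional[float]]
    psi: List[Optional[float]]
    states: List[RamaState]
    nh_nh: List[Tuple[int, int, float]]
    motif: MotifInteraction

    @property
    def bound(self) -> bool:
        return len(self.motif.contacts) > 0


@dataclass
class TransitionReport:
    """Helical-fraction change of each motif residue across residence end."""

    residence_frames: int
    n_frames: int
    helical_fraction_before: Dict[int, float]
    helical_fraction_after: Dict[int, float]

    def to_dict(self) -> dict:
        return {
            "residence_frames": self.residence_frames,
            "n_frames": self.n_frames,
            "helical_fraction_before": self.helical_fraction_before,
            "helical_fraction_after": self.helical_fraction_after,
        }


def _residence_length(bound: Sequence[bool], gap_tolerance: int) -> int:
    """Initial maximal run of bound frames, tolerating gaps shorter than
    ``gap_tolerance`` frames.  Returns 0 when the trajectory starts with a
    full-length gap (or is never bound)."""
    last_bound = -1
    gap = 0
    for i, b in enumerate(bound):
        if b:
            last_bound = i
            gap = 0
        else:
            gap += 1
            if gap >= gap_tolerance:
                break
    return last_bound + 1


def analyze_trajectory(
    frames: Sequence[Tuple[Structure, Optional[AnionModel]]],
    motif_residues: Sequence[int],
    criteria: HBondCriteria = DEFAULT_CRITERIA,
    windows: RamaWindows = DEFAULT_WINDOWS,
    gap_tolerance: int = 10,
    time_step: float = 1.0,
) -> Tuple[List[TrajectoryRecord], int, TransitionReport]:
    """Contact, state and helicity tracking over a frame series.

    Returns per-frame records, the anion residence length in frames (the
    initial maximal run of frames with at least one motif contact, tolerating
    contact-flicker gaps shorter than ``gap_tolerance``), and a transition
    report comparing the helical_R fraction of each motif residue before and
    after residence end.  ``time_step`` sets the time stamp per frame (ps).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    records: List[TrajectoryRecord] = []
    for k, (structure, anion) in enumerate(frames):
        dihed = backbone_dihedrals(structure)
        states = [
            classify_state(p, s, windows)
            if p is not None and s is not None
            else RamaState.other
            for p, s in zip(dihed.phi, dihed.psi)
        ]
        if anion is not None:
            motif = map_anion_contacts(structure, anion, motif_residues, criteria)
        else:
            motif = MotifInteraction(contacts=[], oxygen_map={}, canonical=False)
        records.append(
            TrajectoryRecord(
                frame_index=k,
                time=k * time_step,
                phi=dihed.phi,
                psi=dihed.psi,
                states=states,
                nh_nh=nh_nh_distances(structure),
                motif=motif,
            )
        )

    residence = _residence_length([r.bound for r in records], gap_tolerance)

    res_ids = frames[0][0].peptide_residue_indices()
    pos = {r: res_ids.index(r) for r in motif_residues}
    before: Dict[int, float] = {}
    after: Dict[int, float] = {}
    for r in motif_residues:
        states_r = [rec.states[pos[r]] for rec in records]
        pre = states_r[:residence]
        post = states_r[residence:]
        before[r] = (
            sum(s is RamaState.helical_R for s in pre) / len(pre) if pre else float("nan")
        )
        after[r] = (
            sum(s is RamaState.helical_R for s in post) / len(post) if post else float("nan")
        )
    report = TransitionReport(
        residence_frames=residence,
        n_frames=len(records),
        helical_fraction_before=before,
        helical_fraction_after=after,
    )
    return records, residence, report


def records_to_frame(records: Sequence[TrajectoryRecord]) -> pd.DataFrame:
    """Long-format per-frame, per-residue table for TSV export."""
    rows = []
    for rec in records:
        for j, (p, s, st) in enumerate(zip(rec.phi, rec.psi, rec.states), start=1):
            rows.append(
                {
                    "frame": rec.frame_index,
                    "time": rec.time,
                    "residue": j,
                    "phi": p,
                    "psi": s,
                    "state": st.value,
                    "n_contacts": len(rec.motif.contacts),
                    "bound": rec.bound,
                }
            )
    return pd.DataFrame(rows)
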