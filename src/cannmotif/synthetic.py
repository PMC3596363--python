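"""Seeded generators emulating docking-pose ensembles and binding/unbinding
trajectories, so every analysis stage is testable with known ground truth.

These are statistical stand-ins, not simulations: the anion is rigid, poses
are rigid-body placements solved against target H-bond geometry, ensembles
are Gaussian rigid-body perturbations of a base pose, and trajectories swap
the motif torsions between the helical and polyproline-II windows at a
prescribed unbinding frame while the anion leaves along a smooth path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .builder import (
    build_anion,
    build_backbone,
    get_peptide,
    model_dihedrals,
    motif_residues_for,
)
from .conformation import DEFAULT_WINDOWS, RamaWindows
from .core import AnionModel, BackboneDihedrals, Structure, bond_angle
from .interactions import DEFAULT_CRITERIA, HBondCriteria

__all__ = [
    "PoseTargets",
    "PoseInfeasibleError",
    "generate_canonical_pose",
    "generate_pose_ensemble",
    "generate_switch_trajectory",
]


class PoseInfeasibleError(RuntimeError):
    """Raised when no rigid-body placement meets the requested geometry."""


@dataclass(frozen=True)
class PoseTargets:
    """Target H-bond geometry for the canonical two-oxygen pose.

    One oxygen bridges the Calpha(-1) and N(0) donors, a second contacts
    N(+1) only.  Distances (A) are two-sided targets; angles (degrees) are
    lower bounds -- an X-H...O angle closer to linearity than requested is
    a better hydrogen bond, not a miss.
    """

    d_calpha: float = 2.6
    d_n0: float = 1.9
    d_n1: float = 1.9
    angle_calpha: float = 120.0
    angle_n: float = 160.0

    # acceptance tolerances for the achieved geometry
    tol_d: float = 0.15
    tol_angle: float = 10.0


def _alpha_hydrogen_names(structure: Structure, ca_res: int) -> List[str]:
    names = [n for n in ("HA", "HA2", "HA3") if structure.has_atom(ca_res, n)]
    if not names:
        raise ValueError(f"residue {ca_res} offers no alpha hydrogen donor")
    return names


def _donor_atoms(
    structure: Structure, motif_residues: Sequence[int], ha_name: Optional[str] = None
):
    """((H_ca, CA), (H_n0, N0), (H_n1, N1)) coordinate pairs."""
    ca_res, n0_res, n1_res = motif_residues
    if ha_name is None:
        ha_name = _alpha_hydrogen_names(structure, ca_res)[0]
    return (
        (structure.atom(ca_res, ha_name).xyz, structure.atom(ca_res, "CA").xyz),
        (structure.atom(n0_res, "H").xyz, structure.atom(n0_res, "N").xyz),
        (structure.atom(n1_res, "H").xyz, structure.atom(n1_res, "N").xyz),
    )


def _pose_residuals(
    params: np.ndarray,
    base_oxy: np.ndarray,
    donors,
    targets: PoseTargets,
    criteria: HBondCriteria,
    angle_weight: float = 0.02,
    penalty_weight: float = 4.0,
) -> np.ndarray:
    rot = Rotation.from_rotvec(params[:3])
    t = params[3:]
    oxy = rot.apply(base_oxy) + t  # 4 oxygens
    (h_ca, x_ca), (h_n0, x_n0), (h_n1, x_n1) = donors
    o1, o2 = oxy[0], oxy[1]

    res = [
        np.linalg.norm(o1 - h_ca) - targets.d_calpha,
        np.linalg.norm(o1 - h_n0) - targets.d_n0,
        np.linalg.norm(o2 - h_n1) - targets.d_n1,
        # hinge terms: only an angle below its target counts as error
        angle_weight * max(0.0, targets.angle_calpha - bond_angle(x_ca, h_ca, o1)),
        angle_weight * max(0.0, targets.angle_n - bond_angle(x_n0, h_n0, o1)),
        angle_weight * max(0.0, targets.angle_n - bond_angle(x_n1, h_n1, o2)),
    ]
    # keep the pattern exclusive: non-designated oxygen-donor pairs must
    # stay outside the detection cutoffs (with margin)
    margin = 0.35
    forbidden = [
        (oxy[0], h_n1, criteria.d_max_amide),
        (oxy[1], h_ca, criteria.d_max_calpha),
        (oxy[1], h_n0, criteria.d_max_amide),
    ]
    for k in (2, 3):
        for h, cut in (
            (h_ca, criteria.d_max_calpha),
            (h_n0, criteria.d_max_amide),
            (h_n1, criteria.d_max_amide),
        ):
            forbidden.append((oxy[k], h, cut))
    for o, h, cut in forbidden:
        gap = (cut + margin) - np.linalg.norm(o - h)
        res.append(penalty_weight * max(0.0, gap))
    return np.asarray(res)


def generate_canonical_pose(
    structure: Structure,
    motif_residues: Sequence[int],
    anion_kind: str = "sulfate",
    targets: PoseTargets = PoseTargets(),
    criteria: HBondCriteria = DEFAULT_CRITERIA,
    seed: int = 0,
    n_restarts: int = 16,
) -> Tuple[Structure, AnionModel, Dict[str, float]]:
    """Place an anion at the canonical bridging geometry by rigid-body
    least squares.

    Oxygen O1 is driven to the requested distance/angle from BOTH the
    Calpha(-1)-H and N(0)-H donors and O2 from N(+1)-H, while the remaining
    oxygens are pushed outside the detection cutoffs.  For glycine both
    alpha hydrogens are tried as the Calpha donor.  Several seeded random
    restarts are run per donor choice; the best solution must land within
    ``targets.tol_d`` of each distance target and no more than
    ``targets.tol_angle`` below each angle target, else
    :class:`PoseInfeasibleError` is raised with the achieved geometry.

    Returns (structure, placed anion, achieved-geometry report).
    """
    anion = build_anion(anion_kind)
    base_oxy = np.array([o.xyz for o in anion.oxygens])
    pep_centre = structure.coords().mean(axis=0)

    best_sol = None
    best_donors = None
    for ha_name in _alpha_hydrogen_names(structure, motif_residues[0]):
        donors = _donor_atoms(structure, motif_residues, ha_name)
        (h_ca, _), (h_n0, _), (h_n1, _) = donors
        h_centroid = (h_ca + h_n0 + h_n1) / 3.0
        outward = h_centroid - pep_centre
        outward = outward / (np.linalg.norm(outward) + 1e-12)
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            rotvec = rng.normal(scale=math.pi / 2, size=3)
            t0 = h_centroid + outward * 2.0 + rng.normal(scale=0.8, size=3)
            x0 = np.concatenate([rotvec, t0])
            sol = least_squares(
                _pose_residuals,
                x0,
                args=(base_oxy, donors, targets, criteria),
                xtol=1e-12,
                ftol=1e-12,
            )
            if best_sol is None or sol.cost < best_sol.cost:
                best_sol = sol
                best_donors = donors
            if best_sol.cost < 1e-14:
                break
        if best_sol is not None and best_sol.cost < 1e-14:
            break

    rot = Rotation.from_rotvec(best_sol.x[:3])
    placed = anion.transformed(rot.as_matrix(), best_sol.x[3:])
    oxy = np.array([o.xyz for o in placed.oxygens])
    (h_ca, x_ca), (h_n0, x_n0), (h_n1, x_n1) = best_donors
    achieved = {
        "d_calpha": float(np.linalg.norm(oxy[0] - h_ca)),
        "d_n0": float(np.linalg.norm(oxy[0] - h_n0)),
        "d_n1": float(np.linalg.norm(oxy[1] - h_n1)),
        "angle_calpha": bond_angle(x_ca, h_ca, oxy[0]),
        "angle_n0": bond_angle(x_n0, h_n0, oxy[0]),
        "angle_n1": bond_angle(x_n1, h_n1, oxy[1]),
        "cost": float(best_sol.cost),
    }
    errs_d = [
        abs(achieved["d_calpha"] - targets.d_calpha),
        abs(achieved["d_n0"] - targets.d_n0),
        abs(achieved["d_n1"] - targets.d_n1),
    ]
    errs_a = [
        targets.angle_calpha - achieved["angle_calpha"],
        targets.angle_n - achieved["angle_n0"],
        targets.angle_n - achieved["angle_n1"],
    ]
    if max(errs_d) > targets.tol_d or max(errs_a) > targets.tol_angle:
        raise PoseInfeasibleError(
            "no rigid placement met the target geometry; achieved "
            + ", ".join(f"{k}={v:.3f}" for k, v in achieved.items())
        )
    return structure, placed, achieved


def generate_pose_ensemble(
    structure: Structure,
    anion: AnionModel,
    n: int = 250,
    noise_translation: float = 0.03,
    noise_rotation: float = 2.0,
    seed: int = 0,
) -> List[Tuple[Structure, AnionModel]]:
    """Rigid-body Gaussian perturbations of the anion about a base pose.

    ``noise_translation`` is the isotropic translational sigma in A and
    ``noise_rotation`` the rotational sigma in degrees about the anion
    centre.  With zero noise every pose equals the base pose.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if noise_translation < 0 or noise_rotation < 0:
        raise ValueError("noise levels must be non-negative")
    rng = np.random.default_rng(seed)
    centre = anion.central.xyz.copy()
    out: List[Tuple[Structure, AnionModel]] = []
    for k in range(n):
        rotvec = rng.normal(scale=math.radians(noise_rotation), size=3)
        shift = rng.normal(scale=noise_translation, size=3)
        R = Rotation.from_rotvec(rotvec).as_matrix()
        # rotate about the anion centre, then translate
        t = centre - R @ centre + shift
        perturbed = anion.transformed(R, t)
        model = structure.copy()
        model.model_id = k + 1
        out.append((model, perturbed))
    return out


def _jitter_in_box(
    rng: np.random.Generator,
    centre: Tuple[float, float],
    phi_box,
    psi_box,
    sigma: float,
    margin: float = 0.5,
):
    """Gaussian jitter about ``centre``, clipped strictly inside the
    (phi, psi) box (a half-degree margin keeps build/measure floating-point
    noise from straddling a window boundary)."""
    phi = float(
        np.clip(centre[0] + rng.normal(scale=sigma), phi_box[0] + margin, phi_box[1] - margin)
    )
    psi = float(
        np.clip(centre[1] + rng.normal(scale=sigma), psi_box[0] + margin, psi_box[1] - margin)
    )
    return phi, psi


def generate_switch_trajectory(
    peptide_id: str = "CPS224Ac",
    n_frames: int = 1000,
    unbind_frame: int = 400,
    relax_frames: int = 0,
    anion_kind: str = "sulfate",
    targets: PoseTargets = PoseTargets(),
    windows: RamaWindows = DEFAULT_WINDOWS,
    seed: int = 0,
    torsion_sigma: float = 3.0,
    jitter_translation: float = 0.02,
    jitter_rotation: float = 1.0,
    escape_step: float = 0.5,
    escape_max: float = 30.0,
) -> Tuple[List[Tuple[Structure, AnionModel]], Tuple[int, int, int]]:
    """A bound-then-unbound frame series with known ground truth.

    While bound (frames 0 .. unbind_frame-1) the N(0) and N(+1) motif
    residues hold torsions jittered inside the strict right-handed helical
    window (their crystal-derived values already lie there) and the anion
    sits at the canonical pose, rigid-body jittered.  The Calpha(-1)
    residue keeps its native beta-region torsions throughout: the motif's
    recognition conformation is beta/helical/helical and the conformational
    switch concerns the two amide donors.

    From ``unbind_frame`` on, the anion retreats along a smooth straight
    path while N(0) is resampled in the polyproline-II window; N(+1)
    follows after ``relax_frames`` frames, sitting in the broad helical
    basin (outside the strict window) in between -- mimicking the delayed
    relaxation its helix-promoting neighbour imposes.

    Returns (frames, motif_residues).  Deterministic for a given seed.
    """
    if not (0 < unbind_frame < n_frames):
        raise ValueError("need 0 < unbind_frame < n_frames")
    if relax_frames < 0:
        raise ValueError("relax_frames must be >= 0")

    motif = motif_residues_for(peptide_id)
    ca_res, n0_res, n1_res = motif
    peptide = get_peptide(peptide_id)
    base = model_dihedrals(peptide_id, "native")
    rng = np.random.default_rng(seed)

    base_structure = build_backbone(peptide, base)
    _, base_anion, _ = generate_canonical_pose(
        base_structure, motif, anion_kind, targets, seed=seed
    )
    base_h = _donor_frame_points(base_structure, motif)

    helical_centres = {
        n0_res: (base.phi[n0_res - 1], base.psi[n0_res - 1]),
        n1_res: (base.phi[n1_res - 1], base.psi[n1_res - 1]),
    }
    ppii_centre = (
        0.5 * (windows.ppii_phi[0] + windows.ppii_phi[1]),
        0.5 * (windows.ppii_psi[0] + windows.ppii_psi[1]),
    )
    lag_centre = (-97.0, -20.0)  # broad helical basin, outside strict window

    frames: List[Tuple[Structure, AnionModel]] = []

    for k in range(n_frames):
        dih = BackboneDihedrals(
            phi=list(base.phi), psi=list(base.psi), omega=list(base.omega)
        )
        bound = k < unbind_frame
        for r in (n0_res, n1_res):
            if bound:
                phi, psi = _jitter_in_box(
                    rng,
                    helical_centres[r],
                    windows.helical_phi,
                    windows.helical_psi,
                    torsion_sigma,
                )
            elif r == n1_res and k < unbind_frame + relax_frames:
                phi, psi = _jitter_in_box(
                    rng, lag_centre, windows.broad_phi, windows.broad_psi, torsion_sigma
                )
            else:
                phi, psi = _jitter_in_box(
                    rng, ppii_centre, windows.ppii_phi, windows.ppii_psi, torsion_sigma
                )
            dih.phi[r - 1] = phi
            dih.psi[r - 1] = psi
        structure = build_backbone(peptide, dih)
        structure.model_id = k + 1

        # carry the anion with the motif donors via a rigid superposition
        h_now = _donor_frame_points(structure, motif)
        R, t = _kabsch(base_h, h_now)
        anion = base_anion.transformed(R, t)
        if bound:
            rotvec = rng.normal(scale=math.radians(jitter_rotation), size=3)
            shift = rng.normal(scale=jitter_translation, size=3)
            Rj = Rotation.from_rotvec(rotvec).as_matrix()
            centre = anion.central.xyz.copy()
            anion = anion.transformed(Rj, centre - Rj @ centre + shift)
        else:
            # retreat radially away from the donor hydrogens so the path
            # never re-enters the recognition site
            h_centroid = h_now[(0, 2, 4), :].mean(axis=0)
            away = anion.central.xyz - h_centroid
            away = away / np.linalg.norm(away)
            dist = min(escape_step * (k - unbind_frame + 1), escape_max)
            anion = anion.transformed(np.eye(3), away * dist)
        frames.append((structure, anion))
    return frames, motif


def _donor_frame_points(structure: Structure, motif_residues) -> np.ndarray:
    (h_ca, x_ca), (h_n0, x_n0), (h_n1, x_n1) = _donor_atoms(structure, motif_residues)
    return np.array([h_ca, x_ca, h_n0, x_n0, h_n1, x_n1])


def _kabsch(src: np.ndarray, dst: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping point set src onto dst."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dc - R @ sc
    return R, t
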