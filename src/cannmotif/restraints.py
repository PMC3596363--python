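"""NMR restraint translation: NOE distance classes and the Karplus relation.

NOE cross-peak intensity classes map to interproton upper distance limits
(weak 4.25 A, medium 3.5 A, strong 3.0 A).  The three-bond amide-alpha
coupling constant relates to the backbone torsion phi through

    3J(HN-HA) = A cos^2(theta) + B cos(theta) + C,  theta = |phi - 60 deg|

with A = 6.4, B = -1.4, C = 1.9 Hz.  theta is taken as the wrapped absolute
angular difference on [0, 180], so the relation is well defined on the whole
torsion circle.  Inversion returns every phi interval compatible with a
measured J, each widened by a user window (default +/- 10 deg).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KarplusParams",
    "NOERestraint",
    "NOE_UPPER_LIMITS",
    "noe_upper_limit",
    "karplus_j",
    "karplus_invert",
    "restraints_to_tsv",
    "restraints_from_tsv",
    "to_dyana_upl",
]

NOE_UPPER_LIMITS = {"weak": 4.25, "medium": 3.5, "strong": 3.0}


@dataclass(frozen=True)
class KarplusParams:
    """Coefficients (Hz) and phase offset (deg) of the Karplus curve."""

    A: float = 6.4
    B: float = -1.4
    C: float = 1.9
    offset: float = 60.0


DEFAULT_KARPLUS = KarplusParams()


@dataclass(frozen=True)
class NOERestraint:
    """An interproton upper-limit restraint between two residues."""

    residue_i: int
    residue_j: int
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in NOE_UPPER_LIMITS:
            raise ValueError(
                f"unknown NOE class {self.cls!r}; use weak/medium/strong"
            )

    @property
    def upper_limit(self) -> float:
        return NOE_UPPER_LIMITS[self.cls]


def noe_upper_limit(cls: str) -> float:
    """Upper distance limit (A) for an NOE intensity class."""
    try:
        return NOE_UPPER_LIMITS[cls]
    except KeyError:
        raise ValueError(
            f"unknown NOE class {cls!r}; use weak/medium/strong"
        ) from None


def _theta(phi: float, params: KarplusParams) -> float:
    """Wrapped absolute angular difference |phi - offset| on [0, 180]."""
    d = math.fmod(phi - params.offset, 360.0)
    if d < -180.0:
        d += 360.0
    elif d > 180.0:
        d -= 360.0
    return abs(d)


def karplus_j(phi: float, params: KarplusParams = DEFAULT_KARPLUS) -> float:
    """Three-bond coupling constant (Hz) predicted for torsion ``phi``."""
    c = math.cos(math.radians(_theta(phi, params)))
    return params.A * c * c + params.B * c + params.C


def karplus_invert(
    j: float,
    params: KarplusParams = DEFAULT_KARPLUS,
    window: float = 10.0,
    grid_step: float = 0.1,
) -> List[Tuple[float, float]]:
    """All phi intervals on (-180, 180] whose predicted J equals ``j``.

    Roots are located on a dense grid and refined by bisection, then each
    widened to +/- ``window`` degrees; overlapping intervals are merged.
    An unattainable J yields an empty list with a warning.
    """
    lo, hi = -180.0, 180.0
    grid = np.arange(lo, hi + grid_step, grid_step)
    d = np.mod(grid - params.offset, 360.0)
    theta = np.minimum(d, 360.0 - d)
    c = np.cos(np.radians(theta))
    vals = params.A * c * c + params.B * c + params.C - j

    roots: List[float] = []
    for k in range(len(grid) - 1):
        a, b = vals[k], vals[k + 1]
        if a == 0.0:
            roots.append(float(grid[k]))
        elif a * b < 0.0:
            roots.append(
                float(
                    brentq(lambda p: karplus_j(p, params) - j, grid[k], grid[k + 1])
                )
            )
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    if not roots:
        warnings.warn(f"J = {j:.3f} Hz is outside the attainable range")
        return []

    intervals = sorted((r - window, r + window) for r in roots)
    merged: List[Tuple[float, float]] = [intervals[0]]
    for a, b in intervals[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    return merged


# ---------------------------------------------------------------------------
# restraint list I/O
# ---------------------------------------------------------------------------


def restraints_to_tsv(restraints: Sequence[NOERestraint], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("residue_i\tresidue_j\tclass\tupper_limit\n")
        for r in restraints:
            fh.write(f"{r.residue_i}\t{r.residue_j}\t{r.cls}\t{r.upper_limit}\n")
    return path


def restraints_from_tsv(path: Union[str, Path]) -> List[NOERestraint]:
    out: List[NOERestraint] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            i, j, cls = line.split("\t")[:3]
            out.append(NOERestraint(int(i), int(j), cls.strip()))
    return out


def to_dyana_upl(
    restraints: Sequence[NOERestraint],
    sequence: Sequence[str],
    atom_i: str = "HN",
    atom_j: str = "HN",
) -> str:
    """Upper-limit list in the classic DYANA/CYANA .upl column layout."""
    lines = []
    for r in restraints:
        code_i = sequence[r.residue_i - 1]
        code_j = sequence[r.residue_j - 1]
        lines.append(
            f"{r.residue_i:4d} {code_i:<4s} {atom_i:<4s}"
            f"{r.residue_j:4d} {code_j:<4s} {atom_j:<4s}{r.upper_limit:8.2f}"
        )
    return "\n".join(lines) + "\n"
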