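"""Peptide masses and anion-adduct m/z for negative-mode ESI assignments.

A capped peptide's mass is the sum of its residue masses plus water, with
the N-acetyl (+C2H2O) and C-amide (-OH +NH2) deltas applied.  Non-covalent
peptide-anion complexes observed as doubly charged anions have

    m/z = (M_peptide + M_anion + |z| m_e) / |z|

using monoisotopic masses; the isotopic peak spacing is 1/|z|.  Elemental
and standard-residue compositions come from pyteomics; Aib (C4H7NO) is the
one non-standard residue and is registered here.
"""

from __future__ import annotations

from typing import Optional, Tuple

from pyteomics import mass as pmass

from .core import PeptideModel

__all__ = [
    "ELECTRON_MASS",
    "ANION_COMPOSITIONS",
    "peptide_composition",
    "peptide_mass",
    "anion_mass",
    "adduct_mz",
    "mz_table",
]

ELECTRON_MASS = 0.000548579909  # Da

#: Neutral-fragment elemental compositions of the adduct-forming anions.
ANION_COMPOSITIONS = {
    "sulfate": pmass.Composition(formula="SO4"),
    "phosphate": pmass.Composition(formula="HPO4"),
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_AIB_COMPOSITION = pmass.Composition(formula="C4H7NO")


def _residue_composition(code: str) -> pmass.Composition:
    if code == "AIB":
        return _AIB_COMPOSITION
    try:
        return pmass.std_aa_comp[_THREE_TO_ONE[code]]
    except KeyError:
        raise ValueError(f"unknown residue code {code!r}") from None


def peptide_composition(peptide: PeptideModel) -> pmass.Composition:
    """Elemental composition of the capped peptide."""
    comp = pmass.Composition()
    for res in peptide.residues:
        comp += _residue_composition(res.code)
    comp += pmass.Composition(formula="H2O")
    if peptide.n_cap == "acetyl":
        comp += pmass.Composition(formula="C2H2O")
    if peptide.c_cap == "amide":
        # replace the C-terminal OH by NH2
        comp += pmass.Composition(N=1, H=1, O=-1)
    return comp


def peptide_mass(peptide: PeptideModel, mode: str = "monoisotopic") -> float:
    """Neutral peptide mass in Da (monoisotopic or average)."""
    if mode not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mode {mode!r}")
    comp = peptide_composition(peptide)
    return pmass.calculate_mass(composition=comp, average=(mode == "average"))


def anion_mass(kind: str, mode: str = "monoisotopic") -> float:
    """Mass of the adduct-forming anion fragment (SO4 / HPO4) in Da."""
    try:
        comp = ANION_COMPOSITIONS[kind]
    except KeyError:
        raise ValueError(f"unknown anion kind {kind!r}") from None
    return pmass.calculate_mass(composition=comp, average=(mode == "average"))


def adduct_mz(
    peptide: PeptideModel, anion: str, charge: int
) -> Tuple[float, float]:
    """(m/z, isotopic spacing) of the [peptide + anion]^z- species.

    ``charge`` is a negative integer; the electron masses carried by the
    ion are included (negligible at one-decimal precision but correct).
    """
    if charge == 0:
        raise ValueError("charge must be a non-zero negative integer")
    z = abs(int(charge))
    m = peptide_mass(peptide) + anion_mass(anion) + z * ELECTRON_MASS
    return m / z, 1.0 / z


def mz_table(peptide: PeptideModel, anion: Optional[str], charges=(-1, -2)) -> list:
    """Rows of (species, z, m/z, spacing) for a small printed table."""
    rows = []
    m_pep = peptide_mass(peptide)
    rows.append({"species": f"[{peptide.id}]", "z": 0, "mz": m_pep, "spacing": None})
    if anion is not None:
        for z in charges:
            mz, spacing = adduct_mz(peptide, anion, z)
            rows.append(
                {
                    "species": f"[{peptide.id}+{anion}]{abs(z)}-",
                    "z": z,
                    "mz": mz,
                    "spacing": spacing,
                }
            )
    return rows
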