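"""Per-residue coarse-grain bead table.

Each amino-acid residue is represented by a single sphere carrying the
residue's total electron count and an effective radius.  Electron counts are
the sums of atomic numbers for the in-chain residue composition (i.e. the
free amino acid minus one water, which is what remains after peptide-bond
formation).  Radii are equivalent-sphere radii, ``r = (3 V / 4 pi)**(1/3)``,
computed from the Zamyatnin residue volumes commonly used in protein
biophysics.

The table ships with the package so that coarse-graining is reproducible;
tests reference these entries rather than external data.
"""

from __future__ import annotations

import math

__all__ = ["RESIDUE_ELECTRONS", "RESIDUE_VOLUMES_A3", "RESIDUE_RADII", "bead_parameters"]

# Sum of atomic numbers for the in-chain residue formula (C=6, H=1, N=7, O=8, S=16).
RESIDUE_ELECTRONS: dict[str, float] = {
    "ALA": 38.0,   # C3H5NO
    "ARG": 84.0,   # C6H12N4O
    "ASN": 60.0,   # C4H6N2O2
    "ASP": 60.0,   # C4H5NO3 (ionizable H counted as protonated would add 1)
    "CYS": 54.0,   # C3H5NOS
    "GLN": 68.0,   # C5H8N2O2
    "GLU": 68.0,   # C5H7NO3
    "GLY": 30.0,   # C2H3NO
    "HIS": 72.0,   # C6H7N3O
    "ILE": 62.0,   # C6H11NO
    "LEU": 62.0,   # C6H11NO
    "LYS": 70.0,   # C6H12N2O
    "MET": 70.0,   # C5H9NOS
    "PHE": 78.0,   # C9H9NO
    "PRO": 52.0,   # C5H7NO
    "SER": 46.0,   # C3H5NO2
    "THR": 54.0,   # C4H7NO2
    "TRP": 98.0,   # C11H10N2O
    "TYR": 86.0,   # C9H9NO2
    "VAL": 54.0,   # C5H9NO
}

# Residue volumes in cubic Angstroms (Zamyatnin, 1972).
RESIDUE_VOLUMES_A3: dict[str, float] = {
    "ALA": 88.6,
    "ARG": 173.4,
    "ASN": 114.1,
    "ASP": 111.1,
    "CYS": 108.5,
    "GLN": 143.8,
    "GLU": 138.4,
    "GLY": 60.1,
    "HIS": 153.2,
    "ILE": 166.7,
    "LEU": 166.7,
    "LYS": 168.6,
    "MET": 162.9,
    "PHE": 189.9,
    "PRO": 112.7,
    "SER": 89.0,
    "THR": 116.1,
    "TRP": 227.8,
    "TYR": 193.6,
    "VAL": 140.0,
}

RESIDUE_RADII: dict[str, float] = {
    name: (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
    for name, vol in RESIDUE_VOLUMES_A3.items()
}


class UnknownResidueError(KeyError):
    """Raised when a residue type has no entry in the bead table."""


def bead_parameters(residue_name: str) -> tuple[float, float]:
    """Return ``(radius_A, electron_count)`` for a residue type.

    Raises
    ------
    UnknownResidueError
        If the residue type is not tabulated.  Unknown residues are an error
        rather than being silently dropped, so that ligands/waters must be
        handled explicitly by the caller.
    """
    name = residue_name.strip().upper()
    if name not in RESIDUE_ELECTRONS:
        raise UnknownResidueError(
            f"residue type {residue_name!r} is not in the coarse-grain bead table"
        )
    return RESIDUE_RADII[name], RESIDUE_ELECTRONS[name]
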