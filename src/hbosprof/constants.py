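"""Shared chemical constants: amino-acid codes, atomic masses, chi1 atom map."""

from __future__ import annotations

#: The 20 standard amino acids, three-letter -> one-letter.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

STANDARD_AA: frozenset[str] = frozenset(THREE_TO_ONE)

#: Non-standard residues with an unambiguous standard parent.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine scores against the CYS histograms
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "MLY": "LYS",
}

#: Residue types excluded from scoring: no chi1 torsion exists.
NO_CHI1: frozenset[str] = frozenset({"GLY", "ALA"})

#: The 18 residue types that carry a chi1 and are scored.
SCORED_TYPES: tuple[str, ...] = tuple(sorted(STANDARD_AA - NO_CHI1))

#: Standard atomic masses (heavy atoms found in protein residues), u.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "SE": 78.971,
}

#: Fourth atom of the chi1 torsion N-CA-CB-X per residue type.
CHI1_FOURTH_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

#: Backbone atom names (never part of a sidechain centroid).
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})


def element_mass(element: str) -> float | None:
    """Mass of *element* (case-insensitive), or None if not tabulated."""
    return ATOMIC_MASS.get(element.strip().upper())
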