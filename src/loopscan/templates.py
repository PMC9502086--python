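"""Residue-level chemistry tables.

Donor/acceptor assignments cover heavy (N/O) atoms only: the contact
criterion used throughout the package is a bare heavy-atom distance
cutoff, so sulfur and carbon atoms never enter polar-pair enumeration.
"""

from __future__ import annotations

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

#: canonical one-letter codes of the 20 standard residues
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE: dict[str, str] = {
    k.upper(): v for k, v in protein_letters_3to1.items() if v in STANDARD_AA
}
ONE_TO_THREE: dict[str, str] = {
    k: v.upper() for k, v in protein_letters_1to3.items() if k in STANDARD_AA
}


def one_letter(residue_name: str) -> str:
    """Map a 3-letter residue code to its 1-letter code.

    Raises ``KeyError``-derived :class:`ValueError` for unknown codes so
    callers surface label-formatting mistakes early.
    """
    try:
        return THREE_TO_ONE[residue_name.upper()]
    except KeyError:
        raise ValueError(f"unknown residue code: {residue_name!r}") from None


# Side-chain polar heavy atoms and their hydrogen-bonding role.
# 'donor' atoms bear at least one hydrogen in the standard protonation
# state; 'both' marks hydroxyls and His ring nitrogens.
SIDECHAIN_POLAR: dict[str, dict[str, str]] = {
    "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
    "LYS": {"NZ": "donor"},
    "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
    "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
    "ASN": {"OD1": "acceptor", "ND2": "donor"},
    "GLN": {"OE1": "acceptor", "NE2": "donor"},
    "HIS": {"ND1": "both", "NE2": "both"},
    "SER": {"OG": "both"},
    "THR": {"OG1": "both"},
    "TYR": {"OH": "both"},
    "TRP": {"NE1": "donor"},
}

#: basic side-chain nitrogen sets eligible for salt bridges
BASIC_SIDECHAIN: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}

#: acidic side-chain carboxylate oxygen sets eligible for salt bridges
ACIDIC_SIDECHAIN: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: backbone donor (amide N; absent in proline) and acceptor (carbonyl O)
BACKBONE_DONOR = "N"
BACKBONE_ACCEPTOR = "O"


def sidechain_donor_atoms(residue_name: str) -> tuple[str, ...]:
    table = SIDECHAIN_POLAR.get(residue_name.upper(), {})
    return tuple(a for a, role in table.items() if role in ("donor", "both"))


def sidechain_acceptor_atoms(residue_name: str) -> tuple[str, ...]:
    table = SIDECHAIN_POLAR.get(residue_name.upper(), {})
    return tuple(a for a, role in table.items() if role in ("acceptor", "both"))


# ---------------------------------------------------------------------------
# Coordinate templates for the synthetic trajectory generator.
#
# Geometry is schematic (bond lengths ~0.15 nm) but atom names are the
# standard PDB names, so selection and donor/acceptor logic downstream is
# exercised unchanged.  Each template is oriented with its designated
# "contact" atom at the origin and the rest of the residue extending into
# z < 0; the generator mirrors/offsets templates when placing a pair.
# Units: nanometres.

RESIDUE_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "ARG": {
        "N": (0.10, 0.05, -0.95),
        "CA": (0.00, 0.00, -0.85),
        "C": (-0.10, 0.08, -0.78),
        "O": (-0.20, 0.03, -0.75),
        "CB": (0.02, 0.01, -0.70),
        "CG": (0.00, 0.00, -0.55),
        "CD": (0.02, -0.01, -0.40),
        "NE": (0.00, 0.04, -0.28),
        "CZ": (0.00, 0.00, -0.14),
        "NH1": (0.00, 0.00, 0.00),
        "NH2": (0.00, 0.12, -0.10),
    },
    "GLU": {
        "N": (0.10, 0.05, -0.80),
        "CA": (0.00, 0.00, -0.70),
        "C": (-0.10, 0.08, -0.63),
        "O": (-0.20, 0.03, -0.60),
        "CB": (0.02, 0.01, -0.55),
        "CG": (0.00, 0.00, -0.40),
        "CD": (0.00, 0.02, -0.25),
        "OE1": (0.00, 0.00, 0.00),
        "OE2": (0.00, 0.12, -0.18),
    },
    "ASP": {
        "N": (0.10, 0.05, -0.65),
        "CA": (0.00, 0.00, -0.55),
        "C": (-0.10, 0.08, -0.48),
        "O": (-0.20, 0.03, -0.45),
        "CB": (0.02, 0.01, -0.40),
        "CG": (0.00, 0.02, -0.25),
        "OD1": (0.00, 0.00, 0.00),
        "OD2": (0.00, 0.12, -0.18),
    },
    "LYS": {
        "N": (0.10, 0.05, -0.95),
        "CA": (0.00, 0.00, -0.85),
        "C": (-0.10, 0.08, -0.78),
        "O": (-0.20, 0.03, -0.75),
        "CB": (0.02, 0.01, -0.70),
        "CG": (0.00, 0.00, -0.55),
        "CD": (0.02, -0.01, -0.40),
        "CE": (0.00, 0.02, -0.25),
        "NZ": (0.00, 0.00, 0.00),
    },
    "SER": {
        "N": (0.10, 0.05, -0.40),
        "CA": (0.00, 0.00, -0.30),
        "C": (-0.10, 0.08, -0.23),
        "O": (-0.20, 0.03, -0.20),
        "CB": (0.02, 0.01, -0.15),
        "OG": (0.00, 0.00, 0.00),
    },
    "GLY": {
        "N": (0.10, 0.05, -0.25),
        "CA": (0.00, 0.00, -0.15),
        "C": (-0.10, 0.08, -0.08),
        "O": (0.00, 0.00, 0.00),
    },
    "ALA": {
        "N": (0.10, 0.05, -0.35),
        "CA": (0.00, 0.00, -0.25),
        "C": (-0.10, 0.08, -0.18),
        "O": (-0.20, 0.03, -0.15),
        "CB": (0.00, 0.00, 0.00),
    },
    "GLN": {
        "N": (0.10, 0.05, -0.80),
        "CA": (0.00, 0.00, -0.70),
        "C": (-0.10, 0.08, -0.63),
        "O": (-0.20, 0.03, -0.60),
        "CB": (0.02, 0.01, -0.55),
        "CG": (0.00, 0.00, -0.40),
        "CD": (0.00, 0.02, -0.25),
        "OE1": (0.00, 0.00, 0.00),
        "NE2": (0.00, 0.12, -0.18),
    },
}
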