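"""Reference tables used across the toolkit.

Everything here is plain data: van der Waals radii, ionization pKa sets,
maximum (fully exposed) accessible-surface-area references, residue
hydrophobicity, atomic hydrophobicity for surface-patch typing, and formal
side-chain charge placements.  All tables are module-level dicts so a caller
can pass a modified copy to any function that consumes them.
"""

from __future__ import annotations

# --- van der Waals radii (Angstrom), Bondi-style values -------------------
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70


# --- amino-acid codes ------------------------------------------------------
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


# --- ionization: EMBOSS-style intrinsic pKa values -------------------------
# Each set maps group -> pKa.  Side-chain groups are keyed by one-letter
# residue code; termini by "N_term"/"C_term".  Basic groups (positive when
# protonated): K, R, H, N_term.  Acidic: D, E, C, Y, C_term.
PKA_SETS: dict[str, dict[str, float]] = {
    "emboss": {
        "N_term": 8.6, "C_term": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    # Classic Lehninger textbook values, kept as an alternative set.
    "lehninger": {
        "N_term": 9.69, "C_term": 2.34,
        "K": 10.53, "R": 12.48, "H": 6.0,
        "D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07,
    },
}
BASIC_GROUPS = frozenset({"K", "R", "H", "N_term"})
ACIDIC_GROUPS = frozenset({"D", "E", "C", "Y", "C_term"})


# --- maximum accessible surface area per residue type (A^2) ----------------
# Theoretical maxima (Gly-X-Gly based, Tien et al. style values).  Used as
# the denominator of relative SASA.  The MET entry can be overridden to
# 231.7 A^2 to match published absolute/percent pairs for Met residues.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
MET_MAX_ASA_TABLE4 = 231.7  # implied by a published 47.5 A^2 / 20.5 % pair


# --- residue hydrophobicity (Black & Mould 1991), raw 0..1 scale -----------
# The spatial-aggregation-propensity convention normalizes this scale so
# that Gly = 0 (subtract the Gly value); hydrophilic residues then carry
# negative phi and hydrophobic residues positive phi.
BLACK_MOULD: dict[str, float] = {
    "ALA": 0.616, "ARG": 0.000, "ASN": 0.236, "ASP": 0.028, "CYS": 0.680,
    "GLN": 0.251, "GLU": 0.043, "GLY": 0.501, "HIS": 0.165, "ILE": 0.943,
    "LEU": 0.943, "LYS": 0.283, "MET": 0.738, "PHE": 1.000, "PRO": 0.711,
    "SER": 0.359, "THR": 0.450, "TRP": 0.878, "TYR": 0.880, "VAL": 0.825,
}


def sap_hydrophobicity(scale: dict[str, float] | None = None) -> dict[str, float]:
    """Return a residue hydrophobicity scale normalized so Gly = 0."""
    raw = dict(BLACK_MOULD if scale is None else scale)
    g = raw.get("GLY", 0.0)
    return {res: v - g for res, v in raw.items()}


# --- atomic hydrophobicity for hydrophobic-patch typing --------------------
# Simplified per-element logP-like contributions: carbons (and, weakly,
# sulfur) are hydrophobic; nitrogen and oxygen polar.  Only the sign drives
# patch membership; magnitudes are kept logP-plausible for reporting.
ATOMIC_HYDROPHOBICITY: dict[str, float] = {
    "C": 0.15,
    "S": 0.05,
    "N": -0.50,
    "O": -0.40,
    "H": 0.0,
    "SE": 0.05,
    "P": -0.20,
}


# --- formal side-chain charges at the working pH ---------------------------
# (residue_name, atom_name) -> formal charge placed on that heavy atom.
# Histidine entries are applied only when the charge model protonates His.
SIDECHAIN_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): +1.0,
    ("ARG", "NH1"): +0.5, ("ARG", "NH2"): +0.5,
}
HIS_CHARGES: dict[tuple[str, str], float] = {
    ("HIS", "ND1"): +0.5, ("HIS", "NE2"): +0.5,
}

HIS_IMIDAZOLE_ATOMS = frozenset({"CG", "ND1", "CD2", "CE1", "NE2"})


def element_from_atom_name(name: str) -> str:
    """Infer the element from a PDB atom name when the element column is absent.

    Handles the common protein cases: two-letter elements (SE) and
    digit-prefixed hydrogen names (e.g. ``1HB``).
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped[:2].upper() == "SE":
        return "SE"
    return stripped[0].upper()
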