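"""Fully-exposed side-chain SASA reference (A^2), Gly-X-Gly based.

Generated by scripts/regenerate_sidechain_reference.py (same SASA
engine as the rest of the package; heavy atoms, probe 1.4 A)."""

MAX_SIDECHAIN_SAA: dict[str, float] = {
    "ALA": 50.9,
    "ARG": 185.3,
    "ASN": 116.4,
    "ASP": 113.0,
    "CYS": 87.5,
    "GLN": 136.2,
    "GLU": 137.2,
    "GLY": 0.0,  # no side chain
    "HIS": 143.1,
    "ILE": 139.8,
    "LEU": 134.4,
    "LYS": 141.0,
    "MET": 149.4,
    "PHE": 162.0,
    "PRO": 90.9,
    "SER": 72.5,
    "THR": 94.2,
    "TRP": 202.8,
    "TYR": 187.1,
    "VAL": 114.5,
}
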