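"""Regenerate the fully-exposed side-chain SASA reference table.

For each standard amino acid X, build an extended Gly-X-Gly tripeptide with
RDKit (sequence -> 3D embedding, fixed seed), run the package's own
Shrake-Rupley engine on the heavy atoms, and record the summed SASA of the
central residue's side-chain atoms.  Using the same engine for numerator and
denominator keeps the side-chain exposure ratio self-consistent.

Writes the table to stdout as Python source; the frozen copy lives in
``src/vhhfc/data_sidechain.py``.

Usage:  python scripts/regenerate_sidechain_reference.py
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from vhhfc.data import BACKBONE_ATOMS, ONE_TO_THREE, VDW_RADII, DEFAULT_VDW_RADIUS
from vhhfc.sasa import sasa_brute_force

SEED = 20240101
N_POINTS = 4000
PROBE = 1.4


def sidechain_reference(one_letter: str) -> float:
    mol = Chem.MolFromSequence(f"G{one_letter}G")
    if mol is None:
        raise RuntimeError(f"RDKit could not build G{one_letter}G")
    params = AllChem.ETKDGv3()
    params.randomSeed = SEED
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for G{one_letter}G")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    conf = mol.GetConformer()

    xyz, radii, central_sidechain = [], [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        info = atom.GetPDBResidueInfo()
        pos = conf.GetAtomPosition(atom.GetIdx())
        xyz.append([pos.x, pos.y, pos.z])
        radii.append(VDW_RADII.get(atom.GetSymbol().upper(), DEFAULT_VDW_RADIUS))
        name = info.GetName().strip() if info else ""
        resnum = info.GetResidueNumber() if info else -1
        central_sidechain.append(resnum == 2 and name not in BACKBONE_ATOMS)

    sasa = sasa_brute_force(np.array(xyz), np.array(radii), PROBE, N_POINTS)
    return float(sasa[np.array(central_sidechain)].sum())


def main() -> None:
    print('"""Fully-exposed side-chain SASA reference (A^2), Gly-X-Gly based.')
    print()
    print("Generated by scripts/regenerate_sidechain_reference.py (same SASA")
    print('engine as the rest of the package; heavy atoms, probe 1.4 A)."""')
    print()
    print("MAX_SIDECHAIN_SAA: dict[str, float] = {")
    for one, three in sorted(ONE_TO_THREE.items(), key=lambda kv: kv[1]):
        if one == "G":
            print(f'    "{three}": 0.0,  # no side chain')
            continue
        val = sidechain_reference(one)
        print(f'    "{three}": {val:.1f},')
    print("}")


if __name__ == "__main__":
    main()
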