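"""Shared fixtures: small synthetic structures with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from vhhfc.fixtures import ResidueSpec, make_pose_ensemble, make_toy_structure
from vhhfc.sasa import shrake_rupley
from vhhfc.structure import Atom, Structure


def single_atom(element: str = "C", radius: float = 1.70) -> Structure:
    return Structure([Atom(1, "CA", element, 1, "GLY", "A",
                           0.0, 0.0, 0.0, radius)])


@pytest.fixture(scope="session")
def dipeptide():
    """Exposed Phe-Ser pair: every atom reasonably solvent accessible."""
    structure, truth = make_toy_structure([("PHE", True), ("SER", True)])
    return structure, truth


@pytest.fixture(scope="session")
def dipeptide_profile(dipeptide):
    structure, _ = dipeptide
    return shrake_rupley(structure)


@pytest.fixture(scope="session")
def catalysis_structure():
    """His + buried Met (cage with a channel) + exposed Met at 5.2 A S-S."""
    layout = [
        ResidueSpec("HIS", True),
        ResidueSpec("MET", exposed=False, anchor_distance=9.0,
                    cage_opening=(1, 0, 0)),
        ResidueSpec("MET", True, anchor_distance=5.2),
    ]
    return make_toy_structure(layout)


@pytest.fixture(scope="session")
def small_ensemble():
    """Planted 3 Fc-VHH + 1 VHH-VHH pose ensemble."""
    return make_pose_ensemble({"Fc-VHH": 3, "VHH-VHH": 1}, seed=7)


def brute_force_contacts(xyz_a, xyz_b, cutoff=5.0):
    """O(N^2) cross-set contact enumeration (independent oracle)."""
    pairs = []
    for i in range(len(xyz_a)):
        for j in range(len(xyz_b)):
            if np.linalg.norm(xyz_a[i] - xyz_b[j]) <= cutoff:
                pairs.append((i, j))
    return pairs
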