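"""Synthetic test structures, pose ensembles, and stability tables.

Every generator plants its ground truth by construction and returns it next
to the object, so downstream code can be checked without any external data:

* :func:`make_toy_structure` places minimal residues (coarse side chains in
  a single canonical orientation) on a sparse line, with per-residue control
  of solvent exposure (an exposed side chain points into open solvent; a
  buried one sits inside a dense occluding cage) and exact key-atom
  distances between consecutive residues.
* :func:`make_domain_dumbbell` builds a three-blob monomer whose residue
  numbering maps onto VHH / hinge / Fc boundaries.
* :func:`make_pose_ensemble` assembles multi-model homodimer poses that
  realize a planted binding-mode distribution and planted per-residue
  contact counts.
* :func:`make_stability_table` draws feature/attribute tables with planted
  Pearson correlations.

All randomness is seeded; identical spec + seed reproduces identical
output.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .interfaces import mode_label
from .sasa import fibonacci_sphere
from .structure import Atom, Structure

__all__ = [
    "ResidueSpec", "make_toy_structure",
    "make_domain_dumbbell", "make_pose_ensemble", "make_stability_table",
]


# Coarse side-chain templates: atom name -> offset (A) from the CA position,
# pointing along +z ("up", into solvent when exposed).  Single canonical
# orientation; deterministic geometry beats realism here.
_SIDECHAINS: dict[str, dict[str, tuple[float, float, float]]] = {
    "GLY": {},
    "ALA": {"CB": (0.0, 0.0, 1.5)},
    "SER": {"CB": (0.0, 0.0, 1.5), "OG": (0.0, 0.0, 2.9)},
    "CYS": {"CB": (0.0, 0.0, 1.5), "SG": (0.0, 0.0, 3.2)},
    "THR": {"CB": (0.0, 0.0, 1.5), "OG1": (-0.8, 0.0, 2.7),
            "CG2": (0.8, 0.0, 2.7)},
    "VAL": {"CB": (0.0, 0.0, 1.5), "CG1": (-0.8, 0.0, 2.7), "CG2": (0.8, 0.0, 2.7)},
    "LEU": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "CD1": (-0.8, 0.0, 4.2), "CD2": (0.8, 0.0, 4.2)},
    "PHE": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "CD1": (-1.2, 0.0, 3.7), "CD2": (1.2, 0.0, 3.7),
            "CE1": (-1.2, 0.0, 5.1), "CE2": (1.2, 0.0, 5.1),
            "CZ": (0.0, 0.0, 5.8)},
    "MET": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "SD": (0.0, 0.0, 4.8), "CE": (0.0, 0.0, 6.6)},
    "TRP": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "CD1": (-1.1, 0.0, 3.8), "CD2": (1.1, 0.0, 3.8),
            "NE1": (-0.8, 0.0, 5.1), "CE2": (0.9, 0.0, 5.2),
            "CZ2": (1.9, 0.0, 6.1), "CH2": (0.2, 0.0, 6.6)},
    "HIS": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "ND1": (-1.1, 0.0, 3.8), "CD2": (1.1, 0.0, 3.8),
            "CE1": (-0.7, 0.0, 5.1), "NE2": (0.7, 0.0, 5.1)},
    "LYS": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "CD": (0.0, 0.0, 4.5), "CE": (0.0, 0.0, 6.0),
            "NZ": (0.0, 0.0, 7.4)},
    "ARG": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "CD": (0.0, 0.0, 4.5), "NE": (0.0, 0.0, 5.9),
            "CZ": (0.0, 0.0, 7.2), "NH1": (-1.0, 0.0, 8.0),
            "NH2": (1.0, 0.0, 8.0)},
    "ASP": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "OD1": (-1.0, 0.0, 3.8), "OD2": (1.0, 0.0, 3.8)},
    "GLU": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "CD": (0.0, 0.0, 4.5), "OE1": (-1.0, 0.0, 5.3),
            "OE2": (1.0, 0.0, 5.3)},
    "TYR": {"CB": (0.0, 0.0, 1.5), "CG": (0.0, 0.0, 3.0),
            "CD1": (-1.2, 0.0, 3.7), "CD2": (1.2, 0.0, 3.7),
            "CE1": (-1.2, 0.0, 5.1), "CE2": (1.2, 0.0, 5.1),
            "CZ": (0.0, 0.0, 5.8), "OH": (0.0, 0.0, 7.2)},
}

# atom whose position carries a residue's planted distance ground truth
_KEY_ATOM: dict[str, str] = {"MET": "SD", "HIS": "NE2", "TRP": "NE1"}

_BACKBONE_OFFSETS = {
    "N": (-1.4, -0.9, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.4, -0.9, 0.0),
    "O": (1.6, -2.1, 0.0),
}

_SPACING = 9.0          # A between consecutive residue CA positions
_CAGE_RADIUS = 6.0      # A, occluding shell around a buried residue
_CAGE_POINTS = 350
_CLASH_MIN = 1.2        # A, below this two planned atoms clash


@dataclasses.dataclass
class ResidueSpec:
    """One residue of a toy structure.

    ``anchor_distance`` places this residue so its key atom (SD for Met,
    NE2 for His, NE1 for Trp, CB otherwise) sits exactly that far from the
    previous residue's key atom.
    """

    name: str
    exposed: bool = True
    anchor_distance: float | None = None
    # unit-ish direction: cage points within ~53 degrees of it are omitted,
    # leaving a solvent channel (partial burial) toward that side
    cage_opening: tuple[float, float, float] | None = None


def _element_of(atom_name: str) -> str:
    return "S" if atom_name.startswith("S") else atom_name[0]


def make_toy_structure(layout: Sequence[ResidueSpec | tuple], seed: int = 0,
                       chain_id: str = "A",
                       start_number: int = 1) -> tuple[Structure, dict]:
    """Build a minimal structure from a residue layout; returns ground truth.

    Truth dict keys: ``residues`` (number, name, exposed, key atom name),
    ``key_atom_xyz`` (number -> coordinates), ``distances`` (consecutive
    key-atom distances as planted).
    """
    specs = [r if isinstance(r, ResidueSpec) else ResidueSpec(*r) for r in layout]
    if not specs:
        raise ValueError("empty layout")
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    serial = 1
    truth: dict = {"seed": seed, "residues": [], "key_atom_xyz": {},
                   "distances": {}}
    key_xyz_prev: np.ndarray | None = None
    cage_number = start_number + len(specs) + 100  # numbering gap for cages

    core_positions: list[np.ndarray] = []
    for i, spec in enumerate(specs):
        name = spec.name.upper()
        if name not in _SIDECHAINS:
            raise ValueError(f"no template for residue type {name!r}")
        number = start_number + i
        key_atom = _KEY_ATOM.get(name, "CB" if _SIDECHAINS[name] else "CA")
        key_off = np.array(_SIDECHAINS[name].get(key_atom, (0.0, 0.0, 0.0)))

        ca = np.array([i * _SPACING, 0.0, 0.0])
        if spec.anchor_distance is not None:
            if key_xyz_prev is None:
                raise ValueError("anchor_distance on the first residue")
            # slide along +x so the key atoms sit at the requested distance
            target = key_xyz_prev + np.array([spec.anchor_distance, 0.0, 0.0])
            ca = target - key_off

        placed: dict[str, np.ndarray] = {}
        for aname, off in _BACKBONE_OFFSETS.items():
            placed[aname] = ca + np.array(off)
        for aname, off in _SIDECHAINS[name].items():
            placed[aname] = ca + np.array(off)

        for pos in placed.values():
            for prev in core_positions:
                if np.linalg.norm(pos - prev) < _CLASH_MIN:
                    raise ValueError(
                        f"impossible layout: residue {number} clashes with an "
                        "earlier residue"
                    )
        core_positions.extend(placed.values())

        for aname in list(_BACKBONE_OFFSETS) + list(_SIDECHAINS[name]):
            pos = placed[aname]
            atoms.append(Atom(serial=serial, name=aname,
                              element=_element_of(aname),
                              residue_number=number, residue_name=name,
                              chain_id=chain_id, x=float(pos[0]),
                              y=float(pos[1]), z=float(pos[2]),
                              vdw_radius=_radius(_element_of(aname))))
            serial += 1

        key_xyz = placed[key_atom]
        truth["residues"].append({"number": number, "name": name,
                                  "exposed": spec.exposed,
                                  "key_atom": key_atom})
        truth["key_atom_xyz"][number] = key_xyz.tolist()
        if spec.anchor_distance is not None:
            truth["distances"][(number - 1, number)] = spec.anchor_distance
        key_xyz_prev = key_xyz

        if not spec.exposed:
            center = np.mean(list(placed.values()), axis=0)
            dirs = fibonacci_sphere(_CAGE_POINTS)
            if spec.cage_opening is not None:
                opening = np.asarray(spec.cage_opening, dtype=float)
                opening = opening / np.linalg.norm(opening)
                dirs = dirs[dirs @ opening <= 0.6]
            shell = center + _CAGE_RADIUS * dirs
            # tiny jitter keeps cage shells of different residues distinct
            shell = shell + rng.normal(0.0, 1e-3, shell.shape)
            for k, pos in enumerate(shell):
                atoms.append(Atom(serial=serial, name=f"C{k:03d}",
                                  element="C", residue_number=cage_number,
                                  residue_name="GLY", chain_id=chain_id,
                                  x=float(pos[0]), y=float(pos[1]),
                                  z=float(pos[2]), vdw_radius=_radius("C")))
                serial += 1
            cage_number += 1

    atoms.sort(key=lambda a: (a.residue_number, a.serial))
    atoms = [dataclasses.replace(a, serial=i + 1) for i, a in enumerate(atoms)]
    return Structure(atoms), truth


def _radius(element: str) -> float:
    from .data import DEFAULT_VDW_RADIUS, VDW_RADII
    return VDW_RADII.get(element, DEFAULT_VDW_RADIUS)


# ---------------------------------------------------------------------------
# Domain dumbbell and docked-pose ensembles
# ---------------------------------------------------------------------------

def make_domain_dumbbell(n_vhh: int = 6, n_hinge: int = 3, n_fc: int = 6,
                         chain_id: str = "A", spacing: float = 12.0,
                         ) -> tuple[Structure, dict]:
    """A sparse one-atom-per-residue monomer with VHH / hinge / Fc blocks.

    Residues are numbered 1..n consecutively; the returned truth holds the
    domain boundaries dict (usable with :func:`vhhfc.structure.annotate_domains`)
    and the residue -> domain map.
    """
    n = n_vhh + n_hinge + n_fc
    atoms = []
    domain_of: dict[int, str] = {}
    for i in range(n):
        number = i + 1
        if number <= n_vhh:
            dom = "VHH"
        elif number <= n_vhh + n_hinge:
            dom = "hinge"
        else:
            dom = "Fc"
        domain_of[number] = dom
        atoms.append(Atom(serial=number, name="CA", element="C",
                          residue_number=number, residue_name="ALA",
                          chain_id=chain_id, x=i * spacing, y=0.0, z=0.0,
                          vdw_radius=_radius("C")))
    boundaries = {
        "VHH": (1, n_vhh),
        "hinge": (n_vhh + 1, n_vhh + n_hinge),
        "Fc": (n_vhh + n_hinge + 1, None),
    }
    truth = {"boundaries": boundaries, "domain_of": domain_of,
             "spacing": spacing, "n_residues": n}
    return Structure(atoms), truth


_CONTACT_Z = 3.0  # vertical separation of a planted contact pair (< 5 A)


def make_pose_ensemble(mode_distribution: Mapping[str, int], seed: int = 0,
                       n_vhh: int = 6, n_hinge: int = 3, n_fc: int = 6,
                       contacts_per_pose: tuple[int, int] = (1, 3),
                       ) -> tuple[Structure, dict]:
    """Multi-model homodimer poses realizing a planted mode distribution.

    Each model holds chains A (receptor) and B (ligand), identical residue
    numbering.  For a pose of mode "X-Y", contact pairs are planted between
    residues of domain X on A and domain Y on B only, so the majority-domain
    classification recovers the planted mode exactly.  Unplanted atoms stay
    far (> 5 A) from the partner chain.

    Truth keys: ``modes`` (per-pose labels in model order), ``counts``
    (residue -> summed contact count over poses and both roles), ``ppip``
    (residue -> count / max), ``boundaries``.
    """
    if not mode_distribution or sum(mode_distribution.values()) == 0:
        raise ValueError("empty mode distribution")
    monomer, mono_truth = make_domain_dumbbell(n_vhh, n_hinge, n_fc)
    domain_residues: dict[str, list[int]] = {"VHH": [], "hinge": [], "Fc": []}
    for num, dom in mono_truth["domain_of"].items():
        domain_residues[dom].append(num)

    rng = np.random.default_rng(seed)
    pose_specs: list[tuple[str, str]] = []
    for mode, count in sorted(mode_distribution.items()):
        if count < 0:
            raise ValueError("negative pose count")
        a_dom, b_dom = mode.split("-")
        for d in (a_dom, b_dom):
            if d not in domain_residues:
                raise ValueError(f"unknown domain {d!r} in mode {mode!r}")
        pose_specs.extend([(a_dom, b_dom)] * count)

    n_atoms = monomer.n_atoms
    base = monomer.coords[0]
    atoms = list(monomer.atoms) + [
        dataclasses.replace(a, serial=a.serial + n_atoms, chain_id="B")
        for a in monomer.atoms
    ]

    lo, hi = contacts_per_pose
    counts: dict[int, int] = {}
    modes: list[str] = []
    coords = np.empty((len(pose_specs), 2 * n_atoms, 3))
    for m, (a_dom, b_dom) in enumerate(pose_specs):
        xyz_a = base.copy()
        # chain B rotated into the y direction and parked far away
        xyz_b = base[:, [1, 0, 2]].copy()
        xyz_b[:, 2] += 200.0

        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(domain_residues[a_dom]), len(domain_residues[b_dom]))
        res_a = rng.choice(domain_residues[a_dom], size=k, replace=False)
        res_b = rng.choice(domain_residues[b_dom], size=k, replace=False)
        for ra, rb in zip(res_a, res_b):
            ia = int(ra) - 1          # one atom per residue, in order
            ib = int(rb) - 1
            xyz_b[ib] = xyz_a[ia] + np.array([0.0, 0.0, _CONTACT_Z])
            counts[int(ra)] = counts.get(int(ra), 0) + 1
            counts[int(rb)] = counts.get(int(rb), 0) + 1
        coords[m, :n_atoms] = xyz_a
        coords[m, n_atoms:] = xyz_b
        # planted majority is exact: all A-side contacts in a_dom, B-side in b_dom
        modes.append(mode_label(a_dom, b_dom))

    structure = Structure(atoms, coords)
    peak = max(counts.values())
    truth = {
        "modes": modes,
        "counts": counts,
        "ppip": {num: c / peak for num, c in counts.items()},
        "boundaries": mono_truth["boundaries"],
        "seed": seed,
    }
    return structure, truth


# ---------------------------------------------------------------------------
# Stability tables with planted correlations
# ---------------------------------------------------------------------------

def make_stability_table(n_samples: int = 12,
                         planted: Mapping[tuple[str, str], float] | None = None,
                         n_null_features: int = 0, n_null_attributes: int = 0,
                         seed: int = 0):
    """Feature and attribute tables with planted Pearson correlations.

    ``planted`` maps (feature_name, attribute_name) -> rho; each such pair
    gets its own latent normal draw, with feature = rho * z + sqrt(1-rho^2)
    * noise, so rho = 1 gives exact linear dependence.  Extra independent
    N(0,1) columns are appended for null calibration.  Returns
    (features, attributes, truth) with pandas DataFrames indexed by sample
    name.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    index = [f"S{i + 1}" for i in range(n_samples)]
    feats: dict[str, np.ndarray] = {}
    attrs: dict[str, np.ndarray] = {}
    planted = dict(planted or {})
    for (fname, aname), rho in planted.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        z = rng.standard_normal(n_samples)
        noise = rng.standard_normal(n_samples)
        attrs[aname] = z
        feats[fname] = rho * z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * noise
    for i in range(n_null_features):
        feats[f"null_feat_{i + 1}"] = rng.standard_normal(n_samples)
    for i in range(n_null_attributes):
        attrs[f"null_attr_{i + 1}"] = rng.standard_normal(n_samples)
    if not feats or not attrs:
        raise ValueError("need at least one feature and one attribute column")

    features = pd.DataFrame(feats, index=index)
    attributes = pd.DataFrame(attrs, index=index)
    truth = {"planted": planted, "seed": seed, "n_samples": n_samples}
    return features, attributes, truth
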