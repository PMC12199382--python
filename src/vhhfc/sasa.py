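"""Solvent-accessible surface area and surface patches.

SASA is computed with the Shrake-Rupley rolling-probe quadrature: each atom's
expanded sphere (vdW radius + probe) is sampled on a deterministic Fibonacci
point set and a point counts as accessible when it lies outside every
neighbor's expanded sphere.  To make the result invariant under rigid motions
of the input (to floating-point precision rather than quadrature noise), the
molecule is first rotated into a canonical principal-axes frame; this can be
disabled with ``canonical_frame=False``.

Hydrophobic and ionic surface patches are contiguous (single-linkage,
distance-cutoff) clusters of exposed atoms of one character, with the areas
reported as the summed SASA of the member atoms.  Conventional thresholds for
flagging a patch as significant are > 50 A^2 (hydrophobic) and > 40 A^2
(ionic).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .data import (
    ATOMIC_HYDROPHOBICITY,
    BACKBONE_ATOMS,
    HIS_CHARGES,
    MAX_ASA,
    SIDECHAIN_CHARGES,
)
from .structure import Structure

__all__ = [
    "SASAProfile",
    "Patch",
    "shrake_rupley",
    "relative_sasa",
    "hydrophobic_patches",
    "ionic_patches",
    "fibonacci_sphere",
]


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _canonical_rotation(xyz: np.ndarray) -> np.ndarray:
    """Principal-axes frame with signs fixed by coordinate skewness.

    The sign convention (third moment of the projections non-negative) is a
    property of the point cloud, not of the input basis, so rigidly moved
    copies of a molecule land in the same canonical frame.  Point clouds
    with degenerate principal components or exactly zero skewness (high
    symmetry) remain ambiguous; such inputs are not rotation-stable.
    """
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(3):
        skew = float(np.sum((centered @ vecs[:, k]) ** 3))
        if skew < 0:
            vecs[:, k] = -vecs[:, k]
    return vecs


@dataclasses.dataclass
class SASAProfile:
    """Per-atom and per-residue solvent accessibility for one structure."""

    atom_sasa: np.ndarray                      # (n_atoms,), A^2 (model mean)
    residue_sasa: dict[tuple[str, int], float]             # all atoms
    residue_sidechain_sasa: dict[tuple[str, int], float]   # non-backbone atoms
    probe: float
    n_points: int

    def relative(self, structure: Structure,
                 reference_table: Mapping[str, float] | None = None,
                 ) -> dict[tuple[str, int], float]:
        return relative_sasa(structure, self, reference_table)


def shrake_rupley(structure: Structure, probe: float = 1.4,
                  n_points: int = 960, model: int | None = None,
                  canonical_frame: bool = True) -> SASAProfile:
    """Per-atom SASA (A^2) by Shrake-Rupley quadrature.

    ``model=None`` averages over all models in the structure; an integer
    selects a single model.  Deterministic for a fixed point count.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 92:
        raise ValueError("n_points must be at least 92")
    radii = structure.radii
    models = range(structure.n_models) if model is None else [model]
    per_model = [
        _sasa_single_model(structure.coords[m], radii, probe, n_points,
                           canonical_frame)
        for m in models
    ]
    atom_sasa = np.mean(per_model, axis=0)

    residue_sasa: dict[tuple[str, int], float] = {}
    residue_sc: dict[tuple[str, int], float] = {}
    for i, a in enumerate(structure.atoms):
        key = (a.chain_id, a.residue_number)
        residue_sasa[key] = residue_sasa.get(key, 0.0) + float(atom_sasa[i])
        if a.name not in BACKBONE_ATOMS and a.element != "H":
            residue_sc[key] = residue_sc.get(key, 0.0) + float(atom_sasa[i])
        else:
            residue_sc.setdefault(key, 0.0)
    return SASAProfile(atom_sasa=atom_sasa, residue_sasa=residue_sasa,
                       residue_sidechain_sasa=residue_sc,
                       probe=probe, n_points=n_points)


def _sasa_single_model(xyz: np.ndarray, radii: np.ndarray, probe: float,
                       n_points: int, canonical_frame: bool) -> np.ndarray:
    if not np.isfinite(xyz).all():
        raise ValueError("non-finite coordinates")
    if canonical_frame and xyz.shape[0] > 1:
        rot = _canonical_rotation(xyz)
        xyz = (xyz - xyz.mean(axis=0)) @ rot
    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(xyz)
    search = 2.0 * float(expanded.max())
    out = np.zeros(len(xyz))
    for i in range(len(xyz)):
        r_i = expanded[i]
        pts = xyz[i] + r_i * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], search)
                     if j != i and np.linalg.norm(xyz[j] - xyz[i]) < r_i + expanded[j]]
        if neighbors:
            nb = np.array(neighbors, dtype=int)
            d2 = ((pts[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * r_i ** 2 * frac
    return out


def sasa_brute_force(xyz: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                     n_points: int = 10000) -> np.ndarray:
    """Independent O(N^2) quadrature (no spatial index, no canonical frame).

    Intended as a high-density oracle for validating :func:`shrake_rupley`.
    """
    sphere = fibonacci_sphere(n_points)
    expanded = np.asarray(radii, dtype=float) + probe
    xyz = np.asarray(xyz, dtype=float)
    out = np.zeros(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + expanded[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(xyz)):
            if j == i:
                continue
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[j] ** 2
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return out


def relative_sasa(structure: Structure, profile: SASAProfile,
                  reference_table: Mapping[str, float] | None = None,
                  ) -> dict[tuple[str, int], float]:
    """Percent SASA relative to the fully exposed reference per residue type.

    Values can exceed 100 for terminal or unusually extended residues; they
    are reported as computed.
    """
    ref = dict(MAX_ASA if reference_table is None else reference_table)
    out: dict[tuple[str, int], float] = {}
    for chain_id, num, name in structure.residues():
        if name not in ref:
            raise KeyError(f"no fully-exposed reference SASA for residue type {name!r}")
        out[(chain_id, num)] = 100.0 * profile.residue_sasa[(chain_id, num)] / ref[name]
    return out


# ---------------------------------------------------------------------------
# Surface patches
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Patch:
    """A contiguous cluster of exposed atoms of one surface character."""

    kind: str                       # hydrophobic | positive | negative
    member_atoms: list[int]         # atom indices into the structure
    area: float                     # summed member SASA, A^2

    def residues(self, structure: Structure) -> set[tuple[str, int]]:
        return {(structure.atoms[i].chain_id, structure.atoms[i].residue_number)
                for i in self.member_atoms}


SURFACE_SASA_MIN = 0.1  # A^2: atoms below this are not "surface"


def _cluster_patches(structure: Structure, profile: SASAProfile, kind: str,
                     candidate_idx: np.ndarray, min_area: float,
                     adjacency_cutoff: float, model: int = 0) -> list[Patch]:
    if candidate_idx.size == 0:
        return []
    xyz = structure.coords[model][candidate_idx]
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(adjacency_cutoff, output_type="ndarray")
    # union-find over candidates
    parent = np.arange(candidate_idx.size)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for local in range(candidate_idx.size):
        groups.setdefault(find(local), []).append(local)

    patches = []
    for members in groups.values():
        atoms = [int(candidate_idx[m]) for m in members]
        area = float(profile.atom_sasa[atoms].sum())
        if area > min_area:
            patches.append(Patch(kind=kind, member_atoms=sorted(atoms), area=area))
    patches.sort(key=lambda p: (-p.area, p.member_atoms))
    return patches


def hydrophobic_patches(structure: Structure, profile: SASAProfile,
                        min_area: float = 50.0, adjacency_cutoff: float = 4.5,
                        hydrophobicity: Mapping[str, float] | None = None,
                        ) -> list[Patch]:
    """Surface patches of hydrophobic atoms with summed SASA > ``min_area``.

    An atom participates when it is exposed (SASA > 0.1 A^2) and its
    per-element hydrophobicity contribution is positive (aliphatic/aromatic
    carbon, weakly sulfur).  Patches are sorted by area, largest first.
    """
    table = dict(ATOMIC_HYDROPHOBICITY if hydrophobicity is None else hydrophobicity)
    idx = np.array(
        [i for i, a in enumerate(structure.atoms)
         if profile.atom_sasa[i] > SURFACE_SASA_MIN
         and table.get(a.element, 0.0) > 0.0],
        dtype=int,
    )
    return _cluster_patches(structure, profile, "hydrophobic", idx,
                            min_area, adjacency_cutoff)


def ionic_patches(structure: Structure, profile: SASAProfile,
                  min_area: float = 40.0, adjacency_cutoff: float = 4.5,
                  his_protonated: bool = False) -> list[Patch]:
    """Positive and negative surface patches from formal side-chain charges.

    Charge placement: Asp/Glu carboxylate oxygens -0.5 each, Lys NZ +1,
    Arg NH1/NH2 +0.5 each; His ND1/NE2 +0.5 each only when
    ``his_protonated``.  Positive and negative atoms cluster separately.
    """
    charges = dict(SIDECHAIN_CHARGES)
    if his_protonated:
        charges.update(HIS_CHARGES)
    pos, neg = [], []
    for i, a in enumerate(structure.atoms):
        if profile.atom_sasa[i] <= SURFACE_SASA_MIN:
            continue
        q = charges.get((a.residue_name, a.name), 0.0)
        if q > 0:
            pos.append(i)
        elif q < 0:
            neg.append(i)
    out = _cluster_patches(structure, profile, "positive",
                           np.array(pos, dtype=int), min_area, adjacency_cutoff)
    out += _cluster_patches(structure, profile, "negative",
                            np.array(neg, dtype=int), min_area, adjacency_cutoff)
    out.sort(key=lambda p: (-p.area, p.kind))
    return out
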