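"""Spatial aggregation propensity (SAP) and the developability index (DI).

SAP assigns each atom a local hydrophobic-exposure score: for every residue
with at least one atom within the 5 A sphere around the atom, take the
solvent-accessible area of that residue's side-chain atoms inside the
sphere, divide by the side-chain area of the fully exposed residue of that
type, and weight by the residue's hydrophobicity (Black & Mould scale
normalized so Gly = 0).  Summing the contributions over neighbor residues
gives SAP for the atom; for multi-model inputs the per-model SAP values are
averaged.

The SAP score of a domain is the sum of positive atomic SAP values over the
CDR atoms, and the developability index combines it with the molecule's net
charge q:

    DI = SAP_score - beta * q**2,   beta = 0.0498

so a large exposed hydrophobic CDR surface raises DI (worse) and net charge
of either sign lowers it (electrostatic self-repulsion protects against
aggregation).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .data import BACKBONE_ATOMS, sap_hydrophobicity
from .data_sidechain import MAX_SIDECHAIN_SAA
from .sasa import SASAProfile, shrake_rupley
from .structure import DomainAnnotation, Structure

__all__ = ["SAPResult", "sap_per_atom", "sap_atom", "sap_score",
           "developability_index", "DEFAULT_BETA", "DEFAULT_SAP_RADIUS"]

DEFAULT_BETA = 0.0498
DEFAULT_SAP_RADIUS = 5.0


@dataclasses.dataclass
class SAPResult:
    """Atomic SAP values plus the aggregate score/DI for one structure."""

    atom_sap: np.ndarray
    sap_score: float
    net_charge: float | None = None
    di: float | None = None
    beta: float = DEFAULT_BETA


def _residue_atom_indices(structure: Structure) -> dict[tuple[str, int], list[int]]:
    out: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        out.setdefault((a.chain_id, a.residue_number), []).append(i)
    return out


def sap_per_atom(structure: Structure, profile: SASAProfile | None = None,
                 radius: float = DEFAULT_SAP_RADIUS,
                 hydrophobicity: Mapping[str, float] | None = None,
                 reference_saa: Mapping[str, float] | None = None,
                 model: int | None = None) -> np.ndarray:
    """SAP value for every atom (mean over models when ``model`` is None)."""
    phi = sap_hydrophobicity(dict(hydrophobicity) if hydrophobicity else None)
    ref = dict(MAX_SIDECHAIN_SAA if reference_saa is None else reference_saa)

    resname_of: dict[tuple[str, int], str] = {
        (c, n): name for c, n, name in structure.residues()
    }
    res_atoms = _residue_atom_indices(structure)
    sidechain = np.array(
        [a.name not in BACKBONE_ATOMS and a.element != "H" for a in structure.atoms]
    )

    models = range(structure.n_models) if model is None else [model]
    per_model = []
    for m in models:
        prof = profile if (profile is not None and structure.n_models == 1) \
            else shrake_rupley(structure, model=m)
        per_model.append(_sap_single_model(
            structure, prof, structure.coords[m], radius, phi, ref,
            resname_of, res_atoms, sidechain))
    return np.mean(per_model, axis=0)


def _sap_single_model(structure: Structure, profile: SASAProfile,
                      xyz: np.ndarray, radius: float,
                      phi: Mapping[str, float], ref: Mapping[str, float],
                      resname_of: Mapping[tuple[str, int], str],
                      res_atoms: Mapping[tuple[str, int], list[int]],
                      sidechain: np.ndarray) -> np.ndarray:
    tree = cKDTree(xyz)
    neighbor_lists = tree.query_ball_tree(tree, radius)
    atom_res = [(a.chain_id, a.residue_number) for a in structure.atoms]

    out = np.zeros(structure.n_atoms)
    for i in range(structure.n_atoms):
        near = neighbor_lists[i]
        residues_near = {atom_res[j] for j in near}
        total = 0.0
        for key in residues_near:
            name = resname_of[key]
            if name not in phi:
                raise KeyError(f"no hydrophobicity value for residue type {name!r}")
            weight = phi[name]
            if weight == 0.0:
                continue
            denom = ref.get(name)
            if denom is None:
                raise KeyError(f"no fully-exposed side-chain SAA for {name!r}")
            if denom <= 0.0:
                continue
            near_set = set(near)
            saa_in_sphere = sum(
                float(profile.atom_sasa[j]) for j in res_atoms[key]
                if sidechain[j] and j in near_set
            )
            total += (saa_in_sphere / denom) * weight
        out[i] = total
    return out


def sap_atom(structure: Structure, profile: SASAProfile, atom_index: int,
             radius: float = DEFAULT_SAP_RADIUS,
             hydrophobicity: Mapping[str, float] | None = None,
             reference_saa: Mapping[str, float] | None = None) -> float:
    """SAP value of a single atom (convenience wrapper)."""
    values = sap_per_atom(structure, profile, radius, hydrophobicity,
                          reference_saa)
    return float(values[atom_index])


def sap_score(structure: Structure, atom_sap: np.ndarray,
              cdr_ranges: Sequence[tuple[int, int]] | DomainAnnotation) -> float:
    """Sum of positive atomic SAP values over CDR atoms."""
    if isinstance(cdr_ranges, DomainAnnotation):
        ranges = cdr_ranges.cdr_ranges
    else:
        ranges = list(cdr_ranges)
    if not ranges:
        raise ValueError("empty CDR set: annotate CDR ranges first")
    in_cdr = np.array([
        any(lo <= a.residue_number <= hi for lo, hi in ranges)
        for a in structure.atoms
    ])
    vals = np.asarray(atom_sap)[in_cdr]
    return float(vals[vals > 0].sum())


def developability_index(sap_score_value: float, net_charge: float,
                         beta: float = DEFAULT_BETA) -> float:
    """DI = SAP score - beta * q^2 (lower predicts lower aggregation risk)."""
    return float(sap_score_value - beta * net_charge ** 2)
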