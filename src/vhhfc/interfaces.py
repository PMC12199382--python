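"""Docked dimer pose ensembles: contacts, binding modes, interface preference.

A pose ensemble is a multi-model PDB in which each model holds one docked
dimer (receptor chain + ligand chain).  Cross-partner heavy-atom contacts
within 5 A define the interface of a pose; each pose is classified into a
domain-pair binding mode (Fc-Fc, Fc-VHH, Fc-hinge, hinge-hinge, hinge-VHH,
VHH-VHH) by the domain owning the most interface contacts on each partner.

Per-residue protein-protein interaction preference (PPIP) counts, for every
sequence position, the interface contacts summed over poses, over both
partner roles (the two chains of a homodimer share one numbering), and over
ensembles, then normalizes by the maximum count so values lie in [0, 1].
Residues with PPIP > 0.5 form the aggregation interface.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import DomainAnnotation, Structure, read_pdb

__all__ = [
    "Pose", "PoseEnsemble", "PPIPMap", "ModeSummary",
    "load_pose_ensemble", "interface_contacts", "classify_binding_mode",
    "mode_summary", "ppi_preference", "aggregation_interface",
    "BINDING_MODES", "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 5.0

# Canonical domain order for naming unordered pairs; tie-breaks on a partner
# prefer the designable antigen-binding domain first.
_DOMAIN_ORDER = ("Fc", "hinge", "VHH")
_TIE_PRIORITY = ("VHH", "hinge", "Fc")

BINDING_MODES = (
    "Fc-Fc", "Fc-VHH", "Fc-hinge", "hinge-hinge", "hinge-VHH", "VHH-VHH",
)
UNBOUND = "unbound"


def mode_label(domain_a: str, domain_b: str) -> str:
    a, b = sorted((domain_a, domain_b), key=_DOMAIN_ORDER.index)
    return f"{a}-{b}"


@dataclasses.dataclass
class Pose:
    """One docked dimer: atom indices of each partner within the model."""

    structure: Structure            # shared atom identities
    model: int
    receptor_idx: np.ndarray
    ligand_idx: np.ndarray
    energy: float | None = None


@dataclasses.dataclass
class PoseEnsemble:
    poses: list[Pose]
    label: str = ""

    def __len__(self) -> int:
        return len(self.poses)


def load_pose_ensemble(path: str | Path, energy_table: pd.DataFrame | str | Path | None = None,
                       receptor_chain: str | None = None,
                       ligand_chain: str | None = None,
                       label: str = "") -> PoseEnsemble:
    """Read a multi-model PDB of docked dimers, optionally joining energies.

    Each model must contain exactly two chains unless an explicit
    receptor/ligand chain split is declared.  Energies are joined by pose
    index (file order); a row-count mismatch is an error.
    """
    structure = read_pdb(path)
    chains = structure.chain_ids
    if receptor_chain is None or ligand_chain is None:
        if len(chains) != 2:
            raise ValueError(
                f"{path}: expected exactly 2 chains per model, found {chains}; "
                "declare receptor_chain/ligand_chain explicitly"
            )
        receptor_chain, ligand_chain = chains

    energies: list[float | None]
    if energy_table is None:
        energies = [None] * structure.n_models
    else:
        if not isinstance(energy_table, pd.DataFrame):
            energy_table = pd.read_csv(energy_table)
        if len(energy_table) != structure.n_models:
            raise ValueError(
                f"energy table has {len(energy_table)} rows for "
                f"{structure.n_models} poses"
            )
        col = "energy_kcal_mol" if "energy_kcal_mol" in energy_table.columns \
            else energy_table.columns[-1]
        energies = [float(v) for v in energy_table[col]]

    rec = structure.atom_indices(receptor_chain)
    lig = structure.atom_indices(ligand_chain)
    poses = [
        Pose(structure=structure, model=m, receptor_idx=rec, ligand_idx=lig,
             energy=energies[m])
        for m in range(structure.n_models)
    ]
    return PoseEnsemble(poses=poses, label=label)


def interface_contacts(pose: Pose, cutoff: float = DEFAULT_CONTACT_CUTOFF
                       ) -> list[tuple[int, int]]:
    """Cross-partner heavy-atom pairs within ``cutoff`` (inclusive).

    Returns (receptor_atom_index, ligand_atom_index) pairs in deterministic
    sorted order.
    """
    xyz = pose.structure.coords[pose.model]
    heavy = np.array([a.element != "H" for a in pose.structure.atoms])
    rec = pose.receptor_idx[heavy[pose.receptor_idx]]
    lig = pose.ligand_idx[heavy[pose.ligand_idx]]
    if rec.size == 0 or lig.size == 0:
        return []
    tree_l = cKDTree(xyz[lig])
    pairs: list[tuple[int, int]] = []
    for local_r, r_idx in enumerate(rec):
        for local_l in tree_l.query_ball_point(xyz[r_idx], cutoff):
            pairs.append((int(r_idx), int(lig[local_l])))
    pairs.sort()
    return pairs


def classify_binding_mode(pose: Pose, annotation: DomainAnnotation,
                          cutoff: float = DEFAULT_CONTACT_CUTOFF) -> str:
    """Domain-pair label of a pose by majority contact count per partner.

    Ties on one partner resolve by the fixed priority VHH > hinge > Fc.
    Returns the sentinel ``"unbound"`` when the pose has no contacts.
    """
    contacts = interface_contacts(pose, cutoff)
    if not contacts:
        return UNBOUND
    atoms = pose.structure.atoms

    def majority(side: int) -> str:
        counts: dict[str, int] = {}
        for pair in contacts:
            dom = annotation.domain(atoms[pair[side]].residue_number)
            counts[dom] = counts.get(dom, 0) + 1
        best = max(counts.values())
        tied = [d for d, c in counts.items() if c == best]
        return min(tied, key=_TIE_PRIORITY.index)

    return mode_label(majority(0), majority(1))


@dataclasses.dataclass
class ModeSummary:
    """Counts, percentages and energy statistics per binding mode."""

    counts: dict[str, int]
    percentages: dict[str, float]
    mean_energy: dict[str, float | None]
    sd_energy: dict[str, float | None]
    n_classified: int
    n_unbound: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode": list(BINDING_MODES),
            "count": [self.counts.get(m, 0) for m in BINDING_MODES],
            "percentage": [self.percentages.get(m, 0.0) for m in BINDING_MODES],
            "mean_energy": [self.mean_energy.get(m) for m in BINDING_MODES],
            "sd_energy": [self.sd_energy.get(m) for m in BINDING_MODES],
        })


def mode_summary(ensemble: PoseEnsemble, annotation: DomainAnnotation,
                 cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ModeSummary:
    """Classify every pose and summarize counts, percentages, energies."""
    labels = [classify_binding_mode(p, annotation, cutoff) for p in ensemble.poses]
    classified = [(lab, p.energy) for lab, p in zip(labels, ensemble.poses)
                  if lab != UNBOUND]
    n = len(classified)
    counts: dict[str, int] = {}
    energies: dict[str, list[float]] = {}
    for lab, e in classified:
        counts[lab] = counts.get(lab, 0) + 1
        if e is not None:
            energies.setdefault(lab, []).append(e)
    percentages = {m: 100.0 * c / n for m, c in counts.items()} if n else {}
    mean_e: dict[str, float | None] = {}
    sd_e: dict[str, float | None] = {}
    for m in counts:
        es = energies.get(m, [])
        mean_e[m] = float(np.mean(es)) if es else None
        sd_e[m] = float(np.std(es, ddof=1)) if len(es) > 1 else None
    return ModeSummary(counts=counts, percentages=percentages,
                       mean_energy=mean_e, sd_energy=sd_e,
                       n_classified=n, n_unbound=len(labels) - n)


@dataclasses.dataclass
class PPIPMap:
    """Per-residue interface preference in [0, 1] plus raw contact counts."""

    counts: dict[int, int]
    preference: dict[int, float]

    def preference_of(self, residue_number: int) -> float:
        """Preference of a position; 0.0 for positions never at an interface."""
        return self.preference.get(residue_number, 0.0)

    def as_frame(self) -> pd.DataFrame:
        nums = sorted(self.counts)
        return pd.DataFrame({
            "residue_number": nums,
            "count": [self.counts[n] for n in nums],
            "preference": [self.preference[n] for n in nums],
        })


def _contact_counts(ensemble: PoseEnsemble, cutoff: float) -> dict[int, int]:
    counts: dict[int, int] = {}
    for pose in ensemble.poses:
        atoms = pose.structure.atoms
        for r_idx, l_idx in interface_contacts(pose, cutoff):
            # homodimer symmetry: both roles map onto one sequence numbering
            for idx in (r_idx, l_idx):
                num = atoms[idx].residue_number
                counts[num] = counts.get(num, 0) + 1
    return counts


def ppi_preference(ensembles: PoseEnsemble | Iterable[PoseEnsemble],
                   cutoff: float = DEFAULT_CONTACT_CUTOFF) -> PPIPMap:
    """Interface preference per sequence position across one or more
    ensembles: raw contact counts are summed across all ensembles before a
    single global normalization by the maximum."""
    if isinstance(ensembles, PoseEnsemble):
        ensembles = [ensembles]
    counts: dict[int, int] = {}
    any_pose = False
    for ens in ensembles:
        any_pose = any_pose or len(ens) > 0
        for num, c in _contact_counts(ens, cutoff).items():
            counts[num] = counts.get(num, 0) + c
    if not counts:
        raise ValueError("no contacts in any pose of any ensemble")
    peak = max(counts.values())
    preference = {num: c / peak for num, c in counts.items()}
    return PPIPMap(counts=counts, preference=preference)


def aggregation_interface(ppipmap: PPIPMap, threshold: float = 0.5) -> set[int]:
    """Residues whose interface preference strictly exceeds the threshold."""
    return {num for num, p in ppipmap.preference.items() if p > threshold}
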