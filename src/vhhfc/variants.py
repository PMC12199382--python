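"""Rule-based variant enumeration and evaluation.

Substitution rules per mutable hotspot site:

* Cys -> Ser (chemically similar -OH, removes the labile thiol); the
  reduction-prone cysteine substitution is "always on" - every enumerated
  variant carries it.
* Trp -> Phe (similar aromatic side chain without the oxidation liability).
* Hydrophobic residues (A, V, L, I, F, M, Y) -> Lys or Asp (charged,
  aggregation-suppressing).

Variants are all combinations of per-site options up to ``max_substitutions``
sites that include every always-on site, named M1..Mn deterministically.
Binding-critical sites are never mutated.

Applying a variant to a structure renames the residue and truncates the side
chain beyond C-beta (no rotamer building): recomputed aggregation scores for
variants therefore use the mutant residue's hydrophobicity with roughly the
wild-type exposure geometry.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

from .charge import isoelectric_point, net_charge
from .data import ONE_TO_THREE
from .hotspots import HotspotReport
from .sap import developability_index, sap_per_atom, sap_score
from .structure import Structure

__all__ = ["Substitution", "Variant", "enumerate_variants", "apply_variant",
           "apply_variant_structure", "evaluate_variant", "FeatureDelta"]

HYDROPHOBIC = set("AVLIFMY")


@dataclasses.dataclass(frozen=True, order=True)
class Substitution:
    position: int
    wild_type: str
    mutant: str

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


@dataclasses.dataclass
class Variant:
    name: str
    substitutions: frozenset[Substitution]

    @property
    def label(self) -> str:
        subs = sorted(self.substitutions)
        return "/".join(str(s) for s in subs) if subs else "parent"

    def substitution_set(self) -> set[str]:
        return {str(s) for s in self.substitutions}


def _site_options(position: int, wild_type: str) -> list[str]:
    if wild_type == "C":
        return ["S"]
    if wild_type == "W":
        return ["F"]
    if wild_type in HYDROPHOBIC:
        return ["K", "D"]
    return []


def enumerate_variants(report: HotspotReport | Mapping[int, str] | Sequence[int],
                       parent_sequence: Mapping[int, str],
                       max_substitutions: int = 3,
                       always_on: Sequence[int] | None = None) -> list[Variant]:
    """Enumerate rule-based variants from the mutable hotspot sites.

    ``report`` may be a HotspotReport (its mutable set is used) or a bare
    collection of residue numbers.  ``always_on`` defaults to the mutable
    cysteines (the reduction-prone hinge Cys in the intended use); every
    variant includes all always-on sites.  Naming is M1..Mn over the
    deterministic enumeration order (by substitution count, then
    lexicographic site order).
    """
    if isinstance(report, HotspotReport):
        sites = sorted(report.mutable())
    else:
        sites = sorted(report)
    options: dict[int, list[str]] = {}
    for pos in sites:
        wt = parent_sequence.get(pos)
        if wt is None:
            raise KeyError(f"hotspot position {pos} absent from parent sequence")
        opts = _site_options(pos, wt)
        if opts:
            options[pos] = opts
    if not options:
        raise ValueError("no mutable hotspot site has a substitution rule")

    if always_on is None:
        anchors = [p for p in options if parent_sequence[p] == "C"]
    else:
        anchors = sorted(set(always_on))
        missing = [p for p in anchors if p not in options]
        if missing:
            raise KeyError(f"always-on site(s) {missing} have no substitution rule")

    free_sites = [p for p in options if p not in anchors]
    variants: list[Variant] = []
    seen: set[frozenset[Substitution]] = set()
    max_free = max_substitutions - len(anchors)
    if max_free < 0:
        raise ValueError("max_substitutions smaller than the always-on set")

    for k in range(0, max_free + 1):
        for combo in itertools.combinations(free_sites, k):
            chosen = list(anchors) + list(combo)
            per_site = [[Substitution(p, parent_sequence[p], m)
                         for m in options[p]] for p in sorted(chosen)]
            for picks in itertools.product(*per_site):
                key = frozenset(picks)
                if key and key not in seen:
                    seen.add(key)
                    variants.append(Variant(name="", substitutions=key))
    for i, v in enumerate(variants, start=1):
        variants[i - 1] = Variant(name=f"M{i}", substitutions=v.substitutions)
    return variants


def apply_variant(parent_sequence: Mapping[int, str], variant: Variant
                  ) -> dict[int, str]:
    """Apply substitutions to a sequence; wild-type letters are verified."""
    seq = dict(parent_sequence)
    for sub in sorted(variant.substitutions):
        actual = seq.get(sub.position)
        if actual != sub.wild_type:
            raise ValueError(
                f"wild-type mismatch at position {sub.position}: sequence has "
                f"{actual!r}, substitution expects {sub.wild_type!r}"
            )
        seq[sub.position] = sub.mutant
    return seq


# atoms kept when truncating a side chain to C-beta
_TRUNCATION_KEEP = frozenset({"N", "CA", "C", "O", "OXT", "CB"})


def apply_variant_structure(structure: Structure, variant: Variant) -> Structure:
    """Rename mutated residues and drop side-chain atoms beyond C-beta."""
    by_pos = {s.position: s for s in variant.substitutions}
    for chain in structure.chain_ids:
        seq = structure.sequence(chain)
        for sub in variant.substitutions:
            if sub.position in seq and seq[sub.position] != sub.wild_type:
                raise ValueError(
                    f"wild-type mismatch at {sub.position} in chain {chain}"
                )
    keep_idx = []
    new_atoms = []
    for i, a in enumerate(structure.atoms):
        sub = by_pos.get(a.residue_number)
        if sub is None:
            keep_idx.append(i)
            new_atoms.append(a)
            continue
        if a.name not in _TRUNCATION_KEEP:
            continue
        keep_idx.append(i)
        new_atoms.append(dataclasses.replace(
            a, residue_name=ONE_TO_THREE[sub.mutant]))
    return Structure(new_atoms, structure.coords[:, keep_idx, :])


@dataclasses.dataclass
class FeatureDelta:
    """Feature changes of a variant relative to its parent."""

    variant: Variant
    net_charge_parent: float
    net_charge_variant: float
    pi_parent: float
    pi_variant: float
    sap_score_parent: float | None = None
    sap_score_variant: float | None = None
    di_parent: float | None = None
    di_variant: float | None = None
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def delta_net_charge(self) -> float:
        return self.net_charge_variant - self.net_charge_parent

    @property
    def delta_pi(self) -> float:
        return self.pi_variant - self.pi_parent


def evaluate_variant(parent_sequence: Mapping[int, str], variant: Variant,
                     pH: float = 6.0,
                     parent_structure: Structure | None = None,
                     cdr_ranges: Sequence[tuple[int, int]] | None = None,
                     ) -> FeatureDelta:
    """Recompute charge/pI (and SAP/DI when a structure is given) for a
    variant, reporting deltas and rule-based risk notes."""
    mutated = apply_variant(parent_sequence, variant)
    q0 = net_charge(parent_sequence, pH)
    q1 = net_charge(mutated, pH)
    pi0 = isoelectric_point(parent_sequence)
    pi1 = isoelectric_point(mutated)

    warnings: list[str] = []
    n_asp = sum(1 for s in variant.substitutions if s.mutant == "D")
    if n_asp >= 2:
        warnings.append(
            "colloidal-risk: >= 2 Asp substitutions lower pI/net charge and "
            "can promote aggregation"
        )

    delta = FeatureDelta(variant=variant, net_charge_parent=q0,
                         net_charge_variant=q1, pi_parent=pi0, pi_variant=pi1,
                         warnings=warnings)

    if parent_structure is not None and cdr_ranges:
        sap0 = sap_per_atom(parent_structure)
        score0 = sap_score(parent_structure, sap0, cdr_ranges)
        mut_struct = apply_variant_structure(parent_structure, variant)
        sap1 = sap_per_atom(mut_struct)
        score1 = sap_score(mut_struct, sap1, cdr_ranges)
        delta.sap_score_parent = score0
        delta.sap_score_variant = score1
        delta.di_parent = developability_index(score0, q0)
        delta.di_variant = developability_index(score1, q1)
    return delta
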