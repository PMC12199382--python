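"""Stability hotspot identification rules.

Combines four evidence streams into one residue-level report:

* reduction-prone interchain cysteines (redox classification),
* structural aggregation-prone residues (A3D score > 1) restricted to the
  aggregation interface and not conserved (STAP filter),
* oxidation-liable Met/Trp (relative SASA above 20% / 30%, strict), plus a
  histidine-catalysis rule for buried Met adjacent to an exposed Met,
* binding-critical residues (alanine-scan ddG > 1.0 kcal/mol), which are
  reported but never marked mutable.

Conservation is an input list; external aggregation scores (A3D) and
alanine-scan ddG tables are consumed as files or mappings.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import HIS_IMIDAZOLE_ATOMS
from .redox import RedoxRecord
from .structure import DomainAnnotation, Structure

__all__ = [
    "OxidationFlag", "HotspotEntry", "HotspotReport",
    "oxidation_risk", "his_catalysis", "stap_filter", "binding_critical",
    "hotspot_report",
    "MET_SASA_THRESHOLD", "TRP_SASA_THRESHOLD",
]

MET_SASA_THRESHOLD = 20.0   # percent, strict >
TRP_SASA_THRESHOLD = 30.0   # percent, strict >


@dataclasses.dataclass
class OxidationFlag:
    """Oxidation liability of one Met or Trp residue."""

    residue_number: int
    kind: str                   # "MET" | "TRP"
    sasa_pct: float
    threshold_exceeded: bool
    his_catalysis: bool = False
    nearby_his: list[tuple[int, float]] = dataclasses.field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return self.threshold_exceeded or self.his_catalysis


def oxidation_risk(relative_sasa: Mapping[tuple[str, int], float] | Mapping[int, float],
                   residue_names: Mapping[int, str],
                   met_thr: float = MET_SASA_THRESHOLD,
                   trp_thr: float = TRP_SASA_THRESHOLD) -> list[OxidationFlag]:
    """Evaluate every Met and Trp against the exposure thresholds (strict >).

    ``relative_sasa`` may be keyed by residue number or (chain, number); for
    a homodimer the maximum over chains is used per position.
    """
    pct_of: dict[int, float] = {}
    for key, pct in relative_sasa.items():
        num = key[1] if isinstance(key, tuple) else int(key)
        pct_of[num] = max(pct_of.get(num, 0.0), float(pct))

    flags = []
    for num, name in sorted(residue_names.items()):
        if name not in ("MET", "TRP"):
            continue
        pct = pct_of.get(num)
        if pct is None:
            continue
        thr = met_thr if name == "MET" else trp_thr
        flags.append(OxidationFlag(
            residue_number=num, kind=name, sasa_pct=pct,
            threshold_exceeded=pct > thr,
        ))
    return flags


def his_catalysis(structure: Structure, flags: Sequence[OxidationFlag],
                  his_radius: float = 10.0, met_pair_radius: float = 6.0,
                  model: int = 0) -> list[OxidationFlag]:
    """Update Met flags with the histidine-catalysis rule.

    A methionine becomes catalysis-flagged when (a) at least one histidine
    imidazole heavy atom lies within ``his_radius`` of its sulfur and (b) it
    is itself exposure-flagged OR the sulfur of another exposure-flagged Met
    lies within ``met_pair_radius``: an exposed neighbor Met, once oxidized,
    can relay the reaction to a buried one under imidazole catalysis.
    """
    xyz = structure.coords[model]
    met_sulfur: dict[int, np.ndarray] = {}
    his_atoms: dict[int, list[np.ndarray]] = {}
    for i, a in enumerate(structure.atoms):
        if a.residue_name == "MET" and a.name == "SD":
            met_sulfur[a.residue_number] = xyz[i]
        elif a.residue_name == "HIS" and a.name in HIS_IMIDAZOLE_ATOMS:
            his_atoms.setdefault(a.residue_number, []).append(xyz[i])

    exposed_met = {f.residue_number for f in flags
                   if f.kind == "MET" and f.threshold_exceeded}
    out = []
    for flag in flags:
        if flag.kind != "MET":
            out.append(flag)
            continue
        sd = met_sulfur.get(flag.residue_number)
        if sd is None:
            out.append(flag)
            continue
        nearby: list[tuple[int, float]] = []
        for his_num, coords in his_atoms.items():
            d = min(float(np.linalg.norm(c - sd)) for c in coords)
            if d <= his_radius:
                nearby.append((his_num, round(d, 2)))
        nearby.sort(key=lambda t: t[1])
        paired = any(
            num != flag.residue_number
            and float(np.linalg.norm(met_sulfur[num] - sd)) <= met_pair_radius
            for num in exposed_met if num in met_sulfur
        )
        catalysis = bool(nearby) and (flag.threshold_exceeded or paired)
        out.append(dataclasses.replace(
            flag, his_catalysis=catalysis, nearby_his=nearby))
    return out


def stap_filter(a3d_scores: Mapping[int, float], interface: Iterable[int],
                conserved: Iterable[int] = (), threshold: float = 1.0) -> set[int]:
    """Structural aggregation-prone hotspots on the aggregation interface.

    {r : score(r) > threshold} intersected with the interface, minus the
    conserved residues.
    """
    interface = set(interface)
    conserved = set(conserved)
    positive = {r for r, s in a3d_scores.items() if s > threshold}
    return (positive & interface) - conserved


def binding_critical(ddg_table: Mapping[int, float], threshold: float = 1.0
                     ) -> set[int]:
    """Residues whose alanine substitution costs > threshold kcal/mol of
    antibody-antigen binding free energy (strict >)."""
    return {r for r, ddg in ddg_table.items() if ddg > threshold}


@dataclasses.dataclass
class HotspotEntry:
    residue_number: int
    reasons: set[str]
    excluded_because: set[str]

    @property
    def mutable(self) -> bool:
        return bool(self.reasons) and not self.excluded_because


@dataclasses.dataclass
class HotspotReport:
    entries: dict[int, HotspotEntry]

    def hotspots(self) -> set[int]:
        return {n for n, e in self.entries.items() if e.reasons}

    def mutable(self) -> set[int]:
        return {n for n, e in self.entries.items() if e.mutable}

    def reasons(self, residue_number: int) -> set[str]:
        e = self.entries.get(residue_number)
        return set(e.reasons) if e else set()


REASON_REDOX = "redox"
REASON_STAP = "STAP-interface"
REASON_OXIDATION = "oxidation"
REASON_OX_CATALYSIS = "oxidation-catalysis"


def hotspot_report(redox_cys: Iterable[int] = (),
                   oxidation_flags: Sequence[OxidationFlag] = (),
                   stap_hotspots: Iterable[int] = (),
                   binding_critical_set: Iterable[int] = (),
                   conserved: Iterable[int] = ()) -> HotspotReport:
    """Merge the rule outputs into one residue-level report.

    ``redox_cys``: residue numbers of reduction-prone interchain cysteines.
    A residue is mutable when it has at least one reason and is neither
    conserved nor binding-critical.
    """
    conserved = set(conserved)
    critical = set(binding_critical_set)

    reasons: dict[int, set[str]] = {}

    def add(num: int, reason: str) -> None:
        reasons.setdefault(num, set()).add(reason)

    for num in redox_cys:
        add(num, REASON_REDOX)
    for num in stap_hotspots:
        add(num, REASON_STAP)
    for flag in oxidation_flags:
        if flag.residue_number in conserved:
            continue
        if flag.threshold_exceeded:
            add(flag.residue_number, REASON_OXIDATION)
        if flag.his_catalysis:
            add(flag.residue_number, REASON_OX_CATALYSIS)

    entries: dict[int, HotspotEntry] = {}
    for num, rs in sorted(reasons.items()):
        excluded = set()
        if num in conserved:
            excluded.add("conserved")
        if num in critical:
            excluded.add("binding-critical")
        entries[num] = HotspotEntry(residue_number=num, reasons=rs,
                                    excluded_because=excluded)
    return HotspotReport(entries=entries)
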