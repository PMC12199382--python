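"""Structures, domain annotation, and Kabat CDR identification.

A :class:`Structure` is a flat, numpy-friendly view of a (possibly
multi-model) PDB file: one list of :class:`Atom` identity records shared by
all models, plus a ``(n_models, n_atoms, 3)`` coordinate array.  Reading goes
through Biopython's PDB parser; writing emits standard fixed-column
ATOM/MODEL/ENDMDL records so that a written file re-parses to the same atom
identities and coordinates (3 decimals).

Domain annotation labels every residue number as VHH, hinge, or Fc on the
construct's own sequential numbering.  For a VHH-Fc heavy-chain antibody the
default boundaries put the three hinge cysteines (130/136/139) in the hinge:
VHH 1-129, hinge 130-142, Fc 143-end.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import (
    DEFAULT_VDW_RADIUS,
    THREE_TO_ONE,
    VDW_RADII,
    element_from_atom_name,
)

__all__ = [
    "Atom",
    "Structure",
    "DomainAnnotation",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "annotate_domains",
    "kabat_cdrs",
    "DEFAULT_BOUNDARIES",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a Structure."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom identity record; x/y/z are the first-model coordinates."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    x: float
    y: float
    z: float
    vdw_radius: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.name)


class Structure:
    """Atom identities shared across >=1 models plus per-model coordinates."""

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray | None = None):
        if len(atoms) == 0:
            raise PDBParseError("structure contains zero atoms")
        self.atoms: list[Atom] = list(atoms)
        if coords is None:
            coords = np.array([[[a.x, a.y, a.z] for a in self.atoms]], dtype=float)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != len(self.atoms) or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        self.coords = coords
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise PDBParseError(f"duplicate atom {dup} within a model")
        self._check_monotone_residues()

    # -- basic views --------------------------------------------------------
    @property
    def n_models(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def model_coords(self, model: int = 0) -> np.ndarray:
        return self.coords[model]

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_number, residue_name) triples."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            k = (a.chain_id, a.residue_number)
            if k not in seen:
                seen.add(k)
                out.append((a.chain_id, a.residue_number, a.residue_name))
        return out

    def sequence(self, chain_id: str | None = None) -> dict[int, str]:
        """Residue_number -> one-letter code (first chain by default)."""
        if chain_id is None:
            chain_id = self.chain_ids[0]
        seq: dict[int, str] = {}
        for cid, num, name in self.residues(chain_id):
            seq[num] = THREE_TO_ONE.get(name, "X")
        return seq

    def atom_indices(self, chain_id: str | None = None) -> np.ndarray:
        idx = [i for i, a in enumerate(self.atoms)
               if chain_id is None or a.chain_id == chain_id]
        return np.array(idx, dtype=int)

    def subset(self, indices: Iterable[int]) -> "Structure":
        idx = np.asarray(sorted(indices), dtype=int)
        return Structure([self.atoms[i] for i in idx], self.coords[:, idx, :])

    def _check_monotone_residues(self) -> None:
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain_id)
            if prev is not None and a.residue_number < prev:
                raise PDBParseError(
                    f"residue numbers not increasing in chain {a.chain_id!r} "
                    f"at residue {a.residue_number}"
                )
            last[a.chain_id] = a.residue_number


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, radius_table: Mapping[str, float] | None = None,
             include_hydrogens: bool = True) -> Structure:
    """Parse ATOM/HETATM/MODEL records from a PDB file into a Structure.

    The element is taken from the element column when present and inferred
    from the atom name otherwise; van der Waals radii come from the bundled
    per-element table (overridable).  All models must contain the same atom
    identities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    radii = dict(VDW_RADII if radius_table is None else radius_table)

    from Bio.PDB import PDBParser  # deferred: keeps import cost off light paths

    import warnings
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure("s", str(path))
    except Exception as exc:  # surface the offending line when we can find it
        lineno = _find_malformed_line(path)
        where = f" (line {lineno})" if lineno else ""
        raise PDBParseError(f"cannot parse {path}{where}: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise PDBParseError(f"{path}: no models")

    def model_atoms(model):
        out = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    name = atom.get_name().strip()
                    element = (atom.element or "").strip().upper()
                    if not element:
                        element = element_from_atom_name(name)
                    if not include_hydrogens and element == "H":
                        continue
                    out.append((atom.serial_number, name, element,
                                residue.id[1], residue.get_resname().strip(),
                                chain.id, atom.coord))
        return out

    first = model_atoms(models[0])
    if not first:
        raise PDBParseError(f"{path}: zero atoms")

    atoms = []
    for serial, name, element, resnum, resname, chain_id, coord in first:
        atoms.append(Atom(
            serial=int(serial), name=name, element=element,
            residue_number=int(resnum), residue_name=resname,
            chain_id=str(chain_id),
            x=float(coord[0]), y=float(coord[1]), z=float(coord[2]),
            vdw_radius=float(radii.get(element, DEFAULT_VDW_RADIUS)),
        ))

    ident = [(a.chain_id, a.residue_number, a.name) for a in atoms]
    coords = np.empty((len(models), len(atoms), 3), dtype=float)
    coords[0] = np.array([[a.x, a.y, a.z] for a in atoms])
    for m, model in enumerate(models[1:], start=1):
        rows = model_atoms(model)
        ident_m = [(str(c), int(rn), n) for _, n, _, rn, _, c, _ in rows]
        if ident_m != ident:
            raise PDBParseError(
                f"{path}: model {m + 1} atom identities differ from model 1")
        coords[m] = np.array([r[-1] for r in rows], dtype=float)

    return Structure(atoms, coords)


_ATOM_LINE = re.compile(r"^(ATOM  |HETATM)")


def _find_malformed_line(path: Path) -> int | None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if _ATOM_LINE.match(line):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return i
    return None


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a Structure as fixed-column PDB; multi-model files get
    MODEL/ENDMDL blocks.  Round-trips atom identities and coordinates to
    3 decimals through :func:`read_pdb`."""
    path = Path(path)
    lines: list[str] = []
    multi = structure.n_models > 1
    for m in range(structure.n_models):
        if multi:
            lines.append(f"MODEL {m + 1:>8}")
        xyz = structure.coords[m]
        for i, a in enumerate(structure.atoms):
            name = a.name if len(a.name) == 4 else f" {a.name:<3}"
            lines.append(
                f"ATOM  {a.serial % 100000:>5} {name}{'':1}{a.residue_name:>3} "
                f"{a.chain_id[:1]}{a.residue_number:>4}    "
                f"{xyz[i, 0]:8.3f}{xyz[i, 1]:8.3f}{xyz[i, 2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Domain annotation
# ---------------------------------------------------------------------------

DEFAULT_BOUNDARIES: dict[str, tuple[int, int | None]] = {
    "VHH": (1, 129),
    "hinge": (130, 142),
    "Fc": (143, None),  # None = through the last residue
}


@dataclasses.dataclass
class DomainAnnotation:
    """Domain label per residue number, CDR ranges, conserved residues."""

    domain_of: dict[int, str]
    cdr_ranges: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    conserved: set[int] = dataclasses.field(default_factory=set)

    def domain(self, residue_number: int) -> str:
        try:
            return self.domain_of[residue_number]
        except KeyError:
            raise KeyError(f"residue {residue_number} not annotated") from None

    def in_cdr(self, residue_number: int) -> bool:
        return any(lo <= residue_number <= hi for lo, hi in self.cdr_ranges)

    def near_cdr(self, residue_number: int, k: int = 3) -> bool:
        return any(lo - k <= residue_number <= hi + k for lo, hi in self.cdr_ranges)

    def cdr_residues(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.cdr_ranges:
            out.update(range(lo, hi + 1))
        return out


def annotate_domains(
    structure: Structure,
    boundaries: Mapping[str, tuple[int, int | None]] | None = None,
    cdr_ranges: Sequence[tuple[int, int]] = (),
    conserved: Iterable[int] = (),
) -> DomainAnnotation:
    """Label each residue number with its domain (VHH / hinge / Fc).

    ``boundaries`` maps domain name to an inclusive (start, end) interval;
    ``end=None`` extends through the last residue.  Boundaries must cover
    every residue exactly once.
    """
    bounds = dict(DEFAULT_BOUNDARIES if boundaries is None else boundaries)
    residue_numbers = sorted({num for _, num, _ in structure.residues()})
    last = residue_numbers[-1]

    resolved: dict[str, tuple[int, int]] = {}
    for dom, (lo, hi) in bounds.items():
        resolved[dom] = (lo, last if hi is None else hi)

    domain_of: dict[int, str] = {}
    overlaps: list[int] = []
    for num in residue_numbers:
        owners = [d for d, (lo, hi) in resolved.items() if lo <= num <= hi]
        if len(owners) > 1:
            overlaps.append(num)
        elif owners:
            domain_of[num] = owners[0]
    gaps = [n for n in residue_numbers if n not in domain_of and n not in overlaps]
    if overlaps or gaps:
        raise ValueError(
            f"domain boundaries invalid: overlapping residues {overlaps[:10]}, "
            f"uncovered residues {gaps[:10]}"
        )

    ranges = [(int(lo), int(hi)) for lo, hi in cdr_ranges]
    vhh = resolved.get("VHH")
    if vhh is not None:
        for lo, hi in ranges:
            if not (vhh[0] <= lo <= hi <= vhh[1]):
                raise ValueError(f"CDR range ({lo},{hi}) outside the VHH domain {vhh}")
    for (a_lo, a_hi), (b_lo, b_hi) in zip(ranges, ranges[1:]):
        if b_lo <= a_hi:
            raise ValueError("CDR ranges overlap or are unsorted")

    return DomainAnnotation(domain_of=domain_of, cdr_ranges=ranges,
                            conserved=set(conserved))


# ---------------------------------------------------------------------------
# Kabat CDR identification (anchor heuristics with authoritative override)
# ---------------------------------------------------------------------------

class CDRAnchorError(ValueError):
    """Raised when the Kabat anchor patterns cannot be located."""


def kabat_cdrs(
    sequence: Mapping[int, str] | str,
    override: Sequence[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Heavy-chain CDR ranges by Kabat-style anchor rules.

    An explicit ``override`` is returned verbatim (authoritative).  Otherwise
    anchor patterns are applied to the VHH sequence:

    * CDR1 starts 9 residues after the first framework cysteine (Kabat H1
      begins at 31 when the Cys sits at 22) and ends just before the
      conserved Trp that follows (W36).
    * CDR2 starts 15 residues after the end of CDR1 (Kabat 50) and ends just
      before the first [KR]-[LIVFTA]-[TSIA] framework-3 motif found at least
      8 residues later.
    * CDR3 starts 3 residues after the second framework cysteine (Kabat 95
      for a Cys at 92) and ends just before the W of the W-G-x-G motif.

    Sequences lacking any anchor raise :class:`CDRAnchorError` instructing
    the user to supply explicit ranges.
    """
    if override is not None:
        return [(int(lo), int(hi)) for lo, hi in override]

    if isinstance(sequence, str):
        numbers = list(range(1, len(sequence) + 1))
        letters = list(sequence)
    else:
        numbers = sorted(sequence)
        letters = [sequence[n] for n in numbers]
    pos_of = {i: numbers[i] for i in range(len(numbers))}
    seq = "".join(letters)

    def fail(what: str) -> CDRAnchorError:
        return CDRAnchorError(
            f"Kabat anchor not found ({what}); supply explicit CDR ranges "
            "via the override argument"
        )

    cys = [i for i, c in enumerate(seq) if c == "C"]
    if not cys:
        raise fail("no framework cysteine")
    c1 = cys[0]

    h1_start = c1 + 9
    trp_after = next((i for i in range(h1_start + 1, len(seq)) if seq[i] == "W"), None)
    if trp_after is None or h1_start >= len(seq):
        raise fail("no conserved Trp after CDR1")
    h1 = (h1_start, trp_after - 1)

    h2_start = h1[1] + 15
    if h2_start >= len(seq):
        raise fail("sequence too short for CDR2")
    fr3 = re.compile(r"[KR][LIVFTA][TSIA]")
    m = fr3.search(seq, h2_start + 8)
    if m is None:
        raise fail("no framework-3 motif after CDR2")
    h2 = (h2_start, m.start() - 1)

    c2 = next((i for i in cys if i > h2[1]), None)
    if c2 is None:
        raise fail("no second framework cysteine")
    h3_start = c2 + 3
    wgxg = re.compile(r"WG.G")
    m3 = wgxg.search(seq, h3_start + 1)
    if m3 is None:
        raise fail("no W-G-x-G motif after CDR3")
    h3 = (h3_start, m3.start() - 1)

    ranges = [h1, h2, h3]
    for lo, hi in ranges:
        if lo > hi:
            raise fail("anchor ordering produced an empty CDR")
    return [(pos_of[lo], pos_of[hi]) for lo, hi in ranges]
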