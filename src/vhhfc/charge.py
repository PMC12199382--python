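"""Sequence net charge and isoelectric point (Henderson-Hasselbalch).

The net charge at a given pH is the sum over ionizable groups (side chains
of D, E, C, Y, K, R, H plus the chain termini) of their fractional
protonation charges:

    basic group:   +1 / (1 + 10^(pH - pKa))
    acidic group:  -1 / (1 + 10^(pKa - pH))

with intrinsic, environment-independent pKa values (EMBOSS-style defaults).
The isoelectric point is found by bisection of the monotone net-charge
curve on pH 0..14.  Structure-derived pKa shifts are out of scope; a caller
may substitute any pKa set, including per-protein calibrated ones.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .data import ACIDIC_GROUPS, BASIC_GROUPS, PKA_SETS

__all__ = ["net_charge", "isoelectric_point", "ionizable_groups"]

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def _as_letters(sequence: Mapping[int, str] | str) -> str:
    if isinstance(sequence, str):
        letters = sequence
    else:
        letters = "".join(sequence[k] for k in sorted(sequence))
    letters = letters.upper()
    bad = sorted(set(letters) - _STANDARD)
    if bad:
        raise ValueError(f"nonstandard residue code(s): {bad}")
    return letters


def _resolve_pka(pka_set: str | Mapping[str, float]) -> dict[str, float]:
    if isinstance(pka_set, str):
        try:
            return dict(PKA_SETS[pka_set])
        except KeyError:
            raise KeyError(
                f"unknown pKa set {pka_set!r}; available: {sorted(PKA_SETS)}"
            ) from None
    return dict(pka_set)


def ionizable_groups(sequence: Mapping[int, str] | str,
                     include_termini: bool = True) -> list[str]:
    """The ionizable group labels present in a sequence (with multiplicity)."""
    letters = _as_letters(sequence)
    groups = [c for c in letters if c in BASIC_GROUPS | ACIDIC_GROUPS]
    if include_termini:
        groups += ["N_term", "C_term"]
    return groups


def net_charge(sequence: Mapping[int, str] | str, pH: float = 6.0,
               pka_set: str | Mapping[str, float] = "emboss",
               include_termini: bool = True) -> float:
    """Net charge (elementary charges) of a sequence at the given pH."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    pka = _resolve_pka(pka_set)
    total = 0.0
    for group in ionizable_groups(sequence, include_termini):
        pk = pka.get(group)
        if pk is None:
            continue
        if group in BASIC_GROUPS:
            total += 1.0 / (1.0 + 10.0 ** (pH - pk))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (pk - pH))
    return total


def net_charge_chains(chains: Iterable[Mapping[int, str] | str], pH: float = 6.0,
                      pka_set: str | Mapping[str, float] = "emboss") -> float:
    """Net charge of several independent chains (termini counted per chain)."""
    return sum(net_charge(c, pH, pka_set) for c in chains)


def isoelectric_point(sequence: Mapping[int, str] | str,
                      pka_set: str | Mapping[str, float] = "emboss",
                      tol: float = 1e-4, include_termini: bool = True) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Requires at least one ionizable group of each sign, otherwise the
    net-charge curve never crosses zero and the pI is undefined.
    """
    groups = set(ionizable_groups(sequence, include_termini))
    if not (groups & BASIC_GROUPS and groups & ACIDIC_GROUPS):
        raise ValueError("pI undefined: need ionizable groups of both signs")
    lo, hi = 0.0, 14.0
    f_lo = net_charge(sequence, lo, pka_set, include_termini)
    f_hi = net_charge(sequence, hi, pka_set, include_termini)
    if f_lo < 0 or f_hi > 0:
        raise ValueError("pI undefined: net charge does not change sign on [0, 14]")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        f_mid = net_charge(sequence, mid, pka_set, include_termini)
        if abs(f_mid) < tol:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
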