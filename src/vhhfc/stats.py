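"""Stability readout transforms and the feature-vs-attribute screen.

Raw stability readouts from an accelerated (four-week, 40 degC) storage
study are reduced to per-week rates, appearance descriptors map onto the
ordinal 9/7/5/3/1 grading (clear best, particles worst), and variant
improvement is expressed as the parent/variant rate ratio.

The correlation screen computes a Pearson r and a two-sided p-value (t
statistic, n-2 degrees of freedom) for every feature-attribute column pair,
flagging a pair significant when |r| > 0.5 and p < 0.1.  The absolute-value
reading of the r rule keeps strong negative correlations significant.  No
multiple-testing correction enters the flag; a Benjamini-Hochberg column is
emitted for reference.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rate_of_change", "fold_improvement", "grade_appearance",
    "correlation_screen", "CorrelationResult",
    "APPEARANCE_GRADES", "NOT_MEASURABLE",
]

NOT_MEASURABLE = None  # sentinel for fold improvement over a zero rate

APPEARANCE_GRADES: dict[str, int] = {
    "clear": 9,
    "slight-opalescent": 7,
    "opalescent": 5,
    "turbid": 3,
    "particles": 1,
}


def rate_of_change(v_day0: float, v_day28: float, weeks: float = 4.0) -> float:
    """Per-week rate over the stress window: (day28 - day0) / weeks."""
    if weeks <= 0:
        raise ValueError("weeks must be positive")
    return (v_day28 - v_day0) / weeks


def fold_improvement(parent_rate: float, variant_rate: float):
    """Parent/variant rate ratio to one decimal; ``None`` for a zero
    variant rate (improvement not measurable, no exception)."""
    if variant_rate == 0:
        return NOT_MEASURABLE
    return round(parent_rate / variant_rate, 1)


def grade_appearance(descriptor: str) -> int:
    """Map an appearance descriptor onto the 9/7/5/3/1 ordinal grade."""
    key = descriptor.strip().lower().replace(" ", "-").replace("_", "-")
    try:
        return APPEARANCE_GRADES[key]
    except KeyError:
        raise ValueError(
            f"unknown appearance descriptor {descriptor!r}; expected one of "
            f"{sorted(APPEARANCE_GRADES)}"
        ) from None


@dataclasses.dataclass
class CorrelationResult:
    feature: str
    attribute: str
    r: float
    p: float
    n: int
    significant: bool
    p_bh: float | None = None


R_THRESHOLD = 0.5
P_THRESHOLD = 0.1


def correlation_screen(features: pd.DataFrame, attributes: pd.DataFrame,
                       r_threshold: float = R_THRESHOLD,
                       p_threshold: float = P_THRESHOLD,
                       min_samples: int = 3) -> list[CorrelationResult]:
    """Pearson screen of every feature column against every attribute column.

    Rows are samples, aligned on the index; each pair uses its complete
    cases.  Pairs with fewer than ``min_samples`` shared samples are skipped.
    Significance: |r| > r_threshold and p < p_threshold.
    """
    shared = features.index.intersection(attributes.index)
    feats = features.loc[shared]
    attrs = attributes.loc[shared]

    results: list[CorrelationResult] = []
    for f in feats.columns:
        for a in attrs.columns:
            x = pd.to_numeric(feats[f], errors="coerce")
            y = pd.to_numeric(attrs[a], errors="coerce")
            mask = x.notna() & y.notna()
            n = int(mask.sum())
            if n < min_samples:
                continue
            xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
            if np.std(xv) == 0 or np.std(yv) == 0:
                continue
            r, p = sps.pearsonr(xv, yv)
            r, p = float(r), float(p)
            results.append(CorrelationResult(
                feature=f, attribute=a, r=r, p=p, n=n,
                significant=abs(r) > r_threshold and p < p_threshold,
            ))
    if results:
        _, p_bh, _, _ = multipletests([c.p for c in results], method="fdr_bh")
        for c, q in zip(results, p_bh):
            c.p_bh = float(q)
    return results


def screen_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Long-format (heatmap-ready) table of screen results."""
    return pd.DataFrame([dataclasses.asdict(c) for c in results])


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n (t with n-2 dof)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return 2.0 * sps.t.sf(abs(t), df=n - 2)
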