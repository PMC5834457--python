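"""Stromal inflammation (SI) and PD-L1 scoring.

The SI score of one core is the fraction of the cancer stromal area occupied
by inflammatory cells (lymphocyte/plasma-cell analog); intraepithelial
inflammatory cells do not count.  Scores are recorded on a 0.00-1.00 grid of
0.10 increments with 0.05 midpoints (so the recording grid is effectively
0.05-stepped), the case score is the mean of the two core scores (or the
single available one), and the delta-value |core1 - core2| measures
intratumoral heterogeneity between the two random samples of a tumor.

PD-L1 is the proportion of viable tumor cells with circumferential membrane
staining of any intensity; a core needs at least 100 viable tumor cells to
be scorable, and the high/low stratification cuts at proportion > 0.00.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_si_raw",
    "quantize_si",
    "case_si",
    "delta_value",
    "split_by_median",
    "pdl1_score",
    "pdl1_case_score",
    "pdl1_stratum",
    "concordance",
    "SI_GRID",
    "MIN_VIABLE_CELLS",
]

#: the recording grid: 0.10 increments plus their 0.05 midpoints
SI_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 2)
MIN_VIABLE_CELLS = 100
STROMAL = 2


def compute_si_raw(seg) -> float:
    """Raw SI of one segmented core: inflammatory area over stromal area.

    Numerator: pixels of objects classed ``inflammatory`` that lie inside
    the stromal compartment (peri-tumoral stroma only — any pixels falling
    on epithelium are excluded).  Denominator: all stromal-compartment
    pixels.  Returns NaN with a warning when there is no stromal area.
    """
    stroma = seg.compartments == STROMAL
    denom = int(stroma.sum())
    if denom == 0:
        warnings.warn("no stromal area; SI is NA for this core", stacklevel=2)
        return float("nan")
    infl_ids = seg.cells.table.loc[
        seg.cells.table["class"] == "inflammatory", "id"
    ].to_numpy()
    if infl_ids.size == 0:
        return 0.0
    numer = int((np.isin(seg.cells.label_mask, infl_ids) & stroma).sum())
    return numer / denom


def quantize_si(raw: float) -> float:
    """Record a raw SI fraction on the 0.05 grid.

    Values between two 0.10 increments are recorded as the middle value
    (e.g. anything estimated between 0.30 and 0.40 becomes 0.35), which a
    machine realises as rounding to the nearest 0.05 grid point; exact
    midpoints between grid points round up.  Idempotent on grid values.
    """
    if isinstance(raw, float) and np.isnan(raw):
        return float("nan")
    if not 0.0 <= raw <= 1.0:
        raise ValueError(f"raw SI must lie in [0, 1], got {raw}")
    # round-half-up on a 1/20 grid; epsilon guards against binary float
    # representations of decimal inputs landing a hair below the midpoint
    return float(np.floor(raw * 20.0 + 0.5 + 1e-12) / 20.0)


def case_si(core1: float, core2: float) -> float:
    """Case-level SI: mean of the recorded core scores.

    With one core unscorable the available score is used; with neither
    scored the case is NA.
    """
    vals = [v for v in (core1, core2) if v is not None and not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def delta_value(core1: float, core2: float) -> float:
    """Intratumoral-heterogeneity delta: |core1 - core2|, NA if either is."""
    if core1 is None or core2 is None or np.isnan(core1) or np.isnan(core2):
        return float("nan")
    return abs(core1 - core2)


def split_by_median(deltas) -> pd.Series:
    """Split cases into 'high' (delta > median) and 'low' (delta <= median).

    NA deltas stay NA.  Degenerate when all deltas are equal (everything
    'low'), which is reported with a warning.
    """
    deltas = pd.Series(deltas, dtype=float)
    ok = deltas.notna()
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-NA delta values to split")
    med = deltas[ok].median()
    out = pd.Series(pd.NA, index=deltas.index, dtype=object)
    out[ok] = np.where(deltas[ok] > med, "high", "low")
    if (out[ok] == "low").all():
        warnings.warn("all delta-values <= median; split is degenerate", stacklevel=2)
    return out


def pdl1_score(cells: pd.DataFrame) -> float:
    """PD-L1 proportion score of one core from a per-cell table.

    ``cells`` has boolean columns ``viable`` and ``stained`` (circumferential
    staining of any intensity).  Cores with fewer than 100 viable tumor
    cells are unscorable (NA).
    """
    viable = cells["viable"].to_numpy(bool)
    n_viable = int(viable.sum())
    if n_viable < MIN_VIABLE_CELLS:
        return float("nan")
    stained = cells["stained"].to_numpy(bool) & viable
    return float(stained.sum() / n_viable)


def pdl1_case_score(core1: float, core2: float) -> float:
    """Case PD-L1: mean of the scorable core scores, NA if neither scored."""
    return case_si(core1, core2)


def pdl1_stratum(score: float) -> str | float:
    """'high' for any positive PD-L1 proportion, 'low' for exactly 0.00."""
    if score is None or np.isnan(score):
        return float("nan")
    return "high" if score > 0.0 else "low"


def concordance(scores_a, scores_b) -> float:
    """Spearman rho between two observers' (or runs') paired scores."""
    a = pd.Series(scores_a, dtype=float)
    b = pd.Series(scores_b, dtype=float)
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-NA scores")
    if a[ok].nunique() < 2 or b[ok].nunique() < 2:
        warnings.warn("constant score vector; concordance is NA", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(a[ok], b[ok]).statistic)
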