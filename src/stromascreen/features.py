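"""The fixed 1,536-feature catalogue and per-image feature extraction.

Per image, for each compartment (epithelial, stromal) and object class
(nuclear, cytoplasmic), 96 base measurements of size, shape and texture are
computed per object and then summarised across the objects of that image
with four summaries (mean, standard deviation, maximum, minimum):

    2 compartments x 2 object classes x 96 bases x 4 summaries = 1,536

The 96 bases are 16 morphometric measurements plus 16 intensity statistics
on each of 5 channels (R, G, B, luminance, blue-ratio).  Units are pixels
and pixel^2 throughout; no physical calibration is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops

from ._utils import blue_ratio, luminance

__all__ = [
    "build_catalogue",
    "extract_features",
    "case_average",
    "paired_core_correlation",
    "MORPHOMETRIC_BASES",
    "INTENSITY_STATS",
    "CHANNELS",
    "SUMMARIES",
]

COMPARTMENTS = ("epithelial", "stromal")
OBJECT_CLASSES = ("nuclear", "cytoplasmic")
SUMMARIES = ("mean", "sd", "max", "min")
CHANNELS = ("R", "G", "B", "luma", "blueratio")

MORPHOMETRIC_BASES = (
    "area", "perimeter", "equivalent_diameter", "major_axis", "minor_axis",
    "eccentricity", "solidity", "extent", "circularity", "aspect_ratio",
    "convex_area", "border_length", "radius_mean", "radius_sd",
    "roundness", "compactness",
)

INTENSITY_STATS = (
    "mean", "sd", "min", "max", "median", "mad", "iqr", "p10", "p25",
    "p75", "p90", "range", "skew", "kurtosis", "energy", "entropy",
)

_AREA_UNITS = {"area", "convex_area"}
_LENGTH_UNITS = {
    "perimeter", "equivalent_diameter", "major_axis", "minor_axis",
    "border_length", "radius_mean", "radius_sd",
}


def _base_names() -> list[str]:
    names = list(MORPHOMETRIC_BASES)
    for ch in CHANNELS:
        names.extend(f"{ch}_{st}" for st in INTENSITY_STATS)
    return names


def build_catalogue() -> pd.DataFrame:
    """The ordered, versioned feature catalogue.

    One row per feature: name, compartment, object_class, base, summary,
    units.  The order is stable across calls and releases; downstream
    tables index columns by these names.
    """
    bases = _base_names()
    rows = []
    for comp in COMPARTMENTS:
        for oc in OBJECT_CLASSES:
            for base in bases:
                for summ in SUMMARIES:
                    if base in _AREA_UNITS:
                        units = "px^2"
                    elif base in _LENGTH_UNITS:
                        units = "px"
                    else:
                        units = "unitless"
                    rows.append(
                        (f"{comp}.{oc}.{base}.{summ}", comp, oc, base, summ, units)
                    )
    cat = pd.DataFrame(
        rows, columns=["name", "compartment", "object_class", "base", "summary", "units"]
    )
    assert len(cat) == 1536 and cat["name"].is_unique
    return cat


def _intensity_stats(vals: np.ndarray, scale: float) -> list[float]:
    """The 16 per-object intensity statistics of one channel."""
    v = vals.astype(float)
    sd = v.std()
    p10, p25, med, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    if sd > 0:
        c = v - v.mean()
        m2 = np.mean(c**2)
        skew = float(np.mean(c**3) / m2**1.5)
        kurt = float(np.mean(c**4) / m2**2 - 3.0)  # Fisher convention
    else:
        skew = kurt = 0.0
    hist, _ = np.histogram(v, bins=16, range=(0.0, scale))
    p = hist / max(1, v.size)
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    return [
        float(v.mean()), float(sd), float(v.min()), float(v.max()), float(med),
        float(np.median(np.abs(v - med))), float(p75 - p25), float(p10),
        float(p25), float(p75), float(p90), float(v.max() - v.min()),
        skew, kurt, float(np.mean((v / scale) ** 2)), entropy,
    ]


def _object_table(image: np.ndarray, label_mask: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """(n_objects, 96) base-measurement matrix for the given object ids."""
    img = image.astype(float)
    chans = [img[..., 0], img[..., 1], img[..., 2], luminance(img), blue_ratio(img)]
    scales = [255.0, 255.0, 255.0, 255.0, 1.5]
    wanted = set(int(i) for i in ids)
    rows = []
    for rp in regionprops(label_mask):
        if rp.label not in wanted:
            continue
        area = float(rp.area)
        perim = float(rp.perimeter) if rp.perimeter > 0 else 1.0
        major = float(rp.axis_major_length)
        minor = float(rp.axis_minor_length)
        coords = rp.coords
        d = np.hypot(coords[:, 0] - rp.centroid[0], coords[:, 1] - rp.centroid[1])
        morph = [
            area, perim, float(rp.equivalent_diameter_area), major, minor,
            float(rp.eccentricity), float(rp.solidity), float(rp.extent),
            4.0 * np.pi * area / perim**2,
            major / minor if minor > 0 else 1.0,
            float(rp.area_convex), float(rp.perimeter_crofton),
            float(d.mean()), float(d.std()),
            4.0 * area / (np.pi * major**2) if major > 0 else 1.0,
            perim**2 / area,
        ]
        rc = tuple(coords.T)
        inten = []
        for ch, sc in zip(chans, scales):
            inten.extend(_intensity_stats(ch[rc], sc))
        rows.append(morph + inten)
    if not rows:
        return np.empty((0, 96))
    return np.asarray(rows)


def extract_features(
    image: np.ndarray, seg, cat: pd.DataFrame | None = None
) -> pd.Series:
    """One feature vector (catalogue order) for a segmented image.

    ``seg`` is a :class:`~stromascreen.segment.SegmentationResult`.  A
    compartment/object-class with zero objects yields NA for its whole
    block rather than an error.
    """
    if cat is None:
        cat = build_catalogue()
    table = seg.cells.table
    out = pd.Series(np.nan, index=cat["name"].to_numpy(), dtype=float)
    comp_code = {"epithelial": 1, "stromal": 2}
    for comp in COMPARTMENTS:
        ids = table.loc[table["compartment"] == comp_code[comp], "id"].to_numpy()
        for oc, mask in (("nuclear", seg.cells.label_mask),
                         ("cytoplasmic", seg.cells.cyto_mask)):
            vals = _object_table(image, mask, ids)
            if vals.shape[0] == 0:
                continue
            summaries = {
                "mean": vals.mean(axis=0),
                "sd": vals.std(axis=0),
                "max": vals.max(axis=0),
                "min": vals.min(axis=0),
            }
            for j, base in enumerate(_base_names()):
                for summ in SUMMARIES:
                    out[f"{comp}.{oc}.{base}.{summ}"] = summaries[summ][j]
    return out


def case_average(core1: pd.Series, core2: pd.Series) -> pd.Series:
    """Case-level feature vector: elementwise mean of the two cores.

    If exactly one core is NA for a feature the available value is used;
    both NA stays NA.  The two vectors must share the catalogue index.
    """
    if not core1.index.equals(core2.index):
        raise ValueError("core feature vectors use different catalogues")
    return pd.concat([core1, core2], axis=1).mean(axis=1, skipna=True)


def paired_core_correlation(
    core1: pd.DataFrame, core2: pd.DataFrame, min_pairs: int = 3
) -> pd.Series:
    """Per-feature Spearman rho between first and second cores across cases.

    A readout of intratumoral heterogeneity: low rho means the two random
    samples of a tumor disagree.  Features with fewer than ``min_pairs``
    complete pairs, or constant in either core, are NA.
    """
    if not core1.columns.equals(core2.columns):
        raise ValueError("core tables use different catalogues")
    rhos = pd.Series(np.nan, index=core1.columns, dtype=float)
    for col in core1.columns:
        a, b = core1[col], core2[col]
        ok = a.notna() & b.notna()
        if ok.sum() < min_pairs:
            continue
        a, b = a[ok], b[ok]
        if a.nunique() < 2 or b.nunique() < 2:
            warnings.warn(f"feature {col!r} is constant; rho is NA", stacklevel=2)
            continue
        rhos[col] = stats.spearmanr(a, b).statistic
    return rhos
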