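"""Epithelial/stromal superpixel classification and cell segmentation.

The analysis unit is the superpixel: small SLIC clusters of visually similar
pixels computed over tissue (non-background) area.  A shallow supervised
classifier trained on labeled example superpixels assigns each one to the
epithelial or stromal compartment; nuclei are then segmented by
optical-density thresholding with watershed splitting, assigned to the
compartment under them, and classed as epithelial nuclei or small round
stromal (inflammatory) cells.

Accuracy is audited the way a human reviewer would on a microscope: only
the superpixels and nuclei touching the horizontal diameter (middle row) of
the core are assessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import sobel, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, slic, watershed
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from ._utils import blue_ratio, luminance

__all__ = [
    "SuperpixelMap",
    "CellObjects",
    "SegmentationResult",
    "AuditReport",
    "CompartmentClassifier",
    "compute_superpixels",
    "train_compartment_classifier",
    "classify_compartments",
    "compartment_raster",
    "segment_cells",
    "segment_image",
    "labeled_examples_from_truth",
    "audit_accuracy",
]

EPITHELIAL = 1
STROMAL = 2

DESCRIPTOR_NAMES = [
    "mean_R", "mean_G", "mean_B", "mean_luma", "mean_blueratio",
    "sd_R", "sd_G", "sd_B", "sd_luma", "sd_blueratio",
    "grad_mean", "grad_sd", "dark_fraction", "min_luma", "max_luma",
]


def tissue_mask(image: np.ndarray, white_threshold: float = 235.0) -> np.ndarray:
    """Boolean mask of tissue pixels (background is near-white)."""
    return luminance(image) < white_threshold


@dataclass
class SuperpixelMap:
    """A superpixel partition of the tissue area of one image.

    labels      : (H, W) int raster, 0 = background, 1..K superpixel ids
    descriptors : (K, d) per-superpixel color/texture descriptor matrix,
                  row ``k`` describing superpixel ``k + 1``
    """

    labels: np.ndarray
    descriptors: np.ndarray
    descriptor_names: list[str]

    @property
    def n_superpixels(self) -> int:
        return self.descriptors.shape[0]


def _superpixel_descriptors(image: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = int(labels.max())
    if k == 0:
        return np.empty((0, len(DESCRIPTOR_NAMES)))
    img = image.astype(float)
    luma = luminance(img)
    channels = [img[..., 0], img[..., 1], img[..., 2], luma, blue_ratio(img)]
    idx = np.arange(1, k + 1)
    cols = []
    for ch in channels:
        cols.append(ndi.mean(ch, labels, idx))
    for ch in channels:
        cols.append(ndi.standard_deviation(ch, labels, idx))
    grad = sobel(luma)
    cols.append(ndi.mean(grad, labels, idx))
    cols.append(ndi.standard_deviation(grad, labels, idx))
    cols.append(ndi.mean((luma < 120.0).astype(float), labels, idx))
    cols.append(ndi.minimum(luma, labels, idx))
    cols.append(ndi.maximum(luma, labels, idx))
    return np.column_stack(cols)


def compute_superpixels(image: np.ndarray, target_size: int = 10) -> SuperpixelMap:
    """SLIC superpixels over the tissue area, with descriptors.

    ``target_size`` is the desired superpixel edge length in pixels; the
    number of segments requested from SLIC is ``tissue_area / target_size**2``.
    Background (near-white) pixels are masked out before partitioning and
    keep label 0.
    """
    if target_size < 5:
        raise ValueError("target_size must be at least 5 pixels")
    mask = tissue_mask(image)
    if not mask.any():
        warnings.warn("image contains no tissue; empty superpixel map", stacklevel=2)
        return SuperpixelMap(np.zeros(image.shape[:2], int),
                             np.empty((0, len(DESCRIPTOR_NAMES))), list(DESCRIPTOR_NAMES))
    n_segments = max(1, int(mask.sum() / target_size**2))
    labels = slic(
        image, n_segments=n_segments, compactness=10.0, mask=mask,
        start_label=1, channel_axis=-1, enforce_connectivity=True,
    )
    # SLIC can skip ids; relabel contiguously 1..K
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, int)
    remap[ids] = np.arange(1, ids.size + 1)
    labels = remap[labels]
    desc = _superpixel_descriptors(image, labels)
    return SuperpixelMap(labels, desc, list(DESCRIPTOR_NAMES))


class CompartmentClassifier(BaseEstimator, ClassifierMixin):
    """Shallow supervised epithelial-versus-stromal superpixel classifier.

    A random forest over the ~15 color/texture descriptors, standing in for
    the labeled-example training step a pathologist performs interactively.
    Deterministic for a fixed ``random_state``.
    """

    def __init__(self, n_estimators: int = 100, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        classes = np.unique(y)
        for required in ("epithelial", "stromal"):
            if required not in classes:
                raise ValueError(f"training set has no '{required}' examples")
        self._rf = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        ).fit(X, y)
        self.classes_ = self._rf.classes_
        self.n_features_in_ = X.shape[1]
        self.resubstitution_accuracy_ = float((self._rf.predict(X) == y).mean())
        self.training_size_ = int(len(y))
        return self

    def predict(self, X):
        check_is_fitted(self, "_rf")
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"descriptor dimension {X.shape[1]} != fitted {self.n_features_in_}"
            )
        return self._rf.predict(X)


def train_compartment_classifier(
    examples: list[tuple[np.ndarray, str]], random_state: int = 0
) -> CompartmentClassifier:
    """Fit the compartment classifier from (descriptor, label) examples."""
    if not examples:
        raise ValueError("no training examples")
    X = np.vstack([np.asarray(d, float) for d, _ in examples])
    y = np.array([lab for _, lab in examples])
    return CompartmentClassifier(random_state=random_state).fit(X, y)


def classify_compartments(
    spx: SuperpixelMap, model: CompartmentClassifier
) -> np.ndarray:
    """Predict 'epithelial'/'stromal' for every tissue superpixel."""
    if spx.n_superpixels == 0:
        return np.empty(0, dtype=object)
    return model.predict(spx.descriptors)


def compartment_raster(spx: SuperpixelMap, labels: np.ndarray) -> np.ndarray:
    """Expand per-superpixel labels to a per-pixel compartment raster."""
    lut = np.zeros(spx.n_superpixels + 1, np.uint8)
    for i, lab in enumerate(labels, start=1):
        lut[i] = EPITHELIAL if lab == "epithelial" else STROMAL
    return lut[spx.labels]


def labeled_examples_from_truth(
    spx: SuperpixelMap, compartment_mask: np.ndarray, purity: float = 0.8
) -> list[tuple[np.ndarray, str]]:
    """Training examples from ground truth: the labeled-example analog.

    Superpixels whose pixels are at least ``purity`` one compartment are
    returned with that label, emulating the unambiguous regions an annotator
    would pick.
    """
    out = []
    k = spx.n_superpixels
    if k == 0:
        return out
    idx = np.arange(1, k + 1)
    epi_frac = ndi.mean((compartment_mask == EPITHELIAL).astype(float), spx.labels, idx)
    str_frac = ndi.mean((compartment_mask == STROMAL).astype(float), spx.labels, idx)
    for i in range(k):
        if epi_frac[i] >= purity:
            out.append((spx.descriptors[i], "epithelial"))
        elif str_frac[i] >= purity:
            out.append((spx.descriptors[i], "stromal"))
    return out


# ---------------------------------------------------------------------------
# cell segmentation
# ---------------------------------------------------------------------------

@dataclass
class CellObjects:
    """Segmented nuclear objects with class, compartment and cytoplasm zones.

    label_mask : (H, W) int32, 0 = none, else object id (pairwise disjoint)
    cyto_mask  : (H, W) int32 cytoplasmic zone per object id (disjoint from
                 and keyed to the nuclei)
    table      : one row per object: id, class, compartment, area,
                 centroid_r, centroid_c
    """

    label_mask: np.ndarray
    cyto_mask: np.ndarray
    table: pd.DataFrame


def segment_cells(
    image: np.ndarray,
    compartments: np.ndarray,
    min_size: int = 10,
    nuclear_radius: float = 5.0,
    inflammatory_max_area: float = 60.0,
    inflammatory_min_circularity: float = 0.45,
    cytoplasm_width: int = 4,
) -> CellObjects:
    """Detect and split dark nuclear blobs; assign compartment and class.

    Nuclei are the optically dense (dark) blobs within tissue; touching
    nuclei are split with a distance-transform watershed.  Objects whose
    majority compartment is stromal and that are small (area below
    ``inflammatory_max_area``) and round (circularity above
    ``inflammatory_min_circularity``) are classed as inflammatory cells —
    the lymphocyte/plasma-cell analog; objects in the epithelial compartment
    are epithelial nuclei; remaining stromal objects are 'stromal_other'.
    A cytoplasmic zone up to ``cytoplasm_width`` px, confined to the object's
    compartment, is associated with each nucleus.
    """
    h, w = compartments.shape
    tissue = compartments > 0
    luma = luminance(image)
    if not tissue.any():
        return CellObjects(
            np.zeros((h, w), np.int32), np.zeros((h, w), np.int32),
            pd.DataFrame(columns=["id", "class", "compartment", "area",
                                  "centroid_r", "centroid_c"]),
        )
    thr = threshold_otsu(luma[tissue])
    nuclear = tissue & (luma < thr)
    nuclear = remove_small_objects(nuclear, max_size=min_size - 1)

    dist = ndi.distance_transform_edt(nuclear)
    min_dist = max(2, int(round(nuclear_radius * 0.4)))
    peaks = peak_local_max(
        dist, min_distance=min_dist, labels=nuclear, exclude_border=False
    )
    markers = np.zeros((h, w), np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=nuclear)
    # watershed can orphan blobs with no peak: label them too
    orphan = nuclear & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0).astype(labels.dtype)

    rows = []
    for rp in regionprops(labels):
        if rp.area < min_size:
            labels[labels == rp.label] = 0
            continue
        comp_vals = compartments[tuple(rp.coords.T)]
        comp = EPITHELIAL if (comp_vals == EPITHELIAL).sum() >= (comp_vals == STROMAL).sum() else STROMAL
        perim = rp.perimeter if rp.perimeter > 0 else 1.0
        circularity = 4.0 * np.pi * rp.area / perim**2
        if comp == EPITHELIAL:
            klass = "epithelial_nucleus"
        elif rp.area <= inflammatory_max_area and circularity >= inflammatory_min_circularity:
            klass = "inflammatory"
        else:
            klass = "stromal_other"
        rows.append((rp.label, klass, comp, int(rp.area),
                     float(rp.centroid[0]), float(rp.centroid[1])))
    table = pd.DataFrame(rows, columns=["id", "class", "compartment", "area",
                                        "centroid_r", "centroid_c"])

    # cytoplasmic zone: expansion of each nucleus within its compartment
    expanded = expand_labels(labels, distance=cytoplasm_width)
    cyto = np.where((expanded > 0) & (labels == 0) & tissue, expanded, 0).astype(np.int32)
    comp_of = dict(zip(table["id"], table["compartment"]))
    # strip cytoplasm pixels lying outside the object's own compartment
    if len(table):
        lut = np.zeros(int(labels.max()) + 1, np.uint8)
        for i, c in comp_of.items():
            lut[i] = c
        cyto[lut[cyto] != compartments] = 0
    return CellObjects(labels.astype(np.int32), cyto, table)


@dataclass
class SegmentationResult:
    """Full segmentation of one core: superpixels, compartments, cells."""

    superpixels: SuperpixelMap
    superpixel_labels: np.ndarray  # 'epithelial'/'stromal' per superpixel
    compartments: np.ndarray  # (H, W) uint8 raster
    cells: CellObjects


def segment_image(
    image: np.ndarray,
    model: CompartmentClassifier,
    target_size: int = 10,
    **cell_kwargs,
) -> SegmentationResult:
    """Convenience driver: superpixels -> compartments -> cells."""
    spx = compute_superpixels(image, target_size=target_size)
    labs = classify_compartments(spx, model)
    comp = compartment_raster(spx, labs)
    cells = segment_cells(image, comp, **cell_kwargs)
    return SegmentationResult(spx, labs, comp, cells)


# ---------------------------------------------------------------------------
# accuracy audit
# ---------------------------------------------------------------------------

@dataclass
class AuditReport:
    superpixel_accuracy: float
    nucleus_accuracy: float
    n_superpixels_audited: int
    n_nuclei_audited: int


def audit_accuracy(seg: SegmentationResult, truth) -> AuditReport:
    """Audit accuracy along the horizontal diameter of the core.

    Mirrors a manual review protocol in which the observer assesses every
    superpixel and nucleus in contact with the horizontal midline
    (row ``height // 2``).  Superpixel correctness compares the predicted
    compartment with the ground-truth majority compartment of that
    superpixel; nucleus correctness asks whether each true cell on the
    midline was detected (>= 30% of its pixels covered by some predicted
    object).
    """
    comp_truth = truth.compartment_mask
    if comp_truth.shape != seg.compartments.shape:
        raise ValueError("segmentation and truth rasters differ in shape")
    mid = comp_truth.shape[0] // 2

    spx_ids = np.unique(seg.superpixels.labels[mid, :])
    spx_ids = spx_ids[spx_ids > 0]
    n_spx, n_spx_correct = 0, 0
    for sid in spx_ids:
        m = seg.superpixels.labels == sid
        epi = (comp_truth[m] == EPITHELIAL).sum()
        stro = (comp_truth[m] == STROMAL).sum()
        if epi + stro == 0:
            continue
        true_lab = "epithelial" if epi >= stro else "stromal"
        n_spx += 1
        if seg.superpixel_labels[sid - 1] == true_lab:
            n_spx_correct += 1

    cell_ids = np.unique(truth.cell_mask[mid, :])
    cell_ids = cell_ids[cell_ids > 0]
    n_nuc, n_nuc_correct = 0, 0
    for cid in cell_ids:
        m = truth.cell_mask == cid
        n_nuc += 1
        covered = (seg.cells.label_mask[m] > 0).mean()
        if covered >= 0.3:
            n_nuc_correct += 1

    if n_spx == 0 and n_nuc == 0:
        warnings.warn("no superpixels or nuclei touch the midline; audit is NA",
                      stacklevel=2)
    spx_acc = n_spx_correct / n_spx if n_spx else float("nan")
    nuc_acc = n_nuc_correct / n_nuc if n_nuc else float("nan")
    return AuditReport(spx_acc, nuc_acc, n_spx, n_nuc)
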