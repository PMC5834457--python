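"""Shared fixtures: trained compartment model, default synthetic cores."""

import numpy as np
import pandas as pd
import pytest

from stromascreen.features import build_catalogue
from stromascreen.segment import (
    SegmentationResult, CellObjects, compute_superpixels,
    labeled_examples_from_truth, train_compartment_classifier,
)
from stromascreen.simdata import ImageSimParams, generate_tma_image


@pytest.fixture(scope="session")
def trained_model():
    """Compartment classifier trained on labeled examples from two cores."""
    examples = []
    for seed in (100, 101):
        img, truth = generate_tma_image(ImageSimParams(seed=seed))
        spx = compute_superpixels(img)
        examples.extend(labeled_examples_from_truth(spx, truth.compartment_mask))
    return train_compartment_classifier(examples)


@pytest.fixture(scope="session")
def default_core():
    """One default synthetic core with its ground truth."""
    return generate_tma_image(ImageSimParams(seed=7))


@pytest.fixture(scope="session")
def catalogue():
    return build_catalogue()


def truth_segmentation(image: np.ndarray, truth) -> SegmentationResult:
    """A SegmentationResult that reproduces the ground truth exactly.

    Superpixels come from the image; each is labeled with its ground-truth
    majority compartment, and the cell objects are the true cell mask.
    """
    spx = compute_superpixels(image)
    labels = np.empty(spx.n_superpixels, dtype=object)
    for sid in range(1, spx.n_superpixels + 1):
        m = spx.labels == sid
        epi = (truth.compartment_mask[m] == 1).sum()
        stro = (truth.compartment_mask[m] == 2).sum()
        labels[sid - 1] = "epithelial" if epi >= stro else "stromal"
    comp = truth.compartment_mask.copy()
    rows = []
    for cid, klass in truth.cell_classes.items():
        m = truth.cell_mask == cid
        comp_val = 1 if klass == "epithelial_nucleus" else 2
        rr, cc = np.nonzero(m)
        rows.append((cid, "inflammatory" if klass == "inflammatory" else
                     "epithelial_nucleus", comp_val, int(m.sum()),
                     float(rr.mean()), float(cc.mean())))
    cells = CellObjects(
        truth.cell_mask.astype(np.int32),
        np.zeros_like(truth.cell_mask, dtype=np.int32),
        pd.DataFrame(rows, columns=["id", "class", "compartment", "area",
                                    "centroid_r", "centroid_c"]),
    )
    return SegmentationResult(spx, labels, comp, cells)


@pytest.fixture(scope="session")
def perfect_segmentation(default_core):
    img, truth = default_core
    return truth_segmentation(img, truth)
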