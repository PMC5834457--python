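"""Superpixel partition, compartment classification, cell segmentation and
the midline audit protocol."""

import numpy as np
import pytest

from stromascreen.segment import (
    audit_accuracy, classify_compartments, compartment_raster,
    compute_superpixels, segment_cells, segment_image,
    train_compartment_classifier,
)
from stromascreen.simdata import ImageSimParams, generate_tma_image

from conftest import truth_segmentation


class TestSuperpixels:
    def test_count_scales_with_target_size(self):
        img = np.full((120, 120, 3), 128, np.uint8)
        s = 10
        spx = compute_superpixels(img, target_size=s)
        expect = 120 * 120 / s**2
        assert expect / 2 <= spx.n_superpixels <= expect * 2

    def test_all_white_image_is_empty_with_warning(self):
        img = np.full((64, 64, 3), 255, np.uint8)
        with pytest.warns(UserWarning, match="no tissue"):
            spx = compute_superpixels(img)
        assert spx.n_superpixels == 0

    def test_tissue_fully_partitioned_and_labels_contiguous(self):
        img, _ = generate_tma_image(ImageSimParams(seed=2))
        spx = compute_superpixels(img)
        ids = np.unique(spx.labels)
        assert ids[0] == 0  # background present
        assert list(ids[1:]) == list(range(1, spx.n_superpixels + 1))

    def test_deterministic(self):
        img, _ = generate_tma_image(ImageSimParams(seed=4))
        a = compute_superpixels(img)
        b = compute_superpixels(img)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_small_target_size_rejected(self):
        with pytest.raises(ValueError, match="target_size"):
            compute_superpixels(np.zeros((32, 32, 3), np.uint8), target_size=3)


class TestCompartmentClassifier:
    def _examples(self, rng, n=40):
        # two linearly separable descriptor clouds
        epi = rng.normal(0.0, 1.0, (n, 15))
        stro = rng.normal(4.0, 1.0, (n, 15))
        return [(e, "epithelial") for e in epi] + [(s, "stromal") for s in stro]

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(0)
        ex = [(rng.normal(size=15), "stromal") for _ in range(5)]
        with pytest.raises(ValueError, match="epithelial"):
            train_compartment_classifier(ex)

    def test_separable_examples_classified_accurately(self):
        rng = np.random.default_rng(1)
        model = train_compartment_classifier(self._examples(rng))
        held = self._examples(np.random.default_rng(2))
        X = np.vstack([d for d, _ in held])
        y = np.array([l for _, l in held])
        assert (model.predict(X) == y).mean() >= 0.95

    def test_label_swap_complements_predictions(self):
        rng = np.random.default_rng(3)
        ex = self._examples(rng)
        swap = {"epithelial": "stromal", "stromal": "epithelial"}
        flipped = [(d, swap[l]) for d, l in ex]
        X = np.vstack([d for d, _ in ex])
        a = train_compartment_classifier(ex).predict(X)
        b = train_compartment_classifier(flipped).predict(X)
        assert all(swap[x] == y for x, y in zip(a, b))

    def test_duplicate_examples_do_not_change_predictions(self):
        rng = np.random.default_rng(4)
        ex = self._examples(rng)
        X = np.vstack([d for d, _ in ex])
        a = train_compartment_classifier(ex).predict(X)
        b = train_compartment_classifier(ex + ex).predict(X)
        assert (a == b).all()

    def test_descriptor_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        model = train_compartment_classifier(self._examples(rng))
        with pytest.raises(ValueError, match="dimension"):
            model.predict(np.zeros((3, 7)))

    def test_synthetic_image_majority_accuracy(self, trained_model):
        img, truth = generate_tma_image(ImageSimParams(seed=21))
        spx = compute_superpixels(img)
        pred = classify_compartments(spx, trained_model)
        correct = total = 0
        for sid in range(1, spx.n_superpixels + 1):
            m = spx.labels == sid
            epi = (truth.compartment_mask[m] == 1).sum()
            stro = (truth.compartment_mask[m] == 2).sum()
            true_lab = "epithelial" if epi >= stro else "stromal"
            correct += pred[sid - 1] == true_lab
            total += 1
        assert correct / total >= 0.90

    def test_stroma_only_image_all_stromal(self, trained_model):
        img, _ = generate_tma_image(
            ImageSimParams(seed=8, epithelial_fraction=0.0,
                           stromal_inflammation_density=0.1)
        )
        spx = compute_superpixels(img)
        pred = classify_compartments(spx, trained_model)
        assert (pred == "stromal").mean() >= 0.95

    def test_classification_order_invariant(self, trained_model):
        img, _ = generate_tma_image(ImageSimParams(seed=9))
        spx = compute_superpixels(img)
        pred = classify_compartments(spx, trained_model)
        perm = np.random.default_rng(0).permutation(spx.n_superpixels)
        shuffled = spx.descriptors[perm]
        assert (trained_model.predict(shuffled) == pred[perm]).all()


class TestCellSegmentation:
    def test_detected_count_near_truth(self, trained_model):
        ratios = []
        for seed in range(4):
            img, truth = generate_tma_image(
                ImageSimParams(seed=seed, stromal_inflammation_density=0.2)
            )
            seg = segment_image(img, trained_model)
            ratios.append(len(seg.cells.table) / len(truth.cell_classes))
        assert 0.9 <= np.mean(ratios) <= 1.1

    def test_blank_stroma_has_no_inflammatory_objects(self, trained_model):
        img, truth = generate_tma_image(
            ImageSimParams(seed=5, stromal_inflammation_density=0.0)
        )
        cells = segment_cells(img, truth.compartment_mask)
        assert (cells.table["class"] != "inflammatory").all() or len(cells.table) == 0

    def test_objects_disjoint_and_in_bounds(self, trained_model, default_core):
        img, _ = default_core
        seg = segment_image(img, trained_model)
        # label rasters are disjoint by construction; every object non-empty
        ids = seg.cells.table["id"].to_numpy()
        areas = np.bincount(seg.cells.label_mask.ravel())
        assert (areas[ids] > 0).all()
        assert seg.cells.label_mask.shape == img.shape[:2]
        # nuclei and cytoplasm zones do not overlap
        assert not ((seg.cells.label_mask > 0) & (seg.cells.cyto_mask > 0)).any()

    def test_total_object_area_within_tissue(self, trained_model, default_core):
        img, _ = default_core
        seg = segment_image(img, trained_model)
        assert (seg.cells.label_mask > 0).sum() <= (seg.compartments > 0).sum()


class TestAudit:
    def test_perfect_segmentation_scores_one(self, default_core, perfect_segmentation):
        _, truth = default_core
        rep = audit_accuracy(perfect_segmentation, truth)
        assert rep.superpixel_accuracy == 1.0
        assert rep.nucleus_accuracy == 1.0
        assert rep.n_superpixels_audited > 0 and rep.n_nuclei_audited > 0

    def test_inverted_labels_complement_accuracy(self, default_core, perfect_segmentation):
        import copy

        _, truth = default_core
        seg = copy.deepcopy(perfect_segmentation)
        swap = {"epithelial": "stromal", "stromal": "epithelial"}
        seg.superpixel_labels = np.array(
            [swap[l] for l in seg.superpixel_labels], dtype=object
        )
        rep = audit_accuracy(seg, truth)
        assert rep.superpixel_accuracy == pytest.approx(0.0)

    def test_audit_ignores_changes_off_the_midline(self, default_core):
        img, truth = default_core
        seg = truth_segmentation(img, truth)
        base = audit_accuracy(seg, truth)
        mid = truth.compartment_mask.shape[0] // 2
        off_midline = [
            sid
            for sid in range(1, seg.superpixels.n_superpixels + 1)
            if not (seg.superpixels.labels[mid, :] == sid).any()
        ]
        swap = {"epithelial": "stromal", "stromal": "epithelial"}
        for sid in off_midline[:10]:
            seg.superpixel_labels[sid - 1] = swap[seg.superpixel_labels[sid - 1]]
        rep = audit_accuracy(seg, truth)
        assert rep.superpixel_accuracy == base.superpixel_accuracy

    def test_shape_mismatch_rejected(self, default_core, perfect_segmentation):
        _, truth = default_core
        import copy

        truth2 = copy.deepcopy(truth)
        truth2.compartment_mask = truth2.compartment_mask[:-1]
        with pytest.raises(ValueError, match="shape"):
            audit_accuracy(perfect_segmentation, truth2)
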