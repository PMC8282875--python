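import numpy as np
import pytest

from msmseg.semantic_assignment import (CELL_CANDIDATE, NUCLEUS_CANDIDATE,
                                        ClassMap, QualityScore,
                                        SegmentFeatures, assign_classes,
                                        build_enclosure_hierarchy,
                                        compactness, contour_gradient,
                                        ocin_assign, quality_scores,
                                        select_nuclei)


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def concentric_labels(n=25):
    """0 = background, 1 = ring, 2 = inner disk."""
    labels = np.zeros((n, n), dtype=int)
    c = n // 2
    labels[disk_mask((n, n), c, c, 8)] = 1
    labels[disk_mask((n, n), c, c, 4)] = 2
    return labels


class TestHierarchy:
    def test_concentric_parent_links(self):
        h = build_enclosure_hierarchy(concentric_labels())
        assert h.parent_of == {2: 1, 1: 0}
        assert h.residual == frozenset({0})

    def test_border_sharing_segments_residual(self):
        labels = np.zeros((6, 10), dtype=int)
        labels[:, 5:] = 1
        h = build_enclosure_hierarchy(labels)
        assert h.parent_of == {}
        assert h.residual == frozenset({0, 1})

    def test_three_level_nesting(self):
        labels = np.zeros((33, 33), dtype=int)
        labels[disk_mask((33, 33), 16, 16, 13)] = 1
        labels[disk_mask((33, 33), 16, 16, 9)] = 2
        labels[disk_mask((33, 33), 16, 16, 4)] = 3
        h = build_enclosure_hierarchy(labels)
        assert h.parent_of == {3: 2, 2: 1, 1: 0}

    def test_border_touching_segment_never_child(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[0:3, 2:5] = 1  # touches top border, surrounded otherwise
        h = build_enclosure_hierarchy(labels)
        assert 1 not in h.parent_of


class TestOcin:
    def test_dark_enclosed_disk_is_nucleus(self):
        labels = concentric_labels()
        means = np.array([60.0, 120.0, 40.0])
        out = ocin_assign(labels, means)
        assert out[2] == (NUCLEUS_CANDIDATE, 1)
        assert out[1][0] == CELL_CANDIDATE  # brighter than surround

    def test_bright_enclosed_blob_is_cell(self):
        labels = concentric_labels()
        means = np.array([60.0, 40.0, 150.0])
        out = ocin_assign(labels, means)
        assert out[2] == (CELL_CANDIDATE, 1)

    def test_chain_nucleus_labelled_in_iteration_two(self):
        # ring (1) encloses two adjacent blobs: dark nucleus (2) and a
        # brighter matrix pocket (3); the ring is a child of background (0)
        labels = np.zeros((25, 25), dtype=int)
        labels[disk_mask((25, 25), 12, 12, 10)] = 1
        labels[4:12, 8:17] = 2
        labels[12:20, 8:17] = 3
        means = np.array([65.0, 150.0, 30.0, 70.0])
        out = ocin_assign(labels, means)
        assert out[1] == (CELL_CANDIDATE, 1)  # child of background, brighter
        assert out[2] == (NUCLEUS_CANDIDATE, 2)
        assert out[3][0] == CELL_CANDIDATE

    def test_terminates_with_fallback_on_stall(self, caplog):
        # the middle strip ends up with zero unlabelled neighbours and can
        # never form a 1:1 situation; the neighbour-mean fallback labels it
        labels = np.zeros((6, 12), dtype=int)
        labels[:, 4:8] = 1
        labels[:, 8:] = 2
        means = np.array([40.0, 90.0, 100.0])
        with caplog.at_level("WARNING", logger="msmseg"):
            out = ocin_assign(labels, means)
        assert out[0] == (NUCLEUS_CANDIDATE, 2)
        assert out[2] == (CELL_CANDIDATE, 2)
        assert out[1][0] == CELL_CANDIDATE  # 90 > area-weighted 70
        assert out[1][1] == 3
        assert "stalled" in caplog.text

    def test_raw_pixel_mode_requires_intensity(self):
        labels = concentric_labels()
        means = np.array([60.0, 120.0, 40.0])
        with pytest.raises(ValueError):
            ocin_assign(labels, means, boundary_mode="raw-pixel")

    def test_raw_pixel_mode_agrees_on_clean_rendering(self):
        labels = concentric_labels()
        means = np.array([60.0, 120.0, 40.0])
        rendered = means[labels]
        out = ocin_assign(labels, means, boundary_mode="raw-pixel",
                          intensity=rendered)
        assert out[2] == (NUCLEUS_CANDIDATE, 1)


class TestCompactness:
    def test_rasterized_disk_close_to_one(self):
        mask = disk_mask((61, 61), 30, 30, 20)
        assert compactness(mask) == pytest.approx(1.0, rel=0.05)

    def test_square_close_to_analytic(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        # continuous square: C = (4L)^2 / (4 pi L^2) = 4/pi
        assert compactness(mask, method="pixel-count") == pytest.approx(
            4 / np.pi, rel=0.15)

    def test_elongated_bar_exceeds_disk(self):
        bar = np.zeros((10, 40), dtype=bool)
        bar[3:6, 5:35] = True
        disk = disk_mask((61, 61), 30, 30, 20)
        assert compactness(bar) > 2.0 * compactness(disk)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compactness(np.zeros((5, 5), dtype=bool))


class TestContourGradient:
    def test_constant_image_zero(self):
        mask = disk_mask((21, 21), 10, 10, 5)
        img = np.full((21, 21), 99, dtype=np.uint8)
        assert contour_gradient(mask, img) == 0.0

    def test_square_step_hand_computed(self):
        img = np.full((9, 9), 200, dtype=np.uint8)
        img[3:6, 3:6] = 0
        mask = np.zeros((9, 9), dtype=bool)
        mask[3:6, 3:6] = True
        # 8 contour pixels: 4 corners |grad| = sqrt(100^2+100^2), 4 edge
        # centers |grad| = 100 (central differences across the step)
        expected = (4 * np.hypot(100, 100) + 4 * 100) / 8
        assert contour_gradient(mask, img) == pytest.approx(expected)

    def test_translation_invariance(self, rng):
        img = np.zeros((30, 30), dtype=np.uint8)
        img[8:14, 8:14] = 180
        mask = np.zeros((30, 30), dtype=bool)
        mask[8:14, 8:14] = True
        v1 = contour_gradient(mask, img)
        v2 = contour_gradient(np.roll(mask, (5, 7), (0, 1)),
                              np.roll(img, (5, 7), (0, 1)))
        assert v1 == pytest.approx(v2)


def feat(label, S, grad, C, H, cls=NUCLEUS_CANDIDATE):
    return SegmentFeatures(label=label, S=S, grad=grad, C=C, H=H,
                           ocin_class=cls)


class TestQualityScores:
    def test_ideal_candidate_scores_zero(self):
        f = feat(1, S=7.0, grad=255.0, C=1.0, H=1)
        scores = quality_scores([f], msm_max=7, i_max=255, ocin_max=1)
        assert scores[0].d == pytest.approx(0.0)

    def test_halfway_vector_scores_one(self):
        f = feat(1, S=3.5, grad=127.5, C=2.0, H=2)
        scores = quality_scores([f], msm_max=7, i_max=255, ocin_max=2)
        assert scores[0].d == pytest.approx(1.0)

    def test_only_nucleus_candidates_scored(self):
        fs = [feat(1, 7, 255, 1.0, 1),
              feat(2, 7, 255, 1.0, 1, cls=CELL_CANDIDATE)]
        scores = quality_scores(fs, msm_max=7, i_max=255, ocin_max=1)
        assert [s.label for s in scores] == [1]

    def test_improving_single_feature_decreases_d(self):
        base = feat(1, S=3.0, grad=100.0, C=1.5, H=1)
        better = feat(2, S=5.0, grad=100.0, C=1.5, H=1)
        other = feat(3, S=3.0, grad=100.0, C=2.0, H=1)  # fixes C_max
        scores = quality_scores([base, better, other],
                                msm_max=7, i_max=255, ocin_max=2)
        d = {s.label: s.d for s in scores}
        assert d[2] < d[1]

    def test_invalid_norms_rejected(self):
        with pytest.raises(ValueError):
            quality_scores([feat(1, 1, 1, 1, 1)], msm_max=0, i_max=255)


class TestSelectNuclei:
    def make(self, ds):
        return [QualityScore(label=i, d=d) for i, d in enumerate(ds)]

    def test_tqual_one_selects_nothing(self):
        out = select_nuclei(self.make([0.2, 0.5, 0.9]), 1.0)
        assert not any(s.selected for s in out)

    def test_tqual_zero_selects_all_but_worst(self):
        out = select_nuclei(self.make([0.2, 0.5, 1.0, 1.0]), 0.0)
        sel = {s.label for s in out if s.selected}
        assert sel == {0, 1}

    def test_printed_rule_arithmetic(self):
        # d = {0.2, 0.5, 1.0}, T=0.97 -> threshold 0.224
        out = select_nuclei(self.make([0.2, 0.5, 1.0]), 0.97)
        sel = {s.label for s in out if s.selected}
        assert sel == {0}

    def test_selection_monotone_in_threshold(self, rng):
        ds = rng.random(20).tolist()
        scores = self.make(ds)
        prev = None
        for t in (0.0, 0.3, 0.6, 0.9, 1.0):
            sel = {s.label for s in select_nuclei(scores, t) if s.selected}
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_empty_scores(self):
        assert select_nuclei([], 0.5) == []

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_nuclei(self.make([0.1]), 1.5)


class TestAssignClasses:
    def test_no_nuclei_all_matrix(self):
        labels = concentric_labels()
        ocin = {0: (CELL_CANDIDATE, 2), 1: (CELL_CANDIDATE, 1),
                2: (NUCLEUS_CANDIDATE, 1)}
        cm = assign_classes(labels, [], ocin)
        assert np.all(cm.classes == ClassMap.MATRIX)

    def test_enclosing_cell_candidate_becomes_cytoplasm(self):
        labels = concentric_labels()
        ocin = {0: (CELL_CANDIDATE, 2), 1: (CELL_CANDIDATE, 1),
                2: (NUCLEUS_CANDIDATE, 1)}
        cm = assign_classes(labels, [2], ocin)
        assert np.all(cm.classes[labels == 2] == ClassMap.NUCLEUS)
        assert np.all(cm.classes[labels == 1] == ClassMap.CYTOPLASM)
        assert np.all(cm.classes[labels == 0] == ClassMap.MATRIX)
        assert cm.cytoplasm_of == {2: (1,)}

    def test_nucleus_touching_two_cell_candidates(self):
        labels = np.zeros((12, 12), dtype=int)
        labels[4:8, 0:4] = 1
        labels[4:8, 4:8] = 2   # nucleus in the middle
        labels[4:8, 8:12] = 3
        ocin = {0: (CELL_CANDIDATE, 2), 1: (CELL_CANDIDATE, 1),
                2: (NUCLEUS_CANDIDATE, 1), 3: (CELL_CANDIDATE, 1)}
        cm = assign_classes(labels, [2], ocin, background_label=0)
        assert cm.cytoplasm_of == {2: (1, 3)}

    def test_classes_partition_image(self):
        labels = concentric_labels()
        ocin = {0: (CELL_CANDIDATE, 2), 1: (CELL_CANDIDATE, 1),
                2: (NUCLEUS_CANDIDATE, 1)}
        cm = assign_classes(labels, [2], ocin)
        assert set(np.unique(cm.classes)) <= {0, 1, 2}
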