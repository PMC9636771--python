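"""Nuclear and object segmentation, morphology, layer integration."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk, ellipse

from mibipipe import (EZSegParams, GeometryError, LabelLayer, expand_nuclei,
                      ez_segment, fallback_nuclear_segment, integrate_layers,
                      morphology_features)

from tests.conftest import make_stack


def layer_from(labels, kind="object", cls=None):
    return LabelLayer(np.asarray(labels, dtype=np.int32), kind, cls)


class TestFallbackNuclear:
    def test_blank_image_gives_no_labels(self):
        out = fallback_nuclear_segment(np.zeros((32, 32)))
        assert out.n_labels == 0

    def test_disjoint_disks_counted_by_components_oracle(self):
        img = np.zeros((128, 128))
        rng = np.random.default_rng(0)
        centers = [(16 + 24 * i, 16 + 24 * j) for i in range(4) for j in range(4)][:10]
        for r, c in centers:
            rr, cc = disk((r, c), 4, shape=img.shape)
            img[rr, cc] = 10.0
        out = fallback_nuclear_segment(img, min_px=9)
        n_oracle = ndimage.label(img > 0)[1]
        assert out.n_labels == n_oracle == 10

    def test_touching_disks_split_by_watershed(self):
        img = np.zeros((40, 60))
        for c in (20, 33):  # two equal disks, centers 13 px apart (r=7 each)
            rr, cc = disk((20, c), 7, shape=img.shape)
            img[rr, cc] = 10.0
        assert ndimage.label(img > 0)[1] == 1  # they touch
        out = fallback_nuclear_segment(img, min_px=9)
        assert out.n_labels == 2


class TestExpandNuclei:
    def test_distance_zero_is_identity(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4, 4] = 1
        out = expand_nuclei(layer_from(labels, "cell"), 0)
        assert np.array_equal(out.labels, labels)

    def test_single_pixel_distance3_covers_29px_disk(self):
        """|{(dx,dy): dx^2+dy^2 <= 9}| enumerates to 29 on the grid."""
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[8, 8] = 1
        out = expand_nuclei(layer_from(labels, "cell"), 3)
        enumerated = sum(1 for dx in range(-3, 4) for dy in range(-3, 4)
                         if dx * dx + dy * dy <= 9)
        assert enumerated == 29
        assert (out.labels == 1).sum() == 29

    def test_partition_refinement_and_no_double_assignment(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10, 10] = 1
        labels[10, 20] = 2  # 10 px apart, expansion 8 -> frontier bisects
        out = expand_nuclei(layer_from(labels, "cell"), 8)
        assert out.labels[10, 10] == 1 and out.labels[10, 20] == 2
        assert out.labels[10, 14] == 1 and out.labels[10, 16] == 2
        # equidistant column goes to the lower label
        assert out.labels[10, 15] == 1
        assert out.n_labels == 2

    def test_label_count_unchanged(self, small_phantom):
        _, truth = small_phantom
        nuclei = truth.nucleus_labels
        out = expand_nuclei(nuclei, 3)
        assert set(out.label_ids) == set(nuclei.label_ids)
        inside = nuclei.labels > 0
        assert np.array_equal(out.labels[inside], nuclei.labels[inside])


class TestEZSegment:
    def test_threshold_above_max_gives_empty_layer(self):
        stack = make_stack({"Abeta42": np.full((32, 32), 2.0)})
        params = EZSegParams(["Abeta42"], "plaque", blur_sigma=0,
                             threshold=99.0, min_px=1)
        assert ez_segment(stack, params).n_labels == 0

    def test_size_filter_drops_specks(self):
        img = np.zeros((128, 128))
        for i in range(5):  # 5 plaques of ~120 px (r=6 -> 113 px)
            rr, cc = disk((20 + 20 * i, 60), 6, shape=img.shape)
            img[rr, cc] = 10.0
        for i in range(3):  # 3 specks of 4 px
            img[5, 5 + 6 * i:7 + 6 * i] = 10.0
            img[6, 5 + 6 * i:7 + 6 * i] = 10.0
        params = EZSegParams(["Abeta42"], "plaque", blur_sigma=0,
                             threshold=5.0, min_px=10)
        out = ez_segment(make_stack({"Abeta42": img}), params)
        assert out.n_labels == 5

    def test_binary_image_equals_connected_components(self):
        rng = np.random.default_rng(1)
        img = (rng.uniform(size=(64, 64)) > 0.7).astype(float)
        params = EZSegParams(["c"], "x", blur_sigma=0, threshold=0.5, min_px=1)
        out = ez_segment(make_stack({"c": img}), params)
        n_oracle = ndimage.label(img > 0.5, structure=np.ones((3, 3)))[1]
        assert out.n_labels == n_oracle

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        img = rng.poisson(4, (64, 64)).astype(float)
        stack = make_stack({"c": img})
        areas = []
        for thr in (1.0, 2.0, 4.0, 6.0):
            p = EZSegParams(["c"], "x", blur_sigma=1.0, threshold=thr, min_px=1)
            areas.append((ez_segment(stack, p).labels > 0).sum())
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_quantile_mode_on_zero_image_warns_empty(self):
        stack = make_stack({"c": np.zeros((16, 16))})
        p = EZSegParams(["c"], "x", blur_sigma=0, threshold=0.9,
                        threshold_mode="quantile", min_px=1)
        with pytest.warns(UserWarning):
            out = ez_segment(stack, p)
        assert out.n_labels == 0


class TestMorphology:
    def test_square_area_and_circularity(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        rec = morphology_features(layer_from(labels))[0]
        assert rec.area == 100
        # boundary-pixel perimeter oracle: 4*(10-1) = 36
        assert rec.perimeter == pytest.approx(36)
        assert rec.circularity == pytest.approx(4 * np.pi * 100 / 36 ** 2, abs=1e-6)

    def test_single_pixel_object(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[3, 3] = 1
        rec = morphology_features(layer_from(labels))[0]
        assert rec.area == 1
        assert rec.major_axis == rec.minor_axis

    def test_planted_ellipse_eccentricity(self):
        labels = np.zeros((80, 80), dtype=np.int32)
        rr, cc = ellipse(40, 40, 10, 20)
        labels[rr, cc] = 1
        rec = morphology_features(layer_from(labels))[0]
        # analytic: e = sqrt(1 - (b/a)^2) = sqrt(1 - 0.25) = 0.866
        assert rec.eccentricity == pytest.approx(0.866, abs=0.05)


class TestIntegrateLayers:
    def test_disjoint_layers_empty_table(self):
        cells = np.zeros((16, 16), dtype=np.int32)
        objs = np.zeros((16, 16), dtype=np.int32)
        cells[2:5, 2:5] = 1
        objs[10:13, 10:13] = 1
        tbl = integrate_layers(layer_from(cells, "cell"),
                               [layer_from(objs, "object", "tangle")])
        assert len(tbl) == 0

    def test_tangle_inside_neuron_shares_full_area(self):
        cells = np.zeros((32, 32), dtype=np.int32)
        objs = np.zeros((32, 32), dtype=np.int32)
        rr, cc = disk((16, 16), 8, shape=cells.shape)
        cells[rr, cc] = 1
        rr, cc = disk((16, 16), 3, shape=objs.shape)
        objs[rr, cc] = 1
        tangle_area = (objs == 1).sum()
        tbl = integrate_layers(layer_from(cells, "cell"),
                               [layer_from(objs, "object", "tangle")])
        assert len(tbl) == 1
        assert tbl.iloc[0]["shared_px"] == tangle_area

    def test_phantom_overlaps_match_ground_truth(self, small_phantom):
        _, truth = small_phantom
        tbl = integrate_layers(truth.cell_labels, [truth.object_labels])
        got = sorted((int(r.cell_label), int(r.object_label), int(r.shared_px))
                     for r in tbl.itertuples())
        assert got == truth.true_overlap_pairs

    def test_geometry_mismatch_raises(self):
        with pytest.raises(GeometryError):
            integrate_layers(layer_from(np.zeros((8, 8), dtype=np.int32), "cell"),
                             [layer_from(np.zeros((9, 9), dtype=np.int32))])
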