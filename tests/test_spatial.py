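"""Co-proximity null model, association ratios, regions, synaptic scoring."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mibipipe import (LabelLayer, ProximityParams, association_ratio,
                      boundary_distances, co_proximity, discover_regions,
                      neighborhood_profiles, synaptic_coincidence,
                      voronoi_expand)
from mibipipe.spatial import (DEFAULT_RADII, RegionMap, _boundary_points,
                              assign_anatomical, composition_table)

from tests.conftest import make_stack


def points_layer(points, shape=(64, 64), kind="object", cls="b"):
    labels = np.zeros(shape, dtype=np.int32)
    for i, (r, c) in enumerate(points, start=1):
        labels[r, c] = i
    return LabelLayer(labels, kind, cls)


class TestBoundaryDistances:
    def test_three_four_five_triangle(self):
        layer_a = points_layer([(0, 0)], cls="a")
        layer_b = points_layer([(3, 4)], cls="b")
        d = boundary_distances(layer_a, layer_b)
        assert d.iloc[0, 0] == pytest.approx(5.0)

    def test_self_pairs_excluded(self):
        layer = points_layer([(0, 0), (3, 4)])
        d = boundary_distances(layer, layer)
        assert np.isnan(d.iloc[0, 0]) and np.isnan(d.iloc[1, 1])
        assert d.iloc[0, 1] == pytest.approx(5.0)

    def test_overlapping_objects_distance_zero(self):
        a = np.zeros((16, 16), dtype=np.int32)
        b = np.zeros((16, 16), dtype=np.int32)
        a[2:6, 2:6] = 1
        b[4:8, 4:8] = 1
        d = boundary_distances(LabelLayer(a, "cell"), LabelLayer(b, "object"))
        assert d.iloc[0, 0] == 0.0

    def test_matches_exhaustive_boundary_pixel_oracle(self):
        rng = np.random.default_rng(0)
        labels_a = np.zeros((48, 48), dtype=np.int32)
        labels_b = np.zeros((48, 48), dtype=np.int32)
        for lab in range(1, 8):
            r, c = rng.integers(4, 44, 2)
            labels_a[r - 1:r + 2, c - 1:c + 2] = lab
            r, c = rng.integers(4, 44, 2)
            labels_b[r - 2:r + 1, c - 2:c + 1] = lab
        la, lb = LabelLayer(labels_a, "cell"), LabelLayer(labels_b, "object")
        d = boundary_distances(la, lb)
        pa = _boundary_points(labels_a)
        pb = _boundary_points(labels_b)
        for i in pa:
            for j in pb:
                brute = min(np.hypot(*(p - q))
                            for p in pa[i] for q in pb[j])
                assert d.loc[i, j] == pytest.approx(brute)


class TestCoProximity:
    def test_maximal_clustering_limit(self):
        """All B on top of A: observed = n_B, ratio = A_FOV/(pi t^2)."""
        a = points_layer([(32, 32)], cls="a")
        b = points_layer([(32, 31), (32, 33), (31, 32)], cls="b")
        params = ProximityParams(radii=(5,), type_pairs=[("a", "b")])
        res = co_proximity({"a": a, "b": b}, params)
        row = res.iloc[0]
        assert row["observed"] == 3
        assert row["ratio"] == pytest.approx(
            3 / (3 * np.pi * 25 / (64 * 64)))

    def test_no_b_objects_flagged_undefined(self):
        a = points_layer([(5, 5)], cls="a")
        b = points_layer([], cls="b")
        params = ProximityParams(radii=(5,), type_pairs=[("a", "b")])
        res = co_proximity({"a": a, "b": b}, params)
        assert np.isnan(res.iloc[0]["ratio"])

    def test_default_radius_grid(self):
        assert DEFAULT_RADII == (25, 50, 100, 150, 200, 250, 300)

    def test_uniform_null_calibration(self):
        """Uniformly placed point objects give ratio ~ 1 at every radius."""
        rng = np.random.default_rng(42)
        shape = (256, 256)
        ratios = {t: [] for t in (6, 12, 25)}
        for _ in range(10):
            pa = rng.integers(0, 256, (40, 2))
            pb = rng.integers(0, 256, (200, 2))
            a = points_layer(pa, shape, cls="a")
            b = points_layer(pb, shape, cls="b")
            params = ProximityParams(radii=(6, 12, 25),
                                     type_pairs=[("a", "b")])
            res = co_proximity({"a": a, "b": b}, params)
            for _, row in res.iterrows():
                ratios[row["t"]].append(row["ratio"])
        for t, r in ratios.items():
            assert 0.9 < np.mean(r) < 1.1

    def test_observed_counts_match_boundary_distance_oracle(self):
        rng = np.random.default_rng(1)
        shape = (96, 96)
        pa = rng.integers(8, 88, (6, 2))
        pb = rng.integers(8, 88, (9, 2))
        a = points_layer(pa, shape, cls="a")
        b = points_layer(pb, shape, cls="b")
        t = 20
        res = co_proximity({"a": a, "b": b},
                           ProximityParams(radii=(t,), type_pairs=[("a", "b")]))
        d = boundary_distances(a, b)
        oracle = (d.to_numpy() <= t).sum(axis=1).mean()
        assert res.iloc[0]["observed"] == pytest.approx(oracle)


class TestAssociationRatio:
    def make_table(self, n, lineage="microglia"):
        return pd.DataFrame({
            "object_id": range(1, n + 1), "layer_kind": "cell",
            "object_class": "cell", "lineage": lineage})

    def test_no_overlaps_gives_zero(self):
        tbl = self.make_table(6)
        overlaps = pd.DataFrame(columns=["cell_label", "object_class",
                                         "object_label", "shared_px"])
        res = association_ratio(tbl, overlaps, "tangle")
        assert (res["ratio"] == 0).all()

    def test_balanced_overlap_gives_exactly_one(self):
        tbl = self.make_table(10)
        overlaps = pd.DataFrame({
            "cell_label": [1, 2, 3, 4, 5],
            "object_class": "tangle", "object_label": 1, "shared_px": 2})
        res = association_ratio(tbl, overlaps, "tangle")
        assert res.iloc[0]["ratio"] == 1.0

    def test_two_to_one_planted_ratio(self):
        tbl = self.make_table(9)
        overlaps = pd.DataFrame({
            "cell_label": [1, 2, 3, 4, 5, 6],
            "object_class": "tangle", "object_label": 1, "shared_px": 1})
        res = association_ratio(tbl, overlaps, "tangle")
        assert res.iloc[0]["ratio"] == pytest.approx(2.0)

    def test_zero_denominator_flagged_infinite(self):
        tbl = self.make_table(3)
        overlaps = pd.DataFrame({
            "cell_label": [1, 2, 3], "object_class": "tangle",
            "object_label": 1, "shared_px": 1})
        res = association_ratio(tbl, overlaps, "tangle")
        assert np.isinf(res.iloc[0]["ratio"])

    def test_unknown_class_raises(self):
        tbl = self.make_table(3)
        overlaps = pd.DataFrame({
            "cell_label": [1], "object_class": "tangle",
            "object_label": 1, "shared_px": 1})
        with pytest.raises(ValueError):
            association_ratio(tbl, overlaps, "nonesuch")

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        tbl = self.make_table(20)
        chosen = rng.choice(np.arange(1, 21), 8, replace=False)
        overlaps = pd.DataFrame({
            "cell_label": chosen, "object_class": "tangle",
            "object_label": 1, "shared_px": 1})
        r1 = association_ratio(tbl, overlaps, "tangle").iloc[0]["ratio"]
        perm = rng.permutation(np.arange(1, 21))
        mapping = dict(zip(np.arange(1, 21), perm))
        tbl2 = tbl.assign(object_id=tbl["object_id"].map(mapping))
        overlaps2 = overlaps.assign(
            cell_label=overlaps["cell_label"].map(mapping))
        r2 = association_ratio(tbl2, overlaps2, "tangle").iloc[0]["ratio"]
        assert r1 == r2


class TestAnatomical:
    def make_table(self):
        rng = np.random.default_rng(3)
        return pd.DataFrame({
            "object_id": range(1, 41),
            "object_class": rng.choice(["neuron", "microglia"], 40),
            "centroid_row": rng.uniform(0, 64, 40),
            "centroid_col": rng.uniform(0, 64, 40)})

    def test_single_covering_mask(self):
        tbl = self.make_table()
        masks = {"CA1": np.ones((64, 64), dtype=bool)}
        out = assign_anatomical(tbl, masks)
        assert (out["anatomical_region"] == "CA1").all()

    def test_composition_rows_sum_to_one(self):
        tbl = self.make_table()
        masks = {"CA1": np.zeros((64, 64), dtype=bool),
                 "DG": np.ones((64, 64), dtype=bool)}
        masks["CA1"][:32] = True
        out = assign_anatomical(tbl, masks)
        comp = composition_table(out, "anatomical_region")
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)

    def test_overlapping_masks_warn_and_use_precedence(self):
        tbl = self.make_table()
        full = np.ones((64, 64), dtype=bool)
        with pytest.warns(UserWarning):
            out = assign_anatomical(tbl, {"A": full, "B": full})
        assert (out["anatomical_region"] == "A").all()

    def test_planted_densities_recovered(self):
        rng = np.random.default_rng(4)
        rows = []
        # region A: 80% neurons; region B: 20% neurons
        for i in range(200):
            in_a = i < 100
            r = rng.uniform(0, 32) if in_a else rng.uniform(32, 64)
            p = 0.8 if in_a else 0.2
            rows.append({"object_id": i,
                         "object_class": "neuron" if rng.uniform() < p
                         else "microglia",
                         "centroid_row": r, "centroid_col": rng.uniform(0, 64)})
        tbl = pd.DataFrame(rows)
        masks = {"A": np.zeros((64, 64), dtype=bool),
                 "B": np.zeros((64, 64), dtype=bool)}
        masks["A"][:32] = True
        masks["B"][32:] = True
        comp = composition_table(assign_anatomical(tbl, masks),
                                 "anatomical_region")
        ci = 1.96 * np.sqrt(0.8 * 0.2 / 100)
        assert abs(comp.loc["A", "neuron"] - 0.8) < 2 * ci
        assert abs(comp.loc["B", "neuron"] - 0.2) < 2 * ci


class TestNeighborhoodProfiles:
    def test_isolated_object_is_own_class_indicator(self):
        tbl = pd.DataFrame({
            "object_class": ["neuron", "tangle"],
            "centroid_row": [0.0, 500.0], "centroid_col": [0.0, 500.0]})
        prof = neighborhood_profiles(tbl, radius_px=10)
        assert prof.iloc[0]["neuron"] == 1.0 and prof.iloc[0]["tangle"] == 0.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        tbl = pd.DataFrame({
            "object_class": rng.choice(["a", "b", "c"], 100),
            "centroid_row": rng.uniform(0, 100, 100),
            "centroid_col": rng.uniform(0, 100, 100)})
        prof = neighborhood_profiles(tbl, radius_px=20)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0)

    def test_dense_mixture_converges_to_global_frequencies(self):
        rng = np.random.default_rng(6)
        n = 2000
        classes = rng.choice(["a", "b"], n, p=[0.7, 0.3])
        tbl = pd.DataFrame({
            "object_class": classes,
            "centroid_row": rng.uniform(0, 100, n),
            "centroid_col": rng.uniform(0, 100, n)})
        prof = neighborhood_profiles(tbl, radius_px=30)
        assert abs(prof["a"].mean() - 0.7) < 0.02


class TestDiscoverRegions:
    def test_k_range_of_one(self):
        prof = pd.DataFrame(np.random.default_rng(0).uniform(size=(30, 3)),
                            columns=list("abc"))
        labels, k = discover_regions(prof, ["s1"] * 30, k_range=[1])
        assert k == 1 and len(np.unique(labels)) == 1

    def test_recovers_planted_regions_across_samples(self):
        """5 planted profile archetypes shared by 3 samples -> k=5, ARI>0.8."""
        rng = np.random.default_rng(7)
        archetypes = np.eye(5) * 0.8 + 0.05
        rows, samples, truth = [], [], []
        for s in range(3):
            for a in range(5):
                for _ in range(40):
                    p = np.clip(archetypes[a] + rng.normal(0, 0.03, 5), 0, None)
                    rows.append(p / p.sum())
                    samples.append(f"s{s}")
                    truth.append(a)
        prof = pd.DataFrame(rows, columns=list("abcde"))
        labels, k = discover_regions(prof, samples,
                                     k_range=range(2, 9), seed=0)
        assert k == 5
        assert adjusted_rand_score(truth, labels) > 0.8


class TestVoronoiExpand:
    def test_single_object_claims_all_tissue(self):
        tissue = np.ones((32, 32), dtype=bool)
        tissue[0] = False
        rm = voronoi_expand(np.array([[16.0, 16.0]]), np.array([1]), tissue,
                            ["N"])
        assert (rm.labels[tissue] == 1).all()
        assert (rm.labels[~tissue] == 0).all()

    def test_two_region_bisector(self):
        tissue = np.ones((20, 40), dtype=bool)
        rm = voronoi_expand(np.array([[10.0, 10.0], [10.0, 30.0]]),
                            np.array([1, 2]), tissue, ["N", "TT"])
        assert rm.labels[10, 5] == 1 and rm.labels[10, 35] == 2

    def test_matches_brute_force_nearest_centroid(self):
        rng = np.random.default_rng(8)
        tissue = np.ones((48, 48), dtype=bool)
        pts = rng.uniform(0, 48, (50, 2))
        ids = rng.integers(1, 4, 50)
        rm = voronoi_expand(pts, ids, tissue, ["a", "b", "c"])
        rr, cc = np.mgrid[0:48, 0:48]
        d2 = ((rr[..., None] - pts[:, 0]) ** 2
              + (cc[..., None] - pts[:, 1]) ** 2)
        brute = ids[np.argmin(d2, axis=2)]
        assert np.array_equal(rm.labels, brute)

    def test_idempotent_and_covers_tissue(self):
        rng = np.random.default_rng(9)
        tissue = np.zeros((32, 32), dtype=bool)
        tissue[4:28, 4:28] = True
        pts = rng.uniform(5, 27, (10, 2))
        ids = rng.integers(1, 3, 10)
        rm = voronoi_expand(pts, ids, tissue, ["a", "b"])
        assert ((rm.labels > 0) == tissue).all()
        rm2 = voronoi_expand(pts, ids, tissue, ["a", "b"])
        assert np.array_equal(rm.labels, rm2.labels)

    def test_no_objects_rejected(self):
        with pytest.raises(ValueError):
            voronoi_expand(np.zeros((0, 2)), np.zeros(0, dtype=int),
                           np.ones((8, 8), dtype=bool))


class TestSynapticCoincidence:
    def synaptic_stack(self, tau_frac=0.3, seed=0, n=64):
        rng = np.random.default_rng(seed)
        syp = np.zeros((n, n))
        psd = np.zeros((n, n))
        vglut = np.zeros((n, n))
        sel = rng.uniform(size=(n, n)) < 0.4
        syp[sel] = psd[sel] = vglut[sel] = 5.0
        tau = np.zeros((n, n))
        rr, cc = np.nonzero(sel)
        k = int(round(tau_frac * len(rr)))
        pick = rng.choice(len(rr), k, replace=False)
        tau[rr[pick], cc[pick]] = 5.0
        return make_stack({"SYP": syp, "PSD95": psd, "VGLUT1": vglut,
                           "VGLUT2": np.zeros((n, n)), "PHF1-TAU": tau,
                           "Abeta42": np.zeros((n, n))}), sel

    def region_map(self, n=64):
        return RegionMap(np.ones((n, n), dtype=np.int32), ["TT"])

    def test_zero_proteopathy_gives_zero_fraction(self):
        stack, _ = self.synaptic_stack(tau_frac=0.0)
        res = synaptic_coincidence(stack, self.region_map(),
                                   {c: 1.0 for c in stack.channel_names})
        tau = res[res["proteopathy"] == "tau"].iloc[0]
        assert tau["fraction"] == 0.0

    def test_full_proteopathy_gives_one(self):
        stack, sel = self.synaptic_stack(tau_frac=0.0)
        stack.pixels[stack.index("PHF1-TAU")] = 5.0  # tau(+) everywhere
        res = synaptic_coincidence(stack, self.region_map(),
                                   {c: 1.0 for c in stack.channel_names})
        tau = res[res["proteopathy"] == "tau"].iloc[0]
        assert tau["fraction"] == 1.0

    def test_painted_fraction_recovered(self):
        stack, _ = self.synaptic_stack(tau_frac=0.3, seed=3)
        res = synaptic_coincidence(stack, self.region_map(),
                                   {c: 1.0 for c in stack.channel_names})
        tau = res[res["proteopathy"] == "tau"].iloc[0]
        assert tau["fraction"] == pytest.approx(0.30, abs=0.02)

    def test_region_without_synapses_flagged(self):
        stack, _ = self.synaptic_stack(tau_frac=0.3)
        labels = np.ones((64, 64), dtype=np.int32)
        labels[:0] = 2  # region 2 empty
        rm = RegionMap(labels, ["TT", "empty"])
        res = synaptic_coincidence(stack, rm,
                                   {c: 1.0 for c in stack.channel_names})
        empty_tau = res[(res["region"] == "empty")
                        & (res["proteopathy"] == "tau")].iloc[0]
        assert np.isnan(empty_tau["fraction"])
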