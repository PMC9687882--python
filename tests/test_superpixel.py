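"""LSC superpixels: kernel, embedding, clustering, connectivity, schematic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import panfat as pf
from panfat.errors import InvalidInputError
from panfat.superpixel import (LSCParams, LSCSuperpixels, _summaries,
                               enforce_connectivity, select_r)
from panfat.types import SuperpixelMap

from oracles import pixel_similarity_oracle

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestSimilarityKernel:
    def test_identical_pixels_reach_maximum(self):
        assert pf.pixel_similarity((0.3, 0.7, 0.5), (0.3, 0.7, 0.5), 1, 1) == pytest.approx(3.0)

    def test_opposite_corners_vanish(self):
        assert pf.pixel_similarity((0, 0, 0), (1, 1, 1), 1, 1) == pytest.approx(0.0)

    def test_unit_spatial_offset(self):
        assert pf.pixel_similarity((0, 0.5, 0.5), (1, 0.5, 0.5), 1, 1) == pytest.approx(2.0)

    @given(x1=unit, y1=unit, g1=unit, x2=unit, y2=unit, g2=unit)
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, x1, y1, g1, x2, y2, g2):
        p, q = (x1, y1, g1), (x2, y2, g2)
        assert pf.pixel_similarity(p, q, 0.5, 1.0) == pytest.approx(
            pf.pixel_similarity(q, p, 0.5, 1.0))

    def test_unnormalized_input_rejected(self):
        with pytest.raises(InvalidInputError):
            pf.pixel_similarity((1.2, 0, 0), (0, 0, 0), 1, 1)


class TestFeatureEmbedding:
    def test_self_inner_product_equals_maximum(self):
        f = pf.feature_embed((0.2, 0.8, 0.4), 1, 1)
        assert f @ f == pytest.approx(3.0)

    def test_origin_embedding(self):
        f = pf.feature_embed((0, 0, 0), 0.7, 1.3)
        assert np.allclose(f, [0.7, 0, 0.7, 0, 1.3, 0])

    def test_inner_product_reproduces_kernel(self, rng):
        for _ in range(200):
            p = tuple(rng.uniform(0, 1, 3))
            q = tuple(rng.uniform(0, 1, 3))
            c_s, c_c = rng.uniform(0.05, 1), 1.0
            lhs = pf.feature_embed(p, c_s, c_c) @ pf.feature_embed(q, c_s, c_c)
            assert abs(lhs - pixel_similarity_oracle(p, q, c_s, c_c)) < 1e-12


class TestLSCSegmentation:
    def test_constant_image_gives_near_equal_quadrants(self):
        img = np.full((64, 64), 7.0)
        spmap = pf.lsc_segment(img, LSCParams(n_superpixels=4, r=0.5))
        assert spmap.K_actual == 4
        assert spmap.sizes.sum() == 64 * 64
        # with constant gray the objective reduces to spatial k-means
        assert np.all(np.abs(spmap.sizes - 1024) <= 102)

    def test_partition_invariant(self, spmap_96):
        spmap_96.validate()

    def test_k_too_large_rejected(self):
        with pytest.raises(InvalidInputError):
            pf.lsc_segment(np.zeros((32, 32)), LSCParams(n_superpixels=500))

    def test_deterministic_for_fixed_params(self, slice_pair_96):
        a = pf.lsc_segment(slice_pair_96.water, LSCParams(n_superpixels=40))
        b = pf.lsc_segment(slice_pair_96.water, LSCParams(n_superpixels=40))
        assert np.array_equal(a.labels, b.labels)

    def test_estimator_interface_roundtrip(self, slice_pair_96):
        est = LSCSuperpixels(n_superpixels=40).fit(slice_pair_96.water)
        params = est.get_params()
        assert params["n_superpixels"] == 40
        assert est.labels_.shape == slice_pair_96.water.shape
        assert est.to_map().K_actual == est.n_superpixels_


def _map_from_labels(labels):
    k, centers, sizes = _summaries(labels)
    return SuperpixelMap(labels=labels, K_actual=k, centers=centers, sizes=sizes)


class TestEnforceConnectivity:
    def test_idempotent_on_connected_map(self):
        labels = np.repeat(np.arange(4).reshape(2, 2), 4, axis=0).repeat(4, axis=1)
        spmap = _map_from_labels(labels.astype(np.int32))
        out = enforce_connectivity(spmap, 0.05)
        # unchanged up to relabeling
        assert out.K_actual == 4
        for lab in range(4):
            vals = np.unique(out.labels[labels == lab])
            assert len(vals) == 1

    def test_orphan_pixel_absorbed(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[4, 4] = 1  # single orphan inside superpixel 0
        out = enforce_connectivity(_map_from_labels(labels), 0.25, n_target=2)
        assert out.K_actual == 1
        assert len(np.unique(out.labels)) == 1

    def test_component_count_equals_k_actual(self, spmap_96):
        from skimage import measure
        comp = measure.label(spmap_96.labels, background=-1, connectivity=1)
        assert comp.max() == spmap_96.K_actual


class TestSchematic:
    def test_constant_image_unchanged(self, spmap_96):
        img = np.full(spmap_96.shape, 3.25)
        out = pf.schematic_map(img, spmap_96)
        assert np.allclose(out.values, 3.25)

    def test_two_pixel_average(self):
        labels = np.zeros((1, 2), dtype=np.int32)
        spmap = SuperpixelMap(labels=labels, K_actual=1,
                              centers=np.array([[0, 0]]), sizes=np.array([2]))
        out = pf.schematic_map(np.array([[10.0, 20.0]]), spmap)
        assert np.allclose(out.values, 15.0)

    def test_mean_conservation_and_idempotence(self, slice_pair_96, spmap_96):
        img = slice_pair_96.water.data
        s1 = pf.schematic_map(img, spmap_96).values
        assert s1.mean() == pytest.approx(img.mean(), rel=1e-12)
        s2 = pf.schematic_map(s1, spmap_96).values
        assert np.allclose(s1, s2, atol=1e-9)

    def test_shape_mismatch_rejected(self, spmap_96):
        with pytest.raises(InvalidInputError):
            pf.schematic_map(np.zeros((8, 8)), spmap_96)


class TestSelectR:
    def test_invalid_range_rejected(self, slice_pair_96):
        with pytest.raises(InvalidInputError):
            select_r(slice_pair_96.water, slice_pair_96.gt_mask, r_range=(0.5, 0.1))

    def test_best_so_far_monotone_and_deterministic(self, slice_pair_96):
        kwargs = dict(n_superpixels=40, d=2, seed=3,
                      sa_schedule=pf.SASchedule(steps=12))
        res = select_r(slice_pair_96.water, slice_pair_96.gt_mask, **kwargs)
        best = [t[4] for t in res.trace]
        assert all(b2 <= b1 for b1, b2 in zip(best, best[1:]))
        res2 = select_r(slice_pair_96.water, slice_pair_96.gt_mask, **kwargs)
        assert res2.r_star == res.r_star
        assert res2.i_star == res.i_star
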