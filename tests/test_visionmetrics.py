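"""Viewer-model metric chain: flooring, acuity blur, RNL distances,
segmentation, cluster/edge/secondary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perchmatch.synthgen import PatchSpec, SceneSpec, generate_scene
from perchmatch.visionmetrics import (
    ConeCatchImage,
    EdgeMetrics,
    ViewerModel,
    apply_acuity_filter,
    cluster_stats,
    floor_catches,
    local_edge_intensity,
    metric_row,
    pattern_from_labels,
    rnl_chromatic_distance,
    rnl_luminance_distance,
    secondary_stats,
    segment_rnl,
)


def uniform_image(value=0.3, shape=(16, 16), mm_per_px=1.0):
    return ConeCatchImage(np.full(shape + (5,), value, dtype=float), mm_per_px)


class TestFloor:
    def test_negative_replaced(self, viewer):
        img = uniform_image()
        img.data[0, 0, 0] = -0.2
        img.data[0, 1, 2] = 0.0
        out = floor_catches(img, 0.001)
        assert out.data[0, 0, 0] == 0.001
        assert out.data[0, 1, 2] == 0.001

    def test_positive_untouched(self):
        img = uniform_image(0.5)
        assert (floor_catches(img).data == 0.5).all()

    def test_all_negative_becomes_constant(self):
        img = ConeCatchImage(np.full((4, 4, 5), -1.0), 1.0)
        assert (floor_catches(img).data == 0.001).all()


class TestAcuityFilter:
    def test_object_plane_fwhm(self, viewer):
        # 1/41 degree seen from 5 m spans ~2.128 mm at the object plane
        assert viewer.object_plane_fwhm_mm() == pytest.approx(2.1285, abs=1e-3)

    def test_uniform_unchanged(self, viewer):
        img = uniform_image(0.4, mm_per_px=0.2)
        out = apply_acuity_filter(img, viewer)
        np.testing.assert_allclose(out.data, img.data, rtol=1e-12)

    def test_impulse_mass_preserved(self, viewer):
        img = ConeCatchImage(np.full((33, 33, 5), 1e-9), mm_per_px=0.1)
        img.data[16, 16, :] = 1.0
        out = apply_acuity_filter(img, viewer)
        np.testing.assert_allclose(
            out.data.sum(axis=(0, 1)), img.data.sum(axis=(0, 1)), rtol=1e-9
        )

    def test_channel_means_preserved(self, viewer, rng):
        img = ConeCatchImage(rng.uniform(0.1, 1.0, (24, 24, 5)), mm_per_px=0.3)
        out = apply_acuity_filter(img, viewer)
        np.testing.assert_allclose(
            out.data.mean(axis=(0, 1)), img.data.mean(axis=(0, 1)), rtol=1e-6
        )

    def test_subpixel_kernel_warns_identity(self, viewer):
        img = uniform_image(0.4, mm_per_px=5.0)
        img.data[3, 3, 0] = 0.9
        with pytest.warns(UserWarning, match="below one pixel"):
            out = apply_acuity_filter(img, viewer)
        np.testing.assert_array_equal(out.data, img.data)

    def test_smoothing_never_increases_edge_intensity(self, viewer):
        img = uniform_image(0.2, shape=(20, 20), mm_per_px=0.5)
        img.data[:, 10:, :] = 0.8  # step edge
        roi = np.ones((20, 20), bool)
        before = local_edge_intensity(img, roi, viewer)
        after = local_edge_intensity(apply_acuity_filter(img, viewer), roi, viewer)
        assert after.color_mean <= before.color_mean + 1e-12
        assert after.lum_mean <= before.lum_mean + 1e-12


class TestRNLDistances:
    def test_identical_zero(self, viewer):
        a = np.array([0.3, 0.4, 0.5, 0.6])
        assert rnl_chromatic_distance(a, a, viewer) == 0.0

    def test_dichromat_closed_form(self, viewer):
        # delta-log contrasts (0.1, 0) with noise (0.05, 0.05):
        # |0.1 - 0| / sqrt(0.05^2 + 0.05^2) = 1.414...
        a = [np.exp(0.1), 1.0]
        b = [1.0, 1.0]
        d = rnl_chromatic_distance(a, b, viewer, noise=[0.05, 0.05])
        assert d == pytest.approx(1.41421356, rel=1e-8)

    def test_common_scaling_invariance(self, viewer):
        a = np.array([0.3, 0.4, 0.5, 0.6])
        b = np.array([0.35, 0.38, 0.52, 0.61])
        d1 = rnl_chromatic_distance(a, b, viewer)
        d2 = rnl_chromatic_distance(10 * a, 10 * b, viewer)
        assert d1 == pytest.approx(d2, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.05, 5.0), min_size=8, max_size=8))
    def test_symmetry_and_nonnegativity(self, vals):
        viewer = ViewerModel()
        a, b = np.array(vals[:4]), np.array(vals[4:])
        d_ab = rnl_chromatic_distance(a, b, viewer)
        d_ba = rnl_chromatic_distance(b, a, viewer)
        assert d_ab >= 0
        assert d_ab == pytest.approx(d_ba, rel=1e-12)

    def test_nonpositive_catch_rejected(self, viewer):
        with pytest.raises(ValueError, match="floor"):
            rnl_chromatic_distance([0.0, 1, 1, 1], [1, 1, 1, 1], viewer)

    def test_luminance_closed_form(self, viewer):
        assert rnl_luminance_distance(1.0, 1.0, viewer) == 0.0
        assert rnl_luminance_distance(np.exp(0.05), 1.0, viewer) == pytest.approx(1.0)
        assert rnl_luminance_distance(1.0, np.exp(0.05), viewer) == pytest.approx(1.0)

    def test_unequal_abundances_raise_noise_of_rare_cones(self):
        v = ViewerModel(relative_abundances=(0.4, 0.3, 0.2, 0.1))
        e = v.channel_noise
        assert e[0] == pytest.approx(0.05)  # most abundant keeps the Weber fraction
        assert np.all(np.diff(e) > 0)


class TestSegmentation:
    def test_uniform_single_cluster(self, viewer):
        img = uniform_image(0.3, shape=(12, 12))
        seg = segment_rnl(img, np.ones((12, 12), bool), viewer)
        assert seg.n_clusters == 1
        assert seg.areas_px[0] == 144

    def test_strong_contrast_recovers_planted_areas(self, viewer):
        spec = SceneSpec(
            shape=(32, 32),
            patches=(PatchSpec((0.8, 0.2, 0.2, 0.2, 0.6), 100),),
        )
        img, roi, truth = generate_scene(spec, seed=1)
        seg = segment_rnl(img, roi, viewer, theta_color=3.0, theta_lum=3.0)
        assert seg.n_clusters == 2
        assert sorted(seg.areas_px) == sorted(truth["areas_px"])

    def test_subthreshold_contrast_merges(self, viewer):
        img = uniform_image(0.3, shape=(10, 10))
        # ~1 JND chromatic and ~1 JND luminance contrast on the right half
        img.data[:, 5:, 0] *= np.exp(0.05 * np.sqrt(2) * 0.5)
        img.data[:, 5:, 4] *= np.exp(0.05)
        seg = segment_rnl(img, np.ones((10, 10), bool), viewer, 3.0, 3.0)
        assert seg.n_clusters == 1

    def test_deterministic(self, viewer):
        spec = SceneSpec(
            shape=(24, 24),
            patches=(PatchSpec((0.8, 0.2, 0.2, 0.2, 0.6), 30, 2),),
        )
        img, roi, _ = generate_scene(spec, seed=6)
        a = segment_rnl(img, roi, viewer)
        b = segment_rnl(img, roi, viewer)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_empty_roi_rejected(self, viewer):
        img = uniform_image()
        with pytest.raises(ValueError, match="empty ROI"):
            segment_rnl(img, np.zeros((16, 16), bool), viewer)


class TestClusterStats:
    def test_two_patch_cluster_plus_one(self, viewer):
        labels = np.zeros((6, 6), int)
        labels[0:2, 0:2] = 1  # patch 1 of cluster 1
        labels[4:6, 4:6] = 1  # patch 2 of cluster 1
        img = uniform_image(0.3, shape=(6, 6))
        img.data[labels == 1] = 0.8
        seg = pattern_from_labels(labels, img)
        cm = cluster_stats(seg)
        assert cm.n_clusters == 2
        assert cm.counts_within == 3
        assert cm.area_largest_mm2 == pytest.approx(36 - 8)

    def test_uniform(self, viewer):
        img = uniform_image(0.3, shape=(5, 7), mm_per_px=2.0)
        seg = segment_rnl(img, np.ones((5, 7), bool), viewer)
        cm = cluster_stats(seg)
        assert (cm.n_clusters, cm.counts_within) == (1, 1)
        assert cm.area_largest_mm2 == pytest.approx(5 * 7 * 4.0)

    def test_checkerboard_counts(self):
        k = 8  # 4x4 board: k cells of each label
        labels = np.indices((4, 4)).sum(axis=0) % 2
        img = uniform_image(0.3, shape=(4, 4))
        seg = pattern_from_labels(labels, img)
        cm = cluster_stats(seg, connectivity=4)
        assert cm.counts_within == 2 * k


class TestEdgeIntensity:
    def test_uniform_zero(self, viewer):
        img = uniform_image(0.25, shape=(8, 8))
        em = local_edge_intensity(img, np.ones((8, 8), bool), viewer)
        assert em == EdgeMetrics(0.0, 0.0)

    def test_vertical_step_matches_hand_count(self, viewer):
        # 4x4 ROI, luminance step of exactly 2 JND between columns 1 and 2
        img = uniform_image(0.3, shape=(4, 4))
        img.data[:, 2:, 4] *= np.exp(2 * viewer.weber_luminance)
        roi = np.ones((4, 4), bool)
        em = local_edge_intensity(img, roi, viewer)
        expected = _edge_oracle(img, roi, viewer)
        assert em.lum_mean == pytest.approx(expected[1], rel=1e-9)
        # hand count: per-pixel max is 2 JND exactly for the 8 pixels
        # adjacent to the step (columns 1 and 2), 0 elsewhere; every one of
        # the 16 pixels has a valid neighbor
        assert em.lum_mean == pytest.approx(2.0 * 8 / 16)

    def test_rotation_symmetry(self, viewer):
        img_v = uniform_image(0.3, shape=(6, 6))
        img_v.data[:, 3:, :] = 0.7
        img_h = ConeCatchImage(np.rot90(img_v.data, axes=(0, 1)).copy(), 1.0)
        roi = np.ones((6, 6), bool)
        em_v = local_edge_intensity(img_v, roi, viewer)
        em_h = local_edge_intensity(img_h, roi, viewer)
        assert em_v.color_mean == pytest.approx(em_h.color_mean, rel=1e-12)
        assert em_v.lum_mean == pytest.approx(em_h.lum_mean, rel=1e-12)

    def test_tiny_roi_rejected(self, viewer):
        img = uniform_image()
        roi = np.zeros((16, 16), bool)
        roi[0, 0] = True
        with pytest.raises(ValueError):
            local_edge_intensity(img, roi, viewer)


def _edge_oracle(img, roi, viewer):
    """Brute-force per-pixel max directional contrast, explicit loops."""
    H, W = img.shape
    offs = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, -1), (1, -1), (-1, 1))
    cs, ls = [], []
    for r in range(H):
        for c in range(W):
            if not roi[r, c]:
                continue
            best_c = best_l = None
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and roi[rr, cc]:
                    dchrom = rnl_chromatic_distance(
                        img.data[r, c, :4], img.data[rr, cc, :4], viewer
                    )
                    dlum = rnl_luminance_distance(
                        img.data[r, c, 4], img.data[rr, cc, 4], viewer
                    )
                    best_c = dchrom if best_c is None else max(best_c, dchrom)
                    best_l = dlum if best_l is None else max(best_l, dlum)
            if best_c is not None:
                cs.append(best_c)
                ls.append(best_l)
    return float(np.mean(cs)), float(np.mean(ls))


class TestSecondaryStats:
    def test_uniform_all_zero(self, viewer):
        img = uniform_image(0.3, shape=(8, 8))
        seg = segment_rnl(img, np.ones((8, 8), bool), viewer)
        ss = secondary_stats(seg, viewer)
        assert len(ss) == 12
        assert ss["caa_area_diversity"] == 0.0
        assert ss["caa_area_evenness"] == 1.0
        assert ss["caa_hv_ratio"] == 1.0
        assert all(
            v == 0.0 for k, v in ss.items()
            if k not in ("caa_area_evenness", "caa_hv_ratio")
        )

    def test_two_equal_area_clusters_diversity_ln2(self, viewer):
        labels = np.zeros((8, 8), int)
        labels[:, 4:] = 1
        img = uniform_image(0.3, shape=(8, 8))
        img.data[labels == 1] = 0.8
        ss = secondary_stats(pattern_from_labels(labels, img), viewer)
        assert ss["caa_area_diversity"] == pytest.approx(np.log(2))
        assert ss["caa_area_evenness"] == pytest.approx(1.0)

    def test_always_length_twelve(self, viewer):
        spec = SceneSpec(
            shape=(24, 24),
            patches=(PatchSpec((0.8, 0.2, 0.2, 0.2, 0.6), 20, 2),
                     PatchSpec((0.2, 0.2, 0.8, 0.2, 0.9), 16, 1)),
        )
        img, roi, _ = generate_scene(spec, seed=2)
        seg = segment_rnl(img, roi, viewer)
        assert len(secondary_stats(seg, viewer)) == 12


def test_metric_chain_deterministic(viewer):
    spec = SceneSpec(shape=(24, 24), mm_per_px=3.0,
                     patches=(PatchSpec((0.8, 0.2, 0.2, 0.2, 0.6), 25, 2),))
    img, roi, _ = generate_scene(spec, seed=8)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-pixel blur at this scale
        a = metric_row(img, roi, viewer)
        b = metric_row(img, roi, viewer)
    assert a == b
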