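import numpy as np
import pytest

from vineweed import CLASS_CODES, ConfigurationError
from vineweed.errors import DegenerateDistributionError
from vineweed.indices import IndexRaster, compute_index
from vineweed.objects import SegmentMap, compute_stats
from vineweed.segmentation import (SegmentationParams, classify_objects,
                                   multiresolution_segment, otsu_threshold)
from vineweed.validation import confusion_matrix
from vineweed.vine import VineMask, detect_vines

from conftest import flat_scene


def naive_otsu(values, bins=256):
    """Independent oracle: exhaustive O(bins^2) search over all bin splits,
    scoring splits on integer bin indices; tied maxima resolve to the
    plateau midpoint."""
    v = np.asarray(values, float)
    hist, edges = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    total = int(hist.sum())
    scored = []
    for k in range(bins - 1):
        w0 = int(hist[:k + 1].sum())
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(int(hist[i]) * i for i in range(k + 1)) / w0
        m1 = sum(int(hist[i]) * i for i in range(k + 1, bins)) / w1
        scored.append((w0 * w1 * (m0 - m1) ** 2, k))
    best = max(bc for bc, _ in scored)
    ties = [k for bc, k in scored if bc == best]
    return edges[ties[len(ties) // 2] + 1]


class TestOtsu:
    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mix = np.concatenate([
                rng.normal(rng.uniform(-1, 0), rng.uniform(0.01, 0.3), 400),
                rng.normal(rng.uniform(0.5, 2), rng.uniform(0.01, 0.3), 600),
            ])
            assert otsu_threshold(mix) == naive_otsu(mix)

    def test_symmetric_two_delta_histogram(self):
        v = np.array([0.0] * 100 + [1.0] * 100)
        assert 0 < otsu_threshold(v) < 1

    def test_bimodal_normal_threshold_between_modes(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0.1, 0.02, 5000), rng.normal(0.6, 0.02, 5000)])
        assert otsu_threshold(v) == pytest.approx(0.35, abs=0.05)

    def test_affine_rescaling_maps_threshold(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        t = otsu_threshold(v)
        assert otsu_threshold(3 * v + 7) == pytest.approx(3 * t + 7, rel=1e-9)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            otsu_threshold(np.full(100, 0.4))


class TestMerging:
    def test_two_homogeneous_halves_give_exactly_two_segments(self):
        scene = flat_scene(16, 16)
        for b in scene.bands:
            arr = np.full((16, 16), 0.1)
            arr[8:, :] = 0.9
            scene.bands[b] = arr
        domain = np.ones((16, 16), bool)
        seg = multiresolution_segment(scene, domain, SegmentationParams(scale=5))
        assert seg.n_objects == 2
        assert len(np.unique(seg.labels[:8])) == 1
        assert len(np.unique(seg.labels[8:])) == 1

    def test_infinite_scale_gives_one_segment_per_component(self):
        rng = np.random.default_rng(3)
        scene = flat_scene(30, 30)
        for b in scene.bands:
            scene.bands[b] = rng.uniform(0, 1, (30, 30))
        domain = np.zeros((30, 30), bool)
        domain[2:10, 2:10] = True
        domain[18:28, 15:28] = True
        seg = multiresolution_segment(scene, domain,
                                      SegmentationParams(scale=1e6, shape=0.0))
        assert seg.n_objects == 2

    def test_constant_image_single_segment_at_any_scale(self):
        scene = flat_scene(12, 12)
        domain = np.ones((12, 12), bool)
        for scale in (0.5, 5, 50):
            seg = multiresolution_segment(
                scene, domain, SegmentationParams(scale=scale, shape=0.0))
            assert seg.n_objects == 1

    def test_partition_property(self, small_scene):
        scene, _, _ = small_scene
        sub = flat_scene(120, 120, pixel_size=0.02)
        for b in sub.bands:
            sub.bands[b] = scene.bands[b][:120, :120]
        domain = np.zeros((120, 120), bool)
        domain[10:110, 5:115] = True
        seg = multiresolution_segment(sub, domain)
        assert ((seg.labels > 0) == domain).all()
        assert sum(s.pixel_count for s in seg.object_stats.values()) == domain.sum()

    def test_empty_domain_errors(self):
        scene = flat_scene(8, 8)
        with pytest.raises(ConfigurationError):
            multiresolution_segment(scene, np.zeros((8, 8), bool))

    def test_block_preaggregation_respects_domain(self):
        rng = np.random.default_rng(4)
        scene = flat_scene(40, 40)
        for b in scene.bands:
            scene.bands[b] = rng.uniform(0, 1, (40, 40))
        domain = np.zeros((40, 40), bool)
        domain[1:39, 3:37] = True
        seg = multiresolution_segment(scene, domain,
                                      SegmentationParams(seed_block=2))
        assert ((seg.labels > 0) == domain).all()


class TestClassification:
    def _weed_soil_setup(self, small_scene):
        scene, labels, _ = small_scene
        vm = detect_vines(scene)
        index = compute_index(scene, "ExGR")
        domain = ~vm.mask & ~scene.nodata_mask
        seg = multiresolution_segment(scene, domain)
        return scene, labels, vm, index, seg

    def test_end_to_end_accuracy_and_area_partition(self, small_scene):
        scene, labels, vm, index, seg = self._weed_soil_setup(small_scene)
        cmap = classify_objects(seg, index, vm, transform=scene.transform)
        cm = confusion_matrix(cmap, labels)
        assert cm.overall_accuracy >= 95.0
        pcts = [v["pct"] for v in cmap.area_summary.values()]
        assert sum(pcts) == pytest.approx(100.0, abs=0.01)
        weed_pct = cmap.area_summary["bermudagrass"]["pixels"] / (
            cmap.area_summary["bermudagrass"]["pixels"]
            + cmap.area_summary["bare_soil"]["pixels"])
        truth = (labels.labels == CLASS_CODES["bermudagrass"]).sum() / (
            (labels.labels != CLASS_CODES["vine"]).sum())
        assert weed_pct == pytest.approx(truth, abs=0.02)

    def test_label_permutation_invariance(self, small_scene):
        scene, labels, vm, index, seg = self._weed_soil_setup(small_scene)
        cmap1 = classify_objects(seg, index, vm, transform=scene.transform)
        rng = np.random.default_rng(9)
        perm = np.concatenate([[0], rng.permutation(seg.n_objects) + 1])
        relabeled = perm[seg.labels].astype(np.int32)
        seg2 = SegmentMap(labels=relabeled, object_stats=compute_stats(relabeled, scene))
        cmap2 = classify_objects(seg2, index, vm, transform=scene.transform)
        assert np.array_equal(cmap1.labels, cmap2.labels)

    def test_identical_objects_degenerate_with_guidance(self):
        scene = flat_scene(10, 10)
        lab = np.ones((10, 10), np.int32)
        lab[:, 5:] = 2
        seg = SegmentMap(labels=lab, object_stats=compute_stats(lab, scene))
        index = IndexRaster(values=np.full((10, 10), 0.5), index_name="ExGR",
                            mask=np.zeros((10, 10), bool))
        vm = VineMask(mask=np.zeros((10, 10), bool),
                      soil_reference=np.zeros((10, 10)))
        with pytest.raises(DegenerateDistributionError, match="identical"):
            classify_objects(seg, index, vm, transform=scene.transform)

    def test_fewer_than_two_objects_errors(self):
        scene = flat_scene(6, 6)
        lab = np.ones((6, 6), np.int32)
        seg = SegmentMap(labels=lab, object_stats=compute_stats(lab, scene))
        index = IndexRaster(values=np.zeros((6, 6)), index_name="ExGR",
                            mask=np.zeros((6, 6), bool))
        vm = VineMask(np.zeros((6, 6), bool), np.zeros((6, 6)))
        with pytest.raises(ConfigurationError):
            classify_objects(seg, index, vm)
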