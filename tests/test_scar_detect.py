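import numpy as np
import pytest

from scarquant import imaging_io as io
from scarquant import scar_detect as sd

from oracles import brute_multiotsu, simulate_region_growth


def _stack(voxels):
    voxels = np.asarray(voxels, dtype=float)
    g = io.ImageGeometry(rows=voxels.shape[1], cols=voxels.shape[2],
                         n_slices=voxels.shape[0])
    return io.ImageStack(voxels, g, io.BL)


def _full_wall(stack):
    return io.MyocardiumMask(np.ones(stack.voxels.shape, bool), stack.geometry)


class TestMultiOtsu:
    def test_four_separated_spikes_land_one_per_class(self):
        v = np.repeat([10, 90, 170, 250], 50)
        t = sd.multiotsu_thresholds(v)
        assert 10 <= t.t1 < 90 and 90 <= t.t2 < 170 and 170 <= t.t3 < 250
        # lexicographic tie-break picks the smallest such triple
        assert t.as_tuple() == (10, 90, 170)

    def test_matches_bruteforce_on_random_histograms(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            counts = np.zeros(256)
            nb = int(rng.integers(4, 12))
            bins = rng.choice(28, nb, replace=False)
            counts[bins] = rng.integers(1, 60, nb)
            vals = np.repeat(np.arange(256), counts.astype(int))
            assert sd.multiotsu_thresholds(vals).as_tuple() == \
                brute_multiotsu(counts, 28), trial

    def test_shift_invariance_of_thresholds(self):
        rng = np.random.default_rng(23)
        v = rng.integers(0, 120, 1500)
        base = sd.multiotsu_thresholds(v).as_tuple()
        shifted = sd.multiotsu_thresholds(v + 5).as_tuple()
        assert shifted == tuple(t + 5 for t in base)

    def test_agrees_with_skimage_on_the_same_histogram(self):
        """Independent cross-check: scikit-image's multi-Otsu fed the
        identical 256-bin histogram returns the same threshold triple."""
        from skimage.filters import threshold_multiotsu
        rng = np.random.default_rng(31)
        v = np.concatenate([rng.normal(m, 4, 400) for m in (20, 90, 160, 235)])
        v = np.clip(np.rint(v), 0, 255).astype(int)
        ours = sd.multiotsu_thresholds(v)
        counts = np.bincount(v, minlength=256)
        theirs = threshold_multiotsu(classes=4, hist=(counts, np.arange(256)))
        assert tuple(theirs) == ours.as_tuple()

    def test_too_few_distinct_values_raise(self):
        with pytest.raises(sd.DegenerateHistogramError):
            sd.multiotsu_thresholds(np.repeat([0, 100, 200], 10))


class TestClassify:
    def test_labels_partition_the_wall(self, small_case):
        bl = small_case.pair.bl
        myo = small_case.myocardium
        thr = sd.multiotsu_thresholds(bl.voxels[myo.data])
        cmap = sd.classify_tissue(bl, myo, thr)
        inside = cmap.labels[myo.data]
        assert (cmap.labels[~myo.data] == sd.LABEL_OUTSIDE).all()
        n = (inside == sd.LABEL_HEALTHY).sum() + (inside == sd.LABEL_GRAY_ZONE).sum() \
            + (inside == sd.LABEL_SCAR).sum()
        assert n == myo.pixel_count()

    def test_constant_dark_wall_is_all_healthy(self):
        s = _stack(np.zeros((1, 8, 8)))
        cmap = sd.classify_tissue(s, _full_wall(s), sd.ThresholdTriple(50, 100, 150))
        assert (cmap.labels == sd.LABEL_HEALTHY).all()

    def test_noise_free_phantom_scar_class_equals_truth(self, rim_case):
        bl = rim_case.pair.bl
        myo = rim_case.myocardium
        thr = sd.multiotsu_thresholds(bl.voxels[myo.data])
        cmap = sd.classify_tissue(bl, myo, thr)
        assert np.array_equal(cmap.labels == sd.LABEL_SCAR, rim_case.truth_scar.data)
        # the rim is the gray zone
        rim = myo.data & (bl.voxels == 128)
        assert (cmap.labels[rim] == sd.LABEL_GRAY_ZONE).all()


class TestDefaultSeed:
    def _case(self, img):
        s = _stack(img[None])
        myo = _full_wall(s)
        thr = sd.ThresholdTriple(50, 100, 150)
        return s, myo, thr

    def test_rectangular_blob_seed_is_its_centroid(self):
        img = np.zeros((9, 9))
        img[2:5, 3:8] = 200  # 3x5 blob, centroid (3, 5)
        s, myo, thr = self._case(img)
        assert sd.default_seed(s, myo, thr) == {0: (3, 5)}

    def test_no_scar_class_means_no_seed(self):
        s, myo, thr = self._case(np.zeros((5, 5)))
        assert sd.default_seed(s, myo, thr) == {}

    def test_c_shape_snaps_to_nearest_member_pixel(self):
        img = np.zeros((15, 15))
        img[3:12, 3:5] = 200   # left bar
        img[3:5, 5:12] = 200   # top bar
        img[10:12, 5:12] = 200  # bottom bar
        s, myo, thr = self._case(img)
        (seed,) = sd.default_seed(s, myo, thr).values()
        blob = np.argwhere(img == 200)
        cr, cc = blob.mean(axis=0)
        d2 = (blob[:, 0] - cr) ** 2 + (blob[:, 1] - cc) ** 2
        expected = tuple(blob[int(np.argmin(d2))])  # argwhere is row-major
        assert seed == expected
        assert img[seed] == 200


class TestRegionGrow:
    def test_hand_traced_three_by_three_example(self):
        img = np.array([[10, 200, 210], [12, 205, 60], [11, 15, 14]], dtype=float)
        s = _stack(img[None])
        mask = sd.region_grow(s, _full_wall(s),
                              sd.RegionGrowParams(seeds={0: (0, 2)}, max_deviation=30))
        grown = set(map(tuple, np.argwhere(mask.data[0])))
        assert grown == {(0, 1), (0, 2), (1, 1)}
        assert img[mask.data[0]].mean() == pytest.approx(205.0)

    def test_constant_wall_floods_the_connected_component(self):
        img = np.full((7, 7), 42.0)
        wall = np.zeros((7, 7), bool)
        wall[1:6, 1:3] = True
        wall[5, 5] = True  # disconnected island must stay out
        s = _stack(img[None])
        myo = io.MyocardiumMask(wall[None], s.geometry)
        mask = sd.region_grow(s, myo, sd.RegionGrowParams(seeds={0: (1, 1)}, max_deviation=0))
        assert mask.data[0, 1:6, 1:3].all()
        assert not mask.data[0, 5, 5]

    def test_zero_deviation_on_distinct_values_keeps_only_the_seed(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        s = _stack(img[None])
        mask = sd.region_grow(s, _full_wall(s),
                              sd.RegionGrowParams(seeds={0: (2, 2)}, max_deviation=0))
        assert mask.pixel_count() == 1 and mask.data[0, 2, 2]

    def test_matches_literal_stepwise_simulation_on_random_grids(self):
        rng = np.random.default_rng(29)
        for trial in range(25):
            img = rng.integers(0, 40, (7, 7)).astype(float)
            wall = rng.random((7, 7)) < 0.85
            wall[3, 3] = True
            s = _stack(img[None])
            myo = io.MyocardiumMask(wall[None], s.geometry)
            dev = float(rng.integers(0, 15))
            mask = sd.region_grow(s, myo, sd.RegionGrowParams(seeds={0: (3, 3)},
                                                              max_deviation=dev))
            got = set(map(tuple, np.argwhere(mask.data[0])))
            assert got == simulate_region_growth(img, wall, (3, 3), dev), trial

    def test_region_is_monotone_in_max_deviation(self):
        rng = np.random.default_rng(37)
        img = rng.integers(0, 60, (9, 9)).astype(float)
        s = _stack(img[None])
        myo = _full_wall(s)
        prev = None
        for dev in (0, 5, 10, 20, 40, 200):
            mask = sd.region_grow(s, myo, sd.RegionGrowParams(seeds={0: (4, 4)},
                                                              max_deviation=dev))
            cur = set(map(tuple, np.argwhere(mask.data[0])))
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_seed_outside_wall_raises(self):
        s = _stack(np.zeros((1, 5, 5)))
        wall = np.zeros((1, 5, 5), bool)
        wall[0, 0, 0] = True
        with pytest.raises(sd.SeedError):
            sd.region_grow(s, io.MyocardiumMask(wall, s.geometry),
                           sd.RegionGrowParams(seeds={0: (2, 2)}, max_deviation=5))


class TestDetectDispatch:
    def test_otsu_recovers_truth_exactly_on_noise_free_phantom(self, small_case):
        scar, cmap = sd.detect_scar(small_case.pair, small_case.myocardium, "otsu")
        assert sd.dice(scar.data, small_case.truth_scar.data) == 1.0
        assert cmap is not None

    def test_region_growing_recovers_transmural_truth(self, small_case):
        scar, _ = sd.detect_scar(small_case.pair, small_case.myocardium, "region_growing")
        assert sd.dice(scar.data, small_case.truth_scar.data) == 1.0

    def test_external_mask_passes_through_verbatim(self, small_case, tmp_path):
        io.write_mask(small_case.truth_scar, tmp_path / "m.nii.gz")
        scar, cmap = sd.detect_scar(small_case.pair, small_case.myocardium,
                                    "external", external_mask=tmp_path / "m.nii.gz")
        assert cmap is None
        assert np.array_equal(scar.data, small_case.truth_scar.data)

    def test_external_mask_outside_wall_is_a_containment_error(self, small_case):
        bad = np.ones_like(small_case.truth_scar.data)
        with pytest.raises(sd.ContainmentError):
            sd.detect_scar(small_case.pair, small_case.myocardium, "external",
                           external_mask=sd.ScarMask(bad, small_case.pair.bl.geometry))

    def test_unknown_method_raises(self, small_case):
        with pytest.raises(ValueError, match="unknown detection method"):
            sd.detect_scar(small_case.pair, small_case.myocardium, "fwhm")
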