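import numpy as np
import pytest

from colonquant import (
    Modality,
    MRIVolume,
    classify_content,
    compute_morphology,
    quantify_content,
)
from colonquant.content import DegenerateInputError, MorphologyError
from colonquant.core_io import LabelVolume
from colonquant.phantom import generate_phantom, straight_cylinder_spec
from oracles import exact_kmeans_1d_sse


def _vol_and_seg(values, shape=(10, 10, 10), spacing=(1, 1, 1)):
    """Put `values` into the first voxels of a volume; mask exactly those."""
    data = np.zeros(shape)
    labels = np.zeros(shape, np.int16)
    flat = data.reshape(-1)
    flat[: len(values)] = values
    labels.reshape(-1)[: len(values)] = 1
    vol = MRIVolume(data, spacing, (0, 0, 0), Modality.T1FS)
    seg = LabelVolume(labels, spacing, (0, 0, 0), Modality.T1FS)
    return vol, seg


class TestClassifyContent:
    def test_two_well_separated_groups(self):
        vals = np.array([5.0] * 10 + [200.0] * 10)
        vol, seg = _vol_and_seg(vals)
        cmap = classify_content(vol, seg, k=2, seed=0)
        assert cmap.names == ["gas", "solid"]
        assert cmap.centroids[0] == pytest.approx(5.0)
        assert cmap.centroids[-1] == pytest.approx(200.0)
        in_mask = cmap.classes.reshape(-1)[:20]
        assert np.all(in_mask[:10] == 0) and np.all(in_mask[10:] == 1)

    def test_sse_matches_exact_1d_optimum(self, rng):
        for _ in range(30):
            n = int(rng.integers(20, 200))
            k = int(rng.choice([2, 3]))
            centers = rng.uniform(0, 300, size=3)
            vals = np.concatenate(
                [rng.normal(c, rng.uniform(2, 15), size=n // 3 + 1) for c in centers]
            )
            vals = np.abs(vals)
            vol, seg = _vol_and_seg(vals, shape=(12, 12, 12))
            cmap = classify_content(vol, seg, k=k, seed=1)
            in_vals = vals
            sse = 0.0
            for rank in range(k):
                sel = cmap.classes.reshape(-1)[: len(vals)] == rank
                if np.any(sel):
                    sse += float(np.sum((in_vals[sel] - in_vals[sel].mean()) ** 2))
            assert sse == pytest.approx(exact_kmeans_1d_sse(vals, k), rel=1e-6, abs=1e-6)

    def test_constant_intensity_rejected(self):
        vol, seg = _vol_and_seg(np.full(30, 7.0))
        with pytest.raises(DegenerateInputError):
            classify_content(vol, seg, k=3)

    def test_extremes_are_gas_and_solid(self, small_truth):
        cmap = classify_content(small_truth.t1fs, small_truth.mask_t1fs, k=3, seed=0)
        assert cmap.names[0] == "gas" and cmap.names[-1] == "solid"
        assert np.all(np.diff(cmap.centroids) > 0)
        assert cmap.solid_fraction.min() >= 0.0 and cmap.solid_fraction.max() <= 1.0

    def test_deterministic_given_seed(self, small_truth):
        a = classify_content(small_truth.t1fs, small_truth.mask_t1fs, k=3, seed=5)
        b = classify_content(small_truth.t1fs, small_truth.mask_t1fs, k=3, seed=5)
        np.testing.assert_array_equal(a.classes, b.classes)


class TestQuantifyContent:
    def test_unit_arithmetic(self):
        vals = np.concatenate([np.full(1000, 200.0), np.full(10, 5.0)])
        vol, seg = _vol_and_seg(vals, shape=(11, 11, 11), spacing=(1, 1, 1))
        cmap = classify_content(vol, seg, k=2, seed=0)
        rep = quantify_content(cmap, seg)
        assert rep.totals_ml["solid"] == pytest.approx(1.0)
        assert rep.totals_ml["gas"] == pytest.approx(0.01)

    def test_conservation(self, small_truth):
        cmap = classify_content(small_truth.t1fs, small_truth.mask_t1fs, k=3, seed=0)
        rep = quantify_content(cmap, small_truth.mask_t1fs)
        parts = sum(v for k_, v in rep.totals_ml.items() if k_ != "total")
        assert parts == pytest.approx(rep.totals_ml["total"], abs=1e-6)
        vox_ml = small_truth.mask_t1fs.mask().sum() * np.prod(small_truth.t1fs.spacing) / 1000.0
        assert rep.totals_ml["total"] == pytest.approx(vox_ml, abs=1e-6)

    def test_grid_mismatch_rejected(self, small_truth):
        cmap = classify_content(small_truth.t1fs, small_truth.mask_t1fs, k=2, seed=0)
        other = LabelVolume(
            np.zeros((10, 10, 10), np.int16), (1, 1, 1), (0, 0, 0), Modality.T1FS
        )
        with pytest.raises(ValueError, match="mismatch"):
            quantify_content(cmap, other)


class TestMorphology:
    @pytest.fixture(scope="class")
    def cyl(self):
        return generate_phantom(straight_cylinder_spec(length=200.0, radius=10.0, spacing=1.0))

    def test_cylinder_recovery(self, cyl):
        morph = compute_morphology(cyl.mask_t2, cyl.path_truth)
        total_len = sum(m["length_mm"] for m in morph.values())
        assert total_len == pytest.approx(200.0, rel=0.02)
        radii = [m["mean_radius_mm"] for m in morph.values()]
        perims = [m["mean_perimeter_mm"] for m in morph.values()]
        assert np.nanmean(radii) == pytest.approx(10.0, rel=0.05)
        assert np.nanmean(perims) == pytest.approx(2 * np.pi * 10.0, rel=0.05)

    def test_radius_scales_linearly(self, cyl):
        big = generate_phantom(straight_cylinder_spec(length=120.0, radius=20.0, spacing=1.0))
        morph_small = compute_morphology(cyl.mask_t2, cyl.path_truth)
        morph_big = compute_morphology(big.mask_t2, big.path_truth)
        r_small = np.nanmean([m["mean_radius_mm"] for m in morph_small.values()])
        r_big = np.nanmean([m["mean_radius_mm"] for m in morph_big.values()])
        assert r_big / r_small == pytest.approx(2.0, rel=0.05)

    def test_error_shrinks_with_spacing(self):
        fine = generate_phantom(straight_cylinder_spec(length=100.0, radius=10.0, spacing=1.0))
        coarse = generate_phantom(straight_cylinder_spec(length=100.0, radius=10.0, spacing=2.0))
        def radius_err(truth):
            morph = compute_morphology(truth.mask_t2, truth.path_truth)
            return abs(np.nanmean([m["mean_radius_mm"] for m in morph.values()]) - 10.0)
        assert radius_err(fine) <= radius_err(coarse) + 1e-9

    def test_single_point_path_rejected(self, cyl):
        from colonquant.paths import MedialPath

        path = MedialPath(points=np.array([[10.0, 10.0, 10.0]]), boundary_indices=np.array([], int))
        with pytest.raises(MorphologyError):
            compute_morphology(cyl.mask_t2, path)

    def test_mask_path_mismatch_rejected(self, cyl):
        empty = LabelVolume(
            np.zeros(cyl.mask_t2.shape, np.int16),
            cyl.mask_t2.spacing, cyl.mask_t2.origin, Modality.T2,
        )
        with pytest.raises(MorphologyError, match="station"):
            compute_morphology(empty, cyl.path_truth)
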