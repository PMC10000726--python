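import numpy as np
import pytest

from colonquant import (
    AdaptationConfig,
    Modality,
    MRIVolume,
    RegistrationConfig,
    adapt_colon_to_t1fs,
    build_content_probability,
    dice,
    register_t2_to_t1fs,
    segment_t2,
    transfer_labels,
)
from colonquant.phantom import GaussianBump, generate_phantom
from colonquant.syncnav import DeformationField
from colonquant.t1seg import AdaptationError, ModelError, RegistrationError
from conftest import small_spec


@pytest.fixture(scope="module")
def seg_and_truth():
    truth = generate_phantom(small_spec(seed=0))
    seg = segment_t2(truth.t2, truth.markers)
    return truth, seg


class TestRegistration:
    def test_identity_recovery(self):
        # same geometry, no deformation, only modality re-rendering
        truth = generate_phantom(small_spec(seed=4, n_bumps=0, bump_amplitude=0.0))
        field = register_t2_to_t1fs(truth.t2, truth.t1fs)
        mags = np.linalg.norm(field.displacement.reshape(-1, 3), axis=1)
        assert mags.mean() < float(np.max(truth.t2.spacing))  # < 1 voxel

    def test_translation_recovery(self):
        spec = small_spec(
            seed=5,
            bumps=[GaussianBump(center=(63, 63, 70), amplitude=(5.0, 0.0, 0.0), scale=500.0)],
        )
        # a very wide bump is a near-constant 5 mm translation over the volume
        truth = generate_phantom(spec)
        field = register_t2_to_t1fs(truth.t2, truth.t1fs)
        m = truth.mask_t2.mask()
        world = np.argwhere(m) * truth.t2.spacing + truth.t2.origin
        err = np.linalg.norm(field(world[::9]) - truth.field_truth(world[::9]), axis=1)
        assert err.mean() < 1.5

    def test_self_registration_near_identity(self, small_truth):
        field = register_t2_to_t1fs(small_truth.t2, small_truth.t2)
        mags = np.linalg.norm(field.displacement.reshape(-1, 3), axis=1)
        assert mags.mean() < 0.5 * float(np.max(small_truth.t2.spacing))

    def test_constant_image_rejected(self, small_truth):
        flat = MRIVolume(
            np.full(small_truth.t2.shape, 7.0), small_truth.t2.spacing,
            small_truth.t2.origin, Modality.T1FS,
        )
        with pytest.raises(RegistrationError, match="constant"):
            register_t2_to_t1fs(small_truth.t2, flat)


class TestContentProbability:
    def test_bimodal_separation(self, small_truth):
        mask = small_truth.mask_t1fs.mask()
        cp = build_content_probability(small_truth.t1fs, mask)
        grid = cp.model["intensity_grid"]
        post = cp.model["posterior_grid"]
        assert np.interp(20.0, grid, post) < 0.1
        assert np.interp(210.0, grid, post) > 0.9

    def test_monotone_in_intensity(self, small_truth):
        cp = build_content_probability(small_truth.t1fs, small_truth.mask_t1fs.mask())
        assert np.all(np.diff(cp.model["posterior_grid"]) >= -1e-12)

    def test_too_small_mask_rejected(self, small_truth):
        mask = np.zeros(small_truth.t1fs.shape, bool)
        mask[10, 10, 10] = True
        with pytest.raises(ModelError, match="voxels"):
            build_content_probability(small_truth.t1fs, mask)

    def test_collapsed_mixture_rejected(self, small_truth):
        rng = np.random.default_rng(0)
        shape = small_truth.t1fs.shape
        # wide dynamic range overall, but near-constant inside the mask:
        # the two mixture components then land within 1% of the range
        data = np.linspace(0, 300, shape[0])[:, None, None] * np.ones(shape)
        data[4:20, 4:20, 4:20] = 150.0 + rng.normal(0, 0.05, (16, 16, 16))
        vol = MRIVolume(
            np.abs(data), small_truth.t1fs.spacing, small_truth.t1fs.origin, Modality.T1FS,
        )
        mask = np.zeros(vol.shape, bool)
        mask[4:20, 4:20, 4:20] = True
        with pytest.raises(ModelError, match="collapse"):
            build_content_probability(vol, mask)


class TestTransferAndAdaptation:
    def test_zero_iterations_equals_transfer(self, seg_and_truth):
        truth, seg = seg_and_truth
        transferred = transfer_labels(seg, truth.field_truth, truth.t1fs)
        adapted = adapt_colon_to_t1fs(
            seg, truth.field_truth, truth.t1fs, AdaptationConfig(n_max=0)
        )
        np.testing.assert_array_equal(adapted.labels, transferred.labels)

    def test_empty_segmentation_rejected(self, seg_and_truth):
        truth, seg = seg_and_truth
        from colonquant.core_io import LabelVolume

        empty = LabelVolume(
            np.zeros(seg.shape, np.int16), seg.spacing, seg.origin, seg.space
        )
        with pytest.raises(AdaptationError, match="empty"):
            adapt_colon_to_t1fs(empty, truth.field_truth, truth.t1fs)

    def test_truth_field_dsc(self, seg_and_truth):
        truth, seg = seg_and_truth
        adapted = adapt_colon_to_t1fs(seg, truth.field_truth, truth.t1fs)
        assert dice(adapted, truth.mask_t1fs) >= 0.90

    def test_labels_preserved_by_transfer(self, seg_and_truth):
        truth, seg = seg_and_truth
        transferred = transfer_labels(seg, truth.field_truth, truth.t1fs)
        assert set(np.unique(transferred.labels)) <= set(np.unique(seg.labels))

    def test_adaptation_stays_within_corridor(self, seg_and_truth):
        from scipy import ndimage

        truth, seg = seg_and_truth
        cfg = AdaptationConfig(corridor_mm=6.0)
        transferred = transfer_labels(seg, truth.field_truth, truth.t1fs)
        adapted = adapt_colon_to_t1fs(seg, truth.field_truth, truth.t1fs, cfg)
        tm, am = transferred.mask(), adapted.mask()
        # no adapted voxel farther than corridor + one voxel diagonal from
        # the transferred mask (Hausdorff bound, one direction suffices for
        # expansion-only adaptation)
        dt = ndimage.distance_transform_edt(~tm, sampling=truth.t1fs.spacing)
        diag = float(np.linalg.norm(truth.t1fs.spacing))
        assert dt[am].max() <= cfg.corridor_mm + diag

    def test_uniform_probability_is_identity(self, seg_and_truth, monkeypatch):
        truth, seg = seg_and_truth
        import colonquant.t1seg as t1seg_mod

        def fake_build(t1fs, mask, min_voxels=50):
            return t1seg_mod.ContentProbability(prob=np.full(t1fs.shape, 0.5), model={})

        monkeypatch.setattr(t1seg_mod, "build_content_probability", fake_build)
        transferred = transfer_labels(seg, truth.field_truth, truth.t1fs)
        adapted = t1seg_mod.adapt_colon_to_t1fs(seg, truth.field_truth, truth.t1fs)
        # within one voxel: expansion force is zero at p = 0.5 everywhere
        sym_diff = transferred.mask() ^ adapted.mask()
        assert not np.any(sym_diff)

    def test_wider_corridor_changes_volume_monotonically(self, seg_and_truth):
        truth, seg = seg_and_truth
        base = transfer_labels(seg, truth.field_truth, truth.t1fs).mask().sum()
        changes = []
        for c in (2.0, 4.0, 6.0):
            adapted = adapt_colon_to_t1fs(
                seg, truth.field_truth, truth.t1fs, AdaptationConfig(corridor_mm=c)
            )
            changes.append(abs(int(adapted.mask().sum()) - int(base)))
        assert changes[0] <= changes[1] <= changes[2]
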