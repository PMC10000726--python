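import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonquant import (
    ContentReport,
    Marker,
    MarkerSet,
    Modality,
    MRIVolume,
    read_markers,
    read_volume,
    write_markers,
    write_volume,
)
from colonquant.core_io import FormatError, ValidationError


def _vol(shape=(16, 16, 8), spacing=(2, 2, 3), origin=(0, 0, 0), seed=0):
    rng = np.random.default_rng(seed)
    return MRIVolume(rng.uniform(0, 100, shape), spacing, origin, Modality.T2)


class TestVolumeIO:
    def test_round_trip_preserves_data_and_geometry(self, tmp_path):
        vol = _vol(origin=(5.0, -3.0, 10.0))
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, vol.data)
        np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)
        np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)

    def test_4d_file_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((8, 8, 8, 3)), np.eye(4))
        nib.save(img, str(tmp_path / "bad.nii.gz"))
        with pytest.raises(FormatError, match="3D"):
            read_volume(tmp_path / "bad.nii.gz")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_non_axis_aligned_rejected(self, tmp_path):
        import nibabel as nib

        aff = np.eye(4)
        aff[0, 1] = 0.5  # shear
        nib.save(nib.Nifti1Image(np.zeros((8, 8, 8)), aff), str(tmp_path / "rot.nii.gz"))
        with pytest.raises(FormatError, match="axis-aligned"):
            read_volume(tmp_path / "rot.nii.gz")

    def test_voxel_origin_convention(self, tmp_path):
        vol = _vol(origin=(1.0, 2.0, 3.0))
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.voxel_to_world([0, 0, 0]), [1.0, 2.0, 3.0])

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(shape=(4, 16, 16)), ">= 8 voxels"),
            (dict(spacing=(0, 2, 3)), "positive"),
        ],
    )
    def test_invariants(self, kwargs, match):
        with pytest.raises(ValidationError, match=match):
            _vol(**kwargs)


class TestWorldVoxel:
    def test_origin_maps_to_zero(self):
        vol = _vol(origin=(7, 8, 9))
        np.testing.assert_allclose(vol.world_to_voxel([7, 8, 9]), [0, 0, 0])

    def test_arithmetic(self):
        vol = _vol(spacing=(2, 2, 3), origin=(0, 0, 0))
        np.testing.assert_allclose(vol.world_to_voxel([2, 4, 3]), [1, 2, 1])

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.floats(0, 30), y=st.floats(0, 30), z=st.floats(0, 21),
    )
    def test_inverse_pair(self, x, y, z):
        vol = _vol(spacing=(2, 2, 3), origin=(-5, 0, 5))
        p = np.array([x - 5, y, z + 5])
        np.testing.assert_allclose(vol.voxel_to_world(vol.world_to_voxel(p)), p, atol=1e-9)


def _marker_json(tmp_path, anatomical, refinement=()):
    path = tmp_path / "markers.json"
    path.write_text(
        json.dumps(
            {
                "anatomical": [{"tag": t, "point_mm": list(p)} for t, p in anatomical],
                "refinement": [
                    {"polarity": pol, "point_mm": list(p)} for pol, p in refinement
                ],
            }
        )
    )
    return path


FIVE = [
    ("cecum_start", (2, 2, 2)),
    ("asc_trans", (2, 2, 18)),
    ("trans_desc", (20, 2, 18)),
    ("desc_pelvic", (20, 2, 2)),
    ("pelvic_end", (10, 2, 2)),
]


class TestMarkers:
    def test_five_points_give_four_segments(self, tmp_path):
        ms = read_markers(_marker_json(tmp_path, FIVE))
        assert len(ms.anatomical) == 5
        assert ms.boundary_points().shape == (5, 3)

    def test_four_points_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            read_markers(_marker_json(tmp_path, FIVE[:4]))

    def test_intermediate_points_allowed(self, tmp_path):
        seven = [
            FIVE[0],
            ("intermediate", (2, 2, 10)),
            FIVE[1],
            FIVE[2],
            ("intermediate", (20, 2, 10)),
            FIVE[3],
            FIVE[4],
        ]
        ms = read_markers(_marker_json(tmp_path, seven))
        assert len(ms.anatomical) == 7

    def test_out_of_order_boundary_tags_rejected(self, tmp_path):
        bad = [FIVE[1], FIVE[0]] + FIVE[2:]
        with pytest.raises(ValidationError, match="order"):
            read_markers(_marker_json(tmp_path, bad))

    def test_point_outside_volume_rejected(self, tmp_path):
        vol = _vol(shape=(16, 16, 8), spacing=(2, 2, 3))
        far = FIVE[:4] + [("pelvic_end", (500, 2, 2))]
        with pytest.raises(ValidationError, match="outside"):
            read_markers(_marker_json(tmp_path, far), volume=vol)

    def test_refinement_round_trip(self, tmp_path):
        ms = MarkerSet(
            anatomical=[Marker(t, p) for t, p in FIVE],
            refinement=[((1.0, 2.0, 3.0), "include"), ((4.0, 5.0, 6.0), "exclude")],
        )
        path = tmp_path / "m.json"
        write_markers(ms, path)
        back = read_markers(path)
        assert [pol for _, pol in back.refinement] == ["include", "exclude"]
        np.testing.assert_allclose(back.refinement[0][0], [1, 2, 3])


class TestContentReport:
    def test_json_round_trip(self, tmp_path):
        rep = ContentReport(
            volumes_ml={"ascending": {"gas": 1.0, "mixed": 0.5, "solid": 2.0}},
            totals_ml={"gas": 1.0, "mixed": 0.5, "solid": 2.0, "total": 3.5},
            solid_equivalent_ml=2.25,
            morphology={"ascending": {"length_mm": 100.0, "mean_perimeter_mm": 60.0, "mean_radius_mm": 9.5}},
            evaluation={"dsc": 0.9, "r_containment": 95.0},
        )
        p = tmp_path / "rep.json"
        rep.to_json(p)
        back = ContentReport.from_json(p)
        assert back.totals_ml["total"] == pytest.approx(3.5)
        assert back.evaluation["dsc"] == pytest.approx(0.9)

    def test_total_mismatch_rejected(self, tmp_path):
        rep = ContentReport(totals_ml={"gas": 1.0, "solid": 1.0, "total": 3.0})
        with pytest.raises(ValidationError, match="sum"):
            rep.to_json(tmp_path / "bad.json")

    def test_csv_export(self, tmp_path):
        rep = ContentReport(
            volumes_ml={"ascending": {"gas": 1.0, "solid": 2.0}},
            totals_ml={"gas": 1.0, "solid": 2.0, "total": 3.0},
        )
        p = tmp_path / "rep.csv"
        rep.to_csv(p)
        lines = p.read_text().strip().splitlines()
        assert lines[0].startswith("segment,gas_ml,solid_ml")
        assert lines[1].startswith("ascending,1.0")
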