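import numpy as np
import nibabel as nib
import pandas as pd
import pytest

from atlassel.volio import (
    Atlas,
    AtlasLibrary,
    GridError,
    IntensityVolume,
    LabelVolume,
    VolumeGrid,
    load_library,
    read_volume,
    write_volume,
)


class TestVolumeGrid:
    def test_invariants(self):
        with pytest.raises(ValueError):
            VolumeGrid((0, 3, 3))
        with pytest.raises(ValueError):
            VolumeGrid((3, 3, 3), (1.0, 0.0, 1.0))

    def test_compatibility_is_exact(self):
        g = VolumeGrid((3, 3, 3), (1, 1, 2))
        assert g.compatible_with(VolumeGrid((3, 3, 3), (1, 1, 2)))
        assert not g.compatible_with(VolumeGrid((3, 3, 3), (1, 1, 1)))
        assert not g.compatible_with(VolumeGrid((3, 3, 4), (1, 1, 2)))
        with pytest.raises(GridError):
            g.require_compatible(VolumeGrid((4, 4, 4)))

    def test_voxel_volume(self):
        assert VolumeGrid((2, 2, 2), (1, 1, 2)).voxel_volume_mm3 == 2.0


class TestRoundTrip:
    @pytest.mark.parametrize("as_labels", [False, True])
    def test_write_then_read_identity(self, tmp_path, as_labels):
        rng = np.random.default_rng(0)
        grid = VolumeGrid((5, 6, 7), (1.0, 1.0, 2.0), (1.0, -2.0, 3.0))
        if as_labels:
            vol = LabelVolume(grid, rng.integers(0, 4, grid.shape).astype(np.int32),
                              {1: "a", 2: "b", 3: "c"})
        else:
            vol = IntensityVolume(grid, rng.normal(size=grid.shape))
        p = write_volume(vol, tmp_path / "v.nii.gz")
        back = read_volume(p, as_labels=as_labels)
        assert back.grid.compatible_with(grid)
        if as_labels:
            np.testing.assert_array_equal(back.labels, vol.labels)
        else:
            np.testing.assert_allclose(back.values, vol.values, atol=1e-6)

    def test_header_spacing_passthrough(self, tmp_path):
        grid = VolumeGrid((3, 3, 3), (1.0, 1.0, 2.0))
        p = write_volume(IntensityVolume(grid, np.zeros((3, 3, 3))), tmp_path / "v.nii")
        img = nib.load(str(p))
        assert tuple(float(z) for z in img.header.get_zooms()[:3]) == (1.0, 1.0, 2.0)

    def test_label_id_set_preserved(self, tmp_path):
        arr = np.zeros((3, 3, 3), dtype=np.int32)
        arr[1, 1, 1] = 4
        p = write_volume(LabelVolume(VolumeGrid((3, 3, 3)), arr, {4: "v"}),
                         tmp_path / "l.nii.gz")
        assert read_volume(p, as_labels=True).present_ids() == [0, 4]


class TestReadErrors:
    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_nan_intensity_rejected(self, tmp_path):
        data = np.zeros((3, 3, 3))
        data[0, 0, 0] = np.nan
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "nan.nii"))
        with pytest.raises(ValueError, match="non-finite"):
            read_volume(tmp_path / "nan.nii", as_labels=False)

    def test_non_integer_label_rejected(self, tmp_path):
        data = np.zeros((3, 3, 3))
        data[0, 0, 0] = 2.4
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "f.nii"))
        with pytest.raises(ValueError, match="non-integer label"):
            read_volume(tmp_path / "f.nii", as_labels=True)

    def test_near_integer_labels_rounded(self, tmp_path):
        data = np.full((3, 3, 3), 2.0) + 5e-7
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "r.nii"))
        vol = read_volume(tmp_path / "r.nii", as_labels=True)
        assert vol.present_ids() == [2]


class TestLabelVolume:
    def test_table_must_cover_present_ids(self):
        arr = np.zeros((2, 2, 2), dtype=np.int32)
        arr[0, 0, 0] = 3
        with pytest.raises(ValueError, match="missing from table"):
            LabelVolume(VolumeGrid((2, 2, 2)), arr, {})

    def test_negative_ids_rejected(self):
        arr = np.full((2, 2, 2), -1, dtype=np.int32)
        with pytest.raises(ValueError, match="negative"):
            LabelVolume(VolumeGrid((2, 2, 2)), arr, {})


def _write_member(root, atlas_id, grid):
    shape = grid.shape
    write_volume(IntensityVolume(grid, np.ones(shape)), root / f"{atlas_id}_i.nii.gz")
    c = np.zeros(shape, dtype=np.int32); c[0, 0, 0] = 2
    write_volume(LabelVolume(grid, c, {2: "gm"}), root / f"{atlas_id}_c.nii.gz")
    f = np.zeros(shape, dtype=np.int32); f[0, 0, 0] = 10
    write_volume(LabelVolume(grid, f, {10: "s"}), root / f"{atlas_id}_f.nii.gz")
    return {
        "id": atlas_id,
        "intensity_path": f"{atlas_id}_i.nii.gz",
        "coarse_path": f"{atlas_id}_c.nii.gz",
        "fine_path": f"{atlas_id}_f.nii.gz",
    }


class TestLoadLibrary:
    def test_row_order_preserved(self, tmp_path):
        grid = VolumeGrid((3, 3, 3))
        rows = [_write_member(tmp_path, a, grid) for a in ("b02", "a01", "c03")]
        for r, age in zip(rows, (30, 40, 50)):
            r["age"] = age
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
        lib = load_library(tmp_path / "manifest.csv")
        assert lib.ids == ["b02", "a01", "c03"]
        assert lib["a01"].meta["age"] == 40

    def test_duplicate_id_rejected(self, tmp_path):
        grid = VolumeGrid((3, 3, 3))
        rows = [_write_member(tmp_path, "a01", grid), _write_member(tmp_path, "a01", grid)]
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_library(tmp_path / "manifest.csv")

    def test_incompatible_grid_rejected(self, tmp_path):
        rows = [
            _write_member(tmp_path, "a01", VolumeGrid((3, 3, 3), (2, 2, 2))),
            _write_member(tmp_path, "a02", VolumeGrid((3, 3, 3), (1, 1, 1))),
        ]
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
        with pytest.raises(GridError, match="incompatible"):
            load_library(tmp_path / "manifest.csv")


class TestAtlasLibrary:
    def test_unique_ids_enforced(self, clean_phantom):
        import dataclasses
        dup = dataclasses.replace(clean_phantom)
        with pytest.raises(ValueError, match="duplicate"):
            AtlasLibrary([clean_phantom, dup])
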