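"""Normalization, BraTS label remapping, region masks and NIfTI I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import otsu_bruteforce
from radstruct.volumes import (
    LABEL_ENHANCING,
    LABEL_NECROSIS,
    LABEL_T2_ABNORMALITY,
    DegenerateInputError,
    SubjectVolumes,
    minmax_normalize,
    read_subject,
    region_mask,
    remap_brats_labels,
    write_subject,
)


class TestMinMax:
    def test_endpoint_mapping(self):
        vol = np.zeros((3, 3, 3))
        fg = np.zeros((3, 3, 3), dtype=bool)
        vol[0, 0, :3] = [5.0, 10.0, 7.5]
        fg[0, 0, :3] = True
        out = minmax_normalize(vol, fg)
        np.testing.assert_allclose(out[0, 0, :3], [0.0, 1.0, 0.5])
        assert out[~fg].max() == 0.0

    def test_idempotent_on_unit_range(self):
        rng = np.random.default_rng(0)
        vol = rng.random((4, 4, 4))
        vol.flat[0], vol.flat[1] = 0.0, 1.0
        fg = np.ones(vol.shape, dtype=bool)
        np.testing.assert_allclose(minmax_normalize(vol, fg), vol)

    def test_output_range_exact(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(5, 5, 5)) * 37 + 12
        fg = rng.random(vol.shape) > 0.3
        out = minmax_normalize(vol, fg)
        assert out[fg].min() == 0.0
        assert out[fg].max() == 1.0

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(0.1, 50.0), st.floats(-20.0, 20.0), st.integers(0, 100))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        vol = rng.normal(size=(4, 4, 4))
        fg = np.ones(vol.shape, dtype=bool)
        np.testing.assert_allclose(
            minmax_normalize(a * vol + b, fg), minmax_normalize(vol, fg), atol=1e-9
        )

    def test_constant_foreground_raises(self):
        vol = np.full((3, 3, 3), 2.0)
        with pytest.raises(DegenerateInputError):
            minmax_normalize(vol, np.ones(vol.shape, dtype=bool))


class TestRemap:
    def test_all_zero_mask(self):
        mask = np.zeros((4, 4, 4), dtype=int)
        out = remap_brats_labels(mask, np.zeros((4, 4, 4)))
        assert not out.any()

    def test_label4_is_enhancing(self):
        mask = np.zeros((3, 3, 3), dtype=int)
        mask[1, 1, 1] = 4
        out = remap_brats_labels(mask, np.random.default_rng(0).random((3, 3, 3)))
        assert out[1, 1, 1] == LABEL_ENHANCING
        assert (out != 0).sum() == 1

    def test_bimodal_label1_split_matches_exhaustive_otsu(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((6, 6, 6), dtype=int)
        mask[1:5, 1:5, 1:5] = 1
        t1ce = np.zeros((6, 6, 6))
        vox = np.argwhere(mask == 1)
        # dark core, brighter rim
        dark = rng.normal(0.1, 0.02, size=len(vox) // 2)
        bright = rng.normal(0.6, 0.05, size=len(vox) - len(vox) // 2)
        vals = np.concatenate([dark, bright])
        t1ce[tuple(vox.T)] = vals
        out = remap_brats_labels(mask, t1ce)
        thr = otsu_bruteforce(vals)
        expect_necro = t1ce <= thr
        assert np.array_equal(out == LABEL_NECROSIS, (mask == 1) & expect_necro)
        assert np.array_equal(out == LABEL_T2_ABNORMALITY, (mask == 1) & ~expect_necro)

    def test_voxel_count_preserved(self):
        rng = np.random.default_rng(7)
        mask = rng.choice([0, 1, 2, 4], size=(8, 8, 8), p=[0.7, 0.1, 0.1, 0.1])
        t1ce = rng.random(mask.shape)
        out = remap_brats_labels(mask, t1ce)
        assert (out != 0).sum() == np.isin(mask, (1, 2, 4)).sum()

    def test_unknown_label_rejected(self):
        mask = np.zeros((3, 3, 3), dtype=int)
        mask[0, 0, 0] = 3
        with pytest.raises(ValueError, match="unknown BraTS"):
            remap_brats_labels(mask, np.zeros((3, 3, 3)))


class TestRegions:
    def _subject(self):
        mask = np.zeros((6, 6, 6), dtype=np.int8)
        mask[1, 1, :2] = LABEL_ENHANCING
        mask[2, 2, :3] = LABEL_NECROSIS
        mask[3, 3, :4] = LABEL_T2_ABNORMALITY
        vols = {s: np.random.default_rng(0).random((6, 6, 6)) for s in ("T1", "T1ce", "T2", "FLAIR")}
        return SubjectVolumes("x", vols, mask)

    def test_tumor_core_is_union(self):
        s = self._subject()
        core = region_mask(s, "tumor_core")
        assert core.sum() == region_mask(s, "enhancing").sum() + region_mask(s, "necrosis").sum()

    def test_whole_tumor_counts(self):
        s = self._subject()
        assert region_mask(s, "whole_tumor").sum() == 2 + 3 + 4

    def test_empty_region_warns_and_is_false(self, caplog):
        mask = np.zeros((4, 4, 4), dtype=np.int8)
        mask[0, 0, 0] = LABEL_NECROSIS
        with caplog.at_level("WARNING"):
            out = region_mask(mask, "enhancing")
        assert not out.any()
        assert any("empty" in r.message for r in caplog.records)

    def test_unknown_region(self):
        with pytest.raises(ValueError, match="unknown region"):
            region_mask(np.zeros((2, 2, 2), dtype=np.int8), "midbrain")


class TestIO:
    def test_write_read_roundtrip(self, tmp_path, phantom_subject):
        subject, brats = phantom_subject
        paths = write_subject(tmp_path, subject.volumes, brats)
        back = read_subject(paths, subject_id="x", normalize=False)
        for seq in subject.volumes:
            # float32 storage is the only loss
            np.testing.assert_allclose(back.volumes[seq], subject.volumes[seq], atol=1e-6)
        np.testing.assert_array_equal(back.mask, subject.mask)

    def test_read_normalized_unit_range(self, tmp_path, phantom_subject):
        subject, brats = phantom_subject
        paths = write_subject(tmp_path, subject.volumes, brats)
        back = read_subject(paths, subject_id="x")
        for seq, vol in back.volumes.items():
            assert vol.min() >= 0.0 and vol.max() <= 1.0

    def test_anisotropic_mask_resampled_nearest(self, tmp_path):
        import nibabel as nib

        rng = np.random.default_rng(5)
        mask = rng.choice([0, 1, 2, 4], size=(5, 5, 5)).astype(np.int16)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        vols = {s: rng.random((5, 5, 5)).astype(np.float32) for s in ("t1", "t1ce", "t2", "flair")}
        paths = {}
        for name, arr in {**vols, "mask": mask}.items():
            p = tmp_path / f"{name}.nii"
            nib.save(nib.Nifti1Image(arr, affine), str(p))
            paths[name] = p
        subject = read_subject(paths, subject_id="x")
        assert subject.shape == (10, 10, 10)
        # nearest-neighbour oracle: grid_mode zoom by 2 repeats each voxel
        raw = remap_brats_labels(np.repeat(np.repeat(np.repeat(mask, 2, 0), 2, 1), 2, 2),
                                 np.repeat(np.repeat(np.repeat(vols["t1ce"], 2, 0), 2, 1), 2, 2))
        assert set(np.unique(subject.mask)) <= set(np.unique(raw))

    def test_missing_file_names_sequence(self, tmp_path, phantom_subject):
        subject, brats = phantom_subject
        paths = write_subject(tmp_path, subject.volumes, brats)
        paths["flair"].unlink()
        with pytest.raises(FileNotFoundError, match="flair"):
            read_subject(paths)
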