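"""Cohort data model, attribute coding, round trips, slice extraction."""

import numpy as np
import pandas as pd
import pytest

import mdann as M
from mdann.cohort_io import _scale_unit, apply_coding


def make_phenotype(attr_values, labels=None):
    n = len(attr_values)
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "label": labels if labels is not None else [i % 2 for i in range(n)],
        "sex": attr_values,
    })


class TestCodeAttributes:
    def test_counts_give_majority_and_ratio(self):
        values = ["right"] * 185 + ["left"] * 15
        coding = M.code_attributes(make_phenotype(values), ["sex"])
        code = coding["sex"]
        assert code.majority_value == "right"
        assert code.minority_value == "left"
        assert code.imbalance_ratio == pytest.approx(185 / 15)  # ~12.33

    def test_tie_breaks_lexicographically_with_warning(self):
        values = ["M"] * 50 + ["F"] * 50
        with pytest.warns(UserWarning, match="50/50"):
            coding = M.code_attributes(make_phenotype(values), ["sex"])
        assert coding["sex"].majority_value == "F"
        assert coding["sex"].imbalance_ratio == 1.0

    def test_three_categories_rejected(self):
        values = ["A"] + ["B"] * 2 + ["C"] * 3
        with pytest.raises(ValueError, match="pre-binarize"):
            M.code_attributes(make_phenotype(values), ["sex"])

    def test_permutation_invariant(self, rng):
        values = ["a"] * 30 + ["b"] * 10
        pheno = make_phenotype(values)
        shuffled = pheno.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert M.code_attributes(pheno, ["sex"]) == \
            M.code_attributes(shuffled, ["sex"])

    def test_minority_fraction_equals_ratio_formula(self, small_cohort):
        for i, name in enumerate(small_cohort.attribute_names):
            ratio = small_cohort.coding[name].imbalance_ratio
            frac = small_cohort.coded_attributes[:, i].mean()
            assert frac == pytest.approx(1.0 / (1.0 + ratio))


class TestCohortRoundTrip:
    def test_write_then_read_is_identity(self, small_cohort, tmp_path):
        manifest = M.write_cohort(small_cohort, tmp_path / "c")
        assert len(manifest) == 3
        back = M.read_cohort(manifest["images"], manifest["phenotype"],
                             small_cohort.attribute_names)
        np.testing.assert_array_equal(back.images, small_cohort.images)
        np.testing.assert_array_equal(back.coded_attributes,
                                      small_cohort.coded_attributes)
        np.testing.assert_array_equal(back.labels, small_cohort.labels)

    def test_empty_cohort_rejected(self, small_cohort, tmp_path):
        empty = M.Cohort(images=np.zeros((0, 4, 4)),
                         phenotype=small_cohort.phenotype.iloc[:0],
                         coding={}, coded_attributes=np.zeros((0, 0), int),
                         attribute_names=[])
        with pytest.raises(ValueError, match="empty cohort"):
            M.write_cohort(empty, tmp_path / "e")

    def test_shape_contract(self, tmp_path, rng):
        images = rng.uniform(0, 1, (4, 8, 8))
        pheno = pd.DataFrame({"sample_id": list("abcd"), "label": [0, 1, 0, 1],
                              "sex": ["m", "m", "m", "f"]})
        np.savez_compressed(tmp_path / "img.npz", images=images,
                            sample_id=np.array(list("abcd")))
        pheno.to_csv(tmp_path / "p.csv", index=False)
        cohort = M.read_cohort(tmp_path / "img.npz", tmp_path / "p.csv", ["sex"])
        assert cohort.n == 4
        assert cohort.coded_attributes.shape == (4, 1)

    def test_missing_image_id_named_in_error(self, tmp_path, rng):
        np.savez_compressed(tmp_path / "img.npz",
                            images=rng.uniform(0, 1, (2, 4, 4)),
                            sample_id=np.array(["a", "b"]))
        pheno = pd.DataFrame({"sample_id": ["a", "b", "ghost"],
                              "label": [0, 1, 0], "sex": ["m", "f", "m"]})
        pheno.to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(ValueError, match="ghost"):
            M.read_cohort(tmp_path / "img.npz", tmp_path / "p.csv", ["sex"])

    def test_non_binary_label_rejected(self, tmp_path, rng):
        np.savez_compressed(tmp_path / "img.npz",
                            images=rng.uniform(0, 1, (2, 4, 4)),
                            sample_id=np.array(["a", "b"]))
        pheno = pd.DataFrame({"sample_id": ["a", "b"], "label": [0, 2],
                              "sex": ["m", "f"]})
        pheno.to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(ValueError, match="binary"):
            M.read_cohort(tmp_path / "img.npz", tmp_path / "p.csv", ["sex"])

    def test_out_of_range_intensities_rescaled(self, tmp_path):
        images = np.stack([np.full((4, 4), 100.0), np.zeros((4, 4))])
        np.savez_compressed(tmp_path / "img.npz", images=images,
                            sample_id=np.array(["a", "b"]))
        pd.DataFrame({"sample_id": ["a", "b"], "label": [0, 1],
                      "sex": ["m", "f"]}).to_csv(tmp_path / "p.csv", index=False)
        cohort = M.read_cohort(tmp_path / "img.npz", tmp_path / "p.csv", ["sex"])
        assert cohort.images.min() == 0.0 and cohort.images.max() == 1.0


class TestPngDirectory:
    def test_read_png_directory_matches_bundle(self, tmp_path, rng):
        import imageio.v3 as iio

        images = (rng.uniform(0, 1, (3, 8, 8)) * 255).astype(np.uint8)
        img_dir = tmp_path / "imgs"
        img_dir.mkdir()
        ids = ["s1", "s2", "s3"]
        for sid, img in zip(ids, images):
            iio.imwrite(img_dir / f"{sid}.png", img)
        pheno = pd.DataFrame({"sample_id": ids, "label": [0, 1, 0],
                              "sex": ["m", "f", "m"]})
        pheno.to_csv(tmp_path / "p.csv", index=False)
        cohort = M.read_cohort(img_dir, tmp_path / "p.csv", ["sex"])
        assert cohort.n == 3
        # ids matched by filename stem; intensities rescaled to [0, 1]
        assert cohort.images.max() <= 1.0
        np.testing.assert_allclose(cohort.images[1] * images.max(),
                                   images[1].astype(float), atol=1e-8)


class TestApplyCoding:
    def test_unknown_value_rejected(self):
        pheno = make_phenotype(["m", "f", "x", "m"])
        coding = {"sex": M.AttributeCode("m", "f", 2.0)}
        with pytest.raises(ValueError, match="x"):
            apply_coding(pheno, coding, ["sex"])


class TestScaleUnit:
    def test_constant_outside_range_maps_to_zero(self):
        assert (_scale_unit(np.full((3, 3), 7.0)) == 0).all()

    def test_in_range_untouched(self):
        x = np.array([[0.2, 0.8]])
        np.testing.assert_array_equal(_scale_unit(x), x)


class TestSliceExtraction:
    @pytest.fixture
    def volume_path(self, tmp_path, rng):
        import nibabel as nib

        vol = rng.normal(size=(8, 8, 6))
        nib.save(nib.Nifti1Image(vol, np.eye(4)), tmp_path / "vol.nii.gz")
        return tmp_path / "vol.nii.gz", vol

    def test_middle_slice(self, volume_path):
        path, vol = volume_path
        sl = M.extract_slice_from_volume(path, axis=2, index="middle")
        assert sl.shape == (8, 8)
        expected = _scale_unit(vol[:, :, 3])
        np.testing.assert_allclose(sl, expected, atol=1e-6)

    def test_out_of_bounds_index(self, volume_path):
        path, _ = volume_path
        with pytest.raises(IndexError, match="shape"):
            M.extract_slice_from_volume(path, axis=2, index=6)

    def test_constant_volume_yields_zeros(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.full((4, 4, 4), 9.0), np.eye(4)),
                 tmp_path / "const.nii.gz")
        sl = M.extract_slice_from_volume(tmp_path / "const.nii.gz")
        assert (sl == 0).all()
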