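"""Determinism, geometry and class contracts of the synthetic generator."""

import numpy as np
import pytest

from seq2loc.evaluation import in_mask_fraction
from seq2loc.synthetic_cells import (GeneratorConfig, LocalizationClass,
                                     NucleusParams, NUCLEAR_MOTIF,
                                     PERIPHERAL_MOTIF, generate_dataset,
                                     generate_records, load_dataset,
                                     make_nucleus, make_protein_image,
                                     make_sequence)


class TestMakeNucleus:
    def test_deterministic_given_seed(self):
        a_img, a_mask = make_nucleus(seed=1, size=64)
        b_img, b_mask = make_nucleus(seed=1, size=64)
        np.testing.assert_array_equal(a_img, b_img)
        np.testing.assert_array_equal(a_mask, b_mask)

    def test_different_seeds_differ(self):
        _, a = make_nucleus(seed=1, size=64)
        _, b = make_nucleus(seed=2, size=64)
        assert (a != b).any()

    def test_mask_area_within_bounds(self):
        for seed in range(20):
            _, mask = make_nucleus(seed=seed, size=64)
            assert 0.05 <= mask.mean() <= 0.60

    def test_circle_mask_area_matches_analytic(self):
        # force a centered circle: no eccentricity, jitter or noise
        params = NucleusParams(radius_frac=(0.25, 0.25), eccentricity=(1.0, 1.0),
                               center_jitter_frac=0.0, noise=0.0)
        size = 128
        _, mask = make_nucleus(seed=0, size=size, params=params)
        r = 0.25 * size
        assert mask.sum() == pytest.approx(np.pi * r * r, rel=0.01)

    def test_size_not_divisible_by_patch_edge_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_nucleus(seed=0, size=65, patch_edge=8)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            make_nucleus(seed=0, size=64,
                         params=NucleusParams(radius_frac=(0.0, 0.0)))


class TestMakeSequence:
    def test_nuclear_motif_planted_exactly_once(self):
        seq = make_sequence(seed=5, length=50, loc_class=LocalizationClass.NUCLEAR)
        assert seq.count(NUCLEAR_MOTIF) == 1
        assert PERIPHERAL_MOTIF not in seq

    def test_motif_free_classes_contain_no_motif(self):
        for cls in (LocalizationClass.DIFFUSE, LocalizationClass.CYTOPLASMIC):
            seq = make_sequence(seed=5, length=50, loc_class=cls)
            assert NUCLEAR_MOTIF not in seq and PERIPHERAL_MOTIF not in seq

    def test_deterministic(self):
        args = dict(seed=9, length=40, loc_class=LocalizationClass.PERIPHERAL)
        assert make_sequence(**args) == make_sequence(**args)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_sequence(seed=0, length=6, loc_class=LocalizationClass.NUCLEAR)


class TestMakeProteinImage:
    @pytest.fixture()
    def nucleus(self):
        return make_nucleus(seed=3, size=64)

    def test_nuclear_mass_inside_mask(self, nucleus):
        ref, mask = nucleus
        img = make_protein_image(ref, mask, LocalizationClass.NUCLEAR, seed=1)
        assert in_mask_fraction(img, mask) >= 0.9

    def test_noise_free_nuclear_fraction_is_one(self, nucleus):
        ref, mask = nucleus
        cfg = GeneratorConfig(protein_noise=0.0)
        img = make_protein_image(ref, mask, LocalizationClass.NUCLEAR, seed=1,
                                 config=cfg)
        assert in_mask_fraction(img, mask) == 1.0

    def test_cytoplasmic_mass_outside_mask(self, nucleus):
        ref, mask = nucleus
        img = make_protein_image(ref, mask, LocalizationClass.CYTOPLASMIC, seed=1)
        assert in_mask_fraction(img, mask) <= 0.1

    def test_diffuse_fraction_tracks_mask_area(self, nucleus):
        ref, mask = nucleus
        area = mask.mean()
        fractions = [
            in_mask_fraction(
                make_protein_image(ref, mask, LocalizationClass.DIFFUSE, seed=s),
                mask)
            for s in range(100)]
        assert all(abs(f - area) < 0.2 for f in fractions)

    def test_empty_mask_rejected(self, nucleus):
        ref, _ = nucleus
        with pytest.raises(ValueError, match="empty"):
            make_protein_image(ref, np.zeros_like(ref), LocalizationClass.NUCLEAR,
                               seed=0)


class TestDataset:
    def test_manifest_counts_and_balance(self, tmp_path):
        manifest = generate_dataset(40, seed=0, outdir=tmp_path / "d",
                                    split=(0.8, 0.2))
        assert len(manifest) == 40
        assert (manifest["split"] == "train").sum() == 32
        assert (manifest["split"] == "val").sum() == 8
        assert manifest["loc_class"].value_counts().tolist() == [10, 10, 10, 10]

    def test_regeneration_is_bit_identical(self, tmp_path):
        m1 = generate_dataset(12, seed=4, outdir=tmp_path / "a")
        m2 = generate_dataset(12, seed=4, outdir=tmp_path / "b")
        assert m1.drop(columns=["reference_image", "protein_image",
                                "mask_image"]).equals(
            m2.drop(columns=["reference_image", "protein_image", "mask_image"]))
        for rel in m1["reference_image"]:
            a = (tmp_path / "a" / rel).read_bytes()
            b = (tmp_path / "b" / rel).read_bytes()
            assert a == b

    def test_no_sequence_leakage_between_splits(self, tmp_path):
        generate_dataset(40, seed=2, outdir=tmp_path / "d")
        train = {r.sequence for r in load_dataset(tmp_path / "d", split="train")}
        val = {r.sequence for r in load_dataset(tmp_path / "d", split="val")}
        assert not train & val

    def test_refuses_nonempty_output_dir(self, tmp_path):
        generate_dataset(4, seed=0, outdir=tmp_path / "d")
        with pytest.raises(FileExistsError):
            generate_dataset(4, seed=0, outdir=tmp_path / "d")

    def test_roundtrip_images_close_to_original(self, tmp_path):
        generate_dataset(8, seed=1, outdir=tmp_path / "d")
        loaded = {r.id: r for r in load_dataset(tmp_path / "d")}
        originals = generate_records(8, seed=1)
        for orig in originals:
            # 8-bit quantization on disk
            np.testing.assert_allclose(loaded[orig.id].reference_image,
                                       orig.reference_image, atol=1 / 255)
            assert loaded[orig.id].sequence == orig.sequence


def test_oracle_classifier_separates_nuclear_on_noise_free_data():
    """Thresholding the in-mask intensity fraction at 0.5 must recover
    NUCLEAR vs non-NUCLEAR perfectly when generation noise is off."""
    cfg = GeneratorConfig(protein_noise=0.0,
                          nucleus=NucleusParams(noise=0.0))
    records = generate_records(40, seed=3, config=cfg)
    for r in records:
        call = in_mask_fraction(r.protein_image, r.nucleus_mask) >= 0.5
        assert call == (r.loc_class is LocalizationClass.NUCLEAR)
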