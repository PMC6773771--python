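"""Synthetic cohort generator: determinism, invariants, cohort bookkeeping."""

import numpy as np
import pytest

from histopatch import slide_io
from histopatch.synthetic_slide import (
    CohortManifest,
    SlideSpec,
    generate_cohort,
    generate_slide,
    hue_separation,
)


class TestSlideSpec:
    def test_normal_role_rejects_cancer_fraction(self):
        with pytest.raises(ValueError, match="cancer_fraction"):
            SlideSpec(300, 300, "normal", cancer_fraction=0.3)

    def test_tumor_role_requires_dominant_cancer(self):
        with pytest.raises(ValueError, match="0.8"):
            SlideSpec(300, 300, "tumor", cancer_fraction=0.5)

    def test_undersized_slide_rejected(self):
        with pytest.raises(ValueError, match="stride-50"):
            SlideSpec(150, 300, "normal")

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            SlideSpec(300, 300, "stromal")


class TestGenerateSlide:
    def test_seeded_determinism_bit_identical(self):
        spec = SlideSpec(256, 256, "interface", cancer_fraction=0.5, seed=3)
        s1, m1 = generate_slide(spec)
        s2, m2 = generate_slide(spec)
        assert np.array_equal(s1, s2) and np.array_equal(m1, m2)

    def test_normal_slide_has_empty_mask(self):
        _, mask = generate_slide(SlideSpec(256, 256, "normal", seed=4))
        assert mask.sum() == 0

    def test_interface_cancer_fraction_near_target(self, interface_slide):
        slide, mask = interface_slide
        tissue = slide.min(axis=-1) < 0.9  # background is near-white
        frac = mask[tissue].sum() / tissue.sum()
        assert 0.4 <= frac <= 0.6

    def test_mask_congruent_and_binary(self, interface_slide):
        slide, mask = interface_slide
        assert mask.shape == slide.shape[:2]
        assert set(np.unique(mask)) <= {0, 1}

    def test_background_near_white(self):
        slide, mask = generate_slide(SlideSpec(256, 256, "normal", seed=9, tissue_fraction=0.5))
        # darkest background pixel still bright on every channel
        tissue_ish = slide.min(axis=-1) < 0.85
        background = ~tissue_ish
        assert background.any()
        assert slide[background].mean() > 0.9

    def test_class_hue_separation_positive_margin(self, interface_slide):
        slide, mask = interface_slide
        assert hue_separation(slide, mask) > 0.05

    def test_artifact_region_is_blurred(self):
        base = SlideSpec(256, 256, "tumor", cancer_fraction=0.9, seed=12)
        blurred = SlideSpec(256, 256, "tumor", cancer_fraction=0.9, seed=12, artifact_fraction=0.5)
        s0, _ = generate_slide(base)
        s1, _ = generate_slide(blurred)

        def hf_energy(img):
            return float(np.abs(np.diff(img, axis=0)).mean())

        assert hf_energy(s1) < hf_energy(s0)


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(10, (256, 256), (0.6, 0.2, 0.2), seed=5, out_dir=out)
    return manifest, out


class TestGenerateCohort:

    def test_three_slides_per_patient_split_counts(self, cohort):
        manifest, _ = cohort
        assert len(manifest.rows) == 30
        by_split = {s: {r.patient_id for r in manifest.rows if r.split == s}
                    for s in ("train", "validation", "test")}
        assert (len(by_split["train"]), len(by_split["validation"]), len(by_split["test"])) == (6, 2, 2)

    def test_patient_disjoint_splits(self, cohort):
        manifest, _ = cohort
        manifest.validate()
        splits_per_patient = {}
        for r in manifest.rows:
            splits_per_patient.setdefault(r.patient_id, set()).add(r.split)
        assert all(len(s) == 1 for s in splits_per_patient.values())

    def test_files_exist_with_equal_dimensions(self, cohort):
        manifest, out = cohort
        for r in manifest.rows:
            slide, mask = slide_io.load_pair(out / r.slide, out / r.mask, r)
            assert slide.shape == mask.shape

    def test_different_seeds_differ(self, tmp_path):
        m1 = generate_cohort(3, (256, 256), (1.0, 0.0, 0.0), seed=1, out_dir=tmp_path / "a")
        m2 = generate_cohort(3, (256, 256), (1.0, 0.0, 0.0), seed=2, out_dir=tmp_path / "b")
        s1 = slide_io.read_image(tmp_path / "a" / m1.rows[0].slide)
        s2 = slide_io.read_image(tmp_path / "b" / m2.rows[0].slide)
        assert not np.array_equal(s1, s2)

    def test_manifest_csv_round_trip(self, cohort):
        manifest, out = cohort
        loaded = CohortManifest.read_csv(out / "manifest.csv")
        assert [(r.patient_id, r.slide, r.role, r.split) for r in loaded.rows] == [
            (r.patient_id, r.slide, r.role, r.split) for r in manifest.rows
        ]

    def test_too_few_patients_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="disjoint"):
            generate_cohort(2, (256, 256), (0.5, 0.25, 0.25), seed=1, out_dir=tmp_path)
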