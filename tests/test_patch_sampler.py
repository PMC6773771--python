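"""Patch extraction: center-pixel labels, caps, balancing, tissue filter."""

import dataclasses

import numpy as np
import pytest

from histopatch.patch_sampler import (
    PatchSet,
    SamplingPolicy,
    balance_classes,
    label_at,
    load_patchset,
    sample_patches,
    sample_slide_patches,
    sample_training_patches,
    save_patchset,
    tissue_filter,
)
from histopatch.slide_io import AnnotationMask, Slide
from histopatch.synthetic_slide import SlideSpec, generate_slide


def _pair(role="interface", frac=0.5, seed=31, size=320):
    spec = SlideSpec(size, size, role, cancer_fraction=frac, seed=seed)
    s, m = generate_slide(spec)
    slide = Slide(pixels=s, role=role, split="train", slide_id=f"{role}{seed}")
    return slide, AnnotationMask(m)


class TestLabelAt:
    def test_all_one_mask_is_cancer(self):
        assert label_at(np.ones((101, 101)), (0, 0)) == 1

    def test_only_center_pixel_decides(self):
        mask = np.ones((101, 101))
        mask[50, 50] = 0  # 49.99% coverage but clean center
        assert label_at(mask, (0, 0)) == 0
        mask = np.zeros((101, 101))
        mask[50, 50] = 1
        assert label_at(mask, (0, 0)) == 1

    def test_out_of_bounds_footprint_rejected(self):
        with pytest.raises(ValueError, match="footprint"):
            label_at(np.zeros((120, 120)), (30, 30))


class TestTissueFilter:
    def test_white_patch_excluded(self):
        assert not tissue_filter(np.ones((101, 101, 3), np.float32))

    def test_generated_tissue_patch_kept(self, interface_slide):
        s, _ = interface_slide
        assert tissue_filter(s[100:201, 100:201])

    def test_saturation_boundary_inclusive(self):
        # mean saturation exactly 0.05 must pass (>= is inclusive)
        rgb = np.zeros((4, 4, 3), np.float32)
        rgb[..., 0] = 0.5
        rgb[..., 1] = rgb[..., 2] = 0.5 * (1 - 0.05)  # S = (max-min)/max = 0.05
        assert tissue_filter(rgb)


class TestSampling:
    def test_cap_is_exact_when_candidates_abound(self):
        slide, mask = _pair("tumor", 0.9)
        policy = SamplingPolicy(max_cancer_per_slide=50, max_normal_per_slide=10)
        out = sample_slide_patches(slide, mask, policy, np.random.default_rng(0), 50, 10)
        assert int(out.labels.sum()) == 50

    def test_cap_is_upper_bound_when_candidates_scarce(self):
        slide, mask = _pair("normal", 0.0, size=220)
        policy = SamplingPolicy()
        out = sample_slide_patches(slide, mask, policy, np.random.default_rng(0), 5000, 10**6)
        n_candidates = len(out)
        assert 0 < n_candidates < 10**6  # "up to" the cap, limited by tissue

    def test_balance_within_one_percent(self):
        patches = PatchSet(
            pixels=np.zeros((10_000, 1, 1, 3), np.float32),
            origins=np.zeros((10_000, 2), np.int32),
            labels=np.r_[np.ones(8000, np.uint8), np.zeros(2000, np.uint8)],
            slide_refs=["s"] * 10_000,
        )
        out = balance_classes(patches, np.random.default_rng(0))
        n_pos = int(out.labels.sum())
        n_neg = len(out) - n_pos
        assert n_neg == 2000
        assert n_pos <= 2020  # majority reduced to within 1% of minority

    def test_stored_labels_match_mask_recomputation(self):
        slide, mask = _pair()
        policy = SamplingPolicy(max_cancer_per_slide=30, max_normal_per_slide=30, seed=3)
        out = sample_patches([(slide, mask)], policy, roles=("interface",), balance=False)
        assert len(out) > 0
        for i in range(len(out)):
            assert out.labels[i] == label_at(mask, tuple(out.origins[i]))

    def test_patch_pixels_match_slide_at_origin(self):
        slide, mask = _pair()
        policy = SamplingPolicy(max_cancer_per_slide=5, max_normal_per_slide=5, seed=3)
        out = sample_patches([(slide, mask)], policy, roles=("interface",), balance=False)
        r, c = out.origins[0]
        assert np.array_equal(out.pixels[0], slide.pixels[r : r + 101, c : c + 101])

    def test_seeded_sampling_is_reproducible(self):
        slide, mask = _pair()
        policy = SamplingPolicy(max_cancer_per_slide=20, max_normal_per_slide=20, seed=7)
        a = sample_patches([(slide, mask)], policy, roles=("interface",))
        b = sample_patches([(slide, mask)], policy, roles=("interface",))
        assert np.array_equal(a.origins, b.origins)
        assert np.array_equal(a.pixels, b.pixels)

    def test_training_excludes_interface_slides(self):
        tumor = _pair("tumor", 0.9, seed=1)
        interface = _pair("interface", 0.5, seed=2)
        policy = SamplingPolicy(max_cancer_per_slide=10, max_normal_per_slide=10)
        out = sample_training_patches([tumor, interface], policy)
        assert set(out.slide_refs) <= {tumor[0].slide_id}

    def test_undersized_slide_skipped_with_warning(self, caplog):
        small = Slide(pixels=np.zeros((50, 50, 3), np.float32), slide_id="tiny", role="normal")
        policy = SamplingPolicy()
        with caplog.at_level("WARNING"):
            out = sample_slide_patches(
                small, AnnotationMask(np.zeros((50, 50), np.uint8)), policy,
                np.random.default_rng(0), 10, 10,
            )
        assert len(out) == 0
        assert "skipped" in caplog.text

    def test_even_patch_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SamplingPolicy(patch_size=100)


def test_patchset_round_trip_via_disk(tmp_path):
    slide, mask = _pair()
    policy = SamplingPolicy(max_cancer_per_slide=4, max_normal_per_slide=4, seed=5)
    out = sample_patches([(slide, mask)], policy, roles=("interface",), balance=False)
    save_patchset(out, tmp_path)
    back = load_patchset(tmp_path)
    assert np.array_equal(back.labels, out.labels)
    assert np.array_equal(back.origins, out.origins)
    # PNG quantization: 8-bit round trip within 1/255 per channel
    assert np.abs(back.pixels - out.pixels).max() <= 1.0 / 255 + 1e-6
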