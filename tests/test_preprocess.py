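"""Contrast stretch, boundary detection, ROI, patch tiling, augmentation."""

import numpy as np
import pytest

from ebusml.preprocess import (ContrastParams, RingSpec, augment,
                               contrast_stretch, detect_boundary, extract_roi,
                               percentile_thresholds, ring_mask, select_patches)
from ebusml.synthetic import PhantomSpec, generate_phantom
from ebusml.types import (Cohort, DegenerateContrastError, EbusImage,
                          LesionMask, PatientRecord)

from conftest import SMALL


def _image(arr, center=None, mm=0.09, id="t"):
    arr = np.asarray(arr, dtype=np.uint8)
    if center is None:
        center = (arr.shape[0] // 2, arr.shape[1] // 2)
    return EbusImage(pixels=arr, probe_center=center, mm_per_px=mm, id=id)


class TestContrastStretch:
    def test_below_threshold_maps_to_zero(self):
        img = _image(np.full((4, 4), 32))          # 32/255 = 0.1255
        out = contrast_stretch(img, ContrastParams(L=0.3, H=0.9, gamma=2.0))
        assert (out.pixels == 0).all()

    def test_identity_for_unit_range_gamma_one(self):
        img = _image(np.arange(256, dtype=np.uint8).reshape(16, 16))
        out = contrast_stretch(img, ContrastParams(L=0.0, H=1.0, gamma=1.0))
        assert np.array_equal(out.pixels, img.pixels)

    def test_percentile_stretch_widens_support(self, rng):
        # narrow intensity band: support expands to the full 0..255 range
        vals = np.clip(rng.normal(120, 15, size=(100, 100)), 0, 255).astype(np.uint8)
        img = _image(vals)
        params = percentile_thresholds(img)
        out = contrast_stretch(img, params)
        assert out.pixels.min() == 0 and out.pixels.max() == 255
        # brute-force per-pixel evaluation of the piecewise map
        x = vals / 255.0
        expect = np.where(x < params.L, 0.0,
                          np.where(x > params.H, 1.0, x ** params.gamma))
        assert np.array_equal(out.pixels,
                              np.clip(np.rint(expect * 255), 0, 255).astype(np.uint8))

    def test_monotone_in_input(self, rng):
        params = ContrastParams(L=0.2, H=0.8, gamma=0.7)
        x = np.sort(rng.integers(0, 256, size=64)).astype(np.uint8)
        out = contrast_stretch(_image(x.reshape(8, 8)), params).pixels.ravel()
        assert (np.diff(out[np.argsort(x, kind="stable")]) >= 0).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ContrastParams(L=0.9, H=0.3)


class TestPercentileThresholds:
    def test_uniform_ramp(self):
        img = _image(np.arange(256, dtype=np.uint8).reshape(16, 16))
        p = percentile_thresholds(img)
        assert p.L == pytest.approx(0.01, abs=0.005)
        assert p.H == pytest.approx(0.99, abs=0.005)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateContrastError):
            percentile_thresholds(_image(np.full((8, 8), 7)))

    def test_phantom_thresholds_bracket_median(self, benign_phantom):
        img, _ = benign_phantom
        p = percentile_thresholds(img)
        med = np.median(img.gray) / 255.0
        assert p.L < med < p.H


class TestBoundaryDetection:
    def test_circle_radius_recovered_within_two_px(self):
        n = 300
        rows, cols = np.mgrid[0:n, 0:n]
        dist = np.hypot(rows - 150, cols - 150)
        arr = np.zeros((n, n))
        arr[dist <= 100] = 180
        arr[dist <= 22] = 235
        img = _image(arr, center=(150, 150))
        mask = detect_boundary(img, 360)
        for ang in np.linspace(0, 2 * np.pi, 90, endpoint=False):
            r = np.arange(0, 140)
            rr = np.round(150 + r * np.sin(ang)).astype(int)
            cc = np.round(150 + r * np.cos(ang)).astype(int)
            detected = r[mask.mask[rr, cc]].max()
            assert abs(detected - 100) <= 2

    def test_ray_count_insensitive_on_circle(self):
        n = 300
        rows, cols = np.mgrid[0:n, 0:n]
        dist = np.hypot(rows - 150, cols - 150)
        arr = np.zeros((n, n))
        arr[dist <= 90] = 180
        arr[dist <= 22] = 235
        img = _image(arr, center=(150, 150))
        # a polygon inscribed in a circle loses 1 - (n/2pi) sin(2pi/n) of the
        # area: ~10% at 8 vertices, ~1.3% at 16, so 16 rays is the coarsest
        # sampling that can stay within 5% of the fine-sampled area
        a16 = detect_boundary(img, 16).mask.sum()
        a360 = detect_boundary(img, 360).mask.sum()
        assert abs(a16 - a360) / a360 < 0.05

    def test_phantom_dice(self, malignant_phantom):
        img, truth = malignant_phantom
        enhanced = contrast_stretch(img, percentile_thresholds(img))
        det = detect_boundary(enhanced, 180)
        inter = (det.mask & truth.mask).sum()
        dice = 2 * inter / (det.mask.sum() + truth.mask.sum())
        assert dice >= 0.90


class TestRoi:
    def test_all_ones_and_all_zeros_and_half(self, rng):
        arr = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        img = _image(arr)
        assert np.array_equal(extract_roi(img, LesionMask(np.ones((10, 10)))).pixels, arr)
        assert (extract_roi(img, LesionMask(np.zeros((10, 10)))).pixels == 0).all()
        half = np.zeros((10, 10), dtype=bool)
        half[:, :5] = True
        out = extract_roi(img, LesionMask(half)).pixels
        assert (out[:, 5:] == 0).all()
        assert np.array_equal(out[:, :5], arr[:, :5])
        with pytest.raises(ValueError):
            extract_roi(img, LesionMask(np.ones((5, 5))))


def _oracle_tiling_count(region, s):
    """Exhaustive row-major first-fit enumeration with the corner rule."""
    h, w = region.shape
    occupied = np.zeros((h, w), dtype=bool)
    count = 0
    for r in range(h - s + 1):
        for c in range(w - s + 1):
            corners = (region[r, c] and region[r + s - 1, c]
                       and region[r, c + s - 1] and region[r + s - 1, c + s - 1])
            if corners and not occupied[r:r + s, c:c + s].any():
                occupied[r:r + s, c:c + s] = True
                count += 1
    return count


class TestPatchTiling:
    def test_mask_outside_ring_gives_zero_patches(self, benign_phantom):
        img, _ = benign_phantom
        far = np.zeros(img.gray.shape, dtype=bool)
        far[:20, :20] = True
        assert len(select_patches(img, LesionMask(far))) == 0

    def test_phantom_patch_count_in_published_range(self, benign_phantom):
        img, mask = benign_phantom
        ps = select_patches(img, mask, RingSpec(), probe_radius_mm=2.0)
        assert 1 <= len(ps) <= 14

    def test_windows_disjoint_and_corners_inside(self, malignant_phantom):
        img, mask = malignant_phantom
        ring = RingSpec()
        ps = select_patches(img, mask, ring, probe_radius_mm=2.0)
        region = ring_mask(img.gray.shape, img.probe_center, img.mm_per_px,
                           ring, 2.0) & mask.mask
        seen = np.zeros(img.gray.shape, dtype=bool)
        for p in ps.patches:
            block = seen[p.row:p.row + p.side, p.col:p.col + p.side]
            assert not block.any()
            seen[p.row:p.row + p.side, p.col:p.col + p.side] = True
            for dr in (0, p.side - 1):
                for dc in (0, p.side - 1):
                    assert region[p.row + dr, p.col + dc]

    def test_tiling_matches_oracle_on_random_masks(self, rng):
        from scipy import ndimage
        ring = RingSpec()
        for _ in range(25):
            n = 170
            blob = ndimage.gaussian_filter(rng.standard_normal((n, n)), 12)
            mask = blob > np.quantile(blob, 0.4)
            img = _image(rng.integers(0, 256, size=(n, n)), center=(85, 85))
            ps = select_patches(img, LesionMask(mask), ring, probe_radius_mm=2.0)
            region = ring_mask((n, n), (85, 85), 0.09, ring, 2.0) & mask
            assert len(ps) == _oracle_tiling_count(region, ring.patch_side)


def _toy_cohort(n_mal, n_ben, rng, split="train"):
    images, masks, records, splits = [], [], [], []
    for i in range(n_mal + n_ben):
        label = 1 if i < n_mal else 0
        arr = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        images.append(_image(arr, id=f"im{i}"))
        m = np.zeros((64, 64), dtype=bool)
        m[8:50, 10:60] = True
        masks.append(LesionMask(m))
        records.append(PatientRecord(gender="male", smoking="smoker", age=60,
                                     lesion_size=">=3cm", label=label, id=f"im{i}"))
        splits.append(split)
    return Cohort(images=images, masks=masks, records=records, split=splits)


class TestAugmentation:
    def test_published_counts(self, rng):
        cohort = _toy_cohort(99, 61, rng)
        out = augment(cohort)
        labels = out.labels
        assert (labels == 1).sum() == 297
        assert (labels == 0).sum() == 305
        assert len(out) == 602

    def test_empty_cohort(self):
        out = augment(Cohort(images=[], masks=[], records=[], split=[]))
        assert len(out) == 0

    def test_rotation_group_property_and_mask_consistency(self, rng):
        cohort = _toy_cohort(0, 1, rng)
        out = augment(cohort)
        assert len(out) == 5
        by_id = {im.id: i for i, im in enumerate(out.images)}
        rot90 = out.images[by_id["im0-rot90"]]
        assert np.array_equal(np.rot90(rot90.pixels, 3), cohort.images[0].pixels)
        m90 = out.masks[by_id["im0-rot90"]]
        assert np.array_equal(np.rot90(m90.mask, 3), cohort.masks[0].mask)

    def test_test_split_untouched(self, rng):
        cohort = _toy_cohort(2, 2, rng, split="test")
        out = augment(cohort)
        assert len(out) == 4
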