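"""Segmentation, the 92 descriptors, masked GLCM, and Pearson screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk

from canopytraits.exceptions import DomainError, EmptyMaskError
from canopytraits.features import (FEATURE_NAMES, GLCM_OFFSETS,
                                   SegmentationMask, _cooccurrence,
                                   _quantize_masked, extract_features,
                                   glcm_statistics, masked_glcm_features,
                                   pearson_screen, segment_plant)


# --- independent GLCM oracle: explicit double loop over pixel pairs ----------

def glcm_oracle(q: np.ndarray, offset: tuple[int, int], levels: int) -> dict:
    dr, dc = offset
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and q[r, c] >= 0 and q[r2, c2] >= 0:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1  # symmetric
    total = counts.sum()
    if total == 0:
        counts[0, 0] = 1.0
        total = 1.0
    p = counts / total
    contrast = corr_num = energy = homog = 0.0
    mu_i = mu_j = 0.0
    for i in range(levels):
        for j in range(levels):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = 0.0
    for i in range(levels):
        for j in range(levels):
            contrast += p[i, j] * (i - j) ** 2
            energy += p[i, j] ** 2
            homog += p[i, j] / (1 + abs(i - j))
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
            corr_num += (i - mu_i) * (j - mu_j) * p[i, j]
    if var_i < 1e-15 or var_j < 1e-15:
        correlation = 1.0
    else:
        correlation = corr_num / np.sqrt(var_i * var_j)
    return {"Contrast": contrast, "Correlation": correlation,
            "Energy": energy, "Homogeneity": homog}


class TestGLCM:
    def test_matches_bruteforce_oracle_on_random_patches(self, rng):
        """All four statistics agree with explicit pair enumeration to 1e-10
        on 100 random masked patches up to 8x8."""
        levels = 6
        for _ in range(100):
            h, w = rng.integers(2, 9, size=2)
            q = rng.integers(0, levels, (h, w)).astype(np.int32)
            mask_off = rng.random((h, w)) < 0.2
            q[mask_off] = -1
            for offset in GLCM_OFFSETS:
                ours = glcm_statistics(_cooccurrence(q, offset, levels))
                ref = glcm_oracle(q, offset, levels)
                for key in ref:
                    assert ours[key] == pytest.approx(ref[key], abs=1e-10)

    def test_checkerboard_horizontal_contrast_and_energy(self):
        """2x2 checkerboard of two levels: P = [[0,.5],[.5,0]], so contrast 1
        and energy 0.5 in the horizontal direction."""
        q = np.array([[0, 1], [1, 0]], dtype=np.int32)
        stats = glcm_statistics(_cooccurrence(q, (0, 1), 2))
        assert stats["Contrast"] == pytest.approx(1.0)
        assert stats["Energy"] == pytest.approx(0.5)

    def test_constant_region_is_degenerate(self):
        img = np.full((20, 20, 3), 90, dtype=np.uint8)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        fv = extract_features(img, SegmentationMask.from_array(mask))
        for sp_ch in ("RGB_G", "HSV_V", "LAB_L"):
            assert fv[f"{sp_ch}_Energy"] == pytest.approx(1.0)
            assert fv[f"{sp_ch}_Contrast"] == pytest.approx(0.0)
            assert fv[f"{sp_ch}_Std"] == pytest.approx(0.0)

    def test_quantization_range_from_masked_pixels_only(self, rng):
        comp = rng.random((10, 10)) * 100
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        q = _quantize_masked(comp, mask, 16)
        assert q[~mask].max() == -1
        assert 0 <= q[mask].min() and q[mask].max() <= 15


class TestSegmentation:
    def test_high_iou_against_renderer_mask(self, cultivars, scene):
        from canopytraits.synthdata import render_plant
        for ci in range(3):
            s = render_plant(cultivars[ci], 5, scene)
            m = segment_plant(s.rgb)
            iou = (m.mask & s.mask).sum() / (m.mask | s.mask).sum()
            assert iou >= 0.9

    def test_background_only_image_raises(self, rng):
        bg = np.full((64, 64, 3), 40, dtype=np.uint8)
        bg += rng.integers(0, 6, bg.shape).astype(np.uint8)
        with pytest.raises(EmptyMaskError):
            segment_plant(bg)

    def test_rotation_preserves_mask_area(self, sample):
        n0 = segment_plant(sample.rgb).plant_pixel_count
        n90 = segment_plant(np.rot90(sample.rgb).copy()).plant_pixel_count
        assert n0 == n90


class TestFeatureVector:
    def test_exactly_92_stable_names(self, sample):
        fv = extract_features(sample.rgb, segment_plant(sample.rgb))
        assert list(fv.index) == list(FEATURE_NAMES)
        assert len(fv) == 92
        assert np.isfinite(fv.to_numpy()).all()
        for name in FEATURE_NAMES:
            if name.endswith(("Energy", "Homogeneity")):
                assert 0 < fv[name] <= 1

    def test_color_features_rotation_invariant(self, sample):
        m = segment_plant(sample.rgb)
        fv = extract_features(sample.rgb, m)
        rot = np.rot90(sample.rgb).copy()
        fv_rot = extract_features(rot, SegmentationMask.from_array(
            np.rot90(m.mask).copy()))
        color = [n for n in FEATURE_NAMES if n.endswith(("Average", "Std"))]
        assert np.allclose(fv[color], fv_rot[color])
        # direction-averaged GLCM is invariant to 90-degree rotation too
        texture = [n for n in FEATURE_NAMES
                   if n.endswith(("Contrast", "Energy", "Homogeneity",
                                  "Correlation"))]
        assert np.allclose(fv[texture], fv_rot[texture], rtol=1e-9)

    def test_disk_area_and_perimeter_closed_forms(self):
        img = np.zeros((128, 128, 3), dtype=np.uint8)
        mask = np.zeros((128, 128), bool)
        rr, cc = disk((64, 64), 50)
        mask[rr, cc] = True
        img[mask] = (40, 160, 60)
        fv = extract_features(img, SegmentationMask.from_array(mask))
        assert fv["Area"] == pytest.approx(np.pi * 50 ** 2, rel=0.01)
        assert fv["Perimeter"] == pytest.approx(2 * np.pi * 50, rel=0.05)

    def test_empty_mask_rejected(self, sample):
        with pytest.raises(DomainError):
            extract_features(sample.rgb, np.zeros(sample.rgb.shape[:2], bool))


class TestPearsonScreen:
    def _table(self, rng, n=40):
        y = rng.random(n) * 100
        return pd.DataFrame({
            "perfect": y.copy(),
            "negated": -y,
            "noise": rng.random(n),
            "constant": np.ones(n),
        }), pd.Series(y)

    def test_perfect_and_negated_features_selected(self, rng):
        feats, y = self._table(rng)
        with pytest.warns(UserWarning, match="constant"):
            sel = pearson_screen(feats, y, threshold=0.65)
        assert sel.iloc[0]["feature"] in ("perfect", "negated")
        r = sel.set_index("feature")["r"]
        assert r["perfect"] == pytest.approx(1.0)
        assert r["negated"] == pytest.approx(-1.0)
        assert "noise" not in set(sel["feature"])

    def test_constant_target_rejected(self, rng):
        feats, _ = self._table(rng)
        with pytest.raises(DomainError):
            pearson_screen(feats, pd.Series(np.ones(len(feats))))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=100),
           shift=st.floats(min_value=-50, max_value=50))
    def test_correlation_invariant_to_affine_target_transform(self, scale,
                                                              shift):
        rng = np.random.default_rng(7)
        y = pd.Series(rng.random(30))
        feats = pd.DataFrame({"f": rng.random(30)})
        base = pearson_screen(feats, y, threshold=0.0)["r"][0]
        moved = pearson_screen(feats, y * scale + shift, threshold=0.0)["r"][0]
        assert moved == pytest.approx(base, abs=1e-9)
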