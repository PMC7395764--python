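"""Plant segmentation and the 92 handcrafted image descriptors.

Segmentation thresholds the a* channel of CIEL*a*b* (green vegetation is
strongly negative there, the tray background is not) with an Otsu bimodal
split, fills holes and keeps the largest connected component.

The descriptor set covers 15 color components — the three channels of RGB,
HSV, CIEL*a*b*, YCbCr and HSI — with, per component, the masked mean and
standard deviation (30 color features) and four gray-level co-occurrence
matrix statistics (contrast, correlation, energy, homogeneity; 60 texture
features), plus projected area and perimeter (2 shape features): 92 in all.
GLCM uses 16 quantization levels, displacement 1, statistics averaged over
the four standard directions, masked pixels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.color import rgb2hsv, rgb2lab, rgb2ycbcr
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import perimeter as sk_perimeter

from .exceptions import DomainError, EmptyMaskError

__all__ = [
    "SegmentationMask",
    "segment_plant",
    "extract_features",
    "feature_names",
    "extract_feature_table",
    "pearson_screen",
    "glcm_statistics",
    "FEATURE_NAMES",
]

GLCM_LEVELS = 16
# displacement-1 offsets for 0, 45, 90, 135 degrees as (drow, dcol)
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_SPACES: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("RGB", ("R", "G", "B")),
    ("HSV", ("H", "S", "V")),
    ("LAB", ("L", "A", "B")),
    ("YCrCb", ("Y", "Cr", "Cb")),
    ("HSI", ("H", "S", "I")),
)
_STATS = ("Average", "Std")
_TEXTURES = ("Contrast", "Correlation", "Energy", "Homogeneity")


def feature_names() -> list[str]:
    names = [f"{sp}_{ch}_{st}" for sp, chans in _SPACES
             for ch in chans for st in _STATS]
    names += [f"{sp}_{ch}_{tx}" for sp, chans in _SPACES
              for ch in chans for tx in _TEXTURES]
    names += ["Area", "Perimeter"]
    return names


FEATURE_NAMES = tuple(feature_names())
assert len(FEATURE_NAMES) == 92


@dataclass
class SegmentationMask:
    """Binary plant mask aligned to its image."""

    mask: np.ndarray
    plant_pixel_count: int
    plausible: bool = True

    @classmethod
    def from_array(cls, mask: np.ndarray, plausible: bool = True
                   ) -> "SegmentationMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, plant_pixel_count=int(mask.sum()),
                   plausible=plausible)


def segment_plant(image: np.ndarray, min_foreground_px: int = 16,
                  greenness_margin: float = 8.0) -> SegmentationMask:
    """Adaptive color-threshold segmentation of the plant.

    Splits the within-image a* distribution at the Otsu threshold, takes the
    green (low-a*) side, fills holes and keeps the largest connected
    component.  ``greenness_margin`` guards against images with no vegetation:
    the candidate foreground must be at least that many a* units greener than
    the background.

    Raises
    ------
    EmptyMaskError
        If no plausibly green foreground is found.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise DomainError("expected an (H, W, 3) RGB image")
    lab = rgb2lab(image)
    a = lab[..., 1]
    if float(a.max() - a.min()) < 1e-6:
        raise EmptyMaskError("constant-color image: no foreground found")
    thr = threshold_otsu(a)
    fg = a < thr
    if int(fg.sum()) < min_foreground_px or fg.all():
        raise EmptyMaskError("no foreground found by a* threshold")
    fg_mean = float(a[fg].mean())
    bg_mean = float(a[~fg].mean())
    if bg_mean - fg_mean < greenness_margin:
        raise EmptyMaskError(
            f"foreground not green enough (a* separation "
            f"{bg_mean - fg_mean:.2f} < {greenness_margin})")
    fg = ndimage.binary_fill_holes(fg)
    labels = cc_label(fg)
    if labels.max() == 0:
        raise EmptyMaskError("no connected foreground component")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == int(counts.argmax())
    return SegmentationMask.from_array(keep)


# --- color components ---------------------------------------------------------


def _rgb_to_hsi(rgb01: np.ndarray) -> np.ndarray:
    """Standard HSI: hue in [0,1], saturation 1 - min/intensity, intensity mean."""
    r, g, b = rgb01[..., 0], rgb01[..., 1], rgb01[..., 2]
    i = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(i > 1e-12, 1.0 - mn / np.maximum(i, 1e-12), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        theta = np.arccos(np.clip(num / np.maximum(den, 1e-12), -1.0, 1.0))
    h = np.where(b <= g, theta, 2 * np.pi - theta) / (2 * np.pi)
    h = np.where(den < 1e-12, 0.0, h)
    return np.stack([h, s, i], axis=-1)


def color_components(image: np.ndarray) -> dict[str, np.ndarray]:
    """The 15 color components keyed ``<space>_<channel>``."""
    rgb01 = image.astype(np.float64) / 255.0
    spaces = {
        "RGB": image.astype(np.float64),
        "HSV": rgb2hsv(image),
        "LAB": rgb2lab(image),
        "YCrCb": rgb2ycbcr(image),
        "HSI": _rgb_to_hsi(rgb01),
    }
    # rgb2ycbcr returns (Y, Cb, Cr); reorder to the (Y, Cr, Cb) naming
    ycbcr = spaces["YCrCb"]
    spaces["YCrCb"] = np.stack(
        [ycbcr[..., 0], ycbcr[..., 2], ycbcr[..., 1]], axis=-1)
    out = {}
    for sp, chans in _SPACES:
        arr = spaces[sp]
        for ci, ch in enumerate(chans):
            out[f"{sp}_{ch}"] = arr[..., ci]
    return out


# --- masked GLCM --------------------------------------------------------------


def _quantize_masked(component: np.ndarray, mask: np.ndarray,
                     levels: int) -> np.ndarray:
    """Quantize masked values to 0..levels-1; non-mask pixels get -1."""
    q = np.full(component.shape, -1, dtype=np.int32)
    vals = component[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        q[mask] = 0
        return q
    scaled = (component - lo) / (hi - lo) * levels
    q[mask] = np.clip(scaled[mask].astype(np.int32), 0, levels - 1)
    return q


def _cooccurrence(q: np.ndarray, offset: tuple[int, int],
                  levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix over in-mask pixel pairs."""
    dr, dc = offset
    h, w = q.shape
    r0 = max(0, -dr)
    r1 = min(h, h - dr)
    c0 = max(0, -dc)
    c1 = min(w, w - dc)
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (src >= 0) & (dst >= 0)
    i = src[valid].ravel()
    j = dst[valid].ravel()
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T  # symmetric
    total = counts.sum()
    if total == 0:
        counts[0, 0] = 1.0
        total = 1.0
    return counts / total


def glcm_statistics(p: np.ndarray) -> dict[str, float]:
    """Contrast, correlation, energy (ASM), homogeneity of one normalized GLCM.

    Correlation of a degenerate single-level matrix is defined as 1.0 so the
    feature vector stays finite.
    """
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(p * (ii - jj) ** 2))
    energy = float(np.sum(p ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    var_i = float(np.sum((ii - mu_i) ** 2 * p))
    var_j = float(np.sum((jj - mu_j) ** 2 * p))
    if var_i < 1e-15 or var_j < 1e-15:
        correlation = 1.0
    else:
        correlation = float(
            np.sum((ii - mu_i) * (jj - mu_j) * p) / np.sqrt(var_i * var_j))
    return {"Contrast": contrast, "Correlation": correlation,
            "Energy": energy, "Homogeneity": homogeneity}


def masked_glcm_features(component: np.ndarray, mask: np.ndarray,
                         levels: int = GLCM_LEVELS) -> dict[str, float]:
    """The four texture statistics averaged over the 4 standard directions."""
    q = _quantize_masked(component, mask, levels)
    acc = {name: 0.0 for name in _TEXTURES}
    for offset in GLCM_OFFSETS:
        p = _cooccurrence(q, offset, levels)
        for name, val in glcm_statistics(p).items():
            acc[name] += val
    return {name: val / len(GLCM_OFFSETS) for name, val in acc.items()}


def extract_features(image: np.ndarray,
                     mask: SegmentationMask | np.ndarray) -> pd.Series:
    """The 92-entry named feature vector for one segmented plant image.

    Color statistics and GLCMs are computed over masked pixels only; area is
    the plant pixel count and perimeter the boundary contour length.
    """
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if m.shape != image.shape[:2]:
        raise DomainError("mask shape does not match image")
    if not m.any():
        raise DomainError("mask is empty")
    comps = color_components(image)
    values: dict[str, float] = {}
    for key, comp in comps.items():
        vals = comp[m]
        values[f"{key}_Average"] = float(vals.mean())
        values[f"{key}_Std"] = float(vals.std())
        for tx, v in masked_glcm_features(comp, m).items():
            values[f"{key}_{tx}"] = v
    values["Area"] = float(m.sum())
    values["Perimeter"] = float(sk_perimeter(m))
    out = pd.Series(values).reindex(list(FEATURE_NAMES))
    if not np.isfinite(out.to_numpy()).all():
        raise DomainError("non-finite feature encountered")
    return out


def extract_feature_table(images: dict[str, np.ndarray] | list[np.ndarray],
                          masks: dict | list | None = None) -> pd.DataFrame:
    """Feature matrix (one row per image, 92 named columns).

    Segments each image itself when no masks are supplied.
    """
    if isinstance(images, dict):
        items = list(images.items())
    else:
        items = list(enumerate(images))
    rows = {}
    for key, image in items:
        if masks is None:
            mask = segment_plant(image)
        else:
            mask = masks[key]
        rows[key] = extract_features(image, mask)
    table = pd.DataFrame(rows).T
    table.index.name = "id"
    return table


def pearson_screen(features: pd.DataFrame, target: pd.Series,
                   threshold: float = 0.65) -> pd.DataFrame:
    """Select features with |Pearson r| >= threshold against one trait.

    Returns a frame (feature, r, p) sorted by |r| descending, with two-sided
    significance.  Constant features are skipped with a warning; a constant
    target is a domain error.
    """
    if len(features) < 3:
        raise DomainError("need at least 3 samples for correlation screening")
    y = np.asarray(target, dtype=float)
    if len(y) != len(features):
        raise DomainError("feature table and target lengths differ")
    if float(np.std(y)) < 1e-15:
        raise DomainError("target is constant")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if float(np.std(x)) < 1e-15:
            warnings.warn(f"feature {col!r} is constant; skipped", stacklevel=2)
            continue
        r, p = stats.pearsonr(x, y)
        if abs(r) >= threshold:
            rows.append({"feature": col, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows, columns=["feature", "r", "p"])
    if len(out):
        out = out.reindex(out["r"].abs().sort_values(ascending=False).index)
        out = out.reset_index(drop=True)
    return out
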