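"""Depth-image structural traits: canopy height H, projected area PA and
digital volume V = PA * H, with the three univariate linear models LR-H,
LR-PA and LR-V.

Plant extraction works on the depth map alone: the image is partitioned into
superpixels, the superpixel whose centroid is nearest the image centre seeds
the plant region, and adjacent superpixels whose mean depth is within a
tolerance of the seed's are merged in.  The superpixel backend is pluggable;
the default is SLIC on the depth values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage
from skimage.segmentation import slic

from .exceptions import DomainError
from .features import SegmentationMask

logger = logging.getLogger(__name__)

__all__ = ["StructuralFeatures", "segment_depth", "structural_features",
           "StructuralTraitModel", "fit_lr"]


@dataclass(frozen=True)
class StructuralFeatures:
    """Depth-derived structural traits for one plant.

    ``H`` in cm (mean canopy height above ground over plant pixels), ``PA``
    in pixels (projected area), ``V = PA * H`` in px*cm.  ``pa_cm2`` converts
    PA with a scene calibration when one is known.
    """

    H: float
    PA: int
    V: float
    px_per_cm: float | None = None

    def __post_init__(self) -> None:
        if self.H < 0 or self.PA < 0:
            raise DomainError("H and PA must be non-negative")
        if abs(self.V - self.PA * self.H) > 1e-9 * max(1.0, abs(self.V)):
            raise DomainError("V must equal PA * H")

    @property
    def pa_cm2(self) -> float | None:
        if self.px_per_cm is None:
            return None
        return self.PA / self.px_per_cm ** 2


def _slic_superpixels(depth: np.ndarray, n_superpixels: int) -> np.ndarray:
    d = depth.astype(np.float64)
    rng_span = float(d.max() - d.min())
    if rng_span > 0:
        d = (d - d.min()) / rng_span
    return slic(d, n_segments=n_superpixels, compactness=0.1,
                channel_axis=None, start_label=1, enforce_connectivity=True)


def segment_depth(depth: np.ndarray, n_superpixels: int = 200,
                  merge_tol_mm: float = 25.0,
                  superpixel_fn=None) -> SegmentationMask:
    """Extract the centre plant from a depth map via superpixels.

    Selects the superpixel whose centroid minimizes Euclidean distance to the
    image centre, then grows the region by merging adjacent superpixels whose
    mean depth lies within ``merge_tol_mm`` of the seed's mean depth
    (``merge_tol_mm=0`` keeps the single seed superpixel).

    The returned mask carries a depth-plausibility flag: if the selected
    region is not nearer to the sensor than the surrounding background (as a
    centred plant must be in a nadir view), ``plausible`` is False.
    """
    depth = np.asarray(depth)
    if depth.ndim != 2:
        raise DomainError("expected a single-channel depth image")
    if n_superpixels < 2:
        raise DomainError("n_superpixels must be >= 2")

    if float(depth.max()) == float(depth.min()):
        warnings.warn("constant depth map; returning centre superpixel",
                      stacklevel=2)
        labels = _slic_superpixels(
            np.zeros_like(depth, dtype=float), n_superpixels)
    else:
        fn = superpixel_fn or _slic_superpixels
        labels = fn(depth, n_superpixels)

    ids = np.unique(labels)
    h, w = depth.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    centroids = np.array(ndimage.center_of_mass(
        np.ones_like(labels), labels, ids))
    means = ndimage.mean(depth.astype(np.float64), labels, ids)
    seed_idx = int(np.argmin(np.linalg.norm(centroids - centre, axis=1)))
    seed_id = int(ids[seed_idx])
    seed_depth = float(means[seed_idx])

    mean_by_id = dict(zip(ids.tolist(), means.tolist()))
    selected = {seed_id}
    if merge_tol_mm > 0:
        # region adjacency from 4-neighbour label transitions
        adj: dict[int, set[int]] = {int(i): set() for i in ids}
        for a, b in ((labels[:, :-1], labels[:, 1:]),
                     (labels[:-1, :], labels[1:, :])):
            edge = a != b
            for u, v in zip(a[edge].ravel(), b[edge].ravel()):
                adj[int(u)].add(int(v))
                adj[int(v)].add(int(u))
        frontier = [seed_id]
        while frontier:
            cur = frontier.pop()
            for nb in adj[cur]:
                if nb not in selected and \
                        abs(mean_by_id[nb] - seed_depth) <= merge_tol_mm:
                    selected.add(nb)
                    frontier.append(nb)

    mask = np.isin(labels, list(selected))
    plausible = True
    if mask.any() and not mask.all():
        fg = float(depth[mask].mean())
        bg = float(depth[~mask].mean())
        if fg >= bg:  # selected region is not above the background plane
            plausible = False
            logger.warning("depth-plausibility check failed: selected region "
                           "mean depth %.1f >= background %.1f", fg, bg)
    return SegmentationMask.from_array(mask, plausible=plausible)


def structural_features(depth: np.ndarray,
                        mask: SegmentationMask | np.ndarray,
                        sensor_height: float,
                        px_per_cm: float | None = None) -> StructuralFeatures:
    """H, PA and V from a depth map (mm) and a plant mask.

    ``H = sensor_height - mean(depth_mm / 10)`` over plant pixels (cm),
    clamped at 0 with a warning; ``PA`` is the mask pixel count; ``V = PA*H``.
    """
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if not m.any():
        raise DomainError("mask is empty")
    if m.shape != depth.shape:
        raise DomainError("mask shape does not match depth image")
    mean_depth_cm = float(depth[m].astype(np.float64).mean()) / 10.0
    h_cm = sensor_height - mean_depth_cm
    if h_cm < 0:
        warnings.warn(f"negative canopy height {h_cm:.2f} cm clamped to 0",
                      stacklevel=2)
        h_cm = 0.0
    pa = int(m.sum())
    return StructuralFeatures(H=h_cm, PA=pa, V=pa * h_cm, px_per_cm=px_per_cm)


class StructuralTraitModel:
    """Univariate ordinary-least-squares trait model (LR-H / LR-PA / LR-V)."""

    def __init__(self, feature: pd.Series | np.ndarray,
                 target: pd.Series | np.ndarray, name: str = "feature") -> None:
        x = np.asarray(feature, dtype=float)
        y = np.asarray(target, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise DomainError("need >= 3 paired samples")
        if float(np.std(x)) < 1e-15:
            raise DomainError("predictor is constant")
        self.x = x
        self.y = y
        self.name = name

    def fit(self):
        res = sm.OLS(self.y, sm.add_constant(self.x)).fit()
        return StructuralTraitResults(res, self.x, self.name)


class StructuralTraitResults:
    def __init__(self, ols_results, x: np.ndarray, name: str) -> None:
        self._res = ols_results
        self._x = x
        self.name = name
        self.intercept = float(ols_results.params[0])
        self.slope = float(ols_results.params[1])
        self.r2 = float(ols_results.rsquared)
        self.fitted_values = np.asarray(ols_results.fittedvalues)

    def predict(self, feature) -> np.ndarray:
        x = np.asarray(feature, dtype=float)
        return self.intercept + self.slope * x

    def diagnostics(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept, "r2": self.r2,
            "slope_se": float(self._res.bse[1]),
            "p_value": float(self._res.pvalues[1]),
            "n": int(self._res.nobs),
        }

    def summary(self) -> str:
        return str(self._res.summary())


def fit_lr(feature, target, name: str = "feature"
           ) -> tuple[float, float, dict, np.ndarray]:
    """OLS fit of one structural feature against one trait.

    Returns (slope, intercept, diagnostics, fitted_values).
    """
    res = StructuralTraitModel(feature, target, name=name).fit()
    return res.slope, res.intercept, res.diagnostics(), res.fitted_values
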