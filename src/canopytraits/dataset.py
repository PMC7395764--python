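"""Image preprocessing and stratified dataset partitioning.

Mirrors the data handling used for greenhouse trait-regression studies: crop
each capture to a square around the plant, resize to a common resolution, then
split 8:2 into train/test with every (cultivar, session) stratum represented
on both sides, and carve a validation subset out of the training images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .exceptions import DomainError

__all__ = ["SplitSpec", "DatasetPartition", "center_crop_resize", "split_dataset"]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation split configuration.

    ``val_fraction_of_train`` is taken from the *training* images, so with the
    defaults an N-image set yields 0.8N training images of which 20% serve as
    the validation set during model fitting.
    """

    train_fraction: float = 0.8
    val_fraction_of_train: float = 0.2
    stratify_by: tuple[str, ...] = ("cultivar", "session")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise DomainError("train_fraction must be in (0, 1)")
        if not 0.0 <= self.val_fraction_of_train < 1.0:
            raise DomainError("val_fraction_of_train must be in [0, 1)")


@dataclass(frozen=True)
class DatasetPartition:
    """Disjoint id lists; ``train_ids`` excludes the validation subset."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    @property
    def n_train_total(self) -> int:
        """Training-set size including the validation subset."""
        return len(self.train_ids) + len(self.val_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = ([(i, "train") for i in self.train_ids]
                + [(i, "val") for i in self.val_ids]
                + [(i, "test") for i in self.test_ids])
        return pd.DataFrame(rows, columns=["id", "split"])


def _plant_bbox(image: np.ndarray) -> tuple[int, int, int, int]:
    """Bounding box (x0, y0, x1, y1) of green vegetation via excess-green."""
    rgb = image.astype(np.float64)
    exg = 2 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    fg = exg > max(20.0, 0.25 * float(exg.max()))
    if not fg.any():
        # fall back to full frame when no clear vegetation signal exists
        return 0, 0, image.shape[1], image.shape[0]
    ys, xs = np.nonzero(fg)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def center_crop_resize(image: np.ndarray,
                       crop_box: tuple[int, int, int, int] | str | None = "auto",
                       target_side: int = 900,
                       interpolation_order: int = 1) -> np.ndarray:
    """Crop a square region and resize it to ``target_side`` pixels.

    ``crop_box`` may be an explicit ``(x0, y0, x1, y1)`` rectangle, ``None``
    (largest centred square of the frame), or ``"auto"``: the largest centred
    square containing the plant bounding box plus a 5% margin.  Resampling is
    bilinear by default (``interpolation_order=1``).  A crop that already has
    the target side is returned bitwise identical.
    """
    if target_side <= 0:
        raise DomainError("target_side must be positive")
    if image.ndim != 3 or image.shape[2] != 3:
        raise DomainError("expected an (H, W, 3) RGB image")
    h, w = image.shape[:2]

    if crop_box == "auto":
        x0, y0, x1, y1 = _plant_bbox(image)
        mx = 0.05 * (x1 - x0)
        my = 0.05 * (y1 - y0)
        x0, x1 = x0 - mx, x1 + mx
        y0, y1 = y0 - my, y1 + my
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        side = max(x1 - x0, y1 - y0)
        side = min(max(side, 1.0), min(h, w))
        # keep the square inside the frame
        left = float(np.clip(cx - side / 2.0, 0, w - side))
        top = float(np.clip(cy - side / 2.0, 0, h - side))
        box = (int(round(left)), int(round(top)),
               int(round(left + side)), int(round(top + side)))
    elif crop_box is None:
        side = min(h, w)
        left = (w - side) // 2
        top = (h - side) // 2
        box = (left, top, left + side, top + side)
    else:
        box = tuple(int(v) for v in crop_box)  # type: ignore[assignment]

    x0, y0, x1, y1 = box
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise DomainError(f"crop box {box} outside image bounds {(w, h)}")
    crop = image[y0:y1, x0:x1]
    if crop.shape[0] != crop.shape[1]:
        side = min(crop.shape[:2])
        crop = crop[:side, :side]
    if crop.shape[0] == target_side:
        return crop.copy()
    out = _sk_resize(crop.astype(np.float64), (target_side, target_side, 3),
                     order=interpolation_order, anti_aliasing=crop.shape[0] > target_side,
                     preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _stratum_keys(manifest: pd.DataFrame, by: tuple[str, ...]) -> pd.Series:
    if not by:
        return pd.Series(["all"] * len(manifest), index=manifest.index)
    return manifest[list(by)].astype(str).agg("|".join, axis=1)


def split_dataset(manifest: pd.DataFrame, spec: SplitSpec) -> DatasetPartition:
    """Stratified 8:2 train/test split plus validation subset of the train set.

    The global training size is ``round(train_fraction * N)`` (half-up).
    Within each (cultivar, session) stratum the training count starts at the
    floor of the stratum quota; remaining slots are assigned by largest
    fractional remainder so the stratum counts reconcile exactly to the global
    target.  Every stratum of size >= 2 keeps at least one sample on each side.
    Deterministic for a fixed ``spec.rng_seed``.
    """
    if manifest is None or len(manifest) == 0:
        raise DomainError("manifest is empty")
    if "id" not in manifest.columns:
        raise DomainError("manifest must have an 'id' column")
    n = len(manifest)
    # round half up, matching printed dataset sizes such as 286 -> 229/57
    target_train = int(np.floor(spec.train_fraction * n + 0.5))
    target_train = min(max(target_train, 1), n - 1) if n >= 2 else target_train

    rng = np.random.default_rng(spec.rng_seed)
    keys = _stratum_keys(manifest, spec.stratify_by)
    strata = sorted(keys.unique())

    quota: dict[str, int] = {}
    remainders: list[tuple[float, str]] = []
    sizes: dict[str, int] = {}
    for k in strata:
        size = int((keys == k).sum())
        sizes[k] = size
        exact = spec.train_fraction * size
        quota[k] = int(np.floor(exact))
        remainders.append((exact - quota[k], k))
    # enforce coverage floors before distributing remainders
    for k in strata:
        if sizes[k] >= 2:
            quota[k] = min(max(quota[k], 1), sizes[k] - 1)
    deficit = target_train - sum(quota.values())
    order = sorted(remainders, key=lambda t: (-t[0], t[1]))
    i = 0
    while deficit != 0 and i < 10 * len(strata):
        _, k = order[i % len(strata)]
        if deficit > 0 and quota[k] < (sizes[k] - 1 if sizes[k] >= 2 else sizes[k]):
            quota[k] += 1
            deficit -= 1
        elif deficit < 0 and quota[k] > (1 if sizes[k] >= 2 else 0):
            quota[k] -= 1
            deficit += 1
        i += 1

    train: list[str] = []
    test: list[str] = []
    for k in strata:
        ids = manifest.loc[keys == k, "id"].astype(str).tolist()
        ids = sorted(ids)
        perm = rng.permutation(len(ids))
        ids = [ids[p] for p in perm]
        train.extend(ids[: quota[k]])
        test.extend(ids[quota[k]:])

    n_val = int(np.floor(spec.val_fraction_of_train * len(train) + 0.5))
    train_sorted = sorted(train)
    vperm = rng.permutation(len(train_sorted))
    val = sorted(train_sorted[p] for p in vperm[:n_val])
    train_final = sorted(set(train_sorted) - set(val))
    return DatasetPartition(train_ids=tuple(train_final), val_ids=tuple(val),
                            test_ids=tuple(sorted(test)))
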