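"""Training-set augmentation: right-angle rotations, flips and HSV-brightness
scaling that emulates changing greenhouse illumination.

The default composition rule produces exactly 26 variants per source image:
the 6 geometric variants {identity, rot90, rot180, rot270, horizontal flip,
vertical flip} plus each of the 4 brightness factors applied to each of the 5
non-identity geometric variants (6 + 5*4 = 26).  The factor is always derived
from the rule, never hard-coded, and augmentation is applied to training
images only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv

from .exceptions import DomainError

__all__ = [
    "AugmentationConfig",
    "brightness_adjust",
    "geometric_transform",
    "variant_chains",
    "augmentation_factor",
    "apply_chain",
    "expand_training_set",
]

_GEOMETRIC = ("identity", "rot90", "rot180", "rot270", "fliph", "flipv")


@dataclass(frozen=True)
class AugmentationConfig:
    rotations: tuple[int, ...] = (90, 180, 270)
    flips: tuple[str, ...] = ("horizontal", "vertical")
    brightness_factors: tuple[float, ...] = (0.8, 0.9, 1.1, 1.2)
    composition_rule: str = "default26"

    def __post_init__(self) -> None:
        if any(r % 90 != 0 for r in self.rotations):
            raise DomainError("rotations must be multiples of 90 degrees")
        if any(f <= 0 for f in self.brightness_factors):
            raise DomainError("brightness factors must be positive")
        if any(f not in ("horizontal", "vertical") for f in self.flips):
            raise DomainError("flips must be 'horizontal' or 'vertical'")
        if self.composition_rule not in ("default26", "product"):
            raise DomainError(f"unknown composition rule {self.composition_rule!r}")


def brightness_adjust(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale the HSV value channel by ``factor`` (clipped), H and S unchanged.

    Round-trip quantization through HSV means factor 1.0 reproduces the input
    to within one 8-bit intensity step.
    """
    if factor <= 0:
        raise DomainError("brightness factor must be positive")
    if image.ndim != 3 or image.shape[2] != 3:
        raise DomainError("expected an (H, W, 3) RGB image")
    hsv = rgb2hsv(image)
    hsv[..., 2] = np.clip(hsv[..., 2] * factor, 0.0, 1.0)
    out = hsv2rgb(hsv)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def geometric_transform(image: np.ndarray, name: str) -> np.ndarray:
    """Apply one exact (lossless) geometric variant by name."""
    if name == "identity":
        return image.copy()
    if name == "rot90":
        return np.rot90(image, 1).copy()
    if name == "rot180":
        return np.rot90(image, 2).copy()
    if name == "rot270":
        return np.rot90(image, 3).copy()
    if name == "fliph":
        return image[:, ::-1].copy()
    if name == "flipv":
        return image[::-1, :].copy()
    raise DomainError(f"unknown geometric transform {name!r}")


def _geometric_names(config: AugmentationConfig) -> list[str]:
    names = ["identity"]
    names += [f"rot{r % 360}" for r in config.rotations if r % 360 != 0]
    if "horizontal" in config.flips:
        names.append("fliph")
    if "vertical" in config.flips:
        names.append("flipv")
    return names


def variant_chains(config: AugmentationConfig) -> list[tuple[str, ...]]:
    """Enumerate the transform chains the composition rule produces.

    ``default26``: all geometric variants, plus every brightness factor
    applied to each non-identity geometric variant.  ``product``: every
    brightness factor (plus identity) applied to every geometric variant.
    """
    geoms = _geometric_names(config)
    chains: list[tuple[str, ...]] = [(g,) for g in geoms]
    bright = [f"bright{f:g}" for f in config.brightness_factors]
    if config.composition_rule == "default26":
        for g in geoms:
            if g == "identity":
                continue
            chains.extend((g, b) for b in bright)
    else:  # product
        for g in geoms:
            chains.extend((g, b) for b in bright)
    return chains


def augmentation_factor(config: AugmentationConfig) -> int:
    """Number of output images per source image under the composition rule."""
    return len(variant_chains(config))


def apply_chain(image: np.ndarray, chain: Sequence[str]) -> np.ndarray:
    out = image
    for step in chain:
        if step.startswith("bright"):
            out = brightness_adjust(out, float(step[len("bright"):]))
        else:
            out = geometric_transform(out, step)
    return out


def expand_training_set(train_rows: pd.DataFrame, config: AugmentationConfig,
                        out_dir: Path | str,
                        image_root: Path | str | None = None) -> pd.DataFrame:
    """Write every augmentation variant of every training image.

    ``train_rows`` needs columns ``id`` and ``rgb_path`` (paths resolved
    against ``image_root`` when given).  Returns the augmented manifest with
    provenance columns (aug_id, source_id, transform_chain, path).  Output
    names encode source id and chain, so collisions indicate duplicate ids.
    """
    if train_rows is None or len(train_rows) == 0:
        raise DomainError("training set is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = Path(image_root) if image_root is not None else None
    chains = variant_chains(config)

    rows = []
    seen: set[str] = set()
    for _, rec in train_rows.iterrows():
        src_path = Path(rec["rgb_path"])
        if root is not None and not src_path.is_absolute():
            src_path = root / src_path
        image = np.asarray(Image.open(src_path).convert("RGB"))
        for chain in chains:
            chain_label = "+".join(chain)
            aug_id = f"{rec['id']}__{chain_label.replace('+', '_')}"
            if aug_id in seen:
                raise OSError(f"augmented name collision for {aug_id}")
            seen.add(aug_id)
            variant = apply_chain(image, chain)
            path = out / f"{aug_id}.png"
            Image.fromarray(variant).save(path)
            rows.append({"aug_id": aug_id, "source_id": rec["id"],
                         "transform_chain": chain_label, "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "augmented_manifest.csv", index=False)
    return manifest
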