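"""Synthetic top-view lettuce scenes with ground-truth growth traits.

Renders a rosette of overlapping lobed leaves on a dark tray, together with a
nadir depth map and a per-plant trait vector (leaf fresh weight LFW in g, leaf
dry weight LDW in g, leaf area LA in cm^2).  The three quantities are linked
the way they are in real lettuce: LA is the summed one-sided area of every
modelled leaf (including parts hidden by occlusion), LFW follows a power-law
allometry LFW = alpha * LA**beta with log-normal scatter, and LDW is a dry
matter fraction of LFW with its own scatter.

The generator exists so the whole estimation pipeline (segmentation,
handcrafted features, depth structural traits, CNN regression) can be
exercised end to end with known ground truth.  It is not photorealistic.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage.color import hsv2rgb
from skimage.draw import polygon as draw_polygon

from .exceptions import DomainError

N_SESSIONS = 7

__all__ = [
    "CultivarSpec",
    "SceneSpec",
    "TraitVector",
    "GroundTruth",
    "PlantSample",
    "default_cultivars",
    "render_plant",
    "generate_dataset",
    "N_SESSIONS",
]


@dataclass(frozen=True)
class TraitVector:
    """The regression target: fresh weight (g), dry weight (g), leaf area (cm^2)."""

    lfw: float
    ldw: float
    la: float

    def as_array(self) -> np.ndarray:
        return np.array([self.lfw, self.ldw, self.la], dtype=float)


@dataclass(frozen=True)
class CultivarSpec:
    """Morphology and allometry of one lettuce cultivar.

    ``leaf_count_range`` gives the expected leaf count at the first and last
    weekly session; counts interpolate linearly in between.  ``curl_amplitude``
    controls leaf-margin waviness and the projected-footprint foreshortening of
    curled habits (0 for flat habits).  ``allometry_alpha``/``allometry_beta``
    define LFW = alpha * LA**beta (alpha in g cm^(-2 beta)).
    """

    name: str
    leaf_habit: str  # "flat" or "curled"
    leaf_count_range: tuple[int, int] = (5, 26)
    hue_range: tuple[float, float] = (95.0, 135.0)  # degrees, greens
    curl_amplitude: float = 0.0
    dry_matter_fraction: float = 0.05
    allometry_alpha: float = 0.035
    allometry_beta: float = 1.1

    def __post_init__(self) -> None:
        if self.leaf_habit not in ("flat", "curled"):
            raise DomainError(f"unknown leaf habit {self.leaf_habit!r}")
        if (self.curl_amplitude == 0) != (self.leaf_habit == "flat"):
            raise DomainError("curl_amplitude must be 0 iff leaf_habit is flat")
        if not 0.02 < self.dry_matter_fraction < 0.15:
            raise DomainError("dry_matter_fraction must lie in (0.02, 0.15)")
        if self.curl_amplitude < 0:
            raise DomainError("curl_amplitude must be >= 0")


def default_cultivars() -> list[CultivarSpec]:
    """Two flat-leaf cultivars and one curled-leaf cultivar (butterhead-type
    Flandria and Tiberius, lollo-type Locarno)."""
    return [
        CultivarSpec(name="Flandria", leaf_habit="flat", hue_range=(100.0, 130.0),
                     dry_matter_fraction=0.048),
        CultivarSpec(name="Tiberius", leaf_habit="flat", hue_range=(95.0, 125.0),
                     dry_matter_fraction=0.052),
        CultivarSpec(name="Locarno", leaf_habit="curled", curl_amplitude=1.0,
                     hue_range=(85.0, 115.0), dry_matter_fraction=0.045),
    ]


@dataclass(frozen=True)
class SceneSpec:
    """Camera/scene geometry for a nadir top-view capture.

    ``sensor_height`` is the distance from the depth sensor to the ground
    plane in cm (the default matches a tripod-mounted RGB-D sensor at 78 cm).
    ``px_per_cm`` is the image scale at the canopy plane.
    """

    image_size: int = 256
    sensor_height: float = 78.0
    px_per_cm: float = 10.0
    background_style: str = "dark"
    illumination_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise DomainError("image_size must be positive")
        if self.sensor_height <= 0:
            raise DomainError("sensor_height must be positive")
        if self.px_per_cm <= 0:
            raise DomainError("px_per_cm must be positive")
        if self.illumination_scale <= 0:
            raise DomainError("illumination_scale must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """True traits plus renderer bookkeeping for one scene."""

    traits: TraitVector
    total_leaf_area_cm2: float
    visible_projected_area_px: int


@dataclass
class PlantSample:
    """One plant observation: RGB image, depth map, labels and ground truth.

    ``mask`` is the renderer's own plant/background mask (used as segmentation
    ground truth in tests); real captures would not carry it.
    """

    rgb: np.ndarray  # (H, W, 3) uint8
    depth: np.ndarray | None  # (H, W) uint16, mm
    cultivar: str
    session: int
    traits: TraitVector
    ground_truth: GroundTruth | None = None
    mask: np.ndarray | None = None
    sample_id: str = ""


# --- leaf geometry -----------------------------------------------------------

# Per-session growth trajectory: mean leaf semi-major axis in cm.  Chosen so a
# stage-7 rosette reaches mature-lettuce size (LA order 10^3 cm^2, LFW order
# 10^2 g under the default allometry).
_LEAF_A0 = 0.9
_LEAF_A_SLOPE = 0.85
_SIGMA_FW = 0.08
_SIGMA_DW = 0.08
_N_BOUNDARY = 180  # boundary samples per leaf polygon


def _ellipse_polar_radius(a: float, b: float, phi: np.ndarray) -> np.ndarray:
    """Distance from centre to an axis-aligned ellipse boundary at angle phi."""
    return (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)


def _leaf_boundary(a: float, b: float, lobe_amp: float, n_lobes: int,
                   phase: float, phi: np.ndarray) -> np.ndarray:
    """Lobed-ellipse boundary radius r(phi) in leaf-local polar coordinates."""
    r = _ellipse_polar_radius(a, b, phi)
    return r * (1.0 + lobe_amp * np.cos(n_lobes * phi + phase))


def _polar_area(r: np.ndarray, phi: np.ndarray) -> float:
    """Area enclosed by a star-shaped boundary r(phi), by trapezoid quadrature
    of (1/2) * integral r^2 dphi.  Exact up to quadrature error (~1e-4 relative
    at 180 samples), computed before any rasterization."""
    r2 = r.astype(float) ** 2
    return 0.5 * float(np.trapezoid(np.append(r2, r2[0]),
                                    np.append(phi, phi[0] + 2 * np.pi)))


@dataclass
class _Leaf:
    area_cm2: float          # true one-sided leaf area
    xy_px: np.ndarray        # (n, 2) footprint polygon in pixel coords
    height_cm: float         # canopy height of this leaf above ground
    hue: float               # HSV hue in [0, 1]
    sat: float
    val: float


def _build_leaves(cultivar: CultivarSpec, stage: int, scene: SceneSpec,
                  rng: np.random.Generator,
                  leaf_overrides: dict | None = None) -> list[_Leaf]:
    lo, hi = cultivar.leaf_count_range
    frac = (stage - 1) / (N_SESSIONS - 1)
    expected = lo + (hi - lo) * frac
    n_leaves = max(1, int(round(expected)) + int(rng.integers(-1, 2)))
    mean_a = _LEAF_A0 + _LEAF_A_SLOPE * stage

    if leaf_overrides and "n_leaves" in leaf_overrides:
        n_leaves = leaf_overrides["n_leaves"]

    cx = cy = scene.image_size / 2.0
    # canopy top height: ~3.8 cm at transplanting, ~9.5 cm at harvest
    h_max = 2.8 + 0.95 * stage
    # curled habits foreshorten the projected footprint of each leaf
    shrink = 1.0 / (1.0 + 0.22 * cultivar.curl_amplitude)
    golden = np.deg2rad(137.507764)

    leaves: list[_Leaf] = []
    phi = np.linspace(0.0, 2 * np.pi, _N_BOUNDARY, endpoint=False)
    for i in range(n_leaves):
        a = mean_a * float(rng.lognormal(0.0, 0.18))
        b = a * float(rng.uniform(0.50, 0.65))
        if leaf_overrides and "semi_axes_cm" in leaf_overrides:
            a, b = leaf_overrides["semi_axes_cm"]
        lobe_amp = 0.05 + 0.10 * cultivar.curl_amplitude
        if leaf_overrides and "lobe_amp" in leaf_overrides:
            lobe_amp = leaf_overrides["lobe_amp"]
        n_lobes = 7 if cultivar.leaf_habit == "flat" else 11
        phase = float(rng.uniform(0, 2 * np.pi))

        r = _leaf_boundary(a, b, lobe_amp, n_lobes, phase, phi)
        area = _polar_area(r, phi)

        theta = i * golden + float(rng.normal(0.0, 0.05))
        # leaf centre sits partway out from the rosette centre
        d = 0.45 * a
        if leaf_overrides and "center_offset_cm" in leaf_overrides:
            d = leaf_overrides["center_offset_cm"]
        lx = d * np.cos(theta)
        ly = d * np.sin(theta)

        # footprint polygon in cm, leaf-local orientation along theta
        bx = r * shrink * np.cos(phi + theta) + lx
        by = r * shrink * np.sin(phi + theta) + ly
        xy = np.column_stack([cx + bx * scene.px_per_cm,
                              cy + by * scene.px_per_cm])

        # inner (later) leaves sit higher; the rosette forms a fairly flat
        # dome, so even the outermost leaves sit above half the canopy top
        height = max(0.3, h_max * (0.78 + 0.22 * (i + 1) / n_leaves)
                     * float(rng.uniform(0.97, 1.0)))
        hue = float(rng.uniform(*cultivar.hue_range)) / 360.0
        sat = float(np.clip(rng.normal(0.62, 0.06), 0.35, 0.9))
        val = float(np.clip(0.30 + 0.38 * height / h_max
                            + rng.normal(0.0, 0.04), 0.12, 0.95))
        leaves.append(_Leaf(area, xy, height, hue, sat, val))
    return leaves


def render_plant(cultivar: CultivarSpec, stage: int, scene: SceneSpec,
                 leaf_overrides: dict | None = None) -> PlantSample:
    """Render one rosette scene: RGB image, depth map and ground truth.

    Deterministic for a fixed ``scene.rng_seed``: repeated calls return
    identical bytes.  ``stage`` is the weekly session index, 1..7; leaf count
    and mean leaf size grow with it in expectation.

    ``leaf_overrides`` pins leaf geometry for controlled experiments
    (``n_leaves``, ``semi_axes_cm``, ``lobe_amp``, ``center_offset_cm``).

    Raises
    ------
    DomainError
        If ``stage`` is outside 1..7.
    """
    if not 1 <= int(stage) <= N_SESSIONS:
        raise DomainError(f"stage must be in 1..{N_SESSIONS}, got {stage}")
    stage = int(stage)
    rng = np.random.default_rng(np.random.SeedSequence(scene.rng_seed))

    size = scene.image_size
    leaves = _build_leaves(cultivar, stage, scene, rng, leaf_overrides)

    # z-buffer rasterization: nearest (highest) leaf wins each pixel
    zbuf = np.full((size, size), -np.inf, dtype=np.float64)
    owner = np.full((size, size), -1, dtype=np.int32)
    for idx, leaf in enumerate(leaves):
        rr, cc = draw_polygon(leaf.xy_px[:, 1], leaf.xy_px[:, 0],
                              shape=(size, size))
        if rr.size == 0:
            continue
        # mild radial taper so inner pixels of a leaf sit a little higher
        cxp = float(np.mean(leaf.xy_px[:, 0]))
        cyp = float(np.mean(leaf.xy_px[:, 1]))
        rad = np.hypot(cc - cxp, rr - cyp)
        rmax = max(float(rad.max()), 1.0)
        z = leaf.height_cm * (1.0 - 0.08 * rad / rmax)
        if cultivar.curl_amplitude > 0:
            z = z + 0.12 * cultivar.curl_amplitude * np.cos(rad / 2.0)
        z = np.maximum(z, 0.05)
        better = z > zbuf[rr, cc]
        zbuf[rr, cc] = np.where(better, z, zbuf[rr, cc])
        owner[rr, cc] = np.where(better, idx, owner[rr, cc])

    mask = owner >= 0
    visible_px = int(mask.sum())

    # HSV canvas: dark tray background with texture + illumination gradient
    h = rng.uniform(0.08, 0.12, (size, size))
    s = rng.uniform(0.05, 0.18, (size, size))
    v = 0.10 + 0.05 * rng.random((size, size))
    if scene.background_style == "tray":
        v += 0.04 * ((np.arange(size)[:, None] // 16 +
                      np.arange(size)[None, :] // 16) % 2)
    for idx, leaf in enumerate(leaves):
        sel = owner == idx
        if not sel.any():
            continue
        h[sel] = leaf.hue + rng.normal(0.0, 0.004, int(sel.sum()))
        s[sel] = np.clip(leaf.sat + rng.normal(0.0, 0.03, int(sel.sum())),
                         0.2, 1.0)
        v[sel] = np.clip(leaf.val + rng.normal(0.0, 0.03, int(sel.sum())),
                         0.1, 1.0)
    # smooth left-to-right illumination gradient, as under a greenhouse roof
    grad = 0.9 + 0.2 * (np.arange(size) / max(size - 1, 1))
    v = np.clip(v * grad[None, :] * scene.illumination_scale, 0.0, 1.0)
    h = np.mod(h, 1.0)

    rgb = hsv2rgb(np.stack([h, s, v], axis=-1))
    rgb8 = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)

    # depth in mm: ground plane at sensor height; plant strictly nearer
    ground_mm = scene.sensor_height * 10.0
    depth = np.full((size, size), ground_mm, dtype=np.float64)
    depth[mask] = ground_mm - zbuf[mask] * 10.0
    depth16 = np.clip(np.round(depth), 0, 65535).astype(np.uint16)

    total_la = float(sum(leaf.area_cm2 for leaf in leaves))
    lfw = cultivar.allometry_alpha * total_la ** cultivar.allometry_beta \
        * float(np.exp(rng.normal(0.0, _SIGMA_FW)))
    ldw = cultivar.dry_matter_fraction * lfw \
        * float(np.exp(rng.normal(0.0, _SIGMA_DW)))
    ldw = min(ldw, 0.95 * lfw)  # dry weight is always a fraction of fresh
    traits = TraitVector(lfw=lfw, ldw=ldw, la=total_la)
    gt = GroundTruth(traits=traits, total_leaf_area_cm2=total_la,
                     visible_projected_area_px=visible_px)
    return PlantSample(rgb=rgb8, depth=depth16, cultivar=cultivar.name,
                       session=stage, traits=traits, ground_truth=gt,
                       mask=mask)


def _sample_seed(base_seed: int, index: int) -> int:
    """Stable per-sample seed below 2**31 derived from the scene seed."""
    digest = hashlib.sha256(f"{base_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def save_depth_png(depth: np.ndarray, path: Path | str) -> None:
    """Write a 16-bit single-channel PNG depth map (pixel value = mm)."""
    Image.fromarray(depth.astype(np.uint16)).save(path)


def load_depth_png(path: Path | str) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint16)


def generate_dataset(n_per_cultivar: int, cultivars: Sequence[CultivarSpec],
                     scene: SceneSpec, out_dir: Path | str,
                     write_depth: bool = True) -> pd.DataFrame:
    """Render a full multi-cultivar dataset to disk and return its manifest.

    Sessions 1..7 are balanced per cultivar (round robin).  Writes RGB PNGs,
    16-bit depth PNGs, a ``manifest.csv`` with columns (id, cultivar, session,
    rgb_path, depth_path, lfw_g, ldw_g, la_cm2) and a ``generation.yaml``
    recording the scene and cultivar parameters.  Deterministic per scene seed.
    """
    if n_per_cultivar < N_SESSIONS:
        raise DomainError(
            f"n_per_cultivar must be >= {N_SESSIONS} so every session is covered")
    out = Path(out_dir)
    try:
        (out / "rgb").mkdir(parents=True, exist_ok=True)
        (out / "depth").mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable out_dir
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    rows = []
    idx = 0
    for cultivar in cultivars:
        for j in range(n_per_cultivar):
            session = (j % N_SESSIONS) + 1
            sample_scene = dataclasses.replace(
                scene, rng_seed=_sample_seed(scene.rng_seed, idx))
            sample = render_plant(cultivar, session, sample_scene)
            sid = f"{cultivar.name.lower()}_{j:04d}"
            rgb_path = out / "rgb" / f"{sid}.png"
            Image.fromarray(sample.rgb).save(rgb_path)
            depth_path = ""
            if write_depth:
                depth_path = str(Path("depth") / f"{sid}.png")
                save_depth_png(sample.depth, out / depth_path)
            rows.append({
                "id": sid,
                "cultivar": cultivar.name,
                "session": session,
                "rgb_path": str(Path("rgb") / f"{sid}.png"),
                "depth_path": depth_path,
                "lfw_g": sample.traits.lfw,
                "ldw_g": sample.traits.ldw,
                "la_cm2": sample.traits.la,
            })
            idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False, float_format="%.6f")
    params = {
        "scene": dataclasses.asdict(scene),
        "cultivars": [dataclasses.asdict(c) for c in cultivars],
        "n_per_cultivar": n_per_cultivar,
    }
    (out / "generation.yaml").write_text(yaml.safe_dump(params, sort_keys=True))
    return manifest
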