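"""Raster containers and file I/O.

Rasters are plain numpy arrays in (row, col) convention, origin top-left.
TIFF is read/written with tifffile, PNG with Pillow; an optional affine
geotransform (GDAL-style 6-tuple) is passed through untouched via a JSON
sidecar — no CRS handling or reprojection is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .legend import DEFAULT_LEGEND, ClassLegend


@dataclass
class SceneRaster:
    """3-band 8-bit scene image.

    pixels: (H, W, 3) uint8 array; geotransform: optional GDAL affine
    6-tuple (x0, dx, rx, y0, ry, dy); resolution_m: optional meters/pixel.
    """

    pixels: np.ndarray
    geotransform: tuple[float, ...] | None = None
    resolution_m: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"scene pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("scene must have positive height and width")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("scene intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelMask:
    """Per-pixel class indices with an attached legend.

    classes: (H, W) integer array with values in {0..C-1}.
    """

    classes: np.ndarray
    legend: ClassLegend = field(default_factory=lambda: DEFAULT_LEGEND)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError(f"label mask must be 2-D, got shape {self.classes.shape}")
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        if self.classes.size and (
            self.classes.min() < 0 or self.classes.max() >= self.legend.num_classes
        ):
            raise ValueError(
                f"label values must lie in [0, {self.legend.num_classes - 1}]"
            )
        self.classes = self.classes.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


def encode_labels(color_mask: SceneRaster | np.ndarray, legend: ClassLegend = DEFAULT_LEGEND) -> LabelMask:
    """Map a color-rendered mask to class indices via exact legend-color match.

    Every pixel must match a legend color exactly; otherwise an error names
    the offending colors and how many pixels carry each.
    """
    rgb = color_mask.pixels if isinstance(color_mask, SceneRaster) else np.asarray(color_mask)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("color mask must be (H, W, 3)")
    h, w = rgb.shape[:2]
    # pack RGB into a single int for fast exact matching
    packed = (
        rgb[..., 0].astype(np.uint32) << 16
        | rgb[..., 1].astype(np.uint32) << 8
        | rgb[..., 2].astype(np.uint32)
    )
    out = np.full((h, w), 255, dtype=np.uint8)
    matched = np.zeros((h, w), dtype=bool)
    for i, (r, g, b) in enumerate(legend.colors):
        key = (r << 16) | (g << 8) | b
        hit = packed == key
        out[hit] = i
        matched |= hit
    if not matched.all():
        bad = packed[~matched]
        uniq, counts = np.unique(bad, return_counts=True)
        detail = ", ".join(
            f"rgb({v >> 16}, {(v >> 8) & 255}, {v & 255}): {c} px"
            for v, c in zip(uniq.tolist(), counts.tolist())
        )
        raise ValueError(
            f"{int((~matched).sum())} pixel(s) match no legend color — {detail}"
        )
    return LabelMask(out, legend)


def decode_labels(mask: LabelMask) -> SceneRaster:
    """Render class indices back to the legend's display colors."""
    palette = np.asarray(mask.legend.colors, dtype=np.uint8)
    return SceneRaster(palette[mask.classes])


# ---------------------------------------------------------------------------
# file I/O


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def write_scene(path: str | Path, scene: SceneRaster) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, scene.pixels, photometric="rgb")
    else:
        Image.fromarray(scene.pixels).save(path)
    if scene.geotransform is not None or scene.resolution_m is not None:
        _sidecar(path).write_text(
            json.dumps(
                {
                    "geotransform": list(scene.geotransform) if scene.geotransform else None,
                    "resolution_m": scene.resolution_m,
                }
            )
        )


def read_scene(path: str | Path) -> SceneRaster:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    gt, res = None, None
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
        gt = tuple(meta["geotransform"]) if meta.get("geotransform") else None
        res = meta.get("resolution_m")
    return SceneRaster(arr, geotransform=gt, resolution_m=res)


def write_mask(path: str | Path, mask: LabelMask) -> None:
    """Write class indices as a single-band 8-bit raster plus legend sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.classes)
    else:
        Image.fromarray(mask.classes, mode="L").save(path)
    mask.legend.to_json(path.with_suffix(path.suffix + ".legend.json"))


def read_mask(path: str | Path, legend: ClassLegend | None = None) -> LabelMask:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    if legend is None:
        legend_path = path.with_suffix(path.suffix + ".legend.json")
        legend = ClassLegend.from_json(legend_path) if legend_path.exists() else DEFAULT_LEGEND
    return LabelMask(arr.astype(np.uint8), legend)


def write_probability_map(path: str | Path, probs: np.ndarray) -> None:
    """Write a (H, W, C) probability stack as a multi-band float32 TIFF."""
    probs = np.asarray(probs, dtype=np.float32)
    if probs.ndim != 3:
        raise ValueError("probability map must be (H, W, C)")
    tifffile.imwrite(Path(path), np.moveaxis(probs, 2, 0))


def read_probability_map(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 3:
        raise ValueError("probability map file must hold a multi-band stack")
    return np.moveaxis(arr, 0, 2).astype(np.float32)


def render_map(path: str | Path, mask: LabelMask) -> None:
    """Write a color PNG of the mask using its legend."""
    Image.fromarray(decode_labels(mask).pixels).save(Path(path))
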