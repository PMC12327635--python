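"""Synthetic scene generator.

Produces co-registered (SceneRaster, LabelMask) pairs with the spatial
statistics the segmentation pipeline assumes: six land-cover classes with
controllable area fractions (mangroves around a quarter of the scene by
default), spatially coherent patches from a smoothed Gaussian random field,
aquaculture as jittered rectangular pond grids, water as a connected sinuous
river band, and per-class mean colors with i.i.d. Gaussian pixel noise
clipped to the 8-bit range.

Label geometry is synthesized as follows: aquaculture ponds are pasted
first as rectangles on a jittered grid inside a randomly placed zone; the
remaining pixels are ranked by a smoothed Gaussian field and split at the
renormalized target quantiles, which makes realized fractions near-exact;
a dilated random-walk river is overlaid last and kept to a few percent of
the scene so it cannot push any fraction outside tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .legend import DEFAULT_LEGEND, ClassLegend
from .raster import LabelMask, SceneRaster

#: Class indices with fixed geometric roles in the default legend.
AQUACULTURE = 3
WATER = 5

#: Default area fractions: three mangrove classes jointly ~25%, aquaculture
#: and open water dominating the rest, as in a delta land-cover scene.
DEFAULT_FRACTIONS = (0.10, 0.10, 0.05, 0.30, 0.05, 0.40)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene.

    class_fractions must be non-negative and sum to 1; color_means is one
    RGB triple per class in [0, 255]; color_sd is the per-band Gaussian
    noise sd; texture_scale (pixels) sets the correlation length of the
    patch-forming random field.
    """

    height: int = 512
    width: int = 512
    class_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    color_means: tuple[tuple[float, float, float], ...] = DEFAULT_LEGEND.colors
    color_sd: float = 10.0
    texture_scale: float = 16.0
    seed: int = 0
    legend: ClassLegend = field(default=DEFAULT_LEGEND, compare=False)

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("scene must be at least 32x32 pixels")
        f = np.asarray(self.class_fractions, dtype=float)
        if f.ndim != 1 or len(f) != self.legend.num_classes:
            raise ValueError(
                f"need {self.legend.num_classes} class fractions, got {len(f)}"
            )
        if (f < 0).any():
            raise ValueError("class fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {f.sum()!r}")
        if len(self.color_means) != self.legend.num_classes:
            raise ValueError("need one color mean per class")
        cm = np.asarray(self.color_means, dtype=float)
        if cm.min() < 0 or cm.max() > 255:
            raise ValueError("color means must lie in [0, 255]")
        if self.color_sd < 0:
            raise ValueError("color_sd must be non-negative")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be positive")


def _pond_mask(h: int, w: int, target: int, rng: np.random.Generator) -> np.ndarray:
    """Union of jittered grid rectangles covering ~target pixels."""
    mask = np.zeros((h, w), dtype=bool)
    if target <= 0:
        return mask
    cell = max(8, int(round(min(h, w) / 12)))
    fill = 0.70  # pond area per grid cell after margins
    zone_area = min(h * w, int(target / fill) + cell * cell)
    # zone rectangle with aspect near the scene's, placed at random
    zh = min(h, max(cell, int(round(np.sqrt(zone_area * h / w)))))
    zw = min(w, max(cell, int(round(zone_area / zh))))
    r0 = int(rng.integers(0, h - zh + 1))
    c0 = int(rng.integers(0, w - zw + 1))
    covered = 0
    for rr in range(r0, r0 + zh - cell + 1, cell):
        for cc in range(c0, c0 + zw - cell + 1, cell):
            if covered >= target:
                return mask
            jr = int(rng.integers(0, 3))
            jc = int(rng.integers(0, 3))
            pr0, pc0 = rr + 1 + jr, cc + 1 + jc
            pr1 = min(rr + cell - 1, pr0 + cell - 3)
            pc1 = min(cc + cell - 1, pc0 + cell - 3)
            if pr1 > pr0 and pc1 > pc0:
                mask[pr0:pr1, pc0:pc1] = True
                covered = int(mask.sum())
    return mask


def _river_mask(h: int, w: int, max_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Connected sinuous band spanning the full width."""
    width_px = int(np.clip(round(max_frac * h), 2, max(2, h // 8)))
    walk = np.cumsum(rng.normal(0.0, h / 60.0, size=w))
    center = gaussian_filter1d(walk, sigma=max(2.0, w / 40.0), mode="nearest")
    center = center - center.mean() + h / 2.0
    lo, hi = width_px, h - width_px
    center = np.clip(center, lo, hi)
    rows = np.arange(h)[:, None]
    return np.abs(rows - center[None, :]) <= width_px / 2.0


def generate_scene(spec: SceneSpec) -> tuple[SceneRaster, LabelMask]:
    """Generate a (scene image, label mask) pair. Deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    n = h * w
    fractions = np.asarray(spec.class_fractions, dtype=float)
    labels = np.empty((h, w), dtype=np.uint8)

    constant = np.flatnonzero(fractions >= 1.0 - 1e-12)
    if constant.size:
        labels[:] = constant[0]
    else:
        # 1) aquaculture pond grid
        ponds = _pond_mask(h, w, int(round(fractions[AQUACULTURE] * n)), rng)
        # 2) remaining pixels: smoothed-field quantile assignment
        labels[:] = 0
        labels[ponds] = AQUACULTURE
        others = [k for k in range(len(fractions)) if k != AQUACULTURE]
        free = ~ponds
        n_free = int(free.sum())
        if n_free:
            fld = gaussian_filter(
                rng.normal(size=(h, w)), sigma=spec.texture_scale, mode="reflect"
            )
            order = np.argsort(fld[free], kind="stable")
            other_frac = fractions[others]
            tot = other_frac.sum()
            share = other_frac / tot if tot > 0 else np.full(len(others), 1 / len(others))
            bounds = np.round(np.cumsum(share) * n_free).astype(int)
            flat = np.zeros(n_free, dtype=np.uint8)
            start = 0
            for cls, stop in zip(others, bounds):
                flat[order[start:stop]] = cls
                start = stop
            labels[free] = flat
        # 3) sinuous river overlay (small, so fractions stay within tolerance)
        if 0 < fractions[WATER]:
            river = _river_mask(h, w, min(0.03, fractions[WATER] / 4.0), rng)
            labels[river] = WATER

    colors = np.asarray(spec.color_means, dtype=float)
    image = colors[labels] + rng.normal(0.0, spec.color_sd, size=(h, w, 3))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return (
        SceneRaster(image, resolution_m=5.0),
        LabelMask(labels, spec.legend),
    )


def perturb_labels(mask: LabelMask, flip_rate: float, seed: int) -> LabelMask:
    """Reassign exactly round(flip_rate * N) pixels to a uniformly random
    *different* class — a controllable stand-in for imperfect predictions.
    """
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flat = mask.classes.ravel().copy()
    n = flat.size
    k = int(round(flip_rate * n))
    if k:
        idx = rng.choice(n, size=k, replace=False)
        c = mask.legend.num_classes
        # old + U{1..C-1} mod C is uniform over the other C-1 classes
        flat[idx] = (flat[idx] + rng.integers(1, c, size=k)) % c
    return LabelMask(flat.reshape(mask.shape), mask.legend)
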