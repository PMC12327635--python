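"""Tiling, augmentation, train/validation split and stitching.

Tiles are cut on a non-overlapping grid (0-based row/col origins, half-open
extents); partial edge tiles are dropped rather than padded so class
statistics are not contaminated. Augmentation is restricted to the
label-preserving, interpolation-free dihedral transforms (flips and 90°
rotations) applied identically to image and mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import LabelMask, SceneRaster


@dataclass
class TileSet:
    """Aligned image/mask tiles with their source-raster origins."""

    images: list[np.ndarray]   # each (ts, ts, 3) uint8
    masks: list[np.ndarray]    # each (ts, ts) uint8
    origins: list[tuple[int, int]]
    tile_size: int

    def __post_init__(self) -> None:
        if len(self.images) != len(self.masks) or len(self.images) != len(self.origins):
            raise ValueError("images, masks and origins must be index-aligned")
        ts = self.tile_size
        for im, mk in zip(self.images, self.masks):
            if im.shape[:2] != (ts, ts) or mk.shape != (ts, ts):
                raise ValueError("all tiles must be tile_size x tile_size")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices: list[int] | np.ndarray) -> "TileSet":
        idx = list(np.asarray(indices, dtype=int))
        return TileSet(
            images=[self.images[i] for i in idx],
            masks=[self.masks[i] for i in idx],
            origins=[self.origins[i] for i in idx],
            tile_size=self.tile_size,
        )


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint, exhaustive train/validation tile indices."""

    train_indices: tuple[int, ...]
    val_indices: tuple[int, ...]
    ratio: float
    seed: int


def patchify(image: SceneRaster, mask: LabelMask, tile_size: int = 256) -> TileSet:
    """Cut image and mask into a non-overlapping grid of tiles.

    Tile count is floor(H/ts) * floor(W/ts); partial edge tiles are dropped.
    """
    if image.shape != mask.shape:
        raise ValueError(
            f"image {image.shape} and mask {mask.shape} dimensions differ"
        )
    if tile_size < 1:
        raise ValueError("tile_size must be positive")
    h, w = image.shape
    images, masks, origins = [], [], []
    for r in range(0, (h // tile_size) * tile_size, tile_size):
        for c in range(0, (w // tile_size) * tile_size, tile_size):
            images.append(image.pixels[r : r + tile_size, c : c + tile_size].copy())
            masks.append(mask.classes[r : r + tile_size, c : c + tile_size].copy())
            origins.append((r, c))
    return TileSet(images, masks, origins, tile_size)


# The 8 dihedral transforms of a square; index 0 is the identity.
def _dihedral(arr: np.ndarray, k: int) -> np.ndarray:
    if k >= 4:
        arr = arr[:, ::-1]
    return np.rot90(arr, k % 4)


def augment(tiles: TileSet, seed: int = 0, factor: float | None = None,
            total: int | None = None) -> TileSet:
    """Append flip/rotation copies until the requested tile count is reached.

    Specify either a multiplicative `factor` (>= 1) or an absolute `total`.
    Appended copies cycle through the input tiles with a seeded random
    non-identity dihedral transform applied to image and mask together.
    """
    n = len(tiles)
    if n == 0:
        raise ValueError("cannot augment an empty tile set")
    if total is None:
        if factor is None:
            raise ValueError("specify factor or total")
        if factor < 1:
            raise ValueError("augmentation factor must be >= 1")
        total = int(round(factor * n))
    if total < n:
        raise ValueError(f"requested total {total} is below the input count {n}")
    rng = np.random.default_rng(seed)
    images = list(tiles.images)
    masks = list(tiles.masks)
    origins = list(tiles.origins)
    i = 0
    while len(images) < total:
        src = i % n
        k = int(rng.integers(1, 8))  # never the identity
        images.append(np.ascontiguousarray(_dihedral(tiles.images[src], k)))
        masks.append(np.ascontiguousarray(_dihedral(tiles.masks[src], k)))
        origins.append(tiles.origins[src])
        i += 1
    return TileSet(images, masks, origins, tiles.tile_size)


def split_tiles(tiles: TileSet | int, ratio: float = 0.75, seed: int = 0) -> SplitAssignment:
    """Seeded uniform split: first floor(ratio*n) of a random permutation
    train, the rest validation.
    """
    n = tiles if isinstance(tiles, int) else len(tiles)
    if n == 0:
        raise ValueError("cannot split an empty tile set")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratio * n))
    return SplitAssignment(
        train_indices=tuple(int(i) for i in perm[:n_train]),
        val_indices=tuple(int(i) for i in perm[n_train:]),
        ratio=ratio,
        seed=seed,
    )


def stitch(prob_tiles: list[np.ndarray], origins: list[tuple[int, int]],
           out_shape: tuple[int, int]) -> np.ndarray:
    """Place per-tile (ts, ts, C) probability stacks at their origins.

    Returns an (H, W, C) float32 array; pixels not covered by any tile are
    flagged no-data as NaN. Overlapping tiles are an error.
    """
    if len(prob_tiles) != len(origins):
        raise ValueError("one origin per tile required")
    if not prob_tiles:
        raise ValueError("no tiles to stitch")
    c = prob_tiles[0].shape[2]
    h, w = out_shape
    out = np.full((h, w, c), np.nan, dtype=np.float32)
    covered = np.zeros((h, w), dtype=bool)
    for tile, (r, cc) in zip(prob_tiles, origins):
        th, tw = tile.shape[:2]
        if r < 0 or cc < 0 or r + th > h or cc + tw > w:
            raise ValueError(f"tile at origin ({r}, {cc}) falls outside {out_shape}")
        if covered[r : r + th, cc : cc + tw].any():
            raise ValueError(f"tile at origin ({r}, {cc}) overlaps a previous tile")
        out[r : r + th, cc : cc + tw] = tile
        covered[r : r + th, cc : cc + tw] = True
    return out
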