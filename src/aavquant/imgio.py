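"""Image stack I/O, tile stitching and maximum projection.

A section is captured as a grid of multi-channel z-stacks ("tiles") with a
fixed fractional overlap between neighbours.  Stack processing operates on
maximum projections; per-tile projections are stitched into a single mosaic
per channel that carries an affine pixel<->micron transform so detections can
be reported in the well frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

CHANNELS = ("hoechst", "neun", "gfp")


@dataclass
class MultiChannelStack:
    """Registered 3-D intensity arrays, one per channel, shape (z, y, x)."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 3 or shape[0] < 1:
            raise ValueError("channel arrays must be 3-D (z, y, x) with z >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_z(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]


@dataclass(frozen=True)
class TilePosition:
    row: int
    col: int
    x_um: float  # well-frame position of the tile's top-left corner
    y_um: float


@dataclass
class TileLayout:
    """Grid positions and well-frame offsets of the tiles of one section."""

    tiles: list[TilePosition]
    tile_size_px: int
    overlap_fraction: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        if self.tile_size_px < 1:
            raise ValueError("tile_size_px must be >= 1")

    @property
    def stride_px(self) -> int:
        return int(round(self.tile_size_px * (1.0 - self.overlap_fraction)))

    @property
    def n_rows(self) -> int:
        return 1 + max(t.row for t in self.tiles)

    @property
    def n_cols(self) -> int:
        return 1 + max(t.col for t in self.tiles)

    def position(self, row: int, col: int) -> TilePosition:
        for t in self.tiles:
            if t.row == row and t.col == col:
                return t
        raise KeyError(f"no tile at grid position (row={row}, col={col})")


@dataclass
class Mosaic:
    """Stitched per-channel 2-D images with an invertible px<->um transform.

    Pixel (0, 0) is the mosaic top-left; y grows downward.  The well frame
    shares the same origin and orientation, so the transform is a pure scale
    plus the ``origin_um`` offset.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def px_to_um(self, col: float, row: float) -> tuple[float, float]:
        return (
            self.origin_um[0] + col * self.pixel_size_um,
            self.origin_um[1] + row * self.pixel_size_um,
        )

    def um_to_px(self, x_um: float, y_um: float) -> tuple[float, float]:
        return (
            (x_um - self.origin_um[0]) / self.pixel_size_um,
            (y_um - self.origin_um[1]) / self.pixel_size_um,
        )


def max_project(stack: MultiChannelStack) -> dict[str, np.ndarray]:
    """Per-channel maximum-intensity projection along z.

    Each output pixel is the maximum over all optical slices at that (y, x).
    Idempotent for single-slice stacks.
    """
    return {name: arr.max(axis=0) for name, arr in stack.channels.items()}


def stitch(
    tiles: dict[tuple[int, int], dict[str, np.ndarray]],
    layout: TileLayout,
) -> Mosaic:
    """Stitch per-tile 2-D channel images into one mosaic per channel.

    In overlap zones the per-pixel maximum of the contributing tiles is
    taken, which is order-independent and preserves dim nuclei at seams.
    """
    grid = {(t.row, t.col): t for t in layout.tiles}
    for pos in grid:
        if pos not in tiles:
            raise ValueError(f"missing tile at grid position (row={pos[0]}, col={pos[1]})")
    stride = layout.stride_px
    n_rows, n_cols = layout.n_rows, layout.n_cols
    h = stride * (n_rows - 1) + layout.tile_size_px
    w = stride * (n_cols - 1) + layout.tile_size_px
    channel_names = list(next(iter(tiles.values())).keys())
    out: dict[str, np.ndarray] = {}
    for name in channel_names:
        dtype = next(iter(tiles.values()))[name].dtype
        mosaic = np.zeros((h, w), dtype=dtype)
        for (row, col), imgs in tiles.items():
            if (row, col) not in grid:
                continue
            y0, x0 = row * stride, col * stride
            img = imgs[name]
            region = mosaic[y0 : y0 + img.shape[0], x0 : x0 + img.shape[1]]
            np.maximum(region, img, out=region)
        out[name] = mosaic
    origin = min((t.y_um, t.x_um) for t in layout.tiles)
    return Mosaic(channels=out, pixel_size_um=layout.pixel_size_um, origin_um=(origin[1], origin[0]))


def subtract_background(image: np.ndarray, constant: float) -> np.ndarray:
    """Subtract a constant per-tile background (brightfield-style), clipping at 0.

    Off by default in the pipeline; the constant is a free parameter because
    no instrument-specific correction profile is modelled.
    """
    out = image.astype(np.float64) - float(constant)
    np.clip(out, 0.0, None, out=out)
    return out


# ---------------------------------------------------------------------------
# File I/O: multi-page TIFF per channel plus a plain-text layout table.

def write_stack(stack: MultiChannelStack, directory: str, prefix: str = "tile") -> list[str]:
    """Write one multi-page TIFF per channel; returns the written paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, arr in stack.channels.items():
        path = os.path.join(directory, f"{prefix}_{name}.tif")
        tifffile.imwrite(
            path,
            arr,
            metadata={"pixel_size_um": stack.pixel_size_um, "z_step_um": stack.z_step_um},
        )
        paths.append(path)
    return paths


def read_stack(
    directory: str,
    prefix: str = "tile",
    channels: tuple[str, ...] = CHANNELS,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> MultiChannelStack:
    arrays: dict[str, np.ndarray] = {}
    meta_px, meta_dz = pixel_size_um, z_step_um
    for name in channels:
        path = os.path.join(directory, f"{prefix}_{name}.tif")
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            if arr.ndim == 2:
                arr = arr[None]
            arrays[name] = arr
            if meta_px is None or meta_dz is None:
                md = tf.shaped_metadata[0] if tf.shaped_metadata else {}
                meta_px = meta_px if meta_px is not None else float(md.get("pixel_size_um", 1.0))
                meta_dz = meta_dz if meta_dz is not None else float(md.get("z_step_um", 1.0))
    return MultiChannelStack(channels=arrays, pixel_size_um=meta_px, z_step_um=meta_dz)


def write_layout(layout: TileLayout, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tile_size_px={layout.tile_size_px} overlap_fraction={layout.overlap_fraction} "
                 f"pixel_size_um={layout.pixel_size_um}\n")
        fh.write("row\tcol\tx_um\ty_um\n")
        for t in sorted(layout.tiles, key=lambda t: (t.row, t.col)):
            fh.write(f"{t.row}\t{t.col}\t{t.x_um:.6f}\t{t.y_um:.6f}\n")


def read_layout(path: str) -> TileLayout:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        fh.readline()  # column names
        tiles = []
        for line in fh:
            row, col, x_um, y_um = line.split("\t")
            tiles.append(TilePosition(int(row), int(col), float(x_um), float(y_um)))
    return TileLayout(
        tiles=tiles,
        tile_size_px=int(meta["tile_size_px"]),
        overlap_fraction=float(meta["overlap_fraction"]),
        pixel_size_um=float(meta["pixel_size_um"]),
    )


def write_mosaic(mosaic: Mosaic, directory: str, prefix: str = "mosaic") -> list[str]:
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, arr in mosaic.channels.items():
        path = os.path.join(directory, f"{prefix}_{name}.tif")
        tifffile.imwrite(path, arr, metadata={"pixel_size_um": mosaic.pixel_size_um,
                                              "origin_um": list(mosaic.origin_um)})
        paths.append(path)
    return paths
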