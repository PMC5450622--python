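"""Grayscale image-stack I/O with voxel-geometry metadata.

A stack is a three-dimensional grid of intensity values, ``data[y, x, z]``
(axis 0 = image row, axis 1 = image column, axis 2 = slice), read from and
written to multi-page grayscale TIFF files. Voxel geometry records the
physical size of one voxel in micrometres; confocal z-stacks are typically
anisotropic, with the z-step larger than the in-plane pixel pitch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "StackReadError",
    "InconsistentPagesError",
    "MultiChannelError",
    "UnsupportedBitDepthError",
    "read_stack",
    "write_stack",
]


class StackReadError(ValueError):
    """Base class for stack-reading failures."""


class InconsistentPagesError(StackReadError):
    """TIFF pages do not all share the same dimensions."""


class MultiChannelError(StackReadError):
    """TIFF pages are RGB or multi-channel; only grayscale is supported."""


class UnsupportedBitDepthError(StackReadError):
    """Sample format is not 8-, 12- or 16-bit unsigned grayscale."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel size in micrometres per axis.

    Parameters
    ----------
    dx, dy : float
        In-plane pixel pitch (x = column direction, y = row direction).
    dz : float
        Spacing between consecutive slices.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel dimensions must all be positive")

    @classmethod
    def default(cls) -> "VoxelGeometry":
        """Relative-unit fallback: unit in-plane pitch, z-step twice that.

        Mirrors the common confocal acquisition convention of choosing a
        z-step equal to double the in-plane resolution.
        """
        return cls(1.0, 1.0, 2.0)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)


_ALLOWED_DEPTHS = (8, 12, 16)


@dataclass
class ImageStack:
    """An M×N×Z grayscale voxel grid with bit depth and voxel geometry.

    ``data`` is indexed ``[y, x, z]``; voxel centres sit at integer
    coordinates, 0-based. ``bit_depth`` is one of 8, 12 or 16; 12-bit data
    lives in a 16-bit container with values validated against 4095.
    """

    data: np.ndarray
    bit_depth: int = 8
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry.default)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D, got {self.data.ndim}-D")
        if self.bit_depth not in _ALLOWED_DEPTHS:
            raise UnsupportedBitDepthError(
                f"bit depth must be one of {_ALLOWED_DEPTHS}, got {self.bit_depth}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("stack data must be an integer array")
        if self.data.size and (self.data.min() < 0 or self.data.max() > self.max_value):
            raise ValueError(
                f"values must lie in [0, {self.max_value}] for {self.bit_depth}-bit data"
            )

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dims(self) -> tuple[int, int, int]:
        """(M, N, Z) = (rows, columns, slices)."""
        m, n, z = self.data.shape
        return (m, n, z)

    def slice(self, z: int) -> np.ndarray:
        """The z-th M×N image plane."""
        return self.data[:, :, z]


def _pages_to_volume(pages: list[np.ndarray]) -> np.ndarray:
    first = pages[0]
    for i, p in enumerate(pages):
        if p.ndim == 3:
            raise MultiChannelError(
                f"page {i} has {p.shape[-1]} channels; only grayscale stacks are supported"
            )
        if p.shape != first.shape:
            raise InconsistentPagesError(
                f"page {i} has shape {p.shape}, expected {first.shape}"
            )
    return np.stack(pages, axis=-1)


def _parse_geometry_tag(description: str) -> VoxelGeometry | None:
    fields: dict[str, float] = {}
    for token in description.replace("\n", " ").split():
        if "=" not in token:
            continue
        key, _, val = token.partition("=")
        try:
            fields[key.strip()] = float(val)
        except ValueError:
            continue
    if {"dx", "dy", "dz"} <= fields.keys():
        return VoxelGeometry(fields["dx"], fields["dy"], fields["dz"])
    return None


def read_stack(path, geometry: VoxelGeometry | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Bit depth is inferred from the container dtype (8 → uint8, 16 → uint16);
    12-bit data stored in a 16-bit container is accepted when the file's
    geometry tag or the caller declares ``bit_depth=12`` — here, when the
    metadata written by :func:`write_stack` says so. If no geometry is given
    and none is recorded in the file, a relative-unit default of
    (1, 1, 2) is used with a warning.
    """
    try:
        tif = tifffile.TiffFile(path)
    except FileNotFoundError:
        raise
    with tif:
        pages = [page.asarray() for page in tif.pages]
        if not pages:
            raise StackReadError(f"{path}: TIFF contains no pages")
        volume = _pages_to_volume(pages)
        description = tif.pages[0].description or ""

    if volume.dtype == np.uint8:
        bit_depth = 8
    elif volume.dtype == np.uint16:
        bit_depth = 16
    else:
        raise UnsupportedBitDepthError(
            f"{path}: unsupported sample dtype {volume.dtype}; "
            "expected 8- or 16-bit unsigned grayscale"
        )

    declared = _parse_declared_depth(description)
    if declared is not None:
        if declared == 12 and bit_depth != 16:
            raise UnsupportedBitDepthError(
                f"{path}: 12-bit data must be stored in a 16-bit container"
            )
        bit_depth = declared

    if geometry is None:
        geometry = _parse_geometry_tag(description)
    if geometry is None:
        geometry = VoxelGeometry.default()
        warnings.warn(
            f"{path}: no voxel geometry supplied or recorded; "
            "defaulting to relative units (dx=1, dy=1, dz=2)",
            stacklevel=2,
        )
        logger.warning("%s: using default relative voxel geometry (1, 1, 2)", path)

    return ImageStack(volume, bit_depth=bit_depth, geometry=geometry)


def _parse_declared_depth(description: str) -> int | None:
    for token in description.replace("\n", " ").split():
        if token.startswith("bit_depth="):
            try:
                depth = int(token.split("=", 1)[1])
            except ValueError:
                return None
            if depth not in _ALLOWED_DEPTHS:
                raise UnsupportedBitDepthError(f"declared bit depth {depth} unsupported")
            return depth
    return None


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as an uncompressed multi-page grayscale TIFF.

    Page *i* holds slice *i*; values are bit-exact. Voxel geometry and
    declared bit depth go into the ImageDescription tag as ``key=value``
    text so a bare :func:`read_stack` recovers them.
    """
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    g = stack.geometry
    description = (
        f"dx={g.dx} dy={g.dy} dz={g.dz} bit_depth={stack.bit_depth}"
    )
    pages = np.moveaxis(stack.data.astype(dtype, copy=False), -1, 0)
    tifffile.imwrite(path, pages, description=description, photometric="minisblack")
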