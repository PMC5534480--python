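"""On-disk format core: pyramid geometry, block addressing, metadata.

Conventions
-----------
* ``dims`` and all coordinates are ``(x, y, z)`` with x = slice width,
  y = slice height, z = slice index; 0-based, half-open intervals.
* In-memory voxel arrays are numpy arrays of shape ``(z, y, x)`` (z-major,
  matching the page order of the multi-page TIFF block container).
* Level 1 is full resolution; level ``n+1`` halves every axis of level ``n``
  with ceiling, so no voxel is ever dropped.  The pyramid stops at the first
  level whose every axis is smaller than the block edge ``B``, which
  guarantees the coarsest level fits in a single block.
* Blocks are ``B``×``B``×``B`` cubes; boundary blocks are zero-padded.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import GeometryError, MetadataError, RangeError

#: default block edge in voxels
DEFAULT_BLOCK_SIZE = 512

#: file name of the JSON dataset descriptor inside the storage root
METADATA_FILENAME = "dataset.json"

_MANDATORY_FIELDS = (
    "dims_x", "dims_y", "dims_z",
    "resolution_x", "resolution_y", "resolution_z",
    "bit_depth", "block_size", "n_levels", "file_format", "storage_root",
)


def _check_dims(dims) -> tuple[int, int, int]:
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise GeometryError(f"dims must be three positive voxel counts, got {dims}")
    return dims


def _check_block_size(b: int) -> int:
    b = int(b)
    if b < 8 or (b & (b - 1)) != 0:
        raise GeometryError(f"block_size must be a power of two >= 8, got {b}")
    return b


class LevelGeometry(NamedTuple):
    """Geometry of one pyramid level."""

    level: int                      # 1-based; 1 = full resolution
    dims: tuple[int, int, int]      # voxel counts (x, y, z) at this level
    grid: tuple[int, int, int]      # block counts per axis, ceil(dims / B)

    @property
    def n_blocks(self) -> int:
        return self.grid[0] * self.grid[1] * self.grid[2]


class BlockIndex(NamedTuple):
    """Address of one block: pyramid level plus 0-based block coordinates."""

    level: int
    bx: int
    by: int
    bz: int

    def origin(self, block_size: int) -> tuple[int, int, int]:
        """Block origin in this level's voxel coordinates."""
        return (self.bx * block_size, self.by * block_size, self.bz * block_size)


@dataclass
class Block:
    """A B×B×B voxel cube; ``voxels`` has shape (B, B, B) = (z, y, x)."""

    index: BlockIndex
    voxels: np.ndarray

    def __post_init__(self):
        if self.voxels.ndim != 3 or len(set(self.voxels.shape)) != 1:
            raise GeometryError(f"block voxels must be cubic, got {self.voxels.shape}")


def compute_pyramid_levels(dims, block_size: int = DEFAULT_BLOCK_SIZE) -> list[LevelGeometry]:
    """Ceil-halve ``dims`` per axis until all three axes are below ``block_size``.

    Level 1 always has the input dims; the result is never empty — a volume
    already smaller than one block in every axis has exactly one level.
    """
    dims = _check_dims(dims)
    b = _check_block_size(block_size)
    levels = []
    cur = dims
    n = 1
    while True:
        grid = tuple(-(-d // b) for d in cur)
        levels.append(LevelGeometry(level=n, dims=cur, grid=grid))
        if all(d < b for d in cur):
            break
        cur = tuple(-(-d // 2) for d in cur)
        n += 1
    return levels


def block_grid(geom: LevelGeometry) -> tuple[int, int, int]:
    """Block counts per axis for a level (``ceil(dims / B)`` componentwise)."""
    return geom.grid


def padded_extent(geom: LevelGeometry, block_size: int) -> tuple[int, int, int]:
    """Voxel extent covered by the grid including boundary padding."""
    return tuple(g * block_size for g in geom.grid)


_BLOCK_PATH_RE = re.compile(
    r"^level_(\d+)/z(\d+)/y(\d+)/(\d+)_(\d+)_(\d+)\.tif$"
)


def block_path(idx: BlockIndex) -> str:
    """Relative on-disk path of a block below the storage root.

    Four directory levels: ``level_<L>/z<bz>/y<by>/<bx>_<by>_<bz>.tif``.
    The x_y_z file name times the block edge gives the block origin in
    level voxels.  Inverted exactly by :func:`parse_block_path`.
    """
    return f"level_{idx.level}/z{idx.bz}/y{idx.by}/{idx.bx}_{idx.by}_{idx.bz}.tif"


def parse_block_path(path: str) -> BlockIndex:
    """Inverse of :func:`block_path`."""
    m = _BLOCK_PATH_RE.match(str(path).replace("\\", "/"))
    if not m:
        raise RangeError(f"not a block path: {path!r}")
    level, bz, by, bx, by2, bz2 = (int(g) for g in m.groups())
    if by != by2 or bz != bz2:
        raise RangeError(f"inconsistent block path: {path!r}")
    return BlockIndex(level=level, bx=bx, by=by, bz=bz)


def check_block_index(idx: BlockIndex, levels: list[LevelGeometry]) -> LevelGeometry:
    """Validate an index against a pyramid; returns the level geometry."""
    if not 1 <= idx.level <= len(levels):
        raise RangeError(f"level {idx.level} outside pyramid of {len(levels)} levels")
    geom = levels[idx.level - 1]
    if not all(0 <= b < g for b, g in zip((idx.bx, idx.by, idx.bz), geom.grid)):
        raise RangeError(f"block {idx} outside grid {geom.grid} of level {idx.level}")
    return geom


@dataclass
class DatasetMetadata:
    """Descriptor of a brick dataset: everything needed to address any voxel.

    ``dims_*`` are level-1 voxel counts, ``resolution_*`` the level-1 voxel
    pitch in micrometres.  ``n_levels`` is redundant with the pyramid rule
    and validated against it.
    """

    dims_x: int
    dims_y: int
    dims_z: int
    resolution_x: float
    resolution_y: float
    resolution_z: float
    bit_depth: int
    block_size: int = DEFAULT_BLOCK_SIZE
    n_levels: int = 0
    file_format: str = "tif"
    storage_root: str = "."

    def __post_init__(self):
        _check_dims(self.dims)
        _check_block_size(self.block_size)
        if self.bit_depth not in (8, 16):
            raise MetadataError(f"bit_depth must be 8 or 16, got {self.bit_depth!r}")
        if any(r <= 0 for r in self.resolution):
            raise MetadataError(f"resolution must be positive, got {self.resolution}")
        expected = len(compute_pyramid_levels(self.dims, self.block_size))
        if self.n_levels == 0:
            self.n_levels = expected
        elif self.n_levels != expected:
            raise MetadataError(
                f"n_levels={self.n_levels} inconsistent with pyramid rule ({expected})"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.dims_x, self.dims_y, self.dims_z)

    @property
    def resolution(self) -> tuple[float, float, float]:
        return (self.resolution_x, self.resolution_y, self.resolution_z)

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def levels(self) -> list[LevelGeometry]:
        return compute_pyramid_levels(self.dims, self.block_size)

    def level_resolution(self, level: int) -> tuple[float, float, float]:
        """Voxel pitch in μm at a given level (doubles per level)."""
        f = 2 ** (level - 1)
        return tuple(r * f for r in self.resolution)


def write_metadata(meta: DatasetMetadata, path: str | Path) -> Path:
    """Serialize a descriptor to JSON.  ``path`` may be the storage root."""
    path = Path(path)
    if path.is_dir():
        path = path / METADATA_FILENAME
    payload = asdict(meta)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_metadata(path: str | Path) -> DatasetMetadata:
    """Parse a descriptor; unknown keys are ignored with a warning."""
    path = Path(path)
    if path.is_dir():
        path = path / METADATA_FILENAME
    if not path.exists():
        raise MetadataError(f"no dataset descriptor at {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise MetadataError(f"unparsable descriptor {path}: {e}") from e
    if not isinstance(raw, dict):
        raise MetadataError(f"descriptor {path} is not a JSON object")
    missing = [k for k in _MANDATORY_FIELDS if k not in raw]
    if missing:
        raise MetadataError(f"descriptor {path} missing mandatory field(s): {', '.join(missing)}")
    unknown = set(raw) - set(_MANDATORY_FIELDS)
    if unknown:
        warnings.warn(f"ignoring unknown metadata keys: {sorted(unknown)}", stacklevel=2)
    kwargs = {k: raw[k] for k in _MANDATORY_FIELDS}
    return DatasetMetadata(**kwargs)
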