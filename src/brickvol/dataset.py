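"""Dataset access: sequential block iteration and random ROI reads.

Random reads use the *read-crop* strategy: find the blocks overlapping the
query, fetch them (cache first, then storage), assemble them by position
and crop to the requested region.  A least-recently-used block cache makes
the overlapping reads typical of interactive browsing and of block-wise
transforms cheap without ever changing results — the cache affects I/O
counts only.
"""

from __future__ import annotations

from collections import OrderedDict
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import tifffile

from .errors import IntegrityError, RangeError
from .geometry import (
    BlockIndex,
    DatasetMetadata,
    LevelGeometry,
    block_path,
    check_block_index,
    padded_extent,
    read_metadata,
)


@dataclass
class ROI:
    """An axis-aligned query region in level-1 voxel coordinates.

    ``level`` may be an explicit pyramid level or ``"auto"``, in which case
    the coarsest-necessary level is chosen from a voxel budget.
    """

    origin: tuple[int, int, int]
    size: tuple[int, int, int]
    level: int | str = "auto"

    def __post_init__(self):
        self.origin = tuple(int(v) for v in self.origin)
        self.size = tuple(int(v) for v in self.size)
        if any(s < 1 for s in self.size):
            raise RangeError(f"ROI size must be >= 1 per axis, got {self.size}")
        if any(o < 0 for o in self.origin):
            raise RangeError(f"ROI origin must be >= 0, got {self.origin}")


class BlockCache:
    """LRU cache over block voxel arrays, keyed by :class:`BlockIndex`.

    ``capacity`` counts resident blocks; 0 disables caching.  A hit
    refreshes recency; inserting beyond capacity evicts exactly the least
    recently used entry.
    """

    def __init__(self, capacity: int = 512):
        if capacity < 0:
            raise ValueError("capacity must be >= 0")
        self.capacity = capacity
        self._entries: OrderedDict[BlockIndex, np.ndarray] = OrderedDict()
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, idx: BlockIndex) -> bool:
        return idx in self._entries

    def resident(self) -> set[BlockIndex]:
        return set(self._entries)

    def get(self, idx: BlockIndex) -> np.ndarray | None:
        """Return the cached voxels (refreshing recency) or None on a miss."""
        if idx in self._entries:
            self._entries.move_to_end(idx)
            self.hits += 1
            return self._entries[idx]
        self.misses += 1
        return None

    def put(self, idx: BlockIndex, voxels: np.ndarray) -> None:
        if self.capacity == 0:
            return
        if idx in self._entries:
            self._entries.move_to_end(idx)
            self._entries[idx] = voxels
            return
        while len(self._entries) >= self.capacity:
            self._entries.popitem(last=False)
        self._entries[idx] = voxels


class Dataset:
    """A reformatted brick dataset on disk, opened read-only."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.meta: DatasetMetadata = read_metadata(self.root)
        self.levels = self.meta.levels
        self.block_reads = 0  # storage (not cache) block fetches

    @property
    def block_size(self) -> int:
        return self.meta.block_size

    def level_geometry(self, level: int) -> LevelGeometry:
        if not 1 <= level <= len(self.levels):
            raise RangeError(f"level {level} outside pyramid of {len(self.levels)} levels")
        return self.levels[level - 1]

    def read_block(self, idx: BlockIndex) -> np.ndarray:
        """Load one block from storage as a (B, B, B) array."""
        check_block_index(idx, self.levels)
        path = self.root / block_path(idx)
        if not path.exists():
            raise IntegrityError(f"missing block file {path}")
        try:
            vox = tifffile.imread(path)
        except (OSError, ValueError) as e:
            raise IntegrityError(f"unreadable block file {path}: {e}") from e
        b = self.block_size
        if vox.shape != (b, b, b):
            raise IntegrityError(f"block {path} has shape {vox.shape}, expected {(b, b, b)}")
        self.block_reads += 1
        return vox

    def fetch_block(self, idx: BlockIndex, cache: BlockCache | None) -> np.ndarray:
        """Cache-first block fetch."""
        if cache is not None:
            vox = cache.get(idx)
            if vox is not None:
                return vox
        vox = self.read_block(idx)
        if cache is not None:
            cache.put(idx, vox)
        return vox

    # -- whole-dataset iteration ------------------------------------------

    def sequential_read(self, level: int,
                        visitor: Callable[[BlockIndex, np.ndarray], None],
                        workers: int = 1) -> int:
        """Visit every block of a level exactly once; returns the count.

        With ``workers == 1`` the order is deterministic (z, then y, then x
        outermost-to-innermost ... i.e. bz-major); with more workers the
        order is unspecified but the visited multiset is identical.
        """
        geom = self.level_geometry(level)
        indices = [BlockIndex(level, bx, by, bz)
                   for bz in range(geom.grid[2])
                   for by in range(geom.grid[1])
                   for bx in range(geom.grid[0])]

        def one(idx: BlockIndex) -> None:
            visitor(idx, self.read_block(idx))

        if workers <= 1:
            for idx in indices:
                one(idx)
        else:
            with ThreadPoolExecutor(max_workers=workers) as ex:
                list(ex.map(one, indices))
        return len(indices)

    # -- random (ROI) access ----------------------------------------------

    def read_region(self, level: int, origin, size,
                    cache: BlockCache | None = None) -> np.ndarray:
        """Read-crop an arbitrary region given in *level-L* voxel coordinates.

        The region must lie inside the padded extent of the level's block
        grid; padding voxels read as 0.  Returns shape (size_z, size_y,
        size_x).
        """
        geom = self.level_geometry(level)
        origin = tuple(int(v) for v in origin)
        size = tuple(int(v) for v in size)
        if any(s < 1 for s in size):
            raise RangeError(f"region size must be >= 1, got {size}")
        pad = padded_extent(geom, self.block_size)
        if any(o < 0 or o + s > p for o, s, p in zip(origin, size, pad)):
            raise RangeError(
                f"region origin={origin} size={size} outside padded extent {pad} "
                f"of level {level}"
            )
        b = self.block_size
        out = np.zeros((size[2], size[1], size[0]), dtype=self.meta.dtype)
        b_lo = [origin[a] // b for a in range(3)]
        b_hi = [(origin[a] + size[a] - 1) // b for a in range(3)]
        for bz in range(b_lo[2], b_hi[2] + 1):
            for by in range(b_lo[1], b_hi[1] + 1):
                for bx in range(b_lo[0], b_hi[0] + 1):
                    vox = self.fetch_block(BlockIndex(level, bx, by, bz), cache)
                    # overlap of this block with the query, in level voxels
                    lo = [max(origin[a], (bx, by, bz)[a] * b) for a in range(3)]
                    hi = [min(origin[a] + size[a], ((bx, by, bz)[a] + 1) * b)
                          for a in range(3)]
                    src = vox[lo[2] - bz * b: hi[2] - bz * b,
                              lo[1] - by * b: hi[1] - by * b,
                              lo[0] - bx * b: hi[0] - bx * b]
                    out[lo[2] - origin[2]: hi[2] - origin[2],
                        lo[1] - origin[1]: hi[1] - origin[1],
                        lo[0] - origin[0]: hi[0] - origin[0]] = src
        return out


def select_level(meta: DatasetMetadata, roi_size, budget: int | None = None) -> int:
    """Finest level whose scaled ROI voxel count fits a budget.

    Each level coarser than the last divides the ROI's voxel count by 8; the
    default budget is one block volume (B³ voxels).  Monotone: a larger ROI
    never maps to a finer level.  Clamped to the pyramid depth.
    """
    if budget is None:
        budget = meta.block_size ** 3
    if budget < 1:
        raise RangeError(f"budget must be >= 1, got {budget}")
    nvox = int(np.prod([int(s) for s in roi_size], dtype=np.int64))
    for level in range(1, meta.n_levels + 1):
        if nvox / 8 ** (level - 1) <= budget:
            return level
    return meta.n_levels


def read_roi(dataset: Dataset, roi: ROI, cache: BlockCache | None = None,
             budget: int | None = None) -> tuple[np.ndarray, int]:
    """Random read: ROI given at level-1 scale, served at the realized level.

    The realized level is the explicit ``roi.level`` or the automatic
    budget-based choice.  Level-1 coordinates map to level L by
    ``floor(origin / 2**(L-1))`` and ``ceil(size / 2**(L-1))``.  Returns the
    voxel array (z, y, x) and the realized level.
    """
    geom1 = dataset.level_geometry(1)
    pad1 = padded_extent(geom1, dataset.block_size)
    if any(o + s > p for o, s, p in zip(roi.origin, roi.size, pad1)):
        raise RangeError(
            f"ROI origin={roi.origin} size={roi.size} outside padded level-1 "
            f"extent {pad1}"
        )
    if roi.level == "auto":
        level = select_level(dataset.meta, roi.size, budget)
    else:
        level = int(roi.level)
        dataset.level_geometry(level)  # validates
    f = 2 ** (level - 1)
    origin = tuple(o // f for o in roi.origin)
    size = tuple(-(-s // f) for s in roi.size)
    # clamp to the level's padded extent (ceil mapping can overshoot by < 1 block)
    padL = padded_extent(dataset.level_geometry(level), dataset.block_size)
    size = tuple(min(s, p - o) for s, o, p in zip(size, origin, padL))
    return dataset.read_region(level, origin, size, cache), level
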