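"""Slice-sequence I/O: numbered 2D grayscale images forming a 3D volume.

The reformatter never holds a whole volume; it reads row strips of
individual slices.  For uncompressed TIFF slices the strip read goes
through ``tifffile.memmap`` so only the touched rows are paged in.
Non-TIFF inputs (PNG, BMP, ...) are converted to a temporary TIFF
sequence before reformatting.
"""

from __future__ import annotations

import re
import tempfile
import threading
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import BrickvolError, CorruptInputError

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NUM_RE = re.compile(r"(\d+)")


def natural_key(name: str):
    """Sort key treating digit runs numerically (slice_2 before slice_10)."""
    return [int(t) if t.isdigit() else t.lower() for t in _NUM_RE.split(name)]


def find_slices(source: str | Path) -> list[Path]:
    """Collect slice files from a directory or a glob pattern, natural-sorted."""
    source = Path(source)
    if source.is_dir():
        files = [p for p in source.iterdir() if p.is_file() and not p.name.startswith(".")
                 and p.suffix.lower() not in {".json", ".txt", ".md"}]
    else:
        files = [Path(p) for p in source.parent.glob(source.name)]
    if not files:
        raise BrickvolError(f"no slice files found at {source}")
    return sorted(files, key=lambda p: natural_key(p.name))


class SliceSequence:
    """Read-only view of a stack of same-shaped 2D grayscale slices.

    ``dims`` is ``(x, y, z)``.  ``voxels_read`` counts every voxel served,
    which lets tests assert the single-pass property of the reformatter.
    """

    def __init__(self, paths: Sequence[Path]):
        if not paths:
            raise BrickvolError("empty slice sequence")
        self.paths = [Path(p) for p in paths]
        first = self._load(0)
        if first.ndim != 2:
            raise CorruptInputError(f"{self.paths[0]}: expected 2D grayscale, got shape {first.shape}")
        self.slice_shape = first.shape          # (y, x)
        self.dtype = first.dtype
        if self.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise CorruptInputError(f"unsupported dtype {self.dtype}; need uint8 or uint16")
        self.voxels_read = 0
        self._count_lock = threading.Lock()

    def _count(self, nvox: int) -> None:
        with self._count_lock:
            self.voxels_read += nvox

    @classmethod
    def open(cls, source: str | Path) -> "SliceSequence":
        return cls(find_slices(source))

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.slice_shape[1], self.slice_shape[0], len(self.paths))

    def _load(self, z: int) -> np.ndarray:
        path = self.paths[z]
        try:
            if path.suffix.lower() in _TIFF_SUFFIXES:
                return tifffile.imread(path)
            import imageio.v3 as iio
            return np.asarray(iio.imread(path))
        except OSError as e:
            raise BrickvolError(f"cannot read slice {z} ({path}): {e}") from e

    def read_slice(self, z: int) -> np.ndarray:
        arr = self._load(z)
        if arr.shape != self.slice_shape or arr.dtype != self.dtype:
            raise CorruptInputError(
                f"slice {z} ({self.paths[z]}): shape/dtype {arr.shape}/{arr.dtype} "
                f"differs from first slice {self.slice_shape}/{self.dtype}"
            )
        self._count(arr.size)
        return arr

    def read_rows(self, z: int, y0: int, y1: int) -> np.ndarray:
        """Rows ``[y0, y1)`` of slice ``z`` without loading the full slice.

        Falls back to a whole-slice read when the file is compressed or
        non-TIFF; a memory-mapped read touches only the requested strip.
        """
        path = self.paths[z]
        y1 = min(y1, self.slice_shape[0])
        if y0 >= y1:
            return np.empty((0, self.slice_shape[1]), dtype=self.dtype)
        strip = None
        if path.suffix.lower() in _TIFF_SUFFIXES:
            try:
                mm = tifffile.memmap(path, mode="r")
                if mm.shape == self.slice_shape and mm.dtype == self.dtype:
                    strip = np.array(mm[y0:y1])
                del mm
            except (ValueError, OSError):
                strip = None
        if strip is None:
            strip = self.read_slice(z)[y0:y1].copy()
            self._count(strip.size - self.slice_shape[0] * self.slice_shape[1])
        else:
            self._count(strip.size)
        return strip


def write_slice(path: Path, data: np.ndarray) -> None:
    """Write one grayscale slice as an uncompressed TIFF (bit-exact)."""
    tifffile.imwrite(path, data, photometric="minisblack")


def slice_name(z: int, n_total: int) -> str:
    width = max(5, len(str(max(n_total - 1, 0))))
    return f"slice_{z:0{width}d}.tif"


def ensure_tiff_sequence(source: str | Path, scratch_dir: Path | None = None
                         ) -> tuple[SliceSequence, Path | None]:
    """Open a slice sequence, converting non-TIFF inputs to TIFF first.

    Returns the sequence and the temporary conversion directory (``None``
    when no conversion was needed); the caller owns the cleanup.
    """
    paths = find_slices(source)
    if all(p.suffix.lower() in _TIFF_SUFFIXES for p in paths):
        return SliceSequence(paths), None
    tmp = Path(tempfile.mkdtemp(prefix="brickvol_tiff_", dir=scratch_dir))
    import imageio.v3 as iio
    out_paths = []
    for z, p in enumerate(paths):
        arr = np.asarray(iio.imread(p))
        out = tmp / slice_name(z, len(paths))
        write_slice(out, arr)
        out_paths.append(out)
    return SliceSequence(out_paths), tmp
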