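"""Streamed reformatter: slice sequence -> multi-resolution brick dataset.

Three-stage pipeline, each stage with a provable memory bound:

1. *Subsampling* — each pyramid level is produced from the previous one by
   2×2×2 mean pooling (ceil-halved dims, partial windows at odd edges,
   round half-up), reading at most two source slices at a time and writing
   a temporary slice sequence.
2. *Cuboid reading* — a level's slices are consumed one Y-stripe × Z-slab
   at a time into a WIDTH × B × B working buffer (the *cuboid*), zero-padded
   at the Y/Z boundary.  The cuboid IS the memory bound:
   WIDTH × B × B × bytes-per-voxel per worker.
3. *Block splitting* — each cuboid is cut along X into B×B×B blocks
   (zero-padded at the X boundary) and written as multi-page TIFF files.

Every source voxel of a level is read exactly once during that level's
cuboid pass; output block files are byte-identical for any worker count.
"""

from __future__ import annotations

import shutil
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import BrickvolError, GeometryError
from .geometry import (
    Block,
    BlockIndex,
    DatasetMetadata,
    LevelGeometry,
    block_path,
    compute_pyramid_levels,
    write_metadata,
)
from .slices import SliceSequence, ensure_tiff_sequence, slice_name, write_slice


class BufferLedger:
    """Tracks live working-buffer bytes so tests can assert the peak bound."""

    def __init__(self):
        self._lock = threading.Lock()
        self.current = 0
        self.peak = 0

    def allocate(self, nbytes: int) -> None:
        with self._lock:
            self.current += nbytes
            self.peak = max(self.peak, self.current)

    def release(self, nbytes: int) -> None:
        with self._lock:
            self.current -= nbytes


@dataclass
class Cuboid:
    """The working buffer of one reformatting step.

    Covers the full X extent (WIDTH), rows ``[stripe_y*B, (stripe_y+1)*B)``
    and slices ``[slab_z*B, (slab_z+1)*B)``; ``voxels`` has shape
    (B, B, WIDTH) = (z, y, x), zero-padded where the volume ends.
    """

    level: int
    stripe_y: int
    slab_z: int
    voxels: np.ndarray

    @property
    def nbytes(self) -> int:
        return self.voxels.nbytes


def pool2x2x2(pair: np.ndarray) -> np.ndarray:
    """Mean-pool a (≤2, H, W) slab by 2 along every axis, ceil-halved dims.

    Partial windows at odd edges average the voxels that exist; the result
    stays float64 (rounding happens once, at write time).
    """
    nz, ny, nx = pair.shape
    ys = np.arange(0, ny, 2)
    xs = np.arange(0, nx, 2)
    s = pair.astype(np.float64).sum(axis=0)
    s = np.add.reduceat(s, ys, axis=0)
    s = np.add.reduceat(s, xs, axis=1)
    cy = np.minimum(ys + 2, ny) - ys
    cx = np.minimum(xs + 2, nx) - xs
    counts = nz * cy[:, None] * cx[None, :]
    return s / counts


def _round_half_up(arr: np.ndarray, dtype: np.dtype) -> np.ndarray:
    return np.floor(arr + 0.5).astype(dtype)


def subsample_volume(source: SliceSequence, out_dir: str | Path,
                     workers: int = 1) -> SliceSequence:
    """Produce the next pyramid level as a slice sequence on disk.

    Output dims are the ceil-halved source dims; each output voxel is the
    mean of its ≤2×2×2 source window, rounded half-up.  At most two full
    source slices are resident per worker.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sx, sy, sz = source.dims
    oz = -(-sz // 2)

    def one(z_out: int) -> Path:
        z0 = 2 * z_out
        planes = [source.read_slice(z0)]
        if z0 + 1 < sz:
            planes.append(source.read_slice(z0 + 1))
        pooled = pool2x2x2(np.stack(planes))
        path = out_dir / slice_name(z_out, oz)
        write_slice(path, _round_half_up(pooled, source.dtype))
        return path

    if workers <= 1:
        paths = [one(z) for z in range(oz)]
    else:
        with ThreadPoolExecutor(max_workers=workers) as ex:
            paths = list(ex.map(one, range(oz)))
    return SliceSequence(paths)


def read_cuboid(source: SliceSequence, stripe_y: int, slab_z: int,
                block_size: int, level: int = 1,
                ledger: BufferLedger | None = None) -> Cuboid:
    """Assemble one WIDTH × B × B cuboid from row strips of B slices.

    Rows beyond the volume height and slices beyond its depth stay zero.
    """
    b = block_size
    sx, sy, sz = source.dims
    if stripe_y < 0 or slab_z < 0 or stripe_y * b >= sy or slab_z * b >= sz:
        raise GeometryError(f"stripe_y={stripe_y}, slab_z={slab_z} outside volume {source.dims}")
    buf = np.zeros((b, b, sx), dtype=source.dtype)
    if ledger:
        ledger.allocate(buf.nbytes)
    y0 = stripe_y * b
    y1 = min(y0 + b, sy)
    for k in range(min(b, sz - slab_z * b)):
        strip = source.read_rows(slab_z * b + k, y0, y1)
        buf[k, : strip.shape[0], :] = strip
    return Cuboid(level=level, stripe_y=stripe_y, slab_z=slab_z, voxels=buf)


def split_cuboid(c: Cuboid, block_size: int) -> list[Block]:
    """Cut a cuboid along X into ceil(WIDTH/B) zero-padded blocks."""
    b = block_size
    width = c.voxels.shape[2]
    blocks = []
    for bx in range(-(-width // b)):
        vox = np.zeros((b, b, b), dtype=c.voxels.dtype)
        part = c.voxels[:, :, bx * b: (bx + 1) * b]
        vox[:, :, : part.shape[2]] = part
        idx = BlockIndex(level=c.level, bx=bx, by=c.stripe_y, bz=c.slab_z)
        blocks.append(Block(index=idx, voxels=vox))
    return blocks


def _write_block(root: Path, blk: Block) -> None:
    path = root / block_path(blk.index)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        tifffile.imwrite(path, blk.voxels, photometric="minisblack")
    except OSError as e:
        raise BrickvolError(f"failed writing block {blk.index} to {path}: {e}") from e


@dataclass
class ReformatStats:
    """Instrumentation of one reformat run (bytes, counts; all logical)."""

    peak_buffer_bytes: int = 0
    blocks_written: int = 0
    voxels_read_per_level: dict = field(default_factory=dict)


def _reformat_level(source: SliceSequence, root: Path, geom: LevelGeometry,
                    block_size: int, workers: int, ledger: BufferLedger,
                    stats: ReformatStats) -> None:
    read_before = source.voxels_read

    def one(job: tuple[int, int]) -> int:
        slab_z, stripe_y = job
        cub = read_cuboid(source, stripe_y, slab_z, block_size,
                          level=geom.level, ledger=ledger)
        blocks = split_cuboid(cub, block_size)
        for blk in blocks:
            _write_block(root, blk)
        ledger.release(cub.nbytes)
        return len(blocks)

    jobs = [(bz, by) for bz in range(geom.grid[2]) for by in range(geom.grid[1])]
    if workers <= 1:
        written = [one(j) for j in jobs]
    else:
        with ThreadPoolExecutor(max_workers=workers) as ex:
            written = list(ex.map(one, jobs))
    stats.blocks_written += sum(written)
    stats.voxels_read_per_level[geom.level] = source.voxels_read - read_before


def reformat(source: str | Path | SliceSequence, out_root: str | Path,
             resolution: tuple[float, float, float] = (1.0, 1.0, 1.0),
             block_size: int = 512, workers: int = 1, force: bool = False,
             ) -> tuple[DatasetMetadata, ReformatStats]:
    """Convert a slice sequence into a complete multi-resolution brick dataset.

    Parameters
    ----------
    source : directory, glob pattern, or open :class:`SliceSequence`
        Input slices (8/16-bit grayscale).  Non-TIFF images are converted
        to a temporary TIFF sequence first.
    out_root : directory
        Dataset root; refuses a non-empty existing directory unless
        ``force`` is set.
    resolution : (x, y, z) voxel pitch in μm at full resolution.
    workers : thread count; output files are byte-identical for any value.

    Returns the dataset metadata and per-run instrumentation.
    """
    out_root = Path(out_root)
    if out_root.exists() and any(out_root.iterdir()):
        if not force:
            raise BrickvolError(f"output {out_root} exists and is not empty (use force)")
        shutil.rmtree(out_root)
    out_root.mkdir(parents=True, exist_ok=True)

    conv_tmp = None
    if isinstance(source, SliceSequence):
        seq = source
    else:
        seq, conv_tmp = ensure_tiff_sequence(source)

    levels = compute_pyramid_levels(seq.dims, block_size)
    meta = DatasetMetadata(
        dims_x=seq.dims[0], dims_y=seq.dims[1], dims_z=seq.dims[2],
        resolution_x=resolution[0], resolution_y=resolution[1],
        resolution_z=resolution[2],
        bit_depth=8 * seq.dtype.itemsize, block_size=block_size,
        n_levels=len(levels), file_format="tif", storage_root=str(out_root),
    )
    ledger = BufferLedger()
    stats = ReformatStats()
    tmp_dirs: list[Path] = []
    try:
        cur = seq
        for geom in levels:
            _reformat_level(cur, out_root, geom, block_size, workers, ledger, stats)
            if geom.level < len(levels):
                tmp = out_root / f"_subsample_level_{geom.level + 1}"
                cur = subsample_volume(cur, tmp, workers=workers)
                tmp_dirs.append(tmp)
    finally:
        for tmp in tmp_dirs:
            shutil.rmtree(tmp, ignore_errors=True)
        if conv_tmp is not None:
            shutil.rmtree(conv_tmp, ignore_errors=True)
    stats.peak_buffer_bytes = ledger.peak
    write_metadata(meta, out_root)
    return meta, stats
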