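"""Block-wise rigid transformation and orthogonal re-slicing.

A rigid transform (rotation + translation, 4×4 homogeneous matrix acting on
column vectors (x, y, z, 1)ᵀ) is applied to a whole brick dataset one
*output* block at a time: each target block's corners are mapped through
the inverse transform to find the source axis-aligned bounding box, that
box is fetched with a cached ROI read, and every target voxel is sampled
at its inverse-mapped source coordinate (trilinear by default, nearest on
request; samples outside the source volume are 0, matching the format's
padding semantics).  Peak memory is one source box + one output block +
the block cache, independent of the volume size — and the result is
bit-identical to a dense whole-volume resample, because each fetched box
carries a one-voxel interpolation margin.

Coarser output levels are produced by transforming the matching source
level with the translation scaled down by 2^(L-1) (optionally by
re-subsampling the transformed full-resolution output instead).
"""

from __future__ import annotations

import itertools
import json
import shutil
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from threading import Lock

import numpy as np
from scipy import ndimage

from .dataset import BlockCache, Dataset
from .errors import BrickvolError, RangeError, TransformError
from .geometry import (
    Block,
    BlockIndex,
    DatasetMetadata,
    compute_pyramid_levels,
    write_metadata,
)
from .reformat import _write_block, subsample_volume

_ORTHO_TOL = 1e-4
_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "horizontal": 2}


@dataclass(frozen=True)
class RigidTransform:
    """A 4×4 homogeneous rigid transform in voxel coordinates.

    The upper-left 3×3 must be orthonormal (within 1e-4) and the last row
    (0, 0, 0, 1); translations live in the last column.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise TransformError(f"transform must be 4x4, got {m.shape}")
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m[3], (0, 0, 0, 1), atol=_ORTHO_TOL):
            raise TransformError(f"last row must be (0,0,0,1), got {m[3]}")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=_ORTHO_TOL):
            raise TransformError("upper-left 3x3 is not orthonormal within 1e-4")

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def inverse(self) -> "RigidTransform":
        # numeric inverse rather than the transpose trick: matrices read from
        # files are orthonormal only to ~1e-4 and the inverse must still
        # satisfy inverse @ self == identity to machine precision
        return RigidTransform(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform (..., 3) points given in (x, y, z) order."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def rotation_z(cls, degrees: float) -> "RigidTransform":
        c, s = np.cos(np.radians(degrees)), np.sin(np.radians(degrees))
        return cls(_compose(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]), np.zeros(3)))

    @classmethod
    def rotation_y(cls, degrees: float) -> "RigidTransform":
        c, s = np.cos(np.radians(degrees)), np.sin(np.radians(degrees))
        return cls(_compose(np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]]), np.zeros(3)))

    @classmethod
    def rotation_x(cls, degrees: float) -> "RigidTransform":
        c, s = np.cos(np.radians(degrees)), np.sin(np.radians(degrees))
        return cls(_compose(np.array([[1, 0, 0], [0, c, -s], [0, s, c]]), np.zeros(3)))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        """Read a matrix from JSON ({"matrix": 4×4 rows}) or whitespace text."""
        path = Path(path)
        text = path.read_text()
        try:
            data = json.loads(text)
            rows = data["matrix"] if isinstance(data, dict) else data
        except json.JSONDecodeError:
            vals = [float(t) for t in text.split()]
            if len(vals) != 16:
                raise TransformError(f"{path}: expected 16 numbers, got {len(vals)}")
            rows = np.reshape(vals, (4, 4))
        return cls(np.asarray(rows, dtype=np.float64))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.matrix.tolist()}, indent=2) + "\n")

    def in_voxel_space(self, resolution) -> "RigidTransform":
        """Convert a transform expressed in μm to anisotropic voxel units."""
        s = np.asarray(resolution, dtype=np.float64)
        m = self.matrix.copy()
        m[:3, :3] = m[:3, :3] * s[None, :] / s[:, None]
        m[:3, 3] = m[:3, 3] / s
        return RigidTransform(m)


def _compose(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = rotation
    m[:3, 3] = translation
    return m


def rotated_bounds(dims, transform: RigidTransform
                   ) -> tuple[tuple[int, int, int], np.ndarray]:
    """Size and origin offset of the axis-aligned box containing a
    transformed volume.

    The eight corners of ``[0, dims)`` are transformed; the output dims are
    the rounded (half-up) extents of their bounding box, and ``offset`` is
    the box minimum — i.e. the source-frame position of the output origin,
    so the centre of target voxel q lies at source point T⁻¹(q + 0.5 + offset).
    """
    dims = tuple(int(d) for d in dims)
    if np.abs(np.linalg.det(transform.matrix[:3, :3])) < 1e-12:
        raise TransformError("singular transform")
    corners = np.array(list(itertools.product(*[(0, d) for d in dims])), dtype=np.float64)
    mapped = transform.apply(corners)
    lo, hi = mapped.min(axis=0), mapped.max(axis=0)
    new_dims = tuple(int(np.floor(e + 0.5)) for e in hi - lo)
    return new_dims, lo


def _level_inverse_matrix(transform: RigidTransform, offset: np.ndarray,
                          level: int) -> np.ndarray:
    """Affine mapping target level-L voxels to source level-L voxels.

    p = R⁻¹ q + R⁻¹·offset / 2^(L-1): the rotation part is scale-free, only
    the translation shrinks with the level.
    """
    inv = transform.inverse.matrix.copy()
    t = inv[:3, :3] @ np.asarray(offset, dtype=np.float64) + inv[:3, 3]
    inv[:3, 3] = t / (2 ** (level - 1))
    return inv


def _sample(volume: np.ndarray, coords_xyz: np.ndarray, interpolation: str,
            out_dtype: np.dtype) -> np.ndarray:
    """Sample a (z, y, x) volume at float (N, 3) xyz coordinates; outside -> 0."""
    coords = coords_xyz[:, ::-1].T  # -> (3, N) in (z, y, x) index order
    order = {"trilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise BrickvolError(f"unknown interpolation {interpolation!r}")
    # grid-constant: samples beyond the array blend toward 0 instead of the
    # hard cutoff of plain "constant", which would zero a coordinate of -1e-16
    vals = ndimage.map_coordinates(volume.astype(np.float64), coords, order=order,
                                   mode="grid-constant", cval=0.0, prefilter=False)
    info = np.iinfo(out_dtype)
    return np.clip(np.floor(vals + 0.5), info.min, info.max).astype(out_dtype)


def transform_block(dataset: Dataset, target_idx: BlockIndex,
                    transform: RigidTransform, offset: np.ndarray,
                    cache: BlockCache | None = None,
                    interpolation: str = "trilinear") -> Block:
    """Compute one block of the transformed dataset via inverse mapping.

    The source region is the bounding box of the inverse-mapped target
    block corners, expanded by one voxel for the interpolation support and
    clipped to the source extent; it is fetched through the (cached) ROI
    reader, so repeated nearby target blocks hit the cache.
    """
    b = dataset.block_size
    level = target_idx.level
    geom = dataset.level_geometry(level)
    inv = _level_inverse_matrix(transform, offset, level)
    o = np.array(target_idx.origin(b), dtype=np.float64)
    corners = np.array(list(itertools.product(*[(c, c + b) for c in o])), dtype=np.float64)
    mapped = corners @ inv[:3, :3].T + inv[:3, 3]
    lo = np.floor(mapped.min(axis=0)).astype(int) - 1
    hi = np.ceil(mapped.max(axis=0)).astype(int) + 2  # +1 margin, +1 half-open
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, np.array(geom.dims))
    vox = np.zeros((b, b, b), dtype=dataset.meta.dtype)
    if np.all(hi_c > lo_c):
        region = dataset.read_region(level, tuple(lo_c), tuple(hi_c - lo_c), cache)
        zz, yy, xx = np.meshgrid(np.arange(b), np.arange(b), np.arange(b), indexing="ij")
        q = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1) + o
        # voxel-centre convention: voxel i samples continuous coordinate i+0.5,
        # so a 90-degree rotation is an exact index permutation
        p = (q + 0.5) @ inv[:3, :3].T + inv[:3, 3]
        vox = _sample(region, p - 0.5 - lo_c, interpolation,
                      dataset.meta.dtype).reshape(b, b, b)
    return Block(index=target_idx, voxels=vox)


def apply_rigid(source: Dataset, transform: RigidTransform, out_root: str | Path,
                workers: int = 1, interpolation: str = "trilinear",
                cache_capacity: int = 512, force: bool = False,
                level_mode: str = "transform") -> DatasetMetadata:
    """Transform a whole dataset block-by-block into a new brick dataset.

    ``level_mode="transform"`` (default) computes every output level from
    the matching source level with a level-scaled translation;
    ``"subsample"`` instead mean-pools the transformed full-resolution
    output, trading an extra pass for cross-level consistency.
    """
    out_root = Path(out_root)
    if out_root.exists() and any(out_root.iterdir()):
        if not force:
            raise BrickvolError(f"output {out_root} exists and is not empty (use force)")
        shutil.rmtree(out_root)
    out_root.mkdir(parents=True, exist_ok=True)

    b = source.block_size
    new_dims, offset = rotated_bounds(source.meta.dims, transform)
    new_levels = compute_pyramid_levels(new_dims, b)
    meta = DatasetMetadata(
        dims_x=new_dims[0], dims_y=new_dims[1], dims_z=new_dims[2],
        resolution_x=source.meta.resolution_x, resolution_y=source.meta.resolution_y,
        resolution_z=source.meta.resolution_z, bit_depth=source.meta.bit_depth,
        block_size=b, n_levels=len(new_levels), file_format="tif",
        storage_root=str(out_root),
    )
    cache = BlockCache(cache_capacity)
    cache_lock = Lock()

    if level_mode == "transform":
        target_levels = [g for g in new_levels if g.level <= source.meta.n_levels]
    elif level_mode == "subsample":
        target_levels = new_levels[:1]
    else:
        raise BrickvolError(f"unknown level_mode {level_mode!r}")

    for geom in target_levels:
        indices = [BlockIndex(geom.level, bx, by, bz)
                   for bz in range(geom.grid[2])
                   for by in range(geom.grid[1])
                   for bx in range(geom.grid[0])]

        def one(idx: BlockIndex) -> None:
            with cache_lock:
                blk = transform_block(source, idx, transform, offset, cache, interpolation)
            _write_block(out_root, blk)

        if workers <= 1:
            for idx in indices:
                one(idx)
        else:
            with ThreadPoolExecutor(max_workers=workers) as ex:
                list(ex.map(one, indices))

    if level_mode == "transform" and len(new_levels) > source.meta.n_levels:
        _extra_levels_by_subsampling(out_root, meta, new_levels,
                                     source.meta.n_levels, workers)
    elif level_mode == "subsample":
        _extra_levels_by_subsampling(out_root, meta, new_levels, 1, workers)

    write_metadata(meta, out_root)
    return meta


def _extra_levels_by_subsampling(out_root: Path, meta: DatasetMetadata,
                                 new_levels, from_level: int, workers: int) -> None:
    """Build levels > ``from_level`` by mean-pooling the level below them."""
    from .reformat import _reformat_level, BufferLedger, ReformatStats
    from .slices import SliceSequence
    import tempfile

    # materialize from_level as a temporary slice sequence, then cascade
    tmp_root = Path(tempfile.mkdtemp(prefix="brickvol_lvl_", dir=out_root))
    try:
        ds = Dataset.__new__(Dataset)
        ds.root = out_root
        ds.meta = meta
        ds.levels = new_levels
        ds.block_reads = 0
        geom = new_levels[from_level - 1]
        cur_dir = tmp_root / f"level_{from_level}"
        cur_dir.mkdir()
        from .slices import slice_name, write_slice
        for z in range(geom.dims[2]):
            plane = ds.read_region(from_level, (0, 0, z), (geom.dims[0], geom.dims[1], 1))
            write_slice(cur_dir / slice_name(z, geom.dims[2]), plane[0])
        cur = SliceSequence.open(cur_dir)
        ledger, stats = BufferLedger(), ReformatStats()
        for geom in new_levels[from_level:]:
            nxt = subsample_volume(cur, tmp_root / f"level_{geom.level}", workers=workers)
            _reformat_level(nxt, out_root, geom, meta.block_size, workers, ledger, stats)
            cur = nxt
    finally:
        shutil.rmtree(tmp_root, ignore_errors=True)


def reslice(dataset: Dataset, plane: str, position_um: float,
            thickness_um: float = 0.0, mode: str = "single", level: int = 1,
            cache: BlockCache | None = None
            ) -> tuple[np.ndarray, tuple[float, float]]:
    """Extract an orthogonal section or a maximum-intensity-projection slab.

    ``plane`` is ``sagittal`` (constant x), ``coronal`` (constant y) or
    ``horizontal`` (constant z — the native slice plane).  ``position_um``
    locates the section centre along the plane's normal; ``thickness_um``
    (MIP mode) is the slab depth.  Returns the 2D image and its pixel size
    in μm at the realized level.
    """
    if plane not in _PLANE_AXIS:
        raise RangeError(f"plane must be one of {sorted(_PLANE_AXIS)}, got {plane!r}")
    if mode not in ("single", "mip"):
        raise RangeError(f"mode must be 'single' or 'mip', got {mode!r}")
    if thickness_um < 0:
        raise RangeError("thickness_um must be >= 0")
    axis = _PLANE_AXIS[plane]
    geom = dataset.level_geometry(level)
    res = dataset.meta.level_resolution(level)
    pos = int(np.floor(position_um / res[axis]))
    if not 0 <= pos < geom.dims[axis]:
        raise RangeError(
            f"position {position_um} μm (voxel {pos}) outside extent "
            f"{geom.dims[axis]} of axis {'xyz'[axis]} at level {level}"
        )
    if mode == "single":
        n_thick = 1
        start = pos
    else:
        n_thick = max(1, int(round(thickness_um / res[axis])))
        start = max(0, min(pos - n_thick // 2, geom.dims[axis] - n_thick))
        n_thick = min(n_thick, geom.dims[axis] - start)
    origin = [0, 0, 0]
    size = list(geom.dims)
    origin[axis] = start
    size[axis] = n_thick
    slab = dataset.read_region(level, tuple(origin), tuple(size), cache)
    # slab axes are (z, y, x); reduce the plane's normal
    reduce_axis = 2 - axis
    img = slab.max(axis=reduce_axis) if mode == "mip" else np.take(slab, 0, axis=reduce_axis)
    pixel_axes = [a for a in (0, 1, 2) if a != axis]
    pixel_size = (res[pixel_axes[0]], res[pixel_axes[1]])
    return img, pixel_size
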