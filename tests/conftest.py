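"""Shared fixtures and independent oracles.

The oracles deliberately take the naive whole-volume route (explicit loops,
scipy dense resampling) so they share no code path with the streamed,
block-wise implementations they check.
"""

from pathlib import Path

import numpy as np
import pytest
from scipy import ndimage

import brickvol as bv

FIXTURES = Path(__file__).parent / "fixtures"


# ---------------------------------------------------------------- oracles

def mean_pool_oracle(vol: np.ndarray) -> np.ndarray:
    """Ceil-halved 2x2x2 mean pooling by brute-force window loops."""
    nz, ny, nx = vol.shape
    out = np.empty((-(-nz // 2), -(-ny // 2), -(-nx // 2)), dtype=vol.dtype)
    for k in range(out.shape[0]):
        for j in range(out.shape[1]):
            for i in range(out.shape[2]):
                w = vol[2 * k: 2 * k + 2, 2 * j: 2 * j + 2, 2 * i: 2 * i + 2]
                out[k, j, i] = np.floor(w.mean() + 0.5)
    return out


def pyramid_oracle(vol: np.ndarray, block_size: int) -> list[np.ndarray]:
    """All pyramid levels of a volume, built independently in memory."""
    levels = [vol]
    while not all(s < block_size for s in levels[-1].shape):
        levels.append(mean_pool_oracle(levels[-1]))
    return levels


def dense_resample_oracle(vol: np.ndarray, transform: "bv.RigidTransform",
                          new_dims, offset, interpolation: str) -> np.ndarray:
    """Whole-volume inverse-mapped resample (voxel-centre convention)."""
    inv = transform.inverse.matrix
    nx, ny, nz = new_dims
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    q = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], 1) + 0.5 + np.asarray(offset)
    p = q @ inv[:3, :3].T + inv[:3, 3] - 0.5
    order = 1 if interpolation == "trilinear" else 0
    vals = ndimage.map_coordinates(vol.astype(np.float64), p[:, ::-1].T,
                                   order=order, mode="grid-constant", cval=0.0,
                                   prefilter=False)
    info = np.iinfo(vol.dtype)
    return np.clip(np.floor(vals + 0.5), info.min, info.max
                   ).astype(vol.dtype).reshape(nz, ny, nx)


class LRUOracle:
    """Reference LRU: a plain recency list, no dict tricks."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self.order: list = []  # least-recent first

    def access(self, key) -> bool:
        """Touch a key; returns True on hit."""
        hit = key in self.order
        if hit:
            self.order.remove(key)
        elif self.capacity > 0 and len(self.order) >= self.capacity:
            self.order.pop(0)
        if self.capacity > 0:
            self.order.append(key)
        return hit

    def resident(self) -> set:
        return set(self.order)


def assemble_level(dataset: "bv.Dataset", level: int) -> np.ndarray:
    """Read a full level back block-by-block, unpadded."""
    geom = dataset.level_geometry(level)
    pad = bv.padded_extent(geom, dataset.block_size)
    out = np.zeros((pad[2], pad[1], pad[0]), dtype=dataset.meta.dtype)
    b = dataset.block_size

    def visit(idx, vox):
        out[idx.bz * b:(idx.bz + 1) * b, idx.by * b:(idx.by + 1) * b,
            idx.bx * b:(idx.bx + 1) * b] = vox

    dataset.sequential_read(level, visit)
    return out[: geom.dims[2], : geom.dims[1], : geom.dims[0]]


# ---------------------------------------------------------------- fixtures

CHESS_SPEC = bv.ChessboardSpec(n=64, tile=16, phase_period=16,
                               noise_fraction=0.05, bit_depth=8, seed=7)


@pytest.fixture(scope="session")
def chess_vol() -> np.ndarray:
    return bv.chessboard_volume(CHESS_SPEC)


@pytest.fixture(scope="session")
def chess_dataset(tmp_path_factory) -> "bv.Dataset":
    """A 64-cube noisy chessboard reformatted at B=32 (3 levels)."""
    root = tmp_path_factory.mktemp("chess")
    bv.generate_chessboard(CHESS_SPEC, root / "slices")
    bv.reformat(root / "slices", root / "ds", resolution=(1.0, 1.0, 2.0),
                block_size=32)
    return bv.Dataset(root / "ds")


@pytest.fixture(scope="session")
def registration_matrix() -> "bv.RigidTransform":
    return bv.RigidTransform.load(FIXTURES / "registration_matrix.json")
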