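"""Synthetic benchmark volume: a 3D chessboard with additive Gaussian noise.

The phantom is an n×n×n stack of grayscale slices tiled into black/white
squares (default 256 px in-plane) whose polarity flips every
``phase_period`` slices (default 256), i.e. a 3D checker pattern.  Zero-mean
Gaussian noise with σ = ``noise_fraction`` × dynamic range is added and
clipped to the dtype, emulating the shot-noise texture (and hence the
compressibility) of real light-microscopy data.  Slices are generated and
written one at a time, so memory stays O(n²) at any volume size.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import BrickvolError, GeometryError
from .slices import slice_name, write_slice

GiB = 1024 ** 3


@dataclass(frozen=True)
class ChessboardSpec:
    """Parameters of the chessboard phantom.

    A fixed seed yields a bit-identical volume; each slice's noise is drawn
    from an RNG keyed by (seed, z), so generation order and parallelism do
    not affect the output.
    """

    n: int                        # edge length; the volume is n×n×n voxels
    tile: int = 256               # in-plane tile edge in px
    phase_period: int = 256       # slices between black/white flips
    noise_fraction: float = 0.05  # σ of the noise as a fraction of dtype range
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.tile < 1 or self.phase_period < 1:
            raise GeometryError("n, tile and phase_period must be >= 1")
        if not 0 <= self.noise_fraction < 1:
            raise GeometryError("noise_fraction must be in [0, 1)")
        if self.bit_depth not in (8, 16):
            raise GeometryError("bit_depth must be 8 or 16")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


def chessboard_slice(spec: ChessboardSpec, z: int) -> np.ndarray:
    """One slice of the phantom: checker base pattern plus seeded noise.

    A voxel is white (dtype max) iff ``⌊x/tile⌋ + ⌊y/tile⌋ + ⌊z/phase_period⌋``
    is even, black (0) otherwise.
    """
    dmax = np.iinfo(spec.dtype).max
    idx = np.arange(spec.n) // spec.tile
    parity = (idx[:, None] + idx[None, :] + z // spec.phase_period) % 2
    base = np.where(parity == 0, dmax, 0).astype(np.float64)
    if spec.noise_fraction > 0:
        rng = np.random.default_rng([spec.seed, z])
        base += rng.normal(0.0, spec.noise_fraction * dmax, size=base.shape)
    return np.clip(np.floor(base + 0.5), 0, dmax).astype(spec.dtype)


def chessboard_volume(spec: ChessboardSpec) -> np.ndarray:
    """Whole phantom in memory, shape (z, y, x). For desk-scale use only."""
    return np.stack([chessboard_slice(spec, z) for z in range(spec.n)])


def generate_chessboard(spec: ChessboardSpec, out_dir: str | Path) -> dict:
    """Write the phantom as a numbered TIFF slice sequence plus a manifest.

    The manifest records the spec and a SHA-256 per slice, making the
    determinism contract checkable from disk.  Refuses to start when the
    destination filesystem has less free space than the raw payload.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    required = edge_to_bytes(spec.n, spec.bit_depth)
    free = shutil.disk_usage(out_dir).free
    if required > free:
        raise BrickvolError(
            f"phantom needs {required / GiB:.2f} GiB but only "
            f"{free / GiB:.2f} GiB free at {out_dir}"
        )
    checksums = []
    for z in range(spec.n):
        sl = chessboard_slice(spec, z)
        write_slice(out_dir / slice_name(z, spec.n), sl)
        checksums.append(hashlib.sha256(sl.tobytes()).hexdigest())
    manifest = {
        "spec": asdict(spec),
        "noise_convention": "additive zero-mean Gaussian, sigma = noise_fraction * dtype_max, clipped",
        "slice_sha256": checksums,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def edge_to_bytes(n: int, bit_depth: int) -> int:
    """Raw payload of an n³ volume in bytes."""
    return n ** 3 * (bit_depth // 8)


def edge_to_size(n: int, bit_depth: int) -> float:
    """Raw payload of an n³ volume in GiB (the unit benchmark sizes quote)."""
    return edge_to_bytes(n, bit_depth) / GiB


def size_to_edge(total_bytes: float, bit_depth: int) -> int:
    """Edge length whose cube best matches a byte budget."""
    if total_bytes <= 0:
        raise GeometryError("total_bytes must be positive")
    return round((total_bytes / (bit_depth // 8)) ** (1.0 / 3.0))
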