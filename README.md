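# brickvol

Chunked, multi-resolution brick storage for very large 3D grayscale image
volumes — the terabyte-scale stacks produced by whole-brain light
microscopy — together with the three operations such data constantly needs
and that naive formats make impossibly expensive:

* **Reformatting** a 2D slice sequence into the brick pyramid while holding
  only a thin working buffer in memory, however large the volume is.
* **Random region-of-interest access** at any position, any size, and an
  automatically chosen resolution level, accelerated by an LRU block cache.
* **Rigid transformation** (rotation + translation, e.g. applying a
  registration matrix estimated on downsampled data to the full-resolution
  volume) computed one *output* block at a time, plus orthogonal re-slicing
  with maximum-intensity projection.

## The format

A dataset is a pyramid of levels; level 1 is full resolution and level
*n*+1 ceil-halves every axis of level *n* until all three axes are smaller
than the block edge *B* (default 512). Each level is cut into *B*×*B*×*B*
blocks (zero-padded at the boundary) stored as uncompressed multi-page TIFF
files in a four-deep folder hierarchy,

    level_<L>/z<bz>/y<by>/<bx>_<by>_<bz>.tif

so the file name times *B* is the block's voxel origin. A JSON descriptor
(`dataset.json`) records dims, voxel pitch in μm, bit depth, block size,
level count, container format and storage root.

## The memory-bounded reformatter

Each level is consumed one **cuboid** at a time — the full volume width ×
one *B*-row stripe × one *B*-slice slab — read as row strips so the peak
working set per worker is exactly

    WIDTH × B × B × bytes-per-voxel

(4.64 GiB for a 19012-voxel-wide 8-bit volume at B = 512, independent of
depth and height). Cuboids are split along X into blocks and written out;
coarser levels are produced by 2×2×2 mean pooling (ceil-halved dims,
partial windows at edges, round half-up) two slices at a time. Every source
voxel is read exactly once per level, and output bytes are identical for
any worker count.

## Block-wise rigid transform

For each block of the *rotated* volume, the inverse transform maps its
corners into the source, the enclosing axis-aligned box (+1 voxel margin)
is fetched through the cached ROI reader, and every target voxel is
trilinearly (or nearest-) sampled at its inverse-mapped source coordinate,
voxel-centre convention. Because of the margin the result is *bit-identical*
to a dense whole-volume resample while never holding more than one box,
one block and the cache in memory. The bounding box of a 512³ volume
rotated 45° about z is 724 × 724 × 512 (4 level-1 blocks); a 1000³ volume
becomes 1414 voxels wide and needs 18 blocks where the source needed 8.

## Worked example

```sh
brickvol make-chessboard -n 64 --tile 16 --phase-period 16 --seed 7 -o phantom/
brickvol reformat -i phantom/ -o brain.bv --block-size 32 --resolution 1,1,2
brickvol info -i brain.bv
```

prints

```
dims (x,y,z):   (64, 64, 64)
resolution um:  (1.0, 1.0, 2.0)
bit depth:      8
block size:     32
levels:         3
  level 1: dims (64, 64, 64), grid (2, 2, 2), 8 blocks
  level 2: dims (32, 32, 32), grid (1, 1, 1), 1 blocks
  level 3: dims (16, 16, 16), grid (1, 1, 1), 1 blocks
total blocks:   10
```

i.e. the 64³ chessboard phantom became a 3-level pyramid whose full
resolution occupies a 2×2×2 grid of 32³ bricks. Rotate it and cut a
256-μm-style projection (16 μm at this scale):

```sh
brickvol transform -i brain.bv -o rotated.bv --rotate-z 45
brickvol reslice -i rotated.bv --plane horizontal --position-um 64 \
        --thickness-um 16 --mip -o mip.tif
brickvol read-roi -i brain.bv --origin 8,8,8 --size 24,24,24 --level auto -o roi.tif
```

The same API is available from Python (`brickvol.reformat`,
`brickvol.read_roi`, `brickvol.apply_rigid`, `brickvol.reslice`, ...); see
the module docstrings and `docs/methods.md`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json` first
runs the whole pipeline (phantom → reformat → 45° block-wise rotation) at
desk scale as a self-check, then recomputes the rotated-bounding-volume
extents at the two reference problem sizes (512³ and 1000³ cubes, 45° about
z) and writes them as JSON.
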