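# Methods

This note documents the model behind brickvol's on-disk format and the
numerical choices in its three processing stages, the parameters that
matter, what the synthetic phantom does and does not emulate, and known
limitations.

## Coordinate and storage conventions

Dims and all user-facing coordinates are `(x, y, z)` — x the slice width,
y the slice height, z the slice index — 0-based, half-open. In-memory
arrays are `(z, y, x)`, matching the page order of the multi-page TIFF
block container. Levels are 1-based; level *n*+1 halves every axis of
level *n* **with ceiling**, so odd extents never drop a voxel, and the
pyramid ends at the first level whose axes are all strictly below the
block edge *B* — which guarantees the coarsest level fits in one block.
*B* must be a power of two ≥ 8; the production default is 512, tests run
at 16–32 so that full pyramids, boundary padding and multi-block ROIs are
all exercised in milliseconds.

Boundary blocks are padded with 0; padding is readable (as 0) within the
padded grid extent, while queries beyond it raise a range error — silent
zero-fill outside the dataset would hide caller bugs.

The four-deep folder layout `level_L/z/y/x_y_z.tif` is a stated convention
of this package (the z → y fan-out keeps directory sizes bounded for
petabyte-scale grids); it is bijective with the block index by
construction and covered by a property test.

## Reformatting

* **Downsampling operator.** 2×2×2 arithmetic-mean pooling, partial
  windows at odd edges, with a *single* rounding step (half-up) when the
  accumulated float mean is written back to the integer dtype. Mean
  pooling preserves photometry (the volume mean is invariant up to
  rounding), which gives the conservation properties the tests rely on.
  Rounding half-up rather than banker's rounding keeps the operator
  monotone and easy to reason about; the choice is checked only against
  this package's own oracle.
* **Memory bound.** The working buffer of the block-writing pass is one
  cuboid: `WIDTH × B × B × bytes-per-voxel` per worker. Row strips are
  read through `tifffile.memmap` so a slice never has to be resident
  whole; the subsampling pass holds at most two slices per worker. A
  `BufferLedger` instruments allocations so the bound is asserted, not
  assumed.
* **Two passes per level.** Each level is read once to build the next
  coarser slice sequence and once (cuboid-wise) to emit blocks — every
  source voxel of a level is read exactly once during that level's cuboid
  pass (also instrumented and asserted).
* **Parallelism.** The unit of work is one cuboid (block writing) or one
  output slice (subsampling), executed on a thread pool. Workers own
  disjoint output files, so the dataset bytes are identical for any
  worker count; this determinism contract is what the tests pin down, not
  any particular speed-up.

## ROI access

Read-crop: compute the overlapping blocks, fetch each (cache first),
assemble by position, crop. The cache is a plain LRU over whole blocks
(default capacity 512 blocks); correctness is cache-independent — capacity
only moves the storage-read count, which tests assert is monotone
non-increasing in capacity.

Automatic level selection uses a voxel budget (default one block volume,
B³): the finest level whose ROI voxel count divided by 8 per coarser level
fits the budget, clamped to the pyramid depth. A display-size-driven rule
would be equally defensible; the budget form was chosen because it is
monotone and caller-tunable. ROI coordinates are always given at level-1
scale and mapped to the realized level by `floor` (origin) / `ceil`
(size), so callers address physical space once.

## Rigid transformation

* **Voxel-centre sampling.** Voxel *i* samples continuous coordinate
  *i* + 0.5. This makes 90° rotations exact index permutations (an
  off-by-one-free contract the tests exploit) and identity transforms
  byte-exact.
* **Bounding box.** The eight corners of `[0, dims)` are transformed; the
  output extent is rounded to nearest with ties up (724.08 → 724,
  1414.21 → 1414; ceiling would give 725/1415). The box minimum becomes
  the output origin's source-frame position.
* **Block-wise = dense.** Each target block fetches the AABB of its
  inverse-mapped corners expanded by one voxel. The expansion covers the
  trilinear support, so the block-wise result equals a dense whole-volume
  resample bit for bit; the equivalence is asserted (≤ 1 intensity unit,
  which absorbs the float-associativity edge) against an independent
  `scipy.ndimage.map_coordinates` oracle. Samples outside the source
  volume are 0 (`grid-constant` boundary: values blend toward 0 at the
  edge rather than cutting off at coordinate −ε).
* **Interpolation.** Trilinear by default (intensities), nearest by flag
  (label-like data, exactness tests). Intermediate arithmetic is float64;
  one half-up rounding at the end.
* **Coarser output levels** are produced by transforming the matching
  source level with the translation scaled by 2^(L−1) (the rotation part
  is scale-free). This is cheap and parallel but means level L is *not*
  exactly the mean-pooled level L−1; a `level_mode="subsample"` option
  re-pools the transformed level 1 instead when cross-level consistency
  matters. Output levels deeper than the source pyramid (possible because
  rotation enlarges the bounding box) are always built by re-pooling.
* **Composition** is tested exactly with right-angle rotations
  (90° ∘ 90° = 180° under nearest interpolation, bit-equal). For oblique
  angles the cascaded bounding boxes inflate the frame, so a direct
  voxel-wise comparison would mostly measure interpolation smear on the
  phantom's step edges, not the machinery; the oblique path is instead
  pinned by the dense-resample equivalence above.
* **Units.** Transforms act in level-1 voxel coordinates. A matrix
  expressed in μm can be converted with `in_voxel_space(resolution)`
  (similarity conjugation by the per-axis pitch); the conversion preserves
  physical-point mapping but note that an anisotropically conjugated
  rotation is no longer orthonormal in voxel space unless the rotation
  fixes the anisotropic axis.

## Re-slicing

`horizontal` is the native slice plane (constant z), `coronal` constant y,
`sagittal` constant x. Positions and slab thickness are given in μm and
converted with the realized level's pitch; MIP takes the voxel-wise
maximum over the slab. The returned pixel size is (fast axis, slow axis)
of the 2D image.

## The chessboard phantom

An n³ checker volume — in-plane tiles (default 256 px) whose polarity
flips every `phase_period` slices (default 256) — with additive zero-mean
Gaussian noise, σ = 5 % of the dynamic range by default, clipped to the
dtype. Noise is drawn per slice from an RNG keyed by `(seed, z)`, so
generation is deterministic regardless of order or parallelism, and the
manifest records per-slice SHA-256 checksums. Generation streams one slice
at a time (O(n²) memory).

What it emulates: sharp structure at known positions, a balanced
histogram, and realistic incompressibility. What it does not: anisotropic
PSFs, vignetting, stitching seams, intensity gradients, or sparse
foreground — so a green test establishes geometric/bookkeeping
correctness, not robustness to acquisition artifacts. Tests shrink `tile`
and `phase_period` proportionally (e.g. 16 at n = 64) so every block still
contains multiple tiles and every level still flips phase.

## Degenerate inputs and tie-breaks

Single-slice volumes reformat to one mostly-padded block. A volume smaller
than B in all axes has exactly one level. ROIs of size 1 are legal.
Rounding is half-up everywhere a float meets an integer dtype. Orthonormality
of transforms is enforced within 1e-4 (matrices republished in print carry
~1e-5 per-element error); inverses are numeric, so `T⁻¹ T = I` holds to
machine precision regardless.

## Known limitations

* No compression, cloud backends, HDF5/N5/zarr containers, or
  client-server tile serving.
* Parallelism is thread-based within one process; multi-node execution is
  out of scope.
* The block-wise transformer's peak memory is bounded by design (cache +
  one source box + one output block) but, unlike the reformatter's, is not
  instrumented.
* Registration matrices are consumed, never estimated.
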