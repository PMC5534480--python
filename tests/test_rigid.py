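"""Rigid transforms: matrix validation, rotated bounds, block-wise
resampling against dense oracles, and orthogonal re-slicing."""

import hashlib

import numpy as np
import pytest

import brickvol as bv
from brickvol.errors import RangeError, TransformError

from conftest import dense_resample_oracle, pyramid_oracle


class TestRigidTransform:
    def test_registration_fixture_is_a_rotation(self, registration_matrix):
        t = registration_matrix
        r = t.rotation
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-4)
        assert np.allclose((t.inverse @ t).matrix, np.eye(4), atol=1e-6)
        assert np.allclose(t.translation, 0)

    def _bad_last_row(self):
        m = np.eye(4)
        m[3, 1] = 1e-2
        return m

    @pytest.mark.parametrize("matrix", [
        np.diag([2.0, 1.0, 1.0, 1.0]),   # scaling, not rigid
        "bad_last_row",
        np.eye(3),                       # wrong shape
    ])
    def test_non_rigid_matrices_rejected(self, matrix):
        if isinstance(matrix, str):
            matrix = self._bad_last_row()
        with pytest.raises(TransformError):
            bv.RigidTransform(matrix)

    def test_inverse_roundtrip(self):
        t = (bv.RigidTransform.rotation_z(31.0) @ bv.RigidTransform.rotation_x(-17.0))
        pts = np.random.default_rng(0).uniform(-50, 50, size=(20, 3))
        assert np.allclose(t.inverse.apply(t.apply(pts)), pts, atol=1e-9)

    def test_load_save_roundtrip(self, tmp_path):
        t = bv.RigidTransform.rotation_y(12.5)
        t.save(tmp_path / "m.json")
        assert np.allclose(bv.RigidTransform.load(tmp_path / "m.json").matrix, t.matrix)

    def test_load_plain_text(self, tmp_path):
        (tmp_path / "m.txt").write_text(
            "0 -1 0 0\n1 0 0 0\n0 0 1 0\n0 0 0 1\n")
        t = bv.RigidTransform.load(tmp_path / "m.txt")
        assert np.allclose(t.matrix[:3, :3], bv.RigidTransform.rotation_z(90).rotation)

    def test_anisotropic_voxel_conversion(self):
        # a rotation in isotropic um space, expressed for 1 x 1 x 2 um voxels,
        # must map physical points identically
        t_um = bv.RigidTransform.rotation_z(30)
        res = (1.0, 1.0, 2.0)
        t_vox = t_um.in_voxel_space(res)
        p_vox = np.array([10.0, 4.0, 3.0])
        lhs = t_vox.apply(p_vox) * res
        rhs = t_um.apply(p_vox * res)
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestRotatedBounds:
    def test_single_block_cube_45deg(self):
        dims, offset = bv.rotated_bounds((512, 512, 512), bv.RigidTransform.rotation_z(45))
        assert dims == (724, 724, 512)
        assert np.allclose(offset, (-512 / np.sqrt(2), 0, 0), atol=1e-9)

    def test_thousand_cube_45deg(self):
        dims, _ = bv.rotated_bounds((1000, 1000, 1000), bv.RigidTransform.rotation_z(45))
        assert dims[0] == 1414
        assert dims[2] == 1000

    def test_identity(self):
        dims, offset = bv.rotated_bounds((100, 200, 300), bv.RigidTransform.identity())
        assert dims == (100, 200, 300)
        assert np.allclose(offset, 0)

    def test_right_angle_permutes_dims(self):
        dims, _ = bv.rotated_bounds((100, 200, 300), bv.RigidTransform.rotation_z(90))
        assert dims == (200, 100, 300)


class TestTransformBlock:
    def test_identity_nearest_is_verbatim(self, chess_dataset):
        idx = bv.BlockIndex(1, 1, 0, 1)
        blk = bv.transform_block(chess_dataset, idx, bv.RigidTransform.identity(),
                                 np.zeros(3), interpolation="nearest")
        assert np.array_equal(blk.voxels, chess_dataset.read_block(idx))

    def test_identity_trilinear_is_verbatim(self, chess_dataset):
        idx = bv.BlockIndex(1, 0, 1, 0)
        blk = bv.transform_block(chess_dataset, idx, bv.RigidTransform.identity(),
                                 np.zeros(3))
        assert np.array_equal(blk.voxels, chess_dataset.read_block(idx))

    def test_right_angle_nearest_is_exact_permutation(self, chess_dataset, chess_vol):
        t = bv.RigidTransform.rotation_z(90)
        meta = bv.apply_rigid(chess_dataset, t, chess_dataset.root.parent / "rot90",
                              interpolation="nearest")
        out = bv.Dataset(meta.storage_root)
        got = out.read_region(1, (0, 0, 0), meta.dims)
        # Rz(90): (x,y) -> (-y,x); with the box shifted back, x' = ny-1-y, y' = x
        expected = np.rot90(chess_vol, k=1, axes=(2, 1))
        assert np.array_equal(got, expected)


class TestApplyRigid:
    def test_identity_roundtrips_every_level(self, chess_dataset, tmp_path):
        meta = bv.apply_rigid(chess_dataset, bv.RigidTransform.identity(),
                              tmp_path / "id", interpolation="nearest")
        assert (meta.dims_x, meta.dims_y, meta.dims_z) == chess_dataset.meta.dims
        src = {p.relative_to(chess_dataset.root).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
               for p in sorted(chess_dataset.root.rglob("*_*_*.tif"))}
        dst = {p.relative_to(tmp_path / "id").as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
               for p in sorted((tmp_path / "id").rglob("*_*_*.tif"))}
        assert src == dst

    def test_oblique_rotation_matches_dense_oracle(self, chess_dataset, chess_vol, tmp_path):
        t = bv.RigidTransform.rotation_z(45)
        meta = bv.apply_rigid(chess_dataset, t, tmp_path / "rot", workers=2)
        out = bv.Dataset(tmp_path / "rot")
        new_dims, offset = bv.rotated_bounds(chess_dataset.meta.dims, t)
        oracle = dense_resample_oracle(chess_vol, t, new_dims, offset, "trilinear")
        got = out.read_region(1, (0, 0, 0), new_dims)
        assert np.abs(got.astype(int) - oracle.astype(int)).max() <= 1

    def test_coarse_levels_transform_coarse_source(self, chess_dataset, chess_vol, tmp_path):
        # level 2 of the output is the level-scaled transform of source level 2
        t = bv.RigidTransform.rotation_z(45)
        meta = bv.apply_rigid(chess_dataset, t, tmp_path / "rot2")
        out = bv.Dataset(tmp_path / "rot2")
        geom2 = out.level_geometry(2)
        lvl2_src = pyramid_oracle(chess_vol, 32)[1]
        _, offset = bv.rotated_bounds(chess_dataset.meta.dims, t)
        oracle = dense_resample_oracle(lvl2_src, t, geom2.dims,
                                       np.asarray(offset) / 2, "trilinear")
        got = out.read_region(2, (0, 0, 0), geom2.dims)
        assert np.abs(got.astype(int) - oracle.astype(int)).max() <= 1

    def test_right_angle_composition(self, chess_dataset, tmp_path):
        # two quarter turns block-wise == one half turn block-wise, exactly
        q = bv.RigidTransform.rotation_z(90)
        h = bv.RigidTransform.rotation_z(180)
        m1 = bv.apply_rigid(chess_dataset, q, tmp_path / "q1", interpolation="nearest")
        m2 = bv.apply_rigid(bv.Dataset(tmp_path / "q1"), q, tmp_path / "q2",
                            interpolation="nearest")
        mh = bv.apply_rigid(chess_dataset, h, tmp_path / "h", interpolation="nearest")
        a = bv.Dataset(tmp_path / "q2")
        b = bv.Dataset(tmp_path / "h")
        assert (m2.dims_x, m2.dims_y, m2.dims_z) == (mh.dims_x, mh.dims_y, mh.dims_z)
        dims = (m2.dims_x, m2.dims_y, m2.dims_z)
        assert np.array_equal(a.read_region(1, (0, 0, 0), dims),
                              b.read_region(1, (0, 0, 0), dims))

    def test_ball_volume_conserved_under_rotation(self, tmp_path):
        # binary ball phantom: foreground count changes < 1% under 45 degrees
        import tifffile
        n = 48
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        ball = (((xx - 23.5) ** 2 + (yy - 23.5) ** 2 + (zz - 23.5) ** 2) <= 18 ** 2
                ).astype(np.uint8) * 255
        (tmp_path / "in").mkdir()
        for z in range(n):
            tifffile.imwrite(tmp_path / "in" / f"s{z:02d}.tif", ball[z])
        bv.reformat(tmp_path / "in", tmp_path / "d", block_size=32)
        t = bv.RigidTransform.rotation_z(45)
        meta = bv.apply_rigid(bv.Dataset(tmp_path / "d"), t, tmp_path / "rot",
                              interpolation="nearest")
        out = bv.Dataset(tmp_path / "rot")
        rot = out.read_region(1, (0, 0, 0), (meta.dims_x, meta.dims_y, meta.dims_z))
        n_src = int((ball > 0).sum())
        n_rot = int((rot > 0).sum())
        assert abs(n_rot - n_src) / n_src < 0.01


class TestReslice:
    def test_single_plane_is_array_slice(self, chess_dataset, chess_vol):
        # horizontal = native slice plane (constant z); z pitch is 2 um
        img, pixel = bv.reslice(chess_dataset, "horizontal", position_um=20.0)
        assert np.array_equal(img, chess_vol[10])
        assert pixel == (1.0, 1.0)

    def test_sagittal_and_coronal_planes(self, chess_dataset, chess_vol):
        img, pixel = bv.reslice(chess_dataset, "sagittal", position_um=5.0)
        assert np.array_equal(img, chess_vol[:, :, 5])
        assert pixel == (1.0, 2.0)
        img, _ = bv.reslice(chess_dataset, "coronal", position_um=31.0)
        assert np.array_equal(img, chess_vol[:, 31, :])

    def test_mip_takes_slabwise_maximum(self, chess_dataset, chess_vol):
        # 16 um slab at 2 um z-pitch = 8 slices centred on z voxel 16
        img, _ = bv.reslice(chess_dataset, "horizontal", position_um=32.0,
                            thickness_um=16.0, mode="mip")
        assert np.array_equal(img, chess_vol[12:20].max(axis=0))

    def test_mip_two_values(self, tmp_path):
        import tifffile
        vol = np.full((2, 8, 8), 10, np.uint8)
        vol[1] = 200
        (tmp_path / "in").mkdir()
        for z in range(2):
            tifffile.imwrite(tmp_path / "in" / f"s{z}.tif", vol[z])
        bv.reformat(tmp_path / "in", tmp_path / "d", block_size=8)
        img, _ = bv.reslice(bv.Dataset(tmp_path / "d"), "horizontal", 0.0,
                            thickness_um=2.0, mode="mip")
        assert np.all(img == 200)

    def test_out_of_range_position(self, chess_dataset):
        with pytest.raises(RangeError):
            bv.reslice(chess_dataset, "horizontal", position_um=1e6)
        with pytest.raises(RangeError):
            bv.reslice(chess_dataset, "vertical", position_um=0.0)
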