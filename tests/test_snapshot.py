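"""Rotation-grid enumeration, bond perception and deterministic rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from molsnap.chem_prep import CompoundRecord, Conformer3D, curate_record, embed_3d
from molsnap.elements import UnknownElementError
from molsnap.snapshot import (RotationPose, SnapshotConfig,
                              enumerate_rotations, molecule_scale,
                              perceive_bonds, render_pose, rotation_matrix,
                              snap_molecule, split_sdf_batches)


def _ethanol():
    return embed_3d(curate_record(CompoundRecord("etoh", "CCO", 50)), seed=1)


class TestEnumerateRotations:
    def test_default_increment_yields_27_poses(self):
        assert len(enumerate_rotations((176.0, 176.0, 176.0))) == 27

    def test_full_turn_increment_is_identity_only(self):
        poses = enumerate_rotations((360.0, 360.0, 360.0))
        assert len(poses) == 1
        np.testing.assert_allclose(poses[0].rotation, np.eye(3), atol=1e-12)

    def test_single_axis_grid(self):
        poses = enumerate_rotations((90.0, 360.0, 360.0))
        assert [p.angles[0] for p in poses] == [0.0, 90.0, 180.0, 270.0]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(ix=st.floats(25.0, 360.0), iy=st.floats(25.0, 360.0),
           iz=st.floats(25.0, 360.0))
    def test_cardinality_formula(self, ix, iy, iz):
        expected = (math.ceil(360.0 / ix) * math.ceil(360.0 / iy)
                    * math.ceil(360.0 / iz))
        assert len(enumerate_rotations((ix, iy, iz))) == expected

    def test_nonpositive_increment_rejected(self):
        with pytest.raises(ValueError):
            enumerate_rotations((0.0, 176.0, 176.0))

    def test_rotation_matrices_are_proper(self):
        for pose in enumerate_rotations((120.0, 176.0, 360.0)):
            r = pose.rotation
            np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0)


class TestPerceiveBonds:
    def _two_carbons(self, distance):
        return Conformer3D(elements=["C", "C"],
                           coords=np.array([[0.0, 0, 0], [distance, 0, 0]]))

    def test_typical_cc_distance_bonded(self):
        # ceiling = 0.77 + 0.77 + 0.8 = 2.34 A
        assert perceive_bonds(self._two_carbons(1.54)) == [(0, 1)]

    def test_below_minimum_distance_not_bonded(self):
        assert perceive_bonds(self._two_carbons(0.30)) == []

    def test_far_apart_not_bonded(self):
        assert perceive_bonds(self._two_carbons(5.0)) == []

    def test_ceiling_is_inclusive(self):
        assert perceive_bonds(self._two_carbons(2.34)) == [(0, 1)]
        assert perceive_bonds(self._two_carbons(2.35)) == []

    def test_unknown_element_named_in_error(self):
        conf = Conformer3D(elements=["C", "Xx"], coords=np.zeros((2, 3)))
        with pytest.raises(UnknownElementError, match="Xx"):
            perceive_bonds(conf)


class TestRenderPose:
    def test_default_raster_is_256_rgb(self):
        im = render_pose(_ethanol(), RotationPose((0.0, 0.0, 0.0)))
        assert im.pixels.shape == (256, 256, 3)
        assert im.pixels.dtype == np.uint8

    def test_rendering_is_pure(self):
        conf = _ethanol()
        pose = RotationPose((176.0, 176.0, 0.0))
        a = render_pose(conf, pose)
        b = render_pose(conf, pose)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_single_atom_four_fold_symmetry(self):
        conf = Conformer3D(elements=["He"], coords=np.zeros((1, 3)))
        im = render_pose(conf, RotationPose((0.0, 0.0, 0.0))).pixels
        np.testing.assert_array_equal(im, np.rot90(im))
        np.testing.assert_array_equal(im, im[::-1])
        np.testing.assert_array_equal(im, im[:, ::-1])

    def test_full_turn_equals_identity(self):
        conf = _ethanol()
        a = render_pose(conf, RotationPose((0.0, 0.0, 0.0)))
        b = render_pose(conf, RotationPose((360.0, 360.0, 360.0)))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_zero_atom_conformer_rejected(self):
        conf = Conformer3D(elements=[], coords=np.zeros((0, 3)))
        with pytest.raises(ValueError):
            render_pose(conf, RotationPose((0.0, 0.0, 0.0)))

    def test_prerotated_conformer_matches_posed_render(self):
        """Rotating coordinates then rendering at identity agrees with
        rendering the original at that pose (>= 99% identical pixels)."""
        conf = _ethanol()
        pose = RotationPose((176.0, 0.0, 176.0))
        centered = conf.coords - conf.coords.mean(axis=0)
        pre = Conformer3D(elements=conf.elements,
                          coords=centered @ pose.rotation.T,
                          bonds=conf.bonds, compound_id=conf.compound_id)
        a = render_pose(conf, pose)
        b = render_pose(pre, RotationPose((0.0, 0.0, 0.0)))
        same = np.mean(np.all(a.pixels == b.pixels, axis=-1))
        assert same >= 0.99

    def test_single_atom_projected_area_rotation_invariant(self):
        conf = Conformer3D(elements=["S"], coords=np.zeros((1, 3)))
        bg = np.array([255, 255, 255])
        areas = []
        for pose in enumerate_rotations((90.0, 120.0, 360.0)):
            px = render_pose(conf, pose).pixels
            areas.append(int(np.sum(np.any(px != bg, axis=-1))))
        assert len(set(areas)) == 1  # exact for a single sphere

    def test_projected_area_stable_for_rigid_molecule(self):
        conf = _ethanol()
        bg = np.array([255, 255, 255])
        areas = []
        for pose in enumerate_rotations((176.0, 176.0, 360.0))[:6]:
            px = render_pose(conf, pose).pixels
            areas.append(float(np.sum(np.any(px != bg, axis=-1))))
        mean = np.mean(areas)
        assert max(abs(a - mean) / mean for a in areas) < 0.05


class TestSnapMolecule:
    def test_default_config_writes_27_pngs(self, tmp_path):
        images = snap_molecule(_ethanol(), out_dir=tmp_path)
        assert len(images) == 27
        files = sorted(tmp_path.glob("etoh_*.png"))
        assert len(files) == 27
        with Image.open(files[0]) as im:
            assert im.size == (256, 256)
            assert im.mode == "RGB"

    def test_identity_config_single_png(self, tmp_path):
        cfg = SnapshotConfig(angle_increments=(360.0, 360.0, 360.0))
        images = snap_molecule(_ethanol(), cfg, out_dir=tmp_path)
        assert len(images) == 1
        assert (tmp_path / "etoh_0_0_0.png").exists()

    def test_asymmetric_molecule_poses_differ_pairwise(self):
        images = snap_molecule(_ethanol())
        buffers = [im.pixels.tobytes() for im in images]
        assert len(set(buffers)) == len(buffers)

    def test_apparent_size_constant_across_poses(self):
        conf = _ethanol()
        cfg = SnapshotConfig()
        assert molecule_scale(conf, cfg) == molecule_scale(conf, cfg)
        # the scale feeds every pose, so occupied bounding boxes stay close
        images = snap_molecule(conf, cfg)
        bg = np.array([255, 255, 255])
        widths = []
        for im in images[:5]:
            cols = np.any(np.any(im.pixels != bg, axis=-1), axis=0)
            widths.append(int(cols.sum()))
        assert max(widths) - min(widths) < 0.5 * max(widths)


class TestSplitBatches:
    def test_batching_by_molecules_per_sdf(self):
        confs = [Conformer3D(elements=["C"], coords=np.zeros((1, 3)))
                 for _ in range(7)]
        batches = split_sdf_batches(confs, SnapshotConfig(molecules_per_sdf=3))
        assert [len(b) for b in batches] == [3, 3, 1]


class TestRotationMatrixOrder:
    def test_composition_is_rz_ry_rx(self):
        tx, ty, tz = 30.0, 45.0, 60.0
        expected = (rotation_matrix(0, 0, tz) @ rotation_matrix(0, ty, 0)
                    @ rotation_matrix(tx, 0, 0))
        np.testing.assert_allclose(rotation_matrix(tx, ty, tz), expected,
                                   atol=1e-12)
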