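"""The end-to-end femoral measurement pipeline and its building blocks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from skimage.measure import marching_cubes

from femur3d.femur_axes import (
    MeasureConfig,
    anatomical_axis,
    build_frame,
    compute_angles,
    condyle_spheres,
    distal_joint_line,
    head_and_neck,
    measure_femur,
)
from femur3d.geom_core import Axis3D, Sphere, fit_sphere
from femur3d.mesh_io import TriangleMesh
from femur3d.synthetic_femur import SyntheticFemurSpec, build_femur

from conftest import tube


def sdf_mesh(sdf, lo, hi, pitch=0.5):
    """Marching-cubes extraction of an implicit surface, for phantoms."""
    xs = np.arange(lo[0], hi[0] + pitch, pitch)
    ys = np.arange(lo[1], hi[1] + pitch, pitch)
    zs = np.arange(lo[2], hi[2] + pitch, pitch)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    vol = sdf(pts).reshape(gx.shape).astype(np.float32)
    verts, faces, _, _ = marching_cubes(vol, 0.0, spacing=(pitch,) * 3)
    return TriangleMesh(vertices=verts + np.asarray(lo),
                        faces=faces[:, ::-1].astype(np.int64),
                        provenance="synthetic")


def rotate_mesh(mesh, rot, t):
    return TriangleMesh(vertices=mesh.vertices @ rot.T + np.asarray(t),
                        faces=mesh.faces, provenance=mesh.provenance)


class TestAnatomicalAxis:
    def test_straight_tube(self):
        mesh = tube(radius=4.0, length=100.0)
        axis, loops = anatomical_axis(mesh, proximal_hint=np.array([0, 0, 120.0]))
        ang = np.degrees(np.arccos(np.clip(abs(axis.direction @ [0, 0, 1]),
                                           -1, 1)))
        assert ang < 0.01
        assert axis.direction[2] > 0  # proximal per hint
        assert len(loops) >= 20

    def test_procurvatum_femur_matches_generator_chord(self, default_femur):
        mesh, gt = default_femur
        axis, _ = anatomical_axis(mesh, proximal_hint=gt.head_seed())
        ang = np.degrees(np.arccos(np.clip(
            abs(axis.direction @ gt.anatomical_axis.direction), -1, 1)))
        assert ang < 1.5

    def test_rigid_invariance(self, default_femur):
        mesh, gt = default_femur
        axis0, _ = anatomical_axis(mesh, proximal_hint=gt.head_seed())
        rot = Rotation.random(random_state=2).as_matrix()
        t = np.array([30.0, -10.0, 5.0])
        axis1, _ = anatomical_axis(rotate_mesh(mesh, rot, t),
                                   proximal_hint=rot @ gt.head_seed() + t)
        ang = np.degrees(np.arccos(np.clip(
            abs(axis1.direction @ (rot @ axis0.direction)), -1, 1)))
        assert ang < 0.2


class TestHeadAndNeck:
    def test_femur_head_and_neck_recovery(self, default_femur):
        mesh, gt = default_femur
        head, neck_center, hn = head_and_neck(mesh, gt.head_seed())
        assert np.linalg.norm(head.center - gt.head.center) < 0.5
        # neck center close to the true neck axis
        d = neck_center - gt.head.center
        ax = gt.head_neck_axis.direction
        perp = d - (d @ ax) * ax
        assert np.linalg.norm(perp) < 1.5

    def test_ball_on_cylinder_axis_by_symmetry(self):
        """For a sphere on a coaxial cylinder the head-neck axis must be
        the cylinder axis."""
        center = np.array([0.0, 0.0, 40.0])

        def sdf(p):
            d_sph = np.linalg.norm(p - center, axis=1) - 10.0
            r = np.linalg.norm(p[:, :2], axis=1)
            t = np.clip(p[:, 2], 0.0, 40.0)
            d_cyl = np.sqrt((r - np.minimum(r, 4.0)) ** 2 * 0 +
                            np.maximum(r - 4.0, 0.0) ** 2 +
                            (p[:, 2] - t) ** 2)
            inside = (r <= 4.0) & (p[:, 2] >= 0) & (p[:, 2] <= 40.0)
            d_cyl = np.where(inside, np.maximum(r - 4.0, p[:, 2] - 40.0), d_cyl)
            return np.minimum(d_sph, d_cyl)

        mesh = sdf_mesh(sdf, lo=(-12, -12, -2), hi=(12, 12, 52), pitch=0.5)
        seed = center + np.array([0.0, 0.0, 10.0])
        head, neck_center, hn = head_and_neck(mesh, seed)
        ang = np.degrees(np.arccos(np.clip(abs(hn.direction @ [0, 0, 1.0]),
                                           -1, 1)))
        assert ang < 0.5

    def test_neck_scale_sensitivity(self, default_femur):
        """Moving the neck cut from 1.2 to 1.3 x head radius changes the
        downstream torsion angle by less than a degree."""
        mesh, gt = default_femur
        m12 = measure_femur(mesh, gt.head_seed(), "right",
                            MeasureConfig(neck_scale=1.2))
        m13 = measure_femur(mesh, gt.head_seed(), "right",
                            MeasureConfig(neck_scale=1.3))
        assert abs(m12.FTA - m13.FTA) < 1.0


class TestCondylesAndJointLine:
    def test_hemisphere_points_exact_fit(self):
        """A sphere fitted to one hemisphere of exact surface points is
        recovered to numerical precision (partial coverage is enough)."""
        rng = np.random.default_rng(9)
        v = rng.normal(size=(2000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        v = v[v[:, 2] < 0]  # distal half only
        center = np.array([12.0, -3.0, 5.0])
        s = fit_sphere(center + 14.0 * v)
        assert np.linalg.norm(s.center - center) < 1e-3
        assert abs(s.radius - 14.0) < 1e-3

    def test_condyle_recovery_on_femur(self, default_femur):
        mesh, gt = default_femur
        axis, _ = anatomical_axis(mesh, proximal_hint=gt.head_seed())
        med, lat = condyle_spheres(mesh, axis, side="right")
        for got, want in ((med, gt.condyle_medial), (lat, gt.condyle_lateral)):
            assert abs(got.radius - want.radius) / want.radius < 0.05
            assert np.linalg.norm(got.center - want.center) < 1.0

    def test_equal_radius_tangent_line(self):
        cm = Sphere(center=np.array([0.0, 0.0, 0.0]), radius=10.0)
        cl = Sphere(center=np.array([0.0, 40.0, 0.0]), radius=10.0)
        anat = Axis3D(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
        line = distal_joint_line(cm, cl, anat, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(line.direction, [0, 1, 0], atol=1e-9)
        # tangent point offset by radius along unit(distal+caudal)
        d = np.array([-1.0, 0.0, -1.0]) / np.sqrt(2)
        np.testing.assert_allclose(line.point, cm.center + 10.0 * d, atol=1e-6)

    def test_unequal_radius_tangent_tilt_closed_form(self):
        """Radii 10 and 8 mm, centers 40 mm apart: the common tangent
        tilts by asin((10-8)/40) = 2.866 degrees."""
        cm = Sphere(center=np.array([0.0, 0.0, 0.0]), radius=10.0)
        cl = Sphere(center=np.array([0.0, 40.0, 0.0]), radius=8.0)
        anat = Axis3D(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
        line = distal_joint_line(cm, cl, anat, np.array([1.0, 0.0, 0.0]))
        tilt = np.degrees(np.arccos(np.clip(abs(line.direction @ [0, 1.0, 0]),
                                            -1, 1)))
        expected = np.degrees(np.arcsin(2.0 / 40.0))
        assert tilt == pytest.approx(expected, abs=1e-6)
        # the returned line is genuinely tangent to both spheres (to the
        # 0.01-degree convergence threshold of the iteration)
        for s in (cm, cl):
            rel = s.center - line.point
            dist = np.linalg.norm(rel - (rel @ line.direction) * line.direction)
            assert dist == pytest.approx(s.radius, abs=1e-6)

    def test_joint_line_on_femur(self, default_femur):
        mesh, gt = default_femur
        m = measure_femur(mesh, gt.head_seed(), "right")
        ang = np.degrees(np.arccos(np.clip(
            abs(m.frame.distal_joint_line.direction @ gt.joint_line.direction),
            -1, 1)))
        assert ang < 1.0


class TestFrameAndAngles:
    def canonical_frame(self, side="right"):
        anat = Axis3D(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
        lat = 1.0 if side == "right" else -1.0
        joint = Axis3D(point=np.array([0.0, 0.0, 0.0]),
                       direction=np.array([lat, 0.0, 0.0]))
        head = np.array([-lat * 15.0, 5.0, 170.0])
        return build_frame(anat, joint, head, side)

    def test_canonical_right_frame(self):
        frame = self.canonical_frame("right")
        np.testing.assert_allclose(frame.mediolateral, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.craniocaudal, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(frame.axial_plane_normal, [0, 0, 1],
                                   atol=1e-12)

    def test_trivial_angle_construction(self):
        """Joint line perpendicular to the axis, neck at 135 degrees in the
        frontal plane with no axial deviation: (90, 135, 0)."""
        frame = self.canonical_frame("right")
        fna = np.radians(135.0)
        neck_dir = np.array([-np.sin(fna), 0.0, -np.cos(fna)])
        hn = Axis3D(point=np.zeros(3), direction=neck_dir)
        aldfa, fna_out, fta = compute_angles(frame, hn)
        assert aldfa == pytest.approx(90.0, abs=1e-9)
        assert fna_out == pytest.approx(135.0, abs=1e-9)
        assert fta == pytest.approx(0.0, abs=1e-9)

    def test_frame_equivariance_under_rigid_motion(self):
        frame = self.canonical_frame("right")
        rot = Rotation.random(random_state=4).as_matrix()
        t = np.array([5.0, 6.0, 7.0])
        anat = Axis3D(point=rot @ np.zeros(3) + t,
                      direction=rot @ np.array([0.0, 0.0, 1.0]))
        joint = Axis3D(point=rot @ np.zeros(3) + t,
                       direction=rot @ np.array([1.0, 0.0, 0.0]))
        moved = build_frame(anat, joint, rot @ np.array([-15.0, 5.0, 170.0]) + t,
                            "right")
        np.testing.assert_allclose(moved.mediolateral,
                                   rot @ frame.mediolateral, atol=1e-9)
        np.testing.assert_allclose(moved.craniocaudal,
                                   rot @ frame.craniocaudal, atol=1e-9)


class TestMeasureFemur:
    def test_default_femur_recovery(self, default_femur):
        mesh, gt = default_femur
        m = measure_femur(mesh, gt.head_seed(), "right")
        err = np.abs(np.array(m.angles) - np.array(gt.angles))
        assert err.max() < 2.0
        assert m.qc["head_rms"] < 0.2
        assert m.qc["n_sections"] >= 20

    def test_varus_low_torsion_femur_classifies_pathologic(self):
        """A femur built at the varus/low-torsion deformity means measures
        above the 102-degree aLDFA bound and below the 18-degree FTA bound."""
        spec = SyntheticFemurSpec(target_aLDFA=104.5, target_FNA=133.7,
                                  target_FTA=12.9)
        mesh, gt = build_femur(spec)
        m = measure_femur(mesh, gt.head_seed(), "right")
        assert abs(m.aLDFA - 104.5) < 2.0
        assert abs(m.FTA - 12.9) < 2.0
        assert m.aLDFA > 102.0
        assert m.FTA < 18.0

    def test_rigid_motion_invariance(self, default_femur):
        mesh, gt = default_femur
        base = np.array(measure_femur(mesh, gt.head_seed(), "right").angles)
        for rs in (1, 2):
            rot = Rotation.random(random_state=rs).as_matrix()
            t = np.array([17.0, -4.0, 33.0]) * rs
            m = measure_femur(rotate_mesh(mesh, rot, t),
                              rot @ gt.head_seed() + t, "right")
            assert np.abs(np.array(m.angles) - base).max() < 0.5

    def test_seed_invariance(self, default_femur):
        mesh, gt = default_femur
        n = gt.head_neck_axis.direction
        perp = np.cross(n, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        angles = []
        for tilt in (0.0, 0.4, -0.4):
            d = n * np.cos(tilt) + perp * np.sin(tilt)
            seed = gt.head.center + gt.head.radius * d
            angles.append(measure_femur(mesh, seed, "right").angles)
        angles = np.asarray(angles)
        assert (angles.max(axis=0) - angles.min(axis=0)).max() < 0.5

    def test_mirror_symmetry(self):
        """The left-side mirror femur yields identical angle magnitudes
        under the flipped side flag."""
        right, gt_r = build_femur(SyntheticFemurSpec(voxel_pitch=1.0))
        left, gt_l = build_femur(SyntheticFemurSpec(voxel_pitch=1.0,
                                                    side="left"))
        mr = measure_femur(right, gt_r.head_seed(), "right")
        ml = measure_femur(left, gt_l.head_seed(), "left")
        assert np.abs(np.array(mr.angles) - np.array(ml.angles)).max() < 0.5

    def test_determinism_of_report(self, default_femur):
        mesh, gt = default_femur
        j1 = measure_femur(mesh, gt.head_seed(), "right").to_json()
        j2 = measure_femur(mesh, gt.head_seed(), "right").to_json()
        assert j1 == j2
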