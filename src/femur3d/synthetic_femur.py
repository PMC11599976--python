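"""Parametric generator of canine-femur-like surface meshes.

The generator stands in for patient CT data: it builds a watertight,
single-shell triangle mesh whose three femoral angles (aLDFA, FNA, FTA)
are known exactly from the constructive primitives, so the measurement
pipeline can be validated by parameter recovery.

Anatomy emulated (canonical right-femur frame: +z proximal along the
shaft chord, +y cranial, +x lateral):

* a **shaft** tube following a circular arc in the sagittal plane, bowing
  cranially by the procurvatum angle;
* a **neck** capsule leaving the proximal shaft at angles realising the
  target FNA (frontal inclination) and FTA (axial anteversion);
* a spherical **head** at the neck tip;
* two spherical **condyles** whose common distocaudal tangent line makes
  the target aLDFA with the shaft chord in frontal projection.

The surface is extracted by marching cubes from the signed-distance union
of the primitives, which guarantees a watertight single shell.  Left-side
femurs are exact mirror images of the right-side construction.  The
ground-truth anatomical axis is defined as the chord through the 25 % and
75 % arc-length points of the shaft curve — the same mid-diaphyseal span
the measurement pipeline uses — so that oracle and estimator share one
definition.

Default dimensions approximate a mid-size dog (shaft 160 mm, head radius
11 mm, condyle radius 14 mm, intercondylar width 30 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from skimage.measure import marching_cubes

from .errors import SpecError
from .femur_axes import build_frame, compute_angles
from .geom_core import Axis3D, Sphere, unit
from .mesh_io import TriangleMesh


@dataclass(frozen=True)
class SyntheticFemurSpec:
    """Generator parameters.  Angles in degrees, lengths in millimetres."""

    target_aLDFA: float = 95.0
    target_FNA: float = 135.0
    target_FTA: float = 27.0
    procurvatum: float = 8.0
    shaft_length: float = 160.0
    shaft_radius: float = 6.0
    head_radius: float = 11.0
    neck_length: float = 24.0
    condyle_radius: float = 14.0
    intercondylar_width: float = 30.0
    side: str = "right"
    noise_sd: float = 0.0
    voxel_pitch: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for name in ("shaft_length", "shaft_radius", "head_radius",
                     "neck_length", "condyle_radius", "intercondylar_width",
                     "voxel_pitch"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if not (60.0 <= self.target_aLDFA <= 130.0):
            raise SpecError("target_aLDFA must be in [60, 130] degrees")
        if not (100.0 <= self.target_FNA <= 160.0):
            raise SpecError("target_FNA must be in [100, 160] degrees")
        if not (-20.0 <= self.target_FTA <= 60.0):
            raise SpecError("target_FTA must be in [-20, 60] degrees")
        if not (0.0 <= self.procurvatum < 60.0):
            raise SpecError("procurvatum must be in [0, 60) degrees")
        if self.voxel_pitch > self.shaft_radius / 4.0:
            raise SpecError("voxel_pitch must be <= shaft_radius / 4")
        if self.side not in ("left", "right"):
            raise SpecError("side must be 'left' or 'right'")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.neck_length <= 1.7 * self.head_radius:
            raise SpecError(
                "neck_length must exceed 1.7 x head_radius so the neck "
                "section sphere cuts a clean cylinder"
            )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class GroundTruth:
    """Constructive ground truth recorded before meshing.

    The three angles are obtained by running the measurement angle
    conventions (frame construction + projections) on the constructive
    primitives, so the oracle and the estimator share one definition.
    """

    aLDFA: float
    FNA: float
    FTA: float
    side: str
    head: Sphere
    condyle_medial: Sphere
    condyle_lateral: Sphere
    neck_center: np.ndarray       # point on the neck axis at the default cut
    head_neck_axis: Axis3D        # points into the head
    anatomical_axis: Axis3D       # chord through 25 % / 75 % shaft-arc points
    joint_line: Axis3D            # distocaudal common tangent, points lateral
    shaft_arc: dict               # arc descriptor for section-level checks

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.aLDFA, self.FNA, self.FTA)

    def head_seed(self) -> np.ndarray:
        """A canonical seed click: the outer pole of the head."""
        return self.head.center + self.head.radius * self.head_neck_axis.direction

    def shaft_point(self, frac: float) -> np.ndarray:
        """Point on the shaft arc at a given arc-length fraction (0 = distal)."""
        arc = self.shaft_arc
        if arc["straight"]:
            return np.array([0.0, 0.0, frac * arc["length"]]) * np.array(
                [arc["mirror"], 1.0, 1.0]
            )
        theta = (frac - 0.5) * arc["phi"]
        p = np.array(arc["center"]) + arc["radius"] * (
            np.cos(theta) * np.array([0.0, 1.0, 0.0])
            + np.sin(theta) * np.array([0.0, 0.0, 1.0])
        )
        p[0] *= arc["mirror"]
        return p


def _neck_direction(fna_deg: float, fta_deg: float) -> np.ndarray:
    """Unit neck direction (into the head) in the canonical right frame.

    Frontal projection makes the FNA with the distal shaft direction;
    axial projection makes the FTA with the medial direction (positive
    cranial).  Medial for a right femur is -x, cranial +y, proximal +z.
    """
    fna = np.radians(fna_deg)
    fta = np.radians(fta_deg)
    medial = np.array([-1.0, 0.0, 0.0])
    cranial = np.array([0.0, 1.0, 0.0])
    proximal = np.array([0.0, 0.0, 1.0])
    v = (np.sin(fna) * medial
         + np.sin(fna) * np.tan(fta) * cranial
         - np.cos(fna) * proximal)
    return unit(v)


def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    tt = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + tt[:, None] * ab
    return np.linalg.norm(pts - closest, axis=1)


def _arc_distance(pts: np.ndarray, center: np.ndarray, radius: float,
                  phi: float) -> np.ndarray:
    """Distance to the sagittal-plane circular arc spanning +-phi/2 about
    the +y direction from ``center``."""
    rel = pts - center
    psi = np.arctan2(rel[:, 2], rel[:, 1])  # angle from +y toward +z
    psi_c = np.clip(psi, -phi / 2.0, phi / 2.0)
    qy = center[1] + radius * np.cos(psi_c)
    qz = center[2] + radius * np.sin(psi_c)
    return np.sqrt(pts[:, 0] ** 2 + (pts[:, 1] - qy) ** 2 + (pts[:, 2] - qz) ** 2)


def _primitives(spec: SyntheticFemurSpec) -> dict:
    """Constructive primitives in the canonical right-femur frame."""
    L = spec.shaft_length
    phi = np.radians(spec.procurvatum)
    if phi > 1e-6:
        arc_radius = L / (2.0 * np.sin(phi / 2.0))
        arc_center = np.array([0.0, -arc_radius * np.cos(phi / 2.0), L / 2.0])
        straight = False
        # chord through the 25 % and 75 % arc points is parallel to z,
        # offset cranially by the sagittal bulge at those points
        y_quarter = arc_center[1] + arc_radius * np.cos(phi / 4.0)
    else:
        arc_radius = np.inf
        arc_center = np.array([0.0, 0.0, L / 2.0])
        straight = True
        y_quarter = 0.0

    n_hat = _neck_direction(spec.target_FNA, spec.target_FTA)
    neck_base = np.array([0.0, 0.0, L])
    head_center = neck_base + spec.neck_length * n_hat
    neck_radius = 0.55 * spec.head_radius

    delta = np.radians(spec.target_aLDFA - 90.0)
    j_hat = np.array([np.cos(delta), 0.0, -np.sin(delta)])  # points lateral
    r_c = spec.condyle_radius
    mid = np.array([0.0, -0.45 * r_c, 0.0])
    c_med = mid - 0.5 * spec.intercondylar_width * j_hat
    c_lat = mid + 0.5 * spec.intercondylar_width * j_hat

    # collision checks: the neck/head must stay clear of the condyles
    for c in (c_med, c_lat):
        if np.linalg.norm(head_center - c) < spec.head_radius + r_c + 2.0:
            raise SpecError("head collides with a condyle; invalid spec")
    if head_center[2] < 0.5 * L:
        raise SpecError("neck geometry places the head mid-shaft; invalid spec")

    return {
        "arc_center": arc_center, "arc_radius": arc_radius, "phi": phi,
        "straight": straight, "y_quarter": y_quarter,
        "neck_base": neck_base, "neck_radius": neck_radius, "n_hat": n_hat,
        "head_center": head_center, "j_hat": j_hat,
        "c_med": c_med, "c_lat": c_lat, "mid": mid,
    }


def _sdf(pts: np.ndarray, spec: SyntheticFemurSpec, pr: dict) -> np.ndarray:
    if pr["straight"]:
        d_shaft = _segment_distance(
            pts, np.array([0.0, 0.0, 0.0]), pr["neck_base"]
        ) - spec.shaft_radius
    else:
        d_shaft = _arc_distance(
            pts, pr["arc_center"], pr["arc_radius"], pr["phi"]
        ) - spec.shaft_radius
    d_neck = _segment_distance(pts, pr["neck_base"], pr["head_center"]) \
        - pr["neck_radius"]
    d_head = np.linalg.norm(pts - pr["head_center"], axis=1) - spec.head_radius
    d_cm = np.linalg.norm(pts - pr["c_med"], axis=1) - spec.condyle_radius
    d_cl = np.linalg.norm(pts - pr["c_lat"], axis=1) - spec.condyle_radius
    return np.minimum.reduce([d_shaft, d_neck, d_head, d_cm, d_cl])


def _ground_truth(spec: SyntheticFemurSpec, pr: dict) -> GroundTruth:
    mirror = -1.0 if spec.side == "left" else 1.0
    M = np.array([mirror, 1.0, 1.0])

    anat = Axis3D(
        point=np.array([0.0, pr["y_quarter"], spec.shaft_length / 2.0]) * M,
        direction=np.array([0.0, 0.0, 1.0]),
    )
    n_hat = pr["n_hat"] * M
    head = Sphere(center=pr["head_center"] * M, radius=spec.head_radius)
    neck_center = head.center - 1.25 * spec.head_radius * n_hat
    hn_axis = Axis3D(point=neck_center, direction=n_hat)

    c_med = Sphere(center=pr["c_med"] * M, radius=spec.condyle_radius)
    c_lat = Sphere(center=pr["c_lat"] * M, radius=spec.condyle_radius)
    j_hat = pr["j_hat"] * M  # still points lateral after mirroring
    # distocaudal tangent point on the medial condyle
    caudal = np.array([0.0, -1.0, 0.0])
    d0 = unit(-anat.direction + caudal)
    d_hat = unit(d0 - (d0 @ j_hat) * j_hat)
    joint = Axis3D(point=c_med.center + c_med.radius * d_hat, direction=j_hat)

    frame = build_frame(anat, joint, head.center, spec.side)
    aldfa, fna, fta = compute_angles(frame, hn_axis)

    arc = {
        "straight": pr["straight"],
        "center": [float(x) for x in pr["arc_center"]],
        "radius": float(pr["arc_radius"]) if np.isfinite(pr["arc_radius"]) else None,
        "phi": float(pr["phi"]),
        "length": float(spec.shaft_length),
        "mirror": float(mirror),
    }
    return GroundTruth(
        aLDFA=aldfa, FNA=fna, FTA=fta, side=spec.side,
        head=head, condyle_medial=c_med, condyle_lateral=c_lat,
        neck_center=neck_center, head_neck_axis=hn_axis,
        anatomical_axis=anat, joint_line=joint, shaft_arc=arc,
    )


def build_femur(spec: SyntheticFemurSpec) -> tuple[TriangleMesh, GroundTruth]:
    """Generate the mesh and its analytically known ground truth.

    The surface is the zero level set of the signed-distance union of the
    constructive primitives, sampled on a regular grid of ``voxel_pitch``
    spacing and extracted with marching cubes.  Optional Gaussian vertex
    noise (sd ``noise_sd`` mm, seeded) emulates segmentation roughness.
    Left-side meshes are the exact mirror of the right-side construction.
    """
    spec.validate()
    # always build in the right-handed canonical frame, mirror at the end
    right_spec = replace(spec, side="right")
    pr = _primitives(right_spec)

    pitch = spec.voxel_pitch
    r_max = max(spec.shaft_radius, spec.head_radius,
                spec.condyle_radius, pr["neck_radius"])
    anchors = np.vstack([
        np.zeros(3), pr["neck_base"], pr["head_center"],
        pr["c_med"], pr["c_lat"],
        pr["arc_center"] + [0.0, (pr["arc_radius"] if not pr["straight"]
                                  else 0.0), 0.0],
    ])
    lo = anchors.min(axis=0) - (r_max + 3.0 * pitch)
    hi = anchors.max(axis=0) + (r_max + 3.0 * pitch)
    xs = np.arange(lo[0], hi[0] + pitch, pitch)
    ys = np.arange(lo[1], hi[1] + pitch, pitch)
    zs = np.arange(lo[2], hi[2] + pitch, pitch)
    vol = np.empty((len(xs), len(ys), len(zs)), dtype=np.float32)
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    sheet = np.column_stack([
        np.zeros(yy.size), yy.ravel(), zz.ravel()
    ])
    for ix, x in enumerate(xs):
        sheet[:, 0] = x
        vol[ix] = _sdf(sheet, right_spec, pr).reshape(yy.shape)

    verts, faces, _, _ = marching_cubes(vol, level=0.0,
                                        spacing=(pitch, pitch, pitch))
    verts = verts + lo
    # marching_cubes on a signed distance field (negative inside) produces
    # inward-facing triangles; flip to outward
    faces = faces[:, ::-1].astype(np.int64)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        verts = verts + rng.normal(0.0, spec.noise_sd, size=verts.shape)

    if spec.side == "left":
        verts = verts * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1]

    mesh = TriangleMesh(vertices=verts, faces=faces, provenance="synthetic")
    gt = _ground_truth(spec, pr)
    return mesh, gt


def truth_report(gt: GroundTruth) -> dict:
    """Ground truth serialized with the same key schema as a measurement
    report, so truth and measurement can be diffed directly."""
    return {
        "schema": "femur3d/1",
        "aLDFA": round(float(gt.aLDFA), 2),
        "FNA": round(float(gt.FNA), 2),
        "FTA": round(float(gt.FTA), 2),
        "side": gt.side,
        "head": gt.head.to_dict(),
        "condyle_medial": gt.condyle_medial.to_dict(),
        "condyle_lateral": gt.condyle_lateral.to_dict(),
        "neck_center": [float(x) for x in gt.neck_center],
        "head_neck_axis": gt.head_neck_axis.to_dict(),
        "anatomical_axis": gt.anatomical_axis.to_dict(),
        "distal_joint_line": gt.joint_line.to_dict(),
        "qc": {},
    }


def angle_errors(gt: GroundTruth, measurement) -> dict:
    """Per-angle absolute errors between ground truth and a measurement."""
    return {
        "aLDFA": abs(float(measurement.aLDFA) - float(gt.aLDFA)),
        "FNA": abs(float(measurement.FNA) - float(gt.FNA)),
        "FTA": abs(float(measurement.FTA) - float(gt.FTA)),
    }


def truth_json(gt: GroundTruth) -> str:
    return json.dumps(truth_report(gt), indent=2, sort_keys=True)
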