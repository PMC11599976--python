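"""End-to-end automated femoral angle measurement.

From an isolated femur surface mesh, a side flag and a single seed click on
the femoral head, the pipeline computes three clinically used angles:

* **aLDFA** — anatomical lateral distal femoral angle: frontal-plane angle
  between the anatomical (diaphyseal) axis and the distal joint orientation
  line, measured on the lateral-distal side.  Values above the
  physiological band indicate femoral varus, below it valgus.
* **FNA** — femoral neck (inclination) angle: frontal-plane angle between
  the head–neck axis and the distally pointing anatomical axis
  (about 130–140 degrees in normal dogs).
* **FTA** — femoral torsion (anteversion) angle: signed axial-plane angle
  between the head–neck axis and the transcondylar axis, positive cranial
  (anteversion), negative caudal (retroversion).

The construction follows the measurement chain used in CAD-based
veterinary planning: diaphyseal cross-section centroids define the
anatomical axis; a region-grown best-fit sphere defines the femoral head;
a spherical section concentric with the head isolates the neck, whose
centroid joined to the head center gives the head–neck axis; two best-fit
spheres on the condyles define, through their common distocaudal tangent,
the distal joint orientation line.  Every step is deterministic, uses no
extrinsic coordinate system, and is therefore invariant to how the bone is
oriented in space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AxisFailureError,
    CondyleFailureError,
    DegenerateGeometryError,
    FrameError,
    JointLineError,
    NeckFailureError,
    StageError,
)
from .geom_core import (
    Axis3D,
    SectionLoop,
    Sphere,
    fit_circle_center,
    fit_line,
    fit_sphere,
    fit_sphere_seeded,
    project_to_plane,
    section_by_plane,
    section_by_sphere,
    unit,
)
from .mesh_io import TriangleMesh, remove_internal_shells

SIDES = ("left", "right")


@dataclass
class MeasureConfig:
    """Tunable parameters of the measurement pipeline.

    Defaults are calibrated on the packaged synthetic phantom; the original
    CAD implementation exposes analogous (unpublished) knobs.
    """

    neck_scale: float = 1.25       # neck section radius, x head radius
    inclusion_tol: float = 0.025   # head-fit inclusion band, fraction of radius
    span: tuple = (0.25, 0.75)     # diaphyseal section span, fraction of length
    step: float = 0.02             # section spacing, fraction of length
    distal_fraction: float = 0.20  # condylar candidate region, fraction of length
    max_iter: int = 50             # head region-grow iteration cap

    def validate(self) -> None:
        if not (1.0 < self.neck_scale <= 2.0):
            raise ValueError("neck_scale must be in (1, 2]")
        if not (0.0 < self.inclusion_tol < 0.5):
            raise ValueError("inclusion_tol must be in (0, 0.5)")
        lo, hi = self.span
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("span must satisfy 0 <= lo < hi <= 1")
        if not (0.0 < self.step < hi - lo):
            raise ValueError("step must be positive and smaller than the span")
        if not (0.05 < self.distal_fraction < 0.5):
            raise ValueError("distal_fraction must be in (0.05, 0.5)")

    def to_dict(self) -> dict:
        return {
            "neck_scale": self.neck_scale,
            "inclusion_tol": self.inclusion_tol,
            "span": list(self.span),
            "step": self.step,
            "distal_fraction": self.distal_fraction,
            "max_iter": self.max_iter,
        }


@dataclass
class FemoralFrame:
    """Anatomical reference frame derived from the measured axes.

    ``anatomical_axis`` points proximal, ``distal_joint_line`` points
    lateral; ``mediolateral`` is the joint line projected orthogonal to the
    anatomical axis; ``craniocaudal`` completes the frame with the sign
    fixed by the declared side so that anteversion is positive.
    """

    anatomical_axis: Axis3D
    distal_joint_line: Axis3D
    mediolateral: np.ndarray
    craniocaudal: np.ndarray
    side: str

    @property
    def frontal_plane_normal(self) -> np.ndarray:
        return self.craniocaudal

    @property
    def axial_plane_normal(self) -> np.ndarray:
        return self.anatomical_axis.direction


@dataclass
class FemoralMeasurement:
    """The three femoral angles plus the fitted primitives and QC block."""

    aLDFA: float
    FNA: float
    FTA: float
    head: Sphere
    condyle_medial: Sphere
    condyle_lateral: Sphere
    neck_center: np.ndarray
    head_neck_axis: Axis3D
    frame: FemoralFrame
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.aLDFA < 180.0):
            raise DegenerateGeometryError(f"aLDFA out of range: {self.aLDFA}")
        if not (0.0 < self.FNA < 180.0):
            raise DegenerateGeometryError(f"FNA out of range: {self.FNA}")
        if not (-90.0 < self.FTA < 90.0):
            raise DegenerateGeometryError(f"FTA out of range: {self.FTA}")

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.aLDFA, self.FNA, self.FTA)

    def to_dict(self, round_angles: bool = True) -> dict:
        rnd = (lambda x: round(float(x), 2)) if round_angles else float
        return {
            "schema": "femur3d/1",
            "aLDFA": rnd(self.aLDFA),
            "FNA": rnd(self.FNA),
            "FTA": rnd(self.FTA),
            "side": self.frame.side,
            "head": self.head.to_dict(),
            "condyle_medial": self.condyle_medial.to_dict(),
            "condyle_lateral": self.condyle_lateral.to_dict(),
            "neck_center": [float(x) for x in self.neck_center],
            "head_neck_axis": self.head_neck_axis.to_dict(),
            "anatomical_axis": self.frame.anatomical_axis.to_dict(),
            "distal_joint_line": self.frame.distal_joint_line.to_dict(),
            "qc": self.qc,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(**kw), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# anatomical axis


def _point_in_loop(loop: SectionLoop, query: np.ndarray, normal: np.ndarray) -> bool:
    """Even-odd containment test of a point inside a closed planar loop,
    evaluated in an (arbitrary, result-invariant) in-plane basis."""
    n = unit(normal)
    # any orthonormal complement of n
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(n, a))
    v = np.cross(n, u)
    pts = loop.points - query
    x = pts @ u
    y = pts @ v
    inside = False
    for k in range(len(x) - 1):
        x1, y1, x2, y2 = x[k], y[k], x[k + 1], y[k + 1]
        if (y1 > 0) != (y2 > 0):
            xc = x1 + (0.0 - y1) / (y2 - y1) * (x2 - x1)
            if xc > 0:
                inside = not inside
    return inside


def anatomical_axis(
    mesh: TriangleMesh,
    span: tuple = (0.25, 0.75),
    step: float = 0.02,
    proximal_hint: np.ndarray | None = None,
    max_rounds: int = 5,
) -> tuple[Axis3D, list[SectionLoop]]:
    """Diaphyseal anatomical axis by iterative cross-section re-slicing.

    The initial long axis is the principal direction of all vertices.
    Cross-sections are taken perpendicular to the current axis over the
    mid-diaphyseal ``span`` of projected bone length (default 25-75 %, in
    2 % steps, avoiding epiphyseal flare), the per-level loop is chosen as
    the one containing the previous level's centroid (largest perimeter at
    the first level), the axis is re-fit to the centroids, and the process
    repeats until the direction changes by less than 0.1 degrees or five
    rounds elapse.  The returned direction points proximal, toward
    ``proximal_hint`` (typically the head seed) when given.
    """
    mesh.check()
    verts = mesh.vertices
    center = verts.mean(axis=0)
    cov = np.cov((verts - center).T)
    w, v = np.linalg.eigh(cov)
    direction = unit(v[:, int(np.argmax(w))])

    loops_used: list[SectionLoop] = []
    for _ in range(max_rounds):
        t = verts @ direction
        tmin, tmax = float(t.min()), float(t.max())
        length = tmax - tmin
        fracs = np.arange(span[0], span[1] + 1e-9, step)
        centroids = []
        loops_used = []
        prev_centroid = None
        for frac in fracs:
            tval = tmin + frac * length
            plane_pt = center + (tval - center @ direction) * direction
            loops = section_by_plane(mesh, plane_pt, direction)
            if not loops:
                continue
            if prev_centroid is None:
                chosen = loops[0]  # largest perimeter
            else:
                chosen = None
                for lp in loops:
                    if _point_in_loop(lp, prev_centroid + (
                            tval - prev_centroid @ direction) * direction,
                            direction):
                        chosen = lp
                        break
                if chosen is None:
                    chosen = min(
                        loops,
                        key=lambda lp: float(
                            np.linalg.norm(lp.centroid - prev_centroid)
                        ),
                    )
            c = chosen.centroid
            centroids.append(c)
            loops_used.append(chosen)
            prev_centroid = c
        if len(centroids) < 5:
            raise AxisFailureError(
                f"only {len(centroids)} usable diaphyseal sections"
            )
        axis = fit_line(np.asarray(centroids))
        new_dir = axis.direction
        if new_dir @ direction < 0:
            new_dir = -new_dir
        change = np.degrees(
            np.arccos(np.clip(abs(new_dir @ direction), -1.0, 1.0))
        )
        direction = new_dir
        axis_point = axis.point
        if change < 0.1:
            break

    if proximal_hint is not None:
        hint = np.asarray(proximal_hint, dtype=float)
        if direction @ (hint - axis_point) < 0:
            direction = -direction
    return Axis3D(point=axis_point, direction=direction), loops_used


# ---------------------------------------------------------------------------
# head and neck


def head_and_neck(
    mesh: TriangleMesh,
    seed: np.ndarray,
    neck_scale: float = 1.25,
    inclusion_tol: float = 0.025,
    max_iter: int = 50,
    anatomical: Axis3D | None = None,
) -> tuple[Sphere, np.ndarray, Axis3D]:
    """Femoral head sphere, neck center and head-neck axis.

    The head is fitted with the seeded region-grown sphere fit; the neck is
    isolated as the spherical section concentric with the head at
    ``neck_scale`` times the head radius (escalated from 1.1 to 1.6 in 0.05
    steps if no section is found).  Among candidate section loops the one
    whose centroid direction best matches the head-to-shaft direction is
    taken as the neck; its arc-length centroid is the neck center, and the
    head-neck axis points from the neck center into the head center.
    """
    head, _support = fit_sphere_seeded(
        mesh, seed, inclusion_tol=inclusion_tol, max_iter=max_iter
    )
    # direction from the head center toward the shaft, used to pick the
    # neck loop among candidates
    if anatomical is not None:
        d = anatomical.direction
        foot = anatomical.point + (
            (head.center - anatomical.point) @ d
        ) * d
        anchor_dir = unit(foot - head.center)
    else:
        anchor_dir = unit(mesh.vertices.mean(axis=0) - head.center)

    scales = [neck_scale] + [
        s for s in np.arange(1.10, 1.6001, 0.05) if abs(s - neck_scale) > 1e-9
    ]
    chosen = None
    for s in scales:
        loops = section_by_sphere(mesh, head.center, s * head.radius)
        # surface noise can spawn tiny spurious loops on the cut sphere;
        # only substantial loops are neck candidates
        if loops:
            pmax = loops[0].perimeter
            loops = [lp for lp in loops if lp.perimeter >= 0.25 * pmax]
        if loops:
            chosen = min(
                loops,
                key=lambda lp: -float(
                    unit(lp.centroid - head.center) @ anchor_dir
                ),
            )
            break
    if chosen is None:
        raise NeckFailureError(
            "no neck section found for cut radii 1.1-1.6 x head radius"
        )
    # the neck cross-section is near-circular; a least-squares circle
    # center is a lower-variance neck center than the polyline centroid
    # when the surface is noisy
    neck_center = fit_circle_center(chosen.points[:-1])
    axis = Axis3D(point=neck_center, direction=unit(head.center - neck_center))
    return head, neck_center, axis


# ---------------------------------------------------------------------------
# condyles and joint line


def _closest_axis_point(axis: Axis3D, p: np.ndarray) -> np.ndarray:
    d = axis.direction
    return axis.point + ((p - axis.point) @ d) * d


def _robust_sphere(points: np.ndarray, min_support: int) -> Sphere:
    """Sphere fit with a few inlier re-selection rounds, shedding vertices
    that belong to neighbouring structures (e.g. the distal shaft)."""
    pts = np.asarray(points, dtype=float)
    sel = np.ones(len(pts), dtype=bool)
    sphere = fit_sphere(pts)
    for _ in range(4):
        resid = sphere.distance(pts)
        sigma = 1.4826 * float(np.median(resid[sel]))
        tol = max(0.05 * sphere.radius, 3.0 * sigma)
        new_sel = resid <= tol
        if new_sel.sum() < min_support:
            break
        if np.array_equal(new_sel, sel):
            break
        sel = new_sel
        sphere = fit_sphere(pts[sel])
    return sphere


def condyle_spheres(
    mesh: TriangleMesh,
    anatomical: Axis3D,
    distal_fraction: float = 0.20,
    side: str = "right",
) -> tuple[Sphere, Sphere]:
    """Best-fit spheres on the medial and lateral femoral condyles.

    Candidate vertices are the distal ``distal_fraction`` of projected bone
    length.  The caudal direction is bootstrapped from the mass asymmetry
    of the distal region (the condyles protrude caudally), the region is
    split medially/laterally by the plane containing the anatomical axis
    and the craniocaudal estimate, each subset is restricted to its
    distocaudal articular portion (outward normal with a positive component
    along distal+caudal) and fitted with an inlier-reselecting sphere fit;
    the caudal estimate is refined once from the provisional centers.
    Returns ``(medial, lateral)`` labelled with the side flag.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    mesh.check()
    verts = mesh.vertices
    a_hat = anatomical.direction  # proximal
    t = verts @ a_hat
    tmin, tmax = float(t.min()), float(t.max())
    length = tmax - tmin
    region = np.flatnonzero(t <= tmin + distal_fraction * length)
    if len(region) < 200:
        raise CondyleFailureError("distal candidate region too small")

    tm = mesh.to_trimesh()
    normals = np.asarray(tm.vertex_normals)

    reg_centroid = verts[region].mean(axis=0)
    caudal = unit(project_to_plane(
        reg_centroid - _closest_axis_point(anatomical, reg_centroid), a_hat
    ))

    med = lat = None
    for _pass in range(2):
        cranial = -caudal
        lateral_dir = (
            np.cross(cranial, a_hat) if side == "right"
            else np.cross(a_hat, cranial)
        )
        lateral_dir = unit(lateral_dir)
        dc = unit(-a_hat + caudal)  # distal + caudal
        articular = region[normals[region] @ dc > 0.0]
        s = (verts[articular] - anatomical.point) @ lateral_dir
        spheres = []
        for subset in (articular[s <= 0.0], articular[s > 0.0]):
            if len(subset) < 100:
                raise CondyleFailureError(
                    f"condylar support of {len(subset)} vertices (< 100)"
                )
            spheres.append(_robust_sphere(verts[subset], 100))
        med, lat = spheres
        mid = 0.5 * (med.center + lat.center)
        caudal_new = unit(project_to_plane(
            mid - _closest_axis_point(anatomical, mid), a_hat
        ))
        if float(caudal_new @ caudal) > np.cos(np.radians(1.0)):
            caudal = caudal_new
            break
        caudal = caudal_new

    # enforce the medial/lateral labels from the final lateral direction
    cranial = -caudal
    lateral_dir = unit(
        np.cross(cranial, a_hat) if side == "right"
        else np.cross(a_hat, cranial)
    )
    if (lat.center - med.center) @ lateral_dir < 0:
        med, lat = lat, med
    return med, lat


def distal_joint_line(
    cm: Sphere,
    cl: Sphere,
    anatomical: Axis3D,
    craniocaudal_init: np.ndarray,
) -> Axis3D:
    """Distal joint orientation line: common tangent of the two condylar
    spheres at their distocaudal points.

    Iteratively: with the distocaudal probe direction made orthogonal to
    the current line direction, tangent points are center + radius * probe;
    the line direction is re-estimated from the tangent points until it
    changes by less than 0.01 degrees (at most 10 iterations).  The
    returned direction points lateral (medial tangent point to lateral
    tangent point).
    """
    a_hat = anatomical.direction
    caudal = -unit(np.asarray(craniocaudal_init, dtype=float))
    d0 = unit(-a_hat + caudal)
    line_dir = unit(cl.center - cm.center)
    p_m = p_l = None
    for _ in range(10):
        d_hat = unit(d0 - (d0 @ line_dir) * line_dir)
        p_m = cm.center + cm.radius * d_hat
        p_l = cl.center + cl.radius * d_hat
        new_dir = unit(p_l - p_m)
        change = np.degrees(
            np.arccos(np.clip(abs(new_dir @ line_dir), -1.0, 1.0))
        )
        line_dir = new_dir
        if change < 0.01:
            return Axis3D(point=p_m, direction=line_dir)
    raise JointLineError("common-tangent iteration did not converge")


# ---------------------------------------------------------------------------
# frame and angles


def build_frame(
    anatomical: Axis3D,
    joint_line: Axis3D,
    head_center: np.ndarray,
    side: str,
) -> FemoralFrame:
    """Anatomical frame from the measured axes.

    The axial-plane normal is the (proximal) anatomical direction; the
    mediolateral vector is the joint-line direction projected orthogonal to
    it; the craniocaudal vector completes the right-handed/left-handed
    frame according to the declared side, so that anteversion comes out
    positive (cranial) for either side.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    a_hat = anatomical.direction
    if np.degrees(np.arccos(np.clip(abs(a_hat @ joint_line.direction),
                                    -1.0, 1.0))) < 1.0:
        raise FrameError("anatomical axis and joint line are near-parallel")
    m_hat = unit(project_to_plane(joint_line.direction, a_hat))
    c_hat = np.cross(a_hat, m_hat) if side == "right" \
        else -np.cross(a_hat, m_hat)
    c_hat = unit(c_hat)
    return FemoralFrame(
        anatomical_axis=anatomical,
        distal_joint_line=joint_line,
        mediolateral=m_hat,
        craniocaudal=c_hat,
        side=side,
    )


def compute_angles(frame: FemoralFrame, head_neck: Axis3D) -> tuple[float, float, float]:
    """aLDFA, FNA and FTA (degrees) from a frame and the head-neck axis.

    * aLDFA: frontal-plane angle between the proximal anatomical direction
      and the lateral joint-line direction (90 deg + frontal varus).
    * FNA: frontal-plane angle between the head-neck direction (into the
      head) and the distal anatomical direction.
    * FTA: signed axial-plane angle of the head-neck direction from the
      medial direction, positive cranial (anteversion).
    """
    a_hat = frame.anatomical_axis.direction
    c_hat = frame.craniocaudal
    m_lat = frame.mediolateral
    n_hat = head_neck.direction

    # aLDFA on the lateral-distal side: angle between the proximal axis
    # direction and the lateral joint-line direction
    j_proj = unit(project_to_plane(frame.distal_joint_line.direction, c_hat))
    a_proj = unit(project_to_plane(a_hat, c_hat))
    aldfa = float(np.degrees(np.arccos(np.clip(a_proj @ j_proj, -1.0, 1.0))))

    n_front = unit(project_to_plane(n_hat, c_hat))
    fna = float(np.degrees(np.arccos(np.clip(n_front @ (-a_proj), -1.0, 1.0))))

    fta = float(np.degrees(np.arctan2(n_hat @ c_hat, n_hat @ (-m_lat))))
    return aldfa, fna, fta


# ---------------------------------------------------------------------------
# orchestration


def measure_femur(
    mesh: TriangleMesh,
    seed: np.ndarray,
    side: str,
    config: MeasureConfig | None = None,
) -> FemoralMeasurement:
    """Run the full measurement pipeline on a femur mesh.

    Internal shells are removed first, so raw segmented exports are
    accepted.  Deterministic for fixed inputs and configuration; stage
    failures are re-raised as :class:`StageError` tagged with the stage
    name.
    """
    cfg = config or MeasureConfig()
    cfg.validate()
    seed = np.asarray(seed, dtype=float).reshape(3)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise StageError(name, exc) from exc

    clean = stage("clean", remove_internal_shells, mesh)
    axis, loops = stage(
        "anatomical_axis", anatomical_axis, clean,
        span=cfg.span, step=cfg.step, proximal_hint=seed,
    )
    head, neck_center, hn_axis = stage(
        "head_and_neck", head_and_neck, clean, seed,
        neck_scale=cfg.neck_scale, inclusion_tol=cfg.inclusion_tol,
        max_iter=cfg.max_iter, anatomical=axis,
    )
    cm, cl = stage(
        "condyle_spheres", condyle_spheres, clean, axis,
        distal_fraction=cfg.distal_fraction, side=side,
    )
    mid = 0.5 * (cm.center + cl.center)
    caudal = unit(project_to_plane(
        mid - _closest_axis_point(axis, mid), axis.direction
    ))
    joint = stage("distal_joint_line", distal_joint_line, cm, cl, axis, -caudal)
    frame = stage("build_frame", build_frame, axis, joint, head.center, side)
    aldfa, fna, fta = stage("compute_angles", compute_angles, frame, hn_axis)

    qc = {
        "head_rms": float(head.rms_residual),
        "condyle_rms": float(max(cm.rms_residual, cl.rms_residual)),
        "n_sections": len(loops),
        "converged": True,
        "head_support": int(head.support_count),
    }
    return FemoralMeasurement(
        aLDFA=aldfa, FNA=fna, FTA=fta,
        head=head, condyle_medial=cm, condyle_lateral=cl,
        neck_center=neck_center, head_neck_axis=hn_axis,
        frame=frame, qc=qc,
    )
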