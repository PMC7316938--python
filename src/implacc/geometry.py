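"""Implant pose representation and planned-vs-placed deviation metrics.

An implant's pose is fully described by the centre of its shoulder
(platform) and the centre of its apex: the segment between them is the
longitudinal axis.  Accuracy of guided placement is quantified by four
deviations built from the planned shoulder centre A, the placed shoulder
centre B, and two constructed points:

* **global** — the 3D Euclidean distance |A−B|;
* **lateral** — |A−C|, where C is the point where the placed implant's
  axis pierces the plane through A perpendicular to the planned axis;
* **depth** — |A−D|, where D is the orthogonal projection of B onto the
  planned axis (the foot of the plane, parallel to the shoulder plane,
  that passes through B);
* **angular** — the angle α between the two longitudinal axes.

All coordinates are in millimetres, in a right-handed frame.  Post-op
data must already be registered into the planning frame (see
:mod:`implacc.registration`) before the metrics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "GeometryError",
    "PairingError",
    "UndefinedLateralError",
    "ImplantPose",
    "DeviationRecord",
    "RigidTransform",
    "axis_of",
    "angular_deviation",
    "global_deviation",
    "lateral_deviation",
    "depth_deviation",
    "deviate",
    "apply_transform",
]

#: parallelism guard for the point-C construction
PARALLELISM_TOL = 1e-6
#: tolerance for geometric identities (orthonormality, axis length)
GEOM_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid or degenerate geometric input."""


class PairingError(ValueError):
    """Planned and placed poses do not refer to the same implant site."""


class UndefinedLateralError(GeometryError):
    """The placed axis (nearly) lies in the shoulder plane: point C is
    not uniquely defined."""


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"{name} has non-finite components: {a}")
    return a


@dataclass(frozen=True)
class ImplantPose:
    """One implant's identity and pose (shoulder and apex centres, mm).

    ``role`` distinguishes the virtually planned pose from the pose
    achieved at surgery ("placed").  ``location`` is the FDI two-digit
    tooth code (e.g. "13" = upper right canine).
    """

    patient_id: str
    implant_id: str
    location: str
    role: str  # "planned" | "placed"
    shoulder: np.ndarray
    apex: np.ndarray
    length_mm: Optional[float] = None
    diameter_mm: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "shoulder", _as_vec3(self.shoulder, "shoulder"))
        object.__setattr__(self, "apex", _as_vec3(self.apex, "apex"))
        if self.role not in ("planned", "placed"):
            raise GeometryError(f"role must be 'planned' or 'placed', got {self.role!r}")
        d = float(np.linalg.norm(self.apex - self.shoulder))
        if d <= 0.0:
            raise GeometryError("degenerate pose: shoulder coincides with apex")
        if self.length_mm is not None:
            if self.length_mm <= 0:
                raise GeometryError("length_mm must be positive")
            if abs(d - self.length_mm) > 0.05 * self.length_mm:
                raise GeometryError(
                    f"shoulder-apex distance {d:.3f} mm inconsistent with "
                    f"declared length {self.length_mm} mm (>5% off)"
                )
        if self.diameter_mm is not None and self.diameter_mm <= 0:
            raise GeometryError("diameter_mm must be positive")

    @property
    def axis_length_mm(self) -> float:
        return float(np.linalg.norm(self.apex - self.shoulder))


@dataclass(frozen=True)
class DeviationRecord:
    """The four deviation metrics for one planned/placed implant pair.

    ``lateral_mm`` and ``point_c`` are ``None`` when the placed axis lies
    in the shoulder plane (point C undefined); an implant whose accuracy
    could not be measured at all (e.g. a template misfit) carries ``None``
    in every metric.  ``depth_signed_mm`` is positive when the placed
    shoulder sits apical of the planned one (displaced along the
    shoulder→apex direction); tables report the magnitude only.
    """

    patient_id: str
    location: str
    angular_deg: Optional[float]
    global_mm: Optional[float]
    depth_mm: Optional[float]
    depth_signed_mm: Optional[float]
    lateral_mm: Optional[float]
    point_c: Optional[np.ndarray] = None
    point_d: Optional[np.ndarray] = None
    implant_length_mm: Optional[float] = None

    def __post_init__(self):
        if self.angular_deg is not None and not 0 <= self.angular_deg < 180:
            raise GeometryError(f"angular_deg out of [0, 180): {self.angular_deg}")
        for name in ("global_mm", "depth_mm", "lateral_mm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise GeometryError(f"{name} must be >= 0")
        if (self.depth_mm is None) != (self.depth_signed_mm is None):
            raise GeometryError("depth_mm and depth_signed_mm must be set together")
        if self.depth_mm is not None and abs(abs(self.depth_signed_mm) - self.depth_mm) > 1e-9:
            raise GeometryError("depth_mm must equal |depth_signed_mm|")

    @property
    def is_missing(self) -> bool:
        """True when no metric could be measured for this implant."""
        return self.angular_deg is None and self.global_mm is None


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = _as_vec3(self.translation, "translation")
        if R.shape != (3, 3):
            raise GeometryError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=GEOM_TOL):
            raise GeometryError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > GEOM_TOL:
            raise GeometryError("rotation is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of points through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))


def perpendicular_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair spanning the plane normal to a unit axis."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def axis_of(pose: ImplantPose) -> np.ndarray:
    """Unit longitudinal axis, oriented shoulder→apex."""
    d = pose.apex - pose.shoulder
    n = np.linalg.norm(d)
    if n <= 0:
        raise GeometryError("degenerate pose: shoulder coincides with apex")
    return d / n


def angular_deviation(planned: ImplantPose, placed: ImplantPose) -> float:
    """Angle α between the two longitudinal axes, in degrees ∈ [0, 180).

    Computed with atan2(|u×v|, u·v), which is numerically stable for
    near-parallel axes where arccos loses precision.  Axes are oriented
    shoulder→apex and the angle is *not* folded into [0, 90]: an implant
    placed upside-down reads near 180° and triggers a warning instead of
    silently looking accurate.
    """
    u = axis_of(planned)
    v = axis_of(placed)
    ang = float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))
    if ang >= 180.0:  # arctan2 can only hit 180 exactly for anti-parallel input
        ang = np.nextafter(180.0, 0.0)
    if ang > 90.0:
        warnings.warn(
            f"angular deviation {ang:.1f}° exceeds 90°: placed axis points "
            "against the planned axis (possible flipped pose)",
            stacklevel=2,
        )
    return ang


def global_deviation(planned: ImplantPose, placed: ImplantPose) -> float:
    """3D distance between planned (A) and placed (B) shoulder centres."""
    return float(np.linalg.norm(placed.shoulder - planned.shoulder))


def lateral_deviation(planned: ImplantPose, placed: ImplantPose) -> tuple[float, np.ndarray]:
    """Distance |A−C| and point C.

    C is the intersection of the placed implant's axis with the plane
    through the planned shoulder centre A perpendicular to the planned
    axis.  Raises :class:`UndefinedLateralError` when the placed axis is
    within the parallelism tolerance of lying in that plane.
    """
    u = axis_of(planned)
    v = axis_of(placed)
    denom = float(np.dot(v, u))
    if abs(denom) <= PARALLELISM_TOL:
        raise UndefinedLateralError(
            "placed axis is (nearly) parallel to the planned shoulder plane; "
            "point C has no unique definition"
        )
    A = planned.shoulder
    B = placed.shoulder
    t = -float(np.dot(B - A, u)) / denom
    C = B + t * v
    return float(np.linalg.norm(C - A)), C


def depth_deviation(planned: ImplantPose, placed: ImplantPose) -> tuple[float, float, np.ndarray]:
    """(|A−D|, signed depth, point D).

    D is the foot on the planned axis of the plane, parallel to the
    planned shoulder plane, that passes through the placed shoulder B.
    The signed value is positive when B sits apical of A.
    """
    u = axis_of(planned)
    signed = float(np.dot(placed.shoulder - planned.shoulder, u))
    D = planned.shoulder + signed * u
    return abs(signed), signed, D


def deviate(planned: ImplantPose, placed: ImplantPose) -> DeviationRecord:
    """Assemble all four deviation metrics for one matched implant pair.

    The poses must refer to the same patient and FDI site.  When point C
    is undefined the lateral fields carry an explicit ``None``; the other
    three metrics are still reported.
    """
    if planned.patient_id != placed.patient_id or planned.location != placed.location:
        raise PairingError(
            f"pose pair mismatch: planned ({planned.patient_id}, {planned.location}) "
            f"vs placed ({placed.patient_id}, {placed.location})"
        )
    ang = angular_deviation(planned, placed)
    glob = global_deviation(planned, placed)
    depth, signed, D = depth_deviation(planned, placed)
    try:
        lat, C = lateral_deviation(planned, placed)
    except UndefinedLateralError:
        lat, C = None, None
    return DeviationRecord(
        patient_id=planned.patient_id,
        location=planned.location,
        angular_deg=ang,
        global_mm=glob,
        lateral_mm=lat,
        depth_mm=depth,
        depth_signed_mm=signed,
        point_c=C,
        point_d=D,
        implant_length_mm=planned.length_mm,
    )


def apply_transform(pose: ImplantPose, t: RigidTransform) -> ImplantPose:
    """Map a pose rigidly into another frame (axis length preserved)."""
    return replace(pose, shoulder=t.apply(pose.shoulder), apex=t.apply(pose.apex))
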