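"""Synthetic cohorts with the error anatomy of semi-guided implant surgery.

A patient-specific drilling template constrains drill position and angle
through metal sleeves, but in a semi-guided protocol the implant itself
is seated freehand.  Placement error therefore decomposes into:

* **template seating** — one rigid misfit per patient: a small rotation
  about a roughly horizontal axis through the fulcrum point where the
  template braces against the nasal aperture, plus a small translation.
  All of that patient's implants share it, and its lateral effect grows
  with the lever arm from the fulcrum;
* **sleeve wobble** — an independent per-implant tilt of the drilled
  axis (drill clearance inside the sleeve), with uniform azimuth;
* **unguided depth** — an independent slide along the drilled axis,
  because insertion depth is not mechanically stopped;
* **observer noise** — small pose perturbations added when a human reads
  the achieved position off the post-op scan, used to build ratings
  matrices for inter-observer agreement analysis.

The arch is a schematic circular arc (no anatomical mesh): only the
error geometry matters for exercising the deviation metrics.  Rotation
magnitudes are half-normal (|N(0, σ)|), so a single active error source
has a closed-form mean deviation of σ·√(2/π) — the calibration handle
the tests use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .agreement import RatingsMatrix
from .geometry import (
    DeviationRecord,
    ImplantPose,
    RigidTransform,
    deviate,
    perpendicular_basis as _perp_basis,
)
from .registration import PointCloud

__all__ = [
    "CohortParams",
    "SimulatedPair",
    "make_cohort",
    "lever_arm_check",
    "make_implant_cloud",
    "simulate_observer_ratings",
]

_IMPLANT_LENGTH_MM = 13.0
_IMPLANT_DIAMETER_MM = 3.5
_PLANNED_TILT_DEG = 8.0  # bucco-lingual inclination of planned axes


@dataclass(frozen=True)
class CohortParams:
    """Simulation parameters (all lengths mm, angles degrees).

    Defaults are calibrated so that the default cohort's summary means
    land in the range guided-surgery accuracy studies report for the
    atrophic maxilla (mean angular deviation of several degrees, global
    deviation around 1 mm).
    """

    n_patients: int = 11
    implants_per_patient: int = 2
    arch_radius_mm: float = 25.0
    fulcrum_offset_mm: tuple = (0.0, 8.0, 18.0)
    sigma_seat_deg: float = 1.0
    sigma_seat_trans_mm: float = 0.3
    sigma_sleeve_deg: float = 8.0
    sigma_depth_mm: float = 0.7
    sigma_observer_mm: float = 0.1
    sigma_observer_deg: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 2 <= self.implants_per_patient <= 4:
            raise ValueError("implants_per_patient must be in [2, 4]")
        if self.arch_radius_mm <= 0:
            raise ValueError("arch_radius_mm must be positive")
        if len(self.fulcrum_offset_mm) != 3:
            raise ValueError("fulcrum_offset_mm must be a 3-vector")
        for name in (
            "sigma_seat_deg",
            "sigma_seat_trans_mm",
            "sigma_sleeve_deg",
            "sigma_depth_mm",
            "sigma_observer_mm",
            "sigma_observer_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulatedPair:
    """A planned/placed pose pair with its exactly computed deviations."""

    planned: ImplantPose
    placed: ImplantPose
    truth: DeviationRecord


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, dtype=float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _planned_layout(params: CohortParams) -> list[ImplantPose]:
    """Planned poses for one patient: evenly spaced on the anterior arch,
    axes tilted outward by a fixed small angle from vertical."""
    m = params.implants_per_patient
    R = params.arch_radius_mm
    # anterior arc centred on +y, spread widens with implant count
    half_span = np.radians(15.0 + 12.0 * (m - 1))
    angles = np.linspace(-half_span, half_span, m) + np.pi / 2
    tilt = np.radians(_PLANNED_TILT_DEG)
    poses = []
    fdi = {2: ["13", "23"], 3: ["13", "11", "23"], 4: ["13", "11", "21", "23"]}[m]
    for j, th in enumerate(angles):
        radial = np.array([np.cos(th), np.sin(th), 0.0])
        shoulder = R * radial
        axis = np.array([0.0, 0.0, 1.0]) * np.cos(tilt) + radial * np.sin(tilt)
        apex = shoulder + _IMPLANT_LENGTH_MM * axis
        poses.append(
            ImplantPose(
                patient_id="",
                implant_id="",
                location=fdi[j],
                role="planned",
                shoulder=shoulder,
                apex=apex,
                length_mm=_IMPLANT_LENGTH_MM,
                diameter_mm=_IMPLANT_DIAMETER_MM,
            )
        )
    return poses


def _seating_transform(
    rng: np.random.Generator, fulcrum: np.ndarray, sigma_deg: float, sigma_trans: float
) -> RigidTransform:
    """One template-seating misfit: rotation about a random horizontal
    axis through the fulcrum, composed with a per-component translation."""
    angle = abs(rng.normal(0.0, sigma_deg))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    delta = rng.normal(0.0, sigma_trans, size=3) if sigma_trans > 0 else np.zeros(3)
    u = np.array([np.cos(phi), np.sin(phi), 0.0])
    R = _rotation_about(u, np.radians(angle))
    # x -> R (x - f) + f + delta
    return RigidTransform(R, fulcrum - R @ fulcrum + delta)


def _tilt_pose(pose: ImplantPose, rng: np.random.Generator, sigma_deg: float) -> ImplantPose:
    """Per-implant sleeve wobble: tilt about the shoulder, uniform azimuth."""
    theta = abs(rng.normal(0.0, sigma_deg))
    psi = rng.uniform(0.0, 2.0 * np.pi)
    axis = (pose.apex - pose.shoulder) / np.linalg.norm(pose.apex - pose.shoulder)
    e1, e2 = _perp_basis(axis)
    rot_axis = np.cos(psi) * e1 + np.sin(psi) * e2
    R = _rotation_about(rot_axis, np.radians(theta))
    new_apex = pose.shoulder + R @ (pose.apex - pose.shoulder)
    return replace(pose, apex=new_apex)


def _slide_pose(pose: ImplantPose, rng: np.random.Generator, sigma_mm: float) -> ImplantPose:
    """Unguided insertion depth: slide along the (drilled) placed axis."""
    s = rng.normal(0.0, sigma_mm) if sigma_mm > 0 else 0.0
    axis = (pose.apex - pose.shoulder) / np.linalg.norm(pose.apex - pose.shoulder)
    return replace(pose, shoulder=pose.shoulder + s * axis, apex=pose.apex + s * axis)


def make_cohort(params: CohortParams) -> list[SimulatedPair]:
    """Simulate a cohort of paired planned/placed implant poses.

    Random draws are consumed in a fixed documented order — per patient:
    seating rotation angle, seating axis azimuth, seating translation;
    then per implant: tilt angle, tilt azimuth, depth slide — so cohorts
    are bit-reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    fulcrum = np.asarray(params.fulcrum_offset_mm, dtype=float)
    template = _planned_layout(params)
    pairs: list[SimulatedPair] = []
    for p in range(1, params.n_patients + 1):
        seat = _seating_transform(rng, fulcrum, params.sigma_seat_deg, params.sigma_seat_trans_mm)
        for j, proto in enumerate(template):
            planned = replace(
                proto, patient_id=str(p), implant_id=f"P{p}-{proto.location}"
            )
            placed = replace(
                planned,
                role="placed",
                shoulder=seat.apply(planned.shoulder),
                apex=seat.apply(planned.apex),
            )
            placed = _tilt_pose(placed, rng, params.sigma_sleeve_deg)
            placed = _slide_pose(placed, rng, params.sigma_depth_mm)
            pairs.append(SimulatedPair(planned, placed, deviate(planned, placed)))
    return pairs


def lever_arm_check(
    params: CohortParams,
    distances_mm: Sequence[float],
    n_samples: int = 4000,
) -> list[tuple[float, float]]:
    """Mean lateral deviation vs distance from the seating fulcrum.

    Requires a pure seating-rotation regime (every other sigma zero).
    For an implant whose shoulder sits ``d`` mm from the fulcrum, a
    seating rotation of angle θ displaces the shoulder by ≈ d·θ, so the
    mean lateral deviation grows linearly with the lever arm — the
    mechanical rationale for bracing the template as close to the
    implants as the anatomy allows.
    """
    others = (
        params.sigma_seat_trans_mm,
        params.sigma_sleeve_deg,
        params.sigma_depth_mm,
        params.sigma_observer_mm,
        params.sigma_observer_deg,
    )
    if any(s != 0 for s in others):
        raise ValueError("lever_arm_check requires all non-seating sigmas to be zero")
    rng = np.random.default_rng(params.seed)
    fulcrum = np.asarray(params.fulcrum_offset_mm, dtype=float)
    up = np.array([0.0, 0.0, 1.0])
    out = []
    for d in distances_mm:
        if d < 0:
            raise ValueError("distances must be >= 0")
        shoulder = fulcrum - d * up
        planned = ImplantPose(
            patient_id="lever",
            implant_id=f"d{d}",
            location="11",
            role="planned",
            shoulder=shoulder,
            apex=shoulder + _IMPLANT_LENGTH_MM * up,
        )
        lat = np.empty(n_samples)
        for i in range(n_samples):
            seat = _seating_transform(rng, fulcrum, params.sigma_seat_deg, 0.0)
            placed = replace(
                planned,
                role="placed",
                shoulder=seat.apply(planned.shoulder),
                apex=seat.apply(planned.apex),
            )
            lat[i] = deviate(planned, placed).lateral_mm
        out.append((float(d), float(lat.mean())))
    return out


def make_implant_cloud(
    pose: ImplantPose,
    radius_mm: float = _IMPLANT_DIAMETER_MM / 2,
    n_points: int = 2000,
    surface_sigma_mm: float = 0.0,
    scatter_fraction: float = 0.0,
    seed: int = 0,
) -> PointCloud:
    """Sample a segmented-implant-like point cloud around a pose.

    Points are drawn area-uniformly on a capped cylinder along the pose
    axis (shoulder cap, wall, apex cap), perturbed along the local
    surface normal by N(0, ``surface_sigma_mm``).  ``scatter_fraction``
    of the points are then replaced by uniform outliers inside a box of
    half-width 5 radii around the implant — emulating the scattered
    reconstruction a titanium implant produces in CBCT.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if not 0.0 <= scatter_fraction < 1.0:
        raise ValueError("scatter_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    L = pose.axis_length_mm
    axis = (pose.apex - pose.shoulder) / L
    e1, e2 = _perp_basis(axis)
    r = radius_mm

    area_wall = 2.0 * np.pi * r * L
    area_cap = np.pi * r * r
    probs = np.array([area_cap, area_wall, area_cap])
    probs = probs / probs.sum()
    region = rng.choice(3, size=n_points, p=probs)  # 0 shoulder cap, 1 wall, 2 apex cap

    pts = np.empty((n_points, 3))
    normals = np.empty((n_points, 3))
    for i in range(n_points):
        if region[i] == 1:
            z = rng.uniform(0.0, L)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            radial = np.cos(phi) * e1 + np.sin(phi) * e2
            pts[i] = pose.shoulder + z * axis + r * radial
            normals[i] = radial
        else:
            rho = r * np.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * np.pi)
            radial = np.cos(phi) * e1 + np.sin(phi) * e2
            base = pose.shoulder if region[i] == 0 else pose.apex
            pts[i] = base + rho * radial
            normals[i] = -axis if region[i] == 0 else axis
    if surface_sigma_mm > 0:
        pts += normals * rng.normal(0.0, surface_sigma_mm, size=n_points)[:, None]

    n_out = int(round(scatter_fraction * n_points))
    if n_out > 0:
        centre = 0.5 * (pose.shoulder + pose.apex)
        half = np.array([5 * r, 5 * r, L / 2 + 5 * r])
        local = rng.uniform(-1.0, 1.0, size=(n_out, 3)) * half
        frame = np.stack([e1, e2, axis], axis=1)
        pts[n_points - n_out :] = centre + local @ frame.T
    return PointCloud(pts)


def simulate_observer_ratings(
    pairs: Sequence[SimulatedPair],
    n_observers: int = 2,
    sigma_mm: float = 0.1,
    sigma_deg: float = 0.5,
    seed: int = 0,
    metric: str = "global_mm",
) -> RatingsMatrix:
    """Ratings matrix for inter-observer agreement on one deviation metric.

    Each observer independently re-measures every placed pose with small
    translation and tilt perturbations (reading error on the post-op
    scan), and the chosen deviation metric is recomputed per observer —
    the input the intraclass correlation analysis expects.
    """
    if n_observers < 2:
        raise ValueError("need >= 2 observers")
    rng = np.random.default_rng(seed)
    n = len(pairs)
    values = np.empty((n, n_observers))
    for j in range(n_observers):
        for i, pair in enumerate(pairs):
            noisy = pair.placed
            if sigma_mm > 0:
                shift = rng.normal(0.0, sigma_mm, size=3)
                noisy = replace(noisy, shoulder=noisy.shoulder + shift, apex=noisy.apex + shift)
            if sigma_deg > 0:
                noisy = _tilt_pose(noisy, rng, sigma_deg)
            rec = deviate(pair.planned, noisy)
            values[i, j] = getattr(rec, metric)
    return RatingsMatrix(
        values,
        subject_ids=[p.planned.implant_id for p in pairs],
        observer_ids=[f"observer_{j + 1}" for j in range(n_observers)],
    )
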