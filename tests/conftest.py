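"""Shared fixtures and independent oracles.

The oracle functions deliberately take different computational routes
from the library (root finding for the line–plane intersection, arccos
for the angle, loop-based ANOVA sums of squares) so that agreement
between the two is a real check, not a tautology.
"""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from implacc import ImplantPose, RigidTransform


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_pose(shoulder, apex, role="planned", patient="p1", location="13", **kw):
    return ImplantPose(
        patient_id=patient,
        implant_id=f"{patient}-{location}-{role}",
        location=location,
        role=role,
        shoulder=np.asarray(shoulder, float),
        apex=np.asarray(apex, float),
        **kw,
    )


def random_pose_pair(rng, min_axis_dot=1e-3):
    """A random valid planned/placed pair whose lateral metric is defined."""
    while True:
        A = rng.uniform(-20, 20, 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        B = A + rng.normal(0, 2.0, 3)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if abs(np.dot(u, v)) > min_axis_dot:
            break
    L = rng.uniform(8, 18)
    planned = make_pose(A, A + L * u, role="planned")
    placed = make_pose(B, B + L * v, role="placed")
    return planned, placed


def random_rigid(rng):
    return RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.uniform(-30, 30, 3))


# ---------------------------------------------------------------- oracles

def oracle_angular_deg(planned, placed):
    u = planned.apex - planned.shoulder
    v = placed.apex - placed.shoulder
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def oracle_global_mm(planned, placed):
    return float(np.sqrt(np.sum((placed.shoulder - planned.shoulder) ** 2)))


def oracle_point_c(planned, placed):
    """Point C by bracketed root finding along the placed axis."""
    u = planned.apex - planned.shoulder
    u = u / np.linalg.norm(u)
    v = placed.apex - placed.shoulder
    v = v / np.linalg.norm(v)
    A, B = planned.shoulder, placed.shoulder

    def f(s):
        return float(np.dot(B + s * v - A, u))

    span = 10.0 * (1.0 + np.linalg.norm(B - A)) / max(abs(np.dot(v, u)), 1e-9)
    s = brentq(f, -span, span, xtol=1e-13, rtol=1e-15)
    return B + s * v


def oracle_point_d(planned, placed):
    """Point D by root finding along the planned axis against the plane
    through B parallel to the planned shoulder plane."""
    u = planned.apex - planned.shoulder
    u = u / np.linalg.norm(u)
    A, B = planned.shoulder, placed.shoulder

    def f(s):
        return float(np.dot(A + s * u - B, u))

    span = 10.0 * (1.0 + np.linalg.norm(B - A))
    s = brentq(f, -span, span, xtol=1e-13, rtol=1e-15)
    return A + s * u


def oracle_deviations(planned, placed):
    """All four metrics from direct point constructions."""
    C = oracle_point_c(planned, placed)
    D = oracle_point_d(planned, placed)
    return {
        "angular_deg": oracle_angular_deg(planned, placed),
        "global_mm": oracle_global_mm(planned, placed),
        "lateral_mm": float(np.linalg.norm(C - planned.shoulder)),
        "depth_mm": float(np.linalg.norm(D - planned.shoulder)),
        "point_c": C,
        "point_d": D,
    }


def oracle_icc_a1(x):
    """ICC(A,1) from loop-computed two-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = 0.0
    for i in range(n):
        m = sum(x[i, j] for j in range(k)) / k
        ss_rows += k * (m - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        m = sum(x[i, j] for i in range(n)) / n
        ss_cols += n * (m - grand) ** 2
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
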