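"""Rotation algebra for dual-body relative-orientation analysis.

A focused refinement assigns each particle a ZYZ Euler triple
``(rot, tilt, psi)`` per rigid body; the corresponding rotation matrix is

    R = Rz(psi) @ Ry(tilt) @ Rz(rot)

under the right-handed, counter-clockwise-positive convention of the
refinement package producing the STAR files.  The relative orientation of
the condensing body in the modifying-body frame is

    R_rel = R_mod.T @ R_cond

and is reported as intrinsic z-y-x (Tait-Bryan) angles (alpha, beta, gamma)
with ``R_rel = Rz(alpha) @ Ry(beta) @ Rx(gamma)``, alpha being the swivel
about the long axis.  Canonical ranges: alpha, gamma in (-180, 180],
beta in [-90, 90].

All public angles are degrees; radians appear only transiently inside the
trigonometric kernels.  Functions accept scalars or stacked arrays
(leading axes broadcast), so a whole particle table decomposes in one call.

Worked example (matching the documented convention): (rot, tilt, psi) =
(90, 0, 0) is a pure +90 degree rotation about z and maps the unit x axis
onto the unit y axis.
"""

from __future__ import annotations

import numpy as np

#: Frobenius tolerance for the orthonormality / unit-determinant check.
ORTHONORMAL_TOL = 1e-9
#: Tolerance below which two equivalent orientations are collapsed.
DUPLICATE_TOL = 1e-9
#: |beta - 90| threshold for gimbal-lock handling in the z-y-x decomposition.
GIMBAL_TOL_DEG = 1e-7

_Z = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# elementary rotations

def rot_z(angle_deg):
    """Rotation matrix about z; accepts scalars or arrays (stacked output)."""
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def rot_y(angle_deg):
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def rot_x(angle_deg):
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def axis_angle_matrix(axis, angle_deg):
    """Rodrigues rotation about an arbitrary unit axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if not np.isclose(n, 1.0, atol=1e-6):
        raise ValueError(f"axis must be unit length, got |axis| = {n:.6g}")
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    t = np.deg2rad(angle_deg)
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def check_rotation(m, name: str = "matrix") -> np.ndarray:
    """Validate orthonormality and det = +1; returns the array."""
    m = np.asarray(m, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise ValueError(f"{name} must be 3x3, got shape {m.shape}")
    eye = np.broadcast_to(np.eye(3), m.shape)
    err = np.linalg.norm(np.swapaxes(m, -1, -2) @ m - eye, axis=(-2, -1))
    if np.any(err >= ORTHONORMAL_TOL):
        raise ValueError(f"{name} is not orthonormal (‖MᵀM−I‖_F = {err.max():.3g})")
    det = np.linalg.det(m)
    if np.any(np.abs(det - 1.0) >= ORTHONORMAL_TOL):
        raise ValueError(f"{name} has det = {np.atleast_1d(det).max():.12g}, not +1")
    return m


def wrap_angle(angle_deg):
    """Wrap into the canonical (-180, 180] interval."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


# ---------------------------------------------------------------------------
# ZYZ (refinement) convention

def euler_zyz_to_matrix(rot, tilt=None, psi=None):
    """ZYZ Euler triple(s) in degrees -> rotation matrix R = Rz(psi)Ry(tilt)Rz(rot).

    Accepts three scalars/arrays or a single (..., 3) array ordered
    (rot, tilt, psi).
    """
    if tilt is None:
        e = np.asarray(rot, dtype=float)
        rot, tilt, psi = e[..., 0], e[..., 1], e[..., 2]
    rot = np.asarray(rot, dtype=float)
    if not (np.all(np.isfinite(rot)) and np.all(np.isfinite(tilt)) and np.all(np.isfinite(psi))):
        raise ValueError("Euler angles must be finite")
    return rot_z(psi) @ rot_y(tilt) @ rot_z(rot)


def matrix_to_euler_zyz(m):
    """Inverse of :func:`euler_zyz_to_matrix`; tilt in [0, 180].

    At tilt = 0 or 180 the in-plane degree of freedom goes to psi
    (rot := 0), matching common refinement-package output.
    """
    m = np.asarray(m, dtype=float)
    tilt = np.rad2deg(np.arctan2(np.hypot(m[..., 0, 2], m[..., 1, 2]), m[..., 2, 2]))
    degenerate = np.sin(np.deg2rad(tilt)) < 1e-9
    flip = np.where(m[..., 2, 2] < 0, -1.0, 1.0)  # tilt ~ 180 vs tilt ~ 0
    psi = np.where(
        degenerate,
        np.rad2deg(np.arctan2(flip * m[..., 1, 0], flip * m[..., 0, 0])),
        np.rad2deg(np.arctan2(m[..., 1, 2], m[..., 0, 2])),
    )
    rot = np.where(
        degenerate,
        0.0,
        np.rad2deg(np.arctan2(m[..., 2, 1], -m[..., 2, 0])),
    )
    out = np.stack([rot, tilt, psi], axis=-1)
    return out if out.ndim > 1 else out


# ---------------------------------------------------------------------------
# relative rotation and z-y-x decomposition

def relative_rotation(r_mod, r_cond):
    """Relative orientation R_mod.T @ R_cond (modifying body = reference frame)."""
    r_mod = check_rotation(r_mod, "r_mod")
    r_cond = check_rotation(r_cond, "r_cond")
    return np.swapaxes(r_mod, -1, -2) @ r_cond


def euler_zyx_to_matrix(alpha, beta=None, gamma=None):
    """(alpha, beta, gamma) in degrees -> Rz(alpha) @ Ry(beta) @ Rx(gamma)."""
    if beta is None:
        e = np.asarray(alpha, dtype=float)
        alpha, beta, gamma = e[..., 0], e[..., 1], e[..., 2]
    return rot_z(alpha) @ rot_y(beta) @ rot_x(gamma)


def matrix_to_euler_zyx(m, validate: bool = True):
    """Decompose rotation(s) into intrinsic z-y-x angles (alpha, beta, gamma).

    With R = Rz(a)Ry(b)Rx(g):

        R[2,0] = -sin(b)          -> beta  = arcsin(-R[2,0]) in [-90, 90]
        R[1,0]/R[0,0] = tan(a)    -> alpha = atan2(R[1,0], R[0,0])
        R[2,1]/R[2,2] = tan(g)    -> gamma = atan2(R[2,1], R[2,2])

    At gimbal lock (|beta| = 90 within GIMBAL_TOL_DEG) only alpha -/+ gamma
    is determined; gamma is set to 0 and alpha absorbs the free angle, so
    the rebuilt matrix still reproduces the input.
    Returns a (..., 3) array of degrees.
    """
    if validate:
        m = check_rotation(m)
    else:
        m = np.asarray(m, dtype=float)
    sb = np.clip(-m[..., 2, 0], -1.0, 1.0)
    beta = np.rad2deg(np.arcsin(sb))
    locked = 90.0 - np.abs(beta) < GIMBAL_TOL_DEG
    alpha = np.where(
        locked,
        np.rad2deg(np.arctan2(-m[..., 0, 1], m[..., 1, 1])),
        np.rad2deg(np.arctan2(m[..., 1, 0], m[..., 0, 0])),
    )
    gamma = np.where(
        locked,
        0.0,
        np.rad2deg(np.arctan2(m[..., 2, 1], m[..., 2, 2])),
    )
    beta = np.where(locked, np.sign(sb) * 90.0, beta)
    return np.stack([wrap_angle(alpha), beta, wrap_angle(gamma)], axis=-1)


# ---------------------------------------------------------------------------
# C2 symmetry handling

def c2_equivalents(orientation, axis_mod=_Z, axis_cond=_Z):
    """All z-y-x orientations equivalent under the C2 operator of either body.

    Symmetry expansion composes each body's pose with its internal C2
    operator S (a 180-degree rotation about the body's symmetry axis), so
    the relative rotation R maps onto S_modᵀ R S_cond for S in {I, C2}.
    Returns the deduplicated list (at most 4 members, 1e-9 collapse).
    """
    c_mod = axis_angle_matrix(axis_mod, 180.0)
    c_cond = axis_angle_matrix(axis_cond, 180.0)
    r = euler_zyx_to_matrix(np.asarray(orientation, dtype=float))
    members: list[np.ndarray] = []
    for left in (np.eye(3), c_mod.T):
        for right in (np.eye(3), c_cond):
            candidate = left @ r @ right
            if not any(np.linalg.norm(candidate - m) < DUPLICATE_TOL for m in members):
                members.append(candidate)
    return [tuple(matrix_to_euler_zyx(m, validate=False)) for m in members]


def canonicalize(orientation, axis_mod=_Z, axis_cond=_Z):
    """Deterministic C2-class representative: lexicographic min of (|beta|, |alpha|, |gamma|).

    Ties (e.g. symmetric orientations) break on the signed (beta, alpha,
    gamma) triple so the choice is total; idempotent by construction.
    """
    best = min(
        c2_equivalents(orientation, axis_mod, axis_cond),
        key=lambda o: (
            round(abs(o[1]), 9), round(abs(o[0]), 9), round(abs(o[2]), 9),
            round(o[1], 9), round(o[0], 9), round(o[2], 9),
        ),
    )
    return tuple(float(v) for v in best)


def canonicalize_stack(orientations, axis_mod=_Z, axis_cond=_Z):
    """Vectorized :func:`canonicalize` over an (n, 3) orientation array."""
    o = np.asarray(orientations, dtype=float)
    c_mod = axis_angle_matrix(axis_mod, 180.0)
    c_cond = axis_angle_matrix(axis_cond, 180.0)
    r = euler_zyx_to_matrix(o)                       # (n, 3, 3)
    variants = np.stack([
        matrix_to_euler_zyx(r, validate=False),
        matrix_to_euler_zyx(r @ c_cond, validate=False),
        matrix_to_euler_zyx(c_mod.T @ r, validate=False),
        matrix_to_euler_zyx(c_mod.T @ r @ c_cond, validate=False),
    ])                                               # (4, n, 3)
    key = np.stack([
        np.round(np.abs(variants[..., 1]), 9),
        np.round(np.abs(variants[..., 0]), 9),
        np.round(np.abs(variants[..., 2]), 9),
        np.round(variants[..., 1], 9),
        np.round(variants[..., 0], 9),
        np.round(variants[..., 2], 9),
    ], axis=-1)                                      # (4, n, 6)
    order = np.lexsort(np.moveaxis(key, -1, 0)[::-1], axis=0)[0]
    return variants[order, np.arange(o.shape[0])]
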