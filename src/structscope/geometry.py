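"""Small 3-D geometry helpers shared by the builder and generator modules.

Everything here operates on plain ``numpy`` arrays of shape ``(3,)`` or
``(n, 3)``; structure-aware code lives in :mod:`structscope.model` and above.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "canonical_backbone",
    "rotation_about_axis",
    "random_rotation",
    "apply_rigid",
]


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D bonded to ``c`` from internal coordinates (NeRF).

    ``bond`` is the c-D distance, ``angle_deg`` the b-c-D angle and
    ``dihedral_deg`` the a-b-c-D torsion, all in Å / degrees.
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise ValueError("reference atoms a, b, c are collinear")
    n = n / n_norm
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def canonical_backbone() -> dict[str, np.ndarray]:
    """Ideal backbone frame: CA at the origin, N along -x, C in the xy-plane.

    Bond lengths/angles are standard peptide values (N-CA 1.458 Å,
    CA-C 1.525 Å, N-CA-C 111°).
    """
    n = np.array([-1.458, 0.0, 0.0])
    ca = np.zeros(3)
    c = 1.525 * np.array([np.cos(np.radians(69.0)), np.sin(np.radians(69.0)), 0.0])
    o = place_atom(n, ca, c, 1.231, 120.5, -40.0)
    return {"N": n, "CA": ca, "C": c, "O": o}


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to one point or an array of points."""
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)
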