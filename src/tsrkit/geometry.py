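"""Triangle geometry: edge lengths, the length representative MaxDist,
and the angle representative Theta.

For a triangle with role-ordered vertices (li1, li2, li3):

* ``d12`` — distance between the li1 and li2 vertices,
* ``d13`` — distance between the li1 and li3 vertices,
* ``d3``  — distance from the midpoint of the li1–li2 edge to li3,
* ``MaxDist`` (D) — the maximum pairwise vertex distance,
* ``theta`` (θΔ) — θ1 folded into [0°, 90°], where

  θ1 = arccos( (d13² − (d12/2)² − d3²) / (2 · (d12/2) · d3) )

  and θΔ = θ1 if θ1 ≤ 90° else 180° − θ1.

The fold makes θΔ independent of the sign convention inside the arccos
argument.  Triangles with coincident vertices or with li3 on the
midpoint of the li1–li2 edge (d3 = 0) have no defined angle and are
flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TriangleRecord", "DegenerateTriangleError", "triangle_geometry",
           "triangle_geometry_arrays", "GEOMETRY_DECIMALS"]

#: MaxDist/Theta are rounded to this many decimals before discretization,
#: so geometrically identical triangles observed in different rigid frames
#: produce bit-identical values (float noise from rotations is ~1e-13 Å)
#: and the same-value-same-bin guarantee of the binning step applies.
GEOMETRY_DECIMALS = 6

_EPS = 1e-9


class DegenerateTriangleError(ValueError):
    """Raised for triangles whose angle representative is undefined."""


@dataclass
class TriangleRecord:
    """One triangle of a structure, fully annotated.

    ``vertex_positions`` are residue sequence positions in role order
    (li1's residue first), which records the vertex permutation chosen
    by the label-ordering rule.
    """

    vertex_positions: tuple[int, int, int]
    labels: tuple[int, int, int]
    d12: float
    d13: float
    d3: float
    max_dist: float
    theta: float
    d_bin: int | None = None
    theta_bin: int | None = None
    key: int | None = None


def triangle_geometry(coords):
    """Compute (d12, d13, d3, max_dist, theta) for one role-ordered triangle.

    ``coords`` is a (3, 3) array whose rows are the vertices in role
    order (li1, li2, li3).  Raises :class:`DegenerateTriangleError` for
    degenerate inputs.
    """
    coords = np.asarray(coords, dtype=float)
    d12, d13, d3, max_dist, theta, degen = triangle_geometry_arrays(
        coords[None, 0], coords[None, 1], coords[None, 2]
    )
    if degen[0]:
        raise DegenerateTriangleError("degenerate triangle (coincident vertices or d3 = 0)")
    return float(d12[0]), float(d13[0]), float(d3[0]), float(max_dist[0]), float(theta[0])


def triangle_geometry_arrays(a, b, c):
    """Vectorized geometry for role-ordered vertex arrays of shape (n, 3).

    Returns (d12, d13, d3, max_dist, theta, degenerate_mask); entries of
    degenerate triangles are left as NaN in ``theta``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d12 = np.linalg.norm(a - b, axis=-1)
    d13 = np.linalg.norm(a - c, axis=-1)
    d23 = np.linalg.norm(b - c, axis=-1)
    mid = 0.5 * (a + b)
    d3 = np.linalg.norm(mid - c, axis=-1)
    max_dist = np.maximum(np.maximum(d12, d13), d23)

    degenerate = (d12 < _EPS) | (d13 < _EPS) | (d23 < _EPS) | (d3 < _EPS)
    half = 0.5 * d12
    denom = np.where(degenerate, 1.0, 2.0 * half * d3)
    cos_arg = (d13**2 - half**2 - d3**2) / denom
    degenerate |= np.abs(cos_arg) > 1.0 + _EPS
    cos_arg = np.clip(cos_arg, -1.0, 1.0)
    theta1 = np.degrees(np.arccos(cos_arg))
    theta = np.where(theta1 <= 90.0, theta1, 180.0 - theta1)
    theta = np.where(degenerate, np.nan, theta)
    return d12, d13, d3, max_dist, theta, degenerate
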