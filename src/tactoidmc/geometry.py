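"""Spindle (lens-shaped) container geometry.

The confining domain is the cross-section of two overlapping circles of equal
radius, extruded to a depth ``h`` -- the planar mimic of a nematic tactoid.
The major axis ``Ly`` runs between the two cusps (along y), the minor axis
``Lx`` is the width of the lens (along x), and the cusp opening angle obeys
``alpha = 4 * arccot(Ly / Lx)``.

All lengths are expressed in units of the rod diameter ``d``.  The coordinate
origin sits at the container center with ``z`` in ``[0, h]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpindleGeometry",
    "make_spindle",
    "alpha_from_aspect",
    "aspect_from_alpha",
    "contains_point",
    "capsule_inside",
    "lens_area",
    "lens_volume",
    "count_rods",
    "rod_volume",
    "boundary_points",
]


@dataclass(frozen=True)
class SpindleGeometry:
    """Lens-shaped quasi-2D container.

    Parameters
    ----------
    Ly : float
        Major axis (cusp-to-cusp distance), units of d.
    Lx : float
        Minor axis (maximal width of the lens), units of d.
    h : float
        Container depth along z, units of d.

    Derived attributes
    ------------------
    R : float
        Radius of the two generating circles.
    c : float
        Offset of the circle centers from the origin along x; the circles are
        centered at ``(+c, 0)`` and ``(-c, 0)``.
    alpha : float
        Cusp opening angle in degrees; 180 for a circle (``Ly == Lx``).
    """

    Ly: float
    Lx: float
    h: float

    def __post_init__(self) -> None:
        if not (self.Ly >= self.Lx > 0.0):
            raise ValueError(f"require Ly >= Lx > 0, got Ly={self.Ly}, Lx={self.Lx}")
        if self.h <= 0.0:
            raise ValueError(f"require h > 0, got h={self.h}")

    @property
    def aspect(self) -> float:
        return self.Ly / self.Lx

    @property
    def R(self) -> float:
        return (self.Lx**2 + self.Ly**2) / (4.0 * self.Lx)

    @property
    def c(self) -> float:
        return self.R - self.Lx / 2.0

    @property
    def alpha(self) -> float:
        return alpha_from_aspect(self.aspect)

    @property
    def cusps(self) -> np.ndarray:
        """The two cusp points, shape (2, 2): ``(0, +Ly/2)`` and ``(0, -Ly/2)``."""
        return np.array([[0.0, self.Ly / 2.0], [0.0, -self.Ly / 2.0]])


def make_spindle(Ly: float, aspect: float, h: float) -> SpindleGeometry:
    """Build a spindle with major axis ``Ly``, aspect ratio ``Ly/Lx`` and depth ``h``.

    ``aspect == 1`` gives a circular container (the degenerate, fully
    overlapping case with ``c == 0`` and ``alpha == 180``).
    """
    if Ly <= 0 or h <= 0:
        raise ValueError(f"require Ly > 0 and h > 0, got Ly={Ly}, h={h}")
    if aspect < 1.0:
        raise ValueError(f"require aspect >= 1, got {aspect}")
    return SpindleGeometry(Ly=float(Ly), Lx=float(Ly) / float(aspect), h=float(h))


def alpha_from_aspect(aspect: float) -> float:
    """Cusp opening angle in degrees: ``alpha = 4 * arccot(aspect)``.

    Monotonically decreasing on ``aspect >= 1``; 180 degrees for a circle.
    """
    aspect = float(aspect)
    if aspect < 1.0:
        raise ValueError(f"require aspect >= 1, got {aspect}")
    return math.degrees(4.0 * math.atan(1.0 / aspect))


def aspect_from_alpha(alpha: float) -> float:
    """Inverse of :func:`alpha_from_aspect`: ``aspect = cot(alpha / 4)``."""
    alpha = float(alpha)
    if not (0.0 < alpha <= 180.0):
        raise ValueError(f"require 0 < alpha <= 180 degrees, got {alpha}")
    return 1.0 / math.tan(math.radians(alpha) / 4.0)


def contains_point(geom: SpindleGeometry, p, margin: float = 0.0) -> bool:
    """True iff ``p`` lies in the lens eroded inward by ``margin``.

    The eroded lens is the intersection of the two disks of radius
    ``R - margin`` (the erosion of a convex intersection is the intersection
    of the erosions), with ``z`` restricted to ``[margin, h - margin]``.
    """
    x, y, z = float(p[0]), float(p[1]), float(p[2])
    r_eff = geom.R - margin
    if not (margin <= z <= geom.h - margin):
        return False
    c = geom.c
    return (x - c) ** 2 + y**2 <= r_eff**2 and (x + c) ** 2 + y**2 <= r_eff**2


def capsule_inside(geom: SpindleGeometry, r, u, L: float, d: float) -> bool:
    """True iff a spherocylinder lies entirely inside the container.

    ``r`` is the rod center, ``u`` its unit orientation.  Because the lens
    eroded by ``d/2`` is convex, the capsule is inside iff both centerline
    endpoints are inside the eroded region -- an exact O(1) wall test.
    """
    r = np.asarray(r, dtype=float)
    u = np.asarray(u, dtype=float)
    half = 0.5 * L
    e0 = r - half * u
    e1 = r + half * u
    m = 0.5 * d
    return contains_point(geom, e0, m) and contains_point(geom, e1, m)


def lens_area(geom: SpindleGeometry) -> float:
    """Cross-sectional area of the lens: ``2 R^2 (theta - sin theta cos theta)``
    with ``theta = arcsin(Ly / 2R)``; reduces to ``pi R^2`` for a circle."""
    theta = math.asin(min(1.0, geom.Ly / (2.0 * geom.R)))
    return 2.0 * geom.R**2 * (theta - math.sin(theta) * math.cos(theta))


def lens_volume(geom: SpindleGeometry) -> float:
    return lens_area(geom) * geom.h


def rod_volume(L: float, d: float) -> float:
    """Volume of a spherocylinder: cylinder plus two hemispherical caps."""
    return math.pi / 4.0 * d**2 * L + math.pi / 6.0 * d**3


def count_rods(geom: SpindleGeometry, eta: float, L: float, d: float) -> int:
    """Number of rods realizing volume fraction ``eta`` in the container."""
    if not (0.0 <= eta < 1.0):
        raise ValueError(f"require 0 <= eta < 1, got {eta}")
    return int(round(eta * lens_volume(geom) / rod_volume(L, d)))


def boundary_points(geom: SpindleGeometry, spacing: float) -> np.ndarray:
    """Points sampled along the lens boundary at roughly uniform arc length.

    Always includes the two cusps exactly (for ``aspect > 1``).  Returns an
    array of shape (M, 2) ordered counter-clockwise starting from the bottom
    cusp, right arc first.
    """
    R, c = geom.R, geom.c
    phi0 = math.atan2(geom.Ly / 2.0, c)  # half-opening of each arc
    arc_len = 2.0 * phi0 * R
    n = max(4, int(math.ceil(arc_len / spacing)))
    phis = np.linspace(-phi0, phi0, n + 1)
    # right arc: circle centered at (-c, 0); left arc mirror image
    right = np.column_stack([-c + R * np.cos(phis), R * np.sin(phis)])
    left = np.column_stack([c - R * np.cos(phis), -R * np.sin(phis)])
    if geom.aspect == 1.0:
        # circle: arcs coincide in their endpoints; avoid duplicate seam points
        return np.vstack([right[:-1], left[:-1]])
    return np.vstack([right, left[1:-1]])
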