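"""Analytic director-field fixtures for every pattern class.

Each fixture realizes a multi-defect nematic angle field

    theta(r) = sum_j q_j * atan2(y - y_j, x - x_j) + background

(the standard harmonic solution for point disclinations of charge q_j) on
the same :class:`~tactoidmc.order.LocalOrderField` grid that the simulation
analysis produces, so the entire analysis/classification stack can be
exercised without running Monte Carlo.  The wavy "S"-type patterns add a
smooth (topologically trivial) serpentine modulation on top of the bipolar
defect pair.

With the background angle set to pi/2 (director along the major axis at the
container center) the two-defect fixtures are tangential at the wall,
matching the planar anchoring of hard rods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from .geometry import SpindleGeometry, boundary_points, contains_point
from .order import LocalOrderField, _make_grid

__all__ = ["FieldSpec", "synth_field", "perturb_field", "fixture_spec",
           "FIXTURE_PATTERNS"]

FIXTURE_PATTERNS = ("H", "B", "Bpar", "Dstar", "Dstarstar", "Dh",
                    "S", "Sstarstar", "M4", "M6")


@dataclass(frozen=True)
class FieldSpec:
    pattern: str
    geom: SpindleGeometry
    defect_positions: tuple = ()
    defect_charges: tuple = ()
    background_angle: float = math.pi / 2.0
    wave_amplitude: float = 0.0      # radians; serpentine modulation for S-types
    wave_periods: float = 1.0

    def __post_init__(self) -> None:
        if len(self.defect_positions) != len(self.defect_charges):
            raise ValueError("positions and charges must have equal length")
        for q in self.defect_charges:
            if abs(2 * q - round(2 * q)) > 1e-12 or q == 0:
                raise ValueError(f"charges must be non-zero half-integers, got {q}")
        g = self.geom
        for p in self.defect_positions:
            # allow boundary placement: inflate the lens by a small tolerance
            x, y = float(p[0]), float(p[1])
            if not contains_point(g, (x, y, g.h / 2.0), -1e-6 * max(g.Ly, 1.0)) \
               and not _on_boundary(g, x, y, tol=1e-6 * g.Ly + 1e-9):
                raise ValueError(f"defect position {p} outside the domain")


def _on_boundary(geom: SpindleGeometry, x: float, y: float, tol: float) -> bool:
    b = boundary_points(geom, spacing=geom.Ly / 2000.0)
    return bool(np.min(np.hypot(b[:, 0] - x, b[:, 1] - y)) <= tol + geom.Ly / 1000.0)


def _angle_field(spec: FieldSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    th = np.full(X.shape, spec.background_angle)
    for (px, py), q in zip(spec.defect_positions, spec.defect_charges):
        th = th + q * np.arctan2(Y - py, X - px)
    if spec.wave_amplitude != 0.0:
        # serpentine modulation concentrated near the major axis; the x-window
        # keeps the wall region tangentially anchored
        sigma = spec.geom.Lx / 6.0
        th = th + (spec.wave_amplitude
                   * np.sin(2.0 * np.pi * spec.wave_periods * Y / spec.geom.Ly)
                   * np.exp(-X**2 / (2.0 * sigma**2)))
    return th


def synth_field(spec: FieldSpec, cell_size: float) -> LocalOrderField:
    """Sample the analytic director field of ``spec`` on a cell grid.

    The scalar order is 1 away from defect cores and ramps linearly to 0
    within one cell of each core; occupancy is uniform inside the lens and
    zero outside.
    """
    geom = spec.geom
    nx, ny, xc, yc = _make_grid(geom, cell_size)
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    # nudge sampling points that coincide with a defect core off the
    # singularity so the director stays well defined everywhere
    for (px, py), _q in zip(spec.defect_positions, spec.defect_charges):
        hit = np.hypot(X - px, Y - py) < 1e-9 * max(geom.Ly, 1.0)
        X = np.where(hit, X + 1e-3 * cell_size, X)
        Y = np.where(hit, Y + 1e-3 * cell_size, Y)
    th = _angle_field(spec, X, Y)
    nk = np.zeros((nx, ny, 3))
    nk[..., 0] = np.cos(th)
    nk[..., 1] = np.sin(th)
    # scalar order ramps to zero over ~1.5 cells around each core so that the
    # coarse grid always samples the depressed-S halo of a defect
    Sk = np.ones((nx, ny))
    for (px, py), _q in zip(spec.defect_positions, spec.defect_charges):
        rr = np.hypot(X - px, Y - py)
        Sk = np.minimum(Sk, np.clip(rr / (1.5 * cell_size), 0.0, 1.0))
    inside = np.zeros((nx, ny), dtype=bool)
    for ix in range(nx):
        for iy in range(ny):
            inside[ix, iy] = contains_point(
                geom, (xc[ix], yc[iy], geom.h / 2.0), 0.0)
    occ = np.where(inside, 1.0, 0.0)
    Qk = (Sk[..., None, None]
          * (1.5 * nk[..., :, None] * nk[..., None, :] - 0.5 * np.eye(3)))
    return LocalOrderField(geom=geom, cell_size=cell_size, x_centers=xc,
                           y_centers=yc, Qk=Qk, Sk=Sk, nk=nk, occupancy=occ,
                           inside_mask=inside)


def perturb_field(field: LocalOrderField, noise_sd: float,
                  seed: int = 0) -> LocalOrderField:
    """Add independent in-plane angular noise (sd in radians) per cell."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0.0:
        return field
    rng = np.random.default_rng(seed)
    th = np.arctan2(field.nk[..., 1], field.nk[..., 0])
    th = th + rng.normal(scale=noise_sd, size=th.shape)
    nk = np.zeros_like(field.nk)
    nk[..., 0] = np.cos(th)
    nk[..., 1] = np.sin(th)
    Qk = (field.Sk[..., None, None]
          * (1.5 * nk[..., :, None] * nk[..., None, :] - 0.5 * np.eye(3)))
    return LocalOrderField(geom=field.geom, cell_size=field.cell_size,
                           x_centers=field.x_centers, y_centers=field.y_centers,
                           Qk=Qk, Sk=field.Sk.copy(), nk=nk,
                           occupancy=field.occupancy.copy(),
                           inside_mask=field.inside_mask.copy())


def _arc_xy(geom: SpindleGeometry, frac: float, side: int = +1):
    """Point on the right (side=+1) or left (side=-1) arc; ``frac`` in
    (-1, 1) runs from the bottom cusp to the top cusp."""
    phi0 = math.atan2(geom.Ly / 2.0, geom.c)
    phi = frac * phi0
    x = -geom.c + geom.R * math.cos(phi)
    y = geom.R * math.sin(phi)
    return (side * x, y)


def fixture_spec(pattern: str, geom: SpindleGeometry) -> FieldSpec:
    """Canonical fixture for each pattern class on the given container.

    H: uniform along the major axis (use a slender spindle).  B / Bpar: two
    +1/2 boojums at the poles/cusps.  Dh: the boojums at the minor-axis ends.
    Dstar: one boojum in a cusp, one displaced along an arc.  Dstarstar:
    both displaced (the pair axis oblique).  S / Sstarstar: bipolar variants
    with a serpentine modulation.  M4: three +1/2 boundary defects (one in a
    cusp) and one interior -1/2.  M6: four +1/2 boundary defects and two
    interior -1/2 on the major axis (the central-droplet intermediate).
    """
    g = geom
    top = (0.0, g.Ly / 2.0)
    bot = (0.0, -g.Ly / 2.0)
    if pattern == "H":
        return FieldSpec("H", g)
    if pattern == "B":
        return FieldSpec("B", g, (top, bot), (0.5, 0.5))
    if pattern == "Bpar":
        return FieldSpec("Bpar", g, (top, bot), (0.5, 0.5))
    if pattern == "Dh":
        return FieldSpec("Dh", g, ((g.Lx / 2.0, 0.0), (-g.Lx / 2.0, 0.0)),
                         (0.5, 0.5))
    if pattern == "Dstar":
        return FieldSpec("Dstar", g, (top, _arc_xy(g, -0.45, -1)), (0.5, 0.5))
    if pattern == "Dstarstar":
        return FieldSpec("Dstarstar", g,
                         (_arc_xy(g, 0.55, +1), _arc_xy(g, -0.55, -1)),
                         (0.5, 0.5))
    if pattern == "S":
        return FieldSpec("S", g, (top, bot), (0.5, 0.5),
                         wave_amplitude=math.radians(35.0))
    if pattern == "Sstarstar":
        # defects displaced from the cusps but near-axial, so the pair tilt
        # does not cancel the serpentine modulation
        return FieldSpec("Sstarstar", g,
                         (_arc_xy(g, 0.85, +1), _arc_xy(g, -0.85, -1)),
                         (0.5, 0.5), wave_amplitude=math.radians(35.0))
    if pattern == "M4":
        return FieldSpec("M4", g,
                         (top, _arc_xy(g, 0.15, +1), _arc_xy(g, 0.15, -1),
                          (0.0, 0.30 * g.Ly / 2.0)),
                         (0.5, 0.5, 0.5, -0.5))
    if pattern == "M6":
        return FieldSpec("M6", g,
                         (_arc_xy(g, 0.35, +1), _arc_xy(g, -0.35, +1),
                          _arc_xy(g, 0.35, -1), _arc_xy(g, -0.35, -1),
                          (0.0, 0.30 * g.Ly / 2.0), (0.0, -0.30 * g.Ly / 2.0)),
                         (0.5, 0.5, 0.5, 0.5, -0.5, -0.5))
    raise ValueError(f"unknown pattern {pattern!r}; choose from {FIXTURE_PATTERNS}")
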