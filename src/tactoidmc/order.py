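"""Nematic order fields and topological defect detection.

The global tensor order parameter is

    Q = (1/N) sum_i ( 3/2 u_i (x) u_i - 1/2 I ),

whose top eigenvalue is the scalar order S and whose corresponding
eigenvector is the director n (sign-free).  The local version Q^k is built on
cuboidal sub-volumes of the container's full height, with each rod weighted
by the centerline length l_i^k lying inside sub-volume k.  From the per-cell
directors we compute the angular deficit

    delta = min_angle(n_W, n_E) + min_angle(n_S, n_N),

the sum of minimum nematic angles between opposite-neighbor directors, which
vanishes for a uniform nematic and peaks at defects, and the plaquette
winding number used to locate and charge-classify disclinations.

Boundary singularities (e.g. the +1/2 boojums of the bipolar pattern, whose
cores sit in the cusps outside any closed loop of occupied cells) are
recovered from the open-arc rotation of the director around candidate sites
sampled along the wall: for a defect of charge q at the wall the director
turns by q times the angular span of the surrounding interior cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _kernels
from .geometry import SpindleGeometry, boundary_points, contains_point
from .mc import Configuration

__all__ = [
    "GlobalOrder",
    "LocalOrderField",
    "Defect",
    "global_Q",
    "segment_length_in_box",
    "local_Q_field",
    "angular_deficit",
    "detect_defects",
    "total_charge",
    "nematic_angle_diff",
]


@dataclass(frozen=True)
class GlobalOrder:
    Q: np.ndarray          # symmetric traceless 3x3
    S: float               # top eigenvalue, in [-0.5, 1]
    n: np.ndarray          # unit director (n and -n equivalent)

    @property
    def out_of_plane(self) -> float:
        """|n_z|, the out-of-plane component of the director."""
        return abs(float(self.n[2]))


@dataclass
class Defect:
    position: np.ndarray   # (x, y), units of d
    charge: float          # half-integer
    locale: str = "interior"   # cusp | boundary | interior


@dataclass
class LocalOrderField:
    """Per-cell order data on a uniform grid over the lens bounding box.

    Arrays are indexed ``[ix, iy]``; ``x_centers[ix]``/``y_centers[iy]`` give
    the cell-center coordinates.  ``occupancy`` is the total rod centerline
    length in each cell; quantities are defined only where ``occupied``.
    """

    geom: SpindleGeometry
    cell_size: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    Qk: np.ndarray             # (nx, ny, 3, 3)
    Sk: np.ndarray             # (nx, ny)
    nk: np.ndarray             # (nx, ny, 3)
    occupancy: np.ndarray      # (nx, ny), summed centerline length
    inside_mask: np.ndarray    # (nx, ny) cell center inside the lens
    delta: np.ndarray | None = None

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy > 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.Sk.shape

    def plane_angle(self) -> np.ndarray:
        """In-plane director angle theta = atan2(n_y, n_x), mod pi."""
        th = np.arctan2(self.nk[..., 1], self.nk[..., 0])
        return np.mod(th, np.pi)


def _q_single(u: np.ndarray) -> np.ndarray:
    return 1.5 * np.outer(u, u) - 0.5 * np.eye(3)


def global_Q(orientations) -> GlobalOrder:
    """Global tensor order parameter of a set of unit orientations.

    Accepts an (N, 3) array, a sequence of rods, or a Configuration.
    """
    if isinstance(orientations, Configuration):
        u = orientations.ort
    else:
        u = np.asarray([getattr(o, "u", o) for o in orientations], dtype=float) \
            if not isinstance(orientations, np.ndarray) else orientations
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[0] == 0:
        raise ValueError("need at least one orientation")
    Q = 1.5 * (u[:, :, None] * u[:, None, :]).mean(axis=0) - 0.5 * np.eye(3)
    w, v = np.linalg.eigh(Q)
    return GlobalOrder(Q=Q, S=float(w[-1]), n=v[:, -1].copy())


def segment_length_in_box(p0, p1, lo, hi) -> float:
    """Length of the segment p0-p1 clipped to the axis-aligned box [lo, hi].

    Parametric slab clipping; exact and additive across a partition of space.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    dvec = p1 - p0
    t0, t1 = 0.0, 1.0
    for k in range(len(p0)):
        if abs(dvec[k]) < 1e-300:
            if p0[k] < lo[k] or p0[k] > hi[k]:
                return 0.0
        else:
            ta = (lo[k] - p0[k]) / dvec[k]
            tb = (hi[k] - p0[k]) / dvec[k]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
            if t0 >= t1:
                return 0.0
    return float(np.linalg.norm(dvec)) * (t1 - t0)


def _make_grid(geom: SpindleGeometry, cell_size: float):
    nx = max(1, int(math.ceil(geom.Lx / cell_size - 1e-9)))
    ny = max(1, int(math.ceil(geom.Ly / cell_size - 1e-9)))
    x_centers = (np.arange(nx) - (nx - 1) / 2.0) * cell_size
    y_centers = (np.arange(ny) - (ny - 1) / 2.0) * cell_size
    return nx, ny, x_centers, y_centers


def local_Q_field(config, cell_size: float | None = None) -> LocalOrderField:
    """Length-weighted local tensor order parameter on cuboidal sub-volumes.

    Cells are squares of edge ``cell_size`` (default L/2, resolving defect
    cores of extent ~L with at least two cells) spanning the full depth h.
    ``config`` may also be a sequence of configurations, in which case the
    length-weighted sums are accumulated over all of them (the ensemble
    average over sampled frames) before diagonalizing.
    """
    configs = list(config) if not isinstance(config, Configuration) else [config]
    config = configs[0]
    if cell_size is None:
        cell_size = config.L / 2.0
    if not (config.d <= cell_size <= config.L):
        raise ValueError(
            f"cell_size must lie in [d, L] = [{config.d}, {config.L}], "
            f"got {cell_size}")
    geom = config.geom
    nx, ny, xc, yc = _make_grid(geom, cell_size)
    x_edges = np.concatenate([xc - cell_size / 2.0, [xc[-1] + cell_size / 2.0]])
    y_edges = np.concatenate([yc - cell_size / 2.0, [yc[-1] + cell_size / 2.0]])
    M = np.zeros((nx, ny, 3, 3))
    occ = np.zeros((nx, ny))
    half = 0.5 * config.L
    for cfg_f in configs:
        _kernels.accumulate_local_Q(cfg_f.pos, cfg_f.ort, half,
                                    x_edges, y_edges, M, occ)
    # the kernel fills the upper triangle only
    M[..., 1, 0] = M[..., 0, 1]
    M[..., 2, 0] = M[..., 0, 2]
    M[..., 2, 1] = M[..., 1, 2]
    Sk = np.zeros((nx, ny))
    nk = np.zeros((nx, ny, 3))
    nk[..., 2] = 1.0
    for ix in range(nx):
        for iy in range(ny):
            if occ[ix, iy] > 0.0:
                w, v = np.linalg.eigh(M[ix, iy] / occ[ix, iy])
                Sk[ix, iy] = w[-1]
                nk[ix, iy] = v[:, -1]
    Qk = np.where(occ[..., None, None] > 0, M / np.maximum(occ, 1e-300)[..., None, None], 0.0)
    inside = np.zeros((nx, ny), dtype=bool)
    for ix in range(nx):
        for iy in range(ny):
            inside[ix, iy] = contains_point(
                geom, (xc[ix], yc[iy], geom.h / 2.0), 0.0)
    return LocalOrderField(geom=geom, cell_size=cell_size, x_centers=xc,
                           y_centers=yc, Qk=Qk, Sk=Sk, nk=nk, occupancy=occ,
                           inside_mask=inside)


def nematic_angle_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed director-angle difference folded into (-pi/2, pi/2]."""
    return -(np.mod(-(np.asarray(b) - np.asarray(a)) + np.pi / 2.0, np.pi)
             - np.pi / 2.0)


def _min_line_angle(n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Minimum angle between the lines spanned by unit vectors n1, n2."""
    dot = np.clip(np.abs(np.einsum("...k,...k->...", n1, n2)), 0.0, 1.0)
    return np.arccos(dot)


def angular_deficit(field: LocalOrderField) -> np.ndarray:
    """Per-cell angular deficit delta (radians); NaN where undefined.

    Defined on occupied cells whose four axis neighbors are all occupied:
    the opposite-pair convention delta = ang(n_W, n_E) + ang(n_S, n_N) with
    minimum nematic (line-line) angles.  Stored on ``field.delta`` as well.
    """
    occ = field.occupied
    if occ.sum() < 9:
        raise ValueError("need at least 3x3 occupied cells")
    nx, ny = field.shape
    delta = np.full((nx, ny), np.nan)
    n = field.nk
    core = occ[1:-1, 1:-1] & occ[:-2, 1:-1] & occ[2:, 1:-1] \
        & occ[1:-1, :-2] & occ[1:-1, 2:]
    dwe = _min_line_angle(n[:-2, 1:-1], n[2:, 1:-1])
    dsn = _min_line_angle(n[1:-1, :-2], n[1:-1, 2:])
    inner = np.where(core, dwe + dsn, np.nan)
    delta[1:-1, 1:-1] = inner
    field.delta = delta
    return delta


def _plaquette_winding(field: LocalOrderField) -> np.ndarray:
    """Nematic winding number of every 2x2 plaquette (NaN if not fully occupied).

    The loop runs (ix,iy) -> (ix+1,iy) -> (ix+1,iy+1) -> (ix,iy+1) -> back,
    i.e. counter-clockwise in the (x, y) plane; increments are folded into
    (-pi/2, pi/2] before summing, and the sum is divided by 2 pi.
    """
    th = field.plane_angle()
    occ = field.occupied
    a = th[:-1, :-1]
    b = th[1:, :-1]
    c = th[1:, 1:]
    d = th[:-1, 1:]
    w = (nematic_angle_diff(a, b) + nematic_angle_diff(b, c)
         + nematic_angle_diff(c, d) + nematic_angle_diff(d, a)) / (2.0 * np.pi)
    ok = occ[:-1, :-1] & occ[1:, :-1] & occ[1:, 1:] & occ[:-1, 1:]
    return np.where(ok, w, np.nan)


def loop_winding(field: LocalOrderField, cells: list[tuple[int, int]]) -> float:
    """Nematic winding number along an arbitrary closed loop of occupied cells."""
    th = field.plane_angle()
    total = 0.0
    for (i0, j0), (i1, j1) in zip(cells, cells[1:] + cells[:1]):
        total += float(nematic_angle_diff(th[i0, j0], th[i1, j1]))
    return total / (2.0 * np.pi)


def _boundary_charges(field: LocalOrderField, geom: SpindleGeometry,
                      threshold: float) -> list[Defect]:
    """Estimate boundary singularities from open-arc director rotation.

    For candidate sites along the wall (cusps always included), occupied
    cells in an annulus around the site are sorted by polar angle; the
    nematically-unwrapped director rotation across them divided by their
    angular span estimates the local charge.
    """
    cs = field.cell_size
    sites = boundary_points(geom, spacing=0.75 * cs)
    occ = field.occupied
    ixs, iys = np.nonzero(occ)
    cx = field.x_centers[ixs]
    cy = field.y_centers[iys]
    th = field.plane_angle()[ixs, iys]
    Sv = field.Sk[ixs, iys]
    r_in, r_out = 0.5 * cs, 2.2 * cs
    qhat = np.full(len(sites), 0.0)
    for s, (sx, sy) in enumerate(sites):
        dx = cx - sx
        dy = cy - sy
        rr = np.hypot(dx, dy)
        sel = (rr > r_in) & (rr < r_out)
        if sel.sum() < 4:
            continue
        # a defect core must show a co-localized drop of the scalar order;
        # smooth strongly-bent fields (e.g. radial at the wall) do not
        near = rr < 1.7 * cs
        if near.any() and float(Sv[near].min()) > 0.8:
            continue
        phi = np.arctan2(dy[sel], dx[sel])
        order = np.argsort(phi)
        phi_s = phi[order]
        th_s = th[sel][order]
        # the interior wedge is the arc complementary to the largest phi gap
        gaps = np.diff(np.concatenate([phi_s, [phi_s[0] + 2 * np.pi]]))
        kmax = int(np.argmax(gaps))
        span = 2.0 * np.pi - gaps[kmax]
        if span < math.radians(20.0):
            continue
        ordered = np.roll(np.arange(len(phi_s)), -(kmax + 1))
        rot = float(np.sum(nematic_angle_diff(th_s[ordered][:-1],
                                              th_s[ordered][1:])))
        qhat[s] = rot / span
    # peaks: cyclic local maxima of |qhat| above threshold
    m = len(sites)
    win = max(1, int(math.ceil(1.2 * cs / (0.75 * cs))))
    peaks = []
    aq = np.abs(qhat)
    for s in range(m):
        if aq[s] < threshold:
            continue
        if all(aq[s] >= aq[(s + o) % m] for o in range(-win, win + 1) if o != 0):
            peaks.append(s)
    # merge peaks closer than 1.5 cells (keep the stronger one)
    peaks.sort(key=lambda s: -aq[s])
    kept: list[int] = []
    for s in peaks:
        if all(np.linalg.norm(sites[s] - sites[t]) > 1.5 * cs for t in kept):
            kept.append(s)
    defects = []
    for s in kept:
        # planar anchoring on a convex boundary admits only +1/2 boojums;
        # negative open-arc readings are the anchoring bend of a wall layer
        # (strongest at the cusps when the bulk director crosses them), not
        # disclinations, and sharp wall layers can inflate the estimate, so
        # the boundary charge is clamped to +1/2
        if qhat[s] < 0.0:
            continue
        defects.append(Defect(position=sites[s].copy(), charge=0.5,
                              locale="boundary"))
    return defects


def detect_defects(field: LocalOrderField, geom: SpindleGeometry | None = None,
                   threshold: float = 0.25) -> list[Defect]:
    """Locate disclinations and their half-integer charges.

    Interior defects come from clustering super-threshold 2x2 plaquette
    winding numbers (connected components; charge = cluster winding rounded
    to the nearest half-integer, position = |winding|-weighted centroid).
    Boundary/cusp defects, whose cores sit outside any closed loop of
    occupied cells, come from the open-arc estimator (see module docstring).
    Returns the list sorted by distance from the container center.
    """
    if geom is None:
        geom = field.geom
    w = _plaquette_winding(field)
    wa = np.where(np.isnan(w), 0.0, w)
    strong = np.abs(wa) >= threshold - 1e-12
    defects: list[Defect] = []
    if strong.any():
        lab, nlab = ndimage.label(strong, structure=np.ones((3, 3), dtype=int))
        xs = field.x_centers
        ys = field.y_centers
        occ = field.occupied
        nx, ny = field.shape
        pxc = 0.5 * (xs[:-1] + xs[1:])
        pyc = 0.5 * (ys[:-1] + ys[1:])
        for k in range(1, nlab + 1):
            ii, jj = np.nonzero(lab == k)
            # charge from the winding of a loop of cells enclosing the cluster
            # (robust to folding noise at the core); plaquette (i, j) spans
            # cells i..i+1, j..j+1
            a0, a1 = ii.min() - 1, ii.max() + 2
            b0, b1 = jj.min() - 1, jj.max() + 2
            charge = None
            if a0 >= 0 and b0 >= 0 and a1 < nx and b1 < ny:
                loop = ([(i, b0) for i in range(a0, a1 + 1)]
                        + [(a1, j) for j in range(b0 + 1, b1 + 1)]
                        + [(i, b1) for i in range(a1 - 1, a0 - 1, -1)]
                        + [(a0, j) for j in range(b1 - 1, b0, -1)])
                if all(occ[i, j] for i, j in loop):
                    charge = round(2.0 * loop_winding(field, loop)) / 2.0
            if charge is None:
                charge = round(2.0 * float(wa[ii, jj].sum())) / 2.0
            if charge == 0.0:
                continue
            wt = np.abs(wa[ii, jj])
            px = float(np.average(pxc[ii], weights=wt))
            py = float(np.average(pyc[jj], weights=wt))
            defects.append(Defect(position=np.array([px, py]), charge=charge))
    boundary = _boundary_charges(field, geom, threshold)
    # drop boundary candidates sitting on top of an interior detection
    keep = []
    for b in boundary:
        if all(np.linalg.norm(b.position - d.position) > 1.8 * field.cell_size
               for d in defects):
            keep.append(b)
    defects.extend(keep)
    defects.sort(key=lambda d: float(np.linalg.norm(d.position)))
    return defects


def total_charge(defects) -> float:
    """Sum of defect charges; +1 for any complete pattern on the lens."""
    return float(sum(d.charge for d in defects))


def field_to_table(field: LocalOrderField) -> "np.ndarray":
    """Flat per-cell table (x, y, S, angle, delta, occupancy) for TSV dumps."""
    if field.delta is None:
        try:
            angular_deficit(field)
        except ValueError:
            field.delta = np.full(field.shape, np.nan)
    th = field.plane_angle()
    rows = []
    for ix in range(field.shape[0]):
        for iy in range(field.shape[1]):
            if field.occupancy[ix, iy] > 0:
                rows.append((field.x_centers[ix], field.y_centers[iy],
                             field.Sk[ix, iy], th[ix, iy],
                             field.delta[ix, iy], field.occupancy[ix, iy]))
    return np.array(rows)
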