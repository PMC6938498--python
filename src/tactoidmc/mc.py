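"""Hard-particle Monte Carlo engine.

Rods are hard spherocylinders (capsules) of length ``L`` and diameter ``d``
interacting through steric repulsion only; the particle-wall interaction is
also hard.  MC sweeps serve as the proxy for time.  The sweep driver is
compiled (see :mod:`tactoidmc._kernels`); this module holds the Python-facing
state containers and single-move logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _kernels
from .geometry import SpindleGeometry, capsule_inside, lens_volume, rod_volume

__all__ = [
    "Rod",
    "Configuration",
    "MCParams",
    "Frame",
    "Trajectory",
    "min_distance_segments",
    "overlap",
    "trial_move",
    "run_sweeps",
]


@dataclass
class Rod:
    """A single hard spherocylinder: center ``r``, unit orientation ``u``."""

    r: np.ndarray
    u: np.ndarray
    L: float
    d: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.L <= 0 or self.d <= 0:
            raise ValueError("rod requires L > 0 and d > 0")
        norm = float(np.linalg.norm(self.u))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"orientation must be a unit vector, |u| = {norm}")
        self.u = self.u / norm

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        half = 0.5 * self.L
        return self.r - half * self.u, self.r + half * self.u


class Configuration:
    """Geometry plus rod ensemble; the simulator's state.

    Stores positions and orientations as (N, 3) arrays (all rods share one
    ``L`` and ``d``, as in the monodisperse system simulated here).
    """

    def __init__(self, geom: SpindleGeometry, pos: np.ndarray, ort: np.ndarray,
                 L: float, d: float):
        pos = np.ascontiguousarray(pos, dtype=float)
        ort = np.ascontiguousarray(ort, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != ort.shape:
            raise ValueError("pos and ort must both have shape (N, 3)")
        norms = np.linalg.norm(ort, axis=1)
        if pos.shape[0] and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")
        self.geom = geom
        self.pos = pos
        self.ort = ort
        self.L = float(L)
        self.d = float(d)

    @classmethod
    def from_rods(cls, geom: SpindleGeometry, rods: Sequence[Rod]) -> "Configuration":
        if not rods:
            raise ValueError("need at least one rod")
        L, d = rods[0].L, rods[0].d
        pos = np.array([rod.r for rod in rods])
        ort = np.array([rod.u for rod in rods])
        return cls(geom, pos, ort, L, d)

    def rods(self) -> list[Rod]:
        return [Rod(r=self.pos[i].copy(), u=self.ort[i].copy(), L=self.L, d=self.d)
                for i in range(self.n)]

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def eta(self) -> float:
        """Realized volume fraction."""
        return self.n * rod_volume(self.L, self.d) / lens_volume(self.geom)

    def copy(self) -> "Configuration":
        return Configuration(self.geom, self.pos.copy(), self.ort.copy(),
                             self.L, self.d)

    # -- invariants -------------------------------------------------------
    def first_overlap(self) -> tuple[int, int] | None:
        half = np.full(self.n, 0.5 * self.L)
        i, j = _kernels.any_overlap_allpairs(self.pos, self.ort, half, self.d)
        return None if i < 0 else (int(i), int(j))

    def first_wall_violation(self) -> int | None:
        half = np.full(self.n, 0.5 * self.L)
        g = self.geom
        i = _kernels.all_inside_walls(self.pos, self.ort, half, self.d,
                                      g.R, g.c, g.h)
        return None if i < 0 else int(i)

    def validate(self) -> None:
        """Raise if any rod overlaps another or pokes through the wall."""
        i = self.first_wall_violation()
        if i is not None:
            raise ValueError(f"rod {i} violates the hard wall")
        pair = self.first_overlap()
        if pair is not None:
            raise ValueError(f"rods {pair[0]} and {pair[1]} overlap")


@dataclass(frozen=True)
class MCParams:
    """Move amplitudes and run length.

    Defaults target ~30-50% acceptance at eta = 0.16 for L/d = 20 rods.
    """

    dr_max: float = 0.5        # translation amplitude, units of d
    dtheta_max: float = 0.1    # rotation amplitude, radians
    sweeps: int = 1000
    seed: int = 0
    sample_every: int = 100

    def __post_init__(self) -> None:
        if self.dr_max <= 0 or self.dtheta_max <= 0:
            raise ValueError("move amplitudes must be positive")
        if self.sweeps < 0:
            raise ValueError("sweeps must be >= 0")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")


@dataclass
class Frame:
    sweep: int
    pos: np.ndarray
    ort: np.ndarray


@dataclass
class Trajectory:
    """Sequence of sampled frames plus run metadata (geometry, seed, ...)."""

    frames: list[Frame]
    meta: dict

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def configurations(self, geom: SpindleGeometry, L: float, d: float):
        for f in self.frames:
            yield f.sweep, Configuration(geom, f.pos, f.ort, L, d)


def min_distance_segments(a0, a1, b0, b1) -> float:
    """Minimum Euclidean distance between two closed 3D segments."""
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    d2 = _kernels.segment_dist2(a0[0], a0[1], a0[2], a1[0], a1[1], a1[2],
                                b0[0], b0[1], b0[2], b1[0], b1[1], b1[2])
    return math.sqrt(d2)


def overlap(rod1: Rod, rod2: Rod) -> bool:
    """True iff the two capsules interpenetrate (centerline distance < mean d)."""
    a0, a1 = rod1.endpoints
    b0, b1 = rod2.endpoints
    return min_distance_segments(a0, a1, b0, b1) < 0.5 * (rod1.d + rod2.d)


def _random_rotation(u: np.ndarray, dtheta_max: float, rng: np.random.Generator):
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
    ang = rng.random() * dtheta_max
    ca, sa = math.cos(ang), math.sin(ang)
    rotated = (u * ca + np.cross(axis, u) * sa + axis * np.dot(axis, u) * (1 - ca))
    return rotated / np.linalg.norm(rotated)


def trial_move(config: Configuration, index: int, params: MCParams,
               rng: np.random.Generator) -> bool:
    """Attempt one combined translation+rotation move on rod ``index``.

    The configuration is mutated only if the move keeps the rod inside the
    wall and free of overlaps; returns the acceptance flag.
    """
    if not (0 <= index < config.n):
        raise IndexError(f"rod index {index} out of range (N = {config.n})")
    new_r = config.pos[index] + (rng.random(3) * 2.0 - 1.0) * params.dr_max
    new_u = _random_rotation(config.ort[index], params.dtheta_max, rng)
    if not capsule_inside(config.geom, new_r, new_u, config.L, config.d):
        return False
    half = 0.5 * config.L
    a0 = new_r - half * new_u
    a1 = new_r + half * new_u
    for j in range(config.n):
        if j == index:
            continue
        b0 = config.pos[j] - half * config.ort[j]
        b1 = config.pos[j] + half * config.ort[j]
        d2 = _kernels.segment_dist2(a0[0], a0[1], a0[2], a1[0], a1[1], a1[2],
                                    b0[0], b0[1], b0[2], b1[0], b1[1], b1[2])
        if d2 < config.d**2:
            return False
    config.pos[index] = new_r
    config.ort[index] = new_u
    return True


def _cell_grid(geom: SpindleGeometry, L: float, d: float):
    """Uniform cell grid over the lens bounding box with edge >= L + d."""
    cutoff = L + d
    x0, y0 = -geom.Lx / 2.0 - 1e-9, -geom.Ly / 2.0 - 1e-9
    nx = max(1, int(geom.Lx / cutoff))
    ny = max(1, int(geom.Ly / cutoff))
    cell = max(geom.Lx / nx, geom.Ly / ny, cutoff)
    return x0, y0, 1.0 / cell, nx, ny


def run_sweeps(config: Configuration, params: MCParams,
               observers: Iterable[Callable] = ()) -> Trajectory:
    """Run ``params.sweeps`` MC sweeps, sampling every ``sample_every`` sweeps.

    One sweep is N single-particle trial moves on uniformly random particles.
    Every emitted frame satisfies the hard-core and hard-wall invariants (the
    move set preserves them).  Bitwise reproducible given (seed, params,
    starting configuration).  Observers are called as ``obs(sweep, config)``
    at every sampled frame (including the initial one).
    """
    config.validate()
    g = config.geom
    n = config.n
    half = np.full(n, 0.5 * config.L)
    x0, y0, inv_cell, nx, ny = _cell_grid(g, config.L, config.d)
    ncell = nx * ny
    cell_count = np.zeros(ncell, dtype=np.int64)
    cell_items = np.zeros((ncell, _kernels.CELL_CAP), dtype=np.int64)
    cell_of = np.zeros(n, dtype=np.int64)
    ok = _kernels.build_cells(config.pos, x0, y0, inv_cell, nx, ny,
                              cell_count, cell_items, cell_of)
    if not ok:
        raise RuntimeError("cell-list capacity exceeded; system too dense")

    meta = {
        "Ly": g.Ly, "aspect": g.aspect, "h": g.h,
        "L": config.L, "d": config.d, "eta": config.eta,
        "seed": params.seed,
    }
    _kernels.seed_rng(params.seed % (2**32))
    frames = [Frame(0, config.pos.copy(), config.ort.copy())]
    for obs in observers:
        obs(0, config)
    accepted = 0
    done = 0
    while done < params.sweeps:
        chunk = min(params.sample_every, params.sweeps - done)
        accepted += _kernels.run_sweeps_kernel(
            config.pos, config.ort, half, config.d, g.R, g.c, g.h,
            x0, y0, inv_cell, nx, ny, cell_count, cell_items, cell_of,
            params.dr_max, params.dtheta_max, chunk)
        done += chunk
        frames.append(Frame(done, config.pos.copy(), config.ort.copy()))
        for obs in observers:
            obs(done, config)
    meta["acceptance"] = accepted / max(1, params.sweeps * n)
    return Trajectory(frames=frames, meta=meta)
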