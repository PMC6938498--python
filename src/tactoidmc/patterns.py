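"""Pattern taxonomy, equilibration pathways and equilibration time.

Pattern classes (director-field taxonomy of the confined nematic):

====  ==========================================================
H     homogeneous, director along the major axis, no defects
B     bipolar in a circular container (two +1/2 boojums)
Bpar  bipolar with both +1/2 defects exactly in the cusps
D*    bipolar with exactly one defect displaced from a cusp
D**   bipolar with both defects displaced
Dh    D** special case: defects at the two minor-axis ends
S     wavy ("S"-shaped) director, defects in the cusps
S**   wavy director, defects displaced from the cusps
M_n   multi-domain pattern with n > 2 point defects (M4, M6, ...)
====  ==========================================================

Equilibration pathways from a minor-axis-aligned start (which first forms
Dh): "melt" goes through the six-defect central-droplet intermediate (M6),
"slide" through the four-defect M4 intermediate, and "turn" rotates the
two-defect pattern (a succession of D**) into the bipolar state without
creating extra defect pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .geometry import SpindleGeometry, boundary_points
from .order import (Defect, LocalOrderField, detect_defects, global_Q,
                    nematic_angle_diff)

__all__ = [
    "PatternLabel", "PathwayLabel", "EquilibrationCriteria", "PatternTolerances",
    "locale_of", "classify_pattern", "classify_pathway", "equilibration_time",
    "pathway_statistics", "majority_filter", "NEVER",
]

NEVER = float("inf")   # sentinel for "never equilibrated"


@dataclass(frozen=True)
class PatternLabel:
    label: str             # H, B, Bpar, Dstar, Dstarstar, Dh, S, Sstarstar,
    # M4, M6, Mn, UNKNOWN
    n_defects: int = 0

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class PathwayLabel:
    label: str             # melt | slide | turn | other

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class PatternTolerances:
    """Geometric tolerances for the decision tree.

    Defect cores and wall layers extend over roughly one rod length, which
    sets the scale of the defaults.
    """

    cusp_frac: float = 0.05      # cusp_tol = max(L/2, cusp_frac * Ly)
    minor_frac: float = 0.10     # minor_tol = minor_frac * Lx
    angle_tol_deg: float = 10.0  # H: mean director angle to y-hat below this
    s_wave_tol_deg: float = 15.0  # S: major-axis excursions beyond this

    def cusp_tol(self, geom: SpindleGeometry, L: float) -> float:
        return max(L / 2.0, self.cusp_frac * geom.Ly)

    def boundary_tol(self, L: float) -> float:
        return L / 2.0


@dataclass(frozen=True)
class EquilibrationCriteria:
    """Thresholds declaring the bipolar/homogeneous end state reached."""

    S_min: float = 0.6
    director_tol_deg: float = 5.0
    hold_window: int = 10        # consecutive samples the state must hold

    def __post_init__(self) -> None:
        if not (0.0 < self.S_min < 1.0):
            raise ValueError("S_min must be in (0, 1)")
        if self.director_tol_deg <= 0 or self.hold_window < 1:
            raise ValueError("invalid equilibration criteria")


def locale_of(defect: Defect, geom: SpindleGeometry, cusp_tol: float,
              boundary_tol: float) -> str:
    """cusp / boundary / interior assignment for a defect position."""
    if cusp_tol <= 0 or boundary_tol <= 0:
        raise ValueError("tolerances must be positive")
    p = np.asarray(defect.position, dtype=float)
    if min(np.linalg.norm(p - c) for c in geom.cusps) <= cusp_tol:
        return "cusp"
    b = boundary_points(geom, spacing=min(cusp_tol, boundary_tol) / 2.0)
    if np.min(np.hypot(b[:, 0] - p[0], b[:, 1] - p[1])) <= boundary_tol:
        return "boundary"
    return "interior"


def _s_criterion(field: LocalOrderField, tol: PatternTolerances,
                 defects: list[Defect]) -> bool:
    """Wavy-director test: the director angle sampled along the major axis,
    measured from y-hat, changes sign with excursions beyond s_wave_tol on
    both sides.  Cells within two cells of a defect core are excluded (the
    core halo bends sharply in any two-defect pattern)."""
    xc = field.x_centers
    col = int(np.argmin(np.abs(xc)))
    th = field.plane_angle()[col]
    keep = field.occupied[col].copy()
    yv = field.y_centers
    for d in defects:
        rr = np.hypot(xc[col] - d.position[0], yv - d.position[1])
        keep &= rr > 2.0 * field.cell_size
    if keep.sum() < 3:
        return False
    psi = np.degrees(nematic_angle_diff(np.full(int(keep.sum()), np.pi / 2.0),
                                        th[keep]))
    # near-perpendicular cells (|psi| -> 90) flip sign under the nematic fold
    # (a transverse director is not a wave); only moderate excursions count
    psi = psi[np.abs(psi) < 70.0]
    if len(psi) < 3:
        return False
    return bool(psi.max() > tol.s_wave_tol_deg and psi.min() < -tol.s_wave_tol_deg)


def classify_pattern(field: LocalOrderField, defects: list[Defect] | None = None,
                     geom: SpindleGeometry | None = None,
                     L: float | None = None,
                     tol: PatternTolerances = PatternTolerances()) -> PatternLabel:
    """Decision tree over the defect list and director field."""
    if geom is None:
        geom = field.geom
    if L is None:
        L = 2.0 * field.cell_size  # default grid uses cell_size = L/2
    if field.occupied.sum() < 9:
        raise ValueError("field not analyzable: fewer than 3x3 occupied cells")
    if defects is None:
        defects = detect_defects(field, geom)
    n = len(defects)
    cusp_tol = tol.cusp_tol(geom, L)
    boundary_tol = tol.boundary_tol(L)
    for d in defects:
        d.locale = locale_of(d, geom, cusp_tol, boundary_tol)
    if n == 0:
        occ = field.occupied
        ang = np.degrees(
            np.arccos(np.clip(np.abs(field.nk[occ][:, 1]), 0.0, 1.0)))
        w = field.occupancy[occ]
        if float(np.average(ang, weights=w)) < tol.angle_tol_deg:
            return PatternLabel("H", 0)
        return PatternLabel("UNKNOWN", 0)
    if n == 2:
        wavy = _s_criterion(field, tol, defects)
        locales = sorted(d.locale for d in defects)
        if locales == ["cusp", "cusp"]:
            if geom.aspect == 1.0:
                return PatternLabel("B", 2)
            return PatternLabel("S", 2) if wavy else PatternLabel("Bpar", 2)
        # resolution floor: detected positions are quantized to boundary
        # sites ~0.75 cells apart, so the minor-end tolerance cannot be
        # finer than about one cell
        minor_tol = max(tol.minor_frac * geom.Lx, 1.2 * field.cell_size)
        ends = np.array([[geom.Lx / 2.0, 0.0], [-geom.Lx / 2.0, 0.0]])
        pos = np.array([d.position for d in defects])
        at_ends = (
            min(np.linalg.norm(pos[0] - ends[0]), np.linalg.norm(pos[0] - ends[1]))
            <= minor_tol
            and min(np.linalg.norm(pos[1] - ends[0]),
                    np.linalg.norm(pos[1] - ends[1])) <= minor_tol
            and np.linalg.norm(pos[0] - pos[1]) > geom.Lx / 2.0)
        if at_ends:
            return PatternLabel("Dh", 2)
        if wavy:
            return PatternLabel("Sstarstar", 2)
        if locales.count("cusp") == 1:
            return PatternLabel("Dstar", 2)
        return PatternLabel("Dstarstar", 2)
    if n > 2:
        if n == 4:
            return PatternLabel("M4", 4)
        if n == 6:
            return PatternLabel("M6", 6)
        return PatternLabel("Mn", n)
    return PatternLabel("UNKNOWN", n)


def majority_filter(values, window: int = 5):
    """Sliding-window majority vote (centered, window must be odd-ish).

    Suppresses transient defect-pair creation/annihilation noise in time
    series of defect counts or labels.
    """
    values = list(values)
    if len(values) < window:
        raise ValueError(f"series shorter than the filter window ({window})")
    half = window // 2
    out = []
    for t in range(len(values)):
        lo = max(0, t - half)
        hi = min(len(values), t + half + 1)
        seg = values[lo:hi]
        out.append(max(set(seg), key=seg.count))
    return out


def classify_pathway(defect_counts, labels=None, window: int = 5,
                     negative_counts=None) -> PathwayLabel:
    """Classify an equilibration trajectory into melt / slide / turn / other.

    ``defect_counts`` is the per-sample number of detected defects (the
    series starting after the initial two-defect Dh stage); ``labels`` the
    per-sample :class:`PatternLabel` (or label strings).  After majority
    filtering: a sustained count of six or more marks the central-droplet
    (M6) intermediate -> melt; three to five marks the M4 intermediate ->
    slide; a count never exceeding two marks turn provided the two-defect
    pattern actually passes through displaced (D*/D**/Dh -> rotating)
    states; anything else -> other.

    When ``negative_counts`` (per-sample number of negatively charged
    defects) is supplied it takes precedence for the melt/slide split: the
    M6 droplet intermediate carries two interior -1/2 defects and M4
    exactly one.  The interior negatives come from plaquette winding and
    are robust where coarse cells merge neighboring boundary boojums, so
    this is the same decision rule with better resolution behavior.
    """
    counts = majority_filter([int(c) for c in defect_counts], window)
    cmax = max(counts)
    if negative_counts is not None:
        negs = majority_filter([int(c) for c in negative_counts], window)
        nmax = max(negs)
        if nmax >= 2:
            return PathwayLabel("melt")
        if nmax == 1 or cmax >= 3:
            return PathwayLabel("slide")
    elif cmax >= 6:
        return PathwayLabel("melt")
    elif cmax >= 3:
        return PathwayLabel("slide")
    if labels is not None:
        labs = [str(l) for l in labels]
        labs = majority_filter(labs, window)
        rotating = {"Dstarstar", "Dstar", "Dh"}
        if any(l in rotating for l in labs):
            return PathwayLabel("turn")
        return PathwayLabel("other")
    return PathwayLabel("turn")


def equilibration_time(trajectory, criteria: EquilibrationCriteria
                       = EquilibrationCriteria(),
                       target_director=(0.0, 1.0, 0.0)) -> float:
    """First sweep at which global order is established and holds.

    The criterion is ``S >= S_min`` with the global director within
    ``director_tol_deg`` of the target axis (the major axis by default),
    sustained over ``hold_window`` consecutive samples.  Returns the sweep
    index of the first sample of the sustained window, or ``inf`` if the
    trajectory never equilibrates.
    """
    if target_director is not None:
        target = np.asarray(target_director, dtype=float)
        target = target / np.linalg.norm(target)
    good = []
    sweeps = []
    for f in trajectory.frames:
        g = global_Q(f.ort)
        if target_director is None:
            ang = 0.0  # circular container: any global axis is equivalent
        else:
            ang = math.degrees(
                math.acos(min(1.0, abs(float(np.dot(g.n, target))))))
        good.append(g.S >= criteria.S_min and ang <= criteria.director_tol_deg)
        sweeps.append(f.sweep)
    run = 0
    for k, ok in enumerate(good):
        run = run + 1 if ok else 0
        if run >= criteria.hold_window:
            return float(sweeps[k - criteria.hold_window + 1])
    return NEVER


def pathway_statistics(runner, geoms=None, n_runs: int = 1, seeds=None,
                       **run_kwargs) -> pd.DataFrame:
    """Empirical pathway frequencies over independent runs per geometry.

    ``runner(geom, seed) -> PathwayLabel`` executes one simulation and
    classifies it; any exception is recorded as "other" rather than
    dropped.  ``runner`` may also be the geometry collection itself, in
    which case each run is a full minor-axis-start relaxation experiment
    (``run_relaxation``; ``run_kwargs`` are forwarded).  Returns a tidy
    DataFrame indexed by geometry label with melt/slide/turn/other
    frequencies summing to one per row.
    """
    if not callable(runner):
        runner, geoms = None, runner
    if runner is None:
        from .experiment import run_relaxation

        def runner(geom, seed):
            return run_relaxation(geom, seed=seed, mode="along_minor",
                                  **run_kwargs).pathway

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = list(range(n_runs))
    rows = {}
    for g_label, geom in (geoms.items() if isinstance(geoms, dict)
                          else [(f"{g.Ly:g}", g) for g in geoms]):
        tally = {"melt": 0, "slide": 0, "turn": 0, "other": 0}
        for s in seeds[:n_runs]:
            try:
                lab = str(runner(geom, s))
            except Exception:
                lab = "other"
            tally[lab if lab in tally else "other"] += 1
        rows[g_label] = {k: v / n_runs for k, v in tally.items()}
    df = pd.DataFrame(rows).T
    df.index.name = "geometry"
    return df
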