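"""End-to-end relaxation experiments: simulate, analyze, classify.

A relaxation run builds a controlled initial state (by default all rods
along the minor axis), evolves it by MC sweeps in chunks, and analyzes the
sampled frames: global order and director, local order field (averaged over
a short window of frames, the sampled-ensemble average), defect counts and
pattern labels, the sweep at which the two-defect Dh state first appears,
the equilibration sweep, and the melt/slide/turn pathway label.

Runs stop early once the equilibration criteria have held for the full hold
window, so small containers cost only as many sweeps as they need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from .geometry import SpindleGeometry
from .initial import InitSpec, build_initial
from .mc import Configuration, Frame, MCParams, Trajectory, run_sweeps
from .order import detect_defects, global_Q, local_Q_field, total_charge
from .patterns import (EquilibrationCriteria, PathwayLabel, classify_pathway,
                       classify_pattern, equilibration_time, NEVER)

__all__ = ["RelaxationResult", "run_relaxation", "chunk_seed"]


def chunk_seed(base_seed: int, k: int) -> int:
    """Deterministic child seed for chunk ``k`` of a run seeded ``base_seed``."""
    return int(np.random.SeedSequence([base_seed, k]).generate_state(1)[0]
               % (2**31))


@dataclass
class RelaxationResult:
    geom: SpindleGeometry
    seed: int
    sweeps: np.ndarray          # sample sweep indices
    S: np.ndarray               # global scalar order per sample
    angle_deg: np.ndarray       # global director angle to the major axis
    counts: list                # defects per analyzed sample
    labels: list                # PatternLabel per analyzed sample
    charges: list               # total charge per analyzed sample
    t_dh: float                 # sweep of first Dh classification (inf if never)
    t_eq: float                 # equilibration sweep (inf if never)
    pathway: PathwayLabel
    trajectory: Trajectory
    acceptance: float

    @property
    def dh_fraction(self) -> float:
        """Dh-formation time as a fraction of the equilibration time."""
        if not (math.isfinite(self.t_dh) and math.isfinite(self.t_eq)
                and self.t_eq > 0):
            return float("nan")
        return self.t_dh / self.t_eq


def _is_dh_stage(defects, geom: SpindleGeometry) -> bool:
    """Two positive defects on opposite sides, pair axis nearer the minor
    than the major axis."""
    if len(defects) != 2:
        return False
    pos = [d.position for d in defects]
    if any(d.charge <= 0 for d in defects):
        return False
    v = pos[0] - pos[1]
    if np.linalg.norm(v) < geom.Lx / 2.0:
        return False
    ang = math.degrees(math.atan2(abs(v[1]), abs(v[0])))
    return ang < 45.0


def _analyze_frames(config_seq, cell_size, L, avg_window):
    """Per-sample defect counts/labels using window-averaged local fields."""
    counts, labels, charges, defect_lists = [], [], [], []
    half = avg_window // 2
    n = len(config_seq)
    for t in range(n):
        window = config_seq[max(0, t - half):min(n, t + half + 1)]
        field = local_Q_field(window, cell_size)
        defects = detect_defects(field)
        try:
            lab = classify_pattern(field, defects, L=L)
        except ValueError:
            from .patterns import PatternLabel
            lab = PatternLabel("UNKNOWN", len(defects))
        counts.append(len(defects))
        labels.append(lab)
        charges.append(total_charge(defects))
        defect_lists.append(defects)
    return counts, labels, charges, defect_lists


def run_relaxation(geom: SpindleGeometry, seed: int = 0, *,
                   L: float = 20.0, d: float = 1.0, eta: float = 0.16,
                   mode: str = "along_minor",
                   max_sweeps: int = 600_000, sample_every: int = 2000,
                   cell_size: float | None = None, avg_window: int = 3,
                   criteria: EquilibrationCriteria = EquilibrationCriteria(),
                   params: MCParams | None = None,
                   stop_margin: int = 5) -> RelaxationResult:
    """Run one seeded relaxation experiment and classify its pathway.

    The MC runs in chunks of ``sample_every`` sweeps (one sample per chunk,
    each chunk on a deterministically derived child seed) and stops early
    ``stop_margin`` hold-windows after the equilibration criteria are first
    sustained.  ``cell_size`` defaults to L/2.
    """
    if cell_size is None:
        cell_size = L / 2.0
    if params is None:
        params = MCParams(sweeps=sample_every, sample_every=sample_every,
                          seed=seed)
    config = build_initial(geom, InitSpec(mode, eta, seed=seed), L, d)
    target = None if geom.aspect == 1.0 else np.array([0.0, 1.0, 0.0])

    frames = [Frame(0, config.pos.copy(), config.ort.copy())]
    S_series = []
    ang_series = []

    def record(cfg):
        g = global_Q(cfg.ort)
        S_series.append(g.S)
        if target is None:
            ang_series.append(0.0)
        else:
            ang_series.append(math.degrees(math.acos(
                min(1.0, abs(float(np.dot(g.n, target)))))))

    record(config)
    accepted_frac = []
    n_chunks = max_sweeps // sample_every
    good_run = 0
    for k in range(n_chunks):
        p = MCParams(dr_max=params.dr_max, dtheta_max=params.dtheta_max,
                     sweeps=sample_every, sample_every=sample_every,
                     seed=chunk_seed(seed, k))
        t = run_sweeps(config, p)
        accepted_frac.append(t.meta["acceptance"])
        frames.append(Frame((k + 1) * sample_every, config.pos.copy(),
                            config.ort.copy()))
        record(config)
        ok = (S_series[-1] >= criteria.S_min
              and ang_series[-1] <= criteria.director_tol_deg)
        good_run = good_run + 1 if ok else 0
        if good_run >= criteria.hold_window * stop_margin:
            break

    traj = Trajectory(frames=frames, meta={
        "Ly": geom.Ly, "aspect": geom.aspect, "h": geom.h, "L": L, "d": d,
        "eta": config.eta, "seed": seed})
    t_eq = equilibration_time(
        traj, criteria,
        target_director=(0.0, 1.0, 0.0) if target is not None else None)

    config_seq = [Configuration(geom, f.pos, f.ort, L, d) for f in frames]
    counts, labels, charges, defect_lists = _analyze_frames(
        config_seq, cell_size, L, avg_window)
    # the Dh stage, operationally: the first sample with exactly two
    # (positive) defects on opposite sides whose pair axis lies closer to
    # the minor than the major axis.  The strict Dh label demands the cores
    # within ~a cell of the minor-axis ends, which the coarse grid can miss
    # while the pattern is visibly formed.
    dh_idx = None
    for t in range(len(config_seq)):
        if _is_dh_stage(defect_lists[t], geom) or str(labels[t]) == "Dh":
            dh_idx = t
            break
    t_dh = NEVER if dh_idx is None else float(frames[dh_idx].sweep)

    # pathway: the series after the Dh stage up to equilibration
    start = dh_idx if dh_idx is not None else 0
    end = len(counts)
    if math.isfinite(t_eq):
        end = next((t for t, f in enumerate(frames) if f.sweep >= t_eq),
                   len(counts))
        end = max(end, start + 6)
    seg_counts = counts[start:end]
    seg_labels = labels[start:end]
    seg_negs = [sum(1 for dd in ds if dd.charge < 0)
                for ds in defect_lists[start:end]]
    try:
        pathway = classify_pathway(seg_counts, seg_labels,
                                   negative_counts=seg_negs)
    except ValueError:
        pathway = PathwayLabel("other")

    return RelaxationResult(
        geom=geom, seed=seed,
        sweeps=np.array([f.sweep for f in frames], dtype=float),
        S=np.array(S_series), angle_deg=np.array(ang_series),
        counts=counts, labels=labels, charges=charges,
        t_dh=t_dh, t_eq=t_eq, pathway=pathway, trajectory=traj,
        acceptance=float(np.mean(accepted_frac)) if accepted_frac else 0.0)
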