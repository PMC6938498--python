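"""Configuration files, trajectory and table I/O.

The run configuration is a YAML document with five blocks (``geometry``,
``particles``, ``mc``, ``init``, ``analysis``) plus an optional ``output``
block.  All lengths are expressed in units of the rod diameter ``d``.

Trajectories use an extended-XYZ dialect: per frame, line 1 is the rod
count N, line 2 holds space-separated ``key=value`` tokens (sweep, Ly,
aspect, h, L, d, eta, seed), followed by N lines ``x y z ux uy uz`` at full
float precision (round-trips are bit-identical on re-serialization).  A
compressed NumPy container (``.npz``) is available for long runs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import yaml

from .geometry import SpindleGeometry, make_spindle
from .mc import Frame, MCParams, Trajectory

__all__ = [
    "RunConfig", "ConfigError", "read_config", "write_config",
    "write_trajectory", "read_trajectory", "save_npz", "load_npz",
    "write_field_tsv", "write_defects_tsv",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


@dataclass(frozen=True)
class RunConfig:
    # geometry
    Ly: float = 90.0
    aspect: float = 1.5
    h: float = 6.0
    # particles
    L: float = 20.0
    d: float = 1.0
    eta: float = 0.16
    # mc
    dr_max: float = 0.5
    dtheta_max: float = 0.1
    sweeps: int = 10_000
    sample_every: int = 1000
    seed: int = 0
    # init
    init_mode: str = "along_minor"
    init_seed: int = 0
    # analysis
    cell_size: float | None = None
    # output
    trajectory_path: str | None = None

    def geometry(self) -> SpindleGeometry:
        return make_spindle(self.Ly, self.aspect, self.h)

    def mc_params(self) -> MCParams:
        return MCParams(dr_max=self.dr_max, dtheta_max=self.dtheta_max,
                        sweeps=self.sweeps, sample_every=self.sample_every,
                        seed=self.seed)


_SCHEMA = {
    "geometry": {"Ly": "Ly", "aspect": "aspect", "h": "h"},
    "particles": {"L": "L", "d": "d", "eta": "eta"},
    "mc": {"dr_max": "dr_max", "dtheta_max": "dtheta_max", "sweeps": "sweeps",
           "sample_every": "sample_every", "seed": "seed"},
    "init": {"mode": "init_mode", "seed": "init_seed"},
    "analysis": {"cell_size": "cell_size"},
    "output": {"trajectory": "trajectory_path"},
}


def _validate(cfg: RunConfig) -> RunConfig:
    if cfg.Ly <= 0 or cfg.h <= 0:
        raise ConfigError("geometry.Ly and geometry.h must be positive")
    if cfg.aspect < 1.0:
        raise ConfigError(f"geometry.aspect must be >= 1, got {cfg.aspect}")
    if cfg.L <= 0 or cfg.d <= 0:
        raise ConfigError("particles.L and particles.d must be positive")
    if not (0.0 < cfg.eta < 1.0):
        raise ConfigError(f"particles.eta must be in (0, 1), got {cfg.eta}")
    if cfg.sweeps < 0 or cfg.sample_every < 1:
        raise ConfigError("mc.sweeps must be >= 0 and mc.sample_every >= 1")
    if cfg.dr_max <= 0 or cfg.dtheta_max <= 0:
        raise ConfigError("mc move amplitudes must be positive")
    from .initial import MODES
    if cfg.init_mode not in MODES:
        raise ConfigError(f"init.mode must be one of {MODES}, "
                          f"got {cfg.init_mode!r}")
    if cfg.cell_size is not None and not (cfg.d <= cfg.cell_size <= cfg.L):
        raise ConfigError(f"analysis.cell_size must be in [d, L], "
                          f"got {cfg.cell_size}")
    return cfg


def read_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are errors."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for block, entries in doc.items():
        if block not in _SCHEMA:
            raise ConfigError(f"unknown config block {block!r}")
        if entries is None:
            continue
        if not isinstance(entries, dict):
            raise ConfigError(f"block {block!r} must be a mapping")
        for key, value in entries.items():
            if key not in _SCHEMA[block]:
                raise ConfigError(f"unknown key {block}.{key}")
            kwargs[_SCHEMA[block][key]] = value
    try:
        cfg = RunConfig(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    return _validate(cfg)


def write_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig back to YAML (inverse of :func:`read_config`)."""
    doc: dict = {}
    for block, entries in _SCHEMA.items():
        vals = {}
        for key, attr in entries.items():
            v = getattr(cfg, attr)
            if v is not None:
                vals[key] = v
        if vals:
            doc[block] = vals
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# extended-XYZ trajectories

_META_KEYS = ("sweep", "Ly", "aspect", "h", "L", "d", "eta", "seed")


class TrajectoryParseError(ValueError):
    pass


def write_trajectory(traj: Trajectory, path) -> None:
    """Write frames in the extended-XYZ dialect (full float precision)."""
    def fmt(v):
        if isinstance(v, str):
            return v
        if isinstance(v, (int, np.integer)):
            return str(int(v))
        return repr(float(v))   # shortest exact round-trip representation

    with open(path, "w") as fh:
        for frame in traj.frames:
            n = frame.pos.shape[0]
            meta = dict(traj.meta)
            meta["sweep"] = frame.sweep
            tokens = " ".join(f"{k}={fmt(meta[k])}"
                              for k in _META_KEYS if k in meta)
            fh.write(f"{n}\n{tokens}\n")
            for p, u in zip(frame.pos, frame.ort):
                fh.write(" ".join(repr(float(v)) for v in (*p, *u)) + "\n")


def read_trajectory(path) -> Trajectory:
    """Read an extended-XYZ trajectory; raises on malformed/truncated frames."""
    frames: list[Frame] = []
    meta: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos_line = 0
    frame_idx = 0
    while pos_line < len(lines):
        if lines[pos_line].strip() == "":
            pos_line += 1
            continue
        try:
            n = int(lines[pos_line])
        except ValueError as exc:
            raise TrajectoryParseError(
                f"frame {frame_idx}: bad count line {lines[pos_line]!r}"
            ) from exc
        if pos_line + 2 + n > len(lines):
            raise TrajectoryParseError(
                f"truncated file in frame {frame_idx}; "
                f"last complete frame is {frame_idx - 1}")
        header = lines[pos_line + 1]
        fmeta = {}
        for tok in header.split():
            if "=" not in tok:
                raise TrajectoryParseError(
                    f"frame {frame_idx}: bad header token {tok!r}")
            k, v = tok.split("=", 1)
            try:
                fmeta[k] = int(v)
            except ValueError:
                try:
                    fmeta[k] = float(v)
                except ValueError:
                    fmeta[k] = v.strip("'\"")
        body = lines[pos_line + 2: pos_line + 2 + n]
        pos = np.empty((n, 3))
        ort = np.empty((n, 3))
        for i, ln in enumerate(body):
            parts = ln.split()
            if len(parts) != 6:
                raise TrajectoryParseError(
                    f"frame {frame_idx}, rod {i}: expected 6 columns, "
                    f"got {len(parts)}")
            pos[i] = [float(p) for p in parts[:3]]
            ort[i] = [float(p) for p in parts[3:]]
        sweep = int(fmeta.pop("sweep", frame_idx))
        if not meta:
            meta = fmeta
        frames.append(Frame(sweep, pos, ort))
        pos_line += 2 + n
        frame_idx += 1
    return Trajectory(frames=frames, meta=meta)


def save_npz(traj: Trajectory, path) -> None:
    """Binary container for long runs (same schema as the XYZ dialect)."""
    np.savez_compressed(
        path,
        sweeps=np.array([f.sweep for f in traj.frames]),
        pos=np.stack([f.pos for f in traj.frames]),
        ort=np.stack([f.ort for f in traj.frames]),
        meta_keys=np.array(sorted(traj.meta), dtype=object),
        meta_vals=np.array([repr(traj.meta[k]) for k in sorted(traj.meta)],
                           dtype=object),
    )


def load_npz(path) -> Trajectory:
    import ast

    with np.load(path, allow_pickle=True) as data:
        meta = {k: ast.literal_eval(v) for k, v in
                zip(data["meta_keys"], data["meta_vals"])}
        frames = [Frame(int(s), p.copy(), o.copy())
                  for s, p, o in zip(data["sweeps"], data["pos"], data["ort"])]
    return Trajectory(frames=frames, meta=meta)


# ---------------------------------------------------------------------------
# TSV dumps

def write_field_tsv(field, path) -> None:
    """Per-cell table: x, y, S, angle, delta, occupancy."""
    from .order import field_to_table
    table = field_to_table(field)
    header = "x\ty\tS\tangle\tdelta\toccupancy"
    np.savetxt(path, table, delimiter="\t", header=header, comments="")


def write_defects_tsv(defects, path) -> None:
    """Defect list: x, y, charge, locale."""
    with open(path, "w") as fh:
        fh.write("x\ty\tcharge\tlocale\n")
        for dd in defects:
            fh.write(f"{dd.position[0]:.6g}\t{dd.position[1]:.6g}\t"
                     f"{dd.charge:g}\t{dd.locale}\n")
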