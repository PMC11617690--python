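"""Interaction indicators from paired trajectories: minimum distance and delta-v.

A traffic interaction between two road users is summarized by two surrogate
safety indicators:

* **MD** — the minimum Euclidean distance over the frames where both vehicles
  are observed (the proximity indicator, metres);
* **delta-v** — the change of velocity a collision at the closest approach
  would impose on each vehicle, from both speeds, the masses, and the
  approach angle alpha:

      dv1 = m2/(m1+m2) * sqrt(v1^2 + v2^2 - 2 v1 v2 cos(alpha)),
      dv2 = m1/(m1+m2) * sqrt(v1^2 + v2^2 - 2 v1 v2 cos(alpha)),

  with the larger of the two used as the severity indicator (m/s).

Masses are assigned per vehicle class; the approach angle is either supplied
per pair or estimated from finite-difference headings at the closest-approach
frame.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .exceptions import DataError, NoOverlapError

__all__ = [
    "DEFAULT_MASSES",
    "Trajectory",
    "InteractionRecord",
    "min_distance",
    "delta_v",
    "delta_v_at_min_distance",
    "compute_interactions",
]

DEFAULT_MASSES = {"car": 1500.0, "minivan": 2200.0, "truck": 15000.0}


@dataclass
class Trajectory:
    """Per-frame planar track of one vehicle: frame index, position, speed."""

    frames: np.ndarray  # strictly increasing integers
    x: np.ndarray  # metres
    y: np.ndarray  # metres
    speed: np.ndarray  # m/s
    vehicle_class: str = "car"
    mass: float | None = None  # kg; resolved from class when None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        n = self.frames.size
        if not (self.x.size == self.y.size == self.speed.size == n):
            raise DataError("trajectory columns must have equal length")
        if n and np.any(np.diff(self.frames) <= 0):
            raise DataError("frames must be strictly increasing")
        if np.any(self.speed < 0):
            raise DataError("speeds must be non-negative")
        if self.mass is None:
            if self.vehicle_class not in DEFAULT_MASSES:
                raise DataError(f"unknown vehicle class {self.vehicle_class!r}")
            self.mass = DEFAULT_MASSES[self.vehicle_class]
        if not self.mass > 0:
            raise DataError("mass must be positive")


@dataclass(frozen=True)
class InteractionRecord:
    """One interaction: proximity (md), severity (dv) and bookkeeping."""

    md: float
    dv: float
    n_shared_frames: int
    frame: int | None = None
    dv1: float | None = None
    dv2: float | None = None
    alpha_deg: float | None = None


def min_distance(a: Trajectory, b: Trajectory) -> tuple[float, int]:
    """Minimum Euclidean distance over shared frames; ties -> earliest frame."""
    shared, ia, ib = np.intersect1d(a.frames, b.frames, return_indices=True)
    if shared.size == 0:
        raise NoOverlapError("trajectories share no frame")
    d = np.hypot(a.x[ia] - b.x[ib], a.y[ia] - b.y[ib])
    k = int(np.argmin(d))  # argmin returns the first minimum: earliest frame
    return float(d[k]), int(shared[k])


def delta_v(
    v1: float, v2: float, m1: float, m2: float, alpha: float
) -> tuple[float, float, float]:
    """Per-vehicle delta-v and their maximum; ``alpha`` in degrees."""
    if v1 < 0 or v2 < 0:
        raise DataError("speeds must be non-negative")
    if m1 <= 0 or m2 <= 0:
        raise DataError("masses must be positive")
    rel = np.sqrt(max(v1**2 + v2**2 - 2.0 * v1 * v2 * np.cos(np.radians(alpha)), 0.0))
    dv1 = m2 / (m1 + m2) * rel
    dv2 = m1 / (m1 + m2) * rel
    return float(dv1), float(dv2), float(max(dv1, dv2))


def _heading(traj: Trajectory, frame: int) -> np.ndarray:
    """Finite-difference heading vector at a frame (central where possible)."""
    i = int(np.searchsorted(traj.frames, frame))
    lo = max(i - 1, 0)
    hi = min(i + 1, traj.frames.size - 1)
    h = np.array([traj.x[hi] - traj.x[lo], traj.y[hi] - traj.y[lo]])
    return h


def delta_v_at_min_distance(
    a: Trajectory,
    b: Trajectory,
    alpha: float | None = None,
) -> InteractionRecord:
    """Interaction record: MD plus delta-v at the closest-approach frame.

    Speeds are taken at the MD frame; the approach angle is the supplied
    ``alpha`` (degrees) or, when absent, the angle between the two vehicles'
    finite-difference heading vectors at that frame.
    """
    md, frame = min_distance(a, b)
    n_shared = np.intersect1d(a.frames, b.frames).size
    ia = int(np.searchsorted(a.frames, frame))
    ib = int(np.searchsorted(b.frames, frame))
    v1 = float(a.speed[ia])
    v2 = float(b.speed[ib])
    if alpha is None:
        ha = _heading(a, frame)
        hb = _heading(b, frame)
        na, nb = np.linalg.norm(ha), np.linalg.norm(hb)
        if na == 0 or nb == 0:  # stationary vehicle: no heading, assume head-on
            alpha = 180.0
        else:
            cosang = np.clip(ha @ hb / (na * nb), -1.0, 1.0)
            alpha = float(np.degrees(np.arccos(cosang)))
    dv1, dv2, dv_max = delta_v(v1, v2, a.mass, b.mass, alpha)
    return InteractionRecord(
        md=md,
        dv=dv_max,
        n_shared_frames=int(n_shared),
        frame=frame,
        dv1=dv1,
        dv2=dv2,
        alpha_deg=float(alpha),
    )


def compute_interactions(
    df: pd.DataFrame,
    masses: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Batch indicator computation from a tidy trajectory table.

    Expects columns ``pair_id, vehicle_id, frame, x, y, speed, class`` and
    optionally ``alpha`` (degrees, constant within a pair).  Returns one row
    per pair: ``pair_id, md, dv, n_shared_frames, alpha_deg``.
    """
    required = {"pair_id", "vehicle_id", "frame", "x", "y", "speed", "class"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"trajectory table missing columns: {sorted(missing)}")
    masses = {**DEFAULT_MASSES, **(masses or {})}
    rows = []
    for pair_id, g in df.groupby("pair_id", sort=True):
        vids = sorted(g["vehicle_id"].unique())
        if len(vids) != 2:
            raise DataError(f"pair {pair_id!r} has {len(vids)} vehicles; need 2")
        trajs = []
        for vid in vids:
            gv = g[g["vehicle_id"] == vid].sort_values("frame")
            cls = str(gv["class"].iloc[0])
            trajs.append(
                Trajectory(
                    frames=gv["frame"].to_numpy(),
                    x=gv["x"].to_numpy(),
                    y=gv["y"].to_numpy(),
                    speed=gv["speed"].to_numpy(),
                    vehicle_class=cls,
                    mass=masses.get(cls),
                )
            )
        alpha = float(g["alpha"].iloc[0]) if "alpha" in g.columns else None
        rec = delta_v_at_min_distance(trajs[0], trajs[1], alpha=alpha)
        rows.append(
            {
                "pair_id": pair_id,
                "md": rec.md,
                "dv": rec.dv,
                "n_shared_frames": rec.n_shared_frames,
                "alpha_deg": rec.alpha_deg,
            }
        )
    return pd.DataFrame(rows)
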