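"""Axis projection and instant velocities for single-molecule tracks in cilia.

A tracked membrane protein in a primary cilium moves, to good approximation,
along a one-dimensional curve (the ciliary axis).  This module turns raw 2D
localizations into axis-projected coordinates via PCA, filters out essentially
stationary tracks, and converts the axial coordinate into signed instant
velocities (anterograde = away from the ciliary base).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Trajectory",
    "AxisProjection",
    "VelocitySample",
    "fit_axis",
    "filter_stationary",
    "instant_velocities",
    "pool_condition",
]

#: Direction labels used throughout.  Zero axial displacement belongs to
#: neither class: sign-based classification is undefined at 0.
ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
NEITHER = "none"


@dataclass
class Trajectory:
    """One tracked molecule: ordered positions plus the cell's cilium base.

    Parameters
    ----------
    track_id : str
        Identifier of the track.
    t : ndarray, shape (n,)
        Frame times in seconds, strictly increasing.
    x, y : ndarray, shape (n,)
        Localizations in micrometres (image coordinates).
    base : ndarray, shape (2,)
        Position of the ciliary base (basal-body marker) in the same frame.
    condition : str
        Experimental condition label (e.g. ``"live"``, ``"permeabilized"``).
    """

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    base: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.base = np.asarray(self.base, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError(f"track {self.track_id}: need >= 2 positions")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError(f"track {self.track_id}: ragged columns")
        if not np.all(np.isfinite(self.t)) or not np.all(
            np.isfinite(self.x)
        ) or not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.base)):
            raise ValueError(f"track {self.track_id}: non-finite coordinates")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(
                f"track {self.track_id}: times must be strictly increasing"
            )

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of localizations."""
        return np.column_stack([self.x, self.y])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AxisProjection:
    """A trajectory projected onto its own fitted cilium axis.

    ``s`` is the signed axial coordinate, oriented so that the base projects
    at or below the track median; ``p`` is the perpendicular coordinate.
    """

    track_id: str
    origin: np.ndarray
    direction: np.ndarray
    t: np.ndarray
    s: np.ndarray
    p: np.ndarray
    base_s: float
    flipped: bool
    condition: str = ""

    @property
    def axial_variance(self) -> float:
        """Population variance of the axial coordinate (μm²)."""
        return float(np.var(self.s))


@dataclass
class VelocitySample:
    """Signed instant axial velocities pooled over one or more tracks."""

    v_axial: np.ndarray
    v_perp: np.ndarray
    direction: np.ndarray  # ANTEROGRADE / RETROGRADE / NEITHER per step
    track_ids: np.ndarray
    t: np.ndarray  # time of the earlier frame of each step
    dt: float
    condition: str = ""

    def __post_init__(self) -> None:
        self.v_axial = np.asarray(self.v_axial, dtype=float)
        self.v_perp = np.asarray(self.v_perp, dtype=float)
        self.direction = np.asarray(self.direction, dtype=object)
        self.track_ids = np.asarray(self.track_ids, dtype=object)
        self.t = np.asarray(self.t, dtype=float)

    def __len__(self) -> int:
        return len(self.v_axial)

    def speeds(self, direction: str) -> np.ndarray:
        """Velocity magnitudes restricted to one direction class."""
        mask = self.direction == direction
        return np.abs(self.v_axial[mask])

    def velocities(self, direction: str) -> np.ndarray:
        """Signed velocities restricted to one direction class."""
        return self.v_axial[self.direction == direction]

    def counts(self) -> dict[str, int]:
        return {
            d: int(np.sum(self.direction == d))
            for d in (ANTEROGRADE, RETROGRADE, NEITHER)
        }


def fit_axis(traj: Trajectory) -> AxisProjection:
    """Fit the cilium axis by PCA on the localizations plus the base point.

    The base is included as one additional observation.  The leading
    eigenvector of the covariance defines the axis; its sign is chosen so
    that the base's axial coordinate does not exceed the median axial
    coordinate of the track (anterograde motion is then positive).

    Raises
    ------
    ValueError
        If fewer than 3 distinct positions, or all points coincide.
    """
    pts = traj.positions
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError(f"track {traj.track_id}: need >= 3 distinct positions")
    cloud = np.vstack([pts, traj.base[None, :]])
    origin = cloud.mean(axis=0)
    cov = np.cov(cloud.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or not np.isfinite(evals[-1]):
        raise ValueError(f"track {traj.track_id}: degenerate position covariance")
    direction = evecs[:, -1]
    s = (pts - origin) @ direction
    base_s = float((traj.base - origin) @ direction)
    flipped = False
    if base_s > np.median(s):
        direction = -direction
        s = -s
        base_s = -base_s
        flipped = True
    normal = np.array([-direction[1], direction[0]])
    p = (pts - origin) @ normal
    return AxisProjection(
        track_id=traj.track_id,
        origin=origin,
        direction=direction,
        t=traj.t.copy(),
        s=s,
        p=p,
        base_s=base_s,
        flipped=flipped,
        condition=traj.condition,
    )


def filter_stationary(
    projections: list[AxisProjection], threshold: float = 0.1
) -> tuple[list[AxisProjection], list[AxisProjection]]:
    """Split projections into (kept, excluded) by axial variance.

    A track is excluded iff its axial variance is strictly below
    ``threshold`` (default 0.1 μm²) — essentially stationary molecules are
    treated as outliers, e.g. receptors stuck at the ciliary base.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept, excluded = [], []
    for proj in projections:
        (excluded if proj.axial_variance < threshold else kept).append(proj)
    return kept, excluded


def instant_velocities(
    projection: AxisProjection, dt: float, rtol: float = 0.01
) -> VelocitySample:
    """Instant velocities: consecutive axial differences divided by ``dt``.

    Frame pairs must be evenly spaced at ``dt`` within relative tolerance
    ``rtol``.  Pairs separated by more than one frame interval are treated
    as gaps and contribute no velocity (the track is effectively split);
    pairs spaced *closer* than the nominal interval are an error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    steps = np.diff(projection.t)
    if np.any(steps < dt * (1 - rtol)):
        raise ValueError(
            f"track {projection.track_id}: frame spacing below dt={dt}"
        )
    ok = np.abs(steps - dt) <= rtol * dt  # gap frames are simply dropped
    v = np.diff(projection.s)[ok] / dt
    vp = np.diff(projection.p)[ok] / dt
    direction = np.where(v > 0, ANTEROGRADE, np.where(v < 0, RETROGRADE, NEITHER))
    return VelocitySample(
        v_axial=v,
        v_perp=vp,
        direction=direction,
        track_ids=np.repeat(projection.track_id, len(v)),
        t=projection.t[:-1][ok],
        dt=dt,
        condition=projection.condition,
    )


def pool_condition(
    samples: list[VelocitySample], condition: str = ""
) -> VelocitySample:
    """Concatenate velocity samples from many cilia of one condition.

    All samples must share the same frame interval; provenance track ids are
    preserved so the pool can be split back.
    """
    if not samples:
        raise ValueError("no samples to pool")
    dt = samples[0].dt
    for s in samples:
        if not np.isclose(s.dt, dt, rtol=1e-9):
            raise ValueError(f"mixed frame intervals: {s.dt} vs {dt}")
    return VelocitySample(
        v_axial=np.concatenate([s.v_axial for s in samples]),
        v_perp=np.concatenate([s.v_perp for s in samples]),
        direction=np.concatenate([s.direction for s in samples]),
        track_ids=np.concatenate([s.track_ids for s in samples]),
        t=np.concatenate([s.t for s in samples]),
        dt=dt,
        condition=condition or samples[0].condition,
    )


def split_by_track(sample: VelocitySample) -> dict[str, VelocitySample]:
    """Inverse of :func:`pool_condition`: split a pooled sample by track id."""
    out: dict[str, VelocitySample] = {}
    for tid in dict.fromkeys(sample.track_ids):  # preserves order
        m = sample.track_ids == tid
        out[tid] = VelocitySample(
            v_axial=sample.v_axial[m],
            v_perp=sample.v_perp[m],
            direction=sample.direction[m],
            track_ids=sample.track_ids[m],
            t=sample.t[m],
            dt=sample.dt,
            condition=sample.condition,
        )
    return out
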