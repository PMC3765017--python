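"""Center-of-force trajectories, distance traveled and low-mobility bouts.

The horizontal position of the animal is recovered from the four corner
loads by the principle of moments: x = sum(x_i F_i) / sum(F_i) and
likewise for y, where (x_i, y_i) are the transducer positions.  When the
total load falls below a threshold (animal partially off the plate, e.g.
rearing against the cage wall) the instantaneous position is marked
invalid rather than allowed to blow up.

Positions sampled at 100 Hz are reduced to one point per 0.5 s by block
averaging (the mean of the valid samples in each 50-sample block), which
suppresses tremor-induced jitter of the center of force that would
otherwise inflate apparent travel in strongly tremoring animals.
Distance traveled is the summed Euclidean step length of that 0.5-s
trajectory, over the full session.

A low-mobility bout is scored with a virtual circle of radius 15.0 mm:
a 5.00-s timer runs while the animal stays inside the circle around its
anchor point; leaving the circle re-anchors at the exit point and resets
the timer; surviving 5.00 s inside tallies one bout and resets the timer
(a renewal process), so a motionless animal accrues exactly
floor(T / 5.00) bouts in T seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PlateGeometry, Recording

__all__ = [
    "BOUT_RADIUS_MM",
    "BOUT_DWELL_S",
    "Trajectory",
    "Bout",
    "MobilityMetrics",
    "center_of_force",
    "downsample_positions",
    "distance_traveled",
    "low_mobility_bouts",
    "detect_low_mobility_bouts",
    "mobility_metrics",
    "write_trajectory",
    "write_bout_log",
]

BOUT_RADIUS_MM = 15.0
BOUT_DWELL_S = 5.00
STEP_SECONDS = 0.5
#: Fraction of body weight below which the total load is considered
#: unreliable for the moment computation.
MIN_LOAD_FRACTION = 0.25


@dataclass(frozen=True)
class Trajectory:
    """Center-of-force positions at a fixed time step.

    ``times`` are block end-times (0.5, 1.0, ... s); each point stands for
    one elapsed block.  ``observed`` is False for points carried forward
    from the previous block because no valid raw sample fell in theirs.
    """

    times: np.ndarray
    positions: np.ndarray  # (n, 2) mm, plate-center origin
    observed: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        xy = np.asarray(self.positions, dtype=float)
        obs = np.asarray(self.observed, dtype=bool)
        if xy.ndim != 2 or xy.shape[1] != 2 or t.shape[0] != xy.shape[0]:
            raise ValueError("positions must be (n, 2) aligned with times")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", xy)
        object.__setattr__(self, "observed", obs)

    @property
    def step_seconds(self) -> float:
        if self.times.size >= 2:
            return float(self.times[1] - self.times[0])
        return float(self.times[0]) if self.times.size else STEP_SECONDS

    @property
    def duration_s(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0


@dataclass(frozen=True)
class Bout:
    """One tallied low-mobility bout and the circle that scored it."""

    start_time_s: float
    anchor_x_mm: float
    anchor_y_mm: float


@dataclass(frozen=True)
class MobilityMetrics:
    distance_mm: float
    low_mobility_bouts: int
    session_duration_s: float

    def __post_init__(self) -> None:
        if self.distance_mm < 0 or self.low_mobility_bouts < 0:
            raise ValueError("mobility metrics must be non-negative")


def center_of_force(
    forces: np.ndarray,
    geometry: PlateGeometry,
    min_load: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous center of force by the principle of moments.

    ``forces`` is (4,) or (n, 4) gram-force in the geometry's channel
    order.  Returns (positions (n, 2) mm, valid (n,) bool); a frame is
    invalid when its total load is <= ``min_load`` (positions there are
    NaN).  With non-negative loads the result is a convex combination of
    the transducer positions and therefore lies on the plate.
    """
    F = np.atleast_2d(np.asarray(forces, dtype=float))
    pos = geometry.positions_array()  # (4, 2)
    total = F.sum(axis=1)
    valid = total > max(min_load, 0.0)
    xy = np.full((F.shape[0], 2), np.nan)
    if valid.any():
        xy[valid] = (F[valid] @ pos) / total[valid, None]
    return xy, valid


def downsample_positions(
    positions: np.ndarray,
    valid: np.ndarray,
    sample_rate: float = 100.0,
    step_seconds: float = STEP_SECONDS,
) -> Trajectory:
    """Reduce raw positions to one point per ``step_seconds`` block.

    Each trajectory point is the mean of the valid raw positions in its
    block; a block with no valid sample carries the last valid block
    position forward (leading empty blocks take the first valid position).
    Trailing samples that do not fill a block are dropped.
    """
    xy = np.asarray(positions, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    block = int(round(step_seconds * sample_rate))
    n_blocks = xy.shape[0] // block
    if n_blocks == 0:
        raise ValueError("fewer samples than one downsampling block")
    out = np.empty((n_blocks, 2))
    observed = np.zeros(n_blocks, dtype=bool)
    for b in range(n_blocks):
        sl = slice(b * block, (b + 1) * block)
        v = valid[sl]
        if v.any():
            out[b] = xy[sl][v].mean(axis=0)
            observed[b] = True
        else:
            out[b] = np.nan
    if not observed.any():
        raise ValueError("no valid positions in the whole recording")
    # forward-fill, then back-fill any leading gap
    last = None
    for b in range(n_blocks):
        if observed[b]:
            last = out[b]
        elif last is not None:
            out[b] = last
    first_obs = int(np.flatnonzero(observed)[0])
    out[:first_obs] = out[first_obs]
    times = (np.arange(n_blocks) + 1) * step_seconds
    return Trajectory(times=times, positions=out, observed=observed)


def distance_traveled(traj: Trajectory) -> float:
    """Total path length (mm): summed Euclidean distance between
    consecutive trajectory points."""
    if traj.positions.shape[0] < 2:
        raise ValueError("need at least two trajectory points")
    steps = np.diff(traj.positions, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def low_mobility_bouts(
    traj: Trajectory,
    radius_mm: float = BOUT_RADIUS_MM,
    dwell_s: float = BOUT_DWELL_S,
    mode: str = "renewal",
) -> list[Bout]:
    """Tally low-mobility bouts and return one record per bout.

    ``mode="renewal"`` (default) anchors the circle at the point where the
    timer last reset: leaving the circle re-anchors at the exit point and
    restarts the timer, and a completed dwell re-anchors at the current
    point.  ``mode="trailing"`` instead centers the circle on the current
    point and asks whether every point of the trailing dwell window stayed
    within the radius — an alternative reading of a circle "centered on
    the mouse as it moved"; the two agree for motionless sessions.
    """
    if mode not in ("renewal", "trailing"):
        raise ValueError("mode must be 'renewal' or 'trailing'")
    xy = traj.positions
    step = traj.step_seconds
    n = xy.shape[0]
    if n == 0:
        return []
    bouts: list[Bout] = []

    if mode == "renewal":
        anchor = xy[0]
        timer = 0.0
        timer_start = 0.0
        for i in range(n):
            if np.hypot(*(xy[i] - anchor)) > radius_mm:
                anchor = xy[i]
                timer = 0.0
                timer_start = traj.times[i] - step
            timer += step
            if timer >= dwell_s - 1e-9:
                bouts.append(Bout(timer_start, float(anchor[0]), float(anchor[1])))
                anchor = xy[i]
                timer = 0.0
                timer_start = traj.times[i]
    else:
        window = max(1, int(round(dwell_s / step)))
        i_start = 0  # first index after the last tallied bout
        for i in range(n):
            lo = i - window + 1
            if lo < max(0, i_start):
                continue
            center = xy[i]
            if np.all(np.hypot(*(xy[lo : i + 1] - center).T) <= radius_mm):
                bouts.append(
                    Bout(traj.times[lo] - step, float(center[0]), float(center[1]))
                )
                i_start = i + 1
    return bouts


def detect_low_mobility_bouts(
    traj: Trajectory,
    radius_mm: float = BOUT_RADIUS_MM,
    dwell_s: float = BOUT_DWELL_S,
    mode: str = "renewal",
) -> int:
    """Number of low-mobility bouts in the session."""
    return len(low_mobility_bouts(traj, radius_mm, dwell_s, mode))


def mobility_metrics(
    recording: Recording,
    radius_mm: float = BOUT_RADIUS_MM,
    dwell_s: float = BOUT_DWELL_S,
    downsample: str = "mean",
    mode: str = "renewal",
) -> tuple[Trajectory, MobilityMetrics]:
    """Locomotor pipeline for a full session.

    ``downsample`` selects block-mean positions (default) or the
    instantaneous sample at each 0.5-s boundary.
    """
    min_load = MIN_LOAD_FRACTION * recording.meta.body_weight_g
    xy, valid = center_of_force(recording.forces, recording.geometry, min_load)
    if downsample == "mean":
        traj = downsample_positions(xy, valid, recording.sample_rate)
    elif downsample == "instantaneous":
        block = int(round(STEP_SECONDS * recording.sample_rate))
        idx = np.arange(block - 1, xy.shape[0], block)
        sub_xy, sub_valid = xy[idx], valid[idx]
        traj = downsample_positions(sub_xy, sub_valid, sample_rate=1.0, step_seconds=1.0)
        traj = Trajectory(
            times=(np.arange(sub_xy.shape[0]) + 1) * STEP_SECONDS,
            positions=traj.positions,
            observed=traj.observed,
        )
    else:
        raise ValueError("downsample must be 'mean' or 'instantaneous'")
    metrics = MobilityMetrics(
        distance_mm=distance_traveled(traj),
        low_mobility_bouts=detect_low_mobility_bouts(traj, radius_mm, dwell_s, mode),
        session_duration_s=traj.duration_s,
    )
    return traj, metrics


def write_trajectory(traj: Trajectory, path) -> None:
    """Write (t, x, y) delimited text."""
    data = np.column_stack([traj.times, traj.positions])
    np.savetxt(path, data, fmt="%.4f", delimiter="\t", header="time_s\tx_mm\ty_mm")


def write_bout_log(bouts: list[Bout], path) -> None:
    """Write one row per bout: index, start time, anchor x, anchor y."""
    rows = [
        (i, b.start_time_s, b.anchor_x_mm, b.anchor_y_mm)
        for i, b in enumerate(bouts, start=1)
    ]
    data = np.asarray(rows, dtype=float).reshape(-1, 4)
    np.savetxt(
        path,
        data,
        fmt=["%d", "%.2f", "%.3f", "%.3f"],
        delimiter="\t",
        header="bout\tstart_s\tanchor_x_mm\tanchor_y_mm",
    )
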