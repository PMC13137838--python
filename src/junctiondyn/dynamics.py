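"""Time-resolved metrics: border displacement, migration tracks, TER.

The junctional displacement rate follows the cell-border-tracker readout:
for frame t, d_mean(t) combines the distance between the border skeleton at
t and the skeletons at t - dt and t + dt, and the displacement rate is
d_mean(t) / (2 dt).  The border-to-border distance d(A, B) is the symmetric
mean nearest-neighbour distance between the two skeleton pixel sets, which
makes the rate equal to the single-step border speed for rigid motion and
invariant under time reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segmentation import SegmentationResult


class DynamicsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# border displacement

def _skeleton_points(seg: SegmentationResult, exclude_edge_px: int = 1) -> np.ndarray:
    """Skeleton pixel coordinates, excluding a margin at the field edge
    (edge-clipped borders would otherwise contribute spurious distances)."""
    skel = seg.border_skeleton
    if exclude_edge_px > 0:
        m = exclude_edge_px
        keep = np.zeros_like(skel)
        keep[m:-m, m:-m] = True
        skel = skel & keep
    return np.column_stack(np.nonzero(skel)).astype(float)


def skeleton_distance(
    pts_a: np.ndarray,
    pts_b: np.ndarray,
    metric: str = "nn_mean",
) -> float:
    """Distance (px) between two border-skeleton point sets.

    ``nn_mean`` (default) — symmetric mean nearest-neighbour distance;
    ``hausdorff`` — symmetric Hausdorff distance.  Both satisfy
    d(A, B) = d(B, A).
    """
    if len(pts_a) == 0 or len(pts_b) == 0:
        raise DynamicsError("no borders: empty skeleton")
    ta, tb = cKDTree(pts_a), cKDTree(pts_b)
    d_ab, _ = tb.query(pts_a)
    d_ba, _ = ta.query(pts_b)
    if metric == "nn_mean":
        return float((d_ab.mean() + d_ba.mean()) / 2.0)
    if metric == "hausdorff":
        return float(max(d_ab.max(), d_ba.max()))
    raise DynamicsError(f"unknown border-distance metric: {metric}")


def border_displacement(
    seg_prev: SegmentationResult,
    seg_t: SegmentationResult,
    seg_next: SegmentationResult,
    dt_min: float,
    pixel_size_um: float = 1.0,
    aggregation: str = "sum",
    metric: str = "nn_mean",
) -> dict:
    """One d_mean entry from three consecutive segmentations.

    ``aggregation='sum'`` (default) adds the two neighbour-frame distances,
    so rate = d_mean / (2 dt) equals the mean single-step border speed;
    ``'mean'`` averages them instead (rates halve for rigid motion).
    """
    if dt_min <= 0:
        raise DynamicsError("invalid calibration: dt must be > 0")
    shapes = {seg_prev.labels.shape, seg_t.labels.shape, seg_next.labels.shape}
    if len(shapes) != 1:
        raise DynamicsError("segmentations must share the image shape")
    p_prev, p_t, p_next = (
        _skeleton_points(s) for s in (seg_prev, seg_t, seg_next)
    )
    d_prev = skeleton_distance(p_t, p_prev, metric) * pixel_size_um
    d_next = skeleton_distance(p_t, p_next, metric) * pixel_size_um
    if aggregation == "sum":
        d_mean = d_prev + d_next
    elif aggregation == "mean":
        d_mean = (d_prev + d_next) / 2.0
    else:
        raise DynamicsError(f"unknown dmean_aggregation: {aggregation}")
    return {
        "d_prev_um": d_prev,
        "d_next_um": d_next,
        "d_mean_um": d_mean,
        "rate_um_per_min": d_mean / (2.0 * dt_min),
    }


@dataclass
class BorderDisplacementSeries:
    """Per-frame d_mean and displacement rate; NaN at the first and last
    frame where the centred window is undefined."""

    frame_times_min: np.ndarray
    d_mean_um: np.ndarray
    displacement_rate_um_per_min: np.ndarray
    dt_min: float
    reduced_window: tuple[int, int] | None = None  # [start, end] frame indices
    baseline_rate_um_per_min: float = float("nan")
    window_reduction: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.d_mean_um)),
                "time_min": self.frame_times_min,
                "d_mean_um": self.d_mean_um,
                "rate_um_per_min": self.displacement_rate_um_per_min,
            }
        )


def detect_reduced_window(
    rates: np.ndarray, reduction_fraction: float = 0.20
) -> tuple[tuple[int, int] | None, float]:
    """Largest contiguous window of clearly reduced displacement.

    The baseline is the median rate of frames that are not obviously
    reduced.  The window is the contiguous stretch with the largest total
    evidence of reduction, i.e. the maximum-sum subarray of
    (1 - reduction_fraction / 2) x baseline - rate: frames well below the
    half-reduction threshold pull the window in, frames above it push it
    out, and single borderline frames cannot split an otherwise clear
    window.  Returns ``((start, end), baseline)`` or ``(None, baseline)``.
    """
    rates = np.asarray(rates, dtype=float)
    valid = np.isfinite(rates)
    if valid.sum() < 3:
        return None, float("nan")
    # 3-frame moving median: robust to single-frame measurement noise while
    # shifting window edges by at most one frame
    sm = rates.copy()
    for i in np.nonzero(valid)[0]:
        lo, hi = max(i - 1, 0), min(i + 2, len(rates))
        vals = rates[lo:hi]
        sm[i] = float(np.median(vals[np.isfinite(vals)]))
    rates = sm
    rough = float(np.median(rates[valid]))
    thresh0 = (1.0 - reduction_fraction / 2.0) * rough
    baseline_frames = valid & (rates >= thresh0)
    baseline = float(np.median(rates[baseline_frames])) if baseline_frames.any() else rough
    if baseline <= 0:
        return None, baseline
    threshold = (1.0 - reduction_fraction / 2.0) * baseline
    gains = np.where(valid, threshold - rates, -np.inf)
    # maximum-sum contiguous subarray (Kadane)
    best_sum, best = 0.0, None
    cur_sum, cur_start = 0.0, 0
    for i, g in enumerate(gains.tolist()):
        if cur_sum <= 0 or not np.isfinite(cur_sum):
            cur_sum, cur_start = g, i
        else:
            cur_sum += g
        if np.isfinite(cur_sum) and cur_sum > best_sum:
            best_sum, best = cur_sum, (cur_start, i)
    return best, baseline


def displacement_timeseries(
    segs: list[SegmentationResult],
    dt_min: float,
    pixel_size_um: float = 1.0,
    aggregation: str = "sum",
    metric: str = "nn_mean",
    reduction_fraction: float = 0.20,
) -> BorderDisplacementSeries:
    """Sliding-window displacement rate over a segmented time-lapse, with
    detection of a transiently reduced ("intermediate state") window."""
    n = len(segs)
    if n < 3:
        raise DynamicsError("insufficient frames: need at least 3")
    d_mean = np.full(n, np.nan)
    rate = np.full(n, np.nan)
    for t in range(1, n - 1):
        entry = border_displacement(
            segs[t - 1], segs[t], segs[t + 1], dt_min, pixel_size_um,
            aggregation, metric,
        )
        d_mean[t] = entry["d_mean_um"]
        rate[t] = entry["rate_um_per_min"]
    window, baseline = detect_reduced_window(rate, reduction_fraction)
    reduction = float("nan")
    if window is not None and baseline > 0:
        w_rates = rate[window[0]: window[1] + 1]
        reduction = 1.0 - float(np.nanmean(w_rates)) / baseline
    return BorderDisplacementSeries(
        frame_times_min=np.arange(n) * dt_min,
        d_mean_um=d_mean,
        displacement_rate_um_per_min=rate,
        dt_min=dt_min,
        reduced_window=window,
        baseline_rate_um_per_min=baseline,
        window_reduction=reduction,
    )


# ---------------------------------------------------------------------------
# migration tracks

@dataclass
class MigrationTrack:
    cell_id: int
    positions_um: np.ndarray  # (n, 2) as (x, y)
    times_min: np.ndarray
    velocity_um_per_min: float
    accumulated_distance_um: float
    euclidean_distance_um: float


def migration_metrics(
    positions_um: np.ndarray,
    dt_min: float | None = None,
    times_min: np.ndarray | None = None,
    cell_id: int = 0,
) -> MigrationTrack:
    """Velocity, accumulated path length and net (Euclidean) displacement
    of one centroid track."""
    pos = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    if len(pos) < 2:
        raise DynamicsError("degenerate track: need at least 2 positions")
    if times_min is None:
        if dt_min is None or dt_min <= 0:
            raise DynamicsError("invalid calibration: dt must be > 0")
        times_min = np.arange(len(pos)) * dt_min
    times_min = np.asarray(times_min, dtype=float)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    accumulated = float(steps.sum())
    euclidean = float(np.linalg.norm(pos[-1] - pos[0]))
    elapsed = float(times_min[-1] - times_min[0])
    if elapsed <= 0:
        raise DynamicsError("track times must be increasing")
    return MigrationTrack(
        cell_id=cell_id,
        positions_um=pos,
        times_min=times_min,
        velocity_um_per_min=accumulated / elapsed,
        accumulated_distance_um=accumulated,
        euclidean_distance_um=euclidean,
    )


def migration_table(
    tracks: pd.DataFrame,
    dt_min: float,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Per-track metrics from a long-format table.

    Expects columns ``track_id, frame, x_um, y_um`` (or ``x_px, y_px`` with
    ``pixel_size_um`` for calibration).
    """
    df = tracks.copy()
    if "x_um" not in df.columns:
        if pixel_size_um is None:
            raise DynamicsError("pixel tracks require pixel_size_um")
        df["x_um"] = df["x_px"] * pixel_size_um
        df["y_um"] = df["y_px"] * pixel_size_um
    rows = []
    for tid, grp in df.sort_values("frame").groupby("track_id"):
        m = migration_metrics(
            grp[["x_um", "y_um"]].to_numpy(), dt_min=dt_min, cell_id=int(tid)
        )
        rows.append(
            {
                "track_id": int(tid),
                "n_points": len(grp),
                "velocity_um_per_min": m.velocity_um_per_min,
                "accumulated_distance_um": m.accumulated_distance_um,
                "euclidean_distance_um": m.euclidean_distance_um,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trans-endothelial resistance

@dataclass
class TERSeries:
    """TER time series; ``normalized`` is TER(t) / TER(t0)."""

    times_s: np.ndarray
    ter_ohm: np.ndarray
    t0_index: int = 0
    normalized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.ter_ohm = np.asarray(self.ter_ohm, dtype=float)
        if self.normalized is None:
            baseline = self.ter_ohm[self.t0_index]
            if baseline <= 0:
                raise DynamicsError("invalid baseline: TER(t0) must be > 0")
            self.normalized = self.ter_ohm / baseline

    @property
    def min_normalized(self) -> float:
        return float(np.min(self.normalized))

    @property
    def time_of_min_s(self) -> float:
        return float(self.times_s[int(np.argmin(self.normalized))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times_s, "ter_ohm": self.ter_ohm,
             "normalized": self.normalized}
        )


def normalize_ter(
    times_s: np.ndarray, ter_ohm: np.ndarray, t0_index: int = 0
) -> TERSeries:
    """Normalise a TER recording to its value at the treatment time t0."""
    ter_ohm = np.asarray(ter_ohm, dtype=float)
    if not (0 <= t0_index < len(ter_ohm)):
        raise DynamicsError("t0_index out of range")
    if ter_ohm[t0_index] <= 0:
        raise DynamicsError("invalid baseline: TER(t0) must be > 0")
    return TERSeries(times_s=times_s, ter_ohm=ter_ohm, t0_index=t0_index)
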