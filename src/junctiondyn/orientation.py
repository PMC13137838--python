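"""Structure-tensor orientation analysis ("apparent coherency").

The apparent coherency of a field of cells quantifies how uniformly the
cells are shaped and oriented: 1 means strong alignment along one dominant
direction, 0 means isotropy.  It is computed from the image structure
tensor — Gaussian-derivative gradients, outer products, Gaussian window
smoothing — aggregated over the image by summing the per-pixel tensors
(energy weighting) and taking (l1 - l2) / (l1 + l2) of the summed tensor's
eigenvalues.  The dominant direction is the orientation of the summed
tensor's minor eigenvector (along the texture), in degrees from the +x
axis, mapped to [-90, 90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import ImageSeries, wrap_angle_deg


class OrientationError(ValueError):
    pass


@dataclass
class OrientationAnalysis:
    gradient_sigma_px: float
    window_sigma_px: float
    orientation_deg: np.ndarray  # per-pixel local orientation (along texture)
    energy: np.ndarray  # per-pixel tensor trace
    coherency: float
    dominant_direction_deg: float  # NaN when coherency == 0


def structure_tensor(
    frame: np.ndarray,
    gradient_sigma_px: float = 1.0,
    window_sigma_px: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Jxx, Jxy, Jyy) fields with reflective boundary handling."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 16:
        raise OrientationError("frame must be 2D and at least 16x16")
    if window_sigma_px <= 0:
        raise OrientationError("invalid window: window_sigma_px must be > 0")
    if gradient_sigma_px <= 0:
        raise OrientationError("invalid gradient sigma")
    gx = ndi.gaussian_filter(frame, gradient_sigma_px, order=(0, 1), mode="reflect")
    gy = ndi.gaussian_filter(frame, gradient_sigma_px, order=(1, 0), mode="reflect")
    smooth = lambda a: ndi.gaussian_filter(a, window_sigma_px, mode="reflect")
    return smooth(gx * gx), smooth(gx * gy), smooth(gy * gy)


def _aggregate(jxx, jxy, jyy, aggregation: str) -> tuple[float, float]:
    """(coherency, dominant_direction_deg) from summed tensor fields."""
    sxx, sxy, syy = float(jxx.sum()), float(jxy.sum()), float(jyy.sum())
    trace = sxx + syy
    if trace <= 0 or not np.isfinite(trace):
        return 0.0, float("nan")
    if aggregation == "tensor_sum":
        coher = float(np.hypot(sxx - syy, 2 * sxy) / trace)
    elif aggregation == "mean_coherency":
        tr = jxx + jyy
        num = np.hypot(jxx - jyy, 2 * jxy)
        ok = tr > 1e-12 * tr.max() if tr.max() > 0 else np.zeros_like(tr, bool)
        coher = float(num[ok].mean() / tr[ok].mean()) if ok.any() else 0.0
    else:
        raise OrientationError(f"unknown aggregation: {aggregation}")
    if coher == 0.0:
        return 0.0, float("nan")
    # major (gradient) orientation of the summed tensor; texture runs 90 deg off
    theta_grad = 0.5 * np.degrees(np.arctan2(2 * sxy, sxx - syy))
    return coher, float(wrap_angle_deg(theta_grad + 90.0))


def apparent_coherency(
    frame: np.ndarray,
    gradient_sigma_px: float = 1.0,
    window_sigma_px: float = 4.0,
    aggregation: str = "tensor_sum",
) -> OrientationAnalysis:
    """Image-level apparent coherency and dominant direction.

    A margin of 3 x window_sigma is excluded from aggregation so boundary
    padding never dominates the tensor sum.  A constant frame has zero
    tensor everywhere and returns coherency 0 by convention.
    """
    frame = np.asarray(frame, dtype=float)
    jxx, jxy, jyy = structure_tensor(frame, gradient_sigma_px, window_sigma_px)
    m = int(round(3 * window_sigma_px))
    if 2 * m >= min(frame.shape) - 4:
        m = max((min(frame.shape) - 4) // 4, 0)
    sl = (slice(m, frame.shape[0] - m), slice(m, frame.shape[1] - m))
    coher, direction = _aggregate(jxx[sl], jxy[sl], jyy[sl], aggregation)

    theta_grad = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    return OrientationAnalysis(
        gradient_sigma_px=gradient_sigma_px,
        window_sigma_px=window_sigma_px,
        orientation_deg=wrap_angle_deg(theta_grad + 90.0),
        energy=jxx + jyy,
        coherency=coher,
        dominant_direction_deg=direction,
    )


def coherency_timecourse(
    series: ImageSeries,
    channel: str | int = 0,
    gradient_sigma_px: float = 1.0,
    window_sigma_px: float = 4.0,
    aggregation: str = "tensor_sum",
) -> pd.DataFrame:
    """Per-frame coherency time course of an image series."""
    rows = []
    stack = series.channel(channel)
    for t in range(series.n_frames):
        a = apparent_coherency(
            stack[t], gradient_sigma_px, window_sigma_px, aggregation
        )
        rows.append(
            {
                "frame": t,
                "time": t * series.frame_interval,
                "coherency": a.coherency,
                "dominant_direction_deg": a.dominant_direction_deg,
                "energy": float(a.energy.mean()),
            }
        )
    return pd.DataFrame(rows)
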