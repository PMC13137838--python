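"""Laser-ablation recoil analysis.

After a junctional actin bundle is cut, the severed edge recoils away from
the cut with displacement L(t) = D (1 - exp(-t / tau)) — the Kelvin-Voigt
spring-dashpot response.  D is the force/elasticity ratio (the recoil
plateau) and tau the relaxation time; higher pre-cut tension shows up as a
smaller tau.  This module extracts a kymograph along a scan line, tracks
the recoiling edge at sub-pixel resolution, and fits the model.

The fit uses variable projection: for fixed tau the amplitude D enters the
model linearly and is solved in closed form, leaving a one-dimensional
minimisation over log tau (coarse log-grid scan followed by bounded scalar
refinement).  This removes any dependence on a starting guess for D and is
exact on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar

from .core import ImageSeries, derive_rng


class RecoilError(ValueError):
    pass


class EdgeLostError(RecoilError):
    """Raised when the recoiling edge leaves the scan line."""

    def __init__(self, frame: int, measurement: "RecoilMeasurement | None" = None):
        super().__init__(f"edge lost at frame {frame}")
        self.frame = frame
        self.measurement = measurement


@dataclass
class RecoilMeasurement:
    """Displacement of the tracked edge relative to its pre-cut position;
    t = 0 at the cut."""

    t_s: np.ndarray
    L_um: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.L_um = np.asarray(self.L_um, dtype=float)
        if self.t_s.shape != self.L_um.shape:
            raise RecoilError("t_s and L_um must have the same length")
        if len(self.t_s) and (np.any(np.diff(self.t_s) <= 0) or self.t_s[0] < 0):
            raise RecoilError("times must be non-negative and strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "L_um": self.L_um})


@dataclass
class KelvinVoigtFit:
    D_um: float
    tau_s: float
    sse: float
    r_squared: float
    converged: bool
    n_points: int
    ci_D: tuple[float, float] | None = None
    ci_tau: tuple[float, float] | None = None

    def model(self, t_s: np.ndarray) -> np.ndarray:
        return self.D_um * (1.0 - np.exp(-np.asarray(t_s, float) / self.tau_s))


# ---------------------------------------------------------------------------
# kymograph

def extract_kymograph(
    series: ImageSeries,
    line: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 1,
    channel: str | int = 0,
) -> np.ndarray:
    """Kymograph (space x time) sampled along a scan line.

    ``line`` is ((row0, col0), (row1, col1)) in pixels; intensity is sampled
    bilinearly at 1-px steps along the line and averaged over ``width_px``
    perpendicular offsets.  Columns are frames.
    """
    (r0, c0), (r1, c1) = line
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length < 1:
        raise RecoilError("invalid line: zero length")
    stack = series.channel(channel)
    if stack.shape[0] < 2:
        raise RecoilError("need at least 2 frames")
    n = int(np.floor(length)) + 1
    s = np.linspace(0.0, length, n)
    ur, uc = (r1 - r0) / length, (c1 - c0) / length
    pr, pc = -uc, ur  # perpendicular unit vector
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    kymo = np.zeros((n, stack.shape[0]))
    for t in range(stack.shape[0]):
        acc = np.zeros(n)
        for off in offsets:
            rows = r0 + s * ur + off * pr
            cols = c0 + s * uc + off * pc
            acc += ndi.map_coordinates(
                stack[t], np.vstack([rows, cols]), order=1, mode="nearest"
            )
        kymo[:, t] = acc / len(offsets)
    return kymo


def track_recoil(
    kymo: np.ndarray,
    cut_frame: int,
    pixel_size_um: float,
    dt_s: float = 0.2,
    cut_pos_px: float | None = None,
    threshold_frac: float = 0.5,
) -> RecoilMeasurement:
    """Track the recoiling edge in a kymograph.

    For each post-cut frame the edge is the first position, scanning from
    the cut point outward (increasing line coordinate), where intensity
    rises back above ``threshold_frac`` of the local pre-cut plateau;
    the crossing is localised at sub-pixel precision by linear
    interpolation.  The default frame interval is 0.2 s.
    """
    kymo = np.asarray(kymo, dtype=float)
    n_pos, n_frames = kymo.shape
    if not (0 < cut_frame < n_frames):
        raise RecoilError("cut_frame must lie within the series")
    plateau = kymo[:, :cut_frame].mean(axis=1)
    if cut_pos_px is None:
        # darkest point right after the cut marks the ablation site
        drop = plateau - kymo[:, cut_frame]
        cut_pos_px = float(np.argmax(drop))
    start = int(np.floor(cut_pos_px))

    edges = []
    for t in range(cut_frame, n_frames):
        col = kymo[:, t]
        thresh = threshold_frac * plateau
        idx = None
        for s in range(start, n_pos):
            if col[s] >= thresh[s]:
                idx = s
                break
        if idx is None:
            m = RecoilMeasurement(
                np.arange(len(edges)) * dt_s,
                (np.array(edges) - edges[0]) * pixel_size_um if edges else np.array([]),
            )
            raise EdgeLostError(t, m)
        if idx == start:
            edges.append(float(idx))
            continue
        # linear interpolation between idx-1 (below) and idx (above)
        lo, hi = col[idx - 1] - thresh[idx - 1], col[idx] - thresh[idx]
        frac = 0.0 if hi == lo else -lo / (hi - lo)
        edges.append(idx - 1 + float(np.clip(frac, 0.0, 1.0)))
    edges_arr = np.array(edges)
    return RecoilMeasurement(
        t_s=np.arange(len(edges_arr)) * dt_s,
        L_um=(edges_arr - edges_arr[0]) * pixel_size_um,
    )


# ---------------------------------------------------------------------------
# Kelvin-Voigt fit

def _projected_sse(tau: float, t: np.ndarray, L: np.ndarray) -> tuple[float, float]:
    """(sse, D) at fixed tau with D solved by linear least squares."""
    f = 1.0 - np.exp(-t / tau)
    denom = float(f @ f)
    if denom <= 0:
        return float(L @ L), 0.0
    D = float(f @ L) / denom
    resid = L - D * f
    return float(resid @ resid), D


def fit_kelvin_voigt(
    m: RecoilMeasurement,
    bootstrap_n: int = 0,
    seed: int = 0,
    ci_level: float = 0.95,
) -> KelvinVoigtFit:
    """Least-squares Kelvin-Voigt fit L(t) = D (1 - exp(-t / tau)).

    Optional residual-resampling bootstrap (seeded) yields percentile
    confidence intervals for D and tau.
    """
    t, L = m.t_s, m.L_um
    if len(t) < 5:
        raise RecoilError("insufficient data: need at least 5 samples")
    pos = t[t > 0]
    if len(pos) < 2 or np.max(L) <= 0:
        raise RecoilError("fit failed: no positive displacement to fit")

    def solve(tvec: np.ndarray, Lvec: np.ndarray) -> tuple[float, float, float]:
        lo = np.log(max(pos.min() / 10.0, 1e-9))
        hi = np.log(tvec.max() * 50.0)
        grid = np.linspace(lo, hi, 80)
        sses = [_projected_sse(np.exp(g), tvec, Lvec)[0] for g in grid]
        k = int(np.argmin(sses))
        a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda g: _projected_sse(np.exp(g), tvec, Lvec)[0],
            bounds=(a, b), method="bounded",
            options={"xatol": 1e-12},
        )
        tau = float(np.exp(res.x))
        sse, D = _projected_sse(tau, tvec, Lvec)
        return D, tau, sse

    D, tau, sse = solve(t, L)
    if D <= 0 or tau <= 0 or not np.isfinite(sse):
        raise RecoilError("fit failed: non-positive parameter estimate")
    ss_tot = float(((L - L.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
    fit = KelvinVoigtFit(
        D_um=D, tau_s=tau, sse=sse, r_squared=r2,
        converged=bool(t.max() >= tau), n_points=len(t),
    )

    if bootstrap_n > 0:
        rng = derive_rng(seed, "kv_bootstrap")
        fitted = fit.model(t)
        resid = L - fitted
        ds, taus = [], []
        for _ in range(bootstrap_n):
            Lb = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                Db, taub, _ = solve(t, Lb)
            except Exception:
                continue
            ds.append(Db)
            taus.append(taub)
        if len(ds) >= max(10, bootstrap_n // 2):
            q = [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100]
            fit.ci_D = tuple(np.percentile(ds, q))
            fit.ci_tau = tuple(np.percentile(taus, q))
    return fit
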