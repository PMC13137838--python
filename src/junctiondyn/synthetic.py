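"""Synthetic monolayer, time-lapse, texture, recoil and TER generators.

Every analysis stage in this package is validated against data with exact
ground truth, generated here.  The monolayer generator emulates what the
junction channel of a confluent endothelial culture looks like: convex-ish
cells produced by an anisotropic Voronoi tessellation of jitter-perturbed
grid points, a bright junctional band with a Gaussian cross-profile along
every shared border, and Poisson-plus-Gaussian camera noise.  Motion
programs move the tessellation seed points between frames, including a
transient "intermediate state" in which the programmed border step length
drops by a configurable fraction (default 20%, the effect size reported
for shear-stress onset).

All generators are deterministic: each derives one private PRNG stream
from ``(seed, operation name)``, so calling one generator never perturbs
another's output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import GroundTruth, ImageSeries, borders_from_labels, derive_rng
from .dynamics import TERSeries
from .morphometrics import mask_shape
from .recoil import RecoilMeasurement


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specs

#: density presets (cells/cm^2) spanning sub-confluent to highly confluent
DENSITY_PRESETS = {
    "subconfluent": 7.5e4,
    "confluent": 9.5e4,
    "dense": 11.5e4,
}


@dataclass(frozen=True)
class SyntheticMonolayerSpec:
    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.53
    n_cells: int = 20
    density_cells_per_cm2: float | None = None
    mean_aspect_ratio: float = 1.0
    orientation_mean_deg: float = 0.0
    orientation_concentration: float = 0.0
    junction_amplitude: float = 100.0
    junction_sigma_px: float = 2.0
    background_level: float = 10.0
    poisson_gain: float = 0.0
    gaussian_read_sigma: float = 0.0
    seed: int = 0
    #: when True, tessellation seeds extend one cell ring beyond the field,
    #: so edge cells are genuinely truncated by the crop (as in microscopy);
    #: the label count then exceeds n_cells by the visible ring cells.
    #: When False (default) exactly n_cells cells tile the field.
    crop_from_larger_field: bool = False

    @property
    def field_area_cm2(self) -> float:
        h, w = self.field_size_px
        return (h * self.pixel_size_um * 1e-4) * (w * self.pixel_size_um * 1e-4)

    @property
    def density(self) -> float:
        """Cell density implied by n_cells and the field area (cells/cm^2)."""
        return self.n_cells / self.field_area_cm2

    def validate(self) -> None:
        h, w = self.field_size_px
        if self.n_cells < 2:
            raise SyntheticError("degenerate tessellation: n_cells must be >= 2")
        if min(h, w) < 16 or self.pixel_size_um <= 0:
            raise SyntheticError("invalid field geometry")
        if self.mean_aspect_ratio < 1:
            raise SyntheticError("mean_aspect_ratio must be >= 1")
        if self.orientation_concentration < 0:
            raise SyntheticError("orientation_concentration must be >= 0")
        if self.junction_sigma_px <= 0 or self.junction_amplitude <= 0:
            raise SyntheticError("junction band must have positive amplitude/sigma")
        if h * w / self.n_cells < 16:
            raise SyntheticError("density infeasible: fewer than 16 px per cell")
        if self.density_cells_per_cm2 is not None:
            expected = self.density_cells_per_cm2 * self.field_area_cm2
            if abs(self.n_cells - expected) > 1.0:
                raise SyntheticError(
                    "density infeasible: n_cells inconsistent with "
                    f"density ({self.n_cells} vs {expected:.1f})"
                )

    @classmethod
    def from_density(
        cls, density_cells_per_cm2: float, **kwargs
    ) -> "SyntheticMonolayerSpec":
        """Spec whose n_cells matches a target density for the field."""
        if isinstance(density_cells_per_cm2, str):
            density_cells_per_cm2 = DENSITY_PRESETS[density_cells_per_cm2]
        probe = cls(n_cells=2, **kwargs)
        n = max(2, int(round(density_cells_per_cm2 * probe.field_area_cm2)))
        return cls(
            n_cells=n, density_cells_per_cm2=density_cells_per_cm2, **kwargs
        )


@dataclass(frozen=True)
class MotionProgram:
    kind: str = "static"  # static | rigid_translation | border_jitter | intermediate_state
    speed_um_per_min: float = 0.0
    direction_deg: float = 0.0
    jitter_amplitude_um: float = 0.0
    intermediate_onset_frame: int = 0
    intermediate_release_frame: int = 0
    intermediate_reduction_fraction: float = 0.20

    def validate(self, n_frames: int) -> None:
        kinds = {"static", "rigid_translation", "border_jitter", "intermediate_state"}
        if self.kind not in kinds:
            raise SyntheticError(f"unknown motion program: {self.kind}")
        if self.speed_um_per_min < 0 or self.jitter_amplitude_um < 0:
            raise SyntheticError("speeds/amplitudes must be >= 0")
        if not (0 <= self.intermediate_reduction_fraction <= 1):
            raise SyntheticError("reduction fraction must be in [0, 1]")
        if self.kind == "intermediate_state":
            if not (
                0 < self.intermediate_onset_frame
                <= self.intermediate_release_frame
                < n_frames
            ):
                raise SyntheticError("intermediate window must lie within the movie")


@dataclass(frozen=True)
class RecoilSpec:
    D_um: float = 2.0
    tau_s: float = 15.0
    dt_s: float = 0.2
    duration_s: float = 60.0
    noise_sigma_um: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.D_um, self.tau_s, self.dt_s, self.duration_s) <= 0:
            raise SyntheticError("D, tau, dt and duration must be positive")
        if self.duration_s < 3 * self.dt_s:
            raise SyntheticError("too few samples: duration < 3 dt")
        if self.noise_sigma_um < 0:
            raise SyntheticError("noise sigma must be >= 0")


# ---------------------------------------------------------------------------
# tessellation and rendering

def _seed_points(spec: SyntheticMonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Jitter-perturbed grid of exactly n_cells points, (row, col)."""
    h, w = spec.field_size_px
    n = spec.n_cells
    ny = max(1, int(round(np.sqrt(n * h / w))))
    nx = max(1, int(np.ceil(n / ny)))
    sy, sx = h / ny, w / nx
    rows, cols = np.meshgrid(
        (np.arange(ny) + 0.5) * sy, (np.arange(nx) + 0.5) * sx, indexing="ij"
    )
    pts = np.column_stack([rows.ravel(), cols.ravel()])
    jitter = rng.uniform(-0.35, 0.35, size=pts.shape) * np.array([sy, sx])
    pts = pts + jitter
    if len(pts) > n:
        keep = rng.choice(len(pts), size=n, replace=False)
        pts = pts[np.sort(keep)]
    elif len(pts) < n:
        extra = rng.uniform(0, 1, size=(n - len(pts), 2)) * np.array([h, w])
        pts = np.vstack([pts, extra])
    if spec.crop_from_larger_field:
        ring = []
        for iy in range(-1, ny + 1):
            for ix in range(-1, nx + 1):
                if 0 <= iy < ny and 0 <= ix < nx:
                    continue
                ring.append([(iy + 0.5) * sy, (ix + 0.5) * sx])
        ring_arr = np.asarray(ring) + rng.uniform(
            -0.35, 0.35, size=(len(ring), 2)
        ) * np.array([sy, sx])
        pts = np.vstack([pts, ring_arr])
    return pts


def _cell_orientations(
    spec: SyntheticMonolayerSpec, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Per-cell major-axis angles (deg); von Mises on the doubled angle so
    that concentration 0 is exactly isotropic."""
    if spec.orientation_concentration < 1e-9:
        return rng.uniform(-90.0, 90.0, size=n)
    phi = rng.vonmises(0.0, spec.orientation_concentration, size=n)
    return spec.orientation_mean_deg + np.degrees(phi) / 2.0


def _assign_labels(
    shape: tuple[int, int],
    points: np.ndarray,
    aspect: np.ndarray,
    theta_deg: np.ndarray,
) -> np.ndarray:
    """Anisotropic nearest-seed tessellation.

    Distances to seed i are measured in a frame rotated to the cell's major
    axis and scaled by (1/sqrt(a), sqrt(a)) — area-preserving, so cells
    elongate by a factor ``a`` along ``theta`` without changing size.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    best_d = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    th = np.radians(theta_deg)
    for i, (pr, pc) in enumerate(points):
        dy = rows - pr
        dx = cols - pc
        c, s = np.cos(th[i]), np.sin(th[i])
        a = np.sqrt(aspect[i])
        u = (dx * c + dy * s) / a   # along major axis: distances shrink
        v = (-dx * s + dy * c) * a
        d = u * u + v * v
        closer = d < best_d
        best_d[closer] = d[closer]
        labels[closer] = i + 1
    # guarantee consecutive ids (a seed could in principle capture no pixel)
    ids = np.unique(labels)
    if len(ids) != len(points):
        remap = np.zeros(labels.max() + 1, dtype=np.int32)
        remap[ids] = np.arange(1, len(ids) + 1)
        labels = remap[labels]
    return labels


def render_junction_image(
    border: np.ndarray,
    amplitude: float,
    sigma_px: float,
    background: float = 0.0,
) -> np.ndarray:
    """Junction channel: Gaussian cross-profile of the border band.

    Intensity at distance d from the border line is
    background + amplitude * exp(-d^2 / (2 sigma^2)); the integral across
    the band per unit border length is amplitude * sigma * sqrt(2 pi).
    """
    if not border.any():
        return np.full(border.shape, float(background))
    dist = ndi.distance_transform_edt(~border)
    return background + amplitude * np.exp(-(dist**2) / (2.0 * sigma_px**2))


def apply_camera_noise(
    image: np.ndarray,
    poisson_gain: float,
    read_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scaled-Poisson shot noise followed by additive Gaussian read noise
    (standard fluorescence camera model); either term can be disabled."""
    out = np.asarray(image, dtype=float)
    if poisson_gain > 0:
        out = poisson_gain * rng.poisson(np.maximum(out, 0) / poisson_gain)
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    return np.maximum(out, 0.0)


def _morphology_table(
    labels: np.ndarray, pixel_size_um: float
) -> pd.DataFrame:
    h, w = labels.shape
    edge_ids = set(
        np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        ).tolist()
    )
    rows = []
    for cid in np.unique(labels):
        area, perim, cen, ar, theta = mask_shape(labels == cid, pixel_size_um)
        rows.append(
            {
                "cell_id": int(cid),
                "area_um2": area,
                "perimeter_um": perim,
                "centroid_x_um": cen[0],
                "centroid_y_um": cen[1],
                "aspect_ratio": ar,
                "orientation_deg": theta,
                "is_edge": cid in edge_ids,
            }
        )
    return pd.DataFrame(rows)


def _track_table(
    label_stack: np.ndarray, pixel_size_um: float, frame_interval_min: float
) -> pd.DataFrame:
    rows = []
    for t, labels in enumerate(label_stack):
        ids = np.unique(labels)
        coms = ndi.center_of_mass(np.ones_like(labels), labels, ids)
        for cid, (r, c) in zip(ids.tolist(), coms):
            rows.append(
                {
                    "track_id": int(cid),
                    "frame": t,
                    "time_min": t * frame_interval_min,
                    "x_um": c * pixel_size_um,
                    "y_um": r * pixel_size_um,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generators

def generate_monolayer(
    spec: SyntheticMonolayerSpec,
) -> tuple[ImageSeries, GroundTruth]:
    """One rendered junction-channel frame plus exact ground truth."""
    spec.validate()
    rng = derive_rng(spec.seed, "generate_monolayer")
    pts = _seed_points(spec, rng)
    theta = _cell_orientations(spec, rng, len(pts))
    aspect = np.full(len(pts), float(spec.mean_aspect_ratio))
    labels = _assign_labels(spec.field_size_px, pts, aspect, theta)
    border = borders_from_labels(labels)
    clean = render_junction_image(
        border, spec.junction_amplitude, spec.junction_sigma_px,
        spec.background_level,
    )
    noisy = apply_camera_noise(
        clean, spec.poisson_gain, spec.gaussian_read_sigma, rng
    )
    series = ImageSeries(
        data=noisy[None, None],
        channel_names=("junction",),
        pixel_size_um=spec.pixel_size_um,
        frame_interval=1.0,
        frame_interval_unit="min",
    )
    gt = GroundTruth(
        label_stack=labels[None],
        border_stack=border[None],
        per_cell_morphology=_morphology_table(labels, spec.pixel_size_um),
        per_frame_border_displacement_um=np.zeros(1),
        track_table=_track_table(labels[None], spec.pixel_size_um, 1.0),
    )
    return series, gt


def _program_steps(
    program: MotionProgram,
    n_frames: int,
    n_cells: int,
    frame_interval_min: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame seed-point steps (um) and the programmed per-frame border
    displacement.  steps[t] moves the points from frame t-1 to frame t;
    steps[0] is zero."""
    steps = np.zeros((n_frames, n_cells, 2))  # (d_row, d_col) in um
    truth = np.zeros(n_frames)
    if program.kind == "static":
        return steps, truth
    if program.kind == "rigid_translation":
        step_len = program.speed_um_per_min * frame_interval_min
        ang = np.radians(program.direction_deg)
        vec = np.array([np.sin(ang), np.cos(ang)]) * step_len  # (row, col)
        steps[1:] = vec
        truth[1:] = step_len
        return steps, truth
    # jitter-type programs: every cell takes a step of programmed length in
    # a random direction, so the true per-frame displacement is exact
    for t in range(1, n_frames):
        amp = program.jitter_amplitude_um
        if (
            program.kind == "intermediate_state"
            and program.intermediate_onset_frame
            <= t
            <= program.intermediate_release_frame
        ):
            amp *= 1.0 - program.intermediate_reduction_fraction
        ang = rng.uniform(0, 2 * np.pi, size=n_cells)
        steps[t, :, 0] = amp * np.sin(ang)
        steps[t, :, 1] = amp * np.cos(ang)
        truth[t] = amp
    return steps, truth


def generate_timelapse(
    spec: SyntheticMonolayerSpec,
    program: MotionProgram,
    n_frames: int,
    frame_interval_min: float = 1.0,
) -> tuple[ImageSeries, GroundTruth]:
    """Seeded junction-channel time-lapse with programmed border motion.

    Cell identity is preserved across frames (seed points move, labels keep
    their index), and the programmed per-frame border displacement is
    recorded exactly in the ground truth.
    """
    spec.validate()
    if n_frames < 3:
        raise SyntheticError("insufficient frames: need n_frames >= 3")
    if frame_interval_min <= 0:
        raise SyntheticError("invalid calibration: frame_interval must be > 0")
    program.validate(n_frames)
    rng = derive_rng(spec.seed, "generate_timelapse")
    pts0 = _seed_points(spec, rng)
    theta = _cell_orientations(spec, rng, len(pts0))
    aspect = np.full(len(pts0), float(spec.mean_aspect_ratio))
    steps_um, truth = _program_steps(
        program, n_frames, len(pts0), frame_interval_min, rng
    )
    steps_px = steps_um / spec.pixel_size_um

    h, w = spec.field_size_px
    frames = np.zeros((n_frames, h, w))
    label_stack = np.zeros((n_frames, h, w), dtype=np.int32)
    border_stack = np.zeros((n_frames, h, w), dtype=bool)
    pts = pts0.copy()
    for t in range(n_frames):
        pts = pts + steps_px[t]
        labels = _assign_labels((h, w), pts, aspect, theta)
        border = borders_from_labels(labels)
        clean = render_junction_image(
            border, spec.junction_amplitude, spec.junction_sigma_px,
            spec.background_level,
        )
        frames[t] = apply_camera_noise(
            clean, spec.poisson_gain, spec.gaussian_read_sigma, rng
        )
        label_stack[t] = labels
        border_stack[t] = border

    series = ImageSeries(
        data=frames[None],
        channel_names=("junction",),
        pixel_size_um=spec.pixel_size_um,
        frame_interval=frame_interval_min,
        frame_interval_unit="min",
    )
    gt = GroundTruth(
        label_stack=label_stack,
        border_stack=border_stack,
        per_cell_morphology=_morphology_table(label_stack[0], spec.pixel_size_um),
        per_frame_border_displacement_um=truth,
        track_table=_track_table(
            label_stack, spec.pixel_size_um, frame_interval_min
        ),
    )
    return series, gt


def generate_oriented_texture(
    theta_deg: float,
    anisotropy: float,
    size_px: tuple[int, int] = (128, 128),
    seed: int = 0,
    amplitude: float = 1.0,
    wavelength_px: float = 8.0,
) -> ImageSeries:
    """Texture fixture for coherency analysis.

    ``anisotropy`` blends a pure grating whose stripes run along
    ``theta_deg`` (anisotropy 1) with isotropic band-filtered noise
    (anisotropy 0); ``amplitude`` 0 yields a constant image.
    """
    h, w = size_px
    if min(h, w) < 32:
        raise SyntheticError("texture must be at least 32x32")
    if not 0 <= anisotropy <= 1:
        raise SyntheticError("anisotropy must be in [0, 1]")
    rng = derive_rng(seed, "generate_oriented_texture")
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    # gradient direction is normal to the stripes
    normal = np.radians(theta_deg + 90.0)
    phase = 2 * np.pi * (cols * np.cos(normal) + rows * np.sin(normal)) / wavelength_px
    grating = np.sin(phase)
    noise = ndi.gaussian_filter(rng.standard_normal((h, w)), 2.0)
    std = noise.std()
    noise = noise / std * np.sqrt(0.5) if std > 0 else noise
    blend = anisotropy * grating + (1.0 - anisotropy) * noise
    image = np.maximum(amplitude * (3.0 + blend), 0.0)
    return ImageSeries(
        data=image[None, None],
        channel_names=("texture",),
        pixel_size_um=1.0,
        frame_interval=1.0,
        frame_interval_unit="min",
    )


def generate_recoil_curve(rs: RecoilSpec) -> RecoilMeasurement:
    """Sampled Kelvin-Voigt recoil curve L(t) = D (1 - exp(-t/tau)) with
    optional additive Gaussian noise."""
    rs.validate()
    rng = derive_rng(rs.seed, "generate_recoil_curve")
    t = np.arange(0.0, rs.duration_s + rs.dt_s / 2.0, rs.dt_s)
    L = rs.D_um * (1.0 - np.exp(-t / rs.tau_s))
    if rs.noise_sigma_um > 0:
        L = L + rng.normal(0.0, rs.noise_sigma_um, size=t.shape)
    return RecoilMeasurement(t_s=t, L_um=L)


def render_recoil_movie(
    rs: RecoilSpec,
    pixel_size_um: float = 0.1,
    field_px: tuple[int, int] = (96, 32),
    n_pre_frames: int = 5,
    plateau: float = 100.0,
    background: float = 5.0,
    edge_softness_px: float = 0.8,
) -> tuple[ImageSeries, dict]:
    """Synthetic ablation movie: a fluorescent region whose edge recoils
    along the image rows following the Kelvin-Voigt curve.

    Returns the movie and a dict with the scan ``line``, ``cut_frame`` and
    ``cut_row_px`` suitable for :func:`junctiondyn.recoil.extract_kymograph`
    and :func:`junctiondyn.recoil.track_recoil`.
    """
    rs.validate()
    h, w = field_px
    cut_row = h // 4
    t = np.arange(0.0, rs.duration_s + rs.dt_s / 2.0, rs.dt_s)
    L_px = rs.D_um * (1.0 - np.exp(-t / rs.tau_s)) / pixel_size_um
    if cut_row + L_px.max() > h - 4:
        raise SyntheticError("field too short for the requested recoil")
    rows = np.arange(h, dtype=float)[:, None] * np.ones((1, w))
    frames = []
    for _ in range(n_pre_frames):
        frames.append(np.full((h, w), plateau))
    for Lp in L_px:
        edge = cut_row + Lp
        profile = 1.0 / (1.0 + np.exp(-(rows - edge) / edge_softness_px))
        frames.append(background + (plateau - background) * profile)
    movie = np.stack(frames)
    series = ImageSeries(
        data=movie[None],
        channel_names=("actin",),
        pixel_size_um=pixel_size_um,
        frame_interval=rs.dt_s,
        frame_interval_unit="s",
    )
    meta = {
        "line": ((0.0, w / 2.0), (float(h - 1), w / 2.0)),
        "cut_frame": n_pre_frames,
        "cut_row_px": float(cut_row),
    }
    return series, meta


def generate_ter_series(
    baseline_ohm: float,
    effect: str = "flat",
    n_points: int = 100,
    seed: int = 0,
    dt_s: float = 12.0,
    noise_sigma_ohm: float = 0.0,
    dip_index: int | None = None,
    rise_fraction: float = 0.30,
    dip_depth: float = 0.35,
) -> TERSeries:
    """TER recording presets.

    ``shear_rise`` plateaus at (1 + rise_fraction) x baseline after
    normalisation (default +30%, the barrier strengthening seen when shear
    stress is combined with ROCK inhibition); ``transient_dip`` reaches its
    minimum at ``dip_index``; ``flat`` stays at baseline.  Sampling every
    12 s matches typical impedance instrumentation.
    """
    if baseline_ohm <= 0:
        raise SyntheticError("invalid baseline: must be > 0")
    if n_points < 2:
        raise SyntheticError("need at least 2 points")
    rng = derive_rng(seed, "generate_ter_series")
    i = np.arange(n_points, dtype=float)
    if effect == "flat":
        profile = np.ones(n_points)
    elif effect == "shear_rise":
        n_rise = max(1, int(round(0.4 * n_points)))
        profile = 1.0 + rise_fraction * np.minimum(i / n_rise, 1.0)
    elif effect == "transient_dip":
        k = n_points // 3 if dip_index is None else int(dip_index)
        if not 0 <= k < n_points:
            raise SyntheticError("dip_index out of range")
        width = max(n_points / 12.0, 2.0)
        profile = 1.0 - dip_depth * np.exp(-0.5 * ((i - k) / width) ** 2)
    else:
        raise SyntheticError(f"unknown TER effect: {effect}")
    ter = baseline_ohm * profile
    if noise_sigma_ohm > 0:
        noise = rng.normal(0.0, noise_sigma_ohm, size=n_points)
        noise[0] = 0.0  # keep the normalisation anchor exact
        ter = ter + noise
    return TERSeries(times_s=i * dt_s, ter_ohm=ter, t0_index=0)
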