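"""Shared containers and pixel-level primitives.

Conventions used throughout the package:

* images are ``(row, col)`` arrays, 0-based; stacks are ``(frame, row, col)``;
* geometry is computed in pixels and converted to micrometres only at
  reporting time via ``pixel_size_um``;
* angles are in degrees, measured from the +x (image column) axis towards
  +y (image row), reported in ``[-90, 90)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

SQRT2 = float(np.sqrt(2.0))


def derive_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent PRNG stream for ``(seed, stream)``.

    Each generator call uses its own stream keyed by the operation name so
    that adding randomness to one generator never perturbs another.
    """
    digest = hashlib.sha256(f"{int(seed)}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass(frozen=True)
class ImageSeries:
    """Calibrated 2D+t intensity data.

    ``data`` has shape ``(n_channels, n_frames, height, width)``;
    ``frame_interval`` is expressed in ``frame_interval_unit`` ("s" or "min").
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    frame_interval: float
    frame_interval_unit: str = "min"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 2:
            data = data[None, None]
        elif data.ndim == 3:
            data = data[None]
        if data.ndim != 4:
            raise ValueError("data must be 2D, 3D or 4D (C, T, H, W)")
        if not np.all(np.isfinite(data)):
            raise ValueError("intensities must be finite")
        if data.min() < 0:
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "data", data)
        names = tuple(self.channel_names) or tuple(
            f"c{i}" for i in range(data.shape[0])
        )
        if len(names) != data.shape[0]:
            raise ValueError("channel_names must match channel count")
        object.__setattr__(self, "channel_names", names)
        if self.pixel_size_um <= 0:
            raise ValueError("invalid calibration: pixel_size_um must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("invalid calibration: frame_interval must be > 0")
        if self.frame_interval_unit not in ("s", "min"):
            raise ValueError("frame_interval_unit must be 's' or 'min'")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def frame_interval_s(self) -> float:
        return self.frame_interval * (60.0 if self.frame_interval_unit == "min" else 1.0)

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0

    def channel(self, name: str | int = 0) -> np.ndarray:
        """Frame stack ``(T, H, W)`` for one channel."""
        if isinstance(name, str):
            name = self.channel_names.index(name)
        return self.data[name]

    def frame(self, t: int = 0, channel: str | int = 0) -> np.ndarray:
        return self.channel(channel)[t]

    def with_data(self, data: np.ndarray) -> "ImageSeries":
        return replace(self, data=data)


def borders_from_labels(labels: np.ndarray) -> np.ndarray:
    """Canonical 1-px inter-label boundary of a gap-free label image.

    A pixel is a border pixel when its label differs from the label of the
    pixel directly below or directly to the right (the boundary is carried
    by its upper/left side).  The same convention is used by the synthetic
    ground truth and by the segmentation output, so the two are directly
    comparable.
    """
    labels = np.asarray(labels)
    border = np.zeros(labels.shape, dtype=bool)
    border[:-1, :] |= labels[:-1, :] != labels[1:, :]
    border[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    return border


def adjacency_from_labels(labels: np.ndarray) -> set[tuple[int, int]]:
    """Unordered pairs of distinct labels that touch (4-connectivity),
    computed on a gap-free label image. Label 0 is ignored."""
    pairs: set[tuple[int, int]] = set()
    for a, b in (
        (labels[:-1, :], labels[1:, :]),
        (labels[:, :-1], labels[:, 1:]),
    ):
        diff = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def weighted_pixel_length(mask: np.ndarray) -> float:
    """Length of a thin pixel set: pixel count plus a ``sqrt(2) - 1``
    increment for every purely diagonal link.

    For a straight horizontal or vertical run of N pixels this is exactly N;
    for a diagonal staircase it approaches ``sqrt(2) * N``, so diagonal
    borders are not over-counted relative to their Euclidean length.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        return 0.0
    # diagonal neighbor pairs not bridged by a shared 4-neighbor
    dd = mask[:-1, :-1] & mask[1:, 1:] & ~(mask[:-1, 1:] | mask[1:, :-1])
    da = mask[:-1, 1:] & mask[1:, :-1] & ~(mask[:-1, :-1] | mask[1:, 1:])
    n_diag = int(dd.sum()) + int(da.sum())
    return n + (SQRT2 - 1.0) * n_diag


def wrap_angle_deg(theta: np.ndarray | float) -> np.ndarray | float:
    """Map an orientation (period 180 deg) into ``[-90, 90)``."""
    return (np.asarray(theta) + 90.0) % 180.0 - 90.0


@dataclass
class GroundTruth:
    """Exact truth emitted alongside every synthetic image.

    ``per_frame_border_displacement_um[t]`` is the programmed border motion
    between frame ``t-1`` and frame ``t`` (index 0 is 0 by definition).
    """

    label_stack: np.ndarray
    border_stack: np.ndarray
    per_cell_morphology: "object" = None  # pandas DataFrame
    per_frame_border_displacement_um: np.ndarray = field(
        default_factory=lambda: np.zeros(1)
    )
    track_table: "object" = None  # pandas DataFrame

    def __post_init__(self) -> None:
        self.label_stack = np.asarray(self.label_stack)
        if self.label_stack.ndim == 2:
            self.label_stack = self.label_stack[None]
        self.border_stack = np.asarray(self.border_stack, dtype=bool)
        if self.border_stack.ndim == 2:
            self.border_stack = self.border_stack[None]
        self.per_frame_border_displacement_um = np.asarray(
            self.per_frame_border_displacement_um, dtype=float
        )
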