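"""Per-cell shape and intensity statistics.

Shape descriptors follow the ellipse-of-inertia convention: the aspect
ratio is the major/minor axis ratio of the ellipse sharing the mask's
second central moments, and the orientation is the major-axis angle in
degrees from the +x (column) axis, in [-90, 90).  The junctional statistic
is the one used for junction-associated proteins: integrated intensity in a
band extending ``w`` pixels on each side of the segmentation line, divided
by the border length of that cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import perimeter_crofton

from .core import weighted_pixel_length, wrap_angle_deg
from .segmentation import SegmentationResult, band_mask


class MorphometryError(ValueError):
    pass


@dataclass
class CellMorphology:
    cell_id: int
    area_um2: float
    perimeter_um: float
    centroid_um: tuple[float, float]  # (x, y)
    aspect_ratio: float
    orientation_deg: float


@dataclass
class JunctionalProfile:
    cell_id: int  # 0 denotes the field-level profile
    channel: str
    band_halfwidth_px: int
    integrated_intensity: float
    border_length: float  # px by default, um if converted
    relative_concentration: float


@dataclass
class CellIntensity:
    cell_id: int
    channel: str
    total_intensity: float
    perimeter_um: float


def mask_shape(mask: np.ndarray, pixel_size_um: float = 1.0):
    """(area_um2, perimeter_um, centroid_um, aspect_ratio, orientation_deg)
    of a binary mask.

    Second central moments use the unit-square pixel model (a +1/12
    per-pixel variance term), which makes an axis-aligned a-by-b rectangle
    come out at exactly AR = a/b.  The perimeter uses the Crofton formula
    with 4 directions, which is close to unbiased on smooth digitised
    outlines (a plain chain length systematically overestimates them).
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise MorphometryError("empty mask")
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    mxx = ((xs - cx) ** 2).mean() + 1.0 / 12.0
    myy = ((ys - cy) ** 2).mean() + 1.0 / 12.0
    mxy = ((xs - cx) * (ys - cy)).mean()
    tr, det_part = mxx + myy, np.hypot(mxx - myy, 2 * mxy)
    lam_max = (tr + det_part) / 2
    lam_min = (tr - det_part) / 2
    ar = float(np.sqrt(lam_max / max(lam_min, 1e-12)))
    theta = float(wrap_angle_deg(np.degrees(0.5 * np.arctan2(2 * mxy, mxx - myy))))
    area = n * pixel_size_um**2
    perim = float(perimeter_crofton(mask, directions=4)) * pixel_size_um
    return area, perim, (cx * pixel_size_um, cy * pixel_size_um), ar, theta


def cell_morphology(
    seg: SegmentationResult,
    pixel_size_um: float = 1.0,
    include_edge_cells: bool = False,
) -> list[CellMorphology]:
    """Shape descriptors for every (by default interior) cell."""
    ids = seg.cell_ids if include_edge_cells else seg.interior_cells()
    if not ids:
        raise MorphometryError("no interior cells")
    out = []
    for cid in ids:
        area, perim, cen, ar, theta = mask_shape(seg.labels == cid, pixel_size_um)
        out.append(CellMorphology(cid, area, perim, cen, ar, theta))
    return out


def junctional_concentration(
    frame: np.ndarray,
    seg: SegmentationResult,
    w_px: int = 5,
    per_cell: bool = True,
    channel: str = "junction",
    length_in_um: bool = False,
    pixel_size_um: float = 1.0,
) -> list[JunctionalProfile]:
    """Junctional-band concentration: band intensity / border length.

    ``integrated_intensity`` sums the frame over the band of half-width
    ``w_px`` around the border skeleton; ``border_length`` is the weighted
    pixel length of the skeleton (px by default).  A border pixel shared by
    two cells contributes fully to both cells' profiles — the statistic is
    normalised per cell, so this double counting across cells is intended.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != seg.labels.shape:
        raise MorphometryError("frame shape does not match segmentation")
    scale = pixel_size_um if length_in_um else 1.0

    def profile(cid: int | None) -> JunctionalProfile:
        band = band_mask(seg, w_px, cid)
        skel = seg.border_skeleton if cid is None else seg.cell_border(cid)
        length = weighted_pixel_length(skel) * scale
        if length == 0:
            raise MorphometryError("no border")
        total = float(frame[band].sum())
        return JunctionalProfile(
            cell_id=0 if cid is None else cid,
            channel=channel,
            band_halfwidth_px=w_px,
            integrated_intensity=total,
            border_length=length,
            relative_concentration=total / length,
        )

    if not per_cell:
        return [profile(None)]
    return [profile(cid) for cid in seg.cell_ids]


def cell_intensity(
    frame: np.ndarray,
    seg: SegmentationResult,
    channel: str = "",
    pixel_size_um: float = 1.0,
    include_edge_cells: bool = False,
) -> list[CellIntensity]:
    """Total intensity inside each cell label, paired with the cell
    perimeter (the readout used for monomeric-actin labelling)."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != seg.labels.shape:
        raise MorphometryError("frame shape does not match segmentation")
    morph = {
        m.cell_id: m
        for m in cell_morphology(seg, pixel_size_um, include_edge_cells)
    }
    return [
        CellIntensity(
            cell_id=cid,
            channel=channel,
            total_intensity=float(frame[seg.labels == cid].sum()),
            perimeter_um=morph[cid].perimeter_um,
        )
        for cid in sorted(morph)
    ]


def monolayer_density(seg: SegmentationResult, pixel_size_um: float) -> float:
    """Cell density in cells/cm²; edge-touching cells count half."""
    h, w = seg.labels.shape
    area_cm2 = (h * pixel_size_um * 1e-4) * (w * pixel_size_um * 1e-4)
    if area_cm2 <= 0:
        raise MorphometryError("field area must be positive")
    n_edge = len(seg.edge_cells)
    n_interior = seg.n_cells - n_edge
    return (n_interior + 0.5 * n_edge) / area_cm2


def morphology_table(
    seg: SegmentationResult,
    pixel_size_um: float = 1.0,
    frame: np.ndarray | None = None,
    w_px: int = 5,
    channel: str = "junction",
    include_edge_cells: bool = False,
) -> pd.DataFrame:
    """Per-cell CSV-ready table of morphology and, when a frame is given,
    the junctional-band statistic."""
    rows = []
    for m in cell_morphology(seg, pixel_size_um, include_edge_cells):
        rows.append(
            {
                "cell_id": m.cell_id,
                "area_um2": m.area_um2,
                "perimeter_um": m.perimeter_um,
                "centroid_x_um": m.centroid_um[0],
                "centroid_y_um": m.centroid_um[1],
                "aspect_ratio": m.aspect_ratio,
                "orientation_deg": m.orientation_deg,
            }
        )
    df = pd.DataFrame(rows)
    if frame is not None:
        prof = {
            p.cell_id: p
            for p in junctional_concentration(frame, seg, w_px, channel=channel)
        }
        df["channel"] = channel
        df["integrated_intensity"] = [
            prof[c].integrated_intensity if c in prof else np.nan
            for c in df["cell_id"]
        ]
        df["border_length"] = [
            prof[c].border_length if c in prof else np.nan for c in df["cell_id"]
        ]
        df["relative_concentration"] = [
            prof[c].relative_concentration if c in prof else np.nan
            for c in df["cell_id"]
        ]
    return df
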