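"""Silhouette metrology for unconfined compression tests.

A cylindrical gel sample is photographed side-on during compression with
an ordinary (non-telecentric) lens, so magnification depends on the
distance between the imaged point and the lens.  The pixel-to-millimeter
conversion factor is calibrated at the sample's vertical symmetry plane;
for a point on the cylinder surface at lateral offset ``R_c`` from the
axis, the circular cross-section places the visible surface
``d_i = sqrt(R^2 - R_c^2)`` closer to the lens, where the pinhole model
gives a larger conversion factor.  Heights measured along each image
column are corrected with the local factor; diameters are measured at the
symmetry plane.  Axial engineering stress uses the initial cross-section
from the first frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing

__all__ = [
    "CameraModel",
    "FrameMeasurement",
    "CompressionRecord",
    "SegmentationError",
    "scale_at",
    "depth_offset",
    "measure_frame",
    "compute_stress",
    "process_sequence",
]


class SegmentationError(ValueError):
    """No usable silhouette could be segmented from the image."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera calibrated at the sample's symmetry plane.

    ``base_scale`` is the conversion factor (px/mm) valid for points on
    the symmetry plane; ``working_distance`` is the lens-to-plane
    distance in mm.  A very large working distance approaches the
    telecentric limit (constant scale).
    """

    base_scale: float  # px/mm at the symmetry plane
    working_distance: float  # mm

    def __post_init__(self) -> None:
        if self.base_scale <= 0 or self.working_distance <= 0:
            raise ValueError("base_scale and working_distance must be positive")

    def scale_at(self, d: float):
        return scale_at(self, d)


def scale_at(camera: CameraModel, d):
    """Conversion factor (px/mm) at distance ``d`` mm toward the lens.

    Pinhole similar triangles: ``base_scale * W / (W - d)`` with ``W`` the
    working distance; equals ``base_scale`` on the symmetry plane (d=0)
    and doubles halfway to the lens.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d >= camera.working_distance):
        raise ValueError("point at or beyond the lens (d >= working_distance)")
    out = camera.base_scale * camera.working_distance / (camera.working_distance - d)
    return float(out) if out.ndim == 0 else out


def depth_offset(R, R_c):
    """Distance ``d_i`` from the symmetry plane to the visible surface.

    For a point of the circular cross-section of radius ``R`` at lateral
    offset ``R_c`` (both mm), ``d_i = sqrt(R^2 - R_c^2)``: the surface
    point imaged in that column is this much nearer the lens.
    """
    R = np.asarray(R, dtype=float)
    R_c = np.asarray(R_c, dtype=float)
    if np.any(R_c < 0) or np.any(R_c > R):
        raise ValueError("need 0 <= R_c <= R")
    out = np.sqrt(R * R - R_c * R_c)
    return float(out) if out.ndim == 0 else out


@dataclass
class FrameMeasurement:
    """Geometry of the sample in one frame (cylinder model)."""

    t: float  # s
    height_mm: float
    diameter_mm: float
    volume_mL: float = field(default=None)  # type: ignore[assignment]
    height_uncorrected_mm: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.volume_mL is None:
            self.volume_mL = cylinder_volume_mL(self.height_mm, self.diameter_mm)
        if self.height_mm <= 0 or self.diameter_mm <= 0 or self.volume_mL <= 0:
            raise ValueError("frame measurements must be positive")


def cylinder_volume_mL(height_mm: float, diameter_mm: float) -> float:
    """Volume of the measured cylinder in milliliters (= cm^3)."""
    return math.pi * (diameter_mm / 2.0) ** 2 * height_mm / 1000.0


@dataclass
class CompressionRecord:
    """Per-frame geometry plus the engineering-stress series of one test."""

    frames: list[FrameMeasurement]
    initial_diameter_mm: float
    stress_kPa: np.ndarray
    force_times: np.ndarray
    strain_setpoint: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])

    @property
    def volume_change_mL(self) -> np.ndarray:
        v = np.array([f.volume_mL for f in self.frames])
        return v - v[0]

    @property
    def flags(self) -> np.ndarray:
        return np.array([f.flagged for f in self.frames])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = label(mask)
    props = regionprops(lab)
    if not props:
        raise SegmentationError("no connected component found in the image")
    best = max(props, key=lambda p: p.area)
    return lab == best.label


def measure_frame(
    image: np.ndarray,
    camera: CameraModel,
    threshold: float | None = None,
    t: float = 0.0,
    dark_object: bool = True,
    edge_exclude: float = 0.05,
) -> FrameMeasurement:
    """Measure cylinder height, diameter and volume from one silhouette.

    The image is binarized (Otsu threshold by default, fixed override via
    ``threshold``), closed with a 3x3 structuring element, and the largest
    connected component taken as the sample.  The diameter is the mean of
    per-row silhouette widths converted at the symmetry-plane scale; the
    height is the mean of per-column extents, each converted with the
    perspective factor at the column's depth offset.  Rows/columns within
    ``edge_exclude`` of the silhouette's extremes are excluded from the
    averages.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel grayscale image")
    if img.max() == img.min():
        raise SegmentationError("blank image: no intensity contrast")
    thr = float(threshold) if threshold is not None else float(threshold_otsu(img))
    mask = img < thr if dark_object else img > thr
    if not mask.any():
        raise SegmentationError("binarization produced an empty mask")
    mask = closing(mask, np.ones((3, 3), dtype=bool))
    mask = _largest_component(mask)

    rows_any = np.flatnonzero(mask.any(axis=1))
    cols_any = np.flatnonzero(mask.any(axis=0))
    touches = (
        rows_any[0] == 0 and rows_any[-1] == mask.shape[0] - 1
        and cols_any[0] == 0 and cols_any[-1] == mask.shape[1] - 1
    )
    if touches:
        raise SegmentationError("silhouette touches all image borders")

    # per-row widths -> diameter at the symmetry-plane scale
    first = np.argmax(mask, axis=1).astype(float)
    last = mask.shape[1] - 1 - np.argmax(mask[:, ::-1], axis=1).astype(float)
    widths = np.where(mask.any(axis=1), last - first + 1.0, np.nan)

    n_edge = max(1, int(round(edge_exclude * rows_any.size)))
    core_rows = rows_any[n_edge:-n_edge] if rows_any.size > 2 * n_edge else rows_any
    diameter_mm = float(np.nanmean(widths[core_rows])) / camera.base_scale
    R = diameter_mm / 2.0

    # per-column extents -> height with the perspective correction
    top = np.argmax(mask, axis=0).astype(float)
    bot = mask.shape[0] - 1 - np.argmax(mask[::-1, :], axis=0).astype(float)
    extents = np.where(mask.any(axis=0), bot - top + 1.0, np.nan)
    center_col = 0.5 * (cols_any[0] + cols_any[-1])

    n_edge_c = max(1, int(round(edge_exclude * cols_any.size)))
    core_cols = cols_any[n_edge_c:-n_edge_c] if cols_any.size > 2 * n_edge_c else cols_any
    R_c = np.abs(core_cols - center_col) / camera.base_scale
    R_c = np.minimum(R_c, R)
    d_i = depth_offset(R, R_c)
    h_cols = extents[core_cols] / scale_at(camera, d_i)
    height_mm = float(np.nanmean(h_cols))
    height_unc = float(np.nanmean(extents[core_cols])) / camera.base_scale

    return FrameMeasurement(
        t=t,
        height_mm=height_mm,
        diameter_mm=diameter_mm,
        height_uncorrected_mm=height_unc,
    )


def compute_stress(force_N, initial_diameter_mm: float):
    """Engineering axial stress in kPa on the initial cross-section.

    ``sigma = F / (pi d0^2 / 4)`` with the force in newtons and the
    initial diameter in millimeters (N/mm^2 = MPa, reported as kPa).
    """
    if initial_diameter_mm <= 0:
        raise ValueError("initial diameter must be positive")
    F = np.asarray(force_N, dtype=float)
    area_mm2 = math.pi * initial_diameter_mm ** 2 / 4.0
    out = F / area_mm2 * 1000.0
    return float(out) if out.ndim == 0 else out


def process_sequence(
    images,
    frame_times,
    camera: CameraModel,
    forces=None,
    force_times=None,
    threshold: float | None = None,
    dark_object: bool = True,
    strain_setpoint: float | None = None,
    shadow_mad_factor: float = 3.0,
    shadow_window: int = 7,
) -> CompressionRecord:
    """Measure a time-stamped image sequence and attach the stress series.

    The initial diameter comes from the first frame (taken before probe
    contact).  Frames whose measured height dips more than
    ``shadow_mad_factor`` times the median absolute deviation below a
    rolling median are flagged — water released by the gel can cast a
    'shadow zone' that corrupts the silhouette — but are not deleted.
    """
    images = list(images)
    frame_times = np.asarray(frame_times, dtype=float)
    if len(images) == 0 or frame_times.size != len(images):
        raise ValueError("need a non-empty image list with matching timestamps")

    frames = [
        measure_frame(img, camera, threshold=threshold, t=float(tt),
                      dark_object=dark_object)
        for img, tt in zip(images, frame_times)
    ]
    d0 = frames[0].diameter_mm

    heights = np.array([f.height_mm for f in frames])
    if heights.size >= 3:
        half = shadow_window // 2
        med = np.array([
            np.median(heights[max(0, i - half): i + half + 1])
            for i in range(heights.size)
        ])
        mad = np.median(np.abs(heights - np.median(heights)))
        # floor the scale so constant-height sequences still flag dropouts
        mad = max(mad, 0.005 * float(np.median(heights)))
        for i, f in enumerate(frames):
            if heights[i] < med[i] - shadow_mad_factor * mad:
                f.flagged = True

    if forces is not None:
        forces = np.asarray(forces, dtype=float)
        if force_times is None:
            raise ValueError("force samples need timestamps")
        force_times = np.asarray(force_times, dtype=float)
        if force_times.size != forces.size:
            raise ValueError("forces and force_times must have equal length")
        stress = compute_stress(forces, d0)
    else:
        stress = np.array([])
        force_times = np.array([])

    return CompressionRecord(
        frames=frames,
        initial_diameter_mm=d0,
        stress_kPa=np.atleast_1d(stress),
        force_times=force_times,
        strain_setpoint=strain_setpoint,
    )
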