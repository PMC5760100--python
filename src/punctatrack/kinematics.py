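"""Per-particle kinematic statistics and per-photoreceptor summaries.

The quantities computed here are the five per-particle statistics used to
characterise vesicle-associated particle movement in photoreceptors —
displacement, total trajectory, maximum speed, rotation-corrected
directionality and mean cross-sectional area — plus the basal-body contact
flag (barycenter within 3 px = 630 nm of the BB barycenter).  Per-cell
summaries average these over all eligible (>= 10-frame) tracks of one
photoreceptor, which is the unit plotted as one dot in the study's scatter
plots and one row of its result tables.

Coordinate conventions: x = image column (lateral before rotation),
y = image row (apical at low y); physical units are px * pixel_size (nm).
Axis correction uses the Euler rotation

    x' = x * cos(theta) + y * sin(theta)
    y' = y * cos(theta) - x * sin(theta)

where theta is the angle between the cell's apico-basal axis and the image
vertical axis, so that after rotation y' runs along the apico-basal axis and
x' along the lateral axis.  Directionality = lateral span / apico-basal
span; values < 1 indicate predominantly apico-basal movement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import CellGeometry
    from .tracking import Track

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_NM = 210.0
DEFAULT_FRAME_INTERVAL_S = 1.0


@dataclass(frozen=True)
class ContactConfig:
    """Basal-body contact criterion: barycenter within ``radius_px`` of the BB.

    The boundary is inclusive (distance == radius counts as contact).
    """

    radius_px: float = 3.0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    @property
    def radius_nm(self) -> float:
        return self.radius_px * self.pixel_size_nm

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("contact radius must be positive")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class TrackMetrics:
    """The per-particle statistics for one eligible track."""

    track_id: int
    n_frames: int
    displacement_nm: float
    trajectory_um: float
    max_speed_nm_s: Optional[float]
    directionality: Optional[float]
    area_um2: float
    contacted_bb: bool = False
    n_contact_frames: int = 0


@dataclass
class PRSummary:
    """Per-photoreceptor averages over eligible tracks (one scatter dot)."""

    cell_id: str
    condition: str
    n_tracks: int
    mean_displacement_nm: float = math.nan
    mean_trajectory_um: float = math.nan
    mean_max_speed_nm_s: float = math.nan
    mean_directionality: float = math.nan
    mean_area_um2: float = math.nan
    n_contacting: int = 0
    contact_proportion: float = math.nan
    n_undefined_directionality: int = 0


def rotate_to_cell_axis(points: Sequence, theta: float) -> np.ndarray:
    """Rotate (x, y) points into the cell's apico-basal reference frame.

    Applies x' = x cos(theta) + y sin(theta), y' = y cos(theta) - x sin(theta).
    Distance-preserving for any theta.
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    c, s = math.cos(theta), math.sin(theta)
    x, y = pts[:, 0], pts[:, 1]
    out = np.column_stack((x * c + y * s, y * c - x * s))
    return out[0] if squeeze else out


def rotate_from_cell_axis(points: Sequence, theta: float) -> np.ndarray:
    """Inverse of :func:`rotate_to_cell_axis` (cell frame -> image frame)."""
    return rotate_to_cell_axis(points, -theta)


def _barycenters_nm(track: "Track") -> np.ndarray:
    return np.array([d.barycenter_nm for d in track.detections], dtype=float)


def _barycenters_px(track: "Track") -> np.ndarray:
    return np.array([d.barycenter_px for d in track.detections], dtype=float)


def displacement(track: "Track") -> float:
    """Distance in nm between the first and last barycenter of the track."""
    pts = _barycenters_nm(track)
    return float(np.hypot(*(pts[-1] - pts[0]))) if len(pts) else 0.0


def trajectory_length(track: "Track") -> float:
    """Total path length in um: sum of consecutive-frame step lengths."""
    pts = _barycenters_nm(track)
    if len(pts) < 2:
        return 0.0
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(steps.sum() / 1000.0)


def max_speed(track: "Track", frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> Optional[float]:
    """Largest distance travelled between two consecutive frames, in nm/s.

    Undefined (returns None) for single-frame tracks; such tracks are
    excluded from per-cell summaries.
    """
    pts = _barycenters_nm(track)
    if len(pts) < 2:
        return None
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(steps.max() / frame_interval_s)


def directionality(track: "Track", theta: float) -> Optional[float]:
    """Lateral span over apico-basal span after rotating by theta.

    Span is max - min of the rotated coordinate.  Returns None when the
    apico-basal span is zero (ratio undefined); < 1 indicates predominantly
    apico-basal movement.
    """
    pts = _barycenters_px(track)
    if len(pts) < 2:
        return None
    rot = rotate_to_cell_axis(pts, theta)
    span_x = float(rot[:, 0].max() - rot[:, 0].min())
    span_y = float(rot[:, 1].max() - rot[:, 1].min())
    if span_y == 0.0:
        logger.warning("track %s: zero apico-basal span, directionality undefined", getattr(track, "track_id", "?"))
        return None
    return span_x / span_y


def mean_area(track: "Track", pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM) -> float:
    """Mean cross-sectional area over frames, in um^2.

    Each pixel contributes (pixel_size/1000)^2 um^2; at 210 nm pixels one
    pixel is 0.0441 um^2, so a constant 10-pixel particle measures 0.441
    (printed as 0.44 at two decimals).
    """
    counts = np.array([d.pixel_count for d in track.detections], dtype=float)
    px_area = (pixel_size_nm / 1000.0) ** 2
    return float(counts.mean() * px_area)


def bb_contacts(track: "Track", geometry: "CellGeometry", config: ContactConfig = ContactConfig()) -> tuple[bool, int]:
    """Flag frames where the barycenter is within the contact radius of the BB.

    Distances are measured in pixels between the particle barycenter and the
    BB barycenter; the radius is inclusive.
    """
    pts = _barycenters_px(track)
    bb = np.asarray(geometry.bb_position, dtype=float)
    dists = np.linalg.norm(pts - bb, axis=1)
    n_contact = int(np.count_nonzero(dists <= config.radius_px))
    return n_contact >= 1, n_contact


def compute_track_metrics(
    track: "Track",
    geometry: "CellGeometry",
    contact: ContactConfig = ContactConfig(),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> TrackMetrics:
    """Compute all per-particle statistics for one track."""
    contacted, n_contact = bb_contacts(track, geometry, contact)
    return TrackMetrics(
        track_id=track.track_id,
        n_frames=track.n_frames,
        displacement_nm=displacement(track),
        trajectory_um=trajectory_length(track),
        max_speed_nm_s=max_speed(track, frame_interval_s),
        directionality=directionality(track, geometry.axis_angle_theta),
        area_um2=mean_area(track, pixel_size_nm),
        contacted_bb=contacted,
        n_contact_frames=n_contact,
    )


def summarize_pr(
    metrics: Sequence[TrackMetrics],
    cell_id: str,
    condition: str = "",
) -> PRSummary:
    """Average per-particle statistics over the eligible tracks of one cell.

    Means are unweighted over tracks.  Tracks whose directionality or
    maximum speed is undefined are excluded from that metric's mean only
    (counted in ``n_undefined_directionality``).  With zero eligible tracks
    the summary carries NaN means and ``n_tracks = 0``.
    """
    n = len(metrics)
    if n == 0:
        logger.warning("cell %s: no eligible tracks, summary undefined", cell_id)
        return PRSummary(cell_id=cell_id, condition=condition, n_tracks=0)

    def _mean(values: list[float]) -> float:
        return float(np.mean(values)) if values else math.nan

    dirs = [m.directionality for m in metrics if m.directionality is not None]
    speeds = [m.max_speed_nm_s for m in metrics if m.max_speed_nm_s is not None]
    n_contacting = sum(1 for m in metrics if m.contacted_bb)
    return PRSummary(
        cell_id=cell_id,
        condition=condition,
        n_tracks=n,
        mean_displacement_nm=_mean([m.displacement_nm for m in metrics]),
        mean_trajectory_um=_mean([m.trajectory_um for m in metrics]),
        mean_max_speed_nm_s=_mean(speeds),
        mean_directionality=_mean(dirs),
        mean_area_um2=_mean([m.area_um2 for m in metrics]),
        n_contacting=n_contacting,
        contact_proportion=n_contacting / n,
        n_undefined_directionality=n - len(dirs),
    )
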