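"""Segmentation and tracking-by-assignment of fluorescent puncta.

A registered stack is turned into tracks in three stages:

1. ``segment_frame`` — Gaussian blur (sigma 0.1 px, effectively no
   smoothing), min-max normalisation, fixed threshold (0.30 by default,
   meaningful range 0.29-0.31), 4-connected components, removal of
   components below 2 px, unweighted-centroid barycenters.
2. ``link_tracks`` — for each consecutive frame pair, a minimum-cost
   bipartite assignment in which matching two detections costs
   ``transition_weight * distance_px**2``, leaving a detection unmatched in
   the earlier frame costs ``disappearance_cost`` and in the later frame
   ``appearance_cost`` (defaults 3 / 47 / 9).  Mergers are capped at one
   object and divisions are disabled, so the global tracking problem
   factorises exactly over frame pairs.  No gap closing: a particle lost
   for one frame restarts as a new track.
3. ``filter_tracks`` — only tracks present in >= 10 frames are analysed.

``register_stack`` performs the translation-only drift correction applied
before segmentation, by phase cross-correlation of every frame against
frame 0 of the puncta channel; both channels receive the same shifts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.registration import phase_cross_correlation

from .synthetic import FrameStack

logger = logging.getLogger(__name__)

#: 4-connectivity structuring element for component labelling
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: cost stand-in for forbidden (beyond-gate) assignments
_FORBIDDEN = 1e12


@dataclass(frozen=True)
class SegmentationConfig:
    blur_sigma_px: float = 0.1
    threshold: float = 0.30
    min_size_px: int = 2
    pixel_size_nm: float = 210.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be >= 1")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")


@dataclass
class Detection:
    """One segmented particle in one frame.

    ``barycenter_px`` is the unweighted centroid of the 4-connected pixel
    set, as (x, y) = (column, row); ``barycenter_nm`` is the same scaled by
    the pixel size.
    """

    frame: int
    barycenter_px: tuple[float, float]
    barycenter_nm: tuple[float, float]
    pixel_count: int
    pixel_set: np.ndarray  # (n, 2) array of (row, col)


@dataclass(frozen=True)
class AssignmentCosts:
    """Linking costs; defaults are the optimized tracking parameters."""

    max_objects_per_merger: int = 1
    division_weight: float = 10.0  # stored but inert: divisions disabled
    transition_weight: float = 3.0
    appearance_cost: float = 9.0
    disappearance_cost: float = 47.0
    gating_radius_px: float = 8.0

    def __post_init__(self) -> None:
        for name in ("division_weight", "transition_weight", "appearance_cost", "disappearance_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Track:
    """An ordered chain of detections in strictly consecutive frames."""

    track_id: int
    detections: list[Detection]

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    def __post_init__(self) -> None:
        frames = self.frames
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must increase by exactly 1")


@dataclass
class LinkResult:
    """Tracks plus the summed assignment objective over all frame pairs."""

    tracks: list[Track]
    objective: float


def register_stack(stack: FrameStack, upsample_factor: int = 1) -> tuple[FrameStack, np.ndarray]:
    """Align every frame to frame 0 by translation (drift correction).

    The shift for each frame is estimated on channel 1 (puncta) by phase
    cross-correlation and applied identically to both channels.  Returns
    the registered stack and the applied per-frame shifts as (dx, dy) px.
    All-zero frames get a zero shift with a warning.
    """
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    ref = stack.channel1[0]
    T = stack.n_frames
    shifts = np.zeros((T, 2))
    out = stack.data.copy()
    for t in range(1, T):
        mov = stack.channel1[t]
        if not np.any(mov) or not np.any(ref):
            warnings.warn(f"frame {t}: all-zero image, assuming zero shift")
            continue
        # returned shift is (row, col) displacement that maps mov onto ref
        shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample_factor)
        shifts[t] = (shift[1], shift[0])  # (dx, dy)
        for ch in range(out.shape[0]):
            out[ch, t] = ndimage.shift(stack.data[ch, t], shift, order=1, mode="constant", cval=0.0)
    registered = FrameStack(
        data=np.clip(out, 0.0, None),
        pixel_size_nm=stack.pixel_size_nm,
        frame_interval_s=stack.frame_interval_s,
    )
    return registered, shifts


def segment_frame(frame: np.ndarray, config: SegmentationConfig = SegmentationConfig(), frame_index: int = 0) -> list[Detection]:
    """Segment one frame into particle detections.

    Pipeline: Gaussian blur -> min-max normalisation to [0, 1] ->
    binarisation at ``threshold`` -> 4-connected components -> size filter.
    A constant frame (normalisation undefined) yields no detections.
    """
    img = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ValueError("frame must be finite and non-negative")
    if config.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, config.blur_sigma_px)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return []
    norm = (img - lo) / (hi - lo)
    binary = norm >= config.threshold
    labels, n = ndimage.label(binary, structure=_CROSS)
    detections: list[Detection] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)  # (row, col)
        if len(coords) < config.min_size_px:
            continue
        cy, cx = coords.mean(axis=0)
        detections.append(
            Detection(
                frame=frame_index,
                barycenter_px=(float(cx), float(cy)),
                barycenter_nm=(float(cx) * config.pixel_size_nm, float(cy) * config.pixel_size_nm),
                pixel_count=len(coords),
                pixel_set=coords,
            )
        )
    return detections


def segment_stack(stack: FrameStack, config: SegmentationConfig = SegmentationConfig(), channel: int = 0) -> list[list[Detection]]:
    """Segment every frame of one channel; returns per-frame detection lists."""
    return [segment_frame(stack.data[channel, t], config, frame_index=t) for t in range(stack.n_frames)]


def _pair_assignment(
    prev: Sequence[Detection], curr: Sequence[Detection], costs: AssignmentCosts
) -> tuple[list[tuple[int, int]], float]:
    """Minimum-cost assignment between two consecutive frames.

    Solved as a square LAP on the standard augmented matrix: the
    (n_prev + n_curr) square matrix holds transition costs in the top-left
    block, disappearance costs on the top-right diagonal, appearance costs
    on the bottom-left diagonal, and zeros bottom-right.  Ties break toward
    the lowest detection indices via the solver's row-major scan order.
    """
    n_p, n_c = len(prev), len(curr)
    if n_p == 0 and n_c == 0:
        return [], 0.0
    size = n_p + n_c
    C = np.full((size, size), _FORBIDDEN)
    for i, dp in enumerate(prev):
        for j, dc in enumerate(curr):
            d2 = (dp.barycenter_px[0] - dc.barycenter_px[0]) ** 2 + (
                dp.barycenter_px[1] - dc.barycenter_px[1]
            ) ** 2
            if d2 <= costs.gating_radius_px**2:
                C[i, j] = costs.transition_weight * d2
    for i in range(n_p):
        C[i, n_c + i] = costs.disappearance_cost
    for j in range(n_c):
        C[n_p + j, j] = costs.appearance_cost
    C[n_p:, n_c:] = 0.0
    rows, cols = linear_sum_assignment(C)
    matches: list[tuple[int, int]] = []
    objective = 0.0
    for r, c in zip(rows, cols):
        if r < n_p and c < n_c:
            matches.append((r, c))
            objective += C[r, c]
        elif r < n_p:
            objective += costs.disappearance_cost
        elif c < n_c:
            objective += costs.appearance_cost
    return matches, objective


def link_tracks(detections_per_frame: Sequence[Sequence[Detection]], costs: AssignmentCosts = AssignmentCosts()) -> LinkResult:
    """Link per-frame detections into tracks by frame-pair assignment.

    Every detection belongs to exactly one track; matched chains extend
    tracks, unmatched detections start new ones.  The reported objective is
    the sum of the optimal assignment costs over all consecutive frame
    pairs (appearances in the very first frame are free, as there is no
    earlier frame to pair them with).
    """
    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}  # index in prev frame -> track
    prev: Sequence[Detection] = []
    objective = 0.0
    next_id = 0
    for t, curr in enumerate(detections_per_frame):
        if t == 0:
            new_open: dict[int, Track] = {}
            for j, det in enumerate(curr):
                tr = Track(track_id=next_id, detections=[det])
                next_id += 1
                tracks.append(tr)
                new_open[j] = tr
            open_tracks = new_open
            prev = curr
            continue
        matches, obj = _pair_assignment(prev, curr, costs)
        objective += obj
        matched_j = {}
        for i, j in matches:
            matched_j[j] = open_tracks[i]
        new_open = {}
        for j, det in enumerate(curr):
            if j in matched_j:
                tr = matched_j[j]
                tr.detections.append(det)
            else:
                tr = Track(track_id=next_id, detections=[det])
                next_id += 1
                tracks.append(tr)
            new_open[j] = tr
        open_tracks = new_open
        prev = curr
    return LinkResult(tracks=tracks, objective=objective)


def filter_tracks(tracks: Sequence[Track], min_frames: int = 10) -> list[Track]:
    """Keep only tracks present in at least ``min_frames`` frames."""
    kept = [tr for tr in tracks if tr.n_frames >= min_frames]
    logger.info("filter_tracks: %d of %d tracks eligible (>= %d frames)", len(kept), len(tracks), min_frames)
    return kept
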