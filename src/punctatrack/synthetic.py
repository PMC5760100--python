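"""Ground-truthed synthetic photoreceptor videos.

Emulates two-channel single-focal-plane time-lapse acquisitions of a
polarized photoreceptor: channel 1 carries moving fluorescent puncta
(vesicle-associated particles executing a confined, predominantly
apico-basal random walk in the inner segment, with occasional directed
excursions to the basal body), channel 2 a single static basal-body marker.
Defaults follow the acquisition the analysis is designed for: 210 nm square
pixels, 1 frame/s, 600 frames (10 min).

The motion model is a confined anisotropic Gaussian random walk: per frame,
independent axial N(0, sigma_axial) and lateral N(0, sigma_lateral)
displacements in the cell frame, rotated into image coordinates and
reflected at the inner-segment compartment boundaries.  A Poisson-triggered
excursion overrides diffusion with a constant-speed run to the basal body
and back.  Particles disappear geometrically (bleaching / focal-plane exit)
and new ones appear at a constant birth rate.  Every simulated particle is
returned as a :class:`TruthTrack`, the oracle against which the tracker is
evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .kinematics import rotate_from_cell_axis, rotate_to_cell_axis

DEFAULT_PIXEL_SIZE_NM = 210.0
DEFAULT_FRAME_INTERVAL_S = 1.0
DEFAULT_N_FRAMES = 600


@dataclass
class CellGeometry:
    """One photoreceptor's reference frame for directionality and contacts.

    ``axis_angle_theta`` is the angle (radians, in (-pi, pi]) between the
    cell's apico-basal axis and the image vertical axis; rotating image
    coordinates with this theta makes y' the apico-basal coordinate (apical
    at low y').  ``compartment_bounds`` are the two internal boundaries
    (outer segment / inner segment, inner segment / synaptic region) along
    the rotated axis, in px relative to the cell center.
    """

    cell_id: str
    axis_angle_theta: float
    bb_position: tuple[float, float]  # (x, y) px, image frame
    mask: np.ndarray  # bool, H x W
    compartment_bounds: tuple[float, float]
    center_px: tuple[float, float] = (0.0, 0.0)
    cell_length_px: float = 0.0
    cell_width_px: float = 0.0

    def __post_init__(self) -> None:
        if not (-math.pi < self.axis_angle_theta <= math.pi):
            raise ValueError("axis_angle_theta must lie in (-pi, pi]")
        if self.compartment_bounds[0] >= self.compartment_bounds[1]:
            raise ValueError("compartment_bounds must be strictly ordered")
        bx, by = self.bb_position
        iy, ix = int(round(by)), int(round(bx))
        if not (0 <= iy < self.mask.shape[0] and 0 <= ix < self.mask.shape[1] and self.mask[iy, ix]):
            raise ValueError("bb_position must lie inside the cell mask")
        bb_axial = rotate_to_cell_axis(
            (bx - self.center_px[0], by - self.center_px[1]), self.axis_angle_theta
        )[1]
        if bb_axial >= self.compartment_bounds[0]:
            raise ValueError("bb_position must lie in the apical-most compartment")

    def contains_nm(self, position_nm: Sequence[float], pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM) -> bool:
        """Whether a continuous nm position falls on a mask pixel."""
        x, y = float(position_nm[0]) / pixel_size_nm, float(position_nm[1]) / pixel_size_nm
        iy, ix = int(round(y)), int(round(x))
        return (
            0 <= iy < self.mask.shape[0]
            and 0 <= ix < self.mask.shape[1]
            and bool(self.mask[iy, ix])
        )


@dataclass(frozen=True)
class MotionConfig:
    """Parameters of the particle motion model (per-frame units unless noted).

    Defaults are calibrated so that maximum per-frame steps approach 1 um
    (the observed maximum speed scale at 1 frame/s) and axial motion
    dominates lateral (directionality < 1).
    """

    n_particles: int = 5
    sigma_axial_nm: float = 400.0
    sigma_lateral_nm: float = 150.0
    bb_excursion_prob: float = 0.002
    excursion_speed_nm_s: float = 800.0
    mean_lifetime_frames: float = 400.0
    birth_rate_per_frame: float = 0.01
    max_step_nm: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_axial_nm < 0 or self.sigma_lateral_nm < 0:
            raise ValueError("step standard deviations must be non-negative")
        if not 0.0 <= self.bb_excursion_prob <= 1.0:
            raise ValueError("bb_excursion_prob must be a probability")
        if self.mean_lifetime_frames < 1:
            raise ValueError("mean_lifetime_frames must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Two optional noise layers: Poisson shot noise and Gaussian read noise."""

    poisson: bool = False
    gaussian_sigma: float = 0.0


@dataclass(frozen=True)
class RenderConfig:
    """Rendering of true particle positions into a fluorescence raster."""

    psf_sigma_nm: float = 250.0
    peak_intensity: float = 1000.0
    background_level: float = 10.0
    diffuse_fraction: float = 0.0
    noise: NoiseModel = NoiseModel()
    drift_per_frame_px: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be positive")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValueError("diffuse_fraction must be in [0, 1]")


@dataclass
class TruthTrack:
    """Ground-truth trajectory of one simulated particle.

    ``positions_nm`` has one (x, y) row per frame in
    [birth_frame, death_frame] inclusive, in image-frame nm.
    """

    particle_id: int
    birth_frame: int
    death_frame: int
    positions_nm: np.ndarray  # (n, 2)
    radius_nm: np.ndarray  # (n,)

    @property
    def n_frames(self) -> int:
        return self.death_frame - self.birth_frame + 1


@dataclass
class FrameStack:
    """A two-channel T x H x W intensity stack with physical calibration."""

    data: np.ndarray  # (2, T, H, W); channel 0 = puncta, channel 1 = BB marker
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be positive")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def channel1(self) -> np.ndarray:
        return self.data[0]

    @property
    def channel2(self) -> np.ndarray:
        return self.data[1]


def make_geometry(
    axis_angle_theta: float,
    cell_length_px: float = 60.0,
    cell_width_px: float = 16.0,
    seed: int = 0,
    cell_id: str = "PR0",
    margin_px: float = 4.0,
) -> CellGeometry:
    """Build a rectangular cell footprint rotated by theta.

    The basal body sits at the apical end of the rotated rectangle, in the
    apical-most (outer segment) compartment; compartment boundaries are
    placed at fixed fractions of the cell length.  Deterministic given its
    arguments (``seed`` is accepted for interface symmetry with the
    stochastic generators).
    """
    if cell_length_px < 4 or cell_width_px < 4:
        raise ValueError("cell_length_px and cell_width_px must be >= 4 px")
    L, W = float(cell_length_px), float(cell_width_px)
    c, s = abs(math.cos(axis_angle_theta)), abs(math.sin(axis_angle_theta))
    h = L * c + W * s + 2 * margin_px
    w = L * s + W * c + 2 * margin_px
    H, Wd = int(math.ceil(h)) + 1, int(math.ceil(w)) + 1
    cx, cy = (Wd - 1) / 2.0, (H - 1) / 2.0

    yy, xx = np.mgrid[0:H, 0:Wd]
    rel = np.column_stack(((xx.ravel() - cx), (yy.ravel() - cy)))
    rot = rotate_to_cell_axis(rel, axis_angle_theta)
    inside = (np.abs(rot[:, 0]) <= W / 2.0) & (np.abs(rot[:, 1]) <= L / 2.0)
    mask = inside.reshape(H, Wd)

    bb_offset = max(1.0, 0.05 * L)
    bb_cell = np.array([0.0, -L / 2.0 + bb_offset])
    bb_img = rotate_from_cell_axis(bb_cell, axis_angle_theta) + np.array([cx, cy])
    os_is = -L / 2.0 + max(2.0, 0.15 * L)
    is_syn = L / 2.0 - max(1.0, 0.25 * L)
    return CellGeometry(
        cell_id=cell_id,
        axis_angle_theta=axis_angle_theta,
        bb_position=(float(bb_img[0]), float(bb_img[1])),
        mask=mask,
        compartment_bounds=(os_is, is_syn),
        center_px=(cx, cy),
        cell_length_px=L,
        cell_width_px=W,
    )


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate into [lo, hi] by reflection at the boundaries."""
    if lo >= hi:
        return (lo + hi) / 2.0
    span = hi - lo
    v = (value - lo) % (2.0 * span)
    if v > span:
        v = 2.0 * span - v
    return lo + v


class _Particle:
    __slots__ = ("pid", "cell_pos", "birth", "positions", "state", "origin")

    def __init__(self, pid: int, cell_pos: np.ndarray, birth: int):
        self.pid = pid
        self.cell_pos = cell_pos  # (x', y') nm in cell frame, relative to center
        self.birth = birth
        self.positions: list[np.ndarray] = []
        self.state = "diffuse"  # diffuse | to_bb | from_bb
        self.origin: Optional[np.ndarray] = None


def simulate_tracks(
    config: MotionConfig,
    geometry: CellGeometry,
    n_frames: int = DEFAULT_N_FRAMES,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> list[TruthTrack]:
    """Simulate confined shuffling particle trajectories in one cell.

    Diffusing particles are confined by reflection to the inner-segment
    compartment (between the two compartment boundaries, inset from the
    lateral cell edges).  An excursion overrides diffusion: the particle
    runs at constant speed to within 200 nm of the basal body, then back to
    its starting point, and resumes diffusing.  Reproducible bit-for-bit
    given (config, geometry, n_frames).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not geometry.mask.any():
        raise ValueError("geometry mask is empty")
    rng = np.random.default_rng(config.seed)
    px = pixel_size_nm

    lat_margin = 1.1 * px
    x_lo = -geometry.cell_width_px / 2.0 * px + lat_margin
    x_hi = geometry.cell_width_px / 2.0 * px - lat_margin
    y_lo = geometry.compartment_bounds[0] * px
    y_hi = geometry.compartment_bounds[1] * px
    bb_rel = np.asarray(geometry.bb_position, float) - np.asarray(geometry.center_px, float)
    bb_cell = rotate_to_cell_axis(bb_rel, geometry.axis_angle_theta) * px
    stop_radius = 200.0  # nm from BB at which the outbound leg ends
    step_excursion = config.excursion_speed_nm_s * frame_interval_s

    def _spawn(pid: int, frame: int) -> _Particle:
        pos = np.array([rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)])
        return _Particle(pid, pos, frame)

    p_death = 1.0 / config.mean_lifetime_frames
    particles = [_spawn(i, 0) for i in range(config.n_particles)]
    next_id = config.n_particles
    done: list[TruthTrack] = []
    alive = list(particles)

    def _finish(p: _Particle, last_frame: int) -> None:
        pos = np.array(p.positions)
        img = rotate_from_cell_axis(pos / px, geometry.axis_angle_theta) * px
        img += np.asarray(geometry.center_px, float) * px
        done.append(
            TruthTrack(
                particle_id=p.pid,
                birth_frame=p.birth,
                death_frame=last_frame,
                positions_nm=img,
                radius_nm=np.full(len(pos), 200.0),
            )
        )

    for t in range(n_frames):
        survivors: list[_Particle] = []
        for p in alive:
            if p.positions and rng.random() < p_death:
                _finish(p, t - 1)
                continue
            if p.positions:  # step only after the birth frame
                if p.state == "diffuse" and rng.random() < config.bb_excursion_prob:
                    p.state = "to_bb"
                    p.origin = p.cell_pos.copy()
                if p.state == "diffuse":
                    step = np.array(
                        [
                            rng.normal(0.0, config.sigma_lateral_nm),
                            rng.normal(0.0, config.sigma_axial_nm),
                        ]
                    )
                    norm = float(np.linalg.norm(step))
                    if norm > config.max_step_nm > 0:
                        step *= config.max_step_nm / norm
                    p.cell_pos = np.array(
                        [
                            _reflect(p.cell_pos[0] + step[0], x_lo, x_hi),
                            _reflect(p.cell_pos[1] + step[1], y_lo, y_hi),
                        ]
                    )
                else:
                    target = bb_cell if p.state == "to_bb" else p.origin
                    delta = target - p.cell_pos
                    dist = float(np.linalg.norm(delta))
                    goal = stop_radius if p.state == "to_bb" else 0.0
                    if dist - goal <= step_excursion:
                        if p.state == "to_bb":
                            if dist > goal:
                                p.cell_pos = p.cell_pos + delta * ((dist - goal) / dist)
                            p.state = "from_bb"
                        else:
                            p.cell_pos = target.copy()
                            p.state = "diffuse"
                            p.origin = None
                    else:
                        p.cell_pos = p.cell_pos + delta * (step_excursion / dist)
            p.positions.append(p.cell_pos.copy())
            survivors.append(p)
        for _ in range(rng.poisson(config.birth_rate_per_frame)):
            p = _spawn(next_id, t)
            next_id += 1
            p.positions.append(p.cell_pos.copy())
            survivors.append(p)
        alive = survivors
    for p in alive:
        _finish(p, n_frames - 1)
    done.sort(key=lambda tr: tr.particle_id)
    return done


def render_video(
    truth: Sequence[TruthTrack],
    geometry: CellGeometry,
    render: RenderConfig = RenderConfig(),
    n_frames: Optional[int] = None,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> FrameStack:
    """Rasterize true trajectories into a two-channel fluorescence stack.

    Each particle is an isotropic Gaussian blob centred at its true
    position; channel 2 holds a single static blob at the basal body.
    Stage drift translates the scene by ``drift_per_frame_px`` per frame
    (applied to the true positions before rasterisation, which for integer
    drift is identical to translating the rendered frame).  Poisson and
    Gaussian noise are applied last, from a dedicated seeded generator.
    """
    H, W = geometry.mask.shape
    if n_frames is None:
        n_frames = 1 + max((tr.death_frame for tr in truth), default=0)
    rng = np.random.default_rng(render.seed)
    sigma_px = render.psf_sigma_nm / pixel_size_nm
    halfwin = max(3, int(math.ceil(4.0 * sigma_px)))
    dx, dy = render.drift_per_frame_px
    data = np.zeros((2, n_frames, H, W), dtype=float)
    data += render.background_level

    mask_area = float(geometry.mask.sum())
    peak = render.peak_intensity * (1.0 - render.diffuse_fraction)

    def _add_blob(frame: np.ndarray, x: float, y: float, amplitude: float) -> bool:
        x0, y0 = int(round(x)), int(round(y))
        r0, r1 = max(0, y0 - halfwin), min(H, y0 + halfwin + 1)
        c0, c1 = max(0, x0 - halfwin), min(W, x0 + halfwin + 1)
        if r0 >= r1 or c0 >= c1:
            return False
        yy, xx = np.mgrid[r0:r1, c0:c1]
        frame[r0:r1, c0:c1] += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2)
        )
        return True

    live_frames = np.zeros(n_frames, dtype=bool)
    rendered_frames = np.zeros(n_frames, dtype=bool)
    for tr in truth:
        pos_px = tr.positions_nm / pixel_size_nm
        for i, t in enumerate(range(tr.birth_frame, tr.death_frame + 1)):
            if t >= n_frames:
                break
            live_frames[t] = True
            x = pos_px[i, 0] + dx * t
            y = pos_px[i, 1] + dy * t
            if _add_blob(data[0, t], x, y, peak):
                rendered_frames[t] = True
            if render.diffuse_fraction > 0 and mask_area > 0:
                total = render.peak_intensity * 2.0 * math.pi * sigma_px**2
                data[0, t][geometry.mask] += render.diffuse_fraction * total / mask_area
    if np.any(live_frames & ~rendered_frames):
        raise ValueError("drift pushed all content off the raster in some frames")

    bbx, bby = geometry.bb_position
    for t in range(n_frames):
        _add_blob(data[1, t], bbx + dx * t, bby + dy * t, render.peak_intensity)

    if render.noise.poisson:
        data = rng.poisson(data).astype(float)
    if render.noise.gaussian_sigma > 0:
        data = data + rng.normal(0.0, render.noise.gaussian_sigma, size=data.shape)
        data = np.clip(data, 0.0, None)
    return FrameStack(data=data, pixel_size_nm=pixel_size_nm, frame_interval_s=frame_interval_s)


def mutant_motion(config: MotionConfig = MotionConfig()) -> MotionConfig:
    """Mutant-mode motion: fewer particles, more lateral movement."""
    return replace(
        config,
        n_particles=max(1, config.n_particles // 3),
        sigma_lateral_nm=2.0 * config.sigma_lateral_nm,
    )


def mutant_render(render: RenderConfig = RenderConfig()) -> RenderConfig:
    """Mutant-mode rendering: part of the signal diffuse in the cytoplasm."""
    return replace(render, diffuse_fraction=max(render.diffuse_fraction, 0.3))
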