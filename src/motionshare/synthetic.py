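"""Synthetic kinematics and image sequences for the passive recumbent flexion protocol.

Generates ground-truth gross trunk motion (motorised table profile), per-subject
intervertebral angle series with configurable motion sharing, variance-component
observation matrices for reliability simulations, and rendered image sequences
with known per-frame vertebral poses for closed-loop tracking validation.

Angles are in degrees throughout, flexion positive, expressed as change from the
starting position.  All stochastic operations take an explicit seed; no global
RNG state is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Intervertebral levels, cranial to caudal.
LEVELS = ("L2-L3", "L3-L4", "L4-L5", "L5-S1")

#: Vertebral bodies visible in the field of view, cranial to caudal.
VERTEBRAE = ("L2", "L3", "L4", "L5", "S1")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableProfile:
    """Motorised table kinematic profile for passive recumbent flexion.

    The table accelerates at ``accel`` deg/s^2 until it reaches
    ``plateau_velocity`` deg/s, moves at constant velocity, then decelerates at
    the same rate so that the excursion peaks at exactly ``max_angle`` degrees.
    With ``include_return`` the return phase mirrors the outward kinematics.
    """

    accel: float = 6.0
    plateau_velocity: float = 6.0
    max_angle: float = 40.0
    frame_rate: float = 15.0
    include_return: bool = True

    def __post_init__(self) -> None:
        if self.accel <= 0:
            raise ValueError("accel must be > 0")
        if self.plateau_velocity <= 0:
            raise ValueError("plateau_velocity must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.max_angle < self.ramp_angle * 2:
            raise ValueError(
                f"max_angle={self.max_angle} cannot accommodate acceleration and "
                f"deceleration phases covering {2 * self.ramp_angle} deg"
            )

    @property
    def ramp_time(self) -> float:
        """Duration of the acceleration (= deceleration) phase in seconds."""
        return self.plateau_velocity / self.accel

    @property
    def ramp_angle(self) -> float:
        """Angle covered during acceleration: 1/2 a t^2."""
        return self.plateau_velocity**2 / (2.0 * self.accel)

    @property
    def plateau_angle(self) -> float:
        return self.max_angle - 2.0 * self.ramp_angle

    @property
    def plateau_time(self) -> float:
        return self.plateau_angle / self.plateau_velocity

    @property
    def outward_duration(self) -> float:
        return 2.0 * self.ramp_time + self.plateau_time

    @property
    def total_duration(self) -> float:
        return self.outward_duration * (2.0 if self.include_return else 1.0)


@dataclass(frozen=True)
class SharingProfile:
    """Latent per-level proportional contributions to the gross angle.

    ``base_shares`` are the time-averaged proportions of the gross L2-S1 angle
    taken up by each level; ``share_drift`` sets the amplitude of a smooth
    (sinusoidal) time-varying deviation per level, renormalised so noiseless
    shares still sum to one each frame; ``noise_sd`` is additive Gaussian angle
    noise applied to the level angles, defaulting to the 0.52 deg instrument
    precision limit.
    """

    base_shares: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    share_drift: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    noise_sd: float = 0.52

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_shares", tuple(float(s) for s in self.base_shares))
        object.__setattr__(self, "share_drift", tuple(float(d) for d in self.share_drift))
        if len(self.base_shares) != len(self.share_drift):
            raise ValueError("base_shares and share_drift must have equal length")
        if abs(sum(self.base_shares) - 1.0) > 1e-9:
            raise ValueError("base_shares must sum to 1 within 1e-9")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(d < 0 for d in self.share_drift):
            raise ValueError("share_drift amplitudes must be >= 0")

    @property
    def n_levels(self) -> int:
        return len(self.base_shares)


@dataclass(frozen=True)
class ObserverModel:
    """Variance-component model of repeated biomarker readings.

    Readings follow ``y_ij = mu + s_i + r_j + e_ij`` with independent normal
    subject effects ``s``, rater effects ``r`` and residual errors ``e``.
    """

    between_subject_sd: float
    error_sd: float
    rater_bias_sd: float = 0.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        for name in ("between_subject_sd", "error_sd", "rater_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def population_icc(self) -> float:
        """Implied absolute-agreement ICC of single readings."""
        total = self.between_subject_sd**2 + self.rater_bias_sd**2 + self.error_sd**2
        if total == 0:
            return float("nan")
        return self.between_subject_sd**2 / total


@dataclass
class MotionSequence:
    """Per-frame intervertebral and gross angles for one motion sequence.

    ``gross_angle`` is the L2-S1 angle change from the starting position,
    flexion positive.  ``level_angles`` has shape ``(n_frames, n_levels)`` in
    the order of :data:`LEVELS`; it may be ``None`` for a gross-only skeleton.
    """

    frame_times: np.ndarray
    gross_angle: np.ndarray
    level_angles: np.ndarray | None = None
    phase_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.gross_angle = np.asarray(self.gross_angle, dtype=float)
        if self.frame_times.shape != self.gross_angle.shape:
            raise ValueError("frame_times and gross_angle must share one length")
        if self.level_angles is not None:
            self.level_angles = np.asarray(self.level_angles, dtype=float)
            if self.level_angles.shape[0] != self.n_frames:
                raise ValueError("level_angles length mismatch")
        if self.phase_labels is not None:
            self.phase_labels = np.asarray(self.phase_labels, dtype=object)
            if self.phase_labels.shape[0] != self.n_frames:
                raise ValueError("phase_labels length mismatch")
        if self.n_frames and abs(self.gross_angle[0]) > 1e-9:
            raise ValueError("gross_angle[0] must be 0 (change from start)")
        self.meta.setdefault("angle_units", "deg")
        self.meta.setdefault("sign_convention", "flexion-positive, change from frame 0")

    @property
    def n_frames(self) -> int:
        return self.frame_times.shape[0]

    @property
    def n_levels(self) -> int:
        if self.level_angles is None:
            raise ValueError("sequence has no level angles")
        return self.level_angles.shape[1]


# ---------------------------------------------------------------------------
# Table motion
# ---------------------------------------------------------------------------

def table_angle(profile: TableProfile, t: np.ndarray) -> np.ndarray:
    """Continuous gross table angle at times ``t`` (seconds), vectorised.

    Piecewise: 1/2 a t^2 during acceleration, linear plateau, mirrored
    deceleration; times past the outward peak follow the time-reversed outward
    profile when the profile includes the return phase.
    """
    t = np.asarray(t, dtype=float)
    t_out = profile.outward_duration
    if profile.include_return:
        # Mirror the return half onto the outward profile.
        tt = np.where(t > t_out, 2.0 * t_out - t, t)
    else:
        tt = t
    tt = np.clip(tt, 0.0, t_out)
    a, v = profile.accel, profile.plateau_velocity
    t1 = profile.ramp_time
    t2 = t1 + profile.plateau_time
    angle = np.empty_like(tt)
    m_acc = tt <= t1
    m_pla = (tt > t1) & (tt <= t2)
    m_dec = tt > t2
    angle[m_acc] = 0.5 * a * tt[m_acc] ** 2
    angle[m_pla] = profile.ramp_angle + v * (tt[m_pla] - t1)
    td = t_out - tt[m_dec]
    angle[m_dec] = profile.max_angle - 0.5 * a * td**2
    return angle


def generate_table_motion(profile: TableProfile) -> MotionSequence:
    """Sample the table profile at ``frame_rate`` into a gross-only sequence.

    The first frame is at t = 0; the last frame is the latest sample not past
    the end of the motion.  The peak of the continuous profile equals
    ``max_angle`` exactly.
    """
    dt = 1.0 / profile.frame_rate
    # robust frame count: floor with tolerance for float round-off
    n = int(np.floor(profile.total_duration / dt + 1e-9)) + 1
    times = np.arange(n) * dt
    gross = table_angle(profile, times)
    phase = np.where(times <= profile.outward_duration + 1e-12, "outward", "return")
    return MotionSequence(
        frame_times=times,
        gross_angle=gross,
        phase_labels=phase.astype(object),
        meta={"table_profile": dataclasses.asdict(profile)},
    )


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------

def generate_subject(
    profile: TableProfile, sharing: SharingProfile, seed: int
) -> MotionSequence:
    """Simulate one subject's intervertebral angle series.

    Level angles are ``share_l(t) * gross(t) + noise`` where the shares are the
    base shares plus smooth sinusoidal drift, renormalised so the noiseless
    shares sum to one each frame.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    skel = generate_table_motion(profile)
    n_frames, n_levels = skel.n_frames, sharing.n_levels
    # Per-level sinusoid: frequency in cycles over the whole sequence, random phase.
    freqs = rng.uniform(0.5, 1.5, size=n_levels)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_levels)
    duration = max(skel.frame_times[-1], 1e-12)
    u = skel.frame_times[:, None] / duration
    drift = np.asarray(sharing.share_drift)[None, :] * np.sin(
        2.0 * np.pi * freqs[None, :] * u + phases[None, :]
    )
    shares = np.asarray(sharing.base_shares)[None, :] + drift
    tot = shares.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("drift amplitudes too large: shares sum to <= 0 on some frame")
    shares = shares / tot
    levels = shares * skel.gross_angle[:, None]
    if sharing.noise_sd > 0:
        noise = rng.normal(0.0, sharing.noise_sd, size=levels.shape)
        noise[0, :] = 0.0  # angles are change-from-start; frame 0 is 0 by definition
        levels = levels + noise
    return MotionSequence(
        frame_times=skel.frame_times,
        gross_angle=skel.gross_angle,
        level_angles=levels,
        phase_labels=skel.phase_labels,
        meta={
            "table_profile": dataclasses.asdict(profile),
            "sharing_profile": dataclasses.asdict(sharing),
            "seed": int(seed) if isinstance(seed, (int, np.integer)) else repr(seed),
            "true_shares": shares,
        },
    )


def cohort_sharing_profiles(
    n_subjects: int,
    mean_range: float = 0.24,
    range_sd: float = 0.09,
    share_drift: float = 0.03,
    noise_sd: float = 0.52,
    seed: int = 0,
) -> list[SharingProfile]:
    """Draw per-subject sharing profiles with a controlled share-range distribution.

    Each subject's base shares are an equal split plus a symmetric spread whose
    max-minus-min range is drawn from N(mean_range, range_sd), truncated at 0,
    so the cohort-mean ground-truth share range matches ``mean_range``.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_subjects):
        r = rng.normal(mean_range, range_sd)
        r = float(np.clip(r, 0.0, 0.9))
        spread = np.array([r / 2.0, r / 6.0, -r / 6.0, -r / 2.0])
        rng.shuffle(spread)
        base = 0.25 + spread
        profiles.append(
            SharingProfile(
                base_shares=tuple(base),
                share_drift=(share_drift,) * 4,
                noise_sd=noise_sd,
            )
        )
    return profiles


def generate_observation_matrix(
    model: ObserverModel, n_subjects: int, n_raters: int, seed: int = 0
):
    """Simulate an n_subjects x n_raters reading matrix under the observer model.

    Returns ``(matrix, components)`` where ``matrix`` is a
    :class:`~motionshare.reliability.ObservationMatrix` and ``components`` holds
    the generating variance components and the implied population ICC.
    """
    from .reliability import ObservationMatrix  # local import avoids cycle

    if n_subjects < 2 or n_raters < 2:
        raise ValueError("need n_subjects >= 2 and n_raters >= 2")
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, model.between_subject_sd, size=n_subjects)
    r = rng.normal(0.0, model.rater_bias_sd, size=n_raters)
    e = rng.normal(0.0, model.error_sd, size=(n_subjects, n_raters))
    values = model.mean + s[:, None] + r[None, :] + e
    matrix = ObservationMatrix(
        values=values,
        subject_ids=[f"S{i + 1:02d}" for i in range(n_subjects)],
        rater_ids=[f"R{j + 1}" for j in range(n_raters)],
    )
    components = {
        "mean": model.mean,
        "between_subject_sd": model.between_subject_sd,
        "rater_bias_sd": model.rater_bias_sd,
        "error_sd": model.error_sd,
        "population_icc": model.population_icc,
    }
    return matrix, components


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneGeometry:
    """Layout of the five vertebral body quadrilaterals in the image.

    ``centroids`` are (x, y) pixel positions (origin top-left, x right, y
    down), one per vertebra in :data:`VERTEBRAE` order.  ``quads`` are 4x2
    corner offsets from the centroid in the body frame.
    """

    image_shape: tuple[int, int] = (448, 256)  # (height, width)
    centroids: tuple[tuple[float, float], ...] = (
        (128.0, 60.0),
        (128.0, 130.0),
        (128.0, 200.0),
        (128.0, 270.0),
        (128.0, 340.0),
    )
    quads: tuple[tuple[tuple[float, float], ...], ...] = tuple(
        (
            (-28.0, -18.0),
            (26.0, -16.0),
            (28.0, 18.0),
            (-26.0, 16.0),
        )
        for _ in range(5)
    )
    background_range: tuple[float, float] = (0.10, 0.25)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.centroids) != len(self.quads):
            raise ValueError("centroids and quads must have equal length")
        for q in self.quads:
            if len(q) != 4:
                raise ValueError("each vertebra quad needs exactly 4 corners")

    @property
    def n_vertebrae(self) -> int:
        return len(self.centroids)


@dataclass
class ImageSequence:
    """Rendered frames with per-frame ground-truth poses.

    ``poses`` has shape ``(n_frames, n_vertebrae, 3)`` holding
    ``(tx_px, ty_px, rot_deg)`` for each body relative to its reference pose.
    """

    frames: np.ndarray
    poses: np.ndarray
    geometry: SceneGeometry

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _rotation_matrix(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def _body_texture(u: np.ndarray, v: np.ndarray, k: int) -> np.ndarray:
    """Smooth deterministic intensity pattern in body coordinates."""
    return (
        0.60
        + 0.18 * np.sin(0.42 * u + 0.21 * v + 0.7 * k)
        + 0.12 * np.cos(0.31 * v - 0.17 * u + 1.3 * k)
        + 0.08 * np.sin(0.9 * u + 0.13 * k)
    )


def _background(geometry: SceneGeometry) -> np.ndarray:
    h, w = geometry.image_shape
    lo, hi = geometry.background_range
    col = np.linspace(lo, hi, h)[:, None]
    return np.repeat(col, w, axis=1)


def _quad_coverage(points: np.ndarray, quad: np.ndarray, soft: float = 0.8) -> np.ndarray:
    """Anti-aliased coverage of a convex quad at the given body-frame points.

    Signed distance to the polygon boundary (negative inside) mapped to a
    [0, 1] alpha over a ``soft``-pixel transition; a hard mask would alias the
    body edge and bias sub-degree template matching.
    """
    # orient edge normals by the polygon's signed area
    x, y = quad[:, 0], quad[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    sgn = 1.0 if area2 > 0 else -1.0
    d = np.full(points.shape[0], -np.inf)
    for i in range(len(quad)):
        a = quad[i]
        b = quad[(i + 1) % len(quad)]
        e = b - a
        n = np.array([e[1], -e[0]]) * sgn / np.hypot(*e)
        d = np.maximum(d, (points - a) @ n)
    return np.clip(0.5 - d / soft, 0.0, 1.0)


def render_frame(
    geometry: SceneGeometry,
    rotations_deg: np.ndarray,
    translations_px: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Render one frame with each vertebra rigidly posed.

    ``rotations_deg[k]`` rotates vertebra k about its (translated) centroid;
    ``translations_px[k]`` shifts its centroid.  Raises if any corner leaves
    the image bounds.
    """
    h, w = geometry.image_shape
    img = (_background(geometry) if background is None else background).copy()
    if translations_px is None:
        translations_px = np.zeros((geometry.n_vertebrae, 2))
    yy, xx = np.mgrid[0:h, 0:w]
    for k in range(geometry.n_vertebrae):
        quad = np.asarray(geometry.quads[k], dtype=float)
        c = np.asarray(geometry.centroids[k], dtype=float) + translations_px[k]
        R = _rotation_matrix(rotations_deg[k])
        corners = quad @ R.T + c
        if (
            corners[:, 0].min() < 0
            or corners[:, 1].min() < 0
            or corners[:, 0].max() > w - 1
            or corners[:, 1].max() > h - 1
        ):
            raise ValueError(
                f"vertebra {VERTEBRAE[k] if k < len(VERTEBRAE) else k} drawn outside "
                f"image bounds at rotation {rotations_deg[k]:.2f} deg"
            )
        x0 = max(int(np.floor(corners[:, 0].min())) - 1, 0)
        x1 = min(int(np.ceil(corners[:, 0].max())) + 1, w - 1)
        y0 = max(int(np.floor(corners[:, 1].min())) - 1, 0)
        y1 = min(int(np.ceil(corners[:, 1].max())) + 1, h - 1)
        px = np.column_stack(
            [xx[y0 : y1 + 1, x0 : x1 + 1].ravel(), yy[y0 : y1 + 1, x0 : x1 + 1].ravel()]
        ).astype(float)
        body = (px - c) @ R  # inverse rotation: R^T applied from the left
        alpha = _quad_coverage(body, quad)
        hit = alpha > 0
        if hit.any():
            vals = _body_texture(body[hit, 0], body[hit, 1], k)
            sub = img[y0 : y1 + 1, x0 : x1 + 1].ravel()
            sub[hit] = sub[hit] * (1.0 - alpha[hit]) + vals * alpha[hit]
            img[y0 : y1 + 1, x0 : x1 + 1] = sub.reshape(y1 - y0 + 1, x1 - x0 + 1)
    return np.clip(img, 0.0, 1.0)


def level_rotations(seq: MotionSequence) -> np.ndarray:
    """Absolute per-vertebra rotations implied by the level angles.

    S1 is held fixed; each vertebra above rotates by the cumulative sum of the
    intervertebral angles below it, so inter-body angle differences reproduce
    ``seq.level_angles`` and L2's rotation equals the gross angle.
    """
    if seq.level_angles is None:
        raise ValueError("sequence has no level angles")
    n = seq.n_frames
    rots = np.zeros((n, seq.n_levels + 1))
    # vertebra order L2..S1; level order L2-L3..L5-S1
    rots[:, :-1] = np.cumsum(seq.level_angles[:, ::-1], axis=1)[:, ::-1]
    return rots


def render_frames(
    seq: MotionSequence,
    geometry: SceneGeometry | None = None,
    seed: int | None = None,
) -> ImageSequence:
    """Render an image sequence whose inter-body angles follow ``seq``.

    Each vertebra rotates rigidly about its own centroid (no translation), so
    the ground-truth pose per frame is ``(0, 0, rot_deg)``.  Gaussian pixel
    noise with ``geometry.noise_sd`` is added when nonzero (seeded).
    """
    geometry = geometry or SceneGeometry()
    rots = level_rotations(seq)
    if rots.shape[1] != geometry.n_vertebrae:
        raise ValueError("geometry vertebra count does not match sequence levels + 1")
    bg = _background(geometry)
    h, w = geometry.image_shape
    frames = np.empty((seq.n_frames, h, w), dtype=np.float32)
    for i in range(seq.n_frames):
        frames[i] = render_frame(geometry, rots[i], background=bg)
    if geometry.noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = np.clip(
            frames + rng.normal(0.0, geometry.noise_sd, size=frames.shape), 0.0, 1.0
        ).astype(np.float32)
    poses = np.zeros((seq.n_frames, geometry.n_vertebrae, 3))
    poses[:, :, 2] = rots
    return ImageSequence(frames=frames, poses=poses, geometry=geometry)


def corner_fixture(geometry: SceneGeometry | None = None) -> dict:
    """Nominal corner-landmark fixture for first-image registration.

    Returns ``{vertebra: 4x2 corner list in image px}`` for the reference
    (frame 0) poses of the geometry.
    """
    geometry = geometry or SceneGeometry()
    out = {}
    for k in range(geometry.n_vertebrae):
        c = np.asarray(geometry.centroids[k])
        corners = np.asarray(geometry.quads[k]) + c
        name = VERTEBRAE[k] if k < len(VERTEBRAE) else f"V{k}"
        out[name] = corners.tolist()
    return out
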