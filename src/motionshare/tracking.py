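"""First-image registration and frame-to-frame rigid template tracking.

Recovers per-frame vertebral poses from an image sequence: nominal corner
landmarks (optionally perturbed to emulate repeated manual placement) seed
rectangular templates cut from the first frame, which are then tracked through
the sequence by maximising normalized cross-correlation over a rigid pose grid
(translation window x rotation range) seeded at the previous frame's pose,
with parabolic sub-pixel / sub-degree refinement.  Frames whose best
similarity falls below a threshold are flagged and can be re-tracked with a
widened search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .synthetic import LEVELS, VERTEBRAE, MotionSequence

__all__ = [
    "VertebralTemplate",
    "TrackedPoseSeries",
    "SearchConfig",
    "register_first_image",
    "track_sequence",
    "retrack_failures",
    "extract_intervertebral_angles",
]


@dataclass
class VertebralTemplate:
    """Registered template for one vertebral body.

    ``corner_landmarks`` are the 4 averaged corner placements (px, image
    coordinates, origin top-left, x right, y down).  ``patch`` is the image
    data cut from frame 0 around the tracking outline; ``anchor`` is the
    reference centroid expressed in patch coordinates.
    """

    name: str
    corner_landmarks: np.ndarray
    tracking_outline: np.ndarray
    centroid: np.ndarray
    orientation: float
    patch: np.ndarray
    anchor: np.ndarray

    def __post_init__(self) -> None:
        self.corner_landmarks = np.asarray(self.corner_landmarks, dtype=float)
        if self.corner_landmarks.shape != (4, 2):
            raise ValueError(f"{self.name}: need exactly 4 corner landmarks")
        if not (-180.0 < self.orientation <= 180.0):
            raise ValueError("orientation must lie in (-180, 180]")


@dataclass
class TrackedPoseSeries:
    """Per-frame per-vertebra rigid poses with similarity scores and flags.

    ``poses[f, v] = (tx_px, ty_px, rot_deg)`` relative to the registered
    reference pose; ``scores`` are peak normalized cross-correlations in
    [-1, 1]; ``flags`` marks tracking failures.
    """

    poses: np.ndarray
    scores: np.ndarray
    flags: np.ndarray
    vertebra_names: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.poses.shape[0]

    @property
    def n_vertebrae(self) -> int:
        return self.poses.shape[1]

    def failures(self) -> list[tuple[int, int]]:
        """(frame, vertebra) index pairs of outstanding failures."""
        f, v = np.nonzero(self.flags)
        return list(zip(f.tolist(), v.tolist()))


@dataclass(frozen=True)
class SearchConfig:
    trans_radius: int = 4  # px each side of the predicted position
    rot_radius: float = 1.5  # deg each side of the previous rotation
    rot_step: float = 0.5  # deg
    similarity_threshold: float = 0.5
    refine: bool = True
    patch_margin: int = 3  # px added around the corner bounding box


def _unsharp(img: np.ndarray, radius: float = 2.0, amount: float = 1.0) -> np.ndarray:
    """Optional fixed unsharp-mask edge enhancement."""
    blurred = ndimage.gaussian_filter(img, radius)
    return img + amount * (img - blurred)


def register_first_image(
    frame0: np.ndarray,
    fixture: dict[str, list | np.ndarray],
    n_repeats: int = 5,
    perturbation_sd: float = 0.0,
    seed: int | None = None,
    patch_margin: int = 3,
) -> list[VertebralTemplate]:
    """Build templates from (simulated) repeated manual corner placement.

    Each of the ``n_repeats`` placements perturbs every nominal corner with an
    isotropic Gaussian of ``perturbation_sd`` px; the placements are averaged
    per corner before templates are cut from ``frame0``.  With
    ``perturbation_sd=0`` the templates reproduce the fixture exactly.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    templates = []
    for name, corners in fixture.items():
        corners = np.asarray(corners, dtype=float)
        if corners.shape != (4, 2):
            raise ValueError(f"{name}: fixture must supply exactly 4 corners")
        placements = corners[None] + rng.normal(
            0.0, perturbation_sd, size=(n_repeats, 4, 2)
        )
        avg = placements.mean(axis=0)
        centroid = avg.mean(axis=0)
        edge = avg[1] - avg[0]
        orientation = float(np.degrees(np.arctan2(edge[1], edge[0])))
        if orientation <= -180.0:
            orientation += 360.0
        x0 = int(np.floor(avg[:, 0].min())) - patch_margin
        x1 = int(np.ceil(avg[:, 0].max())) + patch_margin
        y0 = int(np.floor(avg[:, 1].min())) - patch_margin
        y1 = int(np.ceil(avg[:, 1].max())) + patch_margin
        h, w = frame0.shape
        if x0 < 0 or y0 < 0 or x1 >= w or y1 >= h:
            raise ValueError(f"{name}: template window leaves the image")
        patch = np.asarray(frame0[y0 : y1 + 1, x0 : x1 + 1], dtype=float).copy()
        anchor = centroid - np.array([x0, y0])
        templates.append(
            VertebralTemplate(
                name=name,
                corner_landmarks=avg,
                tracking_outline=avg.copy(),
                centroid=centroid,
                orientation=orientation,
                patch=patch,
                anchor=anchor,
            )
        )
    return templates


def _rotate_patch(patch: np.ndarray, deg: float, center_xy: np.ndarray) -> np.ndarray:
    """Rotate a patch by ``deg`` about ``center_xy`` (same convention as the
    renderer: positive angles rotate x-right/y-down points by
    [[c, -s], [s, c]])."""
    if deg == 0.0:
        return patch
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    hh, ww = patch.shape
    yy, xx = np.mgrid[0:hh, 0:ww]
    dx = xx - center_xy[0]
    dy = yy - center_xy[1]
    # inverse rotation of output coords into template coords
    sx = c * dx + s * dy + center_xy[0]
    sy = -s * dx + c * dy + center_xy[1]
    return ndimage.map_coordinates(patch, [sy, sx], order=1, mode="nearest")


def _parabolic_offset(y0: float, y1: float, y2: float) -> float:
    """Sub-sample peak offset of a parabola through three equally spaced points."""
    denom = y0 - 2.0 * y1 + y2
    if denom >= -1e-12:
        return 0.0
    off = 0.5 * (y0 - y2) / denom
    return float(np.clip(off, -0.5, 0.5))


def _match_one(
    frame: np.ndarray,
    tpl: VertebralTemplate,
    pred_pose: np.ndarray,
    config: SearchConfig,
) -> tuple[np.ndarray, float]:
    """Best rigid pose of one template in one frame near a predicted pose."""
    h, w = frame.shape
    ph, pw = tpl.patch.shape
    if ph > h or pw > w:
        raise ValueError(f"{tpl.name}: template larger than frame")
    r = config.trans_radius
    pred_c = tpl.centroid + pred_pose[:2]
    # top-left of the patch if its anchor sat at the predicted centroid
    x0 = int(round(pred_c[0] - tpl.anchor[0]))
    y0 = int(round(pred_c[1] - tpl.anchor[1]))
    rx0, ry0 = max(x0 - r, 0), max(y0 - r, 0)
    rx1, ry1 = min(x0 + pw + r, w), min(y0 + ph + r, h)
    region = frame[ry0:ry1, rx0:rx1]
    if region.shape[0] < ph or region.shape[1] < pw:
        raise ValueError(f"{tpl.name}: search region leaves the image")
    n_steps = max(int(round(config.rot_radius / config.rot_step)), 0)
    rots = pred_pose[2] + np.arange(-n_steps, n_steps + 1) * config.rot_step
    best = None
    rot_scores = np.full(rots.size, -np.inf)
    for j, rot in enumerate(rots):
        rt = _rotate_patch(tpl.patch, rot, tpl.anchor)
        ncc = match_template(region, rt)
        iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
        rot_scores[j] = ncc[iy, ix]
        if best is None or rot_scores[j] > best[0]:
            best = (float(rot_scores[j]), j, iy, ix, ncc)
    score, j, iy, ix, ncc = best
    rot = rots[j]
    fx, fy = float(ix), float(iy)
    if config.refine:
        if 0 < ix < ncc.shape[1] - 1:
            fx += _parabolic_offset(ncc[iy, ix - 1], ncc[iy, ix], ncc[iy, ix + 1])
        if 0 < iy < ncc.shape[0] - 1:
            fy += _parabolic_offset(ncc[iy - 1, ix], ncc[iy, ix], ncc[iy + 1, ix])
        if 0 < j < rots.size - 1 and np.isfinite(rot_scores[j - 1]) and np.isfinite(
            rot_scores[j + 1]
        ):
            rot += config.rot_step * _parabolic_offset(
                rot_scores[j - 1], rot_scores[j], rot_scores[j + 1]
            )
    cx = rx0 + fx + tpl.anchor[0]
    cy = ry0 + fy + tpl.anchor[1]
    pose = np.array([cx - tpl.centroid[0], cy - tpl.centroid[1], rot])
    return pose, score


def track_sequence(
    frames: np.ndarray,
    templates: list[VertebralTemplate],
    config: SearchConfig | None = None,
    edge_enhance: bool = False,
) -> TrackedPoseSeries:
    """Track every template through the frame stack.

    Frame 0 is the registration frame (pose zero by definition).  Each later
    frame is searched around the previous frame's pose.  A frame whose best
    similarity falls below ``config.similarity_threshold`` is flagged and its
    pose carried forward as the seed for the next frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n, h, w) stack")
    config = config or SearchConfig()
    if edge_enhance:
        frames = np.stack([_unsharp(f) for f in frames])
    n_frames = frames.shape[0]
    n_vert = len(templates)
    poses = np.zeros((n_frames, n_vert, 3))
    scores = np.ones((n_frames, n_vert))
    flags = np.zeros((n_frames, n_vert), dtype=bool)
    for f in range(1, n_frames):
        for v, tpl in enumerate(templates):
            pose, score = _match_one(frames[f], tpl, poses[f - 1, v], config)
            scores[f, v] = score
            if score < config.similarity_threshold:
                flags[f, v] = True
                poses[f, v] = poses[f - 1, v]  # carry forward as next seed
            else:
                poses[f, v] = pose
    return TrackedPoseSeries(
        poses=poses,
        scores=scores,
        flags=flags,
        vertebra_names=[t.name for t in templates],
    )


def retrack_failures(
    series: TrackedPoseSeries,
    frames: np.ndarray,
    templates: list[VertebralTemplate],
    config: SearchConfig | None = None,
) -> TrackedPoseSeries:
    """Re-track flagged frames with a widened search window.

    Each flagged span is re-seeded from the last good pose before it; flags
    clear where the similarity recovers, residual failures stay flagged.
    Returns a new series; the input is not modified.
    """
    config = config or SearchConfig()
    wide = replace(
        config,
        trans_radius=config.trans_radius * 2 + 4,
        rot_radius=max(config.rot_radius * 2, 4.0),
    )
    frames = np.asarray(frames, dtype=float)
    poses = series.poses.copy()
    scores = series.scores.copy()
    flags = series.flags.copy()
    for v in range(series.n_vertebrae):
        for f in np.flatnonzero(series.flags[:, v]):
            seed_pose = poses[f - 1, v] if f > 0 else np.zeros(3)
            pose, score = _match_one(frames[f], templates[v], seed_pose, wide)
            scores[f, v] = score
            if score >= wide.similarity_threshold:
                poses[f, v] = pose
                flags[f, v] = False
    return TrackedPoseSeries(
        poses=poses,
        scores=scores,
        flags=flags,
        vertebra_names=list(series.vertebra_names),
    )


def extract_intervertebral_angles(
    series: TrackedPoseSeries,
    frame_rate: float = 15.0,
) -> MotionSequence:
    """Intervertebral and gross angle series from tracked poses.

    The angle at each level (upper, lower) is the upper body's rotation minus
    the lower body's, expressed as change from frame 0; the gross angle is the
    topmost minus the bottom-most rotation.  Refuses sequences with
    outstanding failure flags.
    """
    bad = series.failures()
    if bad:
        names = series.vertebra_names or [str(v) for v in range(series.n_vertebrae)]
        listing = ", ".join(f"frame {f}:{names[v]}" for f, v in bad[:8])
        more = "" if len(bad) <= 8 else f" (+{len(bad) - 8} more)"
        raise ValueError(f"unresolved tracking failures: {listing}{more}")
    rot = series.poses[:, :, 2] - series.poses[0, :, 2]
    levels = rot[:, :-1] - rot[:, 1:]
    gross = rot[:, 0] - rot[:, -1]
    times = np.arange(series.n_frames) / frame_rate
    return MotionSequence(
        frame_times=times,
        gross_angle=gross,
        level_angles=levels,
        meta={
            "source": "tracking",
            "vertebrae": list(series.vertebra_names),
            "levels": list(LEVELS[: levels.shape[1]]) if levels.shape[1] <= 4 else None,
        },
    )
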