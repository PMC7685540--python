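"""Motion-sharing biomarkers from intervertebral angle time series.

Converts an angle series to per-frame proportional contributions of each level
to the gross L2-S1 angle, trims the low-amplitude shoulders of each motion
phase where small denominators amplify measurement error, computes the
per-frame range of proportions (fRC), and summarises it as:

* MSI — the mean of fRC over retained frames (inequality of sharing), and
* MSV — the population standard deviation of fRC (unevenness of sharing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import LEVELS, MotionSequence

__all__ = [
    "ProportionalMotion",
    "MotionShareResult",
    "trim_middle80",
    "to_proportional",
    "frame_range",
    "compute_msi",
    "compute_msv",
    "analyze_sequence",
]


@dataclass
class ProportionalMotion:
    """Per-frame per-level proportions of the gross angle, with trim mask.

    ``proportions`` is NaN outside the retained frames.  ``frc`` (the
    per-frame max-minus-min of the proportions) is filled by
    :func:`frame_range` and NaN outside the mask.
    """

    proportions: np.ndarray
    trim_mask: np.ndarray
    frc: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return int(self.trim_mask.sum())


@dataclass
class MotionShareResult:
    msi: float
    msv: float
    frc: np.ndarray
    trim_mask: np.ndarray
    n_retained: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "msi": float(self.msi),
            "msv": float(self.msv),
            "n_frames_retained": int(self.n_retained),
            "parameters": dict(self.provenance),
        }


def _phase_groups(seq: MotionSequence) -> list[np.ndarray]:
    """Frame-index groups for the outward and (if present) return phases.

    Uses stored phase labels when available, otherwise splits at the peak of
    the gross angle.
    """
    n = seq.n_frames
    if seq.phase_labels is not None:
        labels = np.asarray(seq.phase_labels)
        groups = [np.flatnonzero(labels == lab) for lab in ("outward", "return")]
        return [g for g in groups if g.size]
    peak = int(np.argmax(np.abs(seq.gross_angle)))
    if peak >= n - 1:
        return [np.arange(n)]
    return [np.arange(peak + 1), np.arange(peak + 1, n)]


def trim_middle80(
    seq: MotionSequence,
    mode: str = "amplitude",
    phases: str = "both",
    lower: float = 0.10,
    upper: float = 0.90,
) -> np.ndarray:
    """Boolean mask of frames retained for analysis.

    ``mode="amplitude"`` (default) keeps frames whose gross angle lies within
    [lower, upper] x peak gross angle; ``mode="time"`` keeps the middle
    fraction of frames by index.  Either is applied separately to the outward
    and return phases so both shoulders of each phase are trimmed.
    ``phases="outward"`` restricts analysis to the outward phase.
    """
    gross = np.abs(seq.gross_angle)
    g_max = gross.max()
    if g_max <= 0:
        raise ValueError("gross angle range is zero; nothing to trim")
    if mode not in ("amplitude", "time"):
        raise ValueError(f"unknown trim mode {mode!r}")
    if phases not in ("both", "outward"):
        raise ValueError(f"unknown phases selection {phases!r}")
    mask = np.zeros(seq.n_frames, dtype=bool)
    groups = _phase_groups(seq)
    if phases == "outward":
        groups = groups[:1]
    for idx in groups:
        if mode == "amplitude":
            g = gross[idx]
            keep = (g >= lower * g_max - 1e-12) & (g <= upper * g_max + 1e-12)
            mask[idx[keep]] = True
        else:
            m = idx.size
            lo = int(np.ceil(lower * (m - 1)))
            hi = int(np.floor(upper * (m - 1)))
            mask[idx[lo : hi + 1]] = True
    if mask.sum() < 2:
        raise ValueError("fewer than 2 frames retained after trimming")
    return mask


def to_proportional(
    seq: MotionSequence, trim_mask: np.ndarray | None = None
) -> ProportionalMotion:
    """Scale level angles to proportions of the gross angle per frame.

    Signs are preserved: a level moving against the gross direction yields a
    negative proportion.  Division is only performed on retained frames; a
    retained frame with zero gross angle is an error (trim first).
    """
    if seq.level_angles is None:
        raise ValueError("sequence has no level angles")
    if trim_mask is None:
        trim_mask = np.ones(seq.n_frames, dtype=bool)
    trim_mask = np.asarray(trim_mask, dtype=bool)
    if trim_mask.shape[0] != seq.n_frames:
        raise ValueError("trim_mask length mismatch")
    gross = seq.gross_angle
    if np.any(gross[trim_mask] == 0):
        bad = np.flatnonzero(trim_mask & (gross == 0))
        raise ZeroDivisionError(
            f"zero gross angle on retained frame(s) {bad.tolist()[:5]}; "
            "apply an amplitude trim before scaling"
        )
    prop = np.full_like(seq.level_angles, np.nan)
    prop[trim_mask] = seq.level_angles[trim_mask] / gross[trim_mask, None]
    return ProportionalMotion(proportions=prop, trim_mask=trim_mask)


def frame_range(prop: ProportionalMotion) -> np.ndarray:
    """Per-frame range fRC_i = max - min over levels of the proportions.

    Returns a full-length array, NaN outside the trim mask; also stores it on
    ``prop.frc``.
    """
    frc = np.full(prop.proportions.shape[0], np.nan)
    m = prop.trim_mask
    frc[m] = prop.proportions[m].max(axis=1) - prop.proportions[m].min(axis=1)
    prop.frc = frc
    return frc


def _retained(frc: np.ndarray) -> np.ndarray:
    frc = np.asarray(frc, dtype=float)
    vals = frc[~np.isnan(frc)]
    if vals.size == 0:
        raise ValueError("empty fRC series")
    return vals


def compute_msi(frc: np.ndarray) -> float:
    """MSI = sum(fRC_i) / N over retained frames."""
    vals = _retained(frc)
    return float(vals.sum() / vals.size)


def compute_msv(frc: np.ndarray, msi: float | None = None, ddof: int = 0) -> float:
    """MSV = sqrt( sum((fRC_i - MSI)^2) / N ), population form by default.

    ``ddof=1`` gives the sample-SD variant (non-default).
    """
    vals = _retained(frc)
    if vals.size - ddof < 1:
        raise ValueError("need at least 2 retained frames for MSV")
    if msi is None:
        msi = float(vals.mean())
    return float(np.sqrt(np.sum((vals - msi) ** 2) / (vals.size - ddof)))


def analyze_sequence(
    seq: MotionSequence,
    trim: str = "amplitude",
    phases: str = "both",
    lower: float = 0.10,
    upper: float = 0.90,
    sd_ddof: int = 0,
) -> MotionShareResult:
    """Full biomarker computation for one sequence: trim, scale, fRC, MSI, MSV."""
    mask = trim_middle80(seq, mode=trim, phases=phases, lower=lower, upper=upper)
    prop = to_proportional(seq, mask)
    frc = frame_range(prop)
    msi = compute_msi(frc)
    msv = compute_msv(frc, msi, ddof=sd_ddof)
    return MotionShareResult(
        msi=msi,
        msv=msv,
        frc=frc,
        trim_mask=mask,
        n_retained=prop.n_retained,
        provenance={
            "trim": trim,
            "phases": phases,
            "lower": lower,
            "upper": upper,
            "sd_ddof": sd_ddof,
            "levels": list(LEVELS[: seq.n_levels]),
        },
    )
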