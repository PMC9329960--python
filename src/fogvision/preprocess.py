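"""Scale normalization and kinematic signal derivation.

A walking subject filmed with a fixed monocular camera changes apparent
size with distance.  Per frame, the minimum axis-aligned rectangle over
the visible keypoints is expanded by 30% in each dimension, coordinates
are re-expressed with the expanded rectangle's upper-left corner as the
origin, and everything is multiplied by ``s = 80 / expanded height`` so
the skeleton always occupies a box of normalized height 80.  The
construction is invariant to isotropic scaling and translation of the
raw pixels.

From the normalized coordinates we derive, per frame:

* position, speed and acceleration of each keypoint on each axis
  (forward first differences × fps),
* left/right knee interior angles (degrees),
* the absolute left–right x-axis separation of 8 keypoint pairs (hips,
  knees, ankles, big toes, shoulders, elbows, wrists, ears) — the
  signals whose collapse-and-recovery signature marks a turn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .pose_io import KEYPOINT_NAMES, LR_PAIRS, N_KEYPOINTS, PoseSequence

logger = logging.getLogger(__name__)

DEFAULT_EXPAND_FRAC = 0.30
DEFAULT_TARGET_HEIGHT = 80.0

AXES = ("x", "y")

# Knee-angle vertex triplets: (side, hip, knee, ankle) in BODY_25 indices.
_KNEE_TRIPLETS = (("L", 12, 13, 14), ("R", 9, 10, 11))


class PreprocessError(ValueError):
    pass


@dataclass
class NormalizedSequence:
    """Pose sequence in normalized units plus per-frame rectangle metadata.

    ``rect_origin`` is the expanded rectangle's upper-left corner in
    pixels, ``rect_size`` its (width, height) in pixels, and ``scale``
    the per-frame factor s = target_height / expanded height.
    """

    subject_id: str
    test_id: str
    fps: float
    frame_index: np.ndarray
    xy: np.ndarray            # (n, 25, 2), normalized units
    conf: np.ndarray
    rect_origin: np.ndarray   # (n, 2) pixels
    rect_size: np.ndarray     # (n, 2) pixels (width, height)
    scale: np.ndarray         # (n,)

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)


def normalize_sequence(
    seq: PoseSequence,
    expand_frac: float = DEFAULT_EXPAND_FRAC,
    target_height: float = DEFAULT_TARGET_HEIGHT,
) -> NormalizedSequence:
    """Normalize per-frame scale via the expanded enclosing rectangle.

    Per frame: (1) the minimum axis-aligned rectangle over keypoints with
    positive confidence; (2) width and height each grown by
    ``expand_frac``, symmetric about the rectangle center; (3) translate
    so the expanded rectangle's upper-left corner is the origin;
    (4) multiply by ``target_height / expanded height``.
    """
    n = seq.n_frames
    xy = seq.xy
    valid = seq.conf > 0
    if not valid.any(axis=1).all():
        bad = int(np.flatnonzero(~valid.any(axis=1))[0])
        raise PreprocessError(f"frame {seq.frame_index[bad]} has no visible keypoints")

    big = np.where(valid[:, :, None], xy, -np.inf)
    small = np.where(valid[:, :, None], xy, np.inf)
    hi = big.max(axis=1)            # (n, 2)
    lo = small.min(axis=1)
    size = hi - lo
    center = (hi + lo) / 2.0
    exp_size = size * (1.0 + expand_frac)
    if np.any(exp_size[:, 1] <= 0):
        bad = int(np.flatnonzero(exp_size[:, 1] <= 0)[0])
        raise PreprocessError(
            f"degenerate enclosing rectangle (zero height) at frame "
            f"{seq.frame_index[bad]}"
        )
    origin = center - exp_size / 2.0
    s = target_height / exp_size[:, 1]
    norm_xy = (xy - origin[:, None, :]) * s[:, None, None]
    # invisible keypoints keep no meaningful position; zero them for hygiene
    norm_xy = np.where(valid[:, :, None], norm_xy, 0.0)
    return NormalizedSequence(
        subject_id=seq.subject_id,
        test_id=seq.test_id,
        fps=seq.fps,
        frame_index=seq.frame_index.copy(),
        xy=norm_xy,
        conf=seq.conf.copy(),
        rect_origin=origin,
        rect_size=exp_size,
        scale=s,
    )


@dataclass
class DerivedSignalSet:
    """Named kinematic channels, all the same length, sampled at ``fps``."""

    fps: float
    channels: dict[str, np.ndarray]
    subject_id: str = ""
    test_id: str = ""

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.channels)


def channel_names() -> list[str]:
    """Deterministic full channel-bank order."""
    names = []
    for kind in ("pos", "speed", "acc"):
        for k in KEYPOINT_NAMES:
            for ax in AXES:
                names.append(f"{kind}_{k}_{ax}")
    names += ["knee_angle_L", "knee_angle_R"]
    names += [f"pairdiff_{pair}_x" for pair, _, _ in LR_PAIRS]
    return names


def _forward_diff(x: np.ndarray, fps: float) -> np.ndarray:
    """Forward first difference × fps, last sample replicated."""
    d = np.empty_like(x)
    d[:-1] = np.diff(x, axis=0) * fps
    d[-1] = d[-2]
    return d


def _knee_angle(xy: np.ndarray, hip: int, knee: int, ankle: int) -> np.ndarray:
    """Interior angle at the knee between knee→hip and knee→ankle, degrees.

    Frames with a coincident hip/ankle point carry the previous valid
    value forward (first frame falls back to 180°).
    """
    u = xy[:, hip] - xy[:, knee]
    v = xy[:, ankle] - xy[:, knee]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 0) & (nv > 0)
    cos = np.ones(len(xy))
    cos[ok] = np.clip(
        (u[ok] * v[ok]).sum(axis=1) / (nu[ok] * nv[ok]), -1.0, 1.0
    )
    ang = np.degrees(np.arccos(cos))
    if not ok.all():
        logger.warning("knee angle undefined on %d frames; holding previous value",
                       int((~ok).sum()))
        ang[~ok] = np.nan
        if np.isnan(ang[0]):
            ang[0] = 180.0
        # forward-fill
        idx = np.arange(len(ang))
        good = np.where(~np.isnan(ang), idx, 0)
        np.maximum.accumulate(good, out=good)
        ang = ang[good]
    return ang


def derive_signals(
    nseq: NormalizedSequence,
    lowpass_hz: float | None = None,
) -> DerivedSignalSet:
    """Compute the full signal bank from a normalized sequence.

    ``lowpass_hz`` optionally applies a 4th-order zero-phase Butterworth
    low-pass to the position channels before differencing (off by
    default; human movement energy lives below ~15 Hz).
    """
    if nseq.n_frames < 3:
        raise PreprocessError("need at least 3 frames to derive signals")
    xy = nseq.xy
    if lowpass_hz is not None:
        nyq = nseq.fps / 2.0
        if lowpass_hz < nyq:
            b, a = butter(4, lowpass_hz / nyq)
            xy = filtfilt(b, a, xy, axis=0)

    chans: dict[str, np.ndarray] = {}
    speed = _forward_diff(xy, nseq.fps)
    acc = _forward_diff(speed, nseq.fps)
    for kind, arr in (("pos", xy), ("speed", speed), ("acc", acc)):
        for k, kname in enumerate(KEYPOINT_NAMES):
            for a, ax in enumerate(AXES):
                chans[f"{kind}_{kname}_{ax}"] = np.ascontiguousarray(arr[:, k, a])
    for side, hip, knee, ankle in _KNEE_TRIPLETS:
        chans[f"knee_angle_{side}"] = _knee_angle(xy, hip, knee, ankle)
    for pair, right, left in LR_PAIRS:
        chans[f"pairdiff_{pair}_x"] = np.abs(xy[:, right, 0] - xy[:, left, 0])
    return DerivedSignalSet(
        fps=nseq.fps, channels=chans,
        subject_id=nseq.subject_id, test_id=nseq.test_id,
    )
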