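"""Pose-sequence and annotation I/O for the BODY_25 skeleton layout.

A recording is a time series of 2D keypoint estimates (one skeleton per
frame) in OpenPose's 25-keypoint BODY_25 layout, plus frame-indexed
annotation tracks marking turning intervals and FOG / unknown intervals.
Coordinates are pixels; confidences are unitless in [0, 1].

All frame intervals are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# BODY_25 keypoint order. Index in this tuple == keypoint index.
KEYPOINT_NAMES: tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)
N_KEYPOINTS = 25
KEYPOINT_INDEX: dict[str, int] = {n: i for i, n in enumerate(KEYPOINT_NAMES)}

#: Left/right keypoint pairs whose x-separation collapses during a turn:
#: (pair name, right index, left index).
LR_PAIRS: tuple[tuple[str, int, int], ...] = (
    ("hip", 9, 12),
    ("knee", 10, 13),
    ("ankle", 11, 14),
    ("bigtoe", 22, 19),
    ("shoulder", 2, 5),
    ("elbow", 3, 6),
    ("wrist", 4, 7),
    ("ear", 17, 18),
)

#: Lower-limb keypoints (knees, ankles, heels, toes) — the tremor sites.
LEG_KEYPOINTS: tuple[int, ...] = (10, 11, 13, 14, 19, 20, 21, 22, 23, 24)

DEFAULT_CONF_MIN = 0.1
DEFAULT_FPS = 30.0


class PoseIOError(ValueError):
    """Malformed pose or annotation input."""


@dataclass
class PoseSequence:
    """One recording's keypoint trajectories.

    Attributes
    ----------
    subject_id, test_id : str
        Recording key (e.g. test_id "TUG" or "Narrow").
    fps : float
        Frame rate, frames/s.
    frame_index : (n,) int array, strictly increasing.
    xy : (n, 25, 2) float array of pixel coordinates.
    conf : (n, 25) float array of confidences in [0, 1].
    """

    subject_id: str
    test_id: str
    fps: float
    frame_index: np.ndarray
    xy: np.ndarray
    conf: np.ndarray

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        self.conf = np.asarray(self.conf, dtype=np.float64)
        if self.fps <= 0:
            raise PoseIOError("fps must be positive")
        n = len(self.frame_index)
        if self.xy.shape != (n, N_KEYPOINTS, 2) or self.conf.shape != (n, N_KEYPOINTS):
            raise PoseIOError(
                f"shape mismatch: {n} frames, xy {self.xy.shape}, conf {self.conf.shape}"
            )
        if n and np.any(np.diff(self.frame_index) <= 0):
            raise PoseIOError("frame_index must be strictly increasing")
        if np.any((self.conf < 0) | (self.conf > 1)):
            raise PoseIOError("confidence outside [0, 1]")
        valid = self.conf > 0
        if not np.all(np.isfinite(self.xy[valid])):
            raise PoseIOError("non-finite coordinates at positive confidence")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def copy(self) -> "PoseSequence":
        return replace(
            self,
            frame_index=self.frame_index.copy(),
            xy=self.xy.copy(),
            conf=self.conf.copy(),
        )


@dataclass
class AnnotationTrack:
    """Frame-indexed stage and FOG interval annotations.

    Each interval is half-open ``[start_frame, end_frame)``.  FOG and
    unknown intervals must be mutually disjoint: a span is either
    certainly FOG, certainly ambiguous, or (implicitly) non-FOG.
    """

    turn_intervals: list[tuple[int, int]] = field(default_factory=list)
    fog_intervals: list[tuple[int, int]] = field(default_factory=list)
    unknown_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("turn_intervals", "fog_intervals", "unknown_intervals"):
            ivs = sorted((int(a), int(b)) for a, b in getattr(self, name))
            for a, b in ivs:
                if a < 0 or a >= b:
                    raise PoseIOError(f"invalid interval [{a}, {b}) in {name}")
            setattr(self, name, ivs)
        for fa, fb in self.fog_intervals:
            for ua, ub in self.unknown_intervals:
                if fa < ub and ua < fb:
                    raise PoseIOError(
                        f"fog [{fa},{fb}) overlaps unknown [{ua},{ub})"
                    )

    def validate_length(self, n_frames: int) -> None:
        for name in ("turn_intervals", "fog_intervals", "unknown_intervals"):
            for a, b in getattr(self, name):
                if b > n_frames:
                    raise PoseIOError(
                        f"{name} interval [{a},{b}) exceeds sequence length {n_frames}"
                    )

    def mask(self, kind: str, n_frames: int) -> np.ndarray:
        """Boolean per-frame mask for 'turn', 'fog' or 'unknown'."""
        m = np.zeros(n_frames, dtype=bool)
        for a, b in getattr(self, f"{kind}_intervals"):
            m[a:min(b, n_frames)] = True
        return m


# ---------------------------------------------------------------------------
# OpenPose per-frame JSON reading
# ---------------------------------------------------------------------------

_FRAME_NUM_RE = re.compile(r"(\d+)")


def _person_bbox_area(xy: np.ndarray, conf: np.ndarray) -> float:
    v = conf > 0
    if v.sum() == 0:
        return 0.0
    p = xy[v]
    return float((p[:, 0].max() - p[:, 0].min()) * (p[:, 1].max() - p[:, 1].min()))


def select_person(
    people: Sequence[tuple[np.ndarray, np.ndarray]],
    min_valid_keypoints: int = 13,
) -> int:
    """Pick the index of the subject among detected skeletons.

    Default policy: the largest keypoint bounding-box area among persons
    with at least ``min_valid_keypoints`` keypoints of positive
    confidence (the walking subject dominates the frame); ties break to
    the lower person index, so the choice is deterministic.
    """
    best, best_area = -1, -np.inf
    for i, (xy, conf) in enumerate(people):
        if int((conf > 0).sum()) < min_valid_keypoints:
            continue
        area = _person_bbox_area(xy, conf)
        if area > best_area:
            best, best_area = i, area
    if best < 0:  # no person passed the validity gate; fall back to raw area
        areas = [_person_bbox_area(xy, conf) for xy, conf in people]
        best = int(np.argmax(areas))
    return best


def _parse_people(record: dict, where: str) -> list[tuple[np.ndarray, np.ndarray]]:
    try:
        people = record["people"]
    except (TypeError, KeyError) as exc:
        raise PoseIOError(f"malformed record at {where}: missing 'people'") from exc
    out = []
    for j, person in enumerate(people):
        try:
            flat = np.asarray(person["pose_keypoints_2d"], dtype=float)
        except (TypeError, KeyError) as exc:
            raise PoseIOError(
                f"malformed record at {where}, person {j}: missing pose_keypoints_2d"
            ) from exc
        if flat.size != 3 * N_KEYPOINTS:
            raise PoseIOError(
                f"malformed record at {where}, person {j}: expected "
                f"{3 * N_KEYPOINTS} values, got {flat.size}"
            )
        triplets = flat.reshape(N_KEYPOINTS, 3)
        out.append((triplets[:, :2].copy(), triplets[:, 2].copy()))
    return out


def read_openpose_sequence(
    source: str | Path | Iterable[dict],
    subject_id: str = "",
    test_id: str = "",
    fps: float = DEFAULT_FPS,
    person_policy=select_person,
    allow_empty: bool = False,
) -> PoseSequence:
    """Read a per-frame OpenPose keypoint stream into a :class:`PoseSequence`.

    ``source`` is either a directory of per-frame ``*.json`` files (frame
    index parsed from the last run of digits in the stem, the OpenPose
    file-naming convention) or an iterable of already-parsed per-frame
    dicts of the form ``{"people": [{"pose_keypoints_2d": [...]}]}``.

    One skeleton per frame is selected by ``person_policy``.  A frame with
    zero detected persons raises unless ``allow_empty``, in which case an
    all-zero-confidence frame is emitted.
    """
    if isinstance(source, (str, Path)):
        paths = sorted(Path(source).glob("*.json"))
        if not paths:
            raise PoseIOError(f"no per-frame JSON files under {source}")
        records = []
        for p in paths:
            nums = _FRAME_NUM_RE.findall(p.stem)
            idx = int(nums[-1]) if nums else len(records)
            with open(p) as fh:
                try:
                    records.append((idx, json.load(fh), p.name))
                except json.JSONDecodeError as exc:
                    raise PoseIOError(f"malformed record in {p.name}: {exc}") from exc
    else:
        records = [(i, rec, f"record {i}") for i, rec in enumerate(source)]

    records.sort(key=lambda r: r[0])
    idxs, xys, confs = [], [], []
    for idx, rec, where in records:
        people = _parse_people(rec, where)
        if not people:
            if not allow_empty:
                raise PoseIOError(f"zero persons at {where}")
            xy = np.zeros((N_KEYPOINTS, 2))
            cf = np.zeros(N_KEYPOINTS)
        else:
            sel = person_policy(people)
            xy, cf = people[sel]
        idxs.append(idx)
        xys.append(xy)
        confs.append(np.clip(cf, 0.0, 1.0))
    return PoseSequence(subject_id, test_id, fps,
                        np.array(idxs), np.array(xys), np.array(confs))


# ---------------------------------------------------------------------------
# Native tabular formats (consolidated sequence CSV, annotation TSV)
# ---------------------------------------------------------------------------

def write_sequence(seq: PoseSequence, path: str | Path) -> None:
    """Write the consolidated long-format table: frame, keypoint, x, y, confidence."""
    n = seq.n_frames
    df = pd.DataFrame(
        {
            "frame": np.repeat(seq.frame_index, N_KEYPOINTS),
            "keypoint": np.tile(np.arange(N_KEYPOINTS), n),
            "x": seq.xy[:, :, 0].ravel(),
            "y": seq.xy[:, :, 1].ravel(),
            "confidence": seq.conf.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# subject_id={seq.subject_id} test_id={seq.test_id} fps={seq.fps!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_sequence(path: str | Path) -> PoseSequence:
    with open(path) as fh:
        header = fh.readline()
        m = re.match(r"#\s*subject_id=(\S*)\s+test_id=(\S*)\s+fps=(\S+)", header)
        if not m:
            raise PoseIOError(f"missing sequence header line in {path}")
        subject_id, test_id, fps = m.group(1), m.group(2), float(m.group(3))
        df = pd.read_csv(fh, float_precision="round_trip")
    frames = np.sort(df["frame"].unique())
    piv = df.set_index(["frame", "keypoint"]).sort_index()
    n = len(frames)
    xy = np.empty((n, N_KEYPOINTS, 2))
    xy[:, :, 0] = piv["x"].to_numpy().reshape(n, N_KEYPOINTS)
    xy[:, :, 1] = piv["y"].to_numpy().reshape(n, N_KEYPOINTS)
    conf = piv["confidence"].to_numpy().reshape(n, N_KEYPOINTS)
    return PoseSequence(subject_id, test_id, fps, frames, xy, conf)


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    """Write the annotation TSV: one interval per line (label, start, end)."""
    with open(path, "w") as fh:
        fh.write("label\tstart_frame\tend_frame\n")
        for label, key in (("turn", "turn_intervals"),
                           ("fog", "fog_intervals"),
                           ("unknown", "unknown_intervals")):
            for a, b in getattr(track, key):
                fh.write(f"{label}\t{a}\t{b}\n")


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read the annotation TSV; interval invariants are re-validated."""
    kinds: dict[str, list[tuple[int, int]]] = {"turn": [], "fog": [], "unknown": []}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("label\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PoseIOError(f"{path}:{ln}: expected 3 tab-separated fields")
            label, a, b = parts[0], int(parts[1]), int(parts[2])
            if label not in kinds:
                raise PoseIOError(f"{path}:{ln}: unknown label {label!r}")
            kinds[label].append((a, b))
    return AnnotationTrack(kinds["turn"], kinds["fog"], kinds["unknown"])


# ---------------------------------------------------------------------------
# Low-confidence keypoint repair
# ---------------------------------------------------------------------------

def interpolate_low_confidence(
    seq: PoseSequence, conf_min: float = DEFAULT_CONF_MIN
) -> tuple[PoseSequence, float]:
    """Repair dropouts by per-channel linear interpolation in time.

    For each keypoint, frames with confidence below ``conf_min`` get
    coordinates linearly interpolated between the nearest flanking frames
    with confidence >= conf_min; leading/trailing gaps take the nearest
    valid value.  Repaired confidences are set to ``conf_min`` so the
    operation is idempotent.  Returns the repaired sequence and the
    fraction of keypoint-frames repaired.
    """
    if not 0 <= conf_min < 1:
        raise ValueError("conf_min must be in [0, 1)")
    out = seq.copy()
    t = seq.frame_index.astype(float)
    n_bad_total = 0
    for k in range(N_KEYPOINTS):
        valid = seq.conf[:, k] >= conf_min
        bad = ~valid
        if not bad.any():
            continue
        if not valid.any():
            raise PoseIOError(
                f"keypoint channel {KEYPOINT_NAMES[k]} has zero frames with "
                f"confidence >= {conf_min}"
            )
        for ax in range(2):
            out.xy[bad, k, ax] = np.interp(t[bad], t[valid], seq.xy[valid, k, ax])
        out.conf[bad, k] = conf_min
        n_bad_total += int(bad.sum())
    frac = n_bad_total / (seq.n_frames * N_KEYPOINTS) if seq.n_frames else 0.0
    return out, frac
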