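"""Synthetic 2D gait recordings with exact walk/turn/FOG ground truth.

The generator produces BODY_25 keypoint sequences with the statistical
structure the recognition pipeline relies on, so the full stack is
testable without any recorded video:

* **walking** — limb keypoints oscillate in the locomotor band
  (cadence ~0.8–1.2 Hz, left/right antiphase) while the apparent body
  scale ramps smoothly (the subject approaches or recedes from a fixed
  camera), exercising the per-frame scale normalization;
* **turning** — every left–right x-separation is scaled by |cos(pi u)|
  across the turn, collapsing toward 0 and re-expanding while the
  camera-axis translation pauses;
* **FOG** — locomotor oscillation amplitude is suppressed to 5%,
  lower-limb keypoints gain a 6–8 Hz tremor, and forward progression is
  arrested;

plus per-keypoint Gaussian jitter and confidence-0 dropouts.
Kinematics are stylized sinusoids, not biomechanics: they carry the
spectral and geometric signatures the feature bank measures, nothing
more.  Annotations are exact by construction.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .pose_io import (
    AnnotationTrack,
    LEG_KEYPOINTS,
    N_KEYPOINTS,
    PoseSequence,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Study conditions for the synthetic cohort.

    Frequencies are Hz, durations seconds, amplitudes in template units
    (the skeleton template has height 1; ``gait_amp`` 0.05 is a 5%-of-
    body-height limb excursion), pixel quantities in pixels.
    """

    n_subjects: int = 12
    fog_prevalence: float = 0.26       # fraction of subjects with FOG (13/50 clinically)
    fps: float = 30.0
    tests: tuple[str, ...] = ("TUG", "Narrow")
    walk_s: tuple[float, float] = (8.0, 11.0)    # per walking segment
    turn_s: tuple[float, float] = (2.0, 3.0)     # per turning segment
    cadence_hz: tuple[float, float] = (0.8, 1.2)
    tremor_hz: tuple[float, float] = (6.0, 8.0)
    gait_amp: float = 0.05
    tremor_amp: float = 0.02
    fog_suppression: float = 0.05      # locomotor amplitude multiplier during FOG
    fog_ramp_s: float = 0.6            # raised-cosine onset/offset of the FOG regime
    approach_scale_range: tuple[float, float] = (1.0, 1.5)
    base_height_px: float = 260.0      # pixel height of the template at scale 1
    noise_sd: float = 1.0              # px jitter
    dropout_rate: float = 0.01         # per keypoint-frame
    fog_duration_s: tuple[float, float] = (1.0, 15.0)
    fog_episodes_per_subject: tuple[int, int] = (1, 4)
    turn_fog_prob: float = 0.25        # clinical split: 8 of 33 episodes in turns
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.fog_prevalence, self.dropout_rate):
            if not 0 <= frac <= 1:
                raise SimulationError("rates/fractions must lie in [0, 1]")
        for f in (*self.cadence_hz, *self.tremor_hz):
            if f >= self.fps / 2:
                raise SimulationError("oscillation frequencies must be below Nyquist")


#: Front-view standing template: (x, y) per BODY_25 keypoint; y down,
#: head top at 0, feet at 1; right-side keypoints at negative x.
_TEMPLATE = np.array([
    (0.000, 0.060),   # Nose
    (0.000, 0.170),   # Neck
    (-0.110, 0.180),  # RShoulder
    (-0.140, 0.330),  # RElbow
    (-0.150, 0.470),  # RWrist
    (0.110, 0.180),   # LShoulder
    (0.140, 0.330),   # LElbow
    (0.150, 0.470),   # LWrist
    (0.000, 0.520),   # MidHip
    (-0.070, 0.520),  # RHip
    (-0.080, 0.720),  # RKnee
    (-0.080, 0.920),  # RAnkle
    (0.070, 0.520),   # LHip
    (0.080, 0.720),   # LKnee
    (0.080, 0.920),   # LAnkle
    (-0.020, 0.045),  # REye
    (0.020, 0.045),   # LEye
    (-0.045, 0.055),  # REar
    (0.045, 0.055),   # LEar
    (0.080, 0.980),   # LBigToe
    (0.100, 0.980),   # LSmallToe
    (0.080, 0.940),   # LHeel
    (-0.080, 0.980),  # RBigToe
    (-0.100, 0.980),  # RSmallToe
    (-0.080, 0.940),  # RHeel
])

# per-keypoint gait-oscillation gains: (x gain, y gain, side sign)
# legs swing vertically, arms swing horizontally, head bobs a little.
_SIDE = np.zeros(N_KEYPOINTS)
for _i in (2, 3, 4, 9, 10, 11, 22, 23, 24, 15, 17):
    _SIDE[_i] = -1.0
for _i in (5, 6, 7, 12, 13, 14, 19, 20, 21, 16, 18):
    _SIDE[_i] = 1.0
_GAIT_Y = np.zeros(N_KEYPOINTS)
for _i in (10, 13):          # knees
    _GAIT_Y[_i] = 0.6
for _i in (11, 14, 21, 24):  # ankles, heels
    _GAIT_Y[_i] = 1.0
for _i in (19, 20, 22, 23):  # toes
    _GAIT_Y[_i] = 1.1
_GAIT_X = np.zeros(N_KEYPOINTS)
for _i in (3, 6):            # elbows
    _GAIT_X[_i] = 0.4
for _i in (4, 7):            # wrists
    _GAIT_X[_i] = 0.8
for _i in (11, 14, 21, 24, 19, 20, 22, 23):  # feet swing slightly in x
    _GAIT_X[_i] = 0.25
_HEAD_BOB = np.zeros(N_KEYPOINTS)
for _i in (0, 1, 15, 16, 17, 18):
    _HEAD_BOB[_i] = 0.15

_LEG_MASK = np.zeros(N_KEYPOINTS)
_LEG_MASK[list(LEG_KEYPOINTS)] = 1.0

IMAGE_CENTER = (272.0, 480.0)  # 544 x 960 portrait frame


@dataclass
class SubjectTraits:
    cadence_hz: float
    tremor_hz: float
    gait_amp: float
    tremor_amp: float


@dataclass
class SimulatedRecording:
    sequence: PoseSequence
    annotations: AnnotationTrack
    log: dict = field(default_factory=dict)


def _draw_traits(params: SimParams, rng: np.random.Generator) -> SubjectTraits:
    return SubjectTraits(
        cadence_hz=float(rng.uniform(*params.cadence_hz)),
        tremor_hz=float(rng.uniform(*params.tremor_hz)),
        gait_amp=float(params.gait_amp * rng.uniform(0.8, 1.2)),
        tremor_amp=float(params.tremor_amp * rng.uniform(0.8, 1.2)),
    )


def _plan_segments(params: SimParams, rng: np.random.Generator) -> list[tuple[str, int]]:
    """walk→turn→walk segment plan in frames."""
    fps = params.fps
    plan = []
    for label, rng_s in (("walk", params.walk_s), ("turn", params.turn_s),
                         ("walk", params.walk_s)):
        dur = rng.uniform(*rng_s)
        plan.append((label, int(round(dur * fps))))
    return plan


def _place_fog_episodes(
    segments: list[tuple[str, int, int]],
    n_episodes: int,
    params: SimParams,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Place non-overlapping FOG intervals (frames) inside segments."""
    fps = params.fps
    placed: list[tuple[int, int]] = []
    for _ in range(n_episodes):
        for _attempt in range(30):
            want_turn = rng.uniform() < params.turn_fog_prob
            candidates = [s for s in segments if (s[0] == "turn") == want_turn]
            if not candidates:
                candidates = segments
            label, a, b = candidates[rng.integers(len(candidates))]
            margin = int(round((0.5 if label == "turn" else 1.0) * fps))
            dur_f = int(round(rng.uniform(*params.fog_duration_s) * fps))
            dur_f = min(dur_f, b - a - 2 * margin)
            if dur_f < int(round(params.fog_duration_s[0] * fps)):
                continue
            start = int(rng.integers(a + margin, b - margin - dur_f + 1))
            iv = (start, start + dur_f)
            if all(iv[1] + int(fps) <= p[0] or p[1] + int(fps) <= iv[0] for p in placed):
                placed.append(iv)
                break
    return sorted(placed)


def simulate_recording(
    params: SimParams,
    subject_seed: int,
    subject_id: str = "S00",
    test_id: str = "TUG",
    n_fog_episodes: int = 0,
    traits: SubjectTraits | None = None,
) -> SimulatedRecording:
    """Generate one recording; deterministic under (params.seed, subject_seed, test_id)."""
    rng = np.random.default_rng(
        [params.seed, subject_seed, zlib.crc32(test_id.encode()) % (2 ** 31)]
    )
    if traits is None:
        traits = _draw_traits(params, rng)
    fps = params.fps
    plan = _plan_segments(params, rng)
    n_window = int(round(2.0 * fps))
    if sum(f for _, f in plan) < 2 * n_window:
        raise SimulationError("segment plan shorter than 2 windows")

    # absolute segment bounds
    segments: list[tuple[str, int, int]] = []
    cursor = 0
    for label, nf in plan:
        segments.append((label, cursor, cursor + nf))
        cursor += nf
    n_frames = cursor

    fog_ivs = _place_fog_episodes(segments, n_fog_episodes, params, rng)
    fog_mask = np.zeros(n_frames, dtype=bool)
    for a, b in fog_ivs:
        fog_mask[a:b] = True
    turn_ivs = [(a, b) for label, a, b in segments if label == "turn"]
    turn_mask = np.zeros(n_frames, dtype=bool)
    for a, b in turn_ivs:
        turn_mask[a:b] = True

    # --- per-frame state trajectories -------------------------------------
    # FOG intensity in [0, 1]: 1 deep inside an episode, raised-cosine
    # ramps inside its annotated bounds (freezing builds up and releases
    # gradually; the annotation marks the full episode incl. transitions)
    fog_f = np.zeros(n_frames)
    ramp_f = max(int(round(params.fog_ramp_s * fps)), 1)
    for a, b in fog_ivs:
        r = min(ramp_f, (b - a) // 2)
        prof = np.ones(b - a)
        if r > 0:
            edge = 0.5 * (1 - np.cos(math.pi * np.arange(1, r + 1) / r))
            prof[:r] = edge
            prof[-r:] = edge[::-1]
        fog_f[a:b] = prof

    phi = np.cumsum(np.full(n_frames, 2 * math.pi * traits.cadence_hz / fps))
    psi = np.cumsum(np.where(fog_f > 0, 2 * math.pi * traits.tremor_hz / fps, 0.0))

    # turn progress u in [0, 1] inside each turn segment
    turn_factor = np.ones(n_frames)
    for a, b in turn_ivs:
        u = np.arange(b - a) / max(b - a - 1, 1)
        turn_factor[a:b] = np.abs(np.cos(math.pi * u))

    # apparent-scale ramp: progression weight fades with FOG intensity,
    # alternating direction per walking segment
    lo, hi = params.approach_scale_range
    m = np.empty(n_frames)
    cur = lo
    direction = 1.0
    for label, a, b in segments:
        if label != "walk":
            m[a:b] = cur
            continue
        weight = 1.0 - fog_f[a:b]
        total = max(float(weight.sum()), 1.0)
        target = hi if direction > 0 else lo
        inc = weight * ((target - cur) / total)
        m[a:b] = cur + np.cumsum(inc)
        cur = m[b - 1]
        direction = -direction

    # --- assemble keypoints ----------------------------------------------
    amp = traits.gait_amp * (1.0 - (1.0 - params.fog_suppression) * fog_f)
    osc = np.sin(phi)
    gait_dx = (amp * osc)[:, None] * (_GAIT_X * _SIDE)[None, :]
    gait_dy = (amp * osc)[:, None] * (_GAIT_Y * _SIDE)[None, :] \
        + (amp * np.abs(np.sin(2 * phi)))[:, None] * _HEAD_BOB[None, :]
    trem_dy = (traits.tremor_amp * np.sin(psi) * fog_f)[:, None] \
        * (_LEG_MASK * _SIDE)[None, :]

    x_t = _TEMPLATE[None, :, 0] * turn_factor[:, None] + gait_dx
    y_t = _TEMPLATE[None, :, 1] + gait_dy + trem_dy

    scale_px = params.base_height_px * m
    cx, cy = IMAGE_CENTER
    xy = np.empty((n_frames, N_KEYPOINTS, 2))
    xy[:, :, 0] = cx + x_t * scale_px[:, None]
    xy[:, :, 1] = cy + (y_t - 0.5) * scale_px[:, None]

    xy += rng.normal(0.0, params.noise_sd, size=xy.shape)
    conf = rng.uniform(0.6, 1.0, size=(n_frames, N_KEYPOINTS))
    drop = rng.uniform(size=conf.shape) < params.dropout_rate
    conf[drop] = 0.0

    seq = PoseSequence(
        subject_id=subject_id, test_id=test_id, fps=fps,
        frame_index=np.arange(n_frames), xy=xy, conf=conf,
    )
    ann = AnnotationTrack(turn_intervals=turn_ivs, fog_intervals=fog_ivs)
    log = {
        "segments": [(label, a, b) for label, a, b in segments],
        "fog_intervals": fog_ivs,
        "traits": asdict(traits),
        "subject_seed": subject_seed,
        "test_id": test_id,
    }
    return SimulatedRecording(sequence=seq, annotations=ann, log=log)


def simulate_cohort(params: SimParams) -> list[SimulatedRecording]:
    """Generate the full cohort: per-subject trait draws, FOG subjects chosen
    deterministically, 1–4 FOG episodes per affected subject spread over
    that subject's recordings."""
    if params.n_subjects < 2:
        raise SimulationError("need at least 2 subjects")
    rng = np.random.default_rng([params.seed, 987654321])
    n_fog_subjects = math.ceil(params.fog_prevalence * params.n_subjects)
    fog_subjects = set(
        rng.choice(params.n_subjects, size=n_fog_subjects, replace=False).tolist()
    )
    recordings: list[SimulatedRecording] = []
    for s in range(params.n_subjects):
        subject_id = f"S{s + 1:02d}"
        traits_rng = np.random.default_rng([params.seed, 7, s])
        traits = _draw_traits(params, traits_rng)
        if s in fog_subjects:
            k = int(traits_rng.integers(params.fog_episodes_per_subject[0],
                                        params.fog_episodes_per_subject[1] + 1))
        else:
            k = 0
        # spread episodes over this subject's recordings
        counts = [0] * len(params.tests)
        for _ in range(k):
            counts[int(traits_rng.integers(len(params.tests)))] += 1
        for t, test_id in enumerate(params.tests):
            rec = simulate_recording(
                params, subject_seed=s, subject_id=subject_id, test_id=test_id,
                n_fog_episodes=counts[t], traits=traits,
            )
            recordings.append(rec)
    return recordings


def cohort_manifest(recordings: Sequence[SimulatedRecording]) -> list[dict]:
    """Flat per-recording summary (subject, test, frames, FOG episodes)."""
    out = []
    for rec in recordings:
        out.append(
            {
                "subject_id": rec.sequence.subject_id,
                "test_id": rec.sequence.test_id,
                "n_frames": int(rec.sequence.n_frames),
                "fps": rec.sequence.fps,
                "n_fog_episodes": len(rec.annotations.fog_intervals),
                "fog_intervals": [list(iv) for iv in rec.annotations.fog_intervals],
                "turn_intervals": [list(iv) for iv in rec.annotations.turn_intervals],
            }
        )
    return out
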