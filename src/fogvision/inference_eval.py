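"""Multi-stage inference, episode extraction, and evaluation.

Prediction routes each window through the motion model first: windows
classified as walking are scored by the Walk-FOG model, turning windows
by the Turn-FOG model.  Consecutive equal window decisions merge into
episodes; predicted FOG episodes shorter than the duration threshold
(the 10% quantile of annotated FOG durations in the training folds) are
relabeled non-FOG.

Evaluation is leave-one-subject-out: each fold trains on all other
subjects and scores the held-out subject, so no window of a subject can
influence feature ranking, SMOTE, grid search or the duration threshold
applied to it.  Window metrics (sensitivity, specificity, accuracy, GM,
AUC) apply to the motion model; the FOG task is scored per episode — a
truth FOG episode counts as detected when at least one predicted-FOG
window overlaps it, and a truth non-FOG episode as correct only when
none does.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import META_COLUMNS, feature_columns
from .modeling import (
    ModelConfig,
    ModelingError,
    StagedModelBundle,
    StageModel,
    _train_fog_stage,
    fog_boundaries_s,
    gm_score,
    train_staged_bundle,
    duration_threshold,
    fog_episode_durations_s,
)
from .pose_io import AnnotationTrack

logger = logging.getLogger(__name__)

GAP_TOL = 1e-6


class EvaluationError(ValueError):
    pass


def gm_from_rates(sensitivity: float, specificity: float) -> float:
    """Geometric mean of a sensitivity/specificity pair: sqrt(sens * spec)."""
    return float(np.sqrt(sensitivity * specificity))


# ---------------------------------------------------------------------------
# Window predictions
# ---------------------------------------------------------------------------

def predict_multistage(
    matrix: pd.DataFrame,
    bundle: StagedModelBundle,
    decision_threshold: float = 0.5,
) -> pd.DataFrame:
    """Stage-routed window predictions.

    Returns the meta columns plus ``stage_pred``, ``fog_score`` and
    ``fog_pred`` (fog_pred = fog_score >= decision_threshold).
    """
    preds = matrix[list(META_COLUMNS)].copy()
    stage_score = bundle.motion.predict_score(matrix)
    stage_pred = np.where(stage_score >= decision_threshold, "turn", "walk")
    fog_score = np.empty(len(matrix))
    walk_rows = stage_pred == "walk"
    if walk_rows.any():
        fog_score[walk_rows] = bundle.walk_fog.predict_score(matrix[walk_rows])
    if (~walk_rows).any():
        fog_score[~walk_rows] = bundle.turn_fog.predict_score(matrix[~walk_rows])
    preds["stage_score"] = stage_score
    preds["stage_pred"] = stage_pred
    preds["fog_score"] = fog_score
    preds["fog_pred"] = np.where(fog_score >= decision_threshold, "fog", "nonfog")
    return preds


def predict_single_stage(
    matrix: pd.DataFrame,
    fog_model: StageModel,
    decision_threshold: float = 0.5,
) -> pd.DataFrame:
    """Non-staged comparator: one FOG model scores every window."""
    preds = matrix[list(META_COLUMNS)].copy()
    fog_score = fog_model.predict_score(matrix)
    preds["stage_score"] = np.nan
    preds["stage_pred"] = ""
    preds["fog_score"] = fog_score
    preds["fog_pred"] = np.where(fog_score >= decision_threshold, "fog", "nonfog")
    return preds


# ---------------------------------------------------------------------------
# Episodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Episode:
    label: str        # fog | nonfog
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def overlaps(self, other: "Episode") -> bool:
        return self.t_start < other.t_end and other.t_start < self.t_end


def windows_to_episodes(
    preds: pd.DataFrame,
    step_s: float = 0.1,
    label_column: str = "fog_pred",
) -> list[Episode]:
    """Merge maximal runs of equal window labels into episodes.

    ``preds`` must be the windows of a single recording.  An episode
    spans from the first window's t_start to the last window's t_end.
    A gap between consecutive windows larger than the step splits
    episodes even when the label matches.
    """
    if preds.empty:
        return []
    keys = preds[["subject_id", "test_id"]].drop_duplicates()
    if len(keys) > 1:
        raise EvaluationError("windows_to_episodes expects a single recording")
    p = preds.sort_values("t_start")
    t0 = p["t_start"].to_numpy()
    t1 = p["t_end"].to_numpy()
    labels = p[label_column].to_numpy()
    episodes: list[Episode] = []
    run_start, prev_label = 0, labels[0]
    for i in range(1, len(p) + 1):
        boundary = i == len(p)
        if not boundary:
            gap = t0[i] - t0[i - 1] > step_s + GAP_TOL
            boundary = labels[i] != prev_label or gap
        if boundary:
            episodes.append(Episode(str(prev_label), float(t0[run_start]),
                                    float(t1[i - 1])))
            if i < len(p):
                run_start, prev_label = i, labels[i]
    return episodes


def _merge_adjacent(episodes: Sequence[Episode]) -> list[Episode]:
    out: list[Episode] = []
    for ep in episodes:
        if out and out[-1].label == ep.label and ep.t_start - out[-1].t_end <= GAP_TOL:
            out[-1] = Episode(ep.label, out[-1].t_start, ep.t_end)
        else:
            out.append(ep)
    return out


def postprocess_episodes(
    episodes: Sequence[Episode], min_dur_s: float
) -> list[Episode]:
    """Relabel FOG episodes shorter than ``min_dur_s`` as non-FOG and merge.

    Idempotent; the FOG episode count never increases.
    """
    if min_dur_s < 0:
        raise EvaluationError("min_dur_s must be >= 0")
    relabeled = [
        Episode("nonfog", ep.t_start, ep.t_end)
        if ep.label == "fog" and ep.duration < min_dur_s else ep
        for ep in episodes
    ]
    return _merge_adjacent(relabeled)


def apply_duration_filter(
    preds: pd.DataFrame,
    min_dur_s: float,
    step_s: float = 0.1,
) -> pd.DataFrame:
    """Relabel windows of short predicted FOG runs as non-FOG.

    The window-level counterpart of :func:`postprocess_episodes`: maximal
    runs of predicted-FOG windows whose merged span is shorter than
    ``min_dur_s`` flip to non-FOG.  ``preds`` must belong to a single
    recording.
    """
    if preds.empty or min_dur_s <= 0:
        return preds.copy()
    out = preds.sort_values("t_start").copy()
    t0 = out["t_start"].to_numpy()
    t1 = out["t_end"].to_numpy()
    fog = (out["fog_pred"] == "fog").to_numpy()
    new_labels = out["fog_pred"].to_numpy().copy()
    i = 0
    n = len(out)
    while i < n:
        if not fog[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and fog[j + 1]
               and t0[j + 1] - t0[j] <= step_s + GAP_TOL):
            j += 1
        if t1[j] - t0[i] < min_dur_s:
            new_labels[i:j + 1] = "nonfog"
        i = j + 1
    out["fog_pred"] = new_labels
    return out


def truth_episodes(
    annotations: AnnotationTrack, n_frames: int, fps: float
) -> list[Episode]:
    """FOG / non-FOG truth partition of a recording's timeline.

    Unknown spans are excluded; episodes are the maximal runs of equal
    certain labels between them.
    """
    fog = annotations.mask("fog", n_frames)
    unknown = annotations.mask("unknown", n_frames)
    episodes: list[Episode] = []
    state, start = None, 0
    for i in range(n_frames + 1):
        lab = None
        if i < n_frames and not unknown[i]:
            lab = "fog" if fog[i] else "nonfog"
        if lab != state:
            if state is not None:
                episodes.append(Episode(state, start / fps, i / fps))
            state, start = lab, i
    return episodes


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    sensitivity: float = np.nan
    specificity: float = np.nan
    accuracy: float = np.nan
    gm: float = np.nan
    auc: float | None = None
    counts: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "gm": self.gm,
            "counts": dict(self.counts),
            "flags": list(self.flags),
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    ranks = stats.rankdata(scores)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def window_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> MetricsReport:
    """Confusion-matrix rates over windows; AUC from rank statistics."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = int((y_true & y_pred).sum())
    tn = int((~y_true & ~y_pred).sum())
    fp = int((~y_true & y_pred).sum())
    fn = int((y_true & ~y_pred).sum())
    rep = MetricsReport(counts={"tp": tp, "tn": tn, "fp": fp, "fn": fn})
    flags = []
    if tp + fn:
        rep.sensitivity = tp / (tp + fn)
    else:
        flags.append("no_positive_truth")
    if tn + fp:
        rep.specificity = tn / (tn + fp)
    else:
        flags.append("no_negative_truth")
    total = tp + tn + fp + fn
    if total:
        rep.accuracy = (tp + tn) / total
    rep.gm = gm_from_rates(rep.sensitivity, rep.specificity)
    if scores is not None:
        rep.auc = _rank_auc(y_true, np.asarray(scores, dtype=float))
    rep.flags = flags
    return rep


def episode_metrics(
    pred_windows: Mapping[tuple, pd.DataFrame] | pd.DataFrame,
    truth_eps: Mapping[tuple, Sequence[Episode]] | Sequence[Episode],
) -> MetricsReport:
    """Episode-level rates from final window predictions.

    Accepts either per-recording mappings (pooled evaluation) or the
    predictions/episodes of a single recording.  A window belongs to
    the truth episode containing its midpoint — the same majority logic
    that labels windows — so a 2 s window straddling a FOG boundary
    counts toward the side holding most of it.  A truth FOG episode is
    detected when at least one predicted-FOG window lies in it; a truth
    non-FOG episode is correct when none does.  Windows with unknown
    truth labels are ignored.
    """
    if not isinstance(pred_windows, Mapping):
        pred_windows = {("", ""): pred_windows}
        truth_eps = {("", ""): list(truth_eps)}
    tp = fn = tn = fp = 0
    for key, t_eps in truth_eps.items():
        preds = pred_windows.get(key)
        if preds is None or preds.empty:
            mids = np.empty(0)
        else:
            known = preds[preds["fog_label"] != "unknown"] \
                if "fog_label" in preds.columns else preds
            fog_rows = known[known["fog_pred"] == "fog"]
            mids = ((fog_rows["t_start"] + fog_rows["t_end"]) / 2.0).to_numpy()
        for ep in t_eps:
            # tolerance keeps grid-aligned midpoints off the wrong side of
            # an episode boundary under float noise
            hit = bool(np.any((mids >= ep.t_start - GAP_TOL)
                              & (mids < ep.t_end - GAP_TOL)))
            if ep.label == "fog":
                tp += hit
                fn += not hit
            else:
                fp += hit
                tn += not hit
    rep = MetricsReport(counts={"tp": tp, "tn": tn, "fp": fp, "fn": fn})
    flags = []
    if tp + fn:
        rep.sensitivity = tp / (tp + fn)
    else:
        flags.append("no_truth_fog_episodes")
    if tn + fp:
        rep.specificity = tn / (tn + fp)
    else:
        flags.append("no_truth_nonfog_episodes")
    total = tp + tn + fp + fn
    if total:
        rep.accuracy = (tp + tn) / total
    rep.gm = gm_from_rates(rep.sensitivity, rep.specificity)
    rep.flags = flags
    return rep


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class LosoResult:
    per_fold: list[dict]
    pooled_motion: MetricsReport
    pooled_episode: MetricsReport
    predictions: pd.DataFrame
    pred_episodes: dict
    truth_eps: dict
    fold_fingerprints: dict


def _train_single_fog_model(
    matrix: pd.DataFrame,
    annotations: Mapping[tuple[str, str], tuple[AnnotationTrack, float]],
    config: ModelConfig,
) -> StageModel:
    boundaries = {
        key: fog_boundaries_s(track, fps)
        for key, (track, fps) in annotations.items()
    }
    known = matrix[matrix["fog_label"] != "unknown"]
    return _train_fog_stage("fog", known, boundaries, config)


def loso_evaluate(
    matrix: pd.DataFrame,
    annotations: Mapping[tuple[str, str], tuple[AnnotationTrack, float, int]],
    config: ModelConfig,
    staged: bool = True,
    step_s: float = 0.1,
) -> LosoResult:
    """One fold per subject; pooled metrics over the union of held-out data.

    ``annotations`` maps (subject_id, test_id) to
    (AnnotationTrack, fps, n_frames) for every recording in ``matrix``.
    """
    subjects = sorted(matrix["subject_id"].unique())
    if len(subjects) < 3:
        raise EvaluationError("LOSO needs at least 3 subjects")
    if "fog" not in config.max_selected_features:
        config.max_selected_features["fog"] = 20

    per_fold = []
    all_preds = []
    pred_by_rec: dict = {}
    pred_eps_by_rec: dict = {}
    truth_eps_by_rec: dict = {}
    fingerprints: dict = {}
    for subject in subjects:
        test_mask = matrix["subject_id"] == subject
        test_matrix = matrix[test_mask]
        labeled_test = test_matrix[test_matrix["fog_label"] != "unknown"]
        if labeled_test.empty:
            warnings.warn(f"subject {subject} has no labeled windows; fold skipped",
                          stacklevel=2)
            continue
        train_matrix = matrix[~test_mask]
        train_ann = {
            key: (track, fps)
            for key, (track, fps, _n) in annotations.items()
            if key[0] != subject
        }
        if staged:
            bundle = train_staged_bundle(train_matrix, train_ann, config)
            preds = predict_multistage(test_matrix, bundle,
                                       config.decision_threshold)
            threshold = bundle.fog_duration_threshold_s
            fingerprints[subject] = bundle.provenance["training_fingerprint"]
        else:
            fog_model = _train_single_fog_model(train_matrix, train_ann, config)
            preds = predict_single_stage(test_matrix, fog_model,
                                         config.decision_threshold)
            threshold = duration_threshold(fog_episode_durations_s(train_ann))
            from .modeling import training_fingerprint
            fingerprints[subject] = training_fingerprint(
                train_matrix[train_matrix["fog_label"] != "unknown"]
            )
        fold_preds: dict = {}
        fold_truth_eps: dict = {}
        filtered_parts = []
        for key in preds[["subject_id", "test_id"]].drop_duplicates().itertuples(index=False):
            key = tuple(key)
            rec_preds = preds[
                (preds["subject_id"] == key[0]) & (preds["test_id"] == key[1])
            ]
            rec_known = rec_preds[rec_preds["fog_label"] != "unknown"]
            rec_final = apply_duration_filter(rec_known, threshold, step_s=step_s)
            track, fps, n_frames = annotations[key]
            fold_preds[key] = rec_final
            fold_truth_eps[key] = truth_episodes(track, n_frames, fps)
            filtered_parts.append(rec_final)
            pred_eps_by_rec[key] = windows_to_episodes(rec_final, step_s=step_s)
        truth_eps_by_rec.update(fold_truth_eps)
        pred_by_rec.update(fold_preds)
        all_preds.append(pd.concat(filtered_parts, ignore_index=True))

        known = pd.concat(filtered_parts, ignore_index=True)
        fold = {
            "subject_id": subject,
            "n_test_windows": int(len(known)),
            "fog_duration_threshold_s": float(threshold),
            "episode": episode_metrics(fold_preds, fold_truth_eps).to_dict(),
        }
        if staged:
            fold["motion"] = window_metrics(
                (known["stage_label"] == "turn").to_numpy(),
                (known["stage_pred"] == "turn").to_numpy(),
                known["stage_score"].to_numpy(),
            ).to_dict()
        per_fold.append(fold)

    predictions = pd.concat(all_preds, ignore_index=True)
    pooled_known = predictions[predictions["fog_label"] != "unknown"]
    if staged:
        pooled_motion = window_metrics(
            (pooled_known["stage_label"] == "turn").to_numpy(),
            (pooled_known["stage_pred"] == "turn").to_numpy(),
            pooled_known["stage_score"].to_numpy(),
        )
    else:
        pooled_motion = MetricsReport(flags=["not_applicable"])
    pooled_episode = episode_metrics(pred_by_rec, truth_eps_by_rec)
    return LosoResult(
        per_fold=per_fold,
        pooled_motion=pooled_motion,
        pooled_episode=pooled_episode,
        predictions=predictions,
        pred_episodes=pred_eps_by_rec,
        truth_eps=truth_eps_by_rec,
        fold_fingerprints=fingerprints,
    )


# ---------------------------------------------------------------------------
# Paired per-subject Wilcoxon test
# ---------------------------------------------------------------------------

def paired_subject_wilcoxon(
    matrix: pd.DataFrame,
    feature: str,
    group_label: str = "fog_label",
    groups: tuple[str, str] = ("fog", "nonfog"),
    min_pairs: int = 5,
) -> tuple[float, dict]:
    """Paired Wilcoxon signed-rank test on per-subject group means.

    Windows are autocorrelated and subjects differ in baseline, so the
    test operates on one mean per subject per group.  Subjects missing
    either group are dropped (and counted in the returned info).
    Returns (two-sided p-value, info dict).
    """
    if feature not in matrix.columns:
        raise EvaluationError(f"unknown feature column {feature!r}")
    means = (
        matrix[matrix[group_label].isin(groups)]
        .groupby(["subject_id", group_label], observed=True)[feature]
        .mean()
        .unstack(group_label)
    )
    usable = means.dropna(subset=list(groups))
    n_dropped = len(means) - len(usable)
    if len(usable) < min_pairs:
        raise EvaluationError(
            f"only {len(usable)} subjects have windows in both groups "
            f"(need >= {min_pairs})"
        )
    a = usable[groups[0]].to_numpy()
    b = usable[groups[1]].to_numpy()
    diffs = a - b
    info = {"n_pairs": len(usable), "n_dropped": n_dropped, "degenerate": False}
    if np.allclose(diffs, 0.0):
        info["degenerate"] = True
        return 1.0, info
    res = stats.wilcoxon(a, b)
    return float(res.pvalue), info
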