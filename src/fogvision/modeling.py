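"""Staged gradient-boosted-tree training for FOG recognition.

Three binary classifiers are trained: a motion model (walk vs turn over
all labeled windows) and two stage-specific FOG models (Walk-FOG on
walking windows, Turn-FOG on turning windows).  The FOG models get a
training-only pipeline of transition-window removal (windows starting
within 0.5 s of a FOG boundary carry ambiguous labels), SMOTE
oversampling of the minority FOG class to parity, gain-ranked forward
feature selection, and subject-grouped grid search.  The window-level
selection metric is the geometric mean of sensitivity and specificity
(GM), which penalizes trading one rate for the other on imbalanced data.

All cross-validation inside training is grouped by subject so that no
subject contributes to both sides of a split.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import NearestNeighbors
import xgboost as xgb
from xgboost import XGBClassifier

from .features import META_COLUMNS, feature_columns
from .pose_io import AnnotationTrack

logger = logging.getLogger(__name__)

STAGES = ("walk", "turn")


class ModelingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters and training-pipeline settings.

    ``grid`` maps XGBoost parameter names to candidate values;
    ``max_selected_features`` caps the forward-selection prefix per
    model; ``selection_sizes`` optionally coarsens the ladder of prefix
    sizes evaluated (None = every size up to the cap).
    """

    grid: dict = field(default_factory=lambda: {
        "learning_rate": [0.05, 0.1, 0.3],
        "n_estimators": [50, 100, 200],
        "max_depth": [3, 5, 7],
        "subsample": [0.8, 1.0],
        "colsample_bytree": [0.8, 1.0],
    })
    metric: str = "gm"
    seed: int = 0
    max_selected_features: dict = field(default_factory=lambda: {
        "motion": 50, "walk_fog": 20, "turn_fog": 12,
    })
    smote_k: int = 5
    transition_margin_s: float = 0.5
    n_inner_folds: int = 3
    selection_sizes: tuple[int, ...] | None = None
    decision_threshold: float = 0.5
    max_bin: int = 256        # histogram resolution of the tree builder

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ModelingError("hyperparameter grid must be non-empty")
        if self.transition_margin_s < 0:
            raise ModelingError("transition_margin_s must be >= 0")

    @classmethod
    def fast(cls, seed: int = 0) -> "ModelConfig":
        """Desk-scale configuration: single-point grid, light ensembles,
        coarse forward-selection ladder."""
        return cls(
            grid={
                "learning_rate": [0.1],
                "n_estimators": [30],
                "max_depth": [3],
                "subsample": [1.0],
                "colsample_bytree": [1.0],
            },
            seed=seed,
            selection_sizes=(1, 2, 3, 5, 8, 12, 20, 35, 50),
            max_bin=32,
        )

    def grid_points(self) -> list[dict]:
        """Deterministic enumeration of the grid (sorted keys, product order)."""
        keys = sorted(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]

    def grid_center(self) -> dict:
        return {k: v[len(v) // 2] for k, v in sorted(self.grid.items())}


def _make_xgb(params: dict, seed: int, max_bin: int = 256) -> XGBClassifier:
    return XGBClassifier(
        objective="binary:logistic",
        tree_method="hist",
        max_bin=max_bin,
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        verbosity=0,
        **params,
    )


def gm_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Geometric mean of sensitivity and specificity; NaN if a class is absent."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    pos = y_true.sum()
    neg = (~y_true).sum()
    if pos == 0 or neg == 0:
        return float("nan")
    sens = float((y_pred & y_true).sum()) / pos
    spec = float((~y_pred & ~y_true).sum()) / neg
    return float(np.sqrt(sens * spec))


# ---------------------------------------------------------------------------
# Feature ranking and forward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedFeatures:
    """Gain-ordered feature names with their total gains and the
    forward-selection trace (prefix size -> validation GM)."""

    names: list[str]
    gains: list[float]
    trace: dict[int, float] = field(default_factory=dict)


def rank_features_by_gain(
    X: pd.DataFrame, y: np.ndarray, config: ModelConfig
) -> SelectedFeatures:
    """Rank features by total split gain of one boosted-tree fit.

    The fit uses the grid-center hyperparameters.  Features the ensemble
    never splits on have zero gain and are ranked last, alphabetically.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ModelingError("rank_features_by_gain needs both classes present")
    model = _make_xgb(config.grid_center(), config.seed, config.max_bin)
    model.fit(X, y)
    booster = model.get_booster()
    gains = booster.get_score(importance_type="total_gain")
    scored = [(c, float(gains.get(c, 0.0))) for c in X.columns]
    # gain descending; zero-gain features last, alphabetically
    scored.sort(key=lambda cg: (-cg[1], cg[0]))
    return SelectedFeatures(names=[c for c, _ in scored],
                            gains=[g for _, g in scored])


def _grouped_cv_gm(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    params: dict,
    config: ModelConfig,
) -> float:
    """Mean window GM over subject-grouped folds; NaN folds are skipped."""
    n_groups = len(np.unique(groups))
    n_splits = min(config.n_inner_folds, n_groups)
    if n_splits < 2:
        raise ModelingError("grouped CV needs at least 2 subjects")
    cv = GroupKFold(n_splits=n_splits)
    scores = []
    for tr, te in cv.split(X, y, groups):
        if len(np.unique(y[tr])) < 2:
            continue
        model = _make_xgb(params, config.seed, config.max_bin)
        model.fit(X.iloc[tr], y[tr])
        pred = model.predict_proba(X.iloc[te])[:, 1] >= config.decision_threshold
        s = gm_score(y[te], pred)
        if not np.isnan(s):
            scores.append(s)
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def forward_select(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    ranked: SelectedFeatures,
    config: ModelConfig,
    cap: int | None = None,
) -> SelectedFeatures:
    """Forward selection over gain-ordered prefixes.

    Features are added in gain order; after each addition the prefix is
    scored by subject-grouped CV GM at the grid-center hyperparameters.
    The best-scoring prefix wins, ties going to the smaller prefix; the
    prefix size never exceeds ``cap``.
    """
    if not ranked.names:
        raise ModelingError("ranked feature list is empty")
    cap = cap if cap is not None else len(ranked.names)
    cap = min(cap, len(ranked.names))
    sizes = config.selection_sizes or tuple(range(1, cap + 1))
    sizes = sorted({min(s, cap) for s in sizes if s >= 1})
    params = config.grid_center()
    trace: dict[int, float] = {}
    best_size, best_score = sizes[0], -np.inf
    for size in sizes:
        subset = ranked.names[:size]
        score = _grouped_cv_gm(X[subset], y, groups, params, config)
        trace[size] = score
        if not np.isnan(score) and score > best_score + 1e-12:
            best_size, best_score = size, score
    if not np.isfinite(best_score):
        # too few positive-class subjects for grouped scoring; keep the
        # full gain-ranked prefix rather than an arbitrary single feature
        warnings.warn("forward selection unscorable by grouped CV; "
                      "keeping the capped gain-ranked prefix", stacklevel=2)
        best_size = cap
    chosen = ranked.names[:best_size]
    return SelectedFeatures(
        names=chosen,
        gains=ranked.gains[:best_size],
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Training-set filters: transition removal and SMOTE
# ---------------------------------------------------------------------------

def fog_boundaries_s(annotations: AnnotationTrack, fps: float) -> list[float]:
    """FOG/non-FOG boundary times in seconds (both interval edges)."""
    out = []
    for a, b in annotations.fog_intervals:
        out.extend((a / fps, b / fps))
    return out


def remove_transition_windows(
    matrix: pd.DataFrame,
    boundaries: Mapping[tuple[str, str], Sequence[float]],
    margin_s: float = 0.5,
) -> pd.DataFrame:
    """Drop training windows starting within ``margin_s`` of a FOG boundary.

    ``boundaries`` maps (subject_id, test_id) to that recording's FOG
    boundary times in seconds.  This is a training-only filter; test
    folds are never passed through it.
    """
    if margin_s == 0 or matrix.empty:
        return matrix.copy()
    keep = np.ones(len(matrix), dtype=bool)
    t = matrix["t_start"].to_numpy()
    keys = list(zip(matrix["subject_id"], matrix["test_id"]))
    for key, bounds in boundaries.items():
        if not bounds:
            continue
        in_rec = np.array([k == key for k in keys])
        if not in_rec.any():
            continue
        b = np.asarray(list(bounds))
        near = (np.abs(t[in_rec, None] - b[None, :]) <= margin_s + 1e-9).any(axis=1)
        idx = np.flatnonzero(in_rec)
        keep[idx[near]] = False
    return matrix.iloc[keep].copy()


def smote_balance(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    return_base: bool = False,
):
    """SMOTE: oversample the minority class to parity.

    Each synthetic sample is a convex combination of a minority sample
    and one of its ``k`` nearest minority neighbors at a uniform random
    fraction.  The majority class is untouched.  Deterministic under
    ``seed``.  With ``return_base`` the index (into the original rows)
    of each output row's base sample is also returned, so per-row
    metadata such as the subject group can be propagated.
    """
    Xa = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ModelingError("smote_balance expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    base_idx = np.arange(len(y))
    if n_min == n_maj:
        out = (np.array(X, copy=True), y.copy())
        return (*out, base_idx) if return_base else out
    if n_min < 2:
        raise ModelingError("minority class needs at least 2 samples for SMOTE")
    if n_min < k + 1:
        k_eff = n_min - 1
        warnings.warn(f"SMOTE k reduced from {k} to {k_eff} (minority size {n_min})",
                      stacklevel=2)
    else:
        k_eff = k
    min_idx = np.flatnonzero(y == minority)
    Xm = Xa[min_idx]
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)
    frac = rng.uniform(size=n_new)
    partner = neigh[base, pick]
    X_new = Xm[base] + frac[:, None] * (Xm[partner] - Xm[base])
    X_out = np.concatenate([Xa, X_new])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    base_out = np.concatenate([base_idx, min_idx[base]])
    if isinstance(X, pd.DataFrame):
        X_out = pd.DataFrame(X_out, columns=X.columns)
    return (X_out, y_out, base_out) if return_base else (X_out, y_out)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def grid_search_train(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    config: ModelConfig,
) -> tuple[XGBClassifier, dict, pd.DataFrame]:
    """Subject-grouped grid search; refit the winner on all data.

    Each grid point is scored by mean window GM across grouped folds;
    ties break to the first point in deterministic grid order.  Returns
    (fitted model, best parameters, full grid table).
    """
    if len(np.unique(groups)) < 2:
        raise ModelingError("grid search needs >= 2 subjects")
    rows = []
    best_params, best_score = None, -np.inf
    for params in config.grid_points():
        score = _grouped_cv_gm(X, y, groups, params, config)
        rows.append({**params, "cv_gm": score})
        if not np.isnan(score) and score > best_score + 1e-12:
            best_params, best_score = params, score
    if best_params is None:
        if len(config.grid_points()) > 1:
            raise ModelingError("all grid points degenerate (no scorable fold)")
        # single-point grid: nothing to choose between; fit it directly
        warnings.warn("grouped CV unscorable; fitting the single grid point",
                      stacklevel=2)
        best_params = config.grid_points()[0]
    model = _make_xgb(best_params, config.seed, config.max_bin)
    model.fit(X, y)
    return model, best_params, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Staged bundle
# ---------------------------------------------------------------------------

@dataclass
class StageModel:
    """One classifier of the bundle; ``constant`` marks the degenerate
    always-non-positive predictor used when a stage had no FOG training
    windows."""

    name: str
    features: list[str]
    model: XGBClassifier | None = None
    constant: bool = False
    best_params: dict = field(default_factory=dict)
    selection: SelectedFeatures | None = None

    def predict_score(self, matrix: pd.DataFrame) -> np.ndarray:
        if self.constant:
            return np.zeros(len(matrix))
        missing = [f for f in self.features if f not in matrix.columns]
        if missing:
            raise ModelingError(f"missing feature columns: {missing[:5]}")
        X = matrix[self.features]
        if isinstance(self.model, xgb.Booster):  # reloaded from disk
            return self.model.inplace_predict(X.to_numpy(dtype=np.float32))
        return self.model.predict_proba(X)[:, 1]


@dataclass
class StagedModelBundle:
    motion: StageModel
    walk_fog: StageModel
    turn_fog: StageModel
    fog_duration_threshold_s: float
    provenance: dict = field(default_factory=dict)


def training_fingerprint(matrix: pd.DataFrame) -> str:
    """Stable hash of the identity of the training windows."""
    keys = sorted(
        (s, t, round(float(ts), 6))
        for s, t, ts in zip(matrix["subject_id"], matrix["test_id"],
                            matrix["t_start"])
    )
    return hashlib.sha256(json.dumps(keys).encode()).hexdigest()[:16]


def fog_episode_durations_s(
    annotations: Mapping[tuple[str, str], tuple[AnnotationTrack, float]],
) -> list[float]:
    out = []
    for track, fps in annotations.values():
        out.extend((b - a) / fps for a, b in track.fog_intervals)
    return out


def duration_threshold(durations_s: Sequence[float], quantile: float = 0.10) -> float:
    """Linear-interpolation quantile of annotated FOG episode durations."""
    if not len(durations_s):
        return 0.0
    return float(np.quantile(np.asarray(durations_s, dtype=float), quantile))


def _train_fog_stage(
    name: str,
    stage_matrix: pd.DataFrame,
    boundaries: Mapping[tuple[str, str], Sequence[float]],
    config: ModelConfig,
) -> StageModel:
    trimmed = remove_transition_windows(
        stage_matrix, boundaries, config.transition_margin_s
    )
    y = (trimmed["fog_label"] == "fog").to_numpy()
    if y.sum() == 0 or (~y).sum() == 0:
        logger.warning("%s: single-class training data; constant non-FOG predictor",
                       name)
        return StageModel(name=name, features=[], constant=True)
    cols = feature_columns(trimmed)
    Xb, yb, base = smote_balance(
        trimmed[cols], y, k=config.smote_k, seed=config.seed, return_base=True
    )
    groups = trimmed["subject_id"].to_numpy()[base]
    ranked = rank_features_by_gain(Xb, yb, config)
    cap = config.max_selected_features[name]
    ranked.names = ranked.names[:max(cap, 1)]
    ranked.gains = ranked.gains[:max(cap, 1)]
    selected = forward_select(Xb, yb, groups, ranked, config, cap=cap)
    model, best_params, _ = grid_search_train(
        Xb[selected.names], yb, groups, config
    )
    return StageModel(name=name, features=selected.names, model=model,
                      best_params=best_params, selection=selected)


def train_staged_bundle(
    matrix: pd.DataFrame,
    annotations: Mapping[tuple[str, str], tuple[AnnotationTrack, float]],
    config: ModelConfig,
) -> StagedModelBundle:
    """Train the full three-model bundle on one training split.

    ``matrix`` is the training feature matrix; ``annotations`` maps
    (subject_id, test_id) to (AnnotationTrack, fps) for the training
    recordings only — the FOG duration threshold and transition
    boundaries are computed from them, never from test data.
    Unknown-labeled windows are excluded from all training.
    """
    known = matrix[matrix["fog_label"] != "unknown"].copy()
    if known.empty:
        raise ModelingError("no labeled training windows")
    stages = set(known["stage_label"])
    if not {"walk", "turn"} <= stages:
        raise ModelingError("training windows must span both walk and turn stages")

    boundaries = {
        key: fog_boundaries_s(track, fps)
        for key, (track, fps) in annotations.items()
    }

    # motion model: walk vs turn over all labeled windows (FOG included)
    cols = feature_columns(known)
    y_stage = (known["stage_label"] == "turn").to_numpy()
    groups = known["subject_id"].to_numpy()
    ranked = rank_features_by_gain(known[cols], y_stage, config)
    cap = config.max_selected_features["motion"]
    ranked.names, ranked.gains = ranked.names[:cap], ranked.gains[:cap]
    sel = forward_select(known[cols], y_stage, groups, ranked, config, cap=cap)
    motion_model, motion_params, _ = grid_search_train(
        known[sel.names], y_stage, groups, config
    )
    motion = StageModel(name="motion", features=sel.names, model=motion_model,
                        best_params=motion_params, selection=sel)

    walk_fog = _train_fog_stage(
        "walk_fog", known[known["stage_label"] == "walk"], boundaries, config
    )
    turn_fog = _train_fog_stage(
        "turn_fog", known[known["stage_label"] == "turn"], boundaries, config
    )

    threshold = duration_threshold(fog_episode_durations_s(annotations))
    provenance = {
        "config": asdict(config),
        "seed": config.seed,
        "training_fingerprint": training_fingerprint(known),
        "constant_stages": [
            m.name for m in (walk_fog, turn_fog) if m.constant
        ],
        "n_training_windows": int(len(known)),
    }
    return StagedModelBundle(
        motion=motion, walk_fog=walk_fog, turn_fog=turn_fog,
        fog_duration_threshold_s=threshold, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------

def save_bundle(bundle: StagedModelBundle, directory: str | Path) -> None:
    """Serialize to a directory: native XGBoost model files + YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "fog_duration_threshold_s": float(bundle.fog_duration_threshold_s),
        "provenance": bundle.provenance,
        "stages": {},
    }
    for stage in (bundle.motion, bundle.walk_fog, bundle.turn_fog):
        entry = {
            "features": stage.features,
            "constant": stage.constant,
            "best_params": stage.best_params,
        }
        if stage.model is not None:
            path = directory / f"{stage.name}.ubj"
            booster = (stage.model if isinstance(stage.model, xgb.Booster)
                       else stage.model.get_booster())
            booster.save_model(path)
            entry["model_file"] = path.name
        manifest["stages"][stage.name] = entry
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_bundle(directory: str | Path) -> StagedModelBundle:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    stages = {}
    for name, entry in manifest["stages"].items():
        model = None
        if "model_file" in entry:
            model = xgb.Booster()
            model.load_model(str(directory / entry["model_file"]))
        stages[name] = StageModel(
            name=name, features=list(entry["features"]),
            model=model, constant=bool(entry["constant"]),
            best_params=dict(entry.get("best_params", {})),
        )
    return StagedModelBundle(
        motion=stages["motion"],
        walk_fog=stages["walk_fog"],
        turn_fog=stages["turn_fog"],
        fog_duration_threshold_s=float(manifest["fog_duration_threshold_s"]),
        provenance=dict(manifest.get("provenance", {})),
    )
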