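"""Episode extraction, metrics, postprocessing, and the paired Wilcoxon test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fogvision.inference_eval import (
    Episode,
    EvaluationError,
    episode_metrics,
    gm_from_rates,
    paired_subject_wilcoxon,
    postprocess_episodes,
    truth_episodes,
    window_metrics,
    windows_to_episodes,
)
from fogvision.pose_io import AnnotationTrack


def _preds(labels, step=0.1, window=2.0, subject="s", test="t"):
    t0 = np.arange(len(labels)) * step
    return pd.DataFrame(
        {
            "subject_id": subject,
            "test_id": test,
            "t_start": t0,
            "t_end": t0 + window,
            "stage_label": "walk",
            "fog_label": "nonfog",
            "frac_turn": 0.0,
            "frac_fog": 0.0,
            "frac_unknown": 0.0,
            "fog_pred": labels,
        }
    )


class TestWindowsToEpisodes:
    def test_merge_rule_example(self):
        eps = windows_to_episodes(_preds(["nonfog", "nonfog", "fog", "fog", "fog",
                                          "nonfog"]))
        assert eps == [
            Episode("nonfog", 0.0, 2.1),
            Episode("fog", pytest.approx(0.2), pytest.approx(2.4)),
            Episode("nonfog", 0.5, 2.5),
        ]

    def test_all_nonfog_single_episode(self):
        eps = windows_to_episodes(_preds(["nonfog"] * 10))
        assert len(eps) == 1
        assert eps[0] == Episode("nonfog", 0.0, pytest.approx(2.9))

    def test_alternating_labels(self):
        eps = windows_to_episodes(_preds(["fog", "nonfog", "fog", "nonfog"]))
        assert [e.label for e in eps] == ["fog", "nonfog", "fog", "nonfog"]

    def test_gap_splits_episode(self):
        p = _preds(["fog"] * 6)
        p.loc[3:, "t_start"] += 1.0   # 1 s hole in the window stream
        p.loc[3:, "t_end"] += 1.0
        eps = windows_to_episodes(p)
        assert len(eps) == 2

    def test_multiple_recordings_rejected(self):
        p = pd.concat([_preds(["fog"]), _preds(["fog"], subject="other")])
        with pytest.raises(EvaluationError, match="single recording"):
            windows_to_episodes(p)


class TestPostprocess:
    def test_short_fog_removed(self):
        eps = [Episode("fog", 0.0, 0.3), Episode("nonfog", 0.3, 4.0),
               Episode("fog", 4.0, 9.0)]
        out = postprocess_episodes(eps, 1.0)
        assert [e.label for e in out] == ["nonfog", "fog"]
        assert out[1].duration == pytest.approx(5.0)

    def test_zero_threshold_identity(self):
        eps = [Episode("fog", 0.0, 0.3), Episode("nonfog", 0.3, 4.0)]
        assert postprocess_episodes(eps, 0.0) == eps

    def test_sandwich_merges_to_single_nonfog(self):
        eps = [Episode("nonfog", 0.0, 2.0), Episode("fog", 2.0, 2.3),
               Episode("nonfog", 2.3, 5.0)]
        out = postprocess_episodes(eps, 1.0)
        assert out == [Episode("nonfog", 0.0, 5.0)]

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.05, 4.0), min_size=1, max_size=8),
           st.floats(0.0, 3.0))
    def test_idempotent_and_monotone(self, durations, threshold):
        eps, t = [], 0.0
        for i, d in enumerate(durations):
            eps.append(Episode("fog" if i % 2 else "nonfog", t, t + d))
            t += d
        once = postprocess_episodes(eps, threshold)
        assert postprocess_episodes(once, threshold) == once
        n_fog = sum(e.label == "fog" for e in once)
        stricter = postprocess_episodes(eps, threshold + 0.5)
        assert sum(e.label == "fog" for e in stricter) <= n_fog
        assert n_fog <= sum(e.label == "fog" for e in eps)


class TestTruthEpisodes:
    def test_partition_with_unknown_excluded(self):
        track = AnnotationTrack(fog_intervals=[(30, 60)],
                                unknown_intervals=[(90, 120)])
        eps = truth_episodes(track, 150, 30.0)
        assert eps == [
            Episode("nonfog", 0.0, 1.0),
            Episode("fog", 1.0, 2.0),
            Episode("nonfog", 2.0, 3.0),
            Episode("nonfog", 4.0, 5.0),
        ]


class TestWindowMetrics:
    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0], bool)
        rep = window_metrics(y, y, scores=np.array([0.9, 0.8, 0.2, 0.1]))
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0
        assert rep.gm == 1.0 and rep.auc == 1.0

    def test_constant_scores_auc_half(self):
        y = np.array([1, 0, 1, 0], bool)
        rep = window_metrics(y, y, scores=np.zeros(4))
        assert rep.auc == pytest.approx(0.5)

    def test_hand_confusion_matrix(self):
        truth = np.array([1, 1, 1, 0, 0, 0], bool)
        pred = np.array([1, 1, 0, 0, 0, 0], bool)
        rep = window_metrics(truth, pred)
        assert rep.sensitivity == pytest.approx(2 / 3)
        assert rep.specificity == 1.0
        assert rep.gm == pytest.approx(math.sqrt(2 / 3))
        assert rep.gm ** 2 == pytest.approx(
            rep.sensitivity * rep.specificity, abs=1e-12)

    def test_missing_class_flagged(self):
        rep = window_metrics(np.ones(3, bool), np.ones(3, bool))
        assert "no_negative_truth" in rep.flags
        assert np.isnan(rep.specificity)


def rasterize_episode_metrics(preds, truth_eps, dt=0.01):
    """Frame-rasterizing oracle: paint each truth episode onto a fine
    half-open sample grid, locate every predicted-FOG window's midpoint
    sample, and scan episodes for hits."""
    def idx(t):
        return int(math.floor(round(t / dt, 6)))

    t_max = max(e.t_end for e in truth_eps)
    owner = np.full(idx(t_max) + 1, -1)
    for k, e in enumerate(truth_eps):
        owner[idx(e.t_start):idx(e.t_end)] = k
    hit = np.zeros(len(truth_eps), bool)
    fog_rows = preds[preds["fog_pred"] == "fog"]
    for _, row in fog_rows.iterrows():
        mid = (row["t_start"] + row["t_end"]) / 2.0
        i = idx(mid)
        if 0 <= i < len(owner) and owner[i] >= 0:
            hit[owner[i]] = True
    tp = fn = tn = fp = 0
    for k, e in enumerate(truth_eps):
        if e.label == "fog":
            tp += hit[k]
            fn += not hit[k]
        else:
            fp += hit[k]
            tn += not hit[k]
    return tp, fn, tn, fp


class TestEpisodeMetrics:
    def test_detection_ratio(self):
        """Seven of eight truth FOG episodes hold a predicted-FOG window."""
        truth = [Episode("fog", 10.0 * i, 10.0 * i + 5) for i in range(8)]
        labels = ["fog" if i < 7 else "nonfog" for i in range(8)]
        p = _preds(labels)
        p["t_start"] = [10.0 * i + 1 for i in range(8)]
        p["t_end"] = p["t_start"] + 2.0
        rep = episode_metrics(p, truth)
        assert rep.sensitivity == pytest.approx(0.875)

    def test_printed_rate_pair_gm(self):
        assert round(100 * gm_from_rates(0.8121, 0.9016), 2) == 85.57

    def test_no_predicted_fog(self):
        truth = [Episode("fog", 0, 5), Episode("nonfog", 5, 10)]
        rep = episode_metrics(_preds(["nonfog"] * 5), truth)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0

    def test_boundary_window_counts_toward_majority_side(self):
        truth = [Episode("nonfog", 0.0, 10.0), Episode("fog", 10.0, 15.0)]
        # correctly predicted fog window starting 0.9 s before the episode:
        # midpoint 10.1 -> belongs to the fog episode, no FP for the nonfog one
        p = _preds(["fog"])
        p["t_start"] = [9.1]
        p["t_end"] = [11.1]
        rep = episode_metrics(p, truth)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0

    def test_no_truth_fog_flagged(self):
        rep = episode_metrics(_preds(["nonfog"]), [Episode("nonfog", 0, 10)])
        assert "no_truth_fog_episodes" in rep.flags

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_agrees_with_rasterizing_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random alternating truth partition and random window predictions
        # on a 0.1 s grid so rasterization at 0.01 s is exact
        t, truth = 0.0, []
        for i in range(rng.integers(2, 8)):
            d = rng.integers(5, 40) * 0.1
            truth.append(Episode("fog" if i % 2 else "nonfog",
                                 round(t, 10), round(t + d, 10)))
            t = round(t + d, 10)
        n_windows = max(int(round((t - 2.0) / 0.1)) + 1, 1)
        n_windows = min(n_windows, 50)
        labels = rng.choice(["fog", "nonfog"], size=n_windows, p=[0.3, 0.7])
        p = _preds(list(labels))
        rep = episode_metrics(p, truth)
        tp, fn, tn, fp = rasterize_episode_metrics(p, truth)
        assert rep.counts == {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def exact_signed_rank_p(diffs):
    """Exact two-sided signed-rank p-value by enumerating all 2^n sign
    assignments (no ties, no zeros)."""
    diffs = np.asarray(diffs, float)
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = ranks[diffs > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    mean_w = n * (n + 1) / 4
    p = np.mean(np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return p


class TestPairedWilcoxon:
    def _matrix(self, deltas, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s, d in enumerate(deltas):
            for label, base in (("fog", 10.0 + d), ("nonfog", 10.0)):
                for w in range(4):
                    rows.append(
                        {
                            "subject_id": f"S{s}",
                            "fog_label": label,
                            "feat": base + rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_degenerate_all_zero_differences(self):
        m = self._matrix([0.0] * 6)
        p, info = paired_subject_wilcoxon(m, "feat")
        assert p == 1.0 and info["degenerate"]

    def test_constant_shift_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        jitter = rng.uniform(0.5, 1.5, 10)   # distinct positive differences
        m = self._matrix(jitter)
        p, info = paired_subject_wilcoxon(m, "feat")
        assert info["n_pairs"] == 10
        assert p == pytest.approx(exact_signed_rank_p(jitter))
        assert p == pytest.approx(2 / 2 ** 10)

    def test_mixed_signs_match_enumeration(self):
        rng = np.random.default_rng(6)
        deltas = rng.normal(0.0, 1.0, 8)
        m = self._matrix(deltas)
        p, _ = paired_subject_wilcoxon(m, "feat")
        assert p == pytest.approx(exact_signed_rank_p(deltas))

    def test_subjects_missing_a_group_dropped(self):
        m = self._matrix([1.0] * 6)
        m = m[~((m.subject_id == "S0") & (m.fog_label == "fog"))]
        p, info = paired_subject_wilcoxon(m, "feat")
        assert info["n_pairs"] == 5 and info["n_dropped"] == 1

    def test_too_few_pairs_raises(self):
        m = self._matrix([1.0] * 4)
        with pytest.raises(EvaluationError, match="need >="):
            paired_subject_wilcoxon(m, "feat")

    def test_fog_suppresses_locomotor_band_power(self):
        """On a synthetic cohort where every subject freezes, the per-subject
        paired test detects the drop in heel-speed locomotor band power
        during FOG, and the direction is a suppression."""
        from fogvision.pipeline import extract_cohort
        from fogvision.synthetic import simulate_cohort
        from tests.conftest import tiny_sim_params

        params = tiny_sim_params(n_subjects=6, fog_prevalence=1.0,
                                 fog_duration_s=(2.0, 5.0))
        matrix, _ = extract_cohort(simulate_cohort(params))
        walk = matrix[matrix["stage_label"] == "walk"]
        p, info = paired_subject_wilcoxon(walk, "band_0.5_3__speed_LHeel_y")
        assert info["n_pairs"] >= 5
        assert p < 0.05
        means = walk.groupby("fog_label")["band_0.5_3__speed_LHeel_y"].median()
        assert means["fog"] < means["nonfog"]


class TestLoso:
    def test_one_fold_per_subject(self, tiny_dataset, tiny_loso):
        matrix, _ = tiny_dataset
        subjects = sorted(matrix["subject_id"].unique())
        assert [f["subject_id"] for f in tiny_loso.per_fold] == subjects

    def test_held_out_windows_partition_dataset(self, tiny_dataset, tiny_loso):
        matrix, _ = tiny_dataset
        labeled = matrix[matrix["fog_label"] != "unknown"]
        assert sum(f["n_test_windows"] for f in tiny_loso.per_fold) == len(labeled)
        assert len(tiny_loso.predictions) == len(labeled)

    def test_no_subject_leaks_into_its_training_fold(self, tiny_dataset, tiny_loso):
        """Each fold's training fingerprint equals the fingerprint of the
        dataset minus the held-out subject: nothing of that subject touched
        ranking, SMOTE, selection, grid search or the duration threshold."""
        from fogvision.modeling import training_fingerprint

        matrix, _ = tiny_dataset
        labeled = matrix[matrix["fog_label"] != "unknown"]
        for subject, fp in tiny_loso.fold_fingerprints.items():
            expected = training_fingerprint(
                labeled[labeled["subject_id"] != subject]
            )
            assert fp == expected

    def test_gm_identity_everywhere(self, tiny_loso):
        for fold in tiny_loso.per_fold:
            ep = fold["episode"]
            if not np.isnan(ep["sensitivity"]) and not np.isnan(ep["specificity"]):
                assert ep["gm"] ** 2 == pytest.approx(
                    ep["sensitivity"] * ep["specificity"], abs=1e-12)
        pe = tiny_loso.pooled_episode
        assert pe.gm ** 2 == pytest.approx(pe.sensitivity * pe.specificity,
                                           abs=1e-12)

    def test_constant_bundle_predicts_all_nonfog(self, tiny_dataset):
        from fogvision.modeling import StagedModelBundle, StageModel
        from fogvision.inference_eval import predict_multistage

        matrix, _ = tiny_dataset
        const = StageModel(name="x", features=[], constant=True)
        bundle = StagedModelBundle(
            motion=const, walk_fog=const, turn_fog=const,
            fog_duration_threshold_s=0.0,
        )
        preds = predict_multistage(matrix.head(50), bundle)
        assert (preds["fog_pred"] == "nonfog").all()

    def test_duplicated_windows_get_identical_predictions(self, tiny_dataset, tiny_loso):
        import pandas as pd
        from fogvision.modeling import train_staged_bundle
        from fogvision.inference_eval import predict_multistage
        from tests.conftest import tiny_model_config

        matrix, annotations = tiny_dataset
        ann2 = {k: (t, fps) for k, (t, fps, _n) in annotations.items()}
        subject = sorted(matrix["subject_id"].unique())[0]
        bundle = train_staged_bundle(
            matrix[matrix["subject_id"] != subject], ann2, tiny_model_config()
        )
        test = matrix[matrix["subject_id"] == subject].head(30)
        doubled = pd.concat([test, test], ignore_index=True)
        preds = predict_multistage(doubled, bundle)
        np.testing.assert_array_equal(
            preds["fog_score"].to_numpy()[:30], preds["fog_score"].to_numpy()[30:]
        )
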