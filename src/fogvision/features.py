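"""Sliding-window segmentation and the time/frequency feature bank.

Signals are cut into 2 s windows advanced by 0.1 s.  Each window yields
a bank of time-domain statistics (min, max, mean, mean of absolute
values, mean square, peak-to-peak, 90th percentile, skewness,
non-central kurtosis coefficient, crest factor, clearance factor,
histogram entropy, minimum squared sample) and frequency-domain
statistics computed from a rectangular-window periodogram of the
mean-removed samples (amplitude peak, power-weighted average frequency,
second power peak, band powers, freezing index).

The freezing index (FI) is the power in the 3–8 Hz "freeze" band
divided by the power in the 0.5–3 Hz "locomotor" band; normal stepping
concentrates power in the locomotor band, while freezing suppresses it
and often adds 6–8 Hz leg trembling, so FI rises sharply during FOG.

Windows are labeled from the frame-based annotations: stage = turn when
more than half of a window's frames lie in turn intervals; FOG label =
unknown if the window touches any unknown span, else fog when at least
``fog_frac_min`` of its frames are annotated FOG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .pose_io import AnnotationTrack
from .preprocess import DerivedSignalSet, channel_names

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 2.0
DEFAULT_STEP_S = 0.1
DEFAULT_FOG_FRAC_MIN = 0.5

FREEZE_BAND = (3.0, 8.0)
LOCOMOTOR_BAND = (0.5, 3.0)
FI_EPS = 1e-12
FI_CAP = 1e6

ENTROPY_BINS = 10

TIME_STATS = (
    "min", "max", "mean", "mean_abs", "mse", "ptp", "p90",
    "skewness", "kurtosis_coef", "crest_factor", "clearance_factor",
    "entropy", "min_sq",
)
SPECTRAL_STATS = (
    "freq_amp_peak", "avg_freq", "second_power_peak",
    "band_0.5_3", "band_1_1.5", "band_3.5_15", "fi",
)
ALL_STATS = TIME_STATS + SPECTRAL_STATS

#: Non-feature columns of a feature matrix.
META_COLUMNS = (
    "subject_id", "test_id", "t_start", "t_end",
    "stage_label", "fog_label", "frac_turn", "frac_fog", "frac_unknown",
)


class FeatureConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass
class Window:
    """One sliding-window slice of a recording's signal bank."""

    signals: DerivedSignalSet
    start: int            # sample index of the first frame
    n: int                # samples per window
    stage_label: str = ""     # walk | turn
    fog_label: str = ""       # fog | nonfog | unknown
    frac_turn: float = 0.0
    frac_fog: float = 0.0
    frac_unknown: float = 0.0

    @property
    def subject_id(self) -> str:
        return self.signals.subject_id

    @property
    def test_id(self) -> str:
        return self.signals.test_id

    @property
    def t_start(self) -> float:
        return self.start / self.signals.fps

    @property
    def t_end(self) -> float:
        return (self.start + self.n) / self.signals.fps

    def samples(self, channel: str) -> np.ndarray:
        return self.signals.channels[channel][self.start:self.start + self.n]


def slide_windows(
    signals: DerivedSignalSet,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
) -> list[Window]:
    """Cut a signal bank into overlapping windows.

    Windows start at 0, step_s, 2·step_s, …; the count is
    ``floor((T − window_s)/step_s) + 1`` (sample-exact) and no window
    extends past the signal.  A recording shorter than one window yields
    an empty list with a warning.
    """
    n = int(round(window_s * signals.fps))
    step = int(round(step_s * signals.fps))
    if step <= 0 or n <= 0:
        raise FeatureConfigError("window_s and step_s must be positive")
    total = signals.n_frames
    if total < n:
        warnings.warn(
            f"signal of {total} frames shorter than window ({n}); no windows",
            stacklevel=2,
        )
        return []
    count = (total - n) // step + 1
    return [Window(signals, i * step, n) for i in range(count)]


def label_windows(
    windows: Sequence[Window],
    annotations: AnnotationTrack,
    fog_frac_min: float = DEFAULT_FOG_FRAC_MIN,
) -> list[Window]:
    """Label windows in place from frame-based annotations (also returned)."""
    if not windows:
        return list(windows)
    total = windows[0].signals.n_frames
    annotations.validate_length(total)
    turn = annotations.mask("turn", total)
    fog = annotations.mask("fog", total)
    unknown = annotations.mask("unknown", total)
    for w in windows:
        sl = slice(w.start, w.start + w.n)
        w.frac_turn = float(turn[sl].mean())
        w.frac_fog = float(fog[sl].mean())
        w.frac_unknown = float(unknown[sl].mean())
        w.stage_label = "turn" if w.frac_turn > 0.5 else "walk"
        if w.frac_unknown > 0:
            w.fog_label = "unknown"
        elif w.frac_fog >= fog_frac_min:
            w.fog_label = "fog"
        else:
            w.fog_label = "nonfog"
    return list(windows)


# ---------------------------------------------------------------------------
# Time-domain statistics
# ---------------------------------------------------------------------------

def _time_feature_block(X: np.ndarray, clearance_as_crest: bool = False) -> dict[str, np.ndarray]:
    """All time-domain statistics for a (m, n) block of windows."""
    X = np.asarray(X, dtype=np.float64)
    m, n = X.shape
    out: dict[str, np.ndarray] = {}
    xmin = X.min(axis=1)
    xmax = X.max(axis=1)
    mu = X.mean(axis=1)
    mse = (X ** 2).mean(axis=1)
    rms = np.sqrt(mse)
    out["min"] = xmin
    out["max"] = xmax
    out["mean"] = mu
    out["mean_abs"] = np.abs(X).mean(axis=1)
    out["mse"] = mse
    out["ptp"] = xmax - xmin
    out["p90"] = np.quantile(X, 0.9, axis=1)  # order statistic 1 + 0.9(n-1), linear
    sigma = X.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (X - mu[:, None]) / sigma[:, None]
        skew = np.where(sigma > 0, np.nan_to_num((z ** 3).mean(axis=1)), 0.0)
    out["skewness"] = skew
    out["kurtosis_coef"] = (X ** 4).mean(axis=1)  # non-central, by definition here
    out["crest_factor"] = np.where(rms > 0, xmax / np.where(rms > 0, rms, 1.0), 0.0)
    if clearance_as_crest:
        out["clearance_factor"] = out["crest_factor"]
    else:
        sqrt_mean = np.sqrt(np.abs(X)).mean(axis=1)
        denom = sqrt_mean ** 2
        out["clearance_factor"] = np.where(
            denom > 0, np.abs(X).max(axis=1) / np.where(denom > 0, denom, 1.0), 0.0
        )
    out["entropy"] = _histogram_entropy(X)
    out["min_sq"] = (X ** 2).min(axis=1)
    return out


def _histogram_entropy(X: np.ndarray, bins: int = ENTROPY_BINS) -> np.ndarray:
    """Shannon entropy (nats) of a per-window histogram over `bins` bins."""
    m, n = X.shape
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] <= 0
    width = np.where(span > 0, span, 1.0)
    idx = np.clip(((X - lo) / width * bins).astype(np.int64), 0, bins - 1)
    counts = np.zeros((m, bins))
    rows = np.repeat(np.arange(m), n)
    np.add.at(counts, (rows, idx.ravel()), 1.0)
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    h[flat] = 0.0
    return h


def time_features(x: np.ndarray, clearance_as_crest: bool = False) -> dict[str, float]:
    """Time-domain statistics of one window (see module docstring)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise FeatureConfigError("time_features expects a 1-D window with n >= 2")
    if not np.all(np.isfinite(x)):
        raise FeatureConfigError("non-finite samples in window")
    block = _time_feature_block(x[None, :], clearance_as_crest=clearance_as_crest)
    return {k: float(v[0]) for k, v in block.items()}


# ---------------------------------------------------------------------------
# Spectrum and frequency-domain statistics
# ---------------------------------------------------------------------------

@dataclass
class SpectrumEstimate:
    """One-sided periodogram of a mean-removed window.

    ``power`` is normalized so that ``sum(power) * df`` equals the
    window's variance (Parseval-consistent density); ``amplitude`` is
    the raw magnitude of the real DFT coefficients.
    """

    frequencies: np.ndarray
    power: np.ndarray
    amplitude: np.ndarray

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def _spectrum_block(X: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(freqs, power, amplitude) for a (m, n) block; power rows are densities."""
    m, n = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    F = np.fft.rfft(Xc, axis=1)
    amp = np.abs(F)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = fs / n
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    power = (amp ** 2) * w / (n ** 2 * df)
    return freqs, power, amp


def spectrum(x: np.ndarray, fs: float) -> SpectrumEstimate:
    """Rectangular-window periodogram of one mean-removed window."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 4:
        raise FeatureConfigError("spectrum requires n >= 4")
    freqs, power, amp = _spectrum_block(x[None, :], fs)
    return SpectrumEstimate(freqs, power[0], amp[0])


def band_power(spec_or_freqs, power=None, lo: float = 0.0, hi: float = np.inf) -> float:
    """Trapezoidal integral of the power density over [lo, hi] Hz.

    Band edges between grid points are linearly interpolated, which
    makes the integral exactly additive over adjacent bands.  ``hi``
    above the Nyquist frequency is clipped with a warning.
    """
    if isinstance(spec_or_freqs, SpectrumEstimate):
        freqs, P = spec_or_freqs.frequencies, spec_or_freqs.power[None, :]
    else:
        freqs, P = np.asarray(spec_or_freqs), np.atleast_2d(power)
    return float(_band_power_block(freqs, P, lo, hi)[0])


def _band_power_block(freqs: np.ndarray, P: np.ndarray, lo: float, hi: float) -> np.ndarray:
    nyq = freqs[-1]
    if hi > nyq:
        logger.warning("band upper edge %.3g Hz clipped to Nyquist %.3g Hz", hi, nyq)
        hi = float(nyq)
    lo = max(lo, float(freqs[0]))
    if hi <= lo:
        return np.zeros(P.shape[0])
    inside = (freqs > lo) & (freqs < hi)
    grid = np.concatenate(([lo], freqs[inside], [hi]))
    p_lo = _interp_rows(freqs, P, lo)
    p_hi = _interp_rows(freqs, P, hi)
    vals = np.concatenate([p_lo[:, None], P[:, inside], p_hi[:, None]], axis=1)
    return np.trapezoid(vals, grid, axis=1)


def _interp_rows(freqs: np.ndarray, P: np.ndarray, f: float) -> np.ndarray:
    j = int(np.searchsorted(freqs, f, side="right")) - 1
    j = min(max(j, 0), len(freqs) - 2)
    t = (f - freqs[j]) / (freqs[j + 1] - freqs[j])
    return P[:, j] * (1 - t) + P[:, j + 1] * t


def _second_power_peak(P: np.ndarray) -> np.ndarray:
    """Second-largest local maximum of each power row (0 if fewer than two)."""
    m, nf = P.shape
    pad = np.full((m, 1), -np.inf)
    Pp = np.concatenate([pad, P, pad], axis=1)
    is_max = (Pp[:, 1:-1] > Pp[:, :-2]) & (Pp[:, 1:-1] >= Pp[:, 2:])
    peak_vals = np.where(is_max, P, -np.inf)
    top2 = -np.partition(-peak_vals, 1, axis=1)[:, :2]
    second = top2[:, 1]
    return np.where(np.isfinite(second), second, 0.0)


def _spectral_feature_block(freqs: np.ndarray, P: np.ndarray, amp: np.ndarray) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    out["freq_amp_peak"] = amp.max(axis=1)
    tot = P.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = (P * freqs[None, :]).sum(axis=1) / np.where(tot > 0, tot, 1.0)
    out["avg_freq"] = np.where(tot > 0, avg, 0.0)
    out["second_power_peak"] = _second_power_peak(P)
    out["band_0.5_3"] = _band_power_block(freqs, P, 0.5, 3.0)
    out["band_1_1.5"] = _band_power_block(freqs, P, 1.0, 1.5)
    out["band_3.5_15"] = _band_power_block(freqs, P, 3.5, 15.0)
    freeze = _band_power_block(freqs, P, *FREEZE_BAND)
    loco = _band_power_block(freqs, P, *LOCOMOTOR_BAND)
    out["fi"] = np.where(loco > FI_EPS, freeze / np.where(loco > FI_EPS, loco, 1.0), FI_CAP)
    return out


def spectral_features(spec: SpectrumEstimate) -> dict[str, float]:
    """Frequency-domain statistics of one spectrum estimate."""
    block = _spectral_feature_block(
        spec.frequencies, spec.power[None, :], spec.amplitude[None, :]
    )
    return {k: float(v[0]) for k, v in block.items()}


def freezing_index(x: np.ndarray, fs: float) -> float:
    """Freeze-band (3–8 Hz) power over locomotor-band (0.5–3 Hz) power.

    Returns a capped large value (1e6) when the locomotor power is
    numerically zero (no stepping energy at all).
    """
    spec = spectrum(x, fs)
    freeze = band_power(spec, lo=FREEZE_BAND[0], hi=FREEZE_BAND[1])
    loco = band_power(spec, lo=LOCOMOTOR_BAND[0], hi=LOCOMOTOR_BAND[1])
    if loco < FI_EPS:
        return FI_CAP
    return freeze / loco


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

def feature_name(stat: str, channel: str) -> str:
    return f"{stat}__{channel}"


def default_feature_spec(channels: Iterable[str] | None = None) -> list[tuple[str, str]]:
    """Every statistic crossed with every channel (deterministic order)."""
    chans = list(channels) if channels is not None else channel_names()
    return [(stat, ch) for ch in chans for stat in ALL_STATS]


def write_feature_spec(spec: Sequence[tuple[str, str]], path) -> None:
    """Persist a feature spec as YAML: a list of {statistic, channel} pairs."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump([{"statistic": s, "channel": c} for s, c in spec], fh)


def read_feature_spec(path) -> list[tuple[str, str]]:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    try:
        return [(item["statistic"], item["channel"]) for item in raw]
    except (TypeError, KeyError) as exc:
        raise FeatureConfigError(
            f"feature spec {path} must be a list of statistic/channel pairs"
        ) from exc


def build_feature_matrix(
    windows: Sequence[Window],
    feature_spec: Sequence[tuple[str, str]] | None = None,
    clearance_as_crest: bool = False,
) -> pd.DataFrame:
    """Compute every (statistic, channel) pair for every labeled window.

    Returns a DataFrame with the :data:`META_COLUMNS` followed by one
    column per feature, named ``{stat}__{channel}``, one row per window
    in input order.
    """
    if feature_spec is None:
        if not windows:
            feature_spec = default_feature_spec()
        else:
            feature_spec = default_feature_spec(windows[0].signals.channels)
    for stat, ch in feature_spec:
        if stat not in ALL_STATS:
            raise FeatureConfigError(f"unknown statistic {stat!r}")
    by_channel: dict[str, list[str]] = {}
    for stat, ch in feature_spec:
        by_channel.setdefault(ch, []).append(stat)
    columns = [feature_name(stat, ch) for stat, ch in feature_spec]
    if len(set(columns)) != len(columns):
        raise FeatureConfigError("duplicate (statistic, channel) pairs in feature spec")

    meta = pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "test_id": [w.test_id for w in windows],
            "t_start": [w.t_start for w in windows],
            "t_end": [w.t_end for w in windows],
            "stage_label": [w.stage_label for w in windows],
            "fog_label": [w.fog_label for w in windows],
            "frac_turn": [w.frac_turn for w in windows],
            "frac_fog": [w.frac_fog for w in windows],
            "frac_unknown": [w.frac_unknown for w in windows],
        }
    )
    values = np.empty((len(windows), len(columns)))
    col_pos = {c: i for i, c in enumerate(columns)}

    # group windows by parent signal bank so each channel is windowed once
    groups: dict[int, list[int]] = {}
    sig_of: dict[int, DerivedSignalSet] = {}
    for i, w in enumerate(windows):
        key = id(w.signals)
        groups.setdefault(key, []).append(i)
        sig_of[key] = w.signals
    for key, idxs in groups.items():
        sig = sig_of[key]
        fps = sig.fps
        starts = np.array([windows[i].start for i in idxs])
        n = windows[idxs[0]].n
        for ch, stats in by_channel.items():
            if ch not in sig.channels:
                raise FeatureConfigError(f"unknown channel {ch!r}")
            view = sliding_window_view(sig.channels[ch], n)[starts]
            t_stats = [s for s in stats if s in TIME_STATS]
            s_stats = [s for s in stats if s in SPECTRAL_STATS]
            if t_stats:
                block = _time_feature_block(view, clearance_as_crest=clearance_as_crest)
                for s in t_stats:
                    values[idxs, col_pos[feature_name(s, ch)]] = block[s]
            if s_stats:
                freqs, P, amp = _spectrum_block(view, fps)
                block = _spectral_feature_block(freqs, P, amp)
                for s in s_stats:
                    values[idxs, col_pos[feature_name(s, ch)]] = block[s]
    feat = pd.DataFrame(values, columns=columns)
    out = pd.concat([meta, feat], axis=1)
    if out[columns].isna().any().any():
        bad = [c for c in columns if out[c].isna().any()]
        raise FeatureConfigError(f"NaN features produced: {bad[:5]}")
    return out


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Names of the feature (non-meta) columns of a feature matrix."""
    return [c for c in matrix.columns if c not in META_COLUMNS]
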