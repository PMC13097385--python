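"""Nine-feature sEMG engineering stage.

Six classical Hudgins time-domain features — root mean square (RMS), mean
absolute value (MAV), integrated EMG (iEMG), waveform length (WL), zero
crossings (ZC) and slope-sign changes (SSC) — plus three time–frequency
features derived from continuous-wavelet-transform coefficients: absolute
power (``cwt_power``), kurtosis of the pooled coefficient magnitudes
(``cwt_kurtosis``) and wavelet entropy (``we``, Shannon entropy in nats of
the scale-wise energy distribution).

Definitions, for a window x_1..x_N sampled at f_s (Δt = 1/f_s):

    RMS  = sqrt( (1/N) Σ x_i² )
    MAV  = (1/N) Σ |x_i|
    iEMG = Σ |x_i| · Δt              (rectangle-rule time integral)
    WL   = Σ |x_{i+1} − x_i|
    ZC   = #{ i : x_i·x_{i+1} < 0 and |x_i − x_{i+1}| > ε }
    SSC  = #{ i : (x_i − x_{i−1})(x_i − x_{i+1}) > 0,
               |x_i − x_{i−1}| > ε and |x_i − x_{i+1}| > ε }

The dead-band ε defaults to 0.01 × window RMS (Hudgins convention).

Features are normalized to the mean of the three maximal-voluntary-
contraction (MVC) trials per subject and channel (`mvc_normalize`), which
removes inter-individual amplitude and electrode-impedance differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .preprocess import Window, segment_active_windows

__all__ = [
    "FEATURE_NAMES",
    "HUDGINS_NAMES",
    "CWT_NAMES",
    "hudgins_features",
    "cwt_features",
    "extract_features",
    "default_cwt_scales",
    "session_feature_table",
    "mvc_normalize",
    "group_compare",
]

HUDGINS_NAMES = ("rms", "mav", "iemg", "wl", "zc", "ssc")
CWT_NAMES = ("cwt_power", "cwt_kurtosis", "we")
FEATURE_NAMES = HUDGINS_NAMES + CWT_NAMES

_MOTHER = "morl"  # real Morlet


def _resolve_epsilon(x: np.ndarray, epsilon) -> float:
    if epsilon == "auto":
        return 0.01 * float(np.sqrt(np.mean(x * x)))
    eps = float(epsilon)
    if eps < 0:
        raise ValueError("epsilon must be >= 0")
    return eps


def hudgins_features(
    window: Window | np.ndarray,
    epsilon="auto",
    sampling_rate: float | None = None,
) -> dict[str, float]:
    """The six Hudgins time-domain features of one window."""
    if isinstance(window, Window):
        x, fs = window.samples, window.sampling_rate
    else:
        x = np.asarray(window, dtype=float)
        fs = sampling_rate
        if fs is None:
            raise ValueError("sampling_rate required for a bare array")
    if x.size < 2:
        raise ValueError("Hudgins features need at least 2 samples")
    eps = _resolve_epsilon(x, epsilon)
    dt = 1.0 / fs

    rms = float(np.sqrt(np.mean(x * x)))
    mav = float(np.mean(np.abs(x)))
    iemg = float(np.sum(np.abs(x)) * dt)
    diff = np.diff(x)
    wl = float(np.sum(np.abs(diff)))
    zc = int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(diff) > eps)))
    if x.size >= 3:
        d1, d2 = x[1:-1] - x[:-2], x[1:-1] - x[2:]
        ssc = int(np.sum((d1 * d2 > 0) & (np.abs(d1) > eps) & (np.abs(d2) > eps)))
    else:
        ssc = 0
    return {"rms": rms, "mav": mav, "iemg": iemg, "wl": wl, "zc": zc, "ssc": ssc}


def default_cwt_scales(
    sampling_rate: float,
    n_scales: int = 32,
    f_min: float = 10.0,
    f_max: float = 450.0,
) -> np.ndarray:
    """32 logarithmic Morlet scales spanning 10–450 Hz equivalent frequency."""
    f_max = min(f_max, 0.99 * sampling_rate / 2.0)
    freqs = np.geomspace(f_min, f_max, n_scales)
    fc = pywt.central_frequency(_MOTHER)
    return fc * sampling_rate / freqs


def cwt_features(
    window: Window | np.ndarray,
    scales: np.ndarray | None = None,
    sampling_rate: float | None = None,
) -> dict[str, float]:
    """CWT absolute power, coefficient kurtosis and wavelet entropy.

    ``cwt_power`` is the mean squared coefficient magnitude over all
    scale × time cells; ``cwt_kurtosis`` is the (Pearson, non-excess)
    kurtosis of the pooled |coefficient| distribution; ``we`` is the
    Shannon entropy in nats of p_s = E_s / Σ E_s where E_s is the energy
    at scale s.  A uniform scale-energy vector over S scales gives ln S.
    """
    if isinstance(window, Window):
        x, fs = window.samples, window.sampling_rate
    else:
        x = np.asarray(window, dtype=float)
        fs = sampling_rate
        if fs is None:
            raise ValueError("sampling_rate required for a bare array")
    if x.size < 64:
        raise ValueError("CWT features need at least 64 samples")
    if scales is None:
        scales = default_cwt_scales(fs)
    scales = np.asarray(scales, dtype=float)
    if scales.size < 4:
        raise ValueError("need at least 4 CWT scales")

    coeffs, _ = pywt.cwt(x, scales, _MOTHER, sampling_period=1.0 / fs)
    mag = np.abs(coeffs)
    power = float(np.mean(mag**2))
    if power == 0.0:
        return {"cwt_power": 0.0, "cwt_kurtosis": 0.0, "we": 0.0}
    kurt = float(stats.kurtosis(mag, axis=None, fisher=False))
    energy = (mag**2).sum(axis=1)
    total = energy.sum()
    if total <= 0:
        raise ValueError("zero total CWT energy; wavelet entropy undefined")
    p = energy / total
    p = p[p > 0]
    we = float(-(p * np.log(p)).sum())
    return {"cwt_power": power, "cwt_kurtosis": kurt, "we": we}


def extract_features(
    window: Window,
    epsilon="auto",
    scales: np.ndarray | None = None,
) -> dict[str, float]:
    """All nine engineered features of one window, as an ordered dict."""
    feats = hudgins_features(window, epsilon=epsilon)
    feats.update(cwt_features(window, scales=scales))
    return {name: feats[name] for name in FEATURE_NAMES}


def _window_rows(windows, epsilon, scales):
    rows = []
    for w in windows:
        row = {
            "subject_id": w.subject_id,
            "channel": w.source_channel,
            "trial": w.trial,
            "kind": w.kind,
        }
        row.update(extract_features(w, epsilon=epsilon, scales=scales))
        rows.append(row)
    return rows


def session_feature_table(
    recording,
    channels: tuple[str, ...] = ("br_semg", "fds_semg"),
    epsilon="auto",
    include_trial_reference: bool = True,
) -> pd.DataFrame:
    """Per-trial feature rows for one recording.

    Emits one row per (channel, trial) for the *active* (hold-phase)
    window and, when ``include_trial_reference`` is set, one row per
    (channel, trial) for the whole 5-s MVC trial.  The whole-trial rows
    serve as the MVC normalization reference.
    """
    fs = recording.sampling_rate
    scales = default_cwt_scales(fs)
    rows = []
    for channel in channels:
        active = segment_active_windows(recording, channel)
        rows.extend(_window_rows(active, epsilon, scales))
        if include_trial_reference:
            x = np.asarray(recording.channels[channel], dtype=float)
            trial_windows = [
                Window(
                    samples=x[start:stop],
                    sampling_rate=fs,
                    source_channel=channel,
                    t1=start / fs,
                    t2=stop / fs,
                    subject_id=recording.subject_id,
                    trial=i,
                    kind="trial",
                )
                for i, (start, stop) in enumerate(recording.trial_boundaries)
            ]
            rows.extend(_window_rows(trial_windows, epsilon, scales))
    return pd.DataFrame(rows)


def mvc_normalize(
    feature_table: pd.DataFrame,
    reference_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Normalize features to the mean of the three MVC trials.

    Every feature value is divided by the mean, over the subject's three
    MVC trials on the same channel, of that feature in the *reference*
    table.  With ``reference_table=None`` the table is its own reference,
    so the per-subject mean of normalized trial values is exactly 1.  The
    screening pipeline instead normalizes hold-phase (active-window)
    features by whole-trial references, so fatigue-driven amplitude drift
    during the hold survives normalization.
    """
    if feature_table.empty:
        raise ValueError("empty feature table")
    ref = feature_table if reference_table is None else reference_table
    feature_cols = [c for c in FEATURE_NAMES if c in feature_table.columns]

    ref_means = ref.groupby(["subject_id", "channel"])[feature_cols].agg(["mean", "count"])
    out = feature_table.copy()
    out[feature_cols] = out[feature_cols].astype(float)
    for (subject, channel), group_idx in out.groupby(["subject_id", "channel"]).groups.items():
        if (subject, channel) not in ref_means.index:
            raise ValueError(f"no MVC reference trials for {subject}/{channel}")
        ref_row = ref_means.loc[(subject, channel)]
        for feat in feature_cols:
            n_trials = int(ref_row[(feat, "count")])
            if n_trials != 3:
                raise ValueError(
                    f"{subject}/{channel}: expected 3 MVC reference trials "
                    f"for {feat}, found {n_trials}"
                )
            denom = float(ref_row[(feat, "mean")])
            if denom == 0:
                raise ValueError(
                    f"zero MVC-trial mean for subject {subject}, feature {feat}"
                )
            out.loc[group_idx, feat] = out.loc[group_idx, feat] / denom
    out["normalized"] = True
    return out


def group_compare(
    feature_table: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per-feature two-group comparison (Mann–Whitney U, BH-corrected).

    ``feature_table`` holds one or more rows per subject (rows are first
    averaged within subject so the test unit is the subject); ``labels``
    maps subject_id to ``"healthy"`` / ``"sarcopenia"``.  Returns one row
    per feature with group means, direction, U statistic, raw p and
    Benjamini–Hochberg adjusted p across the nine features.
    """
    from statsmodels.stats.multitest import multipletests

    labels = pd.Series(dict(labels))
    feature_cols = [c for c in FEATURE_NAMES if c in feature_table.columns]
    per_subject = feature_table.groupby("subject_id")[feature_cols].mean()
    groups = labels.loc[per_subject.index]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    for g in names:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    a = per_subject[groups == "healthy"]
    b = per_subject[groups == "sarcopenia"]

    rows = []
    for feat in feature_cols:
        u, p = stats.mannwhitneyu(a[feat], b[feat], alternative="two-sided")
        mean_h, mean_s = float(a[feat].mean()), float(b[feat].mean())
        rows.append(
            {
                "feature": feat,
                "mean_healthy": mean_h,
                "mean_sarcopenia": mean_s,
                "direction": "sarcopenia>healthy" if mean_s > mean_h else "healthy>sarcopenia",
                "U": float(u),
                "p": float(p),
            }
        )
    result = pd.DataFrame(rows).set_index("feature")
    result["p_adj"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    return result
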