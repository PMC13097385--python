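"""Feature engineering: Hudgins set, CWT features, MVC normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from sarcoscreen.features import (
    CWT_NAMES,
    FEATURE_NAMES,
    HUDGINS_NAMES,
    cwt_features,
    extract_features,
    group_compare,
    hudgins_features,
    mvc_normalize,
)
from sarcoscreen.preprocess import Window


def brute_force_hudgins(x, dt, eps):
    """Naive loop re-implementation used as the independent oracle."""
    n = len(x)
    rms = (sum(v * v for v in x) / n) ** 0.5
    mav = sum(abs(v) for v in x) / n
    iemg = sum(abs(v) for v in x) * dt
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    zc = 0
    for i in range(n - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) > eps:
            zc += 1
    ssc = 0
    for i in range(1, n - 1):
        d1, d2 = x[i] - x[i - 1], x[i] - x[i + 1]
        if d1 * d2 > 0 and abs(d1) > eps and abs(d2) > eps:
            ssc += 1
    return {"rms": rms, "mav": mav, "iemg": iemg, "wl": wl, "zc": zc, "ssc": ssc}


class TestHudgins:
    def test_hand_computed_two_sample_window(self):
        f = hudgins_features(np.array([3.0, -4.0]), epsilon=0.0, sampling_rate=1000.0)
        assert f["rms"] == pytest.approx(np.sqrt(12.5))
        assert f["mav"] == pytest.approx(3.5)
        assert f["iemg"] == pytest.approx(0.007)
        assert f["wl"] == pytest.approx(7.0)
        assert f["zc"] == 1

    def test_constant_window_degenerate(self):
        f = hudgins_features(np.full(64, -2.5), epsilon=0.0, sampling_rate=1000.0)
        assert f["rms"] == pytest.approx(2.5)
        assert f["mav"] == pytest.approx(2.5)
        assert f["wl"] == 0 and f["zc"] == 0 and f["ssc"] == 0

    def test_alternating_window(self):
        f = hudgins_features(
            np.array([1.0, -1.0, 1.0, -1.0]), epsilon=0.0, sampling_rate=1000.0
        )
        assert f["zc"] == 3 and f["ssc"] == 2 and f["wl"] == 6

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.integers(-20, 20, size=rng.integers(8, 64)).astype(float)
            got = hudgins_features(x, epsilon=0.0, sampling_rate=500.0)
            want = brute_force_hudgins(list(x), 1 / 500.0, 0.0)
            for k in HUDGINS_NAMES:
                assert got[k] == pytest.approx(want[k], abs=1e-12), k

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hnp.arrays(float, st.integers(2, 64), elements=st.floats(-100, 100)),
    )
    def test_rms_dominates_mav(self, x):
        f = hudgins_features(x, epsilon=0.0, sampling_rate=1000.0)
        assert f["rms"] >= f["mav"] - 1e-12

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=256)
        eps = 0.01 * np.sqrt(np.mean(x * x))
        gain = 7.5
        base = hudgins_features(x, epsilon=eps, sampling_rate=1000.0)
        scaled = hudgins_features(gain * x, epsilon=gain * eps, sampling_rate=1000.0)
        for k in ("rms", "mav", "iemg", "wl"):
            assert scaled[k] == pytest.approx(gain * base[k])
        assert scaled["zc"] == base["zc"] and scaled["ssc"] == base["ssc"]

    def test_short_window_raises(self):
        with pytest.raises(ValueError):
            hudgins_features(np.array([1.0]), sampling_rate=1000.0)


class TestCWT:
    FS = 1000.0

    def test_zero_window_has_zero_power(self):
        f = cwt_features(np.zeros(256), sampling_rate=self.FS)
        assert f["cwt_power"] == 0.0

    def test_narrowband_entropy_below_broadband(self):
        t = np.arange(1024) / self.FS
        rng = np.random.default_rng(11)
        narrow_we = []
        broad_we = []
        for _ in range(5):
            tone = np.sin(2 * np.pi * 80 * t + rng.uniform(0, 2 * np.pi))
            narrow_we.append(cwt_features(tone, sampling_rate=self.FS)["we"])
            broad_we.append(
                cwt_features(rng.normal(size=1024), sampling_rate=self.FS)["we"]
            )
        assert max(narrow_we) < min(broad_we)

    def test_entropy_bounded_by_log_scale_count(self):
        rng = np.random.default_rng(13)
        f = cwt_features(rng.normal(size=512), sampling_rate=self.FS)
        assert 0.0 <= f["we"] <= np.log(32) + 1e-9

    def test_entropy_invariant_to_gain(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=512)
        a = cwt_features(x, sampling_rate=self.FS)["we"]
        b = cwt_features(50.0 * x, sampling_rate=self.FS)["we"]
        assert a == pytest.approx(b, rel=1e-9)


def test_feature_vector_has_exactly_nine_named_entries():
    rng = np.random.default_rng(17)
    w = Window(samples=rng.normal(size=512), sampling_rate=1000.0)
    feats = extract_features(w)
    assert tuple(feats) == FEATURE_NAMES
    assert len(HUDGINS_NAMES) == 6 and len(CWT_NAMES) == 3


def _table(values_by_subject, feature="rms"):
    rows = []
    for subject, vals in values_by_subject.items():
        for trial, v in enumerate(vals):
            rows.append(
                {"subject_id": subject, "channel": "br_semg", "trial": trial,
                 "kind": "active", feature: v}
            )
    return pd.DataFrame(rows)


class TestMVCNormalize:
    def test_simple_arithmetic(self):
        out = mvc_normalize(_table({"A": [2.0, 3.0, 4.0]}))
        assert np.allclose(sorted(out["rms"]), [2 / 3, 1.0, 4 / 3])
        assert out["rms"].mean() == pytest.approx(1.0)

    def test_identical_trials_map_to_ones(self):
        out = mvc_normalize(_table({"A": [5.0, 5.0, 5.0]}))
        assert np.allclose(out["rms"], 1.0)

    def test_per_subject_mean_is_exactly_one(self):
        rng = np.random.default_rng(19)
        table = _table({f"S{i}": rng.uniform(1, 9, 3).tolist() for i in range(6)})
        out = mvc_normalize(table)
        for _, grp in out.groupby("subject_id"):
            assert grp["rms"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_trial_mean_names_the_subject(self):
        with pytest.raises(ValueError, match="ZZ"):
            mvc_normalize(_table({"ZZ": [0.0, 0.0, 0.0]}))

    def test_wrong_trial_count_raises(self):
        with pytest.raises(ValueError, match="3 MVC"):
            mvc_normalize(_table({"A": [1.0, 2.0]}))

    def test_external_reference_preserves_ratio(self):
        active = _table({"A": [4.0, 4.0, 4.0]})
        reference = _table({"A": [2.0, 2.0, 2.0]})
        out = mvc_normalize(active, reference_table=reference)
        assert np.allclose(out["rms"], 2.0)


class TestGroupCompare:
    def test_single_group_raises(self):
        table = _table({"A": [1, 2, 3], "B": [2, 3, 4]})
        with pytest.raises(ValueError):
            group_compare(table, {"A": "healthy", "B": "healthy"})

    def test_shifted_groups_detected_with_direction(self):
        rng = np.random.default_rng(21)
        vals = {}
        labels = {}
        for i in range(12):
            healthy = i < 6
            mu = 1.0 if healthy else 2.0
            vals[f"S{i}"] = (mu + 0.05 * rng.normal(size=3)).tolist()
            labels[f"S{i}"] = "healthy" if healthy else "sarcopenia"
        res = group_compare(_table(vals), labels)
        assert res.loc["rms", "p_adj"] < 0.01
        assert res.loc["rms", "direction"] == "sarcopenia>healthy"
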