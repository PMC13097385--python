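#!/usr/bin/env python
"""Descriptive signal analyses: SNR, median frequency, STFT centroid.

Regenerates the cohort of 01 and measures, per group: the sEMG
signal-to-noise ratio (MVC hold window vs pre-trial rest), the Welch
median frequency of each active window, and the mean STFT spectral
centroid — the spectral summary behind the observation that sarcopenic
sEMG concentrates its energy in lower-frequency bands.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sarcoscreen.cohort import generate_cohort
from sarcoscreen.preprocess import (
    compute_snr,
    median_frequency,
    segment_active_windows,
    spectral_centroid,
    stft_spectrogram,
)

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    recordings, profiles = generate_cohort(n_subjects=75, prevalence=0.4, seed=SEED)

    rows = []
    for rec, prof in zip(recordings, profiles):
        for channel in ("br_semg", "fds_semg"):
            windows = segment_active_windows(rec, channel)
            rest = rec.channels[channel][: rec.trial_boundaries[0][0]]
            for w in windows:
                spec = stft_spectrogram(w.samples, rec.sampling_rate)
                rows.append(
                    {
                        "subject_id": prof.subject_id,
                        "group": prof.group_label,
                        "channel": channel,
                        "trial": w.trial,
                        "median_frequency_hz": median_frequency(w),
                        "snr_db": compute_snr(w.samples, rest),
                        "stft_centroid_hz": float(np.nanmean(spectral_centroid(spec))),
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "signal_analysis_windows.csv", index=False, float_format="%.3f")

    summary = table.groupby("group")[
        ["median_frequency_hz", "snr_db", "stft_centroid_hz"]
    ].mean().round(2)
    summary.to_csv(OUT / "signal_analysis_by_group.csv")
    print("per-group signal statistics (means over active windows):")
    print(summary.to_string())
    mf_h = summary.loc["healthy", "median_frequency_hz"]
    mf_s = summary.loc["sarcopenia", "median_frequency_hz"]
    print(f"\nmedian frequency drops {mf_h:.1f} -> {mf_s:.1f} Hz with sarcopenia; "
          "the STFT centroid shows the same low-frequency shift.")


if __name__ == "__main__":
    main()
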