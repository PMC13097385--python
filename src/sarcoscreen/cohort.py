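"""Synthetic cohorts of coupled sEMG + piezoelectric-strain recordings.

The clinical data this pipeline was designed around are not publicly
deposited, so this module generates virtual cohorts with the statistical
structure the downstream analysis assumes:

* **sEMG** is a superposition of motor-unit action-potential (MUAP)
  trains.  Each motor unit has a recruitment threshold (fraction of
  maximal effort), a biphasic MUAP kernel (first derivative of a
  Gaussian, whose time support sets its spectral content) and a renewal
  firing process with Gamma inter-pulse intervals.
* **Sarcopenia** is modelled as motor-unit loss with enlargement of the
  survivors: fewer units, longer-duration (lower-frequency) and larger
  MUAPs, an attenuated composite amplitude, and a stronger within-hold
  fatigue drift.  These knobs reproduce the characteristic median-
  frequency decline (healthy ≈ 90–120 Hz vs sarcopenic ≈ 65–75 Hz) and
  the raw-amplitude reduction seen on wearable sensors.
* **Strain** is the output of a piezoelectric (PVDF) film: a first-order
  rate-sensitive response to the grip-force envelope, so constant force
  decays to zero and force ramps produce plateaus proportional to the
  ramp slope.
* **Metadata** (sex, age, grip strength, SMI, chair-stand time) are drawn
  per group and rejection-sampled until the AWGS-2019 rule reproduces the
  intended group label, so labels are consistent by construction.

A session mirrors the handgrip protocol: three 5-s maximal voluntary
contractions (trapezoidal effort: ramp up, hold, ramp down) separated by
4–6 s rests, recorded on four channels (sEMG + strain for the
brachioradialis BR and flexor digitorum superficialis FDS) at 1000 Hz.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .screening import classify_awgs

__all__ = [
    "MotorUnit",
    "SubjectProfile",
    "SimulationConfig",
    "Recording",
    "CHANNEL_NAMES",
    "build_motor_unit_pool",
    "muap_kernel",
    "simulate_semg",
    "simulate_strain",
    "trapezoid_effort",
    "generate_session",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

CHANNEL_NAMES = ("br_semg", "br_strain", "fds_semg", "fds_strain")


@dataclass(frozen=True)
class MotorUnit:
    """One motor unit: MUAP kernel shape plus recruitment/firing behaviour."""

    muap_amplitude: float        # mV, kernel peak
    muap_duration: float         # ms, kernel time support (6 sigma)
    recruitment_threshold: float  # fraction of MVC effort, [0, 1)
    mean_firing_rate: float      # Hz at full recruitment

    def __post_init__(self) -> None:
        if self.muap_duration <= 0:
            raise ValueError("muap_duration must be > 0")
        if not 0 <= self.recruitment_threshold < 1:
            raise ValueError("recruitment_threshold must be in [0, 1)")
        if self.mean_firing_rate <= 0:
            raise ValueError("mean_firing_rate must be > 0")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    sex: str                  # "male" | "female"
    age: float                # years, >= 60 in this screening population
    grip_strength: float      # kg, mean of three MVC trials
    smi: float                # kg/m^2
    chair_stand_time: float   # s, five chair stands
    group_label: str          # "healthy" | "sarcopenia"

    def __post_init__(self) -> None:
        if self.age < 60:
            raise ValueError("cohort is restricted to adults aged 60+")
        if self.grip_strength <= 0 or self.smi <= 0:
            raise ValueError("grip_strength and smi must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Frozen generator defaults; the calibration lives here.

    The MUAP duration / duration scale pair is calibrated so Welch median
    frequency lands near 105 Hz for healthy pools and near 70 Hz for
    sarcopenic pools; ``noise_sd`` is set for an MVC-window SNR in the
    low-30-dB range typical of good hydrogel electrodes.
    """

    sampling_rate: float = 1000.0
    # motor-unit pool
    n_motor_units_healthy: int = 60
    n_motor_units_sarcopenic: int = 26
    muap_amplitude_mv: float = 0.13
    muap_duration_ms: float = 10.0
    duration_jitter: float = 0.08
    duration_scale_sarcopenic: float = 1.45
    mu_enlargement_sarcopenic: float = 1.3
    fds_duration_factor: float = 1.0
    threshold_max: float = 0.7
    mean_firing_rate: float = 22.0
    firing_cv: float = 0.15
    # group-level signal knobs
    amplitude_attenuation_sarcopenic: float = 0.55
    fatigue_ramp: float = 0.02              # /s amplitude drift in hold, healthy
    fatigue_ramp_sarcopenic: float = 0.10   # /s, sarcopenic
    ramp_exponent: float = 1.0              # effort ramp shape (t/T)^p, healthy
    ramp_exponent_sarcopenic: float = 2.0   # slowed force development
    fatigue_jitter: float = 0.25            # relative SD of per-subject ramp
    mf_trial_drift: float = 0.02            # duration multiplier per trial index
    noise_sd: float = 0.005                 # mV, sEMG sensor noise
    # strain channel
    strain_gain: float = 0.02               # V per (kg/s) of force rate, times tau
    strain_tau_s: float = 0.2
    strain_noise_sd: float = 0.004          # V
    # protocol timing
    ramp_s: float = 0.5
    hold_s: float = 4.0
    rest_range_s: tuple[float, float] = (4.0, 6.0)
    lead_s: float = 2.0
    tail_s: float = 2.0
    # cohort plumbing
    max_rejections: int = 500
    seed: int = 0

    @property
    def trial_s(self) -> float:
        return 2 * self.ramp_s + self.hold_s

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in (
            "duration_scale_sarcopenic",
            "amplitude_attenuation_sarcopenic",
            "mu_enlargement_sarcopenic",
            "fds_duration_factor",
            "strain_gain",
            "strain_tau_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        data = json.loads(Path(path).read_text())
        if "rest_range_s" in data:
            data["rest_range_s"] = tuple(data["rest_range_s"])
        return cls(**data)


@dataclass
class Recording:
    """One subject session: four synchronized channels plus trial intervals.

    ``trial_boundaries`` are 0-based half-open sample intervals, one per
    MVC trial, each exactly ``trial_s * sampling_rate`` samples long.
    """

    channels: dict[str, np.ndarray]
    sampling_rate: float
    trial_boundaries: list[tuple[int, int]]
    subject_id: str

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNEL_NAMES):
            raise ValueError(f"expected channels {CHANNEL_NAMES}")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        if len(self.trial_boundaries) != 3:
            raise ValueError("a session holds exactly 3 MVC trials")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


# ---------------------------------------------------------------------------
# motor-unit pool and sEMG synthesis
# ---------------------------------------------------------------------------

def build_motor_unit_pool(
    group_label: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    duration_factor: float = 1.0,
) -> list[MotorUnit]:
    """Draw a motor-unit pool for one muscle of one subject.

    Recruitment thresholds are strictly ascending and MUAP amplitude is a
    monotone function of threshold (the size principle: later-recruited
    units are larger).  Sarcopenic pools are smaller, with durations
    scaled by ``duration_scale_sarcopenic`` and amplitudes by
    ``mu_enlargement_sarcopenic`` (surviving units have expanded
    innervation territories).
    """
    if group_label == "healthy":
        n = config.n_motor_units_healthy
        dur_scale, amp_scale = 1.0, 1.0
    elif group_label == "sarcopenia":
        n = config.n_motor_units_sarcopenic
        dur_scale = config.duration_scale_sarcopenic
        amp_scale = config.mu_enlargement_sarcopenic
    else:
        raise ValueError(f"unknown group label {group_label!r}")
    if n <= 0:
        raise ValueError("motor-unit count must be positive")

    thresholds = np.sort(rng.uniform(0.0, config.threshold_max, size=n))
    # enforce strict ordering even under ties
    thresholds = np.maximum.accumulate(thresholds + np.arange(n) * 1e-12)
    durations = (
        config.muap_duration_ms
        * duration_factor
        * rng.lognormal(0.0, config.duration_jitter, size=n)
    )
    rates = config.mean_firing_rate * rng.uniform(0.9, 1.1, size=n)
    amplitudes = config.muap_amplitude_mv * (0.4 + 1.2 * thresholds)
    return [
        MotorUnit(
            muap_amplitude=float(amplitudes[i] * amp_scale),
            muap_duration=float(durations[i] * dur_scale),
            recruitment_threshold=float(thresholds[i]),
            mean_firing_rate=float(rates[i]),
        )
        for i in range(n)
    ]


def muap_kernel(
    duration_ms: float, amplitude_mv: float, sampling_rate: float
) -> np.ndarray:
    """Biphasic MUAP kernel: first derivative of a Gaussian, peak-normalized.

    ``duration_ms`` is the 6-sigma time support; longer kernels have
    lower-frequency spectra (power spectrum ~ f^2 exp(-(2*pi*sigma*f)^2)),
    which is what drives the sarcopenic median-frequency decline.
    """
    sigma = duration_ms / 6.0 / 1000.0  # s
    half = max(1, int(np.ceil(3 * sigma * sampling_rate)))
    t = np.arange(-half, half + 1) / sampling_rate
    kernel = (t / sigma) * np.exp(0.5 - t**2 / (2 * sigma**2))
    return amplitude_mv * kernel


def _renewal_spikes(
    t_start: float,
    t_stop: float,
    rate: float,
    cv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spike times of a Gamma renewal process on [t_start, t_stop)."""
    mean_ipi = 1.0 / rate
    shape = 1.0 / (cv * cv)
    scale = mean_ipi / shape
    times = []
    # random initial phase so trains are not locked to recruitment onset
    t = t_start + rng.uniform(0.0, mean_ipi)
    while t < t_stop:
        times.append(t)
        t += rng.gamma(shape, scale)
    return np.asarray(times)


def simulate_semg(
    pool: list[MotorUnit],
    effort_trace: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    return_spikes: bool = False,
):
    """Composite sEMG (mV) for one effort trace: superposed MUAP trains.

    A unit fires while the instantaneous effort exceeds its recruitment
    threshold; its spike train (Gamma renewal, CV ``firing_cv``) is
    convolved with its MUAP kernel.  Gaussian sensor noise of SD
    ``noise_sd`` is added; zero effort therefore yields noise only.
    """
    effort = np.asarray(effort_trace, dtype=float)
    if effort.size == 0:
        raise ValueError("empty effort trace")
    if effort.min() < 0 or effort.max() > 1:
        raise ValueError("effort must lie in [0, 1]")
    fs = config.sampling_rate
    n = effort.size
    out = np.zeros(n)
    spikes: dict[int, np.ndarray] = {}

    for idx, mu in enumerate(pool):
        recruited = effort > mu.recruitment_threshold
        if not recruited.any():
            if return_spikes:
                spikes[idx] = np.empty(0)
            continue
        train = np.zeros(n)
        unit_times = []
        padded = np.concatenate(([False], recruited, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, stop in zip(edges[::2], edges[1::2]):
            times = _renewal_spikes(
                start / fs, stop / fs, mu.mean_firing_rate, config.firing_cv, rng
            )
            unit_times.append(times)
            sample_idx = np.round(times * fs).astype(int)
            sample_idx = sample_idx[sample_idx < n]
            np.add.at(train, sample_idx, 1.0)
        kernel = muap_kernel(mu.muap_duration, mu.muap_amplitude, fs)
        out += np.convolve(train, kernel, mode="same")
        if return_spikes:
            spikes[idx] = (
                np.concatenate(unit_times) if unit_times else np.empty(0)
            )

    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, size=n)
    return (out, spikes) if return_spikes else out


# ---------------------------------------------------------------------------
# strain channel
# ---------------------------------------------------------------------------

def simulate_strain(
    effort_trace: np.ndarray,
    profile: SubjectProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piezoelectric strain-channel output (V) for one effort trace.

    The PVDF film responds to deformation *rate*: the grip-force envelope
    (effort x grip strength, kg) drives a first-order high-pass with time
    constant ``strain_tau_s``.  Constant force decays to zero; a ramp of
    slope s settles at ``strain_gain * strain_tau_s * s``.  Lower grip
    strength (sarcopenia) directly lowers the peak output.
    """
    effort = np.asarray(effort_trace, dtype=float)
    if effort.min() < 0 or effort.max() > 1:
        raise ValueError("effort must lie in [0, 1]")
    dt = 1.0 / config.sampling_rate
    tau = config.strain_tau_s
    alpha = tau / (tau + dt)
    force = effort * profile.grip_strength
    y = np.zeros_like(force)
    prev_x = 0.0  # the film starts unstrained; initial force is a step
    prev_y = 0.0
    gain = config.strain_gain
    for i in range(force.size):
        prev_y = alpha * (prev_y + gain * (force[i] - prev_x))
        prev_x = force[i]
        y[i] = prev_y
    if config.strain_noise_sd > 0:
        y = y + rng.normal(0.0, config.strain_noise_sd, size=y.size)
    return y


# ---------------------------------------------------------------------------
# session and cohort
# ---------------------------------------------------------------------------

def trapezoid_effort(config: SimulationConfig, ramp_exponent: float = 1.0) -> np.ndarray:
    """Effort trace of one MVC trial: ramp up, hold at 1.0, ramp down.

    ``ramp_exponent`` shapes the ramps as (t/T)^p; p > 1 models the
    slowed rate of force development characteristic of sarcopenic
    muscle (force arrives later within the same ramp time).
    """
    fs = config.sampling_rate
    n_ramp = int(round(config.ramp_s * fs))
    n_hold = int(round(config.hold_s * fs))
    frac = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    up = frac**ramp_exponent
    down = (1.0 - frac) ** ramp_exponent
    return np.concatenate([up, np.ones(n_hold), down])


def _fatigue_profile(config: SimulationConfig, ramp_rate: float) -> np.ndarray:
    """Within-trial amplitude multiplier: drifts up through the hold.

    Fatigue during a maximal contraction recruits additional drive, so
    the sEMG envelope grows through the hold; the multiplier is 1 during
    the ramp-up, grows linearly at ``ramp_rate``/s through the hold, and
    relaxes back to 1 during the ramp-down as drive collapses at release.
    """
    fs = config.sampling_rate
    n_ramp = int(round(config.ramp_s * fs))
    n_hold = int(round(config.hold_s * fs))
    hold_t = np.arange(n_hold) / fs
    hold = 1.0 + ramp_rate * hold_t
    down = np.linspace(hold[-1], 1.0, n_ramp)
    return np.concatenate([np.ones(n_ramp), hold, down])


def generate_session(
    profile: SubjectProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Recording:
    """Simulate one recording session (3 MVC trials, 4 channels).

    Per muscle a motor-unit pool is drawn once; each trial is synthesized
    with a per-trial MUAP-duration multiplier (``1 + mf_trial_drift *
    trial``) so median frequency drifts down across trials, and the
    within-hold fatigue multiplier applied to the sEMG envelope.  The
    sarcopenic composite is attenuated by
    ``amplitude_attenuation_sarcopenic``.  Sensor noise is added to the
    whole session at the end, so rests contain noise only.
    """
    fs = config.sampling_rate
    ramp_exp = (
        config.ramp_exponent_sarcopenic
        if profile.group_label == "sarcopenia"
        else config.ramp_exponent
    )
    effort_trial = trapezoid_effort(config, ramp_exponent=ramp_exp)
    n_trial = effort_trial.size

    rests = [config.lead_s]
    rests += list(rng.uniform(*config.rest_range_s, size=2))
    rests.append(config.tail_s)
    rest_lengths = [int(round(r * fs)) for r in rests]

    boundaries = []
    pos = rest_lengths[0]
    for t in range(3):
        boundaries.append((pos, pos + n_trial))
        pos += n_trial + rest_lengths[t + 1]
    n_total = pos

    effort = np.zeros(n_total)
    for start, stop in boundaries:
        effort[start:stop] = effort_trial

    if profile.group_label == "sarcopenia":
        base_ramp = config.fatigue_ramp_sarcopenic
        attenuation = config.amplitude_attenuation_sarcopenic
    else:
        base_ramp = config.fatigue_ramp
        attenuation = 1.0
    subject_ramp = base_ramp * rng.lognormal(0.0, config.fatigue_jitter)
    fatigue = _fatigue_profile(config, subject_ramp)

    noise_free = replace(config, noise_sd=0.0, strain_noise_sd=0.0)
    channels: dict[str, np.ndarray] = {}
    for muscle, dur_factor in (("br", 1.0), ("fds", config.fds_duration_factor)):
        pool = build_motor_unit_pool(
            profile.group_label, config, rng, duration_factor=dur_factor
        )
        semg = np.zeros(n_total)
        for t, (start, stop) in enumerate(boundaries):
            trial_pool = [
                replace(mu, muap_duration=mu.muap_duration * (1 + config.mf_trial_drift * t))
                for mu in pool
            ]
            trial_sig = simulate_semg(trial_pool, effort_trial, noise_free, rng)
            semg[start:stop] = trial_sig * fatigue * attenuation
        semg += rng.normal(0.0, config.noise_sd, size=n_total)
        channels[f"{muscle}_semg"] = semg
        channels[f"{muscle}_strain"] = simulate_strain(effort, profile, config, rng)

    ordered = {name: channels[name] for name in CHANNEL_NAMES}
    return Recording(
        channels=ordered,
        sampling_rate=fs,
        trial_boundaries=boundaries,
        subject_id=profile.subject_id,
    )


_METADATA = {
    ("healthy", "male"): {"grip": (36.0, 4.0), "smi": (7.9, 0.45), "chair": (9.0, 1.3)},
    ("healthy", "female"): {"grip": (25.0, 3.0), "smi": (6.5, 0.40), "chair": (9.0, 1.3)},
    ("sarcopenia", "male"): {"grip": (21.0, 4.0), "smi": (6.2, 0.40), "chair": (13.0, 2.0)},
    ("sarcopenia", "female"): {"grip": (13.5, 2.5), "smi": (4.9, 0.35), "chair": (13.0, 2.0)},
}


def _sample_profile(
    subject_id: str,
    group_label: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SubjectProfile:
    """Rejection-sample metadata until the AWGS rule matches the label."""
    sex = "male" if rng.uniform() < 0.5 else "female"
    age = float(np.floor(rng.uniform(60, 86)))
    params = _METADATA[(group_label, sex)]
    for _ in range(config.max_rejections):
        grip = max(1.0, rng.normal(*params["grip"]))
        smi = max(1.0, rng.normal(*params["smi"]))
        chair = max(3.0, rng.normal(*params["chair"]))
        if classify_awgs(sex, grip, smi, chair).classification == group_label:
            return SubjectProfile(
                subject_id=subject_id,
                sex=sex,
                age=age,
                grip_strength=float(grip),
                smi=float(smi),
                chair_stand_time=float(chair),
                group_label=group_label,
            )
    raise RuntimeError(
        f"could not sample AWGS-consistent metadata for {group_label}/{sex} "
        f"after {config.max_rejections} rejections"
    )


def generate_cohort(
    n_subjects: int = 75,
    prevalence: float = 0.4,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[list[Recording], list[SubjectProfile]]:
    """Generate a full virtual cohort (recordings + metadata).

    ``prevalence`` fixes the sarcopenia fraction (clipped so both groups
    have at least one subject).  Every profile's ``group_label`` equals
    the AWGS-2019 rule applied to its own metadata.  Deterministic given
    (config, seed): subject streams are spawned from one seed sequence.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    config = config or SimulationConfig()

    n_sarc = int(round(prevalence * n_subjects))
    n_sarc = min(max(n_sarc, 1), n_subjects - 1)
    labels = ["sarcopenia"] * n_sarc + ["healthy"] * (n_subjects - n_sarc)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_subjects)
    recordings, profiles = [], []
    for i, (label, child) in enumerate(zip(labels, child_seeds)):
        rng = np.random.default_rng(child)
        profile = _sample_profile(f"S{i:03d}", label, config, rng)
        recordings.append(generate_session(profile, config, rng))
        profiles.append(profile)
    return recordings, profiles


# ---------------------------------------------------------------------------
# on-disk formats: one CSV per session + a JSON manifest
# ---------------------------------------------------------------------------

def write_cohort(
    recordings: list[Recording],
    profiles: list[SubjectProfile],
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Write per-session CSVs and a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec, prof in zip(recordings, profiles):
        fname = f"{prof.subject_id}.csv"
        t = np.arange(rec.n_samples) / rec.sampling_rate
        df = pd.DataFrame({"time_s": t, **rec.channels})
        df.to_csv(out_dir / fname, index=False, float_format="%.6g")
        entries.append(
            {
                "subject_id": prof.subject_id,
                "file": fname,
                "sex": prof.sex,
                "age": prof.age,
                "grip_kg": prof.grip_strength,
                "smi": prof.smi,
                "chair_stand_s": prof.chair_stand_time,
                "group_label": prof.group_label,
                "sampling_rate": rec.sampling_rate,
                "trial_boundaries": [list(b) for b in rec.trial_boundaries],
                "seed": seed,
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(entries, indent=2))
    return manifest


def load_cohort(manifest_path: str | Path) -> tuple[list[Recording], list[SubjectProfile]]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    recordings, profiles = [], []
    for e in entries:
        df = pd.read_csv(manifest_path.parent / e["file"])
        rec = Recording(
            channels={name: df[name].to_numpy() for name in CHANNEL_NAMES},
            sampling_rate=float(e["sampling_rate"]),
            trial_boundaries=[tuple(b) for b in e["trial_boundaries"]],
            subject_id=e["subject_id"],
        )
        prof = SubjectProfile(
            subject_id=e["subject_id"],
            sex=e["sex"],
            age=float(e["age"]),
            grip_strength=float(e["grip_kg"]),
            smi=float(e["smi"]),
            chair_stand_time=float(e["chair_stand_s"]),
            group_label=e["group_label"],
        )
        recordings.append(rec)
        profiles.append(prof)
    return recordings, profiles
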