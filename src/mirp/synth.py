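"""Synthetic motor-imagery EEG with known ground-truth structure.

The generator emulates a cue-based four-task MI paradigm: per run, 40
trials (10 each of left hand, right hand, both feet, idle) in randomized
order, each trial 9 s (1 s fixation cross, 5 s task, 3 s inter-trial),
sampled at 500 Hz over 26 scalp electrodes.

Signal model per run:

* a 1/f background per channel (exponent configurable, default 1), plus
* one band-limited oscillatory source per (band, region) pair —
  amplitude-modulated narrowband noise, not pure sinusoids, so spatial
  filtering and PSD estimation behave realistically — projected onto the
  scalp through smooth spatial profiles peaked at the region's electrodes.

Class-dependent structure: during the 5-s task period of an MI trial the
alpha and beta sources of the class's motor region are attenuated by the
subject's ERD depth (left hand -> right M1, right hand -> left M1, feet ->
SMA), while theta and gamma sources receive a small task-band boost; idle
trials leave all amplitudes at baseline.

Across a cohort, ERD depth is a monotone function of the subject's
baseline SMA alpha relative power mixed with independent noise; the mixing
weight (``StudyConfig.coupling``) is the ground-truth effect size that the
downstream correlation analysis is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import RawRun, TASK_LABELS
from .preproc import fir_bandpass
from .spectral import BAND_ORDER, DEFAULT_BANDS

#: Class -> scalp region showing event-related desynchronization.
ERD_REGION = {"left": "R_M1", "right": "L_M1", "feet": "SMA"}

REGION_NAMES = ("SMA", "L_PMC", "R_PMC", "L_M1", "R_M1", "L_S1", "R_S1")


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Electrode labels, 2-D unit-disc positions, and region groupings."""

    labels: tuple[str, ...]
    positions: Mapping[str, tuple[float, float]]
    regions: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, members in self.regions.items():
            for e in members:
                if e not in self.labels:
                    raise ValueError(f"region {name!r} references unknown electrode {e!r}")
        seen: set[str] = set()
        for name, members in self.regions.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"regions overlap on electrodes {sorted(overlap)}")
            seen |= set(members)

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def position_array(self) -> np.ndarray:
        return np.array([self.positions[e] for e in self.labels])


_ROWS = {"F": 0.44, "FC": 0.22, "C": 0.0, "CP": -0.22, "P": -0.44}

DEFAULT_ELECTRODES = (
    "F3", "Fz", "F4",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P3", "P4",
)

DEFAULT_REGIONS = {
    "SMA": ("FCz", "Cz", "CPz"),
    "L_PMC": ("FC5", "FC3", "FC1"),
    "R_PMC": ("FC2", "FC4", "FC6"),
    "L_M1": ("C5", "C3", "C1"),
    "R_M1": ("C2", "C4", "C6"),
    "L_S1": ("CP5", "CP3", "CP1"),
    "R_S1": ("CP2", "CP4", "CP6"),
}


def _electrode_position(label: str) -> tuple[float, float]:
    row = label.rstrip("z0123456789")
    y = _ROWS[row]
    tail = label[len(row):]
    if tail == "z":
        return (0.0, y)
    n = int(tail)
    steps = (n + 1) // 2
    sign = -1.0 if n % 2 else 1.0
    return (sign * 0.15 * steps, y)


def default_montage() -> Montage:
    """The 26-electrode frontocentral/centroparietal montage with its seven
    sensorimotor region groupings (SMA, bilateral PMC/M1/S1)."""
    positions = {e: _electrode_position(e) for e in DEFAULT_ELECTRODES}
    return Montage(labels=DEFAULT_ELECTRODES, positions=positions,
                   regions=DEFAULT_REGIONS)


def region_gains(montage: Montage, sigma: float = 0.08) -> np.ndarray:
    """(n_electrodes, n_regions) spatial gains.

    Gain 1 on region members, Gaussian decay with distance to the nearest
    member elsewhere — a smooth, region-peaked forward projection.
    """
    pos = montage.position_array()
    regions = list(montage.regions)
    gains = np.zeros((montage.n_electrodes, len(regions)))
    for j, name in enumerate(regions):
        members = np.array([montage.positions[e] for e in montage.regions[name]])
        d = np.min(np.linalg.norm(pos[:, None, :] - members[None, :, :], axis=2), axis=1)
        gains[:, j] = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return gains


# ---------------------------------------------------------------------------
# Study configuration and subject profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Cohort- and paradigm-level parameters of a simulated study."""

    n_subjects: int = 20
    n_sessions: int = 7
    n_runs: int = 6
    trials_per_run: int = 40
    fs: float = 500.0
    fixation_s: float = 1.0
    task_s: float = 5.0
    intertrial_s: float = 3.0
    lead_in_s: float = 8.0
    #: ground-truth effect size: weight of baseline SMA alpha RP in ERD depth
    coupling: float = 0.8
    erd_depth_range: tuple[float, float] = (0.15, 0.6)
    theta_boost: float = 0.15
    gamma_boost: float = 0.25
    noise_scale: float = 10.0         # 1/f background SD, uV
    background_exponent: float = 1.0
    session_drift_sd: float = 0.05    # per-session band-amplitude jitter (log-SD)
    erd_session_sd: float = 0.25      # per-session multiplicative ERD jitter (log-SD)
    erd_trial_sd: float = 0.4         # per-trial engagement jitter (SD of N(1, sd))
    blink_rate_per_min: float = 10.0
    emg_rate_per_min: float = 3.0
    spatial_sigma: float = 0.08

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("number of subjects must be positive")
        if self.trials_per_run % len(TASK_LABELS):
            raise ValueError(
                f"trials_per_run must be divisible by {len(TASK_LABELS)}")
        if min(self.fixation_s, self.task_s, self.intertrial_s) <= 0:
            raise ValueError("trial phase durations must be positive")
        lo, hi = self.erd_depth_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("ERD depth range must lie within [0, 1]")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie within [0, 1]")

    @property
    def trial_s(self) -> float:
        return self.fixation_s + self.task_s + self.intertrial_s

    def null_effects(self) -> "StudyConfig":
        """Zero-class-information configuration: no ERD and no task-band
        boost, so no task carries any decodable signature."""
        return replace(self, coupling=0.0, erd_depth_range=(0.0, 0.0),
                       theta_boost=0.0, gamma_boost=0.0)


#: Plausible resting band amplitudes (uV, RMS of the narrowband source).
BASE_AMPLITUDES = {"theta": 4.0, "alpha": 9.0, "beta": 4.5, "gamma": 1.5}


@dataclass
class SubjectProfile:
    """Per-subject generative parameters, fully seeded."""

    subject_id: int
    band_region_amp: dict[str, dict[str, float]]
    erd_depth: dict[str, float]          # per MI class, in [0, 1]
    theta_boost: float
    gamma_boost: float
    session_drift_sd: float
    erd_session_sd: float
    blink_rate_per_min: float
    emg_rate_per_min: float
    noise_scale: float
    seed: int

    def __post_init__(self) -> None:
        for cls, d in self.erd_depth.items():
            if not 0 <= d <= 1:
                raise ValueError(f"ERD depth for {cls!r} must be in [0, 1], got {d}")
        for band, per_region in self.band_region_amp.items():
            if any(a <= 0 for a in per_region.values()):
                raise ValueError(f"non-positive amplitude in band {band!r}")
        if self.theta_boost < 0 or self.gamma_boost < 0:
            raise ValueError("task-band boosts must be >= 0")

    def nominal_alpha_rp(self, region: str = "SMA") -> float:
        """Baseline alpha relative power implied by the source amplitudes
        (oscillatory power = amplitude squared; background ignored)."""
        powers = {b: self.band_region_amp[b][region] ** 2 for b in BAND_ORDER}
        return powers["alpha"] / sum(powers.values())


def make_cohort(config: StudyConfig, seed: int) -> list[SubjectProfile]:
    """Draw a cohort whose ERD depth is coupled to baseline SMA alpha RP.

    The ERD depth of subject *i* is a monotone map of
    ``coupling * rank(alpha RP_i) + (1 - coupling) * u_i`` with independent
    uniform ``u_i``: coupling 1 gives a deterministic monotone relation
    (Spearman rho = 1 over the cohort), coupling 0 full independence.
    """
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    subject_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    alpha_latent = rng.uniform(size=n)
    jitters = rng.lognormal(mean=0.0, sigma=0.15, size=(n, len(BAND_ORDER)))
    noise_latent = rng.uniform(size=n)

    profiles: list[SubjectProfile] = []
    for i in range(n):
        amps = {}
        for j, band in enumerate(BAND_ORDER):
            a = BASE_AMPLITUDES[band] * jitters[i, j]
            if band == "alpha":
                a *= 0.6 + 0.8 * alpha_latent[i]
            amps[band] = {r: a for r in REGION_NAMES}
        profiles.append(SubjectProfile(
            subject_id=i + 1,
            band_region_amp=amps,
            erd_depth={c: 0.0 for c in ERD_REGION},
            theta_boost=config.theta_boost,
            gamma_boost=config.gamma_boost,
            session_drift_sd=config.session_drift_sd,
            erd_session_sd=config.erd_session_sd,
            blink_rate_per_min=config.blink_rate_per_min,
            emg_rate_per_min=config.emg_rate_per_min,
            noise_scale=config.noise_scale,
            seed=int(subject_seeds[i]),
        ))

    rp = np.array([p.nominal_alpha_rp() for p in profiles])
    ranks = rp.argsort().argsort() / max(n - 1, 1)
    z = config.coupling * ranks + (1.0 - config.coupling) * noise_latent
    lo, hi = config.erd_depth_range
    depth = lo + (hi - lo) * z
    for p, d in zip(profiles, depth):
        p.erd_depth = {c: float(d) for c in ERD_REGION}
    return profiles


# ---------------------------------------------------------------------------
# Run simulation
# ---------------------------------------------------------------------------

def _one_over_f(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float, scale: float) -> np.ndarray:
    import scipy.fft as sfft

    nfft = sfft.next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, nfft))
    spec = sfft.rfft(white, axis=-1)
    f = sfft.rfftfreq(nfft)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = sfft.irfft(spec * shaping, n=nfft, axis=-1)[:, :n_samples]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * scale


def simulate_run(profile: SubjectProfile, config: StudyConfig,
                 session: int, run: int, seed: int | None = None,
                 montage: Montage | None = None) -> RawRun:
    """Generate one continuous run with its ground-truth event table.

    Deterministic: identical (profile, config, session, run, seed) yields
    bit-identical output.  An explicit seed is required.
    """
    if seed is None:
        raise ValueError("simulate_run requires an explicit seed")
    if montage is None:
        montage = default_montage()
    fs = config.fs
    n_trials = config.trials_per_run
    n_samples = int(round((config.lead_in_s + n_trials * config.trial_s) * fs))
    rng = np.random.default_rng([profile.seed, session, run, seed])

    # Session-level state (shared across the session's runs)
    rng_sess = np.random.default_rng([profile.seed, session, 7777])
    band_drift = {
        b: float(rng_sess.lognormal(0.0, profile.session_drift_sd))
        for b in BAND_ORDER
    }
    erd_mult = {
        c: float(rng_sess.lognormal(0.0, profile.erd_session_sd))
        for c in ERD_REGION
    }
    depth_session = {
        c: float(np.clip(profile.erd_depth[c] * erd_mult[c], 0.0, 0.95))
        for c in ERD_REGION
    }

    # Event table: balanced labels in randomized order, cue-spacing trial_s
    labels = np.repeat(list(TASK_LABELS), n_trials // len(TASK_LABELS))
    labels = labels[rng.permutation(n_trials)]
    onsets = config.lead_in_s + config.fixation_s + np.arange(n_trials) * config.trial_s
    events = pd.DataFrame({
        "onset": onsets, "duration": config.task_s, "trial_type": labels,
    })

    gains = region_gains(montage, config.spatial_sigma)
    regions = list(montage.regions)
    data = np.zeros((montage.n_electrodes, n_samples))
    band_edges = dict(DEFAULT_BANDS.bands)

    # Per-trial MI engagement: trial-to-trial ERD fluctuation (attention)
    engagement = np.clip(
        rng.normal(1.0, config.erd_trial_sd, size=n_trials), 0.0, None)
    task_slices = []
    for k, (onset, label) in enumerate(zip(onsets, labels)):
        s0 = int(round(onset * fs))
        s1 = int(round((onset + config.task_s) * fs))
        task_slices.append((label, slice(s0, s1), engagement[k]))

    for band in BAND_ORDER:
        lo, hi = band_edges[band]
        srcs = fir_bandpass(rng.standard_normal((len(regions), n_samples)),
                            lo, hi, fs)
        srcs /= srcs.std(axis=-1, keepdims=True)
        for j, region in enumerate(regions):
            env = np.full(n_samples,
                          profile.band_region_amp[band][region] * band_drift[band])
            for cls, sl, engage in task_slices:
                factor = 1.0
                if band in ("alpha", "beta") and ERD_REGION.get(cls) == region:
                    depth = min(depth_session[cls] * engage, 0.95)
                    factor *= 1.0 - depth
                if band == "theta" and cls != "idle":
                    factor *= 1.0 + profile.theta_boost * engage
                if band == "gamma" and cls != "idle":
                    factor *= 1.0 + profile.gamma_boost * engage
                if factor != 1.0:
                    env[sl] *= factor
            srcs[j] *= env
        data += gains @ srcs

    if profile.noise_scale > 0:
        data += _one_over_f(rng, montage.n_electrodes, n_samples,
                            config.background_exponent, profile.noise_scale)

    return RawRun(
        data=data,
        channels=list(montage.labels),
        fs=fs,
        events=events,
        montage=montage,
        subject=profile.subject_id,
        session=session,
        run=run,
        extras={"ground_truth": {
            "erd_depth_session": depth_session,
            "band_drift": band_drift,
        }},
    )


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

EOG_CHANNELS = ("HEOG", "VEOG")


def _blink_waveform(fs: float) -> np.ndarray:
    t = np.arange(-0.3, 0.3, 1.0 / fs)
    return np.exp(-(t ** 2) / (2 * 0.08 ** 2))  # ~sub-4 Hz stereotyped bump


def inject_artifacts(run: RawRun, profile: SubjectProfile) -> RawRun:
    """Add blink and EMG-burst artifacts plus two dedicated EOG channels.

    Blinks are stereotyped slow transients added to frontal channels with a
    frontally-decaying gain and recorded (full-scale) on VEOG; EMG bursts
    are 30-100 Hz noise at random onsets on the lateral-most channels.
    Ground-truth artifact time courses are kept in ``extras``.
    """
    montage: Montage = run.montage
    if montage is None:
        raise ValueError("run must carry a montage (frontal channels needed)")
    fs = run.fs
    n = run.n_samples
    rng = np.random.default_rng(
        [profile.seed, run.session or 0, run.run or 0, 4242])
    pos = montage.position_array()
    y = pos[:, 1]
    x = pos[:, 0]

    data = run.data.copy()
    blink_tc = np.zeros(n)
    wave = _blink_waveform(fs)
    n_blinks = rng.poisson(profile.blink_rate_per_min * run.duration / 60.0)
    for _ in range(n_blinks):
        s0 = rng.integers(0, n - len(wave))
        amp = rng.normal(90.0, 10.0)
        blink_tc[s0:s0 + len(wave)] += amp * wave
    frontal_gain = np.clip(y / y.max() if y.max() > 0 else y, 0, None) ** 2 * 0.6
    data += frontal_gain[:, None] * blink_tc[None, :]

    emg_tc = np.zeros(n)
    lateral = np.flatnonzero(np.abs(x) >= 0.4)
    n_bursts = rng.poisson(profile.emg_rate_per_min * run.duration / 60.0)
    for _ in range(n_bursts):
        dur = rng.uniform(0.3, 1.0)
        m = int(dur * fs)
        s0 = int(rng.integers(0, n - m))
        src = rng.standard_normal(m + int(fs))
        src = fir_bandpass(src, 30.0, min(100.0, fs / 2 - 5), fs)[: m]
        src = src / src.std() * 20.0 * np.hanning(m)
        emg_tc[s0:s0 + m] += src
        for ch in lateral:
            data[ch, s0:s0 + m] += rng.uniform(0.5, 1.0) * src

    heog = 0.3 * blink_tc + rng.normal(0, 3.0, n)
    veog = 1.0 * blink_tc + rng.normal(0, 3.0, n)
    out = RawRun(
        data=np.vstack([data, heog, veog]),
        channels=list(run.channels) + list(EOG_CHANNELS),
        fs=fs,
        events=run.events.copy(),
        montage=montage,
        subject=run.subject,
        session=run.session,
        run=run.run,
        extras={**run.extras,
                "blink_truth": blink_tc, "emg_truth": emg_tc},
    )
    return out


def simulate_session_runs(profile: SubjectProfile, config: StudyConfig,
                          session: int, seed: int,
                          montage: Montage | None = None,
                          artifacts: bool = False) -> list[RawRun]:
    """All runs of one session, optionally with artifacts injected."""
    runs = []
    for r in range(1, config.n_runs + 1):
        run = simulate_run(profile, config, session, r, seed=seed, montage=montage)
        if artifacts:
            run = inject_artifacts(run, profile)
        runs.append(run)
    return runs
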