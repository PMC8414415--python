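"""Welch spectra, band power and relative power (RP) tables.

Relative power is the band power divided by the total power over 4-50 Hz,
computed per trial and electrode, then averaged trial -> run -> session.
The ratio-then-average order keeps every per-trial RP inside [0, 1].

The on-task change is ``delta RP = RP(task, MI mean) - RP(pre-task)`` per
band and electrode; because both stage RPs sum to 1 over the four bands,
the per-electrode band sum of delta RP is identically 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import DEFAULT_STAGES, EpochSet, RawRun, StageWindow, extract_epochs

MI_TASKS = ("left", "right", "feet")


@dataclass(frozen=True)
class BandScheme:
    """Contiguous, non-overlapping named bands covering a total range."""

    bands: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(edges, edges[1:]):
            if a_hi != b_lo:
                raise ValueError("bands must be contiguous and non-overlapping")
        if any(lo >= hi for lo, hi in edges):
            raise ValueError("band edges must satisfy lo < hi")

    @property
    def total(self) -> tuple[float, float]:
        edges = sorted(self.bands.values())
        return edges[0][0], edges[-1][1]

    def __iter__(self):
        return iter(self.bands.items())


#: theta / alpha / beta / low-gamma over the 4-50 Hz analysis range.
DEFAULT_BANDS = BandScheme(
    {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0),
     "gamma": (30.0, 50.0)}
)

BAND_ORDER = ("theta", "alpha", "beta", "gamma")


@dataclass
class PSDEstimate:
    freqs: np.ndarray           # Hz, uniform grid, step 1/window_s
    psd: np.ndarray             # (channels, freqs) density, uV^2/Hz
    window_s: float
    n_blocks: int

    def __post_init__(self) -> None:
        if (self.psd < 0).any():
            raise ValueError("PSD densities must be non-negative")


def welch_psd(segment: np.ndarray, fs: float, window_s: float = 0.5) -> PSDEstimate:
    """Welch PSD from Hamming-windowed, non-overlapping blocks.

    One-sided density normalisation: the integral of the PSD over frequency
    approximates the signal variance.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    nperseg = int(round(window_s * fs))
    if segment.shape[-1] < nperseg:
        raise ValueError(
            f"segment of {segment.shape[-1]} samples shorter than one "
            f"{nperseg}-sample Welch window"
        )
    freqs, psd = sps.welch(
        segment, fs=fs, window="hamming", nperseg=nperseg, noverlap=0,
        detrend="constant", scaling="density", axis=-1,
    )
    return PSDEstimate(
        freqs=freqs, psd=psd, window_s=window_s,
        n_blocks=segment.shape[-1] // nperseg,
    )


def band_power(psd: PSDEstimate, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal band power per channel over ``[lo, hi]`` Hz.

    Band edges that fall between grid points are handled by linear
    interpolation of the density, which keeps band power exactly additive
    over contiguous bands.
    """
    if hi <= lo:
        raise ValueError("band requires lo < hi")
    f = psd.freqs
    if lo < f[0] or hi > f[-1]:
        raise ValueError(f"band [{lo}, {hi}] outside PSD grid [{f[0]}, {f[-1]}]")
    inner = f[(f > lo) & (f < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    dens = np.array([np.interp(grid, f, ch) for ch in psd.psd])
    return np.trapezoid(dens, grid, axis=-1)


def relative_power(psd: PSDEstimate, band: tuple[float, float],
                   scheme: BandScheme = DEFAULT_BANDS) -> np.ndarray:
    """Band power normalised by total power over the scheme's full range."""
    lo_t, hi_t = scheme.total
    total = band_power(psd, lo_t, hi_t)
    if np.any(total <= 0):
        raise ValueError("zero total power; relative power undefined")
    return band_power(psd, band[0], band[1]) / total


def _epoch_rp(epochs: EpochSet, scheme: BandScheme, window_s: float) -> np.ndarray:
    """(epoch, band, channel) RP array for an epoch set."""
    out = np.empty((epochs.n_epochs, len(scheme.bands), len(epochs.channels)))
    for i in range(epochs.n_epochs):
        psd = welch_psd(epochs.data[i], epochs.fs, window_s)
        for j, (_, edges) in enumerate(scheme):
            out[i, j] = relative_power(psd, edges, scheme)
    return out


def stage_rp_table(runs: Iterable[RawRun],
                   stages: Sequence[StageWindow] = DEFAULT_STAGES,
                   scheme: BandScheme = DEFAULT_BANDS,
                   window_s: float = 0.5) -> pd.DataFrame:
    """Session-level RP per stage, band and electrode.

    RP is computed per trial, averaged over trials within each run, then
    over the session's runs.  The task stage is split by task into
    ``task_left`` / ``task_right`` / ``task_feet`` / ``task_idle``, and the
    three MI tasks are additionally averaged into ``task_mi_mean``.

    Returns a tidy frame: subject, session, stage, band, electrode, rp.
    """
    band_names = [name for name, _ in scheme]
    # accum[(subject, session, stage)] -> list of per-run (band, channel) means
    accum: dict[tuple, list[np.ndarray]] = {}
    channels = None
    for run in runs:
        if channels is None:
            channels = list(run.channels)
        key0 = (run.subject, run.session)
        for stage in stages:
            if stage.name == "task":
                for task in (*MI_TASKS, "idle"):
                    ep = extract_epochs(run, stage, labels_filter=[task])
                    if not ep.n_epochs:
                        raise ValueError(
                            f"no {task!r} trials for stage {stage.name!r} in run "
                            f"{run.subject}/{run.session}/{run.run}"
                        )
                    rp = _epoch_rp(ep, scheme, window_s).mean(axis=0)
                    accum.setdefault((*key0, f"task_{task}"), []).append(rp)
            else:
                ep = extract_epochs(run, stage)
                if not ep.n_epochs:
                    raise ValueError(
                        f"no trials for stage {stage.name!r} in run "
                        f"{run.subject}/{run.session}/{run.run}"
                    )
                rp = _epoch_rp(ep, scheme, window_s).mean(axis=0)
                accum.setdefault((*key0, stage.name), []).append(rp)
    if channels is None:
        raise ValueError("no runs supplied")

    records = []
    session_means = {key: np.mean(vals, axis=0) for key, vals in accum.items()}
    # MI-task mean over the three MI classes
    mi_keys = {}
    for (subj, sess, stage), arr in session_means.items():
        if stage in {f"task_{t}" for t in MI_TASKS}:
            mi_keys.setdefault((subj, sess), []).append(arr)
    for (subj, sess), arrs in mi_keys.items():
        if len(arrs) == len(MI_TASKS):
            session_means[(subj, sess, "task_mi_mean")] = np.mean(arrs, axis=0)

    for (subj, sess, stage), arr in session_means.items():
        for j, band in enumerate(band_names):
            for k, ch in enumerate(channels):
                records.append((subj, sess, stage, band, ch, arr[j, k]))
    return pd.DataFrame(
        records,
        columns=["subject", "session", "stage", "band", "electrode", "rp"],
    )


def delta_rp(rp_table: pd.DataFrame, task_stage: str = "task_mi_mean",
             baseline_stage: str = "pre_task") -> pd.DataFrame:
    """On-task RP change per (subject, session, band, electrode)."""
    keys = ["subject", "session", "band", "electrode"]
    task = rp_table[rp_table["stage"] == task_stage].set_index(keys)["rp"]
    base = rp_table[rp_table["stage"] == baseline_stage].set_index(keys)["rp"]
    if len(task) == 0 or len(base) == 0:
        raise ValueError(
            f"stages {task_stage!r} and {baseline_stage!r} must both be present"
        )
    if not task.index.sort_values().equals(base.index.sort_values()):
        raise ValueError("task and baseline stages cover different keys")
    out = (task - base).rename("delta_rp").reset_index()
    return out


def region_average(table: pd.DataFrame, montage,
                   regions: Sequence[str] | None = None,
                   value_col: str | None = None) -> pd.DataFrame:
    """Average a per-electrode tidy table over montage regions.

    Every electrode of a requested region must exist in the table; other key
    columns are preserved and the ``electrode`` column is replaced by
    ``region``.
    """
    if value_col is None:
        value_col = "delta_rp" if "delta_rp" in table.columns else "rp"
    if regions is None:
        regions = list(montage.regions)
    frames = []
    for region in regions:
        members = montage.regions.get(region)
        if not members:
            raise ValueError(f"region {region!r} empty or not in montage")
        sub = table[table["electrode"].isin(members)]
        if sub["electrode"].nunique() != len(members):
            raise ValueError(f"table missing electrodes of region {region!r}")
        keys = [c for c in table.columns if c not in ("electrode", value_col)]
        agg = sub.groupby(keys, as_index=False)[value_col].mean()
        agg.insert(len(keys), "region", region)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
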