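"""Data model and on-disk format for multichannel EEG runs.

A :class:`RawRun` couples a channels x samples matrix (microvolts) with its
sampling rate and an event table listing cue onsets and task labels for the
four motor-imagery tasks (left hand, right hand, both feet, idle).

Runs are stored in a BIDS-EEG-inspired layout: ``<prefix>_eeg.dat`` (raw
little-endian float32, channel-major), ``<prefix>_eeg.json`` (sidecar with
channel names, sampling rate, units) and ``<prefix>_events.tsv``
(tab-separated ``onset	duration	trial_type``).

Time convention: seconds relative to cue onset, cue at t = 0; sample
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirp")

TASK_LABELS = ("left", "right", "feet", "idle")

EVENT_COLUMNS = ("onset", "duration", "trial_type")


@dataclass
class StageWindow:
    """A named analysis window in seconds relative to cue onset."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"stage {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


#: Default trial stages: pre-task rest, the fixation-cross second, and the
#: central 4 s of the 5-s task period (first/last 0.5 s discarded).
DEFAULT_STAGES = (
    StageWindow("pre_task", -3.0, -1.0),
    StageWindow("cross", -1.0, 0.0),
    StageWindow("task", 0.5, 4.5),
)


def default_stages() -> list[StageWindow]:
    return [replace(s) for s in DEFAULT_STAGES]


@dataclass
class RawRun:
    """One continuous multichannel recording plus its event table.

    Parameters
    ----------
    data
        Channels x samples array in microvolts.
    channels
        Channel labels, same order as rows of ``data``.
    fs
        Sampling rate in Hz.
    events
        DataFrame with columns ``onset`` (s), ``duration`` (s),
        ``trial_type`` (one of :data:`TASK_LABELS`).
    """

    data: np.ndarray
    channels: list[str]
    fs: float
    events: pd.DataFrame
    montage: object | None = None
    subject: int | None = None
    session: int | None = None
    run: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} rows"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        validate_events(self.events, n_samples=self.data.shape[1], fs=self.fs)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self, data: np.ndarray | None = None) -> "RawRun":
        return RawRun(
            data=self.data.copy() if data is None else data,
            channels=list(self.channels),
            fs=self.fs,
            events=self.events.copy(),
            montage=self.montage,
            subject=self.subject,
            session=self.session,
            run=self.run,
            extras=dict(self.extras),
        )

    def pick(self, channels: Sequence[str]) -> "RawRun":
        """Return a run restricted to the given channels (in that order)."""
        idx = [self.channels.index(c) for c in channels]
        return RawRun(
            data=self.data[idx].copy(), channels=list(channels), fs=self.fs,
            events=self.events.copy(), montage=self.montage,
            subject=self.subject, session=self.session, run=self.run,
            extras=dict(self.extras),
        )


def validate_events(events: pd.DataFrame, n_samples: int | None = None,
                    fs: float | None = None) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    bad = events.index[~events["trial_type"].isin(TASK_LABELS)]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"unknown trial_type {events.loc[row, 'trial_type']!r} in event row {row}; "
            f"expected one of {TASK_LABELS}"
        )
    if n_samples is not None and fs is not None and len(events):
        onsets = events["onset"].to_numpy(float)
        if (onsets < 0).any() or (onsets > n_samples / fs).any():
            raise ValueError("event onsets outside the recording")


# ---------------------------------------------------------------------------
# Disk I/O: float32 binary + JSON sidecar + events.tsv
# ---------------------------------------------------------------------------

def run_prefix(root: Path | str, subject: int, session: int, run: int) -> Path:
    """BIDS-inspired path prefix ``sub-XX/ses-YY/run-ZZ`` under *root*."""
    return Path(root) / f"sub-{subject:02d}" / f"ses-{session:02d}" / f"run-{run:02d}"


def write_run(run: RawRun, prefix: Path | str, quantize_16bit: bool = False) -> None:
    """Write a run as ``<prefix>_eeg.dat`` + ``_eeg.json`` + ``_events.tsv``.

    With ``quantize_16bit`` the samples are stored as int16 over the signal's
    physical range, emulating the sample precision of clinical EDF files.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if quantize_16bit:
        lo = float(run.data.min())
        hi = float(run.data.max())
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        q = np.round((run.data - lo) / scale - 32768.0).astype(np.int16)
        q.tofile(prefix.with_name(prefix.name + "_eeg.dat"))
        encoding = {"dtype": "int16", "physical_min": lo, "physical_max": hi}
    else:
        run.data.astype("<f4").tofile(prefix.with_name(prefix.name + "_eeg.dat"))
        encoding = {"dtype": "float32"}
    sidecar = {
        "channels": list(run.channels),
        "sampling_rate": run.fs,
        "n_samples": run.n_samples,
        "units": "uV",
        "subject": run.subject,
        "session": run.session,
        "run": run.run,
        **encoding,
    }
    prefix.with_name(prefix.name + "_eeg.json").write_text(
        json.dumps(sidecar, indent=1) + "\n"
    )
    run.events.loc[:, list(EVENT_COLUMNS)].to_csv(
        prefix.with_name(prefix.name + "_events.tsv"), sep="\t", index=False
    )


def read_run(prefix: Path | str, montage: object | None = None) -> RawRun:
    """Read a run written by :func:`write_run`."""
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_name(prefix.name + "_eeg.json").read_text())
    n_ch = len(sidecar["channels"])
    raw = np.fromfile(
        prefix.with_name(prefix.name + "_eeg.dat"),
        dtype=np.int16 if sidecar["dtype"] == "int16" else "<f4",
    )
    if raw.size != n_ch * sidecar["n_samples"]:
        raise ValueError(
            f"sample file holds {raw.size} values; sidecar promises "
            f"{n_ch} channels x {sidecar['n_samples']} samples"
        )
    data = raw.reshape(n_ch, sidecar["n_samples"]).astype(float)
    if sidecar["dtype"] == "int16":
        lo, hi = sidecar["physical_min"], sidecar["physical_max"]
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        data = (data + 32768.0) * scale + lo
    events = pd.read_csv(prefix.with_name(prefix.name + "_events.tsv"), sep="\t")
    return RawRun(
        data=data,
        channels=list(sidecar["channels"]),
        fs=sidecar["sampling_rate"],
        events=events,
        montage=montage,
        subject=sidecar.get("subject"),
        session=sidecar.get("session"),
        run=sidecar.get("run"),
    )


# ---------------------------------------------------------------------------
# Epoch extraction
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Labeled 3-D stack of trial segments (epoch x channel x sample)."""

    data: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame  # columns: subject, session, run, trial
    channels: list[str]
    fs: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epoch x channel x sample)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per epoch required")
        if len(self.provenance) != self.data.shape[0]:
            raise ValueError("provenance incomplete")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def __len__(self) -> int:
        return self.n_epochs


def extract_epochs(run: RawRun, window: StageWindow,
                   labels_filter: Iterable[str] | None = None) -> EpochSet:
    """Cut one epoch per matching trial, half-open ``[cue+start, cue+end)``.

    Trials whose window would extend past the recorded data are dropped with
    a logged warning rather than silently truncated.
    """
    fs = run.fs
    n_len = int(round(window.duration * fs))
    keep = run.events
    if labels_filter is not None:
        labels_filter = set(labels_filter)
        keep = keep[keep["trial_type"].isin(labels_filter)]
    segs, labels, prov = [], [], []
    for trial, row in keep.iterrows():
        s0 = int(round((row["onset"] + window.start) * fs))
        s1 = s0 + n_len
        if s0 < 0 or s1 > run.n_samples:
            logger.warning(
                "dropping trial %s: window [%g, %g) s exceeds recording",
                trial, row["onset"] + window.start, row["onset"] + window.end,
            )
            continue
        segs.append(run.data[:, s0:s1])
        labels.append(row["trial_type"])
        prov.append((run.subject, run.session, run.run, trial))
    data = (np.stack(segs) if segs
            else np.empty((0, run.n_channels, n_len)))
    return EpochSet(
        data=data,
        labels=np.asarray(labels, dtype=object),
        provenance=pd.DataFrame(prov, columns=["subject", "session", "run", "trial"]),
        channels=list(run.channels),
        fs=fs,
        window=(window.start, window.end),
    )


def concat_epochs(sets: Sequence[EpochSet]) -> EpochSet:
    """Stack epoch sets from multiple runs (same channels, fs, window)."""
    sets = [s for s in sets if s.n_epochs]
    if not sets:
        raise ValueError("no epochs to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.channels != first.channels or s.fs != first.fs or s.window != first.window:
            raise ValueError("epoch sets are not compatible")
    return EpochSet(
        data=np.concatenate([s.data for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        provenance=pd.concat([s.provenance for s in sets], ignore_index=True),
        channels=list(first.channels),
        fs=first.fs,
        window=first.window,
    )


def split_subepochs(epochs: EpochSet, sub_length_s: float) -> EpochSet:
    """Split each epoch into consecutive non-overlapping sub-epochs.

    Sub-epochs inherit the parent's label and provenance.  The epoch length
    must be an integer multiple of the sub-epoch length.
    """
    n_sub = int(round(sub_length_s * epochs.fs))
    n_len = epochs.data.shape[2]
    if n_sub <= 0:
        raise ValueError("sub-epoch length must be positive")
    if n_len % n_sub:
        raise ValueError(
            f"epoch length {n_len} samples not divisible by "
            f"sub-epoch length {n_sub} samples"
        )
    k = n_len // n_sub
    n_ep, n_ch = epochs.data.shape[:2]
    data = (
        epochs.data.reshape(n_ep, n_ch, k, n_sub)
        .transpose(0, 2, 1, 3)
        .reshape(n_ep * k, n_ch, n_sub)
    )
    prov = epochs.provenance.loc[epochs.provenance.index.repeat(k)].reset_index(drop=True)
    prov["subepoch"] = np.tile(np.arange(k), n_ep)
    start = epochs.window[0]
    return EpochSet(
        data=data,
        labels=np.repeat(epochs.labels, k),
        provenance=prov,
        channels=list(epochs.channels),
        fs=epochs.fs,
        window=(start, start + n_sub / epochs.fs),
    )
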