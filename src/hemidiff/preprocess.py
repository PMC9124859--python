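"""Scalp-level preprocessing: EDF ingest, epoching, band-pass, baselines.

Motor-imagery trials are cut as fixed 4 s windows starting at each task cue
(labels T1-T4) and band-pass filtered to 8-30 Hz, the mu + beta range where
event-related desynchronisation is expressed.  Rest stretches of the
recording are exposed separately as the baseline material from which the
sensor noise covariance is later estimated.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "EpochSet",
    "FilterSpec",
    "read_edf",
    "extract_epochs",
    "bandpass",
    "baseline_segments",
    "BandpassFilter",
]

MI_CLASSES = ("T1", "T2", "T3", "T4")


@dataclass
class RawRecording:
    """A continuous multichannel recording with cue annotations.

    samples : (n_channels, n_times) array in volts.
    annotations : list of ``(onset_s, duration_s, code)`` tuples.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"samples shape {self.samples.shape} does not match "
                f"{len(self.channel_names)} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class EpochSet:
    """Labelled fixed-length trials: ``epochs`` is trials x channels x samples.

    The channel axis can hold scalp electrodes, cortical sources or scout
    series; ``montage`` names the channels where meaningful.
    """

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    montage: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a trials x channels x samples array")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("label count must equal trial count")
        if self.montage is not None:
            self.montage = tuple(self.montage)
            if len(self.montage) != self.epochs.shape[1]:
                raise ValueError("montage length must equal channel count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def save(self, path) -> None:
        """Write epochs + labels to ``.npz`` with a JSON sidecar."""
        path = Path(path)
        np.savez_compressed(path, epochs=self.epochs,
                            labels=self.labels.astype(str))
        sidecar = {
            "fs": self.fs,
            "montage": list(self.montage) if self.montage else None,
            "shape": list(self.epochs.shape),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "EpochSet":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        montage = sidecar["montage"]
        return cls(epochs=data["epochs"], labels=data["labels"],
                   fs=sidecar["fs"],
                   montage=tuple(montage) if montage else None)


@dataclass
class FilterSpec:
    """Band-pass specification; default 8-30 Hz zero-phase Butterworth."""

    low: float = 8.0
    high: float = 30.0
    order: int = 4
    kind: str = "butter"
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low < self.high < fs / 2.0):
            raise ValueError(
                f"band [{self.low}, {self.high}] Hz invalid for fs={fs} Hz "
                "(need 0 < low < high < Nyquist)"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def read_edf(path) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording` (volts)."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    except Exception as exc:  # normalise reader errors to one message
        raise ValueError(f"could not parse EDF file {path.name}: {exc}") from exc
    data = raw.get_data()  # volts
    annotations = [
        (float(on), float(dur), str(desc))
        for on, dur, desc in zip(raw.annotations.onset,
                                 raw.annotations.duration,
                                 raw.annotations.description)
    ]
    if not annotations:
        warnings.warn(f"{path.name}: no annotations found", RuntimeWarning,
                      stacklevel=2)
    return RawRecording(samples=data, fs=float(raw.info["sfreq"]),
                        channel_names=tuple(raw.ch_names),
                        annotations=annotations)


def extract_epochs(
    raw: RawRecording,
    task_map: dict[str, str] | None = None,
    window_s: float = 4.0,
) -> EpochSet:
    """Cut one fixed-length epoch per task cue, starting at cue onset.

    ``task_map`` maps annotation codes to class labels (identity mapping of
    T1-T4 by default).  Cues whose window runs past the end of the recording
    are dropped with a logged count.
    """
    if task_map is None:
        task_map = {c: c for c in MI_CLASSES}
    n_samples = int(round(window_s * raw.fs))
    epochs, labels, dropped = [], [], 0
    for onset, _duration, code in raw.annotations:
        if code not in task_map:
            continue
        start = int(round(onset * raw.fs))
        if start + n_samples > raw.samples.shape[1]:
            dropped += 1
            continue
        epochs.append(raw.samples[:, start:start + n_samples])
        labels.append(task_map[code])
    if dropped:
        logger.info("extract_epochs: dropped %d cue(s) too close to the "
                    "recording end", dropped)
    if epochs:
        arr = np.stack(epochs)
    else:
        arr = np.empty((0, raw.samples.shape[0], n_samples))
    return EpochSet(epochs=arr, labels=np.array(labels, dtype="<U8"),
                    fs=raw.fs, montage=raw.channel_names)


def bandpass(epochs: EpochSet, spec: FilterSpec | None = None) -> EpochSet:
    """Band-pass filter every trial/channel; zero-phase by default.

    Zero-phase filtering runs the IIR filter forward and backward
    (``filtfilt``), doubling the effective order but leaving the 4 s epochs
    without group-delay distortion.
    """
    if spec is None:
        spec = FilterSpec()
    spec.validate(epochs.fs)
    if spec.kind != "butter":
        raise ValueError(f"unknown filter kind {spec.kind!r}")
    sos = sp_signal.butter(spec.order, [spec.low, spec.high],
                           btype="bandpass", fs=epochs.fs, output="sos")
    if spec.zero_phase:
        filtered = sp_signal.sosfiltfilt(sos, epochs.epochs, axis=-1)
    else:
        filtered = sp_signal.sosfilt(sos, epochs.epochs, axis=-1)
    return EpochSet(epochs=filtered, labels=epochs.labels.copy(),
                    fs=epochs.fs, montage=epochs.montage)


def baseline_segments(
    raw: RawRecording,
    policy: str = "rest",
    rest_code: str = "REST",
    min_gap_s: float = 0.5,
) -> list[np.ndarray]:
    """Collect rest segments (channels x samples) for noise-covariance use.

    policy "rest": use annotations labelled ``rest_code``.
    policy "inter-trial": use gaps of at least ``min_gap_s`` between
    annotated task windows.
    """
    segments: list[np.ndarray] = []
    if policy == "rest":
        for onset, duration, code in raw.annotations:
            if code != rest_code:
                continue
            a = int(round(onset * raw.fs))
            b = min(int(round((onset + duration) * raw.fs)),
                    raw.samples.shape[1])
            if b > a:
                segments.append(raw.samples[:, a:b])
    elif policy == "inter-trial":
        spans = sorted(
            (int(round(on * raw.fs)),
             int(round((on + dur) * raw.fs)))
            for on, dur, code in raw.annotations if code != rest_code
        )
        min_len = int(round(min_gap_s * raw.fs))
        prev_end = 0
        for a, b in spans + [(raw.samples.shape[1], raw.samples.shape[1])]:
            if a - prev_end >= min_len:
                segments.append(raw.samples[:, prev_end:a])
            prev_end = max(prev_end, b)
    else:
        raise ValueError(f"unknown baseline policy {policy!r}")
    if not segments:
        raise ValueError(
            f"no baseline segments found under policy {policy!r}; supply a "
            "noise covariance explicitly"
        )
    return segments


class BandpassFilter(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`bandpass`.

    Operates on :class:`EpochSet` or on plain trials x channels x samples
    arrays (then ``fs`` must be given).
    """

    def __init__(self, low: float = 8.0, high: float = 30.0, order: int = 4,
                 zero_phase: bool = True, fs: float | None = None):
        self.low = low
        self.high = high
        self.order = order
        self.zero_phase = zero_phase
        self.fs = fs

    def fit(self, X, y=None):
        fs = X.fs if isinstance(X, EpochSet) else self.fs
        if fs is None:
            raise ValueError("fs must be set to filter plain arrays")
        self._spec().validate(fs)
        self.n_features_in_ = (X.n_channels if isinstance(X, EpochSet)
                               else np.asarray(X).shape[1])
        return self

    def transform(self, X):
        if isinstance(X, EpochSet):
            return bandpass(X, self._spec())
        if self.fs is None:
            raise ValueError("fs must be set to filter plain arrays")
        tmp = EpochSet(epochs=np.asarray(X),
                       labels=np.zeros(np.asarray(X).shape[0], dtype="<U8"),
                       fs=self.fs)
        return bandpass(tmp, self._spec()).epochs

    def _spec(self) -> FilterSpec:
        return FilterSpec(low=self.low, high=self.high, order=self.order,
                          zero_phase=self.zero_phase)
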