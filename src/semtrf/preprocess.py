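"""Deterministic EEG preparation: filtering, resampling, z-scoring, epoching.

Stage order for the analysis pipeline: broadband band-pass (0.1-40 Hz) ->
audio alignment -> resample to 250 Hz -> narrow band-pass (1-20 Hz,
second-order, zero-phase) -> joint z-scoring of EEG and regressors over the
whole recording -> segmentation into fixed-length (default 60 s) trials.
Artifact decomposition (ICA/SOBI) and spherical-spline interpolation are out
of scope; bad channels are accepted as an input list and simply excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

from .features import RegressorSet

__all__ = [
    "EEGRecording",
    "EpochedData",
    "bandpass_filter",
    "resample_recording",
    "standardize",
    "epoch_trials",
    "standard_positions",
    "read_brainvision",
    "read_edf",
    "save_recording",
    "load_recording",
]

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """Multichannel EEG: (channels x samples) data with layout metadata.

    ``positions`` holds head-centered 3-D electrode coordinates in meters
    (row per channel, or None when no layout is known); ``bads`` lists
    channels to exclude from ROIs and adjacency.
    """

    data: np.ndarray
    rate: float
    ch_names: list[str]
    positions: np.ndarray | None = None
    bads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[0], 3):
                raise ValueError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, names: list[str]) -> "EEGRecording":
        idx = [self.ch_names.index(n) for n in names]
        return replace(
            self,
            data=self.data[idx],
            ch_names=list(names),
            positions=None if self.positions is None else self.positions[idx],
            bads=[b for b in self.bads if b in names],
        )


@dataclass
class EpochedData:
    """Fixed-length trials with sample-aligned EEG and regressor segments.

    ``eeg``: (n_trials, n_channels, n_samples); ``regs``: (n_trials,
    n_samples, n_features) in ``feature_names`` order; ``labels``: condition
    label per trial.
    """

    eeg: np.ndarray
    regs: np.ndarray
    feature_names: list[str]
    ch_names: list[str]
    rate: float
    labels: list[str]

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != self.regs.shape[0]:
            raise ValueError("EEG and regressor trial counts differ")
        if self.eeg.shape[2] != self.regs.shape[1]:
            raise ValueError("EEG and regressor trial lengths differ")
        if len(self.labels) != self.eeg.shape[0]:
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]

    def select(self, label: str) -> "EpochedData":
        """Trials of one condition."""
        idx = [i for i, lab in enumerate(self.labels) if lab == label]
        if not idx:
            raise ValueError(f"no trials labelled {label!r}")
        return EpochedData(
            eeg=self.eeg[idx],
            regs=self.regs[idx],
            feature_names=self.feature_names,
            ch_names=self.ch_names,
            rate=self.rate,
            labels=[label] * len(idx),
        )

    @staticmethod
    def concatenate(parts: list["EpochedData"]) -> "EpochedData":
        first = parts[0]
        return EpochedData(
            eeg=np.concatenate([p.eeg for p in parts], axis=0),
            regs=np.concatenate([p.regs for p in parts], axis=0),
            feature_names=first.feature_names,
            ch_names=first.ch_names,
            rate=first.rate,
            labels=[lab for p in parts for lab in p.labels],
        )


def bandpass_filter(
    recording: EEGRecording,
    low: float,
    high: float,
    order: int = 2,
    zero_phase: bool = True,
) -> EEGRecording:
    """Butterworth band-pass; forward-backward (zero-phase) by default."""
    nyq = recording.rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(
            f"invalid band {low}-{high} Hz for rate {recording.rate} Hz"
        )
    sos = signal.butter(order, [low, high], btype="band", fs=recording.rate, output="sos")
    if zero_phase:
        data = signal.sosfiltfilt(sos, recording.data, axis=1)
    else:
        data = signal.sosfilt(sos, recording.data, axis=1)
    logger.info("band-pass %.3g-%.3g Hz (order %d, zero_phase=%s)", low, high, order, zero_phase)
    return replace(recording, data=data)


def bandpass_regressors(
    regressors: RegressorSet,
    low: float,
    high: float,
    order: int = 2,
    zero_phase: bool = True,
) -> RegressorSet:
    """Apply the analysis band-pass to every regressor channel.

    Filtering stimulus features with the same filter as the EEG preserves the
    linear stimulus-response relationship (convolution commutes with the
    filter).
    """
    nyq = regressors.rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band {low}-{high} Hz for rate {regressors.rate} Hz")
    sos = signal.butter(order, [low, high], btype="band", fs=regressors.rate, output="sos")
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    return RegressorSet(
        channels={n: filt(sos, x) for n, x in regressors.channels.items()},
        rate=regressors.rate,
    )


def resample_recording(recording: EEGRecording, target: float) -> EEGRecording:
    """Polyphase anti-aliased resampling to ``target`` Hz."""
    if target > recording.rate:
        raise ValueError("target rate exceeds recording rate")
    if target == recording.rate:
        return recording
    frac = Fraction(target / recording.rate).limit_denominator(10_000)
    data = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    logger.info("resampled %g Hz -> %g Hz", recording.rate, target)
    return replace(recording, data=data, rate=target)


def standardize(
    recording: EEGRecording, regressors: RegressorSet
) -> tuple[EEGRecording, RegressorSet, list[str]]:
    """Z-score every EEG channel and regressor over the full recording.

    Zero-variance EEG channels are excluded (returned in the third element
    and logged); a zero-variance regressor channel is left as zeros rather
    than dropped so that model comparison against a constant channel stays
    well defined.
    """
    sd = recording.data.std(axis=1)
    keep = sd > 1e-12
    excluded = [n for n, k in zip(recording.ch_names, keep) if not k]
    if excluded:
        logger.warning("excluding zero-variance channels: %s", excluded)
    data = recording.data[keep]
    data = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
    rec = replace(
        recording,
        data=data,
        ch_names=[n for n, k in zip(recording.ch_names, keep) if k],
        positions=None if recording.positions is None else recording.positions[keep],
        bads=[b for b in recording.bads if b not in excluded],
    )
    chans = {}
    for name, x in regressors.channels.items():
        s = x.std()
        if s > 1e-12:
            chans[name] = (x - x.mean()) / s
        else:
            logger.warning("regressor %r has zero variance; left at zero", name)
            chans[name] = np.zeros_like(x)
    return rec, RegressorSet(channels=chans, rate=regressors.rate), excluded


def epoch_trials(
    recording: EEGRecording,
    regressors: RegressorSet,
    trial_s: float = 60.0,
    labels: str | list[str] = "Control",
) -> EpochedData:
    """Cut the recording into consecutive non-overlapping fixed-length trials.

    A trailing remainder shorter than one trial is discarded (logged).
    ``labels`` is either one label for every trial or a list with one entry
    per resulting trial.
    """
    if recording.rate != regressors.rate:
        raise ValueError("recording and regressors must share a rate")
    n = min(recording.n_samples, regressors.n_samples)
    length = int(round(trial_s * recording.rate))
    n_trials = n // length
    if n_trials == 0:
        raise ValueError(
            f"recording ({n} samples) shorter than one {trial_s}-s trial"
        )
    rem = n - n_trials * length
    if rem:
        logger.info("discarding %d trailing samples (%.2f s)", rem, rem / recording.rate)
    eeg = np.stack(
        [recording.data[:, i * length : (i + 1) * length] for i in range(n_trials)]
    )
    mat = regressors.as_matrix()
    regs = np.stack([mat[i * length : (i + 1) * length] for i in range(n_trials)])
    if isinstance(labels, str):
        labels = [labels] * n_trials
    if len(labels) != n_trials:
        raise ValueError(f"{len(labels)} labels for {n_trials} trials")
    return EpochedData(
        eeg=eeg,
        regs=regs,
        feature_names=regressors.names,
        ch_names=list(recording.ch_names),
        rate=recording.rate,
        labels=list(labels),
    )


# -- layout and file I/O ---------------------------------------------------

_montage_cache: dict[str, dict[str, np.ndarray]] = {}


def standard_positions(ch_names: list[str]) -> np.ndarray:
    """3-D positions (meters) for standard 10-20/10-10 labels."""
    if "pos" not in _montage_cache:
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            montage = mne.channels.make_standard_montage("standard_1020")
        _montage_cache["pos"] = {
            k: np.asarray(v) for k, v in montage.get_positions()["ch_pos"].items()
        }
    table = _montage_cache["pos"]
    missing = [n for n in ch_names if n not in table]
    if missing:
        raise KeyError(f"no standard position for channels: {missing}")
    return np.stack([table[n] for n in ch_names])


def _from_mne_raw(raw) -> EEGRecording:
    data = raw.get_data()
    names = list(raw.ch_names)
    pos = None
    montage = raw.get_montage()
    if montage is not None:
        ch_pos = montage.get_positions()["ch_pos"]
        if all(n in ch_pos for n in names):
            pos = np.stack([np.asarray(ch_pos[n]) for n in names])
    return EEGRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        ch_names=names,
        positions=pos,
        bads=list(raw.info["bads"]),
    )


def read_brainvision(vhdr_path: str | Path) -> EEGRecording:
    """Read a BrainVision (.vhdr/.eeg/.vmrk) recording."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return _from_mne_raw(raw)


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _from_mne_raw(raw)


def save_recording(recording: EEGRecording, path: str | Path) -> None:
    """Persist a recording in the package's NPZ exchange container."""
    np.savez_compressed(
        str(path),
        data=recording.data,
        rate=recording.rate,
        ch_names=np.array(recording.ch_names),
        positions=np.array([]) if recording.positions is None else recording.positions,
        bads=np.array(recording.bads, dtype=str),
    )


def load_recording(path: str | Path) -> EEGRecording:
    with np.load(str(path), allow_pickle=False) as f:
        pos = f["positions"]
        return EEGRecording(
            data=f["data"],
            rate=float(f["rate"]),
            ch_names=[str(n) for n in f["ch_names"]],
            positions=None if pos.size == 0 else pos,
            bads=[str(b) for b in f["bads"]],
        )
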