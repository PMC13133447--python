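"""Stimulus feature extraction: speech envelope and word-level step regressors.

Three regressors drive the TRF analysis:

* ``envelope`` -- magnitude of the analytic (Hilbert) signal of the audio,
  anti-alias filtered and resampled to the EEG analysis rate;
* ``word_onset`` -- a binary step that rises to 1 at each word onset and is
  held until the next word's onset (adjacent words merge into one step);
* ``word_surprisal`` -- the same step encoding with each step's amplitude
  equal to that word's surprisal in bits.

Audio recorded on an auxiliary EEG channel is aligned to the clean soundtrack
by cross-covariance (:func:`align_offset`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .surprisal import Token, validate_tokens

__all__ = [
    "AudioTrack",
    "RegressorSet",
    "read_wav",
    "compute_envelope",
    "align_offset",
    "step_regressor",
    "assemble_features",
    "write_regressors",
    "read_regressors",
]

FEATURE_NAMES = ("envelope", "word_onset", "word_surprisal")


@dataclass
class AudioTrack:
    """Mono audio: float samples plus a sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("audio rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")


def read_wav(path: str | Path) -> AudioTrack:
    """Read a PCM WAV file as a mono float track (int formats rescaled to ±1)."""
    from scipy.io import wavfile

    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:  # average channels to mono
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioTrack(samples=np.asarray(data, dtype=float), rate=float(rate))


@dataclass
class RegressorSet:
    """Named, equal-length stimulus feature channels at a common rate."""

    channels: dict[str, np.ndarray]
    rate: float

    def __post_init__(self) -> None:
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"regressor channels differ in length: {lengths}")
        self.channels = {
            name: np.asarray(x, dtype=float) for name, x in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def as_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Stack channels into a (samples x features) matrix."""
        names = names or self.names
        return np.column_stack([self.channels[n] for n in names])

    def slice(self, start: int, stop: int) -> "RegressorSet":
        return RegressorSet(
            channels={n: x[start:stop] for n, x in self.channels.items()},
            rate=self.rate,
        )


def _resample(x: np.ndarray, rate: float, target: float) -> np.ndarray:
    frac = Fraction(target / rate).limit_denominator(10_000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def compute_envelope(audio: AudioTrack, target_rate: float) -> np.ndarray:
    """Broadband temporal envelope: ``|hilbert(x)|`` resampled to target_rate.

    An 8th-order Butterworth low-pass at 0.4 x target_rate precedes
    decimation as the anti-alias stage; the result is clipped at zero (the
    analytic magnitude is non-negative; resampling may ring slightly below).
    """
    if target_rate > audio.rate:
        raise ValueError(
            f"target rate {target_rate} exceeds audio rate {audio.rate}"
        )
    if audio.rate < 2 * target_rate:
        raise ValueError("audio rate must be at least twice the target rate")
    env = np.abs(signal.hilbert(audio.samples))
    sos = signal.butter(8, 0.4 * target_rate, btype="low", fs=audio.rate, output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = _resample(env, audio.rate, target_rate)
    return np.clip(env, 0.0, None)


def align_offset(aux_channel: np.ndarray, soundtrack: np.ndarray) -> int:
    """Lag (in samples) at which the soundtrack best matches the aux channel.

    Both signals must share a rate and the soundtrack must not be longer than
    the aux channel.  The returned lag maximizes the cross-covariance; on ties
    the smallest lag wins.  Raises ``ValueError`` when either input is all
    zeros (alignment undefined).
    """
    aux = np.asarray(aux_channel, dtype=float)
    track = np.asarray(soundtrack, dtype=float)
    if len(track) > len(aux):
        raise ValueError("soundtrack longer than the auxiliary recording")
    if not np.any(aux) or not np.any(track):
        raise ValueError("alignment undefined for all-zero input")
    a = aux - aux.mean()
    s = track - track.mean()
    cov = signal.correlate(a, s, mode="valid")
    return int(np.argmax(cov))  # argmax returns the first (smallest) lag on ties


def _onset_sample(t: float, rate: float) -> int:
    """Nearest-sample index with half-up rounding."""
    return int(math.floor(t * rate + 0.5))


def step_regressor(
    tokens: list[Token],
    rate: float,
    duration: float,
    mode: str = "onset",
) -> np.ndarray:
    """Piecewise-constant word regressor sampled at ``rate`` over ``duration``.

    Each word's value (1 in ``"onset"`` mode, its surprisal in
    ``"surprisal"`` mode) is set at the word's onset sample and held across
    the word's extent (to its offset); in running speech consecutive words
    are contiguous, so the step is held until the next word's onset and
    adjacent words merge into a single step.  The channel is zero before the
    first word and during silent pauses, and the onset channel integrates to
    the total spoken time.
    """
    if mode not in ("onset", "surprisal"):
        raise ValueError(f"unknown regressor mode {mode!r}")
    validate_tokens(tokens)
    n = _onset_sample(duration, rate)
    out = np.zeros(n)
    if not tokens:
        return out
    if tokens[-1].offset > duration + 0.5 / rate:
        raise ValueError(
            f"token at {tokens[-1].onset:.3f}s extends beyond duration {duration}s"
        )
    for i, tok in enumerate(tokens):
        start = _onset_sample(tok.onset, rate)
        stop = min(_onset_sample(tok.offset, rate), n)
        if mode == "onset":
            value = 1.0
        else:
            if tok.surprisal is None:
                raise ValueError(f"token {tok.text!r} has no surprisal annotation")
            value = tok.surprisal
        out[start:stop] = value
    return out


def assemble_features(
    envelope: np.ndarray,
    word_onset: np.ndarray,
    word_surprisal: np.ndarray,
    rate: float,
) -> RegressorSet:
    """Bundle the three analysis channels, validating lengths."""
    return RegressorSet(
        channels={
            "envelope": envelope,
            "word_onset": word_onset,
            "word_surprisal": word_surprisal,
        },
        rate=rate,
    )


def write_regressors(regressors: RegressorSet, path: str | Path) -> None:
    """Persist a regressor set as a single TSV (time plus one column/channel)."""
    t = np.arange(regressors.n_samples) / regressors.rate
    df = pd.DataFrame({"time": t, **regressors.channels})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_regressors(path: str | Path) -> RegressorSet:
    df = pd.read_csv(path, sep="\t")
    t = df.pop("time").to_numpy()
    if len(t) > 1:
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        rate = 1.0
    return RegressorSet(
        channels={c: df[c].to_numpy() for c in df.columns}, rate=rate
    )
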