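"""Stimulus pre-processing: midpoint snippets, RMS normalisation, resampling.

Mirrors the preparation applied to experiment stimuli: a fixed-duration
snippet is cut from the midpoint of each (already speech-trimmed) recording,
level-normalised to a common RMS, and down-sampled to a telephone-band rate
typical of forensic casework material.

Levels are digital.  "65 dB RMS" is interpreted against a configurable
full-scale reference: with the default ``reference_db=100`` a 65 dB target
means an RMS of 10**((65 - 100)/20) of full scale, i.e. -35 dBFS.  Absolute
sound pressure has no meaning inside a file, so the reference is explicit
and adjustable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioSnippet",
    "extract_midpoint",
    "rms_normalize",
    "resample",
    "prepare_snippet",
    "read_wav",
    "write_wav",
]

DEFAULT_SNIPPET_S = 1.2
DEFAULT_TARGET_DB = 65.0
DEFAULT_REFERENCE_DB = 100.0
DEFAULT_TARGET_RATE = 8000


@dataclass(frozen=True)
class AudioSnippet:
    """A mono snippet: float samples (nominally in [-1, 1]), rate in Hz."""

    samples: np.ndarray
    rate: int
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def extract_midpoint(
    snippet: AudioSnippet, duration_s: float = DEFAULT_SNIPPET_S
) -> AudioSnippet:
    """Cut a window of ``duration_s`` centred on the signal midpoint.

    The caller is expected to have trimmed leading/trailing non-speech.
    Raises if the signal is shorter than the requested duration.
    """
    n_out = round(duration_s * snippet.rate)
    n = len(snippet.samples)
    if n < n_out:
        raise ValueError(
            f"signal of {n} samples ({n / snippet.rate:.3f}s) shorter than "
            f"requested {duration_s}s window"
        )
    start = (n - n_out) // 2
    return replace(snippet, samples=snippet.samples[start : start + n_out])


def rms_normalize(
    snippet: AudioSnippet,
    target_db: float = DEFAULT_TARGET_DB,
    reference_db: float = DEFAULT_REFERENCE_DB,
) -> AudioSnippet:
    """Scale the snippet linearly so its RMS hits the target level.

    target RMS (linear, re full scale) = 10**((target_db - reference_db)/20).
    An all-zero signal has no defined gain and raises.
    """
    rms = snippet.rms
    if rms == 0:
        raise ValueError("cannot RMS-normalise an all-zero signal")
    target_rms = 10.0 ** ((target_db - reference_db) / 20.0)
    return replace(snippet, samples=snippet.samples * (target_rms / rms))


def resample(
    snippet: AudioSnippet,
    target_rate: int = DEFAULT_TARGET_RATE,
    allow_upsample: bool = False,
) -> AudioSnippet:
    """Band-limited resampling via polyphase filtering.

    Output length scales by target_rate/rate; tones below the target
    Nyquist survive with their frequency intact.  Upsampling is refused
    unless explicitly allowed.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == snippet.rate:
        return snippet
    if target_rate > snippet.rate and not allow_upsample:
        raise ValueError(
            f"upsampling {snippet.rate} -> {target_rate} Hz not allowed "
            "(pass allow_upsample=True to override)"
        )
    g = np.gcd(int(target_rate), int(snippet.rate))
    up, down = target_rate // g, snippet.rate // g
    out = resample_poly(snippet.samples, up, down)
    return AudioSnippet(samples=out, rate=int(target_rate), source_id=snippet.source_id)


def prepare_snippet(
    signal: AudioSnippet,
    duration_s: float = DEFAULT_SNIPPET_S,
    target_db: float = DEFAULT_TARGET_DB,
    reference_db: float = DEFAULT_REFERENCE_DB,
    target_rate: int = DEFAULT_TARGET_RATE,
) -> AudioSnippet:
    """extract_midpoint -> rms_normalize -> resample, the full pipeline."""
    cut = extract_midpoint(signal, duration_s)
    norm = rms_normalize(cut, target_db, reference_db)
    return resample(norm, target_rate)


def read_wav(path, source_id: str = "") -> AudioSnippet:
    """Read a PCM WAV file into float samples scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSnippet(samples=data, rate=int(rate), source_id=source_id or str(path))


def write_wav(path, snippet: AudioSnippet) -> None:
    """Write as 16-bit PCM WAV, clipping to [-1, 1]."""
    clipped = np.clip(snippet.samples, -1.0, 1.0)
    wavfile.write(path, snippet.rate, (clipped * 32767).astype(np.int16))
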