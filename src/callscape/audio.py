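"""Core audio container and WAV I/O.

All DSP in this package operates on :class:`AudioClip`: float samples in
[-1, +1] with an explicit sample rate.  Files are read and written as RIFF
PCM 16-bit WAV via :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioClip", "read_wav", "write_wav", "dbfs_to_amplitude", "amplitude_to_dbfs"]

#: Floor applied when converting zero/near-zero amplitudes to dB.
DB_FLOOR = -120.0


def dbfs_to_amplitude(dbfs: float) -> float:
    """Linear amplitude of a level given in dB relative to full scale."""
    return float(10.0 ** (dbfs / 20.0))


def amplitude_to_dbfs(amplitude: float) -> float:
    """dBFS of a linear amplitude; zero maps to the -120 dB floor."""
    amplitude = abs(float(amplitude))
    if amplitude <= 10.0 ** (DB_FLOOR / 20.0):
        return DB_FLOOR
    return float(20.0 * np.log10(amplitude))


@dataclass
class AudioClip:
    """A sampled waveform with rate and full-scale convention.

    ``samples`` are float64 in [-1, +1]; 0 dBFS corresponds to sample
    value 1.0.
    """

    samples: np.ndarray
    rate_hz: float
    source_id: str = ""
    channel: str = "A"
    gain_db: float = 0.0  # cumulative gain applied by processing steps

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0

    @property
    def peak_dbfs(self) -> float:
        return amplitude_to_dbfs(self.peak)

    def with_samples(self, samples: np.ndarray, **changes) -> "AudioClip":
        return replace(self, samples=np.asarray(samples, dtype=np.float64), **changes)


def read_wav(path, channel: int = 0, source_id: str | None = None) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    Multi-channel files are reduced to the requested channel (default:
    first / channel A).  Integer PCM is rescaled to [-1, +1].
    """
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioClip(samples=samples, rate_hz=float(rate),
                     source_id=source_id or str(path), channel=str(channel))


def write_wav(path, clip: AudioClip) -> None:
    """Write an :class:`AudioClip` as 16-bit PCM WAV."""
    if clip.peak > 1.0 + 1e-9:
        raise ValueError("samples exceed full scale; refusing to clip on write")
    pcm = np.clip(np.round(clip.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(round(clip.rate_hz)), pcm)
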