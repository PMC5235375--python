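"""Synthetic soundscape scenes with ground-truth annotations.

Target calls are harmonic stacks (k-th harmonic at 1/k amplitude) with
raised-cosine note edges; non-target calls are single-harmonic whistles.
Backgrounds exercise the front end's filter ranges: Gaussian broadband
noise, a low-pass wind band below 640 Hz, and a tonal insect cluster at
and above 12 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from ..audio import AudioClip, dbfs_to_amplitude, write_wav
from ..evaluate import AnnotatedEvent

__all__ = [
    "CallSpec",
    "SceneSpec",
    "ClippingError",
    "make_call_waveform",
    "render_scene",
    "write_scene",
    "read_annotations_csv",
]

EDGE_S = 0.005  # raised-cosine ramp at each note edge
F0_JITTER = 0.02  # relative per-note fundamental jitter when an rng is given

WIND_CUTOFF_HZ = 640.0
INSECT_BAND_HZ = 12_000.0


class ClippingError(ValueError):
    """The mixed scene exceeds digital full scale."""


@dataclass(frozen=True)
class CallSpec:
    """One call to embed in a scene: a series of notes at a fundamental."""

    onset_s: float
    n_notes: int = 3
    note_dur_s: float = 0.15
    gap_s: float = 0.12
    f0_hz: float = 1300.0
    n_harmonics: int = 6
    peak_dbfs: float = -20.0
    label: str = "target"

    def __post_init__(self) -> None:
        if self.peak_dbfs > 0:
            raise ValueError("peak_dbfs must be <= 0")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.gap_s < 0 or self.note_dur_s <= 0 or self.n_notes < 1:
            raise ValueError("invalid note geometry")
        if self.label == "target" and self.note_dur_s < 0.05:
            raise ValueError("target notes must last at least 50 ms")
        if self.label not in ("target", "nontarget"):
            raise ValueError("label must be 'target' or 'nontarget'")

    @property
    def duration_s(self) -> float:
        return self.n_notes * self.note_dur_s + (self.n_notes - 1) * self.gap_s


@dataclass
class SceneSpec:
    """A full scene: duration, backgrounds (RMS levels in dBFS), calls, seed."""

    duration_s: float
    sample_rate_hz: float = 48_000.0
    broadband_level_dbfs: float = -60.0
    wind_band_level_dbfs: float = -55.0
    insect_band_level_dbfs: float = -60.0
    calls: list[CallSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for level in (self.broadband_level_dbfs, self.wind_band_level_dbfs,
                      self.insect_band_level_dbfs):
            if level > 0:
                raise ValueError("background levels must be <= 0 dBFS")


def make_call_waveform(spec: CallSpec, rate_hz: float,
                       rng: np.random.Generator | None = None) -> AudioClip:
    """Render one call as an :class:`AudioClip`.

    Harmonics at ``k * f0`` carry ``1/k`` amplitude; harmonics above
    Nyquist are dropped.  Each note gets 5-ms raised-cosine edges.  The
    peak sample equals ``10^(peak_dbfs/20)`` of full scale.  If ``rng``
    is given, each note's fundamental is jittered by up to +/-2%.
    """
    note_len = int(round(spec.note_dur_s * rate_hz))
    gap_len = int(round(spec.gap_s * rate_hz))
    t = np.arange(note_len) / rate_hz
    edge = min(EDGE_S, spec.note_dur_s / 2.0)
    envelope = np.ones(note_len)
    n_edge = int(round(edge * rate_hz))
    if n_edge > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_edge) / n_edge))
        envelope[:n_edge] = ramp
        envelope[-n_edge:] = ramp[::-1]
    pieces = []
    for i in range(spec.n_notes):
        f0 = spec.f0_hz
        if rng is not None:
            f0 *= 1.0 + rng.uniform(-F0_JITTER, F0_JITTER)
        note = np.zeros(note_len)
        for k in range(1, spec.n_harmonics + 1):
            if k * f0 >= rate_hz / 2.0:
                break
            note += np.sin(2.0 * np.pi * k * f0 * t) / k
        pieces.append(note * envelope)
        if i < spec.n_notes - 1:
            pieces.append(np.zeros(gap_len))
    samples = np.concatenate(pieces)
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples *= dbfs_to_amplitude(spec.peak_dbfs) / peak
    return AudioClip(samples, rate_hz, source_id="synthetic-call")


def _band_noise(rng: np.random.Generator, n: int, rate_hz: float, rms_dbfs: float,
                band: str) -> np.ndarray:
    """Shaped Gaussian noise or a tonal cluster, scaled to a target RMS."""
    target_rms = dbfs_to_amplitude(rms_dbfs)
    if band == "broadband":
        x = rng.standard_normal(n)
    elif band == "wind":
        sos = signal.butter(4, WIND_CUTOFF_HZ, btype="lowpass", fs=rate_hz, output="sos")
        x = signal.sosfilt(sos, rng.standard_normal(n))
    elif band == "insect":
        nyq = rate_hz / 2.0
        if INSECT_BAND_HZ >= nyq:
            return np.zeros(n)
        t = np.arange(n) / rate_hz
        freqs = np.linspace(INSECT_BAND_HZ, min(INSECT_BAND_HZ + 4000.0, nyq * 0.98), 5)
        x = np.zeros(n)
        for f in freqs:
            am = 1.0 + 0.3 * np.sin(2.0 * np.pi * rng.uniform(5, 15) * t + rng.uniform(0, 2 * np.pi))
            x += am * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    else:  # pragma: no cover - internal misuse
        raise ValueError(band)
    rms = np.sqrt(np.mean(x**2))
    return x * (target_rms / rms) if rms > 0 else x


def render_scene(spec: SceneSpec) -> tuple[AudioClip, list[AnnotatedEvent]]:
    """Mix backgrounds and calls; return the clip and ground-truth annotations.

    Deterministic for a fixed seed (bit-identical samples).  Raises
    :class:`ClippingError` if the mix exceeds full scale anywhere.
    """
    rate = spec.sample_rate_hz
    n = int(round(spec.duration_s * rate))
    seeds = np.random.SeedSequence(spec.seed).spawn(4)
    mix = _band_noise(np.random.default_rng(seeds[0]), n, rate, spec.broadband_level_dbfs, "broadband")
    mix += _band_noise(np.random.default_rng(seeds[1]), n, rate, spec.wind_band_level_dbfs, "wind")
    mix += _band_noise(np.random.default_rng(seeds[2]), n, rate, spec.insect_band_level_dbfs, "insect")
    call_rng = np.random.default_rng(seeds[3])
    annotations = []
    for call in sorted(spec.calls, key=lambda c: c.onset_s):
        wave = make_call_waveform(call, rate, rng=call_rng).samples
        start = int(round(call.onset_s * rate))
        if start < 0 or start + len(wave) > n:
            raise ValueError(f"call at {call.onset_s} s does not fit in the scene")
        mix[start : start + len(wave)] += wave
        annotations.append(AnnotatedEvent(call.onset_s, call.onset_s + call.duration_s,
                                          call.label, call.peak_dbfs))
    peak = np.max(np.abs(mix)) if n else 0.0
    if peak > 1.0:
        raise ClippingError(f"scene peaks at {20 * np.log10(peak):+.2f} dBFS; lower some levels")
    clip = AudioClip(mix, rate, source_id=f"scene-seed{spec.seed}")
    return clip, annotations


def write_scene(spec: SceneSpec, wav_path, annotations_path) -> tuple[AudioClip, list[AnnotatedEvent]]:
    """Render and persist a scene as WAV plus an annotation CSV."""
    clip, annotations = render_scene(spec)
    write_wav(wav_path, clip)
    pd.DataFrame({
        "start_s": [a.start_s for a in annotations],
        "end_s": [a.end_s for a in annotations],
        "label": [a.label for a in annotations],
        "peak_dbfs": [a.peak_dbfs for a in annotations],
    }).to_csv(annotations_path, index=False)
    return clip, annotations


def read_annotations_csv(path) -> list[AnnotatedEvent]:
    df = pd.read_csv(path)
    return [AnnotatedEvent(float(r.start_s), float(r.end_s), str(r.label),
                           None if pd.isna(r.peak_dbfs) else float(r.peak_dbfs))
            for r in df.itertuples(index=False)]
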