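"""Audio front-end: preprocessing chain and 90-dimensional frame features.

The chain is fixed: AGC rescale -> resample to 24 kHz -> order-10
Butterworth high-pass at 1 kHz (zero-phase) -> 20-ms frames with 5-ms hop
-> 35 linear-frequency cepstral coefficients + 35 deltas + first 20
delta-deltas -> per-dimension min-max standardization to [-1, 1].
Frame energies (dBFS) drive a -50 dB activity gate; by default the gate
uses pre-AGC energy (the recorder's full-range input), with a toggle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.fft import dct, rfft

from .audio import DB_FLOOR, AudioClip

__all__ = [
    "FrontendConfig",
    "FrameFeatures",
    "FeatureStats",
    "agc_rescale",
    "resample_24k",
    "highpass",
    "frame_signal",
    "lfcc",
    "deltas",
    "activity_gate",
    "extract_features",
]

TARGET_RATE_HZ = 24_000
FRAME_LEN = 480  # 20 ms at 24 kHz
FRAME_HOP = 120  # 5 ms at 24 kHz
HOP_S = FRAME_HOP / TARGET_RATE_HZ
WINDOW_S = FRAME_LEN / TARGET_RATE_HZ

_LOG_ENERGY_FLOOR = 1e-12


@dataclass
class FrontendConfig:
    """Tunable parameters of the front end (defaults match the pipeline contract)."""

    n_filters: int = 40
    n_ceps: int = 35
    n_delta2: int = 20
    delta_window: int = 2
    gate_db: float = -50.0
    gate_pre_agc: bool = True
    #: 0 dBFS reference for frame RMS: "square" -> RMS 1.0 (full-scale
    #: constant signal reads 0 dBFS); "sine" -> RMS 1/sqrt(2).
    energy_reference: str = "square"

    @property
    def n_features(self) -> int:
        return self.n_ceps * 2 + self.n_delta2


@dataclass
class FrameFeatures:
    """Per-frame descriptor matrix with timing, energy, and activity mask."""

    features: np.ndarray  # (n_frames, 90)
    frame_start_s: np.ndarray
    frame_energy_dbfs: np.ndarray
    active_mask: np.ndarray
    hop_s: float = HOP_S
    window_s: float = WINDOW_S
    stats_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]


def agc_rescale(clip: AudioClip) -> AudioClip:
    """Rescale so the peak sample magnitude is exactly 1 (adaptive gain control).

    The applied gain in dB is accumulated on ``clip.gain_db`` so that
    pre-gain levels remain recoverable.
    """
    peak = clip.peak
    if len(clip.samples) == 0 or peak == 0.0:
        raise ValueError("cannot AGC-rescale an empty or all-zero clip")
    gain = 1.0 / peak
    return clip.with_samples(clip.samples * gain,
                             gain_db=clip.gain_db + 20.0 * np.log10(gain))


def resample_24k(clip: AudioClip) -> AudioClip:
    """Polyphase down-sample to 24 kHz (Kaiser-windowed anti-alias filter)."""
    if clip.rate_hz < TARGET_RATE_HZ:
        raise ValueError(
            f"input rate {clip.rate_hz} Hz below {TARGET_RATE_HZ} Hz; upsampling is out of contract"
        )
    if clip.rate_hz == TARGET_RATE_HZ:
        return clip
    ratio = Fraction(TARGET_RATE_HZ, int(round(clip.rate_hz))).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    # Kaiser FIR designed for the upsampled grid: pass to ~11.4 kHz,
    # >= 80 dB stopband from ~12.6 kHz, so near-Nyquist content is gone.
    up_nyq = clip.rate_hz * up / 2.0
    width = 1200.0 / up_nyq
    numtaps, beta = signal.kaiserord(80.0, width)
    numtaps |= 1  # odd length keeps the filter symmetric around zero delay
    cutoff = (TARGET_RATE_HZ / 2.0 - 600.0) / up_nyq
    h = up * signal.firwin(numtaps, cutoff, window=("kaiser", beta))
    resampled = signal.resample_poly(clip.samples, up, down, window=h)
    return clip.with_samples(resampled, rate_hz=float(TARGET_RATE_HZ))


def _highpass_sos(rate_hz: float = TARGET_RATE_HZ, order: int = 10, fc_hz: float = 1000.0):
    return signal.butter(order, fc_hz, btype="highpass", fs=rate_hz, output="sos")


def highpass(clip: AudioClip) -> AudioClip:
    """Order-10 Butterworth high-pass at 1 kHz, applied forward-backward (zero phase)."""
    sos = _highpass_sos(clip.rate_hz)
    return clip.with_samples(signal.sosfiltfilt(sos, clip.samples))


def frame_signal(clip: AudioClip, config: FrontendConfig | None = None):
    """Slice into 20-ms frames with 75% overlap; also return frame energies.

    Returns ``(frames, frame_start_s, frame_energy_dbfs)`` where frames is
    an ``(n, 480)`` view-copy.  Energy is dB of frame RMS relative to the
    configured full-scale reference, floored at -120 dBFS.
    """
    config = config or FrontendConfig()
    x = clip.samples
    if len(x) < FRAME_LEN:
        warnings.warn("clip shorter than one analysis window; zero frames produced")
        empty = np.empty((0, FRAME_LEN))
        return empty, np.empty(0), np.empty(0)
    n_frames = (len(x) - FRAME_LEN) // FRAME_HOP + 1
    idx = np.arange(FRAME_LEN)[None, :] + FRAME_HOP * np.arange(n_frames)[:, None]
    frames = x[idx]
    starts = np.arange(n_frames) * HOP_S
    rms = np.sqrt(np.mean(frames**2, axis=1))
    ref = 1.0 if config.energy_reference == "square" else 1.0 / np.sqrt(2.0)
    with np.errstate(divide="ignore"):
        energy = 20.0 * np.log10(rms / ref)
    energy = np.maximum(energy, DB_FLOOR)
    return frames, starts, energy


def lfcc(frames: np.ndarray, rate_hz: float = TARGET_RATE_HZ,
         config: FrontendConfig | None = None) -> np.ndarray:
    """Linear-frequency cepstral coefficients c1..c35 per frame.

    Hamming window -> power spectrum -> 40 linearly spaced triangular
    filters over 0..rate/2 -> log energies (floored) -> orthonormal DCT-II.
    c0 is dropped so the coefficients are invariant to overall gain.
    """
    config = config or FrontendConfig()
    n_fft = frames.shape[1]
    window = np.hamming(n_fft)
    spectrum = np.abs(rfft(frames * window, axis=1)) ** 2
    fbank = _triangular_filterbank(config.n_filters, n_fft, rate_hz)
    energies = spectrum @ fbank.T
    log_e = np.log(np.maximum(energies, _LOG_ENERGY_FLOOR))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)
    return ceps[:, 1 : config.n_ceps + 1]


def _triangular_filterbank(n_filters: int, n_fft: int, rate_hz: float) -> np.ndarray:
    """Linearly spaced triangular filters on the rfft bin grid."""
    n_bins = n_fft // 2 + 1
    freqs = np.linspace(0.0, rate_hz / 2.0, n_bins)
    edges = np.linspace(0.0, rate_hz / 2.0, n_filters + 2)
    bank = np.zeros((n_filters, n_bins))
    for m in range(n_filters):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        rising = (freqs - lo) / (mid - lo)
        falling = (hi - freqs) / (hi - mid)
        bank[m] = np.clip(np.minimum(rising, falling), 0.0, None)
    return bank


def deltas(ceps: np.ndarray, config: FrontendConfig | None = None) -> np.ndarray:
    """First and second temporal derivatives (regression over +/-2 frames).

    Returns 55 columns: all 35 deltas followed by the first 20
    delta-deltas.  Edge frames use replicated padding.
    """
    config = config or FrontendConfig()
    if ceps.shape[0] < 2 * config.delta_window + 1:
        raise ValueError(f"need at least {2 * config.delta_window + 1} frames for deltas")
    d1 = _delta(ceps, config.delta_window)
    d2 = _delta(d1, config.delta_window)
    return np.hstack([d1, d2[:, : config.n_delta2]])


def _delta(x: np.ndarray, w: int) -> np.ndarray:
    pad = np.pad(x, ((w, w), (0, 0)), mode="edge")
    denom = 2.0 * sum(k * k for k in range(1, w + 1))
    out = np.zeros_like(x)
    for k in range(1, w + 1):
        out += k * (pad[w + k : w + k + x.shape[0]] - pad[w - k : w - k + x.shape[0]])
    return out / denom


def activity_gate(frame_energy_dbfs: np.ndarray, threshold_db: float = -50.0) -> np.ndarray:
    """Boolean mask of frames whose energy meets the gate threshold."""
    return np.asarray(frame_energy_dbfs) >= threshold_db


@dataclass
class FeatureStats:
    """Per-dimension min/max learned on training data; maps features to [-1, 1].

    Values beyond the training range are clipped; constant dimensions map
    to 0.  Frozen at training time and persisted with the model.
    """

    min_: np.ndarray
    max_: np.ndarray
    stats_id: str = "default"

    @classmethod
    def fit(cls, features: np.ndarray, stats_id: str = "default") -> "FeatureStats":
        if features.ndim != 2 or features.shape[0] == 0:
            raise ValueError("need a nonempty 2-D feature matrix")
        return cls(features.min(axis=0), features.max(axis=0), stats_id)

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.shape[1] != self.min_.shape[0]:
            raise ValueError(
                f"feature dimension {features.shape[1]} does not match stats "
                f"dimension {self.min_.shape[0]}"
            )
        span = self.max_ - self.min_
        out = np.zeros_like(features)
        ok = span > 0
        out[:, ok] = 2.0 * (features[:, ok] - self.min_[ok]) / span[ok] - 1.0
        return np.clip(out, -1.0, 1.0)

    def to_json(self) -> str:
        return json.dumps({"stats_id": self.stats_id,
                           "min": self.min_.tolist(), "max": self.max_.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "FeatureStats":
        obj = json.loads(text)
        return cls(np.asarray(obj["min"]), np.asarray(obj["max"]), obj["stats_id"])


def save_features(path, feats: FrameFeatures) -> None:
    """Persist features as an NPY-container (.npz) with a JSON metadata entry."""
    meta = json.dumps({"hop_s": feats.hop_s, "window_s": feats.window_s,
                       "stats_id": feats.stats_id, "n_features": feats.features.shape[1]})
    np.savez(path, features=feats.features, frame_start_s=feats.frame_start_s,
             frame_energy_dbfs=feats.frame_energy_dbfs, active_mask=feats.active_mask,
             meta=np.array(meta))


def load_features(path) -> FrameFeatures:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return FrameFeatures(z["features"], z["frame_start_s"], z["frame_energy_dbfs"],
                             z["active_mask"].astype(bool), hop_s=meta["hop_s"],
                             window_s=meta["window_s"], stats_id=meta["stats_id"])


def extract_features(clip: AudioClip, config: FrontendConfig | None = None,
                     stats: FeatureStats | None = None) -> FrameFeatures:
    """Run the full front-end chain on a raw clip.

    Order is fixed: AGC -> resample -> high-pass -> frame -> LFCC+deltas.
    If ``stats`` is given the feature matrix is standardized with it.
    Gate energies refer to pre-AGC level when ``config.gate_pre_agc``.
    """
    config = config or FrontendConfig()
    rescaled = agc_rescale(clip)
    prepared = highpass(resample_24k(rescaled))
    frames, starts, energy = frame_signal(prepared, config)
    if frames.shape[0] == 0:
        return FrameFeatures(np.empty((0, config.n_features)), starts, energy,
                             np.zeros(0, dtype=bool))
    gate_energy = energy - rescaled.gain_db if config.gate_pre_agc else energy
    mask = activity_gate(np.maximum(gate_energy, DB_FLOOR), config.gate_db)
    ceps = lfcc(frames, prepared.rate_hz, config)
    feats = np.hstack([ceps, deltas(ceps, config)])
    stats_id = ""
    if stats is not None:
        feats = stats.transform(feats)
        stats_id = stats.stats_id
    return FrameFeatures(feats, starts, np.maximum(gate_energy, DB_FLOOR), mask,
                         stats_id=stats_id)
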