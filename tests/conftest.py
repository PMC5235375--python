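import numpy as np
import pytest

from callscape.audio import AudioClip
from callscape.synth import CallSpec, SceneSpec, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone(freq_hz: float, rate_hz: float = 48_000.0, duration_s: float = 1.0,
         amplitude: float = 0.5) -> AudioClip:
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    return AudioClip(amplitude * np.sin(2 * np.pi * freq_hz * t), rate_hz)


def make_scene(seed: int, n_target: int, n_nontarget: int = 0, duration_s: float = 60.0,
               target_peak_dbfs: float = -25.0, peak_spread_db: float = 5.0,
               broadband_dbfs: float = -60.0, **scene_kwargs):
    """Random non-overlapping scene with target stacks and non-target whistles."""
    rng = np.random.default_rng(seed + 77_000)
    n = n_target + n_nontarget
    onsets = np.sort(rng.uniform(1.0, duration_s - 3.0, size=n))
    # enforce >= 1.5 s separation so ground-truth events stay distinct
    for i in range(1, n):
        onsets[i] = max(onsets[i], onsets[i - 1] + 1.5)
    if n and onsets[-1] > duration_s - 2.0:
        raise ValueError("scene too short for the requested call count")
    calls = []
    for i, onset in enumerate(onsets):
        if i < n_target:
            calls.append(CallSpec(
                onset_s=float(onset),
                peak_dbfs=float(target_peak_dbfs + rng.uniform(-peak_spread_db, 0)),
            ))
        else:
            calls.append(CallSpec(
                onset_s=float(onset), f0_hz=float(rng.uniform(2000, 4000)),
                n_harmonics=1, peak_dbfs=float(target_peak_dbfs), label="nontarget",
            ))
    spec = SceneSpec(duration_s=duration_s, broadband_level_dbfs=broadband_dbfs,
                     calls=calls, seed=seed, **scene_kwargs)
    return render_scene(spec)
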