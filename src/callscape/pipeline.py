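"""End-to-end helpers: raw clip -> features -> frame scores -> events."""

from __future__ import annotations

import numpy as np

from .audio import AudioClip
from .detector import TargetModel, UbmModel, decide, score
from .events import DetectionEvent, smooth
from .evaluate import match
from .frontend import FeatureStats, FrontendConfig, extract_features

__all__ = ["detect_events", "calibrate_threshold", "score_clip"]


def score_clip(clip: AudioClip, ubm: UbmModel, target: TargetModel,
               stats: FeatureStats, config: FrontendConfig | None = None):
    """Front-end + scoring.  Returns (llr, active_mask, features)."""
    feats = extract_features(clip, config=config, stats=stats)
    llr = np.full(feats.n_frames, -np.inf)
    if feats.active_mask.any():
        llr[feats.active_mask] = score(feats.features[feats.active_mask], ubm, target)
    return llr, feats.active_mask, feats


def detect_events(clip: AudioClip, ubm: UbmModel, target: TargetModel,
                  stats: FeatureStats, threshold: float,
                  config: FrontendConfig | None = None,
                  recording_id: str = "", **smooth_kwargs) -> list[DetectionEvent]:
    """Run the full detector on one clip; inactive frames never fire."""
    llr, active, _ = score_clip(clip, ubm, target, stats, config)
    decisions = decide(llr, threshold) & active
    return smooth(decisions, llr=llr, recording_id=recording_id, **smooth_kwargs)


def calibrate_threshold(clip: AudioClip, annotations, ubm: UbmModel, target: TargetModel,
                        stats: FeatureStats, config: FrontendConfig | None = None,
                        n_grid: int = 60) -> float:
    """Pick the frame threshold maximizing event-level F1 on a development scene."""
    llr, active, _ = score_clip(clip, ubm, target, stats, config)
    finite = llr[active & np.isfinite(llr)]
    if finite.size == 0:
        raise ValueError("no active frames on the development scene")
    lo, hi = np.percentile(finite, [5, 99.5])
    n_targets = sum(1 for a in annotations if a.label == "target")
    best_theta, best_f1 = 0.0, -1.0
    for theta in np.linspace(lo, hi, n_grid):
        events = smooth(decide(llr, theta) & active, llr=llr)
        if not events:
            continue
        summary = match(events, annotations)
        tp, fp = summary.H, summary.I
        fn = n_targets - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, best_theta = f1, float(theta)
    return best_theta
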