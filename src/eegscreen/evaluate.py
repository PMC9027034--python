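"""Ground-truth scoring of detection and denoising on synthetic cohorts.

These helpers exist because the generator knows exactly where artifacts
were injected, so detection recall, false-flag rates and denoising benefit
can be measured against truth — something impossible on real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .artifacts import ArtifactMask, ThresholdPolicy, denoise, sdw_detect
from .io import Recording, RunConfig
from .preprocess import bandpass

__all__ = [
    "detection_scores",
    "DenoiseOutcome",
    "score_contamination_pair",
    "score_suite",
]


def detection_scores(
    detected: ArtifactMask,
    truth: ArtifactMask,
    n_samples: int,
    window_samples: int,
    covered_threshold: float = 0.5,
) -> Tuple[float, float, int, int]:
    """Event recall and clean-window false-flag rate for one recording.

    A ground-truth event counts as recalled when at least
    ``covered_threshold`` of its samples are flagged (an event whose tail
    crosses a window boundary is still a detection hit when its body is
    flagged).  A clean window is a
    full detection window with no overlap with any truth event; the
    false-flag rate is the fraction of clean windows that were flagged.
    Returns (recall, false_flag_rate, n_events, n_clean_windows); recall is
    NaN when there are no truth events.
    """
    if len(truth) == 0:
        recall = float("nan")
    else:
        hits = sum(
            detected.covered_fraction(s, e) >= covered_threshold for s, e in truth
        )
        recall = hits / len(truth)
    truth_flags = truth.to_boolean(n_samples)
    det_flags = detected.to_boolean(n_samples)
    n_windows = n_samples // window_samples
    clean = flagged_clean = 0
    for w in range(n_windows):
        sl = slice(w * window_samples, (w + 1) * window_samples)
        if not truth_flags[sl].any():
            clean += 1
            if det_flags[sl].any():
                flagged_clean += 1
    ffr = flagged_clean / clean if clean else float("nan")
    return recall, ffr, len(truth), clean


@dataclass
class DenoiseOutcome:
    """Per-recording denoising scores against ground truth."""

    recall: float
    false_flag_rate: float
    rms_error_before: float
    rms_error_after: float
    n_flagged_intervals: int

    @property
    def improved(self) -> bool:
        return self.rms_error_after < self.rms_error_before


def _aligned_reference(
    clean: Recording, contaminated: Recording, config: RunConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Preprocess the contaminated recording and express the clean ground
    truth in the same normalized units.

    Both signals are band-passed identically; the contaminated one is then
    z-normalized with its own statistics and the same affine map is applied
    to the clean signal, so the only difference between the two returned
    arrays is the artifact content (plus what denoising changes).
    """
    bp_kwargs = dict(
        low=config.bandpass_low_hz,
        high=config.bandpass_high_hz,
        order=config.bandpass_order,
    )
    dirty_bp = bandpass(contaminated, **bp_kwargs).samples
    clean_bp = bandpass(clean, **bp_kwargs).samples
    mu, sd = dirty_bp.mean(), dirty_bp.std()
    return (clean_bp - mu) / sd, (dirty_bp - mu) / sd


def score_contamination_pair(
    clean: Recording,
    contaminated: Recording,
    truth: ArtifactMask,
    config: Optional[RunConfig] = None,
) -> DenoiseOutcome:
    """Run preprocess+denoise on a contaminated recording and score it.

    RMS errors are measured against the aligned clean ground truth inside
    the detected intervals (where cleaning acts); when nothing is flagged
    they are measured over the truth intervals instead, so a missed
    artifact still counts as un-repaired error.
    """
    config = config or RunConfig()
    ref, dirty = _aligned_reference(clean, contaminated, config)
    rec = contaminated.copy_with(dirty)
    cleaned_rec, detected = denoise(rec, config)
    window = int(round(config.sdw_window_s * contaminated.fs))
    recall, ffr, _, _ = detection_scores(
        detected, truth, contaminated.n_samples, window
    )
    score_mask = detected if len(detected) else truth
    flags = score_mask.to_boolean(contaminated.n_samples)
    if flags.any():
        before = float(np.sqrt(np.mean((dirty[flags] - ref[flags]) ** 2)))
        after = float(
            np.sqrt(np.mean((cleaned_rec.samples[flags] - ref[flags]) ** 2))
        )
    else:
        before = after = 0.0
    return DenoiseOutcome(
        recall=recall,
        false_flag_rate=ffr,
        rms_error_before=before,
        rms_error_after=after,
        n_flagged_intervals=len(detected),
    )


def score_suite(
    suite: List[Tuple[Recording, Recording, ArtifactMask]],
    config: Optional[RunConfig] = None,
    denoise_stage: bool = True,
) -> dict:
    """Aggregate detection / denoising metrics over a contamination suite.

    With ``denoise_stage=False`` only detection is run (cheap).  Returns
    mean event recall, mean clean-window false-flag rate, the fraction of
    recordings whose in-interval RMS error strictly decreased, and the
    per-recording outcomes.
    """
    config = config or RunConfig()
    outcomes: List[DenoiseOutcome] = []
    for clean, dirty, truth in suite:
        if denoise_stage:
            outcomes.append(score_contamination_pair(clean, dirty, truth, config))
        else:
            ref, dirty_z = _aligned_reference(clean, dirty, config)
            rec = dirty.copy_with(dirty_z)
            policy = ThresholdPolicy(
                k_mad=config.sdw_k_mad, absolute=config.sdw_abs_threshold
            )
            detected = sdw_detect(rec, window_s=config.sdw_window_s, policy=policy)
            window = int(round(config.sdw_window_s * dirty.fs))
            recall, ffr, _, _ = detection_scores(
                detected, truth, dirty.n_samples, window
            )
            outcomes.append(
                DenoiseOutcome(
                    recall=recall,
                    false_flag_rate=ffr,
                    rms_error_before=float("nan"),
                    rms_error_after=float("nan"),
                    n_flagged_intervals=len(detected),
                )
            )
    recalls = [o.recall for o in outcomes if not np.isnan(o.recall)]
    ffrs = [o.false_flag_rate for o in outcomes if not np.isnan(o.false_flag_rate)]
    result = {
        "mean_recall": float(np.mean(recalls)) if recalls else float("nan"),
        "mean_false_flag_rate": float(np.mean(ffrs)) if ffrs else float("nan"),
        "outcomes": outcomes,
    }
    if denoise_stage:
        improved = [o.improved for o in outcomes]
        result["improved_fraction"] = float(np.mean(improved))
    return result
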