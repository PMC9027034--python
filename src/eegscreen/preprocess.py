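"""Band limiting and per-recording standardization.

EEG traces are band-limited to 1-30 Hz with a zero-phase Butterworth filter
and then z-normalized (mean 0, population variance 1) so that subjects with
different electrode impedances and amplifier gains become comparable.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import Recording, RunConfig

__all__ = ["bandpass", "znormalize", "preprocess"]


def bandpass(
    recording: Recording, low: float = 1.0, high: float = 30.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    output has no group delay and the same length as the input; the
    effective magnitude response is the squared Butterworth response.
    """
    nyq = recording.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; "
            f"got low={low}, high={high}, fs={recording.fs}"
        )
    sos = butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return recording.copy_with(sosfiltfilt(sos, recording.samples))


def znormalize(recording: Recording) -> Recording:
    """Standardize to mean 0 and population variance 1.

    Idempotent, and invariant under positive affine rescaling of the input.
    Raises on (numerically) constant signals, where the variance is zero.
    """
    x = recording.samples
    mu = x.mean()
    sd = x.std()  # population
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("constant signal: z-normalization undefined")
    return recording.copy_with((x - mu) / sd)


def preprocess(recording: Recording, config: RunConfig | None = None) -> Recording:
    """Band-pass then z-normalize, per the run configuration."""
    config = config or RunConfig()
    rec = bandpass(
        recording,
        low=config.bandpass_low_hz,
        high=config.bandpass_high_hz,
        order=config.bandpass_order,
    )
    return znormalize(rec)
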