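"""Spectral features: per-second power spectra, 1-Hz bins, band powers,
and control-referenced relative power.

A cleaned recording is cut into non-overlapping windows (1 s by default),
each window is tapered and Fourier-transformed, and the magnitude-squared
spectrum is averaged across windows.  Features are the 45 integer-frequency
bins 1..45 Hz plus ten canonical EEG band powers; the candidate feature set
for the statistical stage is therefore 55 columns.  Relative power divides
every subject's features by the control-group mean so the control mean is
exactly 1 in every feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .io import Recording

__all__ = [
    "BAND_EDGES",
    "BAND_NAMES",
    "GENERATOR_BANDS",
    "band_bins",
    "FeatureVector",
    "stft_power",
    "bin_features",
    "band_powers",
    "feature_table",
    "relative_power",
    "FEATURE_COLUMNS",
]

#: Canonical EEG band edges in Hz.  Bands are half-open [low, high) except
#: gamma, which is closed at 45 Hz so that bin 45 belongs to it.  With 1 Hz
#: bins this makes delta = {1,2,3}, alpha1 = {8}, alpha2 = {9,10},
#: alpha3 = {11,12}, gamma = {30..45}.
BAND_EDGES: Dict[str, tuple] = {
    "delta": (1, 4),
    "theta": (4, 8),
    "alpha": (8, 13),
    "alpha1": (8, 9),
    "alpha2": (9, 11),
    "alpha3": (11, 13),
    "beta": (13, 30),
    "beta1": (13, 20),
    "beta2": (20, 30),
    "gamma": (30, 45),
}

BAND_NAMES = tuple(BAND_EDGES)

#: The eight non-overlapping bands the cohort generator mixes (broad alpha
#: and beta are derived unions and are not separate noise sources).
GENERATOR_BANDS = ("delta", "theta", "alpha1", "alpha2", "alpha3", "beta1", "beta2", "gamma")

BIN_MIN_HZ = 1
BIN_MAX_HZ = 45

FEATURE_COLUMNS: List[str] = [f"bin_{hz}" for hz in range(BIN_MIN_HZ, BIN_MAX_HZ + 1)] + list(
    BAND_NAMES
)


def band_bins(name: str) -> np.ndarray:
    """Integer 1-Hz bins belonging to a named band.

    Half-open [low, high) for every band except gamma, whose upper edge
    (45 Hz) is included.
    """
    low, high = BAND_EDGES[name]
    upper = high + 1 if name == "gamma" else high
    return np.arange(low, upper)


@dataclass
class FeatureVector:
    """45 bin powers plus 10 band powers for one recording."""

    bin_powers: np.ndarray  # index 0 -> 1 Hz, ..., index 44 -> 45 Hz
    band_powers: Dict[str, float] = field(default_factory=dict)
    normalization: str = "raw"  # raw | sum_to_one | control_relative

    def __post_init__(self) -> None:
        self.bin_powers = np.asarray(self.bin_powers, dtype=float)
        if self.bin_powers.shape != (BIN_MAX_HZ - BIN_MIN_HZ + 1,):
            raise ValueError(
                f"expected {BIN_MAX_HZ - BIN_MIN_HZ + 1} bin powers, "
                f"got shape {self.bin_powers.shape}"
            )
        if np.any(self.bin_powers < 0):
            raise ValueError("bin powers must be non-negative")

    def bin_power(self, hz: int) -> float:
        return float(self.bin_powers[hz - BIN_MIN_HZ])

    def as_series(self) -> pd.Series:
        values = list(self.bin_powers) + [self.band_powers[b] for b in BAND_NAMES]
        return pd.Series(values, index=FEATURE_COLUMNS, dtype=float)


def stft_power(
    recording: Recording, window_s: float = 1.0, taper: str = "hann"
) -> np.ndarray:
    """Per-window power spectra of a recording.

    The signal is cut into consecutive non-overlapping windows of
    ``window_s`` seconds (trailing partial window dropped), each window is
    multiplied by the taper, and the one-sided magnitude-squared spectrum is
    computed.  The scaling is chosen so that for a boxcar taper the bins of
    one window sum to that window's mean square (a discrete Parseval
    identity); for other tapers the same identity holds for the tapered
    window normalized by the taper energy.

    Returns an array of shape (n_windows, n_rfft_bins); row k's bin j is the
    power at frequency j / window_s Hz, so with 1 s windows bin indices are
    integer frequencies in Hz.
    """
    nper = int(round(recording.fs * window_s))
    if nper < 2:
        raise ValueError("window too short for the sampling rate")
    x = recording.samples
    n_windows = x.size // nper
    if n_windows < 1:
        raise ValueError(
            f"recording of {x.size} samples shorter than one "
            f"{window_s} s window ({nper} samples)"
        )
    frames = x[: n_windows * nper].reshape(n_windows, nper)
    w = get_window(taper, nper, fftbins=True)
    spec = np.fft.rfft(frames * w, axis=1)
    power = np.abs(spec) ** 2
    # one-sided doubling for all bins except DC and (for even nper) Nyquist
    power[:, 1:] *= 2.0
    if nper % 2 == 0:
        power[:, -1] /= 2.0
    power /= nper * np.sum(w**2)
    return power


def bin_features(
    spectra: np.ndarray,
    window_s: float = 1.0,
    normalize: str = "sum_to_one",
) -> FeatureVector:
    """Average per-window spectra into integer 1-Hz bin features (1-45 Hz).

    The per-bin mean over windows is taken for integer frequencies
    1..45 Hz, then scaled to sum to one (``sum_to_one``) or left raw.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[0] < 1:
        raise ValueError("need at least one spectral window")
    mean_spec = spectra.mean(axis=0)
    # bin j of a window_s-second window sits at frequency j / window_s
    bins = np.arange(BIN_MIN_HZ, BIN_MAX_HZ + 1)
    idx = np.round(bins * window_s).astype(int)
    if idx[-1] >= mean_spec.size:
        raise ValueError(
            f"spectra only reach {(mean_spec.size - 1) / window_s:g} Hz; "
            f"need {BIN_MAX_HZ} Hz"
        )
    values = mean_spec[idx]
    if normalize == "sum_to_one":
        total = values.sum()
        if total <= 0:
            raise ValueError("all-zero spectrum: sum-to-one normalization undefined")
        values = values / total
        state = "sum_to_one"
    elif normalize == "raw":
        state = "raw"
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    fv = FeatureVector(bin_powers=values, normalization=state)
    return band_powers(fv)


def band_powers(features: FeatureVector) -> FeatureVector:
    """Fill band powers as the mean of each band's constituent 1-Hz bins."""
    for name in BAND_NAMES:
        bins = band_bins(name)
        features.band_powers[name] = float(
            np.mean([features.bin_power(hz) for hz in bins])
        )
    return features


def extract_features(
    recording: Recording, window_s: float = 1.0, taper: str = "hann"
) -> FeatureVector:
    """Convenience: STFT then normalized bin + band features."""
    return bin_features(stft_power(recording, window_s, taper), window_s)


def feature_table(
    recordings: Sequence[Recording],
    window_s: float = 1.0,
    taper: str = "hann",
) -> pd.DataFrame:
    """One row per subject: 45 bins, 10 bands, group, mmse."""
    rows = []
    for rec in recordings:
        s = extract_features(rec, window_s, taper).as_series()
        s["subject_id"] = rec.subject_id
        s["group"] = rec.group
        s["mmse"] = rec.mmse
        rows.append(s)
    df = pd.DataFrame(rows).set_index("subject_id")
    return df


def relative_power(
    table: pd.DataFrame, reference_group: str = "healthy"
) -> pd.DataFrame:
    """Express every subject's features relative to the reference-group mean.

    After scaling, the reference group's mean is exactly 1 in every feature
    column.  Raises if the reference group is empty or has zero mean in any
    feature (division undefined).
    """
    if "group" not in table.columns:
        raise ValueError("feature table must carry a 'group' column")
    ref = table[table["group"] == reference_group]
    if len(ref) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    out = table.copy()
    ref_mean = ref[FEATURE_COLUMNS].mean(axis=0)
    zero = ref_mean[ref_mean <= 0]
    if len(zero):
        raise ValueError(
            f"reference mean is zero in feature(s) {list(zero.index)}: "
            "relative power undefined"
        )
    out[FEATURE_COLUMNS] = table[FEATURE_COLUMNS] / ref_mean
    return out
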