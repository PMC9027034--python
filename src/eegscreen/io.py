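"""Recordings, manifests, run configuration, and MMSE-based group labels.

The canonical on-disk format for a recording is a two-column CSV
(``sample_index, amplitude``) with a header row; sample indices are 0-based
and intervals everywhere in the package are half-open ``[start, end)`` in
samples.  EDF input is supported read-only when :mod:`mne` is installed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "Recording",
    "RunConfig",
    "FormatError",
    "mmse_to_group",
    "read_recording",
    "write_recording",
    "read_edf_recording",
    "read_manifest",
    "write_manifest",
]

#: Diagnostic group labels, ordered by increasing cognitive score.
GROUPS = ("dementia", "mci", "healthy")


class FormatError(ValueError):
    """A data file violates the documented on-disk format."""


def mmse_to_group(score: int) -> str:
    """Map an MMSE score (0-30) to a diagnostic group label.

    The Mini-Mental State Examination is a 30-point cognitive screen; the
    labeling rule is: 24 or lower -> ``dementia``, 25-27 -> ``mci``,
    28 or higher -> ``healthy``.
    """
    if isinstance(score, bool) or not isinstance(score, (int, np.integer)):
        raise TypeError(f"MMSE score must be an integer, got {score!r}")
    if not 0 <= score <= 30:
        raise ValueError(f"MMSE score must lie in [0, 30], got {score}")
    if score <= 24:
        return "dementia"
    if score <= 27:
        return "mci"
    return "healthy"


@dataclass
class Recording:
    """One subject's single-channel EEG trace plus metadata.

    Amplitude units are arbitrary: the pipeline z-normalizes every recording,
    so only relative structure matters.  ``channel`` defaults to the left
    prefrontal electrode Fp1 of the 10-20 placement system.
    """

    subject_id: str
    samples: np.ndarray
    fs: float
    channel: str = "Fp1"
    mmse: Optional[int] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.mmse is not None:
            expected = mmse_to_group(int(self.mmse))
            if self.group is None:
                self.group = expected
            elif self.group != expected:
                raise ValueError(
                    f"group {self.group!r} inconsistent with MMSE {self.mmse} "
                    f"(expected {expected!r})"
                )
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def copy_with(self, samples: np.ndarray) -> "Recording":
        """Return a copy of this recording with new sample values."""
        return dataclasses.replace(self, samples=np.asarray(samples, float).copy())


@dataclass
class RunConfig:
    """Every tunable of the pipeline, JSON round-trippable.

    Defaults reproduce the documented analysis: 1-30 Hz band limit, 2 s
    detection windows, EEMD with 100 noise realizations at 0.2 x segment SD,
    between-IMF rejection at 0.5, 1 s Hann STFT windows, Bonferroni-corrected
    Kruskal-Wallis selection at the 5% level, SMOTE with 5 neighbours and an
    RBF-kernel SVM under stratified tenfold cross-validation.
    """

    # preprocess
    bandpass_low_hz: float = 1.0
    bandpass_high_hz: float = 30.0
    bandpass_order: int = 4
    # artifact detection (SDW)
    sdw_window_s: float = 2.0
    sdw_k_mad: float = 2.0
    sdw_abs_threshold: Optional[float] = None
    # EEMD + IMF rejection
    eemd_ensemble: int = 100
    eemd_noise_sd: float = 0.2
    emd_max_imfs: int = 10
    emd_max_sifts: int = 12
    emd_sd_stop: float = 0.2
    imf_reject_threshold: float = 0.5
    imf_reject_mode: str = "vs_original"  # or "between"
    crossfade_s: float = 0.1
    # spectral features
    stft_window_s: float = 1.0
    stft_taper: str = "hann"  # or "boxcar"
    bin_min_hz: int = 1
    bin_max_hz: int = 45
    feature_normalization: str = "sum_to_one"  # or "zscore"
    reference_group: str = "healthy"
    # statistics
    alpha: float = 0.05
    p_adjust_method: str = "bonferroni"  # or "bh_fdr"
    # classification
    smote_k_neighbors: int = 5
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    cv_folds: int = 10
    leakage_mode: str = "safe"  # or "global"
    # stage gating and seeding
    run_denoise: bool = True
    run_classification: bool = True
    seed: int = 0

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if "{" not in text:  # a path, not inline JSON
            p = Path(text)
            if not p.exists():
                raise FileNotFoundError(f"configuration file not found: {p}")
            text = p.read_text()
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as two-column CSV (sample_index, amplitude)."""
    df = pd.DataFrame(
        {
            "sample_index": np.arange(recording.n_samples, dtype=int),
            "amplitude": recording.samples,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_recording(
    path: str | Path,
    fs_hint: float,
    subject_id: Optional[str] = None,
    mmse: Optional[int] = None,
    group: Optional[str] = None,
) -> Recording:
    """Read a two-column recording CSV written by :func:`write_recording`.

    Raises :class:`FormatError` (with the offending line number where it can
    be located) for empty files, missing columns, or a non-monotone index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty recording file") from exc
    for col in ("sample_index", "amplitude"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: recording contains no samples")
    idx = df["sample_index"].to_numpy()
    steps = np.diff(idx)
    if idx[0] != 0 or (steps.size and np.any(steps != 1)):
        bad = 0 if idx[0] != 0 else int(np.argmax(steps != 1)) + 1
        # +2: one for the header row, one for 1-based line numbering
        raise FormatError(
            f"{path}: non-monotone or gapped sample_index at line {bad + 2}"
        )
    return Recording(
        subject_id=subject_id or path.stem,
        samples=df["amplitude"].to_numpy(dtype=float),
        fs=fs_hint,
        mmse=mmse,
        group=group,
    )


def read_edf_recording(path: str | Path, channel: Optional[str] = None) -> Recording:
    """Read one channel of an EDF file as a Recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF input requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    name = channel or raw.ch_names[0]
    if name not in raw.ch_names:
        raise ValueError(f"channel {name!r} not present in {path}")
    data = raw.get_data(picks=[name])[0]
    return Recording(
        subject_id=Path(str(path)).stem,
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel=name,
    )


MANIFEST_COLUMNS = ("subject_id", "path", "mmse", "group", "seed")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Read a cohort manifest CSV, optionally verifying referenced files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty manifest") from exc
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    if check_files:
        for rec_path in df["path"]:
            p = Path(rec_path)
            if not p.is_absolute():
                p = path.parent / p
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest {path} references missing recording: {rec_path}"
                )
    return df
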