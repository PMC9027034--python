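import numpy as np
import pandas as pd
import pytest

from eegscreen.features import (
    BAND_EDGES,
    FEATURE_COLUMNS,
    FeatureVector,
    band_bins,
    band_powers,
    bin_features,
    extract_features,
    feature_table,
    relative_power,
    stft_power,
)
from eegscreen.io import Recording
from .conftest import make_tone


def test_band_scheme_partitions():
    """Sub-bands tile their parent bands; edges strictly increase."""
    alpha = set(band_bins("alpha"))
    assert set(band_bins("alpha1")) | set(band_bins("alpha2")) | set(band_bins("alpha3")) == alpha
    beta = set(band_bins("beta"))
    assert set(band_bins("beta1")) | set(band_bins("beta2")) == beta
    for lo, hi in BAND_EDGES.values():
        assert lo < hi
    assert list(band_bins("delta")) == [1, 2, 3]
    assert list(band_bins("alpha1")) == [8]
    assert list(band_bins("alpha2")) == [9, 10]
    assert 45 in band_bins("gamma")


def test_stft_zero_signal():
    rec = Recording("z", np.zeros(512 * 4), fs=512)
    spectra = stft_power(rec)
    assert spectra.shape[0] == 4
    assert np.all(spectra == 0.0)


def test_stft_pure_tone_concentration():
    """With a rectangular taper a 10 Hz tone is a single-bin line."""
    rec = make_tone(10.0, duration_s=3.0)
    spectra = stft_power(rec, taper="boxcar")
    for row in spectra:
        assert row[10] / row.sum() >= 0.99


def test_stft_parseval(rng):
    """Summed bin power equals the tapered window's mean square."""
    x = rng.standard_normal(512 * 5)
    rec = Recording("w", x, fs=512)
    spectra = stft_power(rec, taper="boxcar")
    frames = x.reshape(5, 512)
    for row, frame in zip(spectra, frames):
        assert np.isclose(row.sum(), np.mean(frame**2), rtol=1e-9)


def test_stft_trailing_partial_dropped():
    rec = Recording("p", np.ones(512 * 2 + 100), fs=512)
    assert stft_power(rec).shape[0] == 2


def test_stft_too_short():
    with pytest.raises(ValueError):
        stft_power(Recording("s", np.ones(100), fs=512))


def test_bin_features_single_window_normalized():
    rec = make_tone(10.0, duration_s=1.0)
    fv = bin_features(stft_power(rec, taper="boxcar"))
    assert fv.normalization == "sum_to_one"
    assert np.isclose(fv.bin_powers.sum(), 1.0, atol=1e-9)
    assert fv.bin_power(10) >= 0.99


def test_bin_features_hand_computed_mean():
    """Two windows with known bins match mean-then-normalize arithmetic."""
    nbins = 257
    w1 = np.zeros(nbins)
    w2 = np.zeros(nbins)
    w1[10], w1[20] = 4.0, 2.0
    w2[10], w2[20] = 2.0, 2.0
    fv = bin_features(np.vstack([w1, w2]))
    # means: bin10 = 3, bin20 = 2 -> normalized 0.6 / 0.4
    assert np.isclose(fv.bin_power(10), 0.6)
    assert np.isclose(fv.bin_power(20), 0.4)


def test_bin_features_all_zero_rejected():
    with pytest.raises(ValueError, match="normalization undefined"):
        bin_features(np.zeros((3, 257)))


def test_band_power_half_open_convention():
    """Power at exactly 4 Hz counts toward theta, not delta."""
    nbins = 257
    w = np.zeros(nbins)
    w[4] = 1.0
    fv = bin_features(w[None, :])
    assert fv.band_powers["delta"] == 0.0
    assert fv.band_powers["theta"] > 0.0
    w2 = np.zeros(nbins)
    w2[2] = 1.0
    fv2 = bin_features(w2[None, :])
    assert fv2.band_powers["delta"] > 0.0
    assert all(fv2.band_powers[b] == 0.0 for b in ("theta", "alpha", "beta", "gamma"))


def test_flat_bins_give_equal_band_powers():
    w = np.ones(257)
    fv = bin_features(w[None, :])
    common = fv.bin_power(1)
    for band in BAND_EDGES:
        assert np.isclose(fv.band_powers[band], common)


def test_band_bin_consistency(short_recording):
    fv = extract_features(short_recording)
    for band in BAND_EDGES:
        expected = np.mean([fv.bin_power(hz) for hz in band_bins(band)])
        assert np.isclose(fv.band_powers[band], expected)


# --- relative power --------------------------------------------------------


def _toy_table():
    rows = []
    rng = np.random.default_rng(0)
    for i in range(6):
        vals = rng.uniform(0.5, 1.5, size=len(FEATURE_COLUMNS))
        row = pd.Series(vals, index=FEATURE_COLUMNS)
        row["group"] = "healthy" if i < 3 else "dementia"
        row["mmse"] = 29 if i < 3 else 20
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    return df


def test_relative_power_reference_mean_is_one():
    rel = relative_power(_toy_table(), "healthy")
    ref_mean = rel[rel["group"] == "healthy"][FEATURE_COLUMNS].mean()
    assert np.allclose(ref_mean.to_numpy(), 1.0, atol=1e-12)


def test_relative_power_single_reference_subject():
    df = _toy_table().iloc[[0, 3, 4]]
    rel = relative_power(df, "healthy")
    assert np.allclose(rel.iloc[0][FEATURE_COLUMNS].astype(float).to_numpy(), 1.0)


def test_relative_power_zero_reference_named():
    df = _toy_table()
    df.loc[df["group"] == "healthy", "bin_7"] = 0.0
    with pytest.raises(ValueError, match="bin_7"):
        relative_power(df, "healthy")


def test_relative_power_empty_reference():
    df = _toy_table()
    with pytest.raises(ValueError, match="empty"):
        relative_power(df, "mci")
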