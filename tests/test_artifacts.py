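import numpy as np
import pytest

from eegscreen.artifacts import (
    ArtifactMask,
    ThresholdPolicy,
    _local_extrema,
    _zero_crossings,
    denoise,
    eemd,
    emd,
    max_lag_xcorr,
    reconstruct,
    reject_imfs,
    sdw_detect,
    sdw_score,
)
from eegscreen.io import Recording, RunConfig
from eegscreen.preprocess import preprocess
from eegscreen.synth import ArtifactSpec, default_profiles, generate_recording, inject_artifacts


# --- mask ------------------------------------------------------------------


def test_mask_invariants():
    with pytest.raises(ValueError):
        ArtifactMask(intervals=[(5, 3)])
    with pytest.raises(ValueError):
        ArtifactMask(intervals=[(0, 10), (5, 20)])
    m = ArtifactMask.from_intervals([(5, 10), (0, 5)], merge=True)
    assert m.intervals == [(0, 10)]


# --- SDW -------------------------------------------------------------------


def test_sdw_score_known_values():
    assert sdw_score(np.full(50, 3.0)) == 0.0
    alternating = np.tile([0.0, 1.0], 10)
    assert sdw_score(alternating) == len(alternating) - 1
    ramp = np.arange(8.0)
    assert sdw_score(ramp) == 7.0


def test_sdw_score_too_short():
    with pytest.raises(ValueError):
        sdw_score(np.array([1.0]))


def test_sdw_detect_constant_empty():
    rec = Recording("c", np.concatenate([np.zeros(4096), [1.0], np.zeros(4095)]), 512)
    # a near-constant signal with one spike: the spike window is flagged
    mask = sdw_detect(rec, policy=ThresholdPolicy(absolute=0.5))
    assert len(mask) == 1
    rec2 = Recording("c", np.random.default_rng(0).standard_normal(8192), 512)
    assert len(sdw_detect(rec2, policy=ThresholdPolicy(absolute=np.inf))) == 0


def test_sdw_detect_too_short():
    with pytest.raises(ValueError):
        sdw_detect(Recording("s", np.ones(100), 512), window_s=2.0)


def test_sdw_detect_flags_large_blink():
    """A well-interior high-amplitude blink is flagged and fully covered."""
    prof = default_profiles()["healthy"]
    rec = generate_recording(prof, fs=512, duration_s=30, seed=42)
    x = rec.samples.copy()
    rms = np.sqrt(np.mean(x**2))
    start, dur = 5 * 1024 + 300, 154  # interior of window 5
    bump = 0.5 * (1 - np.cos(2 * np.pi * (np.arange(dur) + 1) / (dur + 1)))
    x[start : start + dur] += 20 * rms * bump
    pre = preprocess(Recording("b", x, 512))
    mask = sdw_detect(pre)
    assert mask.covered_fraction(start, start + dur) >= 0.9


def test_trailing_partial_window_never_flagged():
    x = np.random.default_rng(1).standard_normal(1024 * 3 + 500)
    x[-400:] += 100.0  # huge offset only inside the trailing partial window
    mask = sdw_detect(Recording("t", x, 512))
    for s, e in mask:
        assert e <= 1024 * 3


# --- EMD -------------------------------------------------------------------


def test_emd_monotone_ramp():
    d = emd(np.linspace(0.0, 1.0, 200))
    assert d.n_imfs == 0
    assert np.allclose(d.residual, np.linspace(0.0, 1.0, 200))


def test_emd_too_short():
    with pytest.raises(ValueError):
        emd(np.array([1.0, 2.0, 3.0]))


def test_emd_two_tone_separation():
    """First IMF captures the fast (20 Hz) component of a 2+20 Hz mixture."""
    t = np.arange(1024) / 512
    fast = np.sin(2 * np.pi * 20 * t)
    slow = np.sin(2 * np.pi * 2 * t)
    d = emd(fast + slow)
    assert d.n_imfs >= 2
    r = np.corrcoef(d.imfs[0], fast)[0, 1]
    assert r > 0.9


def test_emd_completeness_random(rng):
    for _ in range(10):
        x = rng.standard_normal(600)
        d = emd(x)
        assert np.max(np.abs(d.reconstruction() - x)) < 1e-8


def test_imf_count_property(rng):
    """Each IMF's extrema and zero-crossing counts differ by at most one."""
    x = rng.standard_normal(1024)
    d = emd(x)
    assert d.n_imfs >= 2
    for imf in d.imfs:
        mx, mn = _local_extrema(imf)
        assert abs((mx.size + mn.size) - _zero_crossings(imf)) <= 1


def test_imf_frequency_ordering(rng):
    """Zero-crossing rate is non-increasing from first to last IMF."""
    t = np.arange(2048) / 512
    x = (
        np.sin(2 * np.pi * 25 * t)
        + np.sin(2 * np.pi * 9 * t)
        + np.sin(2 * np.pi * 2.5 * t)
    )
    d = emd(x)
    rates = [_zero_crossings(imf) for imf in d.imfs]
    assert all(a >= b for a, b in zip(rates, rates[1:]))


# --- EEMD ------------------------------------------------------------------


def test_eemd_reduces_to_emd():
    x = np.random.default_rng(3).standard_normal(512)
    a = eemd(x, n_ensemble=1, noise_sd=0.0, seed=0)
    b = emd(x)
    assert a.n_imfs == b.n_imfs
    for i1, i2 in zip(a.imfs, b.imfs):
        assert np.array_equal(i1, i2)


def test_eemd_determinism():
    x = np.random.default_rng(4).standard_normal(512)
    a = eemd(x, n_ensemble=20, noise_sd=0.2, seed=7)
    b = eemd(x, n_ensemble=20, noise_sd=0.2, seed=7)
    for i1, i2 in zip(a.imfs, b.imfs):
        assert np.array_equal(i1, i2)


def test_eemd_exact_completeness():
    """Paired noise realizations cancel, so the average is complete."""
    x = np.random.default_rng(5).standard_normal(700)
    d = eemd(x, n_ensemble=20, noise_sd=0.2, seed=1)
    assert np.max(np.abs(d.reconstruction() - x)) < 1e-8


def test_eemd_two_tone_frequency_separation():
    t = np.arange(1024) / 512
    x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 2 * t)
    d = eemd(x, n_ensemble=50, noise_sd=0.2, seed=2)
    assert _zero_crossings(d.imfs[0]) > _zero_crossings(d.imfs[-1])


# --- rejection & reconstruction -------------------------------------------


def test_single_imf_kept():
    t = np.arange(512) / 512
    d = emd(np.sin(2 * np.pi * 5 * t) + 0.001 * t)
    one = d.imfs[:1]
    from eegscreen.artifacts import IMFDecomposition

    res = reject_imfs(IMFDecomposition(imfs=one, residual=d.residual))
    assert res.kept_indices == [0]
    assert res.scores == [0.0]


def test_identical_imfs_rejected():
    from eegscreen.artifacts import IMFDecomposition

    t = np.arange(512) / 512
    imf = np.sin(2 * np.pi * 8 * t)
    d = IMFDecomposition(imfs=[imf.copy(), imf.copy()], residual=np.zeros(512))
    res = reject_imfs(d, threshold=0.5, mode="between")
    assert res.rejected_indices == [0, 1]


def test_separated_tones_kept():
    """5 Hz and 20 Hz tones have max-lag cross-correlation well below 0.5."""
    from eegscreen.artifacts import IMFDecomposition

    t = np.arange(4096) / 512
    a = np.sin(2 * np.pi * 5 * t)
    b = np.sin(2 * np.pi * 20 * t)
    assert max_lag_xcorr(a, b) < 0.3
    d = IMFDecomposition(imfs=[a, b], residual=np.zeros(t.size))
    res = reject_imfs(d, threshold=0.5, mode="between")
    assert res.kept_indices == [0, 1]


def test_reconstruct_all_none_subset(rng):
    x = rng.standard_normal(800)
    d = emd(x)
    assert np.max(np.abs(reconstruct(d.imfs, d.residual) - x)) < 1e-8
    assert np.array_equal(reconstruct([], d.residual), d.residual)
    subset = d.imfs[::2]
    expected = d.residual + np.sum(subset, axis=0)
    assert np.allclose(reconstruct(subset, d.residual), expected)


def test_reconstruct_length_mismatch():
    with pytest.raises(ValueError):
        reconstruct([np.ones(5)], np.ones(6))


# --- denoise ---------------------------------------------------------------


def test_denoise_noop_with_conservative_threshold(short_recording):
    cfg = RunConfig(sdw_abs_threshold=np.inf)
    pre = preprocess(short_recording)
    out, mask = denoise(pre, cfg)
    assert len(mask) == 0
    assert np.array_equal(out.samples, pre.samples)


def test_denoise_untouched_outside_mask(short_recording):
    spec = ArtifactSpec(blink_rate=6.0, blink_amplitude=15.0)
    dirty, _ = inject_artifacts(short_recording, spec, seed=8)
    pre = preprocess(dirty)
    cfg = RunConfig(eemd_ensemble=10)
    out, mask = denoise(pre, cfg)
    flags = mask.to_boolean(pre.n_samples)
    assert np.array_equal(out.samples[~flags], pre.samples[~flags])


def test_denoise_determinism(short_recording):
    spec = ArtifactSpec(blink_rate=6.0, blink_amplitude=15.0)
    dirty, _ = inject_artifacts(short_recording, spec, seed=8)
    pre = preprocess(dirty)
    cfg = RunConfig(eemd_ensemble=10)
    out1, m1 = denoise(pre, cfg)
    out2, m2 = denoise(pre, cfg)
    assert m1.intervals == m2.intervals
    assert np.array_equal(out1.samples, out2.samples)
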