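import numpy as np
import pytest
from hypothesis import given, strategies as st

from gpbr import (AudioClip, DenoiseConfig, NoiseProfile, apply_gain,
                  compute_gain, denoise_clip, estimate_noise,
                  smooth_spectrogram, stft, istft)
from gpbr.synthdata import (IndividualProfile, NoiseProfileSpec,
                            default_profiles, generate_components)


def test_stft_roundtrip_white_noise(rng):
    clip = AudioClip(rng.normal(size=44100), 44100)
    S = stft(clip)
    x = istft(S, len(clip))
    assert np.max(np.abs(x - clip.samples)) < 1e-6


def test_stft_sine_concentrates_energy():
    sr, win, hop = 44100, 2048, 512
    k = 50                                 # exact bin-centred frequency
    f = k * sr / win
    t = np.arange(sr) / sr
    clip = AudioClip(0.5 * np.sin(2 * np.pi * f * t), sr)
    S = stft(clip, win, hop)
    mag = np.abs(S.values)
    interior = mag[:, 5:-5]
    assert np.all(interior.argmax(axis=0) == k)
    assert S.values.shape[0] == win // 2 + 1


def test_stft_zero_clip_and_too_short():
    S = stft(AudioClip(np.zeros(8192), 44100))
    assert np.all(S.values == 0)
    with pytest.raises(ValueError):
        stft(AudioClip(np.zeros(100), 44100), window_samples=2048)


def test_smoothing_constant_row_fixed_point():
    x = np.full((3, 50), 7.5)
    assert np.allclose(smooth_spectrogram(x, 0.9), x)


def test_smoothing_small_constant_is_identity():
    rng = np.random.default_rng(1)
    x = np.abs(rng.normal(size=(4, 30)))
    assert np.allclose(smooth_spectrogram(x, 1e-9), x, atol=1e-6)


def test_smoothing_impulse_matches_direct_recursion():
    """Forward-backward first-order recursion, hand-run as the oracle."""
    a = 0.5
    x = np.zeros(9)
    x[4] = 1.0

    def recurse(seq, a):
        y = np.empty_like(seq)
        prev = seq[0]
        for i, v in enumerate(seq):
            prev = a * prev + (1 - a) * v
            y[i] = prev
        return y

    fwd = recurse(x, a)
    expected = recurse(fwd[::-1], a)[::-1]
    got = smooth_spectrogram(x[None, :], a)[0]
    assert np.allclose(got, expected, atol=1e-12)
    # two-sided decay away from the impulse
    assert np.all(np.diff(expected[:5]) > 0) and np.all(np.diff(expected[4:]) < 0)


def test_smoothing_rejects_bad_constant():
    for a in (0.0, 1.0, -0.2, 2.0):
        with pytest.raises(ValueError):
            smooth_spectrogram(np.ones((2, 4)), a)


def test_estimate_noise_stationary_row_statistics():
    S = np.array([[1.0, 2.0, 3.0, 4.0],
                  [0.0, 0.0, 0.0, 8.0]])
    out = estimate_noise(S, n_std=1.0, stationary=True).N
    assert np.allclose(out[0], 2.5 + np.sqrt(1.25))
    assert np.allclose(out[1], 2.0 + np.sqrt(12.0))
    const = np.full((3, 6), 4.2)
    assert np.allclose(estimate_noise(const, n_std=0.0, stationary=True).N, 4.2)
    assert np.all(estimate_noise(np.zeros((2, 5)), stationary=True).N == 0)


def test_gain_hand_case_and_identity():
    spec = stft(AudioClip(np.ones(8192) * 0.1, 44100))
    mag = np.abs(spec.values)
    # N = 0 -> G = 1 -> X = S
    out = apply_gain(spec, mag, NoiseProfile(np.zeros_like(mag)))
    assert np.allclose(out.values, spec.values)
    # hand-evaluated cell: |S| = 2, Ssmooth = 2, N = 1 -> G = 0.5, |X| = 1
    G = compute_gain(np.array([[2.0]]), NoiseProfile(np.array([[1.0]]))).G
    assert np.allclose(G, 0.5)
    # N >= Ssmooth clamps to zero
    G = compute_gain(np.array([[2.0]]), NoiseProfile(np.array([[5.0]]))).G
    assert np.allclose(G, 0.0)
    # zero-signal cell fully gated
    G = compute_gain(np.array([[0.0]]), NoiseProfile(np.array([[0.0]]))).G
    assert np.allclose(G, 0.0)


@given(st.integers(0, 2**31 - 1))
def test_gain_bounds_property(seed):
    rng = np.random.default_rng(seed)
    S = np.abs(rng.normal(size=(5, 7)))
    N = np.abs(rng.normal(size=(5, 7)))
    G = compute_gain(S, NoiseProfile(N)).G
    assert np.all(G >= 0) and np.all(G <= 1)


def test_gain_monotone_in_noise(rng):
    spec = stft(AudioClip(rng.normal(size=20000), 44100))
    mag = np.abs(spec.values)
    Ssm = smooth_spectrogram(mag, 0.9)
    N1 = 0.3 * Ssm
    N2 = 0.6 * Ssm                      # elementwise larger noise estimate
    X1 = np.abs(apply_gain(spec, Ssm, NoiseProfile(N1)).values)
    X2 = np.abs(apply_gain(spec, Ssm, NoiseProfile(N2)).values)
    assert np.all(X2 <= X1 + 1e-12)
    assert np.all(X1 <= mag + 1e-12)    # gain never amplifies


def test_gain_shape_mismatch():
    spec = stft(AudioClip(np.ones(8192), 44100))
    with pytest.raises(ValueError):
        apply_gain(spec, np.ones((2, 2)), NoiseProfile(np.ones((2, 2))))


def test_denoise_zero_noise_estimate_is_identity():
    sr = 44100
    t = np.arange(3 * sr) / sr
    clip = AudioClip(0.4 * np.sin(2 * np.pi * 1000 * t), sr)
    cfg = DenoiseConfig(thresh_factor=0.0)  # N = 0 -> G = 1 everywhere
    out = denoise_clip(clip, cfg)
    rel = np.linalg.norm(out.samples - clip.samples) / np.linalg.norm(clip.samples)
    assert rel < 1e-3
    assert len(out) == len(clip)


def test_denoise_all_zero_input():
    out = denoise_clip(AudioClip(np.zeros(44100), 44100))
    assert np.allclose(out.samples, 0.0)


def test_denoise_improves_snr_on_burst_fixture():
    """Known clean events + known collar noise: >= 3 dB SNR gain (defaults)."""
    prof = default_profiles()["eating"]
    ind = IndividualProfile("neutral", 0.0, 0.0, 1.0)
    noise = NoiseProfileSpec(friction_burst_rate=1.0, wind_level=0.08,
                             stationary_floor=0.03)
    clean, nz, _ = generate_components(prof, ind, noise, seconds=6.0,
                                       rate=44100, seed=3)
    mix = clean + nz

    def snr(sig, ref):
        return 10 * np.log10(np.sum(ref ** 2) / np.sum((sig - ref) ** 2))

    out = denoise_clip(AudioClip(mix, 44100)).samples
    assert snr(out, clean) >= snr(mix, clean) + 3.0
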