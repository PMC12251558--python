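"""Mel-spectrogram features.

A (denoised) clip is converted into the single-channel log-mel tensor the
classifier consumes. The chain is the field-standard one: pre-emphasis,
centred framing with a Hann window, FFT power spectrum per frame, a bank
of triangular filters with centres equally spaced on the mel scale

    mel(f) = 2595 * log10(1 + f / 700),

energy summation per filter, and log compression. Under the default
configuration (64 mel filters, 0.16 s analysis window, 0.06 s hop,
centred framing) a 60 s clip at 44,100 Hz maps to a tensor of shape
(1, 64, 1001).

Framing convention: the waveform is zero-padded by half a window on both
sides and frames start every ``hop`` samples, so that

    n_frames = 1 + floor(n_samples / hop)        (window length even).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .audio_io import AudioClip

__all__ = [
    "FeatureConfig",
    "MelFilterbank",
    "MelFeature",
    "hz_to_mel",
    "mel_to_hz",
    "build_filterbank",
    "power_spectrogram",
    "melspectrogram",
    "standardize",
]


@dataclass
class FeatureConfig:
    n_mels: int = 64
    window_seconds: float = 0.16
    hop_seconds: float = 0.06
    pre_emphasis: float = 0.97
    log_floor: float = 1e-10
    center: bool = True

    def window_samples(self, sample_rate: int) -> int:
        return int(round(self.window_seconds * sample_rate))

    def hop_samples(self, sample_rate: int) -> int:
        return int(round(self.hop_seconds * sample_rate))

    def n_fft(self, sample_rate: int) -> int:
        return _next_pow2(self.window_samples(sample_rate))


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


@dataclass
class MelFilterbank:
    """Triangular filterbank ``H`` of shape (n_mels, n_fft//2 + 1)."""

    H: np.ndarray
    center_freqs: np.ndarray  # Hz, length n_mels

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)
        self.center_freqs = np.asarray(self.center_freqs, dtype=np.float64)
        if np.any(self.H < 0):
            raise ValueError("filterbank responses must be non-negative")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("filter centre frequencies must be strictly increasing")


@dataclass
class MelFeature:
    """Log-mel network input of shape (1, n_mels, n_frames)."""

    values: np.ndarray
    frame_hop_s: float
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != 1:
            raise ValueError(f"expected shape (1, n_mels, T), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature contains non-finite values")


def hz_to_mel(f):
    """Mel value of frequency ``f`` (Hz); strictly increasing, mel(0) = 0."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return out if out.ndim else float(out)


def mel_to_hz(m):
    """Inverse of :func:`hz_to_mel`."""
    m = np.asarray(m, dtype=np.float64)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return out if out.ndim else float(out)


def build_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> MelFilterbank:
    """Triangular filters with centres equally spaced on the mel axis.

    Filter ``m`` rises linearly from the (m-1)-th centre, peaks at 1 at its
    own centre and falls to zero at the (m+1)-th centre; the outermost
    edges sit at 0 Hz and Nyquist.
    """
    if n_mels < 1:
        raise ValueError("n_mels must be >= 1")
    if n_fft < 2 * n_mels or (n_fft & (n_fft - 1)) != 0:
        raise ValueError(
            f"n_fft must be a power of two >= 2*n_mels, got n_fft={n_fft}, n_mels={n_mels}"
        )
    nyquist = sample_rate / 2.0
    mel_pts = np.linspace(0.0, hz_to_mel(nyquist), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)  # edges f_{m-1}, centres f_m, edges f_{m+1}
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    H = np.zeros((n_mels, bin_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        rising = (bin_freqs - lo) / (ctr - lo)
        falling = (hi - bin_freqs) / (hi - ctr)
        H[m] = np.maximum(0.0, np.minimum(rising, falling))
    if np.any(H.sum(axis=1) == 0):
        raise ValueError("some filters cover no FFT bin; decrease n_mels or raise n_fft")
    return MelFilterbank(H=H, center_freqs=hz_pts[1:-1])


def _frame(x: np.ndarray, win: int, hop: int, center: bool) -> np.ndarray:
    if center:
        x = np.pad(x, (win // 2, win // 2))
    if x.size < win:
        raise ValueError("clip shorter than one analysis window")
    n_frames = 1 + (x.size - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def power_spectrogram(clip: AudioClip, config: FeatureConfig | None = None) -> np.ndarray:
    """Per-frame FFT power spectrum ``P(f)``, shape (n_fft//2 + 1, n_frames)."""
    cfg = config or FeatureConfig()
    sr = clip.sample_rate
    x = clip.samples
    if cfg.pre_emphasis > 0:
        x = np.concatenate(([x[0] * (1.0 - cfg.pre_emphasis)],
                            x[1:] - cfg.pre_emphasis * x[:-1]))
    win = cfg.window_samples(sr)
    hop = cfg.hop_samples(sr)
    frames = _frame(x, win, hop, cfg.center)
    window = get_window("hann", win, fftbins=True)
    spec = np.fft.rfft(frames * window, n=cfg.n_fft(sr), axis=1)
    return (np.abs(spec) ** 2).T


def melspectrogram(clip: AudioClip, config: FeatureConfig | None = None,
                   log: bool = True, clip_id: str | None = None) -> MelFeature:
    """Log-mel feature tensor of shape (1, n_mels, n_frames).

    With ``log=False`` the linear filterbank energies are returned instead
    (useful for energy-bookkeeping checks).
    """
    cfg = config or FeatureConfig()
    P = power_spectrogram(clip, cfg)
    fb = build_filterbank(cfg.n_mels, cfg.n_fft(clip.sample_rate), clip.sample_rate)
    M = fb.H @ P  # (n_mels, n_frames)
    if log:
        M = 10.0 * np.log10(np.maximum(M, cfg.log_floor))
    return MelFeature(
        values=M[None, :, :],
        frame_hop_s=cfg.hop_seconds,
        clip_id=clip_id or (clip.source_path or ""),
    )


def standardize(feature: MelFeature) -> MelFeature:
    """Per-clip zero-mean, unit-variance scaling (applied before the network)."""
    v = feature.values
    mu, sigma = v.mean(), v.std()
    if sigma == 0:
        sigma = 1.0
    return MelFeature(values=(v - mu) / sigma, frame_hop_s=feature.frame_hop_s,
                      clip_id=feature.clip_id)
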