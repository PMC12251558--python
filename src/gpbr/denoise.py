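"""Non-stationary spectral-gating noise reduction.

Collar-mounted recorders pick up strong broadband interference (collar
friction, wind) on top of the faint acoustic events that carry behavioural
information. Denoising works on the short-time Fourier transform (STFT)
magnitude: a time-smoothed spectrogram ``Ssmooth`` is compared against a
noise estimate ``N(f, t)`` and each time-frequency cell is attenuated by
the gain

    G(f, t) = max(1 - N(f, t) / Ssmooth(f, t), 0),

so cells whose magnitude sits at or below the noise estimate are gated to
zero while cells well above it pass nearly unchanged. The gain scales the
complex STFT (phase untouched) and the inverse STFT returns the denoised
waveform.

Two noise estimators are provided:

* ``stationary`` — per-frequency time statistics, N(f) = mu_f + n_std * sigma_f;
* non-stationary (default) — a much more slowly smoothed version of the
  spectrogram tracks the slowly varying noise floor, so transient events
  rise above it while drifting background is gated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import ShortTimeFFT, get_window, lfilter

from .audio_io import AudioClip

__all__ = [
    "ComplexSpectrogram",
    "NoiseProfile",
    "GainField",
    "DenoiseConfig",
    "stft",
    "istft",
    "smooth_spectrogram",
    "estimate_noise",
    "compute_gain",
    "apply_gain",
    "denoise_clip",
]


@dataclass
class ComplexSpectrogram:
    """Complex STFT ``S(f, t)`` with its analysis metadata."""

    values: np.ndarray  # complex, shape (n_freq, n_frames)
    window_samples: int
    hop_samples: int
    sample_rate: int
    window_kind: str = "hann"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("spectrogram must be 2-D (freq, time)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class NoiseProfile:
    """Estimated noise magnitude ``N(f, t)``, broadcastable to the spectrogram."""

    N: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=np.float64)
        if np.any(self.N < 0):
            raise ValueError("noise profile must be non-negative")


@dataclass
class GainField:
    """Multiplicative spectral gain, elementwise in [0, 1]."""

    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.float64)
        if np.any(self.G < 0) or np.any(self.G > 1):
            raise ValueError("gain must lie in [0, 1]")


@dataclass
class DenoiseConfig:
    """Spectral-gating parameters.

    The smoothing constants are the pole of the first-order zero-phase
    recursive smoother applied along time per frequency row; larger values
    smooth over longer horizons. ``thresh_factor`` scales the
    non-stationary noise estimate; ``n_std`` sets the stationary threshold
    in per-frequency standard deviations.
    """

    window_samples: int = 2048
    hop_samples: int = 512
    window_kind: str = "hann"
    smoothing_constant: float = 0.9
    mode: Literal["stationary", "nonstationary"] = "nonstationary"
    n_std: float = 1.5
    thresh_factor: float = 1.0
    slow_smoothing_constant: float = 0.99


def _make_sft(window_samples: int, hop_samples: int, sample_rate: int,
              window_kind: str) -> ShortTimeFFT:
    win = get_window(window_kind, window_samples, fftbins=True)
    return ShortTimeFFT(win, hop=hop_samples, fs=sample_rate, fft_mode="onesided")


def stft(clip: AudioClip, window_samples: int = 2048, hop_samples: int = 512,
         window_kind: str = "hann") -> ComplexSpectrogram:
    """Windowed STFT of a clip; invertible by :func:`istft`."""
    if not (window_samples >= hop_samples >= 1):
        raise ValueError("require window_samples >= hop_samples >= 1")
    if len(clip) < window_samples:
        raise ValueError(
            f"clip of {len(clip)} samples shorter than one window ({window_samples})"
        )
    sft = _make_sft(window_samples, hop_samples, clip.sample_rate, window_kind)
    values = sft.stft(clip.samples)
    return ComplexSpectrogram(
        values=values,
        window_samples=window_samples,
        hop_samples=hop_samples,
        sample_rate=clip.sample_rate,
        window_kind=window_kind,
    )


def istft(spec: ComplexSpectrogram, length: int) -> np.ndarray:
    """Inverse STFT back to ``length`` time-domain samples."""
    sft = _make_sft(spec.window_samples, spec.hop_samples, spec.sample_rate,
                    spec.window_kind)
    x = sft.istft(spec.values, k1=length)
    return np.ascontiguousarray(x[:length])


def smooth_spectrogram(S_mag: np.ndarray, smoothing_constant: float) -> np.ndarray:
    """Zero-phase first-order recursive smoothing along time, per frequency row.

    Runs y[t] = a*y[t-1] + (1-a)*x[t] forward then backward (initialised at
    the boundary sample so a constant row is a fixed point).
    """
    a = float(smoothing_constant)
    if not (0.0 < a < 1.0):
        raise ValueError(f"smoothing_constant must lie in (0, 1), got {a}")
    x = np.asarray(S_mag, dtype=np.float64)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("magnitude spectrogram must be non-negative and finite")
    b, aa = [1.0 - a], [1.0, -a]
    zi = a * x[..., :1]
    y, _ = lfilter(b, aa, x, axis=-1, zi=zi)
    zi = a * y[..., -1:]
    yrev, _ = lfilter(b, aa, y[..., ::-1], axis=-1, zi=zi)
    out = yrev[..., ::-1]
    return np.maximum(out, 0.0)


def estimate_noise(Ssmooth: np.ndarray, n_std: float = 1.5, stationary: bool = False,
                   thresh_factor: float = 1.0,
                   slow_smoothing_constant: float = 0.99) -> NoiseProfile:
    """Estimate the noise magnitude spectrogram from the smoothed spectrogram."""
    Ssmooth = np.asarray(Ssmooth, dtype=np.float64)
    if np.any(Ssmooth < 0):
        raise ValueError("smoothed spectrogram must be non-negative")
    if stationary:
        mu = Ssmooth.mean(axis=-1, keepdims=True)
        sigma = Ssmooth.std(axis=-1, keepdims=True)
        N = np.broadcast_to(mu + n_std * sigma, Ssmooth.shape).copy()
    else:
        slow = smooth_spectrogram(Ssmooth, slow_smoothing_constant)
        N = thresh_factor * slow
    return NoiseProfile(N=np.maximum(N, 0.0))


def compute_gain(Ssmooth: np.ndarray, noise: NoiseProfile) -> GainField:
    """Spectral gain G = max(1 - N/Ssmooth, 0), with G = 0 where Ssmooth = 0."""
    Ssmooth = np.asarray(Ssmooth, dtype=np.float64)
    if Ssmooth.shape != noise.N.shape:
        raise ValueError(
            f"shape mismatch: Ssmooth {Ssmooth.shape} vs N {noise.N.shape}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        G = 1.0 - noise.N / Ssmooth
    G[Ssmooth == 0] = 0.0
    return GainField(G=np.clip(G, 0.0, 1.0))


def apply_gain(S: ComplexSpectrogram, Ssmooth: np.ndarray,
               noise: NoiseProfile) -> ComplexSpectrogram:
    """Attenuate the complex STFT by the spectral gain (phase preserved)."""
    if np.asarray(Ssmooth).shape != S.values.shape:
        raise ValueError("Ssmooth shape does not match spectrogram")
    gain = compute_gain(Ssmooth, noise)
    return ComplexSpectrogram(
        values=S.values * gain.G,
        window_samples=S.window_samples,
        hop_samples=S.hop_samples,
        sample_rate=S.sample_rate,
        window_kind=S.window_kind,
    )


def denoise_clip(clip: AudioClip, config: DenoiseConfig | None = None) -> AudioClip:
    """Full spectral-gating chain: STFT -> smooth -> noise estimate -> gain -> iSTFT.

    The output has exactly the input's length and sample rate; the chain is
    deterministic for a fixed input and configuration.
    """
    cfg = config or DenoiseConfig()
    S = stft(clip, cfg.window_samples, cfg.hop_samples, cfg.window_kind)
    Ssmooth = smooth_spectrogram(S.magnitude, cfg.smoothing_constant)
    noise = estimate_noise(
        Ssmooth,
        n_std=cfg.n_std,
        stationary=(cfg.mode == "stationary"),
        thresh_factor=cfg.thresh_factor,
        slow_smoothing_constant=cfg.slow_smoothing_constant,
    )
    X = apply_gain(S, Ssmooth, noise)
    y = istft(X, length=len(clip))
    if y.size < len(clip):  # defensive: pad to exact input length
        y = np.pad(y, (0, len(clip) - y.size))
    return AudioClip(
        samples=y,
        sample_rate=clip.sample_rate,
        label=clip.label,
        individual=clip.individual,
        source_path=clip.source_path,
    )
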