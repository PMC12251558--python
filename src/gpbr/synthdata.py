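"""Synthetic labelled bioacoustic clips.

The real recordings are unreleased, so every stage is exercised on
generated audio that carries the same *structure* the method assumes:
behaviours are mixtures of short basic acoustic events (chewing bursts,
breathing, footsteps, rhythmic gurgles, cub squeaks over a resting base),
individuals colour those events with bounded timbre perturbations (pitch
shift, timing jitter, amplitude scaling), and recordings are corrupted by
non-stationary collar noise (friction bursts, wind-like coloured noise,
a stationary floor). Event times are Poisson; event spectra are band-pass
filtered noise bursts or harmonic stacks — deliberately simple, so their
presence is independently detectable by envelope/band-energy oracles.

The default five behaviour profiles mirror the heavy class imbalance of
captive-panda data (resting and eating dominate; nursing and drinking are
rare) and make nursing deliberately confusable with resting (a resting
base plus sparse squeaks).

A "two-cue" variant gives every class two spectrally disjoint diagnostic
tones (one low-band, one high-band). Either cue alone identifies the
class, which makes the competitive-learning mechanism falsifiable: under
competition the two branches can only reduce their overlap penalty by
splitting the cues between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from .audio_io import AudioClip, DatasetManifest, save_clip, write_manifest

__all__ = [
    "EventSpec", "BehaviorProfile", "IndividualProfile", "NoiseProfileSpec",
    "default_profiles", "two_cue_profiles", "default_individuals",
    "generate_clip", "generate_components", "generate_dataset",
    "DEFAULT_RATE", "DEFAULT_SECONDS",
]

# Desk-scale defaults: full-length collar segments are 60 s at 44,100 Hz;
# tests and examples use 6 s at 8,000 Hz, running identical code paths.
DEFAULT_RATE = 8000
DEFAULT_SECONDS = 6.0

_EVENT_KINDS = ("burst", "tone", "gurgle", "thump", "squeak", "breath")


@dataclass
class EventSpec:
    """One basic acoustic event type within a behaviour."""

    kind: str
    rate: float            # mean events per second (Poisson)
    band: tuple[float, float]   # Hz
    amplitude: float = 1.0
    duration: float = 0.06      # seconds per event

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("event rate must be non-negative")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError(f"invalid band {self.band}")


@dataclass
class BehaviorProfile:
    name: str
    events: list[EventSpec]
    base_noise: float = 0.005


@dataclass
class IndividualProfile:
    """Bounded per-individual timbre perturbation."""

    name: str
    pitch_shift: float = 0.0     # semitones, |.| <= 4
    timing_jitter: float = 0.02  # seconds, <= 0.2
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.pitch_shift) > 4:
            raise ValueError("pitch_shift must satisfy |shift| <= 4 semitones")
        if not (0 <= self.timing_jitter <= 0.2):
            raise ValueError("timing_jitter must lie in [0, 0.2] s")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")


@dataclass
class NoiseProfileSpec:
    """Additive non-stationary recording noise."""

    friction_burst_rate: float = 0.8   # events/s of broadband collar friction
    wind_level: float = 0.05           # slowly AM-modulated low-passed noise
    stationary_floor: float = 0.01     # white-noise floor

    def __post_init__(self) -> None:
        if min(self.friction_burst_rate, self.wind_level, self.stationary_floor) < 0:
            raise ValueError("noise levels must be non-negative")


def default_profiles() -> dict[str, BehaviorProfile]:
    """The five default behaviours (nursing = resting base + sparse squeaks)."""
    breath = EventSpec("breath", 0.4, (80.0, 400.0), 0.35, duration=0.8)
    return {
        "eating": BehaviorProfile("eating", [
            EventSpec("burst", 2.0, (800.0, 3000.0), 1.0, duration=0.05),
            breath,
        ]),
        "resting": BehaviorProfile("resting", [breath]),
        "moving": BehaviorProfile("moving", [
            EventSpec("thump", 1.5, (60.0, 220.0), 1.0, duration=0.12),
            EventSpec("burst", 0.3, (800.0, 3000.0), 0.3, duration=0.05),
        ]),
        "nursing": BehaviorProfile("nursing", [
            breath,
            EventSpec("squeak", 0.8, (1500.0, 3500.0), 0.4, duration=0.15),
        ]),
        "drinking": BehaviorProfile("drinking", [
            EventSpec("gurgle", 1.2, (250.0, 900.0), 0.8, duration=0.35),
        ]),
    }


def two_cue_profiles(n_classes: int = 5, rate: int = DEFAULT_RATE
                     ) -> dict[str, BehaviorProfile]:
    """Classes with two spectrally disjoint diagnostic tone cues each.

    Cue A of class k sits in a low band, cue B in a high band; the bands of
    different classes do not overlap, so each cue alone is diagnostic.
    """
    nyq = rate / 2
    low_lo, low_hi = 0.06 * nyq, 0.42 * nyq
    high_lo, high_hi = 0.5 * nyq, 0.92 * nyq
    profiles = {}
    for k in range(n_classes):
        fa = low_lo + (low_hi - low_lo) * (k + 0.5) / n_classes
        fb = high_lo + (high_hi - high_lo) * (k + 0.5) / n_classes
        width_a = 0.5 * (low_hi - low_lo) / n_classes
        width_b = 0.5 * (high_hi - high_lo) / n_classes
        name = f"twocue_{k}"
        profiles[name] = BehaviorProfile(name, [
            EventSpec("tone", 2.5, (fa - width_a, fa + width_a), 1.0, duration=0.12),
            EventSpec("tone", 2.5, (fb - width_b, fb + width_b), 1.0, duration=0.12),
        ])
    return profiles


def default_individuals(n: int, seed: int = 0) -> list[IndividualProfile]:
    """Deterministic roster of individuals with bounded timbre spread."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(IndividualProfile(
            name=f"panda_{i}",
            pitch_shift=float(rng.uniform(-2.5, 2.5)),
            timing_jitter=float(rng.uniform(0.0, 0.05)),
            amplitude_scale=float(rng.uniform(0.7, 1.3)),
        ))
    return out


# ---------------------------------------------------------------------------
# event synthesis
# ---------------------------------------------------------------------------

def _bandpass_noise(n: int, band, rate: int, rng) -> np.ndarray:
    nyq = rate / 2
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.999)
    x = rng.standard_normal(n)
    sos = butter(4, [lo, hi], btype="band", output="sos")
    y = sosfilt(sos, x)
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def _harmonic_stack(n: int, f0: float, rate: int, n_harm: int = 3,
                    phase: float = 0.0) -> np.ndarray:
    ts = np.arange(n) / rate
    y = np.zeros(n)
    for h in range(1, n_harm + 1):
        if h * f0 < rate / 2:
            y += np.sin(2 * np.pi * h * f0 * ts + phase * h) / h
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def _event_waveform(spec: EventSpec, rate: int, rng,
                    pitch_factor: float) -> np.ndarray:
    n = max(int(spec.duration * rate), 8)
    band = (spec.band[0] * pitch_factor, spec.band[1] * pitch_factor)
    band = (min(band[0], rate / 2 * 0.95), min(band[1], rate / 2 * 0.97))
    kind = spec.kind
    if kind in ("burst", "breath"):
        y = _bandpass_noise(n, band, rate, rng)
        env = np.hanning(n) if kind == "burst" else np.sin(np.pi * np.arange(n) / n) ** 2
    elif kind == "thump":
        f0 = np.sqrt(band[0] * band[1])
        ts = np.arange(n) / rate
        y = np.sin(2 * np.pi * f0 * ts) * np.exp(-ts * 25.0)
        env = np.ones(n)
    elif kind in ("tone", "squeak"):
        f0 = float(rng.uniform(*band))
        y = _harmonic_stack(n, f0, rate, n_harm=3 if kind == "tone" else 2,
                            phase=float(rng.uniform(0, 2 * np.pi)))
        env = np.hanning(n)
    elif kind == "gurgle":
        f0 = float(rng.uniform(*band))
        y = _harmonic_stack(n, f0, rate, n_harm=2)
        ts = np.arange(n) / rate
        y = y * (0.55 + 0.45 * np.sin(2 * np.pi * 16.0 * ts))  # rhythmic AM
        env = np.hanning(n)
    else:  # pragma: no cover - guarded by EventSpec
        raise ValueError(kind)
    return spec.amplitude * y * env


def _place_events(total: np.ndarray, spec: EventSpec, rate: int, seconds: float,
                  rng, individual: IndividualProfile) -> int:
    """Superimpose Poisson-timed events; returns the number placed."""
    pitch_factor = 2.0 ** (individual.pitch_shift / 12.0)
    n_events = rng.poisson(spec.rate * seconds)
    for _ in range(n_events):
        t0 = rng.uniform(0.0, seconds)
        t0 += rng.normal(0.0, individual.timing_jitter)
        start = int(t0 * rate)
        wav = _event_waveform(spec, rate, rng, pitch_factor)
        wav = wav * individual.amplitude_scale
        if start < 0:
            wav = wav[-start:]
            start = 0
        end = min(start + wav.size, total.size)
        if end > start:
            total[start:end] += wav[: end - start]
    return int(n_events)


def _noise_waveform(noise: NoiseProfileSpec, n: int, rate: int, rng) -> np.ndarray:
    out = noise.stationary_floor * rng.standard_normal(n)
    if noise.wind_level > 0:
        wind = _bandpass_noise(n, (20.0, 500.0), rate, rng)
        ts = np.arange(n) / rate
        am = 0.5 + 0.5 * np.abs(np.sin(2 * np.pi * 0.3 * ts + rng.uniform(0, np.pi)))
        out += noise.wind_level * wind * am
    n_fric = rng.poisson(noise.friction_burst_rate * n / rate)
    for _ in range(n_fric):
        start = int(rng.uniform(0, n))
        dur = max(int(rng.uniform(0.02, 0.08) * rate), 8)
        wav = _bandpass_noise(dur, (400.0, rate / 2 * 0.9), rate, rng)
        wav *= np.hanning(dur) * rng.uniform(0.1, 0.35)
        end = min(start + dur, n)
        out[start:end] += wav[: end - start]
    return out


def generate_components(behavior: BehaviorProfile, individual: IndividualProfile,
                        noise: NoiseProfileSpec, seconds: float = DEFAULT_SECONDS,
                        rate: int = DEFAULT_RATE, seed: int = 0):
    """Clean event waveform and noise waveform, before mixing/normalisation.

    Returns ``(clean, noise_wave, event_counts)`` where ``event_counts``
    maps event kind to the number of events placed.
    """
    if seconds <= 0:
        raise ValueError("seconds must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(seconds * rate))
    clean = np.zeros(n)
    counts: dict[str, int] = {}
    for spec in behavior.events:
        counts[spec.kind] = counts.get(spec.kind, 0) + _place_events(
            clean, spec, rate, seconds, rng, individual)
    if behavior.base_noise > 0:
        clean += behavior.base_noise * rng.standard_normal(n)
    noise_wave = _noise_waveform(noise, n, rate, rng)
    return clean, noise_wave, counts


def generate_clip(behavior: BehaviorProfile, individual: IndividualProfile,
                  noise: NoiseProfileSpec, seconds: float = DEFAULT_SECONDS,
                  rate: int = DEFAULT_RATE, seed: int = 0) -> AudioClip:
    """One labelled clip: events + individual timbre + noise, peak-normalised.

    Deterministic for a fixed seed. The mixture is scaled to peak 0.9
    (clean and noise scaled together, preserving their ratio); an all-zero
    mixture (no events, no noise) is returned as silence.
    """
    clean, noise_wave, _ = generate_components(behavior, individual, noise,
                                               seconds, rate, seed)
    mix = clean + noise_wave
    peak = np.max(np.abs(mix))
    if peak > 0:
        mix = 0.9 * mix / peak
    return AudioClip(samples=mix, sample_rate=rate, label=behavior.name,
                     individual=individual.name)


# Class-mix shape mirroring the imbalance of real captive-panda recordings
# (eating and resting dominate; nursing and drinking are rare).
DEFAULT_CLASS_MIX = {
    "eating": 10, "resting": 16, "moving": 5, "nursing": 3, "drinking": 2,
}


def generate_dataset(out_dir: str | Path, n_individuals: int = 3,
                     class_mix: dict[str, int] | None = None,
                     seconds: float = DEFAULT_SECONDS, rate: int = DEFAULT_RATE,
                     seed: int = 0, two_cue: bool = False,
                     noise: NoiseProfileSpec | None = None) -> DatasetManifest:
    """Write a labelled WAV dataset plus manifest CSV; returns the manifest.

    ``class_mix`` gives clips per class per individual. In two-cue mode the
    classes are the synthetic two-cue classes regardless of ``class_mix``
    keys (its values are reused in order, or a balanced mix by default).
    """
    if n_individuals < 2:
        raise ValueError("need at least two individuals for leave-one-out folds")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if two_cue:
        profiles = two_cue_profiles(rate=rate)
        if class_mix is None:
            class_mix = {name: 8 for name in profiles}
        else:
            class_mix = {name: c for name, c in
                         zip(profiles, list(class_mix.values()))}
    else:
        profiles = default_profiles()
        class_mix = dict(class_mix or DEFAULT_CLASS_MIX)
    unknown = set(class_mix) - set(profiles)
    if unknown:
        raise ValueError(f"class_mix names not in profiles: {sorted(unknown)}")
    if any(c < 1 for c in class_mix.values()):
        raise ValueError("class_mix counts must be >= 1")
    individuals = default_individuals(n_individuals, seed=seed)
    noise = noise or NoiseProfileSpec()
    records = []
    clip_seed = np.random.SeedSequence(seed)
    counter = 0
    for indiv in individuals:
        for cls_name, count in class_mix.items():
            for i in range(count):
                child_seed = int(clip_seed.spawn(1)[0].generate_state(1)[0] % (2**31))
                clip = generate_clip(profiles[cls_name], indiv, noise,
                                     seconds, rate, seed=child_seed)
                fname = f"{indiv.name}_{cls_name}_{i:03d}.wav"
                save_clip(clip, out_dir / fname)
                records.append((str(out_dir / fname), indiv.name, cls_name))
                counter += 1
    manifest = DatasetManifest(
        records=records,
        class_names=list(class_mix.keys()),
        individual_names=[p.name for p in individuals],
    )
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
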