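"""Audio and manifest I/O.

Clips are mono floating-point waveforms in [-1, 1]. Collar recordings are
nominally 60 s mono at 44,100 Hz; everything here is rate-agnostic so the
synthetic desk-scale fixtures (shorter clips, lower rates) run through the
identical code paths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

__all__ = [
    "AudioClip",
    "DatasetManifest",
    "load_clip",
    "save_clip",
    "segment_clip",
    "read_manifest",
    "write_manifest",
]


@dataclass
class AudioClip:
    """A labelled mono audio clip.

    Parameters
    ----------
    samples
        1-D float array of amplitudes, nominal range [-1, 1].
    sample_rate
        Sampling rate in Hz.
    label
        Behaviour class name, if known.
    individual
        Individual (animal) identifier, if known.
    source_path
        Originating file, if any.
    """

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    individual: str | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {self.samples.shape}")
        if self.samples.size < 1:
            raise ValueError("clip must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if int(self.sample_rate) <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        self.sample_rate = int(self.sample_rate)

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class DatasetManifest:
    """Mapping of audio files to individuals and behaviour labels.

    ``class_names`` and ``individual_names`` preserve first-appearance
    order, matching how per-class counts and per-individual folds are
    reported downstream.
    """

    records: list[tuple[str, str, str]]  # (path, individual, behavior)
    class_names: list[str] = field(default_factory=list)
    individual_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            self.class_names = _unique_ordered(r[2] for r in self.records)
        if not self.individual_names:
            self.individual_names = _unique_ordered(r[1] for r in self.records)
        known = set(self.class_names)
        for path, indiv, behavior in self.records:
            if behavior not in known:
                raise ValueError(f"behavior {behavior!r} of {path!r} not in class_names")
        known_ind = set(self.individual_names)
        for path, indiv, _ in self.records:
            if indiv not in known_ind:
                raise ValueError(f"individual {indiv!r} of {path!r} not in individual_names")
        if len(self.class_names) < 2:
            raise ValueError("manifest must contain at least two behaviour classes")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        """Number of clips per behaviour class, ordered as ``class_names``."""
        index = {c: i for i, c in enumerate(self.class_names)}
        counts = np.zeros(len(self.class_names), dtype=np.int64)
        for _, _, behavior in self.records:
            counts[index[behavior]] += 1
        return counts

    def subset(self, indices: np.ndarray | list[int]) -> "DatasetManifest":
        recs = [self.records[i] for i in indices]
        return DatasetManifest(
            records=recs,
            class_names=list(self.class_names),
            individual_names=_unique_ordered(r[1] for r in recs),
        )


def _unique_ordered(items) -> list[str]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x, None)
    return list(seen)


def load_clip(path: str | Path, target_rate: int = 44_100) -> AudioClip:
    """Read a WAV file as a mono clip at ``target_rate``.

    Multi-channel audio is mixed to mono by averaging channels before
    resampling. Integer PCM is scaled to [-1, 1] by the type's full scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path} contains no audio samples")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:  # (n_samples, n_channels) -> mean over channels
        data = data.mean(axis=1)
    if rate != target_rate:
        frac = Fraction(int(target_rate), int(rate))
        data = resample_poly(data, frac.numerator, frac.denominator)
    return AudioClip(samples=data, sample_rate=target_rate, source_path=str(path))


def save_clip(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.sample_rate, (x * 32767.0).astype(np.int16))


def segment_clip(clip: AudioClip, seg_seconds: float) -> list[AudioClip]:
    """Cut a clip into consecutive non-overlapping fixed-length segments.

    A trailing remainder shorter than ``seg_seconds`` is dropped; a clip
    shorter than one segment yields an empty list.
    """
    if seg_seconds <= 0:
        raise ValueError(f"seg_seconds must be positive, got {seg_seconds}")
    seg_len = int(round(seg_seconds * clip.sample_rate))
    n_segments = len(clip) // seg_len
    out = []
    for i in range(n_segments):
        out.append(
            replace(clip, samples=clip.samples[i * seg_len : (i + 1) * seg_len].copy())
        )
    return out


_MANIFEST_COLUMNS = ("path", "individual", "behavior")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a dataset manifest CSV with columns path, individual, behavior.

    Duplicate paths are kept (a clip may legitimately appear twice, e.g.
    under different segmentations) but logged as a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"manifest {path} is empty") from exc
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"manifest {path} missing required column(s): {missing}")
    if len(df) == 0:
        raise ValueError(f"manifest {path} has a header but no records")
    dup = df["path"].duplicated()
    if dup.any():
        logger.warning("manifest %s: %d duplicate path rows kept", path, int(dup.sum()))
    records = list(df[list(_MANIFEST_COLUMNS)].itertuples(index=False, name=None))
    return DatasetManifest(records=records)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(manifest.records, columns=list(_MANIFEST_COLUMNS)).to_csv(
        path, index=False
    )
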