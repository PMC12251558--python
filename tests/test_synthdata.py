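import numpy as np
import pytest
from scipy.signal import butter, sosfilt
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from gpbr import class_weights, read_manifest
from gpbr.synthdata import (BehaviorProfile, EventSpec, IndividualProfile,
                            NoiseProfileSpec, default_individuals,
                            default_profiles, generate_clip,
                            generate_components, generate_dataset,
                            two_cue_profiles)


def _band_event_count(x, rate, band, thresh_rel=0.25, min_gap_s=0.02):
    """Envelope-threshold event counter: the detection oracle."""
    sos = butter(4, [band[0] / (rate / 2), band[1] / (rate / 2)],
                 btype="band", output="sos")
    env = np.abs(sosfilt(sos, x))
    k = max(int(0.01 * rate), 1)
    env = np.convolve(env, np.ones(k) / k, mode="same")
    above = env > thresh_rel * env.max()
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1)
    if edges.size == 0:
        return 0
    kept = [edges[0]]
    for t in edges[1:]:
        if t - kept[-1] > min_gap_s * rate:
            kept.append(t)
    return len(kept)


def test_same_seed_bit_identical():
    prof = default_profiles()["eating"]
    ind = default_individuals(1)[0]
    nz = NoiseProfileSpec()
    a = generate_clip(prof, ind, nz, seed=11)
    b = generate_clip(prof, ind, nz, seed=11)
    assert np.array_equal(a.samples, b.samples)
    c = generate_clip(prof, ind, nz, seed=12)
    assert not np.array_equal(a.samples, c.samples)


def test_zero_rates_zero_noise_is_silence():
    prof = BehaviorProfile("quiet", [EventSpec("burst", 0.0, (500, 1000))],
                           base_noise=0.0)
    ind = IndividualProfile("p", 0, 0, 1)
    clip = generate_clip(prof, ind, NoiseProfileSpec(0, 0, 0), seed=0)
    assert np.all(clip.samples == 0)


def test_clip_bounds_and_labels():
    prof = default_profiles()["moving"]
    ind = default_individuals(2)[1]
    clip = generate_clip(prof, ind, NoiseProfileSpec(), seed=4)
    assert clip.label == "moving"
    assert clip.individual == ind.name
    assert np.all(np.isfinite(clip.samples))
    assert np.max(np.abs(clip.samples)) <= 0.9 + 1e-12


def test_chewing_burst_count_poisson():
    """Detected bursts over 60 s lie within 3 sigma of rate * duration."""
    prof = default_profiles()["eating"]
    ind = IndividualProfile("neutral", 0.0, 0.0, 1.0)
    clean, _, placed = generate_components(
        prof, ind, NoiseProfileSpec(0, 0, 0), seconds=60, rate=8000, seed=5)
    expected = 2.0 * 60
    detected = _band_event_count(clean, 8000, (800, 3000))
    assert abs(detected - expected) <= 3 * np.sqrt(expected)
    assert abs(placed["burst"] - expected) <= 3 * np.sqrt(expected)


def test_snr_reproducible_for_fixed_seed():
    prof = default_profiles()["eating"]
    ind = default_individuals(1)[0]
    nz = NoiseProfileSpec()

    def snr(seed):
        clean, noise, _ = generate_components(prof, ind, nz, seed=seed)
        return 10 * np.log10(np.sum(clean ** 2) / np.sum(noise ** 2))

    assert abs(snr(7) - snr(7)) < 0.1


def test_dataset_bookkeeping(tmp_path):
    mix = {"eating": 2, "resting": 3, "moving": 1, "nursing": 1, "drinking": 1}
    manifest = generate_dataset(tmp_path, n_individuals=2, class_mix=mix, seed=0)
    assert len(manifest.records) == 2 * sum(mix.values())
    assert manifest.n_classes == 5
    assert len(manifest.individual_names) == 2
    reread = read_manifest(tmp_path / "manifest.csv")
    assert reread.class_names == manifest.class_names
    for path, _, _ in manifest.records:
        assert (tmp_path / path.split("/")[-1]).exists()


def test_imbalanced_mix_orders_class_weights(tmp_path):
    mix = {"eating": 10, "resting": 16, "moving": 3, "nursing": 2, "drinking": 1}
    manifest = generate_dataset(tmp_path, n_individuals=2, class_mix=mix, seed=0)
    counts = manifest.class_counts()
    alpha = class_weights(counts).alpha
    assert np.array_equal(np.argsort(alpha), np.argsort(counts)[::-1])


def test_dataset_validation(tmp_path):
    with pytest.raises(ValueError):
        generate_dataset(tmp_path, n_individuals=1)
    with pytest.raises(ValueError):
        generate_dataset(tmp_path, n_individuals=2, class_mix={"eating": 0})
    with pytest.raises(ValueError):
        generate_dataset(tmp_path, n_individuals=2, class_mix={"flying": 3})


def test_two_cue_bands_disjoint():
    profiles = two_cue_profiles(5, rate=8000)
    assert len(profiles) == 5
    bands = []
    for prof in profiles.values():
        assert len(prof.events) == 2
        low, high = prof.events
        assert low.band[1] < high.band[0]          # the two cues are disjoint
        bands.extend([low.band, high.band])
    bands.sort()
    for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
        assert hi1 <= lo2 + 1e-9                   # classes do not overlap


def test_linear_separability_of_oracle_features():
    """Band-energy/event-count oracle features separate the 5 defaults."""
    profiles = default_profiles()
    individuals = default_individuals(3, seed=0)
    nz = NoiseProfileSpec()
    bands = [(60, 220), (80, 400), (250, 900), (800, 3000), (1500, 3500)]
    X, y = [], []
    seed = 0
    for ci, prof in enumerate(profiles.values()):
        for ind in individuals:
            for _ in range(6):
                seed += 1
                clip = generate_clip(prof, ind, nz, seconds=6, rate=8000,
                                     seed=seed)
                feats = []
                for band in bands:
                    sos = butter(4, [band[0] / 4000, band[1] / 4000],
                                 btype="band", output="sos")
                    e = sosfilt(sos, clip.samples)
                    feats.append(np.log10(np.mean(e ** 2) + 1e-12))
                    feats.append(_band_event_count(clip.samples, 8000, band))
                X.append(feats)
                y.append(ci)
    clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=5000))
    assert clf.fit(X, y).score(X, y) > 0.95
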