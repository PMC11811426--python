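"""Synthetic corpus generator: determinism, invariants, class signals.

The class-signal checks use independent oracles: an autocorrelation pitch
tracker for audio and a brute-force threshold sweep on inter-frame motion
energy for video.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from mmdepnet.synthetic import (GeneratorConfig, SubjectRecord, draw_records,
                                generate_audio, generate_corpus, generate_video,
                                load_audio, load_clip, load_manifest)

from conftest import make_record


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def autocorrelation_pitch(wave: np.ndarray, sr: int, fmin=60.0, fmax=400.0) -> float:
    """Fundamental frequency from the highest autocorrelation peak."""
    x = wave - wave.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    lo = int(sr / fmax)
    hi = int(sr / fmin)
    lag = lo + int(np.argmax(ac[lo:hi]))
    return sr / lag


def motion_energy(clip: np.ndarray) -> float:
    """Mean absolute inter-frame difference."""
    return float(np.abs(np.diff(clip, axis=0)).mean())


def best_threshold_accuracy(values: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force sweep of a single threshold on a scalar statistic."""
    best = 0.0
    for t in np.unique(values):
        for sign in (1, -1):
            pred = (sign * values >= sign * t).astype(int)
            best = max(best, (pred == labels).mean())
    return best


def _records(n, labels_seed=0):
    rng = np.random.default_rng(labels_seed)
    labels = np.arange(n) % 2
    rng.shuffle(labels)
    return [make_record(label=int(l), subject_id=f"S{i:04d}") for i, l in enumerate(labels)]


# ---------------------------------------------------------------------------
# record / metadata invariants
# ---------------------------------------------------------------------------

def test_subject_record_validates_fields():
    with pytest.raises(ValueError):
        SubjectRecord("S1", label=2, phq8=5, sex="male")
    with pytest.raises(ValueError):
        SubjectRecord("S1", label=0, phq8=30, sex="male")
    with pytest.raises(ValueError):
        SubjectRecord("S1", label=0, phq8=5, sex="other")


def test_label_matches_threshold_rule_for_every_record():
    cfg = GeneratorConfig(n_subjects=300, seed=3)
    for rec in draw_records(cfg):
        assert rec.label == (1 if rec.phq8 > cfg.positive_threshold else 0)
        assert 0 <= rec.phq8 <= 24


def test_forced_prevalence_counts():
    cfg = GeneratorConfig(n_subjects=10, prevalence=0.5, seed=1)
    recs = draw_records(cfg)
    assert len(recs) == 10
    assert sum(r.label for r in recs) == 5


def test_full_prevalence_gives_all_positive_scores():
    cfg = GeneratorConfig(n_subjects=20, prevalence=1.0, seed=2)
    assert all(r.phq8 > 10 for r in draw_records(cfg))


def test_split_sizes_emulate_229_subject_partition():
    cfg = GeneratorConfig(n_subjects=229, seed=5)
    recs = draw_records(cfg)
    counts = {s: sum(r.split == s for r in recs) for s in ("train", "val", "test")}
    assert abs(counts["train"] - 163) <= 1
    assert abs(counts["val"] - 56) <= 1
    assert abs(counts["test"] - 10) <= 1
    assert sum(counts.values()) == 229


def test_configurable_positive_threshold():
    cfg = GeneratorConfig(n_subjects=100, positive_threshold=5, seed=7)
    for rec in draw_records(cfg):
        assert rec.label == (1 if rec.phq8 > 5 else 0)


# ---------------------------------------------------------------------------
# per-record generators
# ---------------------------------------------------------------------------

def test_audio_repeatable_and_correct_length():
    cfg = GeneratorConfig(clip_seconds=0.5, seed=11)
    rec = make_record(label=1)
    w1 = generate_audio(rec, cfg)
    w2 = generate_audio(rec, cfg)
    np.testing.assert_array_equal(w1, w2)
    assert w1.shape == (int(cfg.sample_rate * cfg.clip_seconds),)


def test_audio_invalid_config_raises():
    with pytest.raises(ValueError):
        generate_audio(make_record(), GeneratorConfig(clip_seconds=-1.0))
    with pytest.raises(ValueError):
        generate_audio(make_record(), GeneratorConfig(sample_rate=0))


def test_video_repeatable_bounded_and_shaped():
    cfg = GeneratorConfig(frames_per_clip=6, frame_size=(16, 16), seed=13)
    rec = make_record(label=0)
    c1 = generate_video(rec, cfg)
    np.testing.assert_array_equal(c1, generate_video(rec, cfg))
    assert c1.shape == (6, 16, 16, 3)
    assert c1.min() >= 0.0 and c1.max() <= 1.0


def test_video_frame_size_too_small_raises():
    with pytest.raises(ValueError):
        generate_video(make_record(), GeneratorConfig(frame_size=(4, 4)))


def test_zero_effect_removes_audio_class_signal():
    cfg = GeneratorConfig(effect_size=0.0, clip_seconds=1.0, seed=17)
    pitches = {0: [], 1: []}
    for rec in _records(60):
        pitches[rec.label].append(autocorrelation_pitch(generate_audio(rec, cfg),
                                                        cfg.sample_rate))
    _, p = stats.ttest_ind(pitches[0], pitches[1])
    assert p > 0.01  # no detectable difference


def test_effect3_audio_pitch_gap_detected_by_oracle():
    cfg = GeneratorConfig(effect_size=3.0, clip_seconds=1.0, seed=19)
    pitches = {0: [], 1: []}
    for rec in _records(200):
        pitches[rec.label].append(autocorrelation_pitch(generate_audio(rec, cfg),
                                                        cfg.sample_rate))
    _, p = stats.ttest_ind(pitches[0], pitches[1])
    assert p < 0.01
    assert np.mean(pitches[1]) < np.mean(pitches[0])  # depressed = lower tone
    assert np.var(pitches[1]) < np.var(pitches[0])    # and more monotonous


def test_effect3_video_motion_separates_classes():
    cfg = GeneratorConfig(effect_size=3.0, frames_per_clip=8, frame_size=(32, 32),
                          seed=23)
    recs = _records(200)
    energy = np.array([motion_energy(generate_video(r, cfg)) for r in recs])
    labels = np.array([r.label for r in recs])
    assert best_threshold_accuracy(energy, labels) > 0.9


def test_zero_effect_video_motion_indistinguishable():
    cfg = GeneratorConfig(effect_size=0.0, frames_per_clip=8, frame_size=(32, 32),
                          seed=29)
    recs = _records(80)
    energy = np.array([motion_energy(generate_video(r, cfg)) for r in recs])
    labels = np.array([r.label for r in recs])
    _, p = stats.ttest_ind(energy[labels == 0], energy[labels == 1])
    assert p > 0.01


def test_separability_nondecreasing_in_effect_size():
    """Oracle AUC on the motion statistic grows with effect size."""
    from sklearn.metrics import roc_auc_score
    aucs = []
    for effect in (0.0, 1.0, 2.0, 3.0):
        cfg = GeneratorConfig(effect_size=effect, frames_per_clip=6,
                              frame_size=(16, 16), seed=31)
        recs = _records(80)
        energy = [motion_energy(generate_video(r, cfg)) for r in recs]
        labels = [r.label for r in recs]
        aucs.append(roc_auc_score(labels, -np.asarray(energy)))
    slack = 0.05
    assert all(b >= a - slack for a, b in zip(aucs, aucs[1:])), aucs
    assert aucs[-1] > 0.95


# ---------------------------------------------------------------------------
# corpus on disk
# ---------------------------------------------------------------------------

def test_corpus_files_and_manifest(tiny_corpus, tiny_generator_config):
    out, manifest = tiny_corpus
    cfg = tiny_generator_config
    assert len(manifest) == cfg.n_subjects
    assert set(manifest.columns) == {"subject_id", "label", "phq8", "sex",
                                     "audio_path", "video_path", "split"}
    row = manifest.iloc[0]
    wave, sr = load_audio(out / row["audio_path"])
    assert sr == cfg.sample_rate
    clip = load_clip(out / row["video_path"])
    assert clip.shape == (cfg.frames_per_clip, *cfg.frame_size, cfg.channels)
    reloaded = load_manifest(out / "manifest.csv")
    assert reloaded.equals(manifest)


def test_corpus_refuses_overwrite(tiny_corpus, tiny_generator_config):
    out, _ = tiny_corpus
    with pytest.raises(FileExistsError):
        generate_corpus(tiny_generator_config, out)


def test_corpus_bit_identical_across_regenerations(tmp_path):
    cfg = GeneratorConfig(n_subjects=4, frames_per_clip=4, frame_size=(16, 16),
                          clip_seconds=0.25, seed=99)
    a, b = tmp_path / "a", tmp_path / "b"
    generate_corpus(cfg, a)
    generate_corpus(cfg, b)
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel


def test_different_seed_changes_corpus(tmp_path):
    cfg = GeneratorConfig(n_subjects=4, frames_per_clip=4, frame_size=(16, 16),
                          clip_seconds=0.25, seed=99)
    cfg2 = dataclasses.replace(cfg, seed=100)
    generate_corpus(cfg, tmp_path / "a")
    generate_corpus(cfg2, tmp_path / "b")
    wa, _ = load_audio(tmp_path / "a" / "audio" / "S0000.wav")
    wb, _ = load_audio(tmp_path / "b" / "audio" / "S0000.wav")
    assert not np.array_equal(wa, wb)
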