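"""Synthetic multimodal corpus generator.

Produces labelled audio/video fixtures carrying the class structure the
screening networks are designed to detect, so the full pipeline can be
exercised without any clinical download:

* **Audio** — depressed speakers tend to speak in a monotonous, lower tone
  than controls.  Each clip is a harmonic voice-like tone (fundamental plus
  two harmonics) whose pitch drifts as an Ornstein–Uhlenbeck process;
  positive-label subjects get a lower mean fundamental and a smaller
  drift variance, with the class gap scaled by ``effect_size``.
* **Video** — a smooth moving 2-D Gaussian blob standing in for facial
  dynamics; positive-label subjects get smaller and slower oscillation of
  the blob centre (reduced facial motion), again scaled by ``effect_size``.
* **Metadata** — a PHQ-8-like severity score in [0, 24] coupled to the
  binary label by a threshold rule (label 1 iff score > 10 by default),
  a sex attribute for grouped evaluation, and a subject-level
  train/val/test split.

Everything is a pure function of :class:`GeneratorConfig` (including the
seed): regenerating a corpus yields byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import lfilter

__all__ = [
    "SubjectRecord", "GeneratorConfig", "generate_audio", "generate_video",
    "generate_corpus", "load_manifest", "load_clip", "load_audio", "draw_records",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["subject_id", "label", "phq8", "sex", "audio_path", "video_path", "split"]

# modality codes mixed into the per-subject seed stream
_META, _AUDIO, _VIDEO = 0, 1, 2


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: the unit of splitting and of file generation."""

    subject_id: str
    label: int
    phq8: int
    sex: str
    audio_path: str = ""
    video_path: str = ""
    split: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if not 0 <= self.phq8 <= 24:
            raise ValueError(f"phq8 must be in [0, 24], got {self.phq8}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Fully determines a corpus; identical configs give identical bytes.

    ``effect_size`` scales the separation between the class-conditional
    signal distributions in both modalities; 0 removes the signal entirely
    (labels become uninformative), ~3 gives a clearly detectable effect at
    a couple of hundred subjects.
    """

    n_subjects: int = 229
    prevalence: float = 0.5
    effect_size: float = 2.0
    frames_per_clip: int = 16
    frame_size: tuple[int, int] = (64, 64)
    channels: int = 3
    sample_rate: int = 16000
    clip_seconds: float = 2.0
    seed: int = 0
    # split fractions emulate the 163/56/10 partition of a 229-interview corpus
    split_fracs: tuple[float, float, float] = (163 / 229, 56 / 229, 10 / 229)
    positive_threshold: int = 10

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.prevalence < 1.0 and self.prevalence not in (0.0, 1.0):
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.frames_per_clip < 1:
            raise ValueError("frames_per_clip must be positive")
        if min(self.frame_size) < 8:
            raise ValueError(f"frame_size must be at least 8x8, got {self.frame_size}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.clip_seconds <= 0:
            raise ValueError(f"clip_seconds must be positive, got {self.clip_seconds}")
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValueError("split_fracs must sum to 1")
        if not 0 <= self.positive_threshold < 24:
            raise ValueError("positive_threshold must be in [0, 24)")


def _record_rng(record: SubjectRecord, cfg: GeneratorConfig, modality: int) -> np.random.Generator:
    key = zlib.crc32(record.subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, key, modality]))


# ---------------------------------------------------------------------------
# audio
# ---------------------------------------------------------------------------

_F0_BASE = 165.0      # Hz, gender-agnostic speaking fundamental
_F0_GAP = 7.5         # Hz shift per unit effect size, per class, each direction
_F0_SUBJECT_SD = 8.0  # between-subject spread of the fundamental
_PITCH_SD_BASE = 6.0  # stationary SD of the OU pitch drift at effect 0
_OU_THETA = 3.0       # OU mean-reversion rate (1/s)
_HARMONICS = (1.0, 0.5, 0.25)
_NOISE_SD = 0.02


def audio_class_params(label: int, effect_size: float) -> tuple[float, float]:
    """(mean fundamental Hz, OU stationary pitch SD Hz) for a class."""
    if label == 1:  # lower tone, more monotonous
        f0 = _F0_BASE - _F0_GAP * effect_size
        sd = _PITCH_SD_BASE / (1.0 + 0.6 * effect_size)
    else:
        f0 = _F0_BASE + _F0_GAP * effect_size
        sd = _PITCH_SD_BASE * (1.0 + 0.3 * effect_size)
    return f0, sd


def generate_audio(record: SubjectRecord, cfg: GeneratorConfig) -> np.ndarray:
    """Synthesize one mono waveform in [-1, 1], length ``sr * clip_seconds``."""
    cfg.validate()
    rng = _record_rng(record, cfg, _AUDIO)
    n = int(round(cfg.sample_rate * cfg.clip_seconds))
    f0_mean, pitch_sd = audio_class_params(record.label, cfg.effect_size)
    f0 = f0_mean + _F0_SUBJECT_SD * rng.standard_normal()

    # exact discretisation of the OU pitch-drift process, x0 at stationarity;
    # the AR(1) recursion x[i] = decay*x[i-1] + innov[i] runs through lfilter
    dt = 1.0 / cfg.sample_rate
    decay = np.exp(-_OU_THETA * dt)
    innov_sd = pitch_sd * np.sqrt(1.0 - decay**2)
    eps = rng.standard_normal(n)
    innov = innov_sd * eps
    innov[0] = pitch_sd * eps[0]
    drift = lfilter([1.0], [1.0, -decay], innov)

    freq = np.maximum(f0 + drift, 50.0)
    phase = 2.0 * np.pi * np.cumsum(freq) * dt
    wave = np.zeros(n)
    for h, amp in enumerate(_HARMONICS, start=1):
        wave += amp * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    wave *= 0.3 / sum(_HARMONICS)
    wave += _NOISE_SD * rng.standard_normal(n)
    return np.clip(wave, -1.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# video
# ---------------------------------------------------------------------------

_BLOB_SIGMA_FRAC = 0.15
_MOTION_AMP_FRAC = 0.12   # oscillation amplitude as a fraction of frame size
_MOTION_CYCLES = 1.0      # oscillation cycles per clip at effect 0
_PIXEL_NOISE_SD = 0.02
_CHANNEL_GAIN = (1.0, 0.8, 0.6)


def video_class_params(label: int, effect_size: float) -> tuple[float, float]:
    """(amplitude fraction, cycles per clip) of the blob oscillation."""
    if label == 1:  # damped facial dynamics
        amp = _MOTION_AMP_FRAC / (1.0 + 0.5 * effect_size)
        cyc = _MOTION_CYCLES / (1.0 + 0.4 * effect_size)
    else:
        amp = _MOTION_AMP_FRAC * (1.0 + 0.5 * effect_size)
        cyc = _MOTION_CYCLES * (1.0 + 0.4 * effect_size)
    return amp, cyc


def generate_video(record: SubjectRecord, cfg: GeneratorConfig) -> np.ndarray:
    """One clip (frames, height, width, channels), pixel values in [0, 1]."""
    cfg.validate()
    rng = _record_rng(record, cfg, _VIDEO)
    h, w = cfg.frame_size
    t_frames = cfg.frames_per_clip
    amp, cyc = video_class_params(record.label, cfg.effect_size)
    amp *= float(np.exp(0.1 * rng.standard_normal()))  # subject-level jitter

    c0 = np.array([0.5, 0.5]) + 0.05 * rng.standard_normal(2)
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, size=2)
    sigma = _BLOB_SIGMA_FRAC * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]

    clip = np.empty((t_frames, h, w, cfg.channels), dtype=np.float32)
    ts = np.arange(t_frames) / max(t_frames - 1, 1)
    noise = rng.standard_normal(clip.shape)
    for t in range(t_frames):
        cy = (c0[0] + amp * np.sin(2 * np.pi * cyc * ts[t] + phase_y)) * h
        cx = (c0[1] + amp * np.cos(2 * np.pi * cyc * ts[t] + phase_x)) * w
        blob = 0.8 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        for ch in range(cfg.channels):
            gain = _CHANNEL_GAIN[ch % len(_CHANNEL_GAIN)]
            clip[t, :, :, ch] = gain * blob
    clip += _PIXEL_NOISE_SD * noise
    return np.clip(clip, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fracs: tuple[float, ...]) -> list[int]:
    raw = [n * f for f in fracs]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def draw_records(cfg: GeneratorConfig) -> list[SubjectRecord]:
    """Draw the subject metadata (labels, PHQ-8, sex, split) for a corpus."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0, _META]))
    n = cfg.n_subjects
    n_pos = int(round(cfg.prevalence * n))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    labels = labels[rng.permutation(n)]
    thr = cfg.positive_threshold
    phq8 = np.where(
        labels == 1,
        rng.integers(thr + 1, 25, size=n),
        rng.integers(0, thr + 1, size=n),
    )
    sexes = np.where(rng.random(n) < 0.5, "female", "male")

    # stratified-by-label split so validation and test retain both classes
    splits = np.empty(n, dtype=object)
    names = ("train", "val", "test")
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        counts = _largest_remainder(len(idx), cfg.split_fracs)
        start = 0
        for name, cnt in zip(names, counts):
            splits[idx[start:start + cnt]] = name
            start += cnt

    return [
        SubjectRecord(
            subject_id=f"S{i:04d}", label=int(labels[i]), phq8=int(phq8[i]),
            sex=str(sexes[i]), split=str(splits[i]),
        )
        for i in range(n)
    ]


def generate_corpus(cfg: GeneratorConfig, out_dir: str | Path,
                    overwrite: bool = False) -> pd.DataFrame:
    """Write WAV audio, ``.npz`` video clips and a manifest; return the manifest.

    Refuses to clobber an existing manifest unless ``overwrite`` is set.
    """
    cfg.validate()
    out = Path(out_dir)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to regenerate"
        )
    (out / "audio").mkdir(parents=True, exist_ok=True)
    (out / "video").mkdir(parents=True, exist_ok=True)

    rows = []
    for rec in draw_records(cfg):
        audio_rel = f"audio/{rec.subject_id}.wav"
        video_rel = f"video/{rec.subject_id}.npz"
        rec = replace(rec, audio_path=audio_rel, video_path=video_rel)
        wave = generate_audio(rec, cfg)
        wavfile.write(out / audio_rel, cfg.sample_rate,
                      (wave * 32767.0).astype(np.int16))
        clip = generate_video(rec, cfg)
        with open(out / video_rel, "wb") as fh:
            np.savez_compressed(fh, frames=clip)
        rows.append([rec.subject_id, rec.label, rec.phq8, rec.sex,
                     audio_rel, video_rel, rec.split])

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(Path(path))
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def load_clip(path: str | Path) -> np.ndarray:
    with np.load(Path(path)) as data:
        return data["frames"]


def load_audio(path: str | Path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(Path(path))
    if data.dtype == np.int16:
        data = data.astype(np.float32) / 32767.0
    return data.astype(np.float32), int(sr)
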