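"""Canned synthetic-corpus experiments (overfit, signal recovery, ablation).

These are the package's benchmark settings: desk-scale corpora (8-frame
32×32 clips, 2-s audio at 16 kHz) that a single CPU can train in minutes.
Both the test suite and the acceptance script drive these functions, so
study conditions live in exactly one place.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from .pipeline import MultimodalDepressionPipeline, featurize_corpus
from .synthetic import GeneratorConfig, generate_corpus

__all__ = ["small_corpus_config", "make_dataset", "overfit_experiment",
           "signal_recovery_experiment"]

# desk-scale clip geometry shared by all benchmark corpora
_GEOMETRY = dict(frames_per_clip=8, frame_size=(32, 32), clip_seconds=2.0)


def small_corpus_config(n_subjects: int, effect_size: float, seed: int) -> GeneratorConfig:
    return GeneratorConfig(n_subjects=n_subjects, prevalence=0.5,
                           effect_size=effect_size, seed=seed, **_GEOMETRY)


def make_dataset(cfg: GeneratorConfig, workdir: str | Path | None = None) -> dict:
    """Generate a corpus under ``workdir`` (or a temp dir) and featurize it."""
    base = Path(workdir) if workdir is not None else Path(tempfile.mkdtemp())
    out = base / f"corpus_n{cfg.n_subjects}_e{cfg.effect_size:g}_s{cfg.seed}"
    generate_corpus(cfg, out, overwrite=True)
    return featurize_corpus(out)


def overfit_experiment(seed: int = 0, n_subjects: int = 32, iterations: int = 500,
                       workdir=None) -> dict:
    """Fit the fused system on a tiny corpus and score it on its own
    training split — a capacity sanity check (the networks must be able to
    memorise 32 subjects)."""
    cfg = replace(small_corpus_config(n_subjects, effect_size=3.0, seed=seed),
                  split_fracs=(1.0, 0.0, 0.0))
    dataset = make_dataset(cfg, workdir)
    pipe = MultimodalDepressionPipeline(
        modality="fused", seed=seed, video_iterations=iterations,
        audio_iterations=iterations, fusion_iterations=iterations)
    pipe.fit(dataset)
    report = pipe.evaluate(dataset, split="train")
    return {"train_f1": report.f1, "train_auc": report.auc,
            "n_subjects": n_subjects, "iterations": iterations}


def signal_recovery_experiment(effect_size: float, seeds=(0, 1, 2),
                               n_subjects: int = 200, video_iterations: int = 300,
                               audio_iterations: int = 300,
                               fusion_iterations: int = 200,
                               with_ablation: bool = False, workdir=None) -> dict:
    """Train branch + fused models per seed and report validation metrics.

    With ``with_ablation`` the per-seed single-modality reports are also
    collected (from the same trained branches and splits), giving the
    fused-vs-single-modality comparison for free.
    """
    fused_auc, fused_f1, video_f1, audio_f1 = [], [], [], []
    for seed in seeds:
        dataset = make_dataset(small_corpus_config(n_subjects, effect_size, seed),
                               workdir)
        pipe = MultimodalDepressionPipeline(
            modality="fused", seed=seed, video_iterations=video_iterations,
            audio_iterations=audio_iterations, fusion_iterations=fusion_iterations)
        pipe.fit(dataset)
        report = pipe.evaluate(dataset, split="val")
        fused_auc.append(report.auc)
        fused_f1.append(report.f1)
        if with_ablation:
            pipe.modality = "video"
            video_f1.append(pipe.evaluate(dataset, split="val").f1)
            pipe.modality = "audio"
            audio_f1.append(pipe.evaluate(dataset, split="val").f1)
            pipe.modality = "fused"
    out = {
        "effect_size": effect_size, "n_subjects": n_subjects, "seeds": list(seeds),
        "fused_val_auc_mean": float(np.mean(fused_auc)),
        "fused_val_f1_mean": float(np.mean([f for f in fused_f1 if f is not None])),
        "fused_val_auc": fused_auc,
    }
    if with_ablation:
        out["video_val_f1_mean"] = float(np.mean(video_f1))
        out["audio_val_f1_mean"] = float(np.mean(audio_f1))
    return out
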