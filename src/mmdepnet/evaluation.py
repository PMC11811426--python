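"""Ablation and grouped-evaluation harnesses.

``ablate`` retrains the system with components removed or replaced —
attention stripped from the video branch, GCN or LSTM dropped from the
audio branch, single-modality heads instead of fusion — under identical
splits and seeds, and tabulates one evaluation row per variant (model,
F1, RMSE, MAE), mirroring the usual ablation-table layout.

``grouped_eval`` recomputes metrics per subject group (sex by default)
plus the mixed group; groups with a single class get their AUC/F1 flagged
missing, empty groups are omitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audio_net import GCNLSTMClassifier
from .metrics import EvalReport, compute_metrics
from .pipeline import MultimodalDepressionPipeline
from .visual import TSNetClassifier

__all__ = ["ABLATION_VARIANTS", "ablate", "grouped_eval"]

ABLATION_VARIANTS = ("no_tsam", "gcn_only", "lstm_only", "video_only",
                     "audio_only", "fused")


def ablate(dataset: dict, variants=("video_only", "audio_only", "fused"),
           seed: int = 0, eval_split: str = "val",
           pipeline_kwargs: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Train each requested variant and evaluate on a common split.

    Returns (table with columns model/F1/RMSE/MAE, {variant: EvalReport}).
    Branch models shared between variants (e.g. the attention-full video
    net used by both ``video_only`` and ``fused``) are trained once.
    """
    variants = list(variants)
    unknown = set(variants) - set(ABLATION_VARIANTS)
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}; "
                         f"choose from {ABLATION_VARIANTS}")
    kwargs = dict(pipeline_kwargs or {})

    def make(modality, **overrides):
        return MultimodalDepressionPipeline(modality=modality, seed=seed,
                                            **{**kwargs, **overrides})

    cache: dict[str, MultimodalDepressionPipeline] = {}

    def base_fused():
        if "fused" not in cache:
            cache["fused"] = make("fused").fit(dataset)
        return cache["fused"]

    reports: dict[str, EvalReport] = {}
    if "fused" in variants:
        base_fused()  # train first so single-modality variants reuse its branches
    for variant in variants:
        if variant == "fused":
            pipe = base_fused()
        elif variant == "video_only":
            if "video" not in cache:
                if "fused" in cache:
                    pipe = make("video")
                    pipe.video = cache["fused"].video
                else:
                    pipe = make("video").fit(dataset)
                cache["video"] = pipe
            pipe = cache["video"]
            pipe.modality = "video"
        elif variant == "audio_only":
            if "audio" not in cache:
                if "fused" in cache:
                    pipe = make("audio")
                    pipe.audio = cache["fused"].audio
                else:
                    pipe = make("audio").fit(dataset)
                cache["audio"] = pipe
            pipe = cache["audio"]
            pipe.modality = "audio"
        elif variant == "no_tsam":
            pipe = make("video")
            pipe.video = TSNetClassifier(**{**pipe.video.get_params(),
                                            "use_tsam": False})
            pipe.fit(dataset)
        elif variant in ("gcn_only", "lstm_only"):
            pipe = make("audio")
            pipe.audio = GCNLSTMClassifier(**{**pipe.audio.get_params(),
                                              "variant": variant})
            pipe.fit(dataset)
        reports[variant] = pipe.evaluate(dataset, split=eval_split)

    table = pd.DataFrame(
        [{"model": v, "F1": r.f1, "RMSE": r.rmse, "MAE": r.mae}
         for v, r in reports.items()]
    )
    return table, reports


def grouped_eval(scores: np.ndarray, labels: np.ndarray,
                 groups: np.ndarray, phq8_pred: np.ndarray | None = None,
                 phq8_true: np.ndarray | None = None,
                 threshold: float = 0.5) -> dict[str, EvalReport]:
    """Per-group metrics plus the mixed (union) group.

    Empty groups are omitted; the mixed report is always present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    out: dict[str, EvalReport] = {}
    for g in sorted(set(groups.tolist())):
        mask = groups == g
        if not mask.any():
            continue
        out[str(g)] = compute_metrics(
            scores[mask], labels[mask],
            phq8_pred=None if phq8_pred is None else np.asarray(phq8_pred)[mask],
            phq8_true=None if phq8_true is None else np.asarray(phq8_true)[mask],
            threshold=threshold, group=str(g))
    out["mixed"] = compute_metrics(scores, labels, phq8_pred=phq8_pred,
                                   phq8_true=phq8_true, threshold=threshold,
                                   group="mixed")
    return out
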