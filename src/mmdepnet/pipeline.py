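"""End-to-end orchestration: corpus → features → branch nets → fusion.

``featurize_corpus`` loads a generated (or compatible) corpus from disk and
produces the two modality inputs: clip arrays for the video branch and
MFCC similarity graphs for the audio branch.  ``MultimodalDepressionPipeline``
then trains the branches on the training split and the fusion network on
their frozen features (staged training: branch learning rate 1e-4, fusion
5e-5).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .audio_features import MfccConfig, build_graph, compute_mfcc
from .audio_net import GCNLSTMClassifier, GcnLstmConfig, GcnLstmModel
from .fusion import VAFNClassifier, VafnConfig, VafnModel
from .io import config_hash, load_checkpoint, save_checkpoint
from .metrics import EvalReport, compute_metrics
from .synthetic import load_audio, load_clip, load_manifest
from .training import LR_BRANCH, LR_FUSION
from .visual import TSNetClassifier, TsnetConfig, TsnetModel

__all__ = ["FeaturizeConfig", "featurize_corpus", "MultimodalDepressionPipeline"]


@dataclass(frozen=True)
class FeaturizeConfig:
    mfcc: MfccConfig = field(default_factory=MfccConfig)
    graph_threshold: float = 0.5
    threshold_on: str = "similarity"
    weight_cap: float = 1e6
    frame_stride: int = 4              # decimate MFCC frames before graph building
    node_scaling: str = "unit_distance"  # none | zscore | unit_distance


def featurize_corpus(corpus_dir: str | Path, cfg: FeaturizeConfig | None = None) -> dict:
    """Load a corpus directory into in-memory modality inputs.

    Returns a dataset dict with keys ``manifest``, ``clips`` (n, T, H, W, C),
    ``graphs`` (list of AudioGraph), ``labels``, ``phq8``, ``sex``, ``split``.

    ``node_scaling`` controls the feature scale the edge threshold sees:
    ``zscore`` standardises coefficients within each clip; ``unit_distance``
    additionally divides by sqrt(2·n_mfcc) so two uncorrelated frames sit at
    distance ≈ 1 — the similarity cutoff then connects frame pairs that are
    more alike than chance, and monotonous (low-variability) speech yields
    denser graphs.
    """
    cfg = cfg or FeaturizeConfig()
    if cfg.node_scaling not in ("none", "zscore", "unit_distance"):
        raise ValueError(f"unknown node_scaling {cfg.node_scaling!r}")
    corpus = Path(corpus_dir)
    manifest = load_manifest(corpus / "manifest.csv")
    clips, graphs = [], []
    for _, row in manifest.iterrows():
        clips.append(load_clip(corpus / row["video_path"]))
        wave, sr = load_audio(corpus / row["audio_path"])
        mfcc = compute_mfcc(wave, sr, cfg.mfcc)
        scaled = mfcc
        if cfg.node_scaling != "none":
            vals = mfcc.values
            vals = (vals - vals.mean(axis=0)) / (vals.std(axis=0) + 1e-8)
            if cfg.node_scaling == "unit_distance":
                vals = vals / np.sqrt(2.0 * vals.shape[1])
            scaled = type(mfcc)(values=vals, frame_times=mfcc.frame_times)
        graph = build_graph(scaled, threshold=cfg.graph_threshold,
                            weight_cap=cfg.weight_cap,
                            threshold_on=cfg.threshold_on,
                            stride=cfg.frame_stride)
        # edges come from scale-free distances; node attributes keep the
        # absolute cepstra (the mean-pitch signal lives in those)
        graph.node_features = mfcc.values[::cfg.frame_stride]
        graphs.append(graph)
    return {
        "manifest": manifest,
        "clips": np.stack(clips),
        "graphs": graphs,
        "labels": manifest["label"].to_numpy(int),
        "phq8": manifest["phq8"].to_numpy(float),
        "sex": manifest["sex"].to_numpy(str),
        "split": manifest["split"].to_numpy(str),
    }


def _subset(dataset: dict, mask: np.ndarray) -> dict:
    idx = np.flatnonzero(mask)
    return {
        "manifest": dataset["manifest"].iloc[idx],
        "clips": dataset["clips"][idx],
        "graphs": [dataset["graphs"][i] for i in idx],
        "labels": dataset["labels"][idx],
        "phq8": dataset["phq8"][idx],
        "sex": dataset["sex"][idx],
        "split": dataset["split"][idx],
    }


class MultimodalDepressionPipeline:
    """Staged trainer/evaluator for the three-network system.

    ``modality`` selects what is trained: "video", "audio" or "fused"
    (fused trains both branches, then the fusion net on their features).
    Estimator instances may be injected; otherwise desk-scale defaults are
    built from ``seed``.
    """

    def __init__(self, modality: str = "fused", video: TSNetClassifier | None = None,
                 audio: GCNLSTMClassifier | None = None,
                 fusion: VAFNClassifier | None = None, seed: int = 0,
                 video_iterations: int = 500, audio_iterations: int = 400,
                 fusion_iterations: int = 300):
        if modality not in ("video", "audio", "fused"):
            raise ValueError(f"modality must be video/audio/fused, got {modality!r}")
        self.modality = modality
        self.seed = seed
        self.video = video if video is not None else TSNetClassifier(
            depth="tsnet32", base_channels=4, attention_reduction=4,
            feature_dim=32, lr=LR_BRANCH, iterations=video_iterations,
            batch_size=8, seed=seed)
        self.audio = audio if audio is not None else GCNLSTMClassifier(
            gcn_hidden=16, lstm_hidden=32, feature_dim=24, subsample=1,
            lr=LR_BRANCH, iterations=audio_iterations, batch_size=8, seed=seed + 1)
        self.fusion = fusion if fusion is not None else VAFNClassifier(
            pool_window=4, lr=LR_FUSION, iterations=fusion_iterations,
            batch_size=16, seed=seed + 2)

    # -- training ------------------------------------------------------------
    def fit(self, dataset: dict, split: str = "train", skip_fitted: bool = False):
        """Staged training on one split; ``skip_fitted`` reuses already
        fitted branch estimators (e.g. restored from checkpoints)."""
        train = _subset(dataset, dataset["split"] == split)
        y = np.column_stack([train["labels"], train["phq8"]])
        if self.modality in ("video", "fused"):
            if not (skip_fitted and hasattr(self.video, "model_")):
                self.video.fit(train["clips"], y)
        if self.modality in ("audio", "fused"):
            if not (skip_fitted and hasattr(self.audio, "model_")):
                self.audio.fit(train["graphs"], y)
        if self.modality == "fused":
            f_v = self.video.transform(train["clips"])
            f_a = self.audio.transform(train["graphs"])
            self.fusion.fit((f_v, f_a), y)
        return self

    # -- inference -----------------------------------------------------------
    def _head(self):
        return {"video": self.video, "audio": self.audio, "fused": self.fusion}[self.modality]

    def decision_function(self, dataset: dict) -> np.ndarray:
        if self.modality == "video":
            return self.video.decision_function(dataset["clips"])
        if self.modality == "audio":
            return self.audio.decision_function(dataset["graphs"])
        return self.fusion.decision_function(self._fusion_inputs(dataset))

    def predict_severity(self, dataset: dict) -> np.ndarray:
        if self.modality == "video":
            return self.video.predict_severity(dataset["clips"])
        if self.modality == "audio":
            return self.audio.predict_severity(dataset["graphs"])
        return self.fusion.predict_severity(self._fusion_inputs(dataset))

    def _fusion_inputs(self, dataset: dict):
        return (self.video.transform(dataset["clips"]),
                self.audio.transform(dataset["graphs"]))

    # -- evaluation ----------------------------------------------------------
    def evaluate(self, dataset: dict, split: str | None = "val",
                 group: str | None = None) -> EvalReport:
        sub = dataset if split is None else _subset(dataset, dataset["split"] == split)
        if group is not None:
            sub = _subset(sub, sub["sex"] == group)
        logits = self.decision_function(sub)
        scores = 1.0 / (1.0 + np.exp(-logits))
        phq8_pred = self.predict_severity(sub)
        return compute_metrics(scores, sub["labels"], phq8_pred=phq8_pred,
                               phq8_true=sub["phq8"], group=group)

    # -- persistence ---------------------------------------------------------
    _AUX = {
        "video": ("pixel_mean_", "pixel_scale_", "phq8_mean_", "phq8_scale_"),
        "audio": ("feature_mean_", "feature_scale_", "phq8_mean_", "phq8_scale_"),
        "fusion": ("video_mean_", "video_scale_", "audio_mean_", "audio_scale_",
                   "phq8_mean_", "phq8_scale_"),
    }
    _MODEL_CLS = {
        "video": (TsnetModel, TsnetConfig),
        "audio": (GcnLstmModel, GcnLstmConfig),
        "fusion": (VafnModel, VafnConfig),
    }

    def save(self, path) -> str:
        """Single-file checkpoint of all fitted estimators; returns config hash.

        The stored configuration embeds every branch's network config, so the
        overall hash pins the branch configurations a fused checkpoint was
        built from; mismatched reloads are refused.
        """
        state: dict = {}
        config: dict = {"modality": self.modality, "seed": self.seed}
        for name in ("video", "audio", "fusion"):
            est = getattr(self, name)
            if not hasattr(est, "model_"):
                continue
            for k, v in est.model_.state_dict().items():
                state[f"{name}/{k}"] = v
            for aux in self._AUX[name]:
                state[f"{name}.aux.{aux}"] = np.asarray(getattr(est, aux))
            config[name] = {"params": est.get_params(), "net": asdict(est.config_)}
            config[name]["hash"] = config_hash(config[name]["net"])
        return save_checkpoint(path, state, config)

    @classmethod
    def load(cls, path, expect_hash: str | None = None) -> "MultimodalDepressionPipeline":
        state, meta = load_checkpoint(path, expect_hash=expect_hash)
        config = meta["config"]
        pipe = cls(modality=config["modality"], seed=int(config["seed"]))
        for name in ("video", "audio", "fusion"):
            if name not in config:
                continue
            est = getattr(pipe, name)
            params = config[name]["params"]
            est.set_params(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in params.items()})
            model_cls, cfg_cls = cls._MODEL_CLS[name]
            net_cfg = cfg_cls(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in config[name]["net"].items()})
            rng = np.random.default_rng(0)  # weights replaced by the checkpoint
            est.config_ = net_cfg
            est.model_ = model_cls(net_cfg, rng)
            est.model_.load_state_dict(
                {k[len(name) + 1:]: v for k, v in state.items()
                 if k.startswith(f"{name}/")})
            est.model_.eval()
            for aux in cls._AUX[name]:
                arr = state[f"{name}.aux.{aux}"]
                setattr(est, aux, float(arr) if arr.ndim == 0 else arr)
            est.classes_ = np.array([0, 1])
        return pipe
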