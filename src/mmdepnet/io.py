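"""Checkpoint archives: single-file ``.npz`` with parameters + config hash.

The configuration dictionary is serialised to canonical JSON and its
SHA-256 digest stored alongside the weights; loading verifies the digest,
and fused checkpoints can carry the branch config hashes to refuse
mismatched reloads.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

__all__ = ["config_hash", "save_checkpoint", "load_checkpoint"]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def save_checkpoint(path: str | Path, state: dict, config: dict,
                    extra: dict | None = None) -> str:
    """Write weights + config (+ optional metadata); returns the config hash."""
    digest = config_hash(config)
    meta = {"config": config, "config_hash": digest, "extra": extra or {}}
    arrays = {f"param::{k}": np.asarray(v) for k, v in state.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, default=str).encode("utf-8"), dtype=np.uint8)
    with open(Path(path), "wb") as fh:
        np.savez_compressed(fh, **arrays)
    return digest


def load_checkpoint(path: str | Path, expect_hash: str | None = None) -> tuple[dict, dict]:
    """Return (state dict, metadata); verifies the stored config hash."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode("utf-8"))
        state = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    stored = meta.get("config_hash")
    if stored != config_hash(meta.get("config", {})):
        raise ValueError(f"checkpoint {path}: config hash mismatch (corrupt or edited)")
    if expect_hash is not None and stored != expect_hash:
        raise ValueError(
            f"checkpoint {path}: config hash {stored[:12]}… does not match the "
            f"expected {expect_hash[:12]}…")
    return state, meta
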