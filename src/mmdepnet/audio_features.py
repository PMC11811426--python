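"""MFCC extraction and the frame-similarity audio graph.

The cepstral pipeline runs in the classical order — pre-emphasis, framing,
windowing, FFT, power spectrum, Mel filterbank, log, DCT-II — with the
usual speech-processing defaults (25 ms frames, 10 ms hop, Hamming window,
26 HTK-mel triangular filters, 13 coefficients).

Each MFCC frame then becomes a node of an undirected graph.  Similarity
between two frames is ``s = 1 / (1 + d)`` with ``d`` the Euclidean distance
between their coefficient vectors; an edge is added when ``s >= 0.5``
(equivalently ``d <= 1``), and carries weight ``1/d`` capped for coincident
frames.  A distance-thresholded reading is available via
``threshold_on="distance"`` since "threshold of 0.5" is ambiguous between
the two conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.fft import dct, rfft
from scipy.signal import get_window
from scipy.spatial.distance import pdist

__all__ = [
    "MfccConfig", "MfccMatrix", "AudioGraph", "pre_emphasize", "mel_filterbank",
    "compute_mfcc", "frame_similarity", "build_graph", "save_graph", "load_graph",
]


@dataclass(frozen=True)
class MfccConfig:
    pre_emphasis: float = 0.97
    frame_length: float = 0.025   # seconds
    hop_length: float = 0.010     # seconds
    window: str = "hamming"
    n_fft: int | None = None      # default: next power of two >= frame samples
    n_mels: int = 26
    n_mfcc: int = 13
    log_floor: float = 1e-10

    def validate(self) -> None:
        if not 0.0 <= self.pre_emphasis < 1.0:
            raise ValueError(f"pre_emphasis must be in [0, 1), got {self.pre_emphasis}")
        if self.frame_length < self.hop_length:
            raise ValueError("frame_length must be >= hop_length")
        if self.window not in ("hamming", "hann"):
            raise ValueError(f"window must be hamming or hann, got {self.window!r}")
        if self.n_mfcc > self.n_mels:
            raise ValueError("n_mfcc must not exceed n_mels")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")

    def fft_size(self, sr: int) -> int:
        n_frame = int(round(self.frame_length * sr))
        if self.n_fft is not None:
            if self.n_fft < n_frame:
                raise ValueError("n_fft must be at least the frame length in samples")
            return self.n_fft
        return int(2 ** np.ceil(np.log2(n_frame)))


@dataclass(frozen=True)
class MfccMatrix:
    """Per-frame cepstral vectors (n_frames, n_mfcc) with frame-centre times."""

    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("values must be a non-empty (n_frames, n_mfcc) matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MFCC values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def pre_emphasize(x: np.ndarray, coef: float) -> np.ndarray:
    """y[n] = x[n] - coef * x[n-1], with y[0] = x[0]; linear in x."""
    x = np.asarray(x, dtype=np.float64)
    y = x.copy()
    y[1:] -= coef * x[:-1]
    return y


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sr: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular unit-height HTK-mel filters, shape (n_mels, n_fft//2 + 1)."""
    fmax = sr / 2.0
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sr).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for m in range(1, n_mels + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, ctr):
            if ctr > lo:
                fb[m - 1, k] = (k - lo) / (ctr - lo)
        for k in range(ctr, hi):
            if hi > ctr:
                fb[m - 1, k] = (hi - k) / (hi - ctr)
    return fb


def compute_mfcc(waveform: np.ndarray, sr: int, cfg: MfccConfig | None = None) -> MfccMatrix:
    """Run the cepstral pipeline on a mono waveform.

    Steps, in order: pre-emphasis -> framing -> windowing -> FFT -> power
    spectrum -> Mel filterbank -> log (floored at ``log_floor``) -> DCT-II
    (orthonormal), keeping the first ``n_mfcc`` coefficients.
    """
    cfg = cfg or MfccConfig()
    cfg.validate()
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    n_frame = int(round(cfg.frame_length * sr))
    n_hop = int(round(cfg.hop_length * sr))
    if x.size < n_frame:
        raise ValueError(f"waveform ({x.size} samples) shorter than one frame ({n_frame})")

    emphasized = pre_emphasize(x, cfg.pre_emphasis)
    n_frames = 1 + (x.size - n_frame) // n_hop
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = emphasized[idx]
    win = get_window(cfg.window, n_frame, fftbins=False)
    frames = frames * win

    n_fft = cfg.fft_size(sr)
    spectrum = rfft(frames, n=n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    fb = mel_filterbank(sr, n_fft, cfg.n_mels)
    energies = power @ fb.T
    log_e = np.log(np.maximum(energies, cfg.log_floor))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, :cfg.n_mfcc]

    times = (n_hop * np.arange(n_frames) + 0.5 * n_frame) / sr
    return MfccMatrix(values=coeffs.astype(np.float64), frame_times=times)


def frame_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Similarity s = 1 / (1 + ||a - b||): 1 iff identical, decreasing in distance."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("vectors must be finite")
    return float(1.0 / (1.0 + np.linalg.norm(a - b)))


@dataclass
class AudioGraph:
    """Weighted undirected graph over MFCC frames, in temporal node order.

    ``edges`` holds pairs (i, j) with i < j; ``node_order`` maps row index
    to temporal position (identity after construction, preserved through
    relabelings by callers).
    """

    node_features: np.ndarray
    edges: list[tuple[int, int]]
    edge_weights: np.ndarray
    node_order: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edge_weights = np.asarray(self.edge_weights, dtype=np.float64)
        if len(self.edges) != self.edge_weights.size:
            raise ValueError("edges and edge_weights length mismatch")
        for (i, j), w in zip(self.edges, self.edge_weights):
            if i == j:
                raise ValueError(f"self-edge at node {i}")
            if not (0 < w < np.inf):
                raise ValueError(f"edge weight must be positive and finite, got {w}")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency (no self-loops)."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in zip(self.edges, self.edge_weights):
            a[i, j] = a[j, i] = w
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n_nodes):
            g.add_node(i, order=int(self.node_order[i]))
        for (i, j), w in zip(self.edges, self.edge_weights):
            g.add_edge(i, j, weight=float(w))
        return g


def build_graph(mfcc: MfccMatrix, threshold: float = 0.5, weight_cap: float = 1e6,
                threshold_on: str = "similarity", stride: int = 1) -> AudioGraph:
    """Thresholded similarity graph over (optionally strided) MFCC frames.

    With ``threshold_on="similarity"`` an edge joins frames i, j whenever
    ``1/(1+d_ij) >= threshold`` (the default 0.5 means d <= 1); with
    ``"distance"`` the rule is ``d_ij <= threshold`` directly.  Edge weight
    is the inverse distance ``1/d``, capped at ``weight_cap`` so coincident
    frames stay finite.
    """
    if threshold_on not in ("similarity", "distance"):
        raise ValueError(f"threshold_on must be similarity or distance, got {threshold_on!r}")
    if threshold_on == "similarity" and not 0.0 < threshold <= 1.0:
        raise ValueError(f"similarity threshold must be in (0, 1], got {threshold}")
    if threshold_on == "distance" and threshold <= 0:
        raise ValueError(f"distance threshold must be positive, got {threshold}")
    if weight_cap <= 0:
        raise ValueError("weight_cap must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    feats = mfcc.values[::stride]
    times = mfcc.frame_times[::stride] if mfcc.frame_times is not None else None
    n = feats.shape[0]
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    if n > 1:
        d = pdist(feats)
        k = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                dij = d[k]
                k += 1
                keep = (1.0 / (1.0 + dij) >= threshold) if threshold_on == "similarity" \
                    else (dij <= threshold)
                if keep:
                    edges.append((i, j))
                    weights.append(min(1.0 / dij, weight_cap) if dij > 0 else weight_cap)
    return AudioGraph(
        node_features=feats, edges=edges, edge_weights=np.asarray(weights),
        node_order=np.arange(n), frame_times=times,
    )


# ---------------------------------------------------------------------------
# portable text round-trip: edge list + node-feature table
# ---------------------------------------------------------------------------

def save_graph(graph: AudioGraph, edge_path: str | Path, node_path: str | Path) -> None:
    """Write ``node_i node_j weight`` edge lines and a TSV of node features."""
    with open(edge_path, "w") as fh:
        for (i, j), w in zip(graph.edges, graph.edge_weights):
            fh.write(f"{i} {j} {float(w)!r}\n")
    header = "order\t" + "\t".join(f"c{k}" for k in range(graph.node_features.shape[1]))
    rows = np.column_stack([graph.node_order, graph.node_features])
    np.savetxt(node_path, rows, delimiter="\t", header=header, comments="")


def load_graph(edge_path: str | Path, node_path: str | Path) -> AudioGraph:
    table = np.loadtxt(node_path, delimiter="\t", skiprows=1, ndmin=2)
    node_order = table[:, 0].astype(int)
    feats = table[:, 1:]
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    text = Path(edge_path).read_text().strip()
    if text:
        for line in text.splitlines():
            si, sj, sw = line.split()
            edges.append((int(si), int(sj)))
            weights.append(float(sw))
    return AudioGraph(node_features=feats, edges=edges,
                      edge_weights=np.asarray(weights), node_order=node_order)
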