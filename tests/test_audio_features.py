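"""MFCC pipeline and audio-graph construction.

``naive_mfcc`` is an independent re-derivation of the cepstral pipeline:
explicit O(N²) DFT, triangular Mel filters built point by point, and the
orthonormal DCT-II written out as its defining sum.  Agreement with the
package implementation is required to 1e-6 per coefficient.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmdepnet.audio_features import (AudioGraph, MfccConfig, MfccMatrix,
                                     build_graph, compute_mfcc, frame_similarity,
                                     load_graph, mel_filterbank, pre_emphasize,
                                     save_graph)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def naive_mfcc(x, sr, cfg: MfccConfig):
    x = np.asarray(x, dtype=np.float64)
    n_frame = int(round(cfg.frame_length * sr))
    n_hop = int(round(cfg.hop_length * sr))
    n_fft = cfg.fft_size(sr)
    n_bins = n_fft // 2 + 1

    # pre-emphasis
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, x.size):
        y[i] = x[i] - cfg.pre_emphasis * x[i - 1]

    # symmetric window, written out
    n = np.arange(n_frame)
    if cfg.window == "hamming":
        win = 0.54 - 0.46 * np.cos(2 * np.pi * n / (n_frame - 1))
    else:
        win = 0.5 - 0.5 * np.cos(2 * np.pi * n / (n_frame - 1))

    # explicit DFT matrix for the first n_bins frequencies
    k = np.arange(n_bins)[:, None]
    t = np.arange(n_fft)[None, :]
    cos_m = np.cos(-2 * np.pi * k * t / n_fft)
    sin_m = np.sin(-2 * np.pi * k * t / n_fft)

    # triangular filters from the HTK mel scale, point by point
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    pts = imel(np.linspace(mel(0.0), mel(sr / 2.0), cfg.n_mels + 2))
    bins = np.floor((n_fft + 1) * pts / sr).astype(int)
    fb = np.zeros((cfg.n_mels, n_bins))
    for m in range(cfg.n_mels):
        for kk in range(bins[m], bins[m + 1]):
            fb[m, kk] = (kk - bins[m]) / max(bins[m + 1] - bins[m], 1)
        for kk in range(bins[m + 1], bins[m + 2]):
            fb[m, kk] = (bins[m + 2] - kk) / max(bins[m + 2] - bins[m + 1], 1)

    n_frames = 1 + (x.size - n_frame) // n_hop
    out = np.zeros((n_frames, cfg.n_mfcc))
    mm = cfg.n_mels
    for fi in range(n_frames):
        frame = np.zeros(n_fft)
        frame[:n_frame] = y[fi * n_hop: fi * n_hop + n_frame] * win
        re = cos_m @ frame
        im = sin_m @ frame
        power = re**2 + im**2
        energies = fb @ power
        log_e = np.log(np.maximum(energies, cfg.log_floor))
        for c in range(cfg.n_mfcc):
            scale = np.sqrt(1.0 / mm) if c == 0 else np.sqrt(2.0 / mm)
            out[fi, c] = scale * np.sum(
                log_e * np.cos(np.pi * c * (2 * np.arange(mm) + 1) / (2 * mm)))
    return out


# ---------------------------------------------------------------------------
# MFCC pipeline
# ---------------------------------------------------------------------------

def test_pre_emphasis_of_constant_signal():
    y = pre_emphasize(np.ones(5), 0.97)
    np.testing.assert_allclose(y, [1.0, 0.03, 0.03, 0.03, 0.03], atol=1e-12)


@given(st.floats(0.5, 2.0), st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_pre_emphasis_is_linear(alpha, seed):
    x = np.random.default_rng(seed).normal(size=64)
    np.testing.assert_allclose(pre_emphasize(alpha * x, 0.97),
                               alpha * pre_emphasize(x, 0.97), atol=1e-9)


def test_all_zero_waveform_gives_floor_cepstrum():
    cfg = MfccConfig()
    sr = 8000
    mfcc = compute_mfcc(np.zeros(sr // 2), sr, cfg)
    # every filter energy hits the floor: c0 = DCT of a constant log vector,
    # higher coefficients vanish
    expected_c0 = np.sqrt(cfg.n_mels) * np.log(cfg.log_floor)
    np.testing.assert_allclose(mfcc.values[:, 0], expected_c0, rtol=1e-9)
    np.testing.assert_allclose(mfcc.values[:, 1:], 0.0, atol=1e-9)


def test_mfcc_matches_bruteforce_oracle_on_sine():
    sr = 16000
    t = np.arange(sr) / sr
    wave = np.sin(2 * np.pi * 440.0 * t)
    cfg = MfccConfig()
    ours = compute_mfcc(wave, sr, cfg).values
    ref = naive_mfcc(wave, sr, cfg)
    assert np.abs(ours - ref).max() < 1e-6


def test_mfcc_matches_bruteforce_oracle_on_random_signals():
    sr = 4000  # keep the O(N^2) oracle cheap
    cfg = MfccConfig()
    rng = np.random.default_rng(7)
    for _ in range(10):
        wave = rng.normal(size=sr // 4)
        ours = compute_mfcc(wave, sr, cfg).values
        ref = naive_mfcc(wave, sr, cfg)
        assert np.abs(ours - ref).max() < 1e-6


def test_mfcc_rejects_short_and_invalid_input():
    with pytest.raises(ValueError):
        compute_mfcc(np.zeros(10), 16000, MfccConfig())
    with pytest.raises(ValueError):
        compute_mfcc(np.zeros((100, 2)), 16000, MfccConfig())
    with pytest.raises(ValueError):
        MfccConfig(n_mfcc=30, n_mels=26).validate()
    with pytest.raises(ValueError):
        MfccConfig(frame_length=0.005, hop_length=0.010).validate()
    with pytest.raises(ValueError):
        MfccConfig(pre_emphasis=1.0).validate()


def test_filterbank_shape_and_support():
    fb = mel_filterbank(16000, 512, 26)
    assert fb.shape == (26, 257)
    assert fb.min() >= 0.0 and fb.max() <= 1.0


# ---------------------------------------------------------------------------
# similarity and graph construction
# ---------------------------------------------------------------------------

def test_frame_similarity_closed_forms():
    assert frame_similarity(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 1.0
    # distance 1 sits exactly at the 0.5 edge threshold
    assert frame_similarity(np.zeros(1), np.ones(1)) == pytest.approx(0.5)
    assert frame_similarity(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == pytest.approx(1 / 6)


def test_frame_similarity_rejects_mismatch():
    with pytest.raises(ValueError):
        frame_similarity(np.zeros(2), np.zeros(3))


def _matrix_from_points(points):
    points = np.asarray(points, dtype=float)
    return MfccMatrix(values=points, frame_times=np.arange(len(points), dtype=float))


def test_graph_single_frame_has_no_edges():
    g = build_graph(_matrix_from_points([[0.0, 0.0]]))
    assert g.n_nodes == 1 and g.edges == []


def test_graph_three_nodes_hand_enumerated():
    # pairwise distances: d01 = 0.5, d02 = 2.0, d12 = 1.5
    g = build_graph(_matrix_from_points([[0.0], [0.5], [2.0]]))
    assert g.edges == [(0, 1)]
    np.testing.assert_allclose(g.edge_weights, [2.0])


def test_graph_weight_cap_for_identical_frames():
    g = build_graph(_matrix_from_points([[1.0, 1.0], [1.0, 1.0]]), weight_cap=1e6)
    assert g.edges == [(0, 1)]
    np.testing.assert_allclose(g.edge_weights, [1e6])


def test_graph_distance_threshold_semantics():
    pts = [[0.0], [1.5], [3.2]]  # d01 = 1.5, d12 = 1.7, d02 = 3.2
    g_sim = build_graph(_matrix_from_points(pts), threshold=0.5,
                        threshold_on="similarity")
    assert g_sim.edges == []  # all distances exceed 1
    g_dist = build_graph(_matrix_from_points(pts), threshold=2.0,
                         threshold_on="distance")
    assert g_dist.edges == [(0, 1), (1, 2)]


def test_graph_threshold_monotonicity():
    rng = np.random.default_rng(11)
    pts = rng.normal(scale=0.7, size=(12, 3))
    edges_prev = None
    for thr in (0.3, 0.5, 0.7, 0.9):
        edges = set(build_graph(_matrix_from_points(pts), threshold=thr).edges)
        if edges_prev is not None:
            assert edges.issubset(edges_prev)
        edges_prev = edges


def test_graph_adjacency_symmetric_with_positive_weights():
    rng = np.random.default_rng(13)
    g = build_graph(_matrix_from_points(rng.normal(scale=0.5, size=(10, 2))))
    a = g.adjacency()
    np.testing.assert_array_equal(a, a.T)
    assert np.all(np.diag(a) == 0)
    assert np.all(g.edge_weights > 0)


def test_graph_invalid_threshold_raises():
    m = _matrix_from_points([[0.0], [1.0]])
    with pytest.raises(ValueError):
        build_graph(m, threshold=0.0)
    with pytest.raises(ValueError):
        build_graph(m, threshold=1.5)
    with pytest.raises(ValueError):
        build_graph(m, threshold=-1.0, threshold_on="distance")


def test_graph_text_roundtrip(tmp_path):
    rng = np.random.default_rng(17)
    g = build_graph(_matrix_from_points(rng.normal(scale=0.5, size=(8, 3))))
    save_graph(g, tmp_path / "edges.txt", tmp_path / "nodes.tsv")
    g2 = load_graph(tmp_path / "edges.txt", tmp_path / "nodes.tsv")
    assert g2.edges == g.edges
    np.testing.assert_allclose(g2.edge_weights, g.edge_weights)
    np.testing.assert_allclose(g2.node_features, g.node_features)
    np.testing.assert_array_equal(g2.node_order, g.node_order)


def test_audiograph_rejects_self_edges_and_bad_weights():
    feats = np.zeros((3, 2))
    with pytest.raises(ValueError):
        AudioGraph(node_features=feats, edges=[(1, 1)], edge_weights=np.array([1.0]),
                   node_order=np.arange(3))
    with pytest.raises(ValueError):
        AudioGraph(node_features=feats, edges=[(0, 1)], edge_weights=np.array([0.0]),
                   node_order=np.arange(3))
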