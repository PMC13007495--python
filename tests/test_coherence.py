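"""Phase-locking values, spatial coherence, adjacency thresholding and
graph metrics, checked against exact brute-force oracles."""

import math
import warnings
from itertools import combinations

import numpy as np
import pytest

from proteodyn.coherence import (
    CoherenceError,
    clustering_coefficient,
    edge_fraction,
    global_efficiency,
    instantaneous_phase,
    plv_matrix,
    plv_pair,
    spatial_coherence,
    threshold_adjacency,
    threshold_robustness,
    windowed_network_metrics,
)
from proteodyn.recording import Recording, make_windows
from proteodyn.synthetic import SyntheticSpec, block_coupling, gen_coupled_network


# ------------------------------------------------------------------ oracles

def bfs_oracle(adj):
    """All-pairs shortest paths by explicit breadth-first traversal."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    for src in range(n):
        d[src, src] = 0
        frontier = [src]
        depth = 0
        seen = {src}
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and v not in seen:
                        seen.add(v)
                        d[src, v] = depth
                        nxt.append(v)
            frontier = nxt
    return d


def eglob_oracle(adj):
    d = bfs_oracle(adj)
    n = adj.shape[0]
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def clustering_oracle(adj):
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        t = sum(adj[a, b] for a, b in combinations(nbrs, 2))
        cs.append(2.0 * t / (k * (k - 1)))
    return float(np.mean(cs)), np.array(cs)


def random_graph(rng, n):
    a = np.zeros((n, n), dtype=int)
    iu = np.triu_indices(n, 1)
    a[iu] = rng.integers(0, 2, len(iu[0]))
    return a + a.T


# ------------------------------------------------------------------- phases

def test_tone_phase_slope():
    fs, f0 = 10.0, 0.01
    t = np.arange(int(400 / f0 * fs)) / fs
    rec = Recording(voltages=np.sin(2 * np.pi * f0 * t)[None, :], sampling_rate=fs)
    ph = np.unwrap(instantaneous_phase(rec).phases[0])
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    slope = np.polyfit(t[mid], ph[mid], 1)[0]
    assert slope == pytest.approx(2 * np.pi * f0, rel=0.01)


def test_quadrature_pair_offset():
    t = np.arange(20_000) / 100.0
    rec = Recording(
        voltages=np.vstack(
            [np.sin(2 * np.pi * 0.5 * t), np.cos(2 * np.pi * 0.5 * t)]
        ),
        sampling_rate=100.0,
    )
    ph = instantaneous_phase(rec).phases
    d = np.angle(np.exp(1j * (ph[1] - ph[0])))
    inner = slice(1000, -1000)
    assert np.median(d[inner]) == pytest.approx(np.pi / 2, abs=0.01)


def test_am_tone_phase_unchanged():
    fs = 100.0
    t = np.arange(60_000) / fs
    carrier = np.sin(2 * np.pi * 1.0 * t)
    am = (1.0 + 0.5 * np.sin(2 * np.pi * 0.01 * t)) * carrier
    rec = Recording(voltages=np.vstack([carrier, am]), sampling_rate=fs)
    ph = instantaneous_phase(rec).phases
    inner = slice(5000, -5000)
    diff = np.angle(np.exp(1j * (ph[0] - ph[1])))[inner]
    assert np.max(np.abs(diff)) < 0.05


def test_constant_channel_rejected():
    rec = Recording(voltages=np.ones((1, 100)), sampling_rate=1.0)
    with pytest.raises(CoherenceError):
        instantaneous_phase(rec)


# ---------------------------------------------------------------------- PLV

def test_plv_identical_and_offset():
    ph = np.random.default_rng(0).uniform(-np.pi, np.pi, 1000)
    assert plv_pair(ph, ph) == pytest.approx(1.0)
    assert plv_pair(ph, ph + np.pi / 4) == pytest.approx(1.0)


def test_plv_common_phase_invariance(rng):
    a = rng.uniform(-np.pi, np.pi, 500)
    b = rng.uniform(-np.pi, np.pi, 500)
    common = rng.uniform(-np.pi, np.pi, 500)
    assert plv_pair(a, b) == pytest.approx(plv_pair(a + common, b + common))


def test_plv_null_rayleigh_scaling():
    """Independent phases: E[PLV] ~ sqrt(pi)/2 * T^(-1/2) at T = 1000."""
    T = 1000
    vals = [
        plv_pair(
            np.random.default_rng(2 * s).uniform(-np.pi, np.pi, T),
            np.random.default_rng(2 * s + 1).uniform(-np.pi, np.pi, T),
        )
        for s in range(200)
    ]
    expected = math.sqrt(math.pi) / 2 / math.sqrt(T)
    assert np.mean(vals) == pytest.approx(expected, rel=0.20)


def test_plv_length_mismatch():
    with pytest.raises(CoherenceError):
        plv_pair(np.zeros(10), np.zeros(11))


def test_plv_matrix_agrees_with_pairwise(rng):
    ph = rng.uniform(-np.pi, np.pi, (4, 300))
    from proteodyn.coherence import PhaseSeries

    m = plv_matrix(PhaseSeries(phases=ph))
    for i, j in combinations(range(4), 2):
        assert m[i, j] == pytest.approx(plv_pair(ph[i], ph[j]), abs=1e-12)


# -------------------------------------------------------------------- isync

def test_isync_copies_is_one():
    t = np.arange(3000) / 10.0
    x = np.sin(2 * np.pi * 0.3 * t) + 0.01 * np.random.default_rng(0).normal(size=3000)
    rec = Recording(voltages=np.tile(x, (8, 1)), sampling_rate=10.0)
    state = spatial_coherence(instantaneous_phase(rec))
    assert state.isync == pytest.approx(1.0)
    assert state.plv.shape == (8, 8)


def test_isync_independent_low(rng):
    from proteodyn.coherence import PhaseSeries

    ph = rng.uniform(-np.pi, np.pi, (8, 1000))
    assert spatial_coherence(PhaseSeries(phases=ph)).isync < 0.1


def test_isync_mixture_between(rng):
    from proteodyn.coherence import PhaseSeries

    shared = rng.uniform(-np.pi, np.pi, 1000)
    ph_sync = np.tile(shared, (8, 1))
    ph_mix = np.vstack([np.tile(shared, (4, 1)), rng.uniform(-np.pi, np.pi, (4, 1000))])
    ph_ind = rng.uniform(-np.pi, np.pi, (8, 1000))
    lo = spatial_coherence(PhaseSeries(phases=ph_ind)).isync
    mid = spatial_coherence(PhaseSeries(phases=ph_mix)).isync
    hi = spatial_coherence(PhaseSeries(phases=ph_sync)).isync
    assert lo < mid < hi


def test_isync_relabel_invariant(rng):
    from proteodyn.coherence import PhaseSeries

    ph = rng.uniform(-np.pi, np.pi, (6, 500))
    perm = rng.permutation(6)
    a = spatial_coherence(PhaseSeries(phases=ph)).isync
    b = spatial_coherence(PhaseSeries(phases=ph[perm])).isync
    assert a == pytest.approx(b)


# -------------------------------------------------------------- thresholding

def test_75th_percentile_quarter_edges(rng):
    """28 distinct PLVs at the 75th percentile -> 7 edges = 25% retention."""
    n = 8
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.permutation(np.linspace(0.1, 0.9, 28))
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    state = threshold_adjacency(m, 75.0)
    assert edge_fraction(state) == pytest.approx(0.25)
    assert state.adjacency.sum() // 2 == 7


def test_all_equal_plvs_zero_edges():
    m = np.full((4, 4), 0.5)
    np.fill_diagonal(m, 1.0)
    with pytest.warns(UserWarning):
        state = threshold_adjacency(m, 75.0)
    assert state.adjacency.sum() == 0
    assert state.degenerate_ties


def test_percentile_zero_complete_graph(rng):
    n = 5
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.permutation(np.linspace(0.2, 0.8, len(iu[0])))
    m = m + m.T
    state = threshold_adjacency(m, 0.0)
    # strict > excludes exactly the minimum value(s)
    assert state.adjacency.sum() // 2 == len(iu[0]) - 1


def test_threshold_robustness_range(rng):
    n = 8
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.uniform(0.1, 0.9, 28)
    m = m + m.T
    states = threshold_robustness(m)
    fracs = [edge_fraction(s) for s in states.values()]
    assert fracs == sorted(fracs, reverse=True)  # higher percentile, fewer edges


# ------------------------------------------------------------- graph metrics

@pytest.mark.parametrize(
    "adj,expected",
    [
        (1 - np.eye(8, dtype=int), 1.0),               # complete graph
        (np.zeros((8, 8), dtype=int), 0.0),            # empty graph
        (np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]), 5.0 / 6.0),  # path on 3
    ],
)
def test_global_efficiency_examples(adj, expected):
    assert global_efficiency(np.asarray(adj)).e_glob == pytest.approx(expected)


@pytest.mark.parametrize(
    "adj,expected",
    [
        (np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]), 1.0),          # triangle
        (np.array([[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]]), 0.0),  # star
        # triangle {0,1,2} + pendant 3-0: (1/3 + 1 + 1 + 0)/4
        (np.array([[0, 1, 1, 1], [1, 0, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]]), 7.0 / 12.0),
    ],
)
def test_clustering_examples(adj, expected):
    assert clustering_coefficient(adj).c_glob == pytest.approx(expected)


def test_graph_metrics_vs_bruteforce_oracle(rng):
    """500 random graphs on <= 8 nodes: BFS distances, efficiency and
    clustering all match exhaustive enumeration."""
    for _ in range(500):
        n = int(rng.integers(2, 9))
        a = random_graph(rng, n)
        m = global_efficiency(a)
        assert m.e_glob == pytest.approx(eglob_oracle(a))
        np.testing.assert_array_equal(m.shortest_paths, bfs_oracle(a))
        cg, ci = clustering_oracle(a)
        assert m.c_glob == pytest.approx(cg)
        np.testing.assert_allclose(m.per_node_clustering, ci)


def test_efficiency_monotone_under_edge_addition(rng):
    for _ in range(100):
        n = int(rng.integers(3, 9))
        a = random_graph(rng, n)
        e0 = global_efficiency(a).e_glob
        zeros = np.argwhere(np.triu(1 - a, 1))
        if len(zeros) == 0:
            continue
        i, j = zeros[rng.integers(len(zeros))]
        b = a.copy()
        b[i, j] = b[j, i] = 1
        assert global_efficiency(b).e_glob >= e0 - 1e-12


def test_metrics_node_permutation_invariant(rng):
    a = random_graph(rng, 7)
    p = rng.permutation(7)
    b = a[np.ix_(p, p)]
    assert global_efficiency(a).e_glob == pytest.approx(global_efficiency(b).e_glob)
    assert clustering_coefficient(a).c_glob == pytest.approx(
        clustering_coefficient(b).c_glob
    )


def test_nonsymmetric_rejected():
    a = np.array([[0, 1], [0, 0]])
    with pytest.raises(CoherenceError):
        global_efficiency(a)


# ------------------------------------------------------------ windowed layer

def test_block_structure_detected():
    """Two disconnected 4-channel diffusively coupled blocks: within-block
    PLV exceeds between-block PLV."""
    within, between = [], []
    for seed in range(5):
        k = block_coupling(8, [[0, 1, 2, 3], [4, 5, 6, 7]], 0.3)
        spec = SyntheticSpec(
            n_channels=8, sampling_rate=1.0, duration=2000.0,
            coupling=k, noise_sd=1.0, seed=seed,
        )
        rec, _ = gen_coupled_network(spec, g="leak", tau_leak=50.0)
        from proteodyn.preprocessing import highpass

        ph = instantaneous_phase(highpass(rec, 1e-3))
        m = plv_matrix(ph)
        for i, j in combinations(range(8), 2):
            same = (i < 4) == (j < 4)
            (within if same else between).append(m[i, j])
    assert np.mean(within) > np.mean(between)


def test_windowed_metrics_deterministic(small_recording):
    grid = make_windows(small_recording, 500, 250)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = windowed_network_metrics(small_recording, grid)
        b = windowed_network_metrics(small_recording, grid)
    for key in a:
        np.testing.assert_array_equal(a[key].values, b[key].values)
    assert np.all((a["I_sync"].values >= 0) & (a["I_sync"].values <= 1))
    assert np.all((a["E_glob"].values >= 0) & (a["E_glob"].values <= 1))
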