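"""Hilbert-phase functional connectivity and graph-theoretic network states.

Per analysis window: pairwise phase-locking values (PLV) across the 8
electrode channels (28 unordered pairs), their mean (the spatial coherence
index I_sync), a binary adjacency from an adaptive percentile threshold on
the PLV matrix (75th percentile by default, i.e. ~25% edge retention), and
global efficiency / mean local clustering of that graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.signal import hilbert

from .recording import Recording, WindowGrid, WindowedMetricTrace


class CoherenceError(ValueError):
    pass


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) per channel."""

    phases: np.ndarray  # (n_channels, n_samples)
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if not np.all(np.isfinite(self.phases)):
            raise CoherenceError("phases must be finite")


@dataclass
class ConnectivityState:
    """Pairwise PLV matrix, its mean (I_sync) and the thresholded adjacency."""

    plv: np.ndarray
    isync: float
    threshold: float | None = None
    adjacency: np.ndarray | None = None
    percentile: float | None = None
    degenerate_ties: bool = False


@dataclass
class NetworkMetrics:
    e_glob: float
    c_glob: float
    per_node_clustering: np.ndarray
    shortest_paths: np.ndarray


def instantaneous_phase(recording: Recording, channels: list[str] | None = None) -> PhaseSeries:
    """Phase of the analytic signal (Hilbert transform), per mV channel.

    Channels should be high-pass filtered first so the analytic-signal phase
    is meaningful; a constant channel has no defined phase and raises.
    """
    idx = (
        [recording.channel_labels.index(c) for c in channels]
        if channels is not None
        else recording.mv_channel_indices()
    )
    phases = np.empty((len(idx), recording.n_samples))
    for row, i in enumerate(idx):
        ch = recording.voltages[i]
        if np.all(ch == ch[0]):
            raise CoherenceError(
                f"channel {recording.channel_labels[i]} is constant; phase undefined"
            )
        phases[row] = np.angle(hilbert(ch))
    return PhaseSeries(
        phases=phases,
        channel_labels=tuple(recording.channel_labels[i] for i in idx),
    )


def plv_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase-locking value: modulus of the time-averaged unit phasor of the
    phase difference. 1 for a persistent phase relation, ~T^(-1/2) under
    independence."""
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise CoherenceError("phase series must have equal length")
    if phase_x.size < 2:
        raise CoherenceError("need T >= 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))


def plv_matrix(phases: PhaseSeries) -> np.ndarray:
    """Symmetric pairwise PLV matrix (diagonal 1, ignored downstream)."""
    ph = phases.phases
    n = ph.shape[0]
    # vectorized: mean phasor per channel pair
    z = np.exp(1j * ph)
    m = np.abs(z @ z.conj().T) / ph.shape[1]
    np.fill_diagonal(m, 1.0)
    return np.clip((m + m.T) / 2.0, 0.0, 1.0)


def spatial_coherence(phases: PhaseSeries) -> ConnectivityState:
    """I_sync: mean PLV across all unordered channel pairs.

    Per-pair time average -> modulus -> average across pairs, in that order,
    so the result lies in [0, 1]. For 8 channels there are C(8,2)=28 pairs.
    """
    n = phases.phases.shape[0]
    if n < 2:
        raise CoherenceError("need at least 2 channels")
    plv = plv_matrix(phases)
    iu = np.triu_indices(n, k=1)
    return ConnectivityState(plv=plv, isync=float(np.mean(plv[iu])))


def threshold_adjacency(
    plv: np.ndarray, percentile: float = 75.0
) -> ConnectivityState:
    """Binary adjacency by adaptive percentile thresholding of the PLV matrix.

    theta_w is the given percentile (linear interpolation between order
    statistics) of the off-diagonal PLVs of the current window; an edge is
    kept iff PLV > theta_w (strict), yielding ~25% edge retention at the
    default 75th percentile when values are distinct. Ties at the threshold
    are excluded and flagged, not corrected.
    """
    plv = np.asarray(plv, dtype=float)
    n = plv.shape[0]
    if n < 2 or plv.shape[0] != plv.shape[1]:
        raise CoherenceError("PLV matrix must be square with >= 2 nodes")
    iu = np.triu_indices(n, k=1)
    vals = plv[iu]
    theta = float(np.percentile(vals, percentile))
    adj = np.zeros_like(plv, dtype=int)
    adj[iu] = (vals > theta).astype(int)
    adj = adj + adj.T
    degenerate = bool(np.all(vals == vals[0]))
    if degenerate:
        warnings.warn("all PLVs equal: strict threshold retains zero edges")
    isync = float(np.mean(vals))
    return ConnectivityState(
        plv=plv,
        isync=isync,
        threshold=theta,
        adjacency=adj,
        percentile=percentile,
        degenerate_ties=degenerate,
    )


def edge_fraction(state: ConnectivityState) -> float:
    """Fraction of the C(n,2) possible edges retained after thresholding."""
    n = state.adjacency.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.sum(state.adjacency[iu]) / len(iu[0]))


def threshold_robustness(
    plv: np.ndarray, percentiles: tuple[float, ...] = (70.0, 75.0, 80.0)
) -> dict[float, ConnectivityState]:
    """Re-threshold the same PLV matrix across a percentile range (the
    70th-80th robustness check)."""
    return {p: threshold_adjacency(plv, p) for p in percentiles}


def _validate_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise CoherenceError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise CoherenceError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise CoherenceError("adjacency diagonal must be zero")
    if not np.isin(a, (0, 1)).all():
        raise CoherenceError("adjacency must be binary")
    return a.astype(int)


def shortest_path_matrix(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs BFS shortest-path lengths; inf for disconnected pairs."""
    a = _validate_adjacency(adjacency)
    g = nx.from_numpy_array(a)
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, L in lengths.items():
            d[src, dst] = L
    return d


def global_efficiency(adjacency: np.ndarray) -> NetworkMetrics:
    """Mean inverse BFS shortest-path length over ordered node pairs.

    Disconnected pairs have d = inf and contribute 1/d = 0. Returns the
    distance matrix alongside; clustering fields are filled too so one call
    yields the full per-window metric set.
    """
    a = _validate_adjacency(adjacency)
    d = shortest_path_matrix(a)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d), 0.0, np.divide(1.0, np.where(d == 0, np.inf, d)))
    e_glob = float(np.sum(inv[off]) / (n * (n - 1)))
    ci = clustering_coefficient(a).per_node_clustering
    return NetworkMetrics(
        e_glob=e_glob,
        c_glob=float(np.mean(ci)),
        per_node_clustering=ci,
        shortest_paths=d,
    )


def clustering_coefficient(adjacency: np.ndarray) -> NetworkMetrics:
    """Watts-Strogatz mean local clustering: C_i = 2 t_i / (k_i (k_i - 1)),
    averaged over all nodes, with C_i = 0 for degree < 2 by convention.
    (This is the mean local coefficient, not the transitivity ratio.)"""
    a = _validate_adjacency(adjacency)
    g = nx.from_numpy_array(a)
    ci = np.array([nx.clustering(g, i) for i in range(a.shape[0])], dtype=float)
    d = shortest_path_matrix(a)
    return NetworkMetrics(
        e_glob=float("nan"),
        c_glob=float(np.mean(ci)),
        per_node_clustering=ci,
        shortest_paths=d,
    )


def weighted_efficiency(plv: np.ndarray) -> float:
    """Weighted global efficiency on the full PLV graph with edge length
    1/W_ij (robustness companion to the binarized metric)."""
    plv = np.asarray(plv, dtype=float)
    n = plv.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in combinations(range(n), 2):
        if plv[i, j] > 0:
            g.add_edge(i, j, length=1.0 / plv[i, j])
    total = 0.0
    for src in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, src, weight="length")
        for dst, L in lengths.items():
            if dst != src and L > 0:
                total += 1.0 / L
    return total / (n * (n - 1))


def window_connectivity(
    recording: Recording, grid: WindowGrid, percentile: float = 75.0,
    window_selector: np.ndarray | None = None,
) -> list[ConnectivityState]:
    """One thresholded ConnectivityState per analysis window (independent
    graph per window)."""
    idx = recording.mv_channel_indices()
    labels = [recording.channel_labels[i] for i in idx]
    sel = (
        np.ones(grid.n_windows, dtype=bool)
        if window_selector is None
        else np.asarray(window_selector, dtype=bool)
    )
    states = []
    for sl, keep in zip(grid.slices(), sel):
        if not keep:
            continue
        sub = Recording(
            voltages=recording.voltages[idx][:, sl],
            sampling_rate=recording.sampling_rate,
            channel_labels=tuple(labels),
        )
        phases = instantaneous_phase(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            states.append(threshold_adjacency(plv_matrix(phases), percentile))
    return states


def windowed_network_metrics(
    recording: Recording,
    grid: WindowGrid,
    percentile: float = 75.0,
    window_selector: np.ndarray | None = None,
) -> dict[str, WindowedMetricTrace]:
    """I_sync, E_glob and C_glob traces over the window grid, plus the
    weighted-efficiency robustness companion."""
    sel = (
        np.ones(grid.n_windows, dtype=bool)
        if window_selector is None
        else np.asarray(window_selector, dtype=bool)
    )
    centers = grid.centers(recording.sampling_rate)[sel]
    states = window_connectivity(recording, grid, percentile, window_selector)
    isync = np.array([s.isync for s in states])
    e_glob = np.empty(len(states))
    c_glob = np.empty(len(states))
    w_eff = np.empty(len(states))
    for k, s in enumerate(states):
        m = global_efficiency(s.adjacency)
        e_glob[k] = m.e_glob
        c_glob[k] = m.c_glob
        w_eff[k] = weighted_efficiency(s.plv)
    return {
        "I_sync": WindowedMetricTrace("I_sync", centers, isync),
        "E_glob": WindowedMetricTrace("E_glob", centers, e_glob),
        "C_glob": WindowedMetricTrace("C_glob", centers, c_glob),
        "E_glob_weighted": WindowedMetricTrace("E_glob_weighted", centers, w_eff),
    }
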