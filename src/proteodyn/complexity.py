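"""Windowed algorithmic-complexity metrics: Lempel-Ziv (LZ76) complexity of
mean-thresholded binary sequences, and Bandt-Pompe permutation entropy.

C_LZ quantifies information density of the voltage pattern inside each
analysis window; H_PE quantifies the diversity of ordinal (rank-order)
patterns, insensitive to amplitude. Both are reported per window on a
sliding grid (default 1000 samples, step 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Recording, WindowGrid, WindowedMetricTrace


class ComplexityError(ValueError):
    pass


@dataclass
class BinarySequence:
    """0/1 symbol sequence produced by thresholding a window at its mean."""

    bits: np.ndarray
    source_mean: float
    degenerate: bool = False  # all-equal source window

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.size < 2:
            raise ComplexityError("binary sequence needs length >= 2")
        if np.any(self.bits > 1):
            raise ComplexityError("alphabet must be {0, 1}")


@dataclass
class ComplexityResult:
    """LZ76 phrase count with both published normalizations.

    ``clz_primary`` = c(n)·log2(n)/n (the finite-length bound normalization,
    ≈1 for random binary sequences); ``clz_secondary`` = c(n)/(n·log2 n),
    an alternative rendering kept for comparability. Both derive from the
    same phrase count.
    """

    c_n: int
    n: int
    clz_primary: float
    clz_secondary: float
    normalization_used: str = "c(n)*log2(n)/n"


@dataclass
class PermutationEntropyResult:
    m: int
    pattern_counts: dict[tuple[int, ...], int]
    h_pe: float
    degenerate: bool = False


def binarize(window: np.ndarray) -> BinarySequence:
    """Threshold a voltage window at its own mean: 1 iff V > mean (strict).

    Ties at the mean map to 0. An all-equal window yields an all-zero
    sequence flagged degenerate.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ComplexityError("window must have length >= 2")
    mu = float(window.mean())
    bits = (window > mu).astype(np.uint8)
    degenerate = bool(np.all(window == window[0]))
    return BinarySequence(bits=bits, source_mean=mu, degenerate=degenerate)


def lz76_phrase_count(bits: np.ndarray) -> int:
    """LZ76 exhaustive-history phrase count c(n).

    Each new phrase is the shortest extension not reproducible by copying
    from anywhere in the prior history (Lempel-Ziv production process). For
    an all-zero string of length 10 this parses as "0" + "000000000",
    giving c = 2.
    """
    s = np.asarray(bits, dtype=np.uint8).tobytes()
    n = len(s)
    if n == 0:
        return 0
    c = 0
    j = 0
    while j < n:
        # longest L with s[j:j+L] reproducible from an occurrence starting
        # before j (overlap into the phrase allowed); monotone in L, so
        # binary search with C-speed substring find
        lo, hi = 0, n - j
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if s.find(s[j : j + mid]) < j:
                lo = mid
            else:
                hi = mid - 1
        j += lo + 1  # phrase = reproducible prefix + one innovative symbol
        c += 1
    return c


def lz_complexity(seq: BinarySequence | np.ndarray) -> ComplexityResult:
    """LZ76 complexity with both normalizations of the same phrase count."""
    bits = seq.bits if isinstance(seq, BinarySequence) else np.asarray(seq)
    if np.any(np.asarray(bits) > 1):
        raise ComplexityError("alphabet must be {0, 1}")
    n = len(bits)
    if n < 2:
        raise ComplexityError("sequence must have length >= 2")
    c = lz76_phrase_count(bits)
    log2n = math.log2(n)
    return ComplexityResult(
        c_n=c,
        n=n,
        clz_primary=c * log2n / n,
        clz_secondary=c / (n * log2n),
    )


def ordinal_pattern(values: np.ndarray) -> tuple[int, ...]:
    """Rank pattern of ``values`` with ties broken by order of occurrence
    (earlier index ranks lower, the common Bandt-Pompe convention)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(len(values))
    return tuple(int(r) for r in ranks)


def permutation_entropy(
    window: np.ndarray, m: int = 3, delay: int = 1
) -> PermutationEntropyResult:
    """Normalized permutation entropy of order ``m`` (default 3, giving
    3! = 6 possible ordinal patterns) at embedding delay ``delay``.

    h_pe = -(1/log2 m!) * sum p_j log2 p_j over observed pattern
    frequencies p_j; 0 for monotone windows, 1 when all m! patterns are
    equally frequent.
    """
    x = np.asarray(window, dtype=float)
    if m < 2:
        raise ComplexityError("m must be >= 2")
    n_pat = len(x) - (m - 1) * delay
    if n_pat < 2 or len(x) < m + 1:
        raise ComplexityError(f"window too short for m={m}, delay={delay}")
    # vectorized rank patterns with stable (order-of-occurrence) tie-breaks
    emb = x[np.arange(n_pat)[:, None] + np.arange(m)[None, :] * delay]
    order = np.argsort(emb, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(m), (n_pat, m)), axis=1
    )
    codes = ranks @ (m ** np.arange(m))
    uniq, freq = np.unique(codes, return_counts=True)
    counts: dict[tuple[int, ...], int] = {}
    for code, f in zip(uniq, freq):
        digits = []
        c = int(code)
        for _ in range(m):
            digits.append(c % m)
            c //= m
        counts[tuple(digits)] = int(f)
    p = freq.astype(float)
    p /= p.sum()
    h = float(-(p * np.log2(p)).sum() / math.log2(math.factorial(m)))
    degenerate = bool(np.all(x == x[0]))
    return PermutationEntropyResult(
        m=m, pattern_counts=counts, h_pe=min(max(h, 0.0), 1.0) + 0.0, degenerate=degenerate
    )


def windowed_complexity(
    recording: Recording,
    grid: WindowGrid,
    m: int = 3,
    delay: int = 1,
    window_selector: np.ndarray | None = None,
) -> dict[str, list[WindowedMetricTrace]]:
    """Per-window C_LZ and H_PE traces for every mV channel, plus the
    channel-mean trace (labelled ``"mean"``).

    ``window_selector`` (boolean, one per window) drops windows that overlap
    masked spans. Returns ``{"C_LZ": [...], "H_PE": [...]}``.
    """
    centers = grid.centers(recording.sampling_rate)
    sel = (
        np.ones(grid.n_windows, dtype=bool)
        if window_selector is None
        else np.asarray(window_selector, dtype=bool)
    )
    centers = centers[sel]
    slices = [sl for sl, keep in zip(grid.slices(), sel) if keep]
    out: dict[str, list[WindowedMetricTrace]] = {"C_LZ": [], "H_PE": []}
    clz_all, hpe_all = [], []
    for idx in recording.mv_channel_indices():
        ch = recording.voltages[idx]
        label = recording.channel_labels[idx]
        clz = np.empty(len(slices))
        hpe = np.empty(len(slices))
        for w, sl in enumerate(slices):
            win = ch[sl]
            clz[w] = lz_complexity(binarize(win)).clz_primary
            hpe[w] = permutation_entropy(win, m=m, delay=delay).h_pe
        out["C_LZ"].append(WindowedMetricTrace("C_LZ", centers, clz, channel=label))
        out["H_PE"].append(WindowedMetricTrace("H_PE", centers, hpe, channel=label))
        clz_all.append(clz)
        hpe_all.append(hpe)
    if clz_all:
        out["C_LZ"].append(
            WindowedMetricTrace("C_LZ", centers, np.mean(clz_all, axis=0), channel="mean")
        )
        out["H_PE"].append(
            WindowedMetricTrace("H_PE", centers, np.mean(hpe_all, axis=0), channel="mean")
        )
    return out


SUMMARY_ROWS = ("Mean", "Std Dev", "Min", "25%", "Median", "75%", "Max")


def summary_statistics(values: np.ndarray) -> dict[str, float]:
    """Descriptive-statistics block in the standard report row order."""
    v = np.asarray(values, dtype=float)
    return {
        "Mean": float(np.mean(v)),
        "Std Dev": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        "Min": float(np.min(v)),
        "25%": float(np.percentile(v, 25)),
        "Median": float(np.median(v)),
        "75%": float(np.percentile(v, 75)),
        "Max": float(np.max(v)),
    }


def traces_to_tidy(traces: list[WindowedMetricTrace]) -> pd.DataFrame:
    """Long-format table: window_center_s, channel, metric, value."""
    frames = [
        pd.DataFrame(
            {
                "window_center_s": t.window_centers,
                "channel": t.channel,
                "metric": t.metric_name,
                "value": t.values,
            }
        )
        for t in traces
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["window_center_s", "channel", "metric", "value"]
    )
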