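"""Dual-regime (fast/slow) classification of voltage dynamics.

Two complementary classifiers are provided, emitted side by side:

* a fit-based route — detect transient peaks, fit the post-peak decay with
  exponential ``V0 exp(-t/tau)`` and logarithmic ``V0 + A log t`` models,
  take the characteristic timescale (tau, or t_c = exp(-V0/A) for the log
  model) and label tau < 600 s as Regime I (volatile), tau > 3600 s as
  Regime II (nonvolatile), in between as transitional;

* a window-based route — per analysis window, voltage standard deviation
  sigma_V against its 60th percentile plus the autocorrelation 1/e decay
  time tau_AC; volatile windows have high sigma_V and short tau_AC, while
  Regime II additionally requires plateau persistence and, when stimuli
  exist, a post-offset return to within 10% of baseline.

Slow baseline drift is quantified separately by AIC-selected logarithmic
vs exponential fits over contiguous long segments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .preprocessing import running_median
from .recording import Recording, WindowGrid

REGIME_I_TAU_MAX = 600.0     # s; faster than 10 min -> volatile
REGIME_II_TAU_MIN = 3600.0   # s; slower than 1 h -> nonvolatile


class RegimeError(ValueError):
    pass


@dataclass
class DecayFit:
    model: str                 # "exponential" | "logarithmic"
    V0: float
    tau: float | None = None   # exponential decay constant, s
    A: float | None = None     # logarithmic amplitude, mV
    t_c: float | None = None   # log characteristic time e^(-V0/A), s
    r2: float = float("nan")
    aic: float = float("nan")

    @property
    def timescale(self) -> float:
        return self.tau if self.model == "exponential" else self.t_c


@dataclass
class DriftFit:
    model: str                       # "logarithmic" | "exponential"
    params: dict[str, float]
    aic: float
    aic_alternative: float
    segment: tuple[float, float]     # (t_start, t_end) s
    exact_fit: bool = False


@dataclass
class RegimeSegment:
    span: tuple[float, float]
    label: str                       # "I" | "II" | "transitional" | "unlabeled"
    tau: float | None
    source: str                      # "fit" | "window-rule"
    channel: str | None = None


@dataclass
class WindowRegimeRule:
    """Operational window-labelling thresholds.

    sigma_v_percentile : percentile of per-window sigma_V above which a
        window counts as volatile (default 60, per channel)
    tau_ac_max : s; volatile windows must decorrelate faster than this
        (default 0.1 s, appropriate at kHz-scale sampling)
    plateau_min : hours of sustained low variability required for Regime II
        (default 10)
    baseline_return_tol : fractional post-stimulus return-to-baseline
        tolerance for the memory criterion (default 0.10)
    """

    sigma_v_percentile: float = 60.0
    tau_ac_max: float = 0.1
    plateau_min: float = 10.0
    baseline_return_tol: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.sigma_v_percentile < 100:
            raise RegimeError("sigma_v_percentile must be in (0, 100)")
        if min(self.tau_ac_max, self.plateau_min, self.baseline_return_tol) <= 0:
            raise RegimeError("rule tolerances must be positive")


# ---------------------------------------------------------------- peaks

def detect_peaks(
    channel: np.ndarray,
    ma_window: int = 10000,
    k_sigma: float = 2.0,
) -> np.ndarray:
    """Indices of local maxima exceeding (moving average + k_sigma * moving SD).

    The moving statistics use a centered ``ma_window``-sample window
    (shrinking at the edges). Adjacent super-threshold samples collapse to
    the single local maximum of their run.
    """
    x = np.asarray(channel, dtype=float)
    s = pd.Series(x)
    ma = s.rolling(ma_window, center=True, min_periods=2).mean().to_numpy()
    sd = s.rolling(ma_window, center=True, min_periods=2).std().to_numpy()
    thresh = ma + k_sigma * np.nan_to_num(sd)
    above = x > thresh
    peaks = []
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            run = slice(i, j + 1)
            k = i + int(np.argmax(x[run]))
            # require a genuine local maximum relative to neighbours
            left = x[k - 1] if k > 0 else -np.inf
            right = x[k + 1] if k < n - 1 else -np.inf
            if x[k] >= left and x[k] >= right and not (left == x[k] == right):
                peaks.append(k)
            i = j + 1
        else:
            i += 1
    return np.array(peaks, dtype=int)


# ---------------------------------------------------------------- decay fits

def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)


def aic_least_squares(rss: float, n: int, k: int) -> float:
    """AIC for a least-squares fit: n*ln(RSS/n) + 2k. RSS = 0 returns -inf."""
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k


def fit_exponential_decay(t: np.ndarray, v: np.ndarray, span: float) -> DecayFit | None:
    """Least-squares fit of V(t) = V0 * exp(-t/tau), initialized from the
    log-linearized slope, tau bounded to [one sample, span]."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    pos = v > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(v[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else span
        v0_0 = math.exp(intercept)
    else:
        tau0, v0_0 = span / 2, float(v[0]) if v[0] != 0 else 1.0
    tau0 = float(np.clip(tau0, dt, span))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda tt, V0, tau: V0 * np.exp(-tt / tau),
                t, v,
                p0=[v0_0, tau0],
                bounds=([-np.inf, dt * 1e-3], [np.inf, span * 100]),
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return None
    V0, tau = float(popt[0]), float(popt[1])
    yhat = V0 * np.exp(-t / tau)
    rss = float(np.sum((v - yhat) ** 2))
    return DecayFit(
        model="exponential", V0=V0, tau=tau,
        r2=_r2(v, yhat), aic=aic_least_squares(rss, len(v), 2),
    )


def fit_logarithmic_decay(t: np.ndarray, v: np.ndarray) -> DecayFit | None:
    """Linear least squares for V(t) = V0 + A*log(t) (natural log; the
    characteristic time t_c = exp(-V0/A) presumes base e)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(t <= 0):
        dt = t[1] - t[0] if len(t) > 1 else 1.0
        t = t + (dt - t.min()) if t.min() <= 0 else t
    A, V0 = np.polyfit(np.log(t), v, 1)
    yhat = V0 + A * np.log(t)
    rss = float(np.sum((v - yhat) ** 2))
    t_c = float(np.exp(-V0 / A)) if A != 0 else None
    return DecayFit(
        model="logarithmic", V0=float(V0), A=float(A), t_c=t_c,
        r2=_r2(v, yhat), aic=aic_least_squares(rss, len(v), 2),
    )


def fit_decay(
    segment: np.ndarray,
    sampling_rate: float,
    t: np.ndarray | None = None,
) -> DecayFit | None:
    """Fit a post-peak decay segment with both models; the winner is the one
    with higher R^2. Returns None when neither fit converges."""
    v = np.asarray(segment, dtype=float)
    if len(v) < 10:
        raise RegimeError("decay segment must have >= 10 samples")
    if t is None:
        t = np.arange(len(v)) / sampling_rate
    span = float(t[-1] - t[0]) if t[-1] > t[0] else len(v) / sampling_rate
    fits = [f for f in (
        fit_exponential_decay(t, v, span),
        fit_logarithmic_decay(t, v),
    ) if f is not None]
    if not fits:
        return None
    return max(fits, key=lambda f: f.r2)


def classify_regime(tau: float) -> str:
    """Partition of timescales: "I" (tau < 600 s), "II" (tau > 3600 s),
    "transitional" otherwise."""
    if tau is None or not np.isfinite(tau) or tau <= 0:
        raise RegimeError("tau must be a positive finite timescale")
    if tau < REGIME_I_TAU_MAX:
        return "I"
    if tau > REGIME_II_TAU_MIN:
        return "II"
    return "transitional"


def decay_segments_after_peaks(
    channel: np.ndarray,
    peaks: np.ndarray,
    segment_samples: int = 1000,
) -> list[tuple[int, np.ndarray]]:
    """Post-peak decay segments, truncated at the next peak when peaks
    overlap and dropped when shorter than 10 samples."""
    out = []
    peaks = np.sort(np.asarray(peaks, dtype=int))
    for i, p in enumerate(peaks):
        end = min(p + segment_samples, len(channel))
        if i + 1 < len(peaks):
            end = min(end, peaks[i + 1])
        if end - p >= 10:
            out.append((int(p), np.asarray(channel[p:end], dtype=float)))
    return out


def classify_decays(
    channel: np.ndarray,
    sampling_rate: float,
    ma_window: int = 10000,
    segment_samples: int = 1000,
    channel_label: str | None = None,
) -> list[RegimeSegment]:
    """Fit-based regime segments: peak detection -> decay fits -> tau labels."""
    peaks = detect_peaks(channel, ma_window=ma_window)
    segments = []
    for p, seg in decay_segments_after_peaks(channel, peaks, segment_samples):
        fit = fit_decay(seg, sampling_rate)
        if fit is None or fit.timescale is None or fit.timescale <= 0:
            continue
        t0 = p / sampling_rate
        segments.append(
            RegimeSegment(
                span=(t0, t0 + len(seg) / sampling_rate),
                label=classify_regime(fit.timescale),
                tau=float(fit.timescale),
                source="fit",
                channel=channel_label,
            )
        )
    return segments


# ---------------------------------------------------------------- drift fits

def fit_drift(
    channel: np.ndarray,
    sampling_rate: float,
    segment_length: float = 10000.0,
    t0: float = 1.0,
    times: np.ndarray | None = None,
) -> list[DriftFit]:
    """AIC-selected drift model per contiguous ``segment_length``-second
    segment of a (transient-removed) trace.

    Models: logarithmic V(t) = V0 + A*log(t/t0) (t0 fixed; linear in ln t,
    k=2) versus exponential V(t) = V1 + B*exp(-t/tau2) (k=3). The model with
    the lower AIC wins; RSS = 0 maps to AIC -inf with an exact-fit flag.
    """
    v = np.asarray(channel, dtype=float)
    t = np.arange(len(v)) / sampling_rate if times is None else np.asarray(times, float)
    seg_samples = max(int(round(segment_length * sampling_rate)), 2)
    fits = []
    for s0 in range(0, len(v) - seg_samples + 1, seg_samples):
        sl = slice(s0, s0 + seg_samples)
        ts, vs = t[sl], v[sl]
        ts_pos = np.where(ts <= 0, ts + (ts[1] - ts[0]), ts)
        A, c = np.polyfit(np.log(ts_pos / t0), vs, 1)
        log_hat = c + A * np.log(ts_pos / t0)
        rss_log = float(np.sum((vs - log_hat) ** 2))
        aic_log = aic_least_squares(rss_log, len(vs), 2)

        aic_exp = math.inf
        exp_params: dict[str, float] = {}
        span = float(ts[-1] - ts[0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda tt, V1, B, tau2: V1 + B * np.exp(-(tt - ts[0]) / tau2),
                    ts, vs,
                    p0=[float(vs[-1]), float(vs[0] - vs[-1]), max(span / 3, 1e-6)],
                    bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, span * 1e3]),
                    maxfev=5000,
                )
            exp_hat = popt[0] + popt[1] * np.exp(-(ts - ts[0]) / popt[2])
            rss_exp = float(np.sum((vs - exp_hat) ** 2))
            aic_exp = aic_least_squares(rss_exp, len(vs), 3)
            exp_params = {"V1": float(popt[0]), "B": float(popt[1]), "tau2": float(popt[2])}
        except (RuntimeError, ValueError):
            pass

        if aic_log <= aic_exp:
            fits.append(DriftFit(
                model="logarithmic",
                params={"V0": float(c), "A": float(A), "t0": t0},
                aic=aic_log, aic_alternative=aic_exp,
                segment=(float(ts[0]), float(ts[-1])),
                exact_fit=not math.isfinite(aic_log),
            ))
        else:
            fits.append(DriftFit(
                model="exponential",
                params=exp_params,
                aic=aic_exp, aic_alternative=aic_log,
                segment=(float(ts[0]), float(ts[-1])),
                exact_fit=not math.isfinite(aic_exp),
            ))
    return fits


# ---------------------------------------------------------------- window rule

def autocorrelation_decay_time(window: np.ndarray, sampling_rate: float) -> float:
    """Lag (seconds) at which the normalized autocorrelation first decays to
    1/e, with linear interpolation between the bracketing lags."""
    x = np.asarray(window, dtype=float)
    if len(x) < 10:
        raise RegimeError("window must have >= 10 samples")
    if np.all(x == x[0]):
        raise RegimeError("autocorrelation undefined for a constant window")
    x = x - x.mean()
    target = 1.0 / math.e
    denom = float(np.dot(x, x))
    prev = 1.0
    max_lag = len(x) - 1
    for lag in range(1, max_lag + 1):
        r = float(np.dot(x[:-lag], x[lag:]) / denom)
        if r < target:
            frac = (prev - target) / (prev - r)
            return (lag - 1 + frac) / sampling_rate
        prev = r
    return max_lag / sampling_rate


def baseline_return_satisfied(
    channel: np.ndarray,
    sampling_rate: float,
    stimulus_onset: float,
    stimulus_offset: float,
    tol: float = 0.10,
    settle: float = 10.0,
) -> bool:
    """Memory criterion: post-offset voltage returns to within ``tol`` of the
    pre-stimulus baseline (fractional deviation relative to the stimulus-driven
    excursion)."""
    fs = sampling_rate
    pre = channel[: max(int(stimulus_onset * fs), 1)]
    i_off = int(stimulus_offset * fs)
    post = channel[min(i_off + int(settle * fs), len(channel) - 1):]
    if len(pre) == 0 or len(post) == 0:
        return False
    baseline = float(np.median(pre))
    during = channel[int(stimulus_onset * fs): i_off]
    excursion = float(np.max(np.abs(during - baseline))) if len(during) else 0.0
    if excursion == 0:
        return True
    return abs(float(np.median(post)) - baseline) <= tol * excursion


def label_windows(
    recording: Recording,
    grid: WindowGrid,
    rule: WindowRegimeRule | None = None,
    channels: list[str] | None = None,
) -> list[RegimeSegment]:
    """Window-rule regime segments per channel.

    Regime I: sigma_V above its (per-channel) percentile threshold AND
    tau_AC < tau_ac_max. Regime II: sigma_V below threshold sustained over a
    contiguous run longer than plateau_min hours; when stimulus events exist
    the baseline-return memory criterion must also hold. Contiguous
    same-label windows merge into segments.
    """
    rule = rule or WindowRegimeRule()
    idx = (
        [recording.channel_labels.index(c) for c in channels]
        if channels
        else recording.mv_channel_indices()
    )
    fs = recording.sampling_rate
    centers = grid.centers(fs)
    segments: list[RegimeSegment] = []
    for i in idx:
        ch = recording.voltages[i]
        sigma = np.array([float(np.std(ch[sl])) for sl in grid.slices()])
        thr = float(np.percentile(sigma, rule.sigma_v_percentile))
        tau_ac = np.empty(grid.n_windows)
        for w, sl in enumerate(grid.slices()):
            win = ch[sl]
            try:
                tau_ac[w] = autocorrelation_decay_time(win, fs)
            except RegimeError:
                tau_ac[w] = np.inf
        labels = np.full(grid.n_windows, "unlabeled", dtype=object)
        labels[(sigma > thr) & (tau_ac < rule.tau_ac_max)] = "I"

        # Regime II: contiguous low-variability runs exceeding the plateau span
        low = sigma <= thr
        w = 0
        min_span = rule.plateau_min * 3600.0
        while w < grid.n_windows:
            if low[w]:
                j = w
                while j + 1 < grid.n_windows and low[j + 1]:
                    j += 1
                span = (grid.window_starts[j] + grid.window_length - grid.window_starts[w]) / fs
                if span > min_span:
                    ok = True
                    if recording.stimulus_events:
                        ok = all(
                            baseline_return_satisfied(
                                ch, fs, onset, onset + 1.0, rule.baseline_return_tol
                            )
                            for onset in recording.stimulus_events
                        )
                    if ok:
                        labels[w : j + 1] = "II"
                w = j + 1
            else:
                w += 1

        # merge contiguous same-label windows
        w = 0
        while w < grid.n_windows:
            lab = labels[w]
            j = w
            while j + 1 < grid.n_windows and labels[j + 1] == lab:
                j += 1
            if lab in ("I", "II"):
                t0 = grid.window_starts[w] / fs
                t1 = (grid.window_starts[j] + grid.window_length) / fs
                segments.append(
                    RegimeSegment(
                        span=(float(t0), float(t1)),
                        label=str(lab),
                        tau=None,
                        source="window-rule",
                        channel=recording.channel_labels[i],
                    )
                )
            w = j + 1
    return segments


def segments_to_table(segments: list[RegimeSegment]) -> pd.DataFrame:
    """BED-like tabular export: channel, t_start_s, t_end_s, label, tau_s, source."""
    return pd.DataFrame(
        [
            {
                "channel": s.channel,
                "t_start_s": s.span[0],
                "t_end_s": s.span[1],
                "label": s.label,
                "tau_s": s.tau,
                "source": s.source,
            }
            for s in segments
        ],
        columns=["channel", "t_start_s", "t_end_s", "label", "tau_s", "source"],
    )
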