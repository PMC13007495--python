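"""Seeded generator of proteinoid-like multichannel recordings with known
ground truth, built from the dynamical laws observed in the recordings:

* slow per-channel baseline: exponential stabilization followed by
  logarithmic drift, ``V0 + A exp(-t/tau1)`` then ``V1 + B log(t/t0)``;
* spontaneous burst trains with geometrically shortening intervals
  ``dt(n) = dt(1) exp(-alpha (n-1))`` and decaying peak amplitudes
  ``Vmax(n) = Vmax(1) exp(-beta (n-1))``, optionally augmented by a
  learning-rate adaptation ``dt(n+1) = dt(n) exp(-alpha) - k h(V_n)``;
* damped harmonic transients ``V'' + gamma V' + omega0^2 V = 0``;
* diffusive inter-channel coupling ``dVi/dt = g(Vi) + sum_j k_ij (Vj - Vi)``;
* saturating stimulus relaxation ``V = V0 + (Vpeak - V0)(1 - exp(-t/tau))``;
* additive white Gaussian noise.

Defaults reproduce the observed study conditions: 8 channels at 1 Hz over
~50 h, first burst intervals/amplitudes 714 s -> 580 s and 7.9 mV -> 4.27 mV,
and the Channel-C-style drift ``-40 + 15 log(t/1e4)`` mV. Identical spec
(including seed) yields a bit-identical recording; every generated recording
carries a ground-truth sidecar for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .recording import Recording, DEFAULT_CHANNEL_LABELS


class SyntheticError(ValueError):
    pass


@dataclass
class SlowDriftParams:
    """Piecewise slow baseline: V0 + A*exp(-t/tau1) for t < t_transition,
    V1 + B*log(t/t0) after. Continuity at the transition is NOT enforced
    (the two branches are independent fits in the source dynamics); the
    jump magnitude is reported in the ground truth."""

    V0: float = -40.0
    A: float = 20.0
    tau1: float = 5000.0
    t_transition: float = 4.0e4
    V1: float = -40.0
    B: float = 15.0
    t0: float = 1.0e4

    def discontinuity(self) -> float:
        pre = self.V0 + self.A * math.exp(-self.t_transition / self.tau1)
        post = self.V1 + self.B * math.log(self.t_transition / self.t0)
        return post - pre


@dataclass
class BurstParams:
    """Burst-train timing/amplitude laws (intervals in s, amplitudes in mV)."""

    dt_first: float = 714.0                  # 11.9 min
    alpha: float = math.log(11.9 / 9.67)     # -> second interval 9.67 min
    vmax_first: float = 7.9
    beta: float = math.log(7.9 / 4.27)       # -> second amplitude 4.27 mV
    width: float = 30.0                      # raised-cosine pulse width, s
    t_first: float = 100.0                   # first event onset, s
    adapt_k: float = 0.0                     # learning rate of the interval rule
    adapt_h: float = 1.0                     # h(V_n) taken constant


@dataclass
class DampedParams:
    """Damped harmonic transient: gamma damping (1/s), omega0 natural
    frequency (rad/s), initial amplitude (mV), onset times (s)."""

    gamma: float = 0.02
    omega0: float = 0.05
    amplitude: float = 5.0
    onsets: tuple[float, ...] = ()


@dataclass
class SyntheticSpec:
    n_channels: int = 8
    sampling_rate: float = 1.0
    duration: float = 1.8e5
    slow: SlowDriftParams = field(default_factory=SlowDriftParams)
    bursts: BurstParams = field(default_factory=BurstParams)
    damped: DampedParams = field(default_factory=DampedParams)
    coupling: np.ndarray | None = None       # k_ij >= 0, zero diagonal
    relaxation_tau: float = 273.0            # saturating-relaxation constant, s
    noise_sd: float = 0.5                    # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.sampling_rate <= 0 or self.duration <= 0:
            raise SyntheticError("invalid spec dimensions")
        if self.slow.t0 <= 0 or self.slow.tau1 <= 0:
            raise SyntheticError("t0 and tau1 must be positive")
        if self.bursts.dt_first <= 0:
            raise SyntheticError("first burst interval must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def gen_slow_drift(spec: SyntheticSpec, channel: int = 0,
                   params: SlowDriftParams | None = None) -> np.ndarray:
    """Per-channel slow baseline (exponential -> logarithmic), channel index
    only offsets the baseline slightly so channels are distinguishable."""
    p = params or spec.slow
    t = spec.times()
    v = np.empty_like(t)
    pre = t < p.t_transition
    v[pre] = p.V0 + p.A * np.exp(-t[pre] / p.tau1)
    with np.errstate(divide="ignore"):
        post_t = np.where(t >= p.t_transition, t, p.t0)
        v[~pre] = p.V1 + p.B * np.log(post_t[~pre] / p.t0)
    return v + 2.0 * channel


def gen_burst_train(spec: SyntheticSpec,
                    params: BurstParams | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Burst event times and peak amplitudes, truncated at the duration.

    Interval law: next = prev * exp(-alpha) - adapt_k * adapt_h. With
    adapt_k = 0 this is the pure geometric rule; with alpha = 0 and constant
    h it degenerates to arithmetic shortening. The geometric rule has a
    finite-time accumulation point, so the train also stops once the
    interval falls below one sampling interval (no longer resolvable).
    """
    p = params or spec.bursts
    min_dt = 1.0 / spec.sampling_rate
    times, amps = [], []
    t = p.t_first
    dt = p.dt_first
    n = 0
    while t < spec.duration and dt >= min_dt:
        times.append(t)
        amps.append(p.vmax_first * math.exp(-p.beta * n))
        t = t + dt
        dt = dt * math.exp(-p.alpha) - p.adapt_k * p.adapt_h
        n += 1
    return np.array(times), np.array(amps)


def raised_cosine_pulse(t: np.ndarray, onset: float, width: float,
                        amplitude: float) -> np.ndarray:
    """Single raised-cosine burst waveform of the given width and peak."""
    x = (t - onset) / width
    inside = (x >= 0) & (x <= 1)
    out = np.zeros_like(t)
    out[inside] = amplitude * 0.5 * (1 - np.cos(2 * np.pi * x[inside]))
    return out


def render_bursts(spec: SyntheticSpec, times: np.ndarray,
                  amps: np.ndarray) -> np.ndarray:
    t = spec.times()
    out = np.zeros_like(t)
    for onset, amp in zip(times, amps):
        out += raised_cosine_pulse(t, onset, spec.bursts.width, amp)
    return out


def damped_transient(t: np.ndarray, gamma: float, omega0: float,
                     amplitude: float) -> np.ndarray:
    """Closed-form solution of V'' + gamma V' + omega0^2 V = 0 with
    V(0) = amplitude, V'(0) = 0 (under-, over- and critically damped)."""
    if omega0 <= 0:
        raise SyntheticError("omega0 must be positive")
    if gamma < 0:
        raise SyntheticError("gamma must be non-negative")
    disc = gamma * gamma / 4.0 - omega0 * omega0
    if abs(disc) < 1e-15 * omega0 * omega0:       # critical damping
        r = -gamma / 2.0
        return amplitude * (1 - r * t) * np.exp(r * t)
    if disc < 0:                                   # underdamped
        wd = math.sqrt(-disc)
        return amplitude * np.exp(-gamma * t / 2.0) * (
            np.cos(wd * t) + (gamma / (2 * wd)) * np.sin(wd * t)
        )
    # overdamped
    sq = math.sqrt(disc)
    r1, r2 = -gamma / 2.0 + sq, -gamma / 2.0 - sq
    c1 = -r2 * amplitude / (r1 - r2)
    c2 = r1 * amplitude / (r1 - r2)
    return c1 * np.exp(r1 * t) + c2 * np.exp(r2 * t)


def gen_damped_transient(spec: SyntheticSpec,
                         params: DampedParams | None = None) -> np.ndarray:
    """Damped harmonic transients added at each onset time."""
    p = params or spec.damped
    t = spec.times()
    out = np.zeros_like(t)
    for onset in p.onsets:
        after = t >= onset
        out[after] += damped_transient(t[after] - onset, p.gamma, p.omega0, p.amplitude)
    return out


def saturating_relaxation(t: np.ndarray, V0: float, V_peak: float,
                          tau: float) -> np.ndarray:
    """Saturating step response V0 + (Vpeak - V0)(1 - exp(-t/tau))."""
    return V0 + (V_peak - V0) * (1.0 - np.exp(-np.asarray(t, float) / tau))


def gen_coupled_network(
    spec: SyntheticSpec,
    g: str | None = "leak",
    tau_leak: float = 1000.0,
    v_init: np.ndarray | None = None,
) -> tuple[Recording, dict]:
    """Euler-Maruyama integration of diffusive inter-channel coupling
    dVi/dt = g(Vi) + sum_j k_ij (Vj - Vi) at the sampling step.

    ``g`` is "leak" (linear leak -V/tau_leak, the default intrinsic
    dynamic) or None (pure consensus: with a connected coupling matrix and
    no noise the channels converge to their common mean). Raises when the
    explicit step is unstable (max total coupling rate * dt >= 1).
    """
    n = spec.n_channels
    k = spec.coupling if spec.coupling is not None else np.zeros((n, n))
    k = np.asarray(k, dtype=float)
    if k.shape != (n, n) or np.any(k < 0) or np.any(np.diag(k) != 0):
        raise SyntheticError("coupling must be n x n, non-negative, zero diagonal")
    dt = 1.0 / spec.sampling_rate
    rate = float(np.max(k.sum(axis=1))) + (1.0 / tau_leak if g == "leak" else 0.0)
    if rate * dt >= 1.0:
        raise SyntheticError(
            f"unstable Euler step: max rate {rate:.3g}/s * dt {dt:.3g}s >= 1"
        )
    rng = np.random.default_rng(spec.seed)
    v = np.empty((n, spec.n_samples))
    v[:, 0] = v_init if v_init is not None else rng.normal(0.0, 10.0, n)
    sd_step = spec.noise_sd * math.sqrt(dt)
    L = k - np.diag(k.sum(axis=1))          # graph Laplacian (negated) action
    for s in range(1, spec.n_samples):
        x = v[:, s - 1]
        drift = L @ x
        if g == "leak":
            drift = drift - x / tau_leak
        v[:, s] = x + drift * dt + rng.normal(0.0, sd_step, n)
    rec = Recording(
        voltages=v, sampling_rate=spec.sampling_rate,
        channel_labels=tuple(DEFAULT_CHANNEL_LABELS[:n]) if n <= 8 else (),
    )
    truth = {"coupling": k.tolist(), "g": g, "tau_leak": tau_leak,
             "seed": spec.seed, "noise_sd": spec.noise_sd}
    return rec, truth


def block_coupling(n_channels: int, blocks: list[list[int]],
                   strength: float) -> np.ndarray:
    """Coupling matrix with all-to-all edges inside each block, none between."""
    k = np.zeros((n_channels, n_channels))
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    k[i, j] = strength
    return k


def noise_sd_for_rho(signal_sd: float, gain: float, rho: float) -> float:
    """Additive-noise SD giving a designed Pearson correlation rho between
    gain*signal and gain*signal + noise (attenuation formula
    rho = 1/sqrt(1 + sigma^2/(gain^2 var(signal))))."""
    if not 0 < rho <= 1:
        raise SyntheticError("rho must be in (0, 1]")
    return abs(gain) * signal_sd * math.sqrt(1.0 / (rho * rho) - 1.0)


def gen_stimulus_response(
    spec: SyntheticSpec,
    stimulus: np.ndarray,
    gains: np.ndarray,
    noise_sd: float | np.ndarray = 0.0,
    kernel_tau: float | None = None,
) -> tuple[Recording, dict]:
    """Simulated recording of optical-stimulation outputs.

    Each output channel is gain * (stimulus filtered by a first-order
    saturating kernel with time constant ``kernel_tau``; the kernel's step
    response is the saturating relaxation law) plus white noise.
    ``kernel_tau=None`` uses a delta-like kernel (identity). Channel 0
    carries the stimulus itself, flagged as the volt-unit input channel.
    """
    stim = np.asarray(stimulus, dtype=float)
    gains = np.atleast_1d(np.asarray(gains, dtype=float))
    rng = np.random.default_rng(spec.seed)
    if kernel_tau is not None and kernel_tau > 0:
        dt = 1.0 / spec.sampling_rate
        a = math.exp(-dt / kernel_tau)
        driven = sps.lfilter([1 - a], [1, -a], stim)
    else:
        driven = stim
    sds = np.broadcast_to(np.atleast_1d(np.asarray(noise_sd, float)), gains.shape)
    outs = [g * driven + rng.normal(0.0, sd, len(stim)) if sd > 0 else g * driven
            for g, sd in zip(gains, sds)]
    volts = np.vstack([stim] + outs)
    n = volts.shape[0]
    labels = tuple(DEFAULT_CHANNEL_LABELS[:n]) if n <= 8 else tuple(
        f"Ch{i}" for i in range(n))
    rec = Recording(
        voltages=volts, sampling_rate=spec.sampling_rate,
        channel_labels=labels,
        units_per_channel=("V",) + ("mV",) * (n - 1),
    )
    truth = {"gains": gains.tolist(), "kernel_tau": kernel_tau,
             "noise_sd": np.asarray(sds, float).tolist(), "seed": spec.seed}
    return rec, truth


def generate_recording(spec: SyntheticSpec) -> tuple[Recording, dict]:
    """Full synthetic recording: per-channel slow drift + burst train +
    damped transients + white noise, with a ground-truth sidecar (event
    times, amplitudes, drift parameters, discontinuity, regime spans)."""
    rng = np.random.default_rng(spec.seed)
    t = spec.times()
    burst_times, burst_amps = gen_burst_train(spec)
    bursts = render_bursts(spec, burst_times, burst_amps)
    damped = gen_damped_transient(spec)
    v = np.empty((spec.n_channels, spec.n_samples))
    for c in range(spec.n_channels):
        v[c] = (
            gen_slow_drift(spec, c)
            + bursts
            + damped
            + rng.normal(0.0, spec.noise_sd, spec.n_samples)
        )
    rec = Recording(
        voltages=v, sampling_rate=spec.sampling_rate,
        channel_labels=tuple(DEFAULT_CHANNEL_LABELS[: spec.n_channels])
        if spec.n_channels <= 8 else (),
    )
    truth = {
        "burst_times": burst_times.tolist(),
        "burst_amplitudes": burst_amps.tolist(),
        "slow": asdict(spec.slow),
        "slow_discontinuity_mV": spec.slow.discontinuity(),
        "damped": {"gamma": spec.damped.gamma, "omega0": spec.damped.omega0,
                   "amplitude": spec.damped.amplitude,
                   "onsets": list(spec.damped.onsets)},
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return rec, truth


def gen_regime_recording(
    sampling_rate: float = 1.0,
    burst_hours: float = 10.0,
    plateau_hours: float = 11.0,
    burst_noise_sd: float = 5.0,
    plateau_noise_sd: float = 0.05,
    plateau_level: float = 60.0,
    seed: int = 0,
) -> tuple[Recording, dict]:
    """Single-channel ground-truthed recording for regime-label recovery:
    an initial span of fast, high-variance fluctuations (volatile) followed
    by a long stable plateau (nonvolatile).

    The default proportions keep both regimes expressible under the
    percentile-based window rule: the sigma_V threshold is a percentile of
    the per-window SD distribution, so it can only separate the regimes when
    the volatile fraction of windows is comparable to (1 - percentile/100);
    the plateau span still exceeds the 10 h persistence requirement.
    """
    rng = np.random.default_rng(seed)
    n_burst = int(burst_hours * 3600 * sampling_rate)
    n_plat = int(plateau_hours * 3600 * sampling_rate)
    burst = rng.normal(0.0, burst_noise_sd, n_burst)
    plateau = plateau_level + rng.normal(0.0, plateau_noise_sd, n_plat)
    v = np.concatenate([burst, plateau])[None, :]
    rec = Recording(voltages=v, sampling_rate=sampling_rate,
                    channel_labels=("ChA",))
    truth = {
        "volatile_span_s": (0.0, n_burst / sampling_rate),
        "plateau_span_s": (n_burst / sampling_rate,
                           (n_burst + n_plat) / sampling_rate),
        "seed": seed,
    }
    return rec, truth
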