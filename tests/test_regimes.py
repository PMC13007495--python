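"""Dual-regime classification: peak detection, decay/drift fitting,
autocorrelation timescales and window labelling against generator truth."""

import math

import numpy as np
import pytest

from proteodyn.recording import Recording, make_windows
from proteodyn.regimes import (
    RegimeError,
    WindowRegimeRule,
    autocorrelation_decay_time,
    baseline_return_satisfied,
    classify_decays,
    classify_regime,
    detect_peaks,
    fit_decay,
    fit_drift,
    label_windows,
    segments_to_table,
)
from proteodyn.synthetic import gen_regime_recording


# ---------------------------------------------------------------- detection

def test_single_spike_detected(rng):
    x = rng.normal(0, 0.5, 20_000)
    x[10_000] += 20.0  # ~40 sigma
    peaks = detect_peaks(x, ma_window=10_000)
    assert 10_000 in peaks


def test_monotone_ramp_no_peaks():
    assert len(detect_peaks(np.arange(20_000, dtype=float), ma_window=10_000)) == 0


def test_adjacent_suprathreshold_collapse(rng):
    x = rng.normal(0, 0.1, 20_000)
    x[5000:5005] += np.array([5.0, 8.0, 10.0, 8.0, 5.0])
    peaks = detect_peaks(x, ma_window=10_000)
    nearby = [p for p in peaks if 4995 <= p <= 5010]
    assert nearby == [5002]


def test_noise_peak_rate_reasonable():
    """Pure Gaussian noise: the detected rate stays within 50% of a
    Monte-Carlo oracle computed with the same threshold rule."""
    rates, oracle_rates = [], []
    for s in range(5):
        r = np.random.default_rng(s)
        x = r.normal(size=30_000)
        peaks = detect_peaks(x, ma_window=10_000, k_sigma=2.0)
        rates.append(len(peaks) / len(x))
        # oracle: fraction of strict local maxima above mean + 2 SD
        loc = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])
        above = x[1:-1] > x.mean() + 2 * x.std()
        oracle_rates.append(np.sum(loc & above) / len(x))
    assert np.mean(rates) == pytest.approx(np.mean(oracle_rates), rel=0.5)


# ------------------------------------------------------------------- decays

def test_exponential_recovery_noiseless():
    t = np.linspace(0, 1000, 1000)
    fit = fit_decay(50 * np.exp(-t / 300.0), sampling_rate=1.0, t=t)
    assert fit.model == "exponential"
    assert fit.tau == pytest.approx(300.0, abs=1.0)
    assert fit.r2 > 0.999


def test_logarithmic_decay_wins():
    # the slow-drift law observed on one channel: -40 + 15 log(t/1e4) mV
    t = np.linspace(4e4, 5e4, 1000)
    fit = fit_decay(-40 + 15 * np.log(t / 1e4), sampling_rate=1.0, t=t)
    assert fit.model == "logarithmic"
    assert fit.A == pytest.approx(15.0, rel=1e-6)


def test_tc_closed_form():
    # V0 = 0, A = 1 -> t_c = e^0 = 1 s
    t = np.linspace(1, 100, 500)
    fit = fit_decay(0.0 + 1.0 * np.log(t), sampling_rate=1.0, t=t)
    assert fit.model == "logarithmic"
    assert fit.t_c == pytest.approx(1.0, rel=1e-6)


@pytest.mark.parametrize("tau,label", [(300, "I"), (5000, "II"), (1800, "transitional")])
def test_classify_regime(tau, label):
    assert classify_regime(tau) == label


def test_classify_regime_partition(rng):
    for tau in 10 ** rng.uniform(-1, 6, 200):
        assert classify_regime(float(tau)) in ("I", "II", "transitional")


def test_classify_regime_rejects_nonpositive():
    with pytest.raises(RegimeError):
        classify_regime(0.0)


def test_decay_parameter_recovery_under_noise():
    """Median recovered tau within 10% of truth at 5% amplitude noise,
    tau in {60, 300, 3000, 1e4} s, 50 seeds each."""
    for tau in (60.0, 300.0, 3000.0, 1.0e4):
        span = 3 * tau
        t = np.linspace(0, span, 500)
        clean = 50.0 * np.exp(-t / tau)
        recovered = []
        for s in range(50):
            r = np.random.default_rng(s)
            noisy = clean + r.normal(0, 0.05 * 50.0, len(t))
            fit = fit_decay(noisy, sampling_rate=len(t) / span, t=t)
            if fit is not None and fit.model == "exponential":
                recovered.append(fit.tau)
        assert len(recovered) >= 45
        med = np.median(recovered)
        assert abs(med - tau) / tau < 0.10


# -------------------------------------------------------------------- drift

def test_drift_generative_model_wins_noiseless():
    t = np.arange(10_000, dtype=float)
    log_sig = -40 + 15 * np.log((t + 1) / 1e4)
    exp_sig = 5 + 3 * np.exp(-t / 2000.0)
    assert fit_drift(log_sig, 1.0)[0].model == "logarithmic"
    assert fit_drift(exp_sig, 1.0)[0].model == "exponential"


def test_drift_aic_selection_power():
    """Log-generated drift with 1 mV noise: log model selected in >= 90%
    of 50 seeds."""
    t = np.arange(10_000, dtype=float)
    clean = -40 + 15 * np.log((t + 1) / 1e4)
    wins = 0
    for s in range(50):
        r = np.random.default_rng(s)
        fit = fit_drift(clean + r.normal(0, 1.0, len(t)), 1.0)[0]
        wins += fit.model == "logarithmic"
    assert wins >= 45


def test_drift_exact_fit_flag():
    # constant signal: log model with A=0 fits exactly, RSS = 0 -> -inf AIC
    fits = fit_drift(np.full(5000, 3.0), 1.0, segment_length=5000)
    assert fits[0].exact_fit
    assert fits[0].aic == -math.inf


# ---------------------------------------------------------- autocorrelation

def test_white_noise_tau_ac_below_one_sample(rng):
    x = rng.normal(size=1000)
    assert autocorrelation_decay_time(x, 1000.0) <= 1.0 / 1000.0


def test_ar1_tau_ac_closed_form():
    """AR(1) with phi = 0.9: ACF = phi^k crosses 1/e at -1/ln(phi) ~ 9.49
    samples; recovered within 20% over seeds."""
    fs = 1000.0
    taus = []
    for s in range(50):
        r = np.random.default_rng(s)
        x = np.empty(5000)
        x[0] = 0.0
        e = r.normal(size=5000)
        for i in range(1, 5000):
            x[i] = 0.9 * x[i - 1] + e[i]
        taus.append(autocorrelation_decay_time(x, fs))
    expected = -1.0 / math.log(0.9) / fs
    assert np.mean(taus) == pytest.approx(expected, rel=0.20)


def test_slow_sinusoid_long_tau_ac():
    # cosine ACF first crosses 1/e at ~0.193 periods; a slow tone in a
    # short window decorrelates far slower than the 0.1 s volatility rule
    fs = 1000.0
    t = np.arange(1000) / fs
    x = np.sin(2 * np.pi * 0.5 * t)  # period 2 s >> window
    assert autocorrelation_decay_time(x, fs) > 0.1


def test_constant_window_rejected():
    with pytest.raises(RegimeError):
        autocorrelation_decay_time(np.ones(100), 1.0)


# ---------------------------------------------------------- window labelling

def _label_rule():
    # tau_AC volatility cutoff expressed in samples-equivalent at 1 Hz
    return WindowRegimeRule(tau_ac_max=2.0, plateau_min=10.0)


def test_burst_then_plateau_labels():
    """1 h of fast high-variance activity then 20 h plateau: the burst span
    is labelled I and the plateau II, per generator ground truth."""
    rec, truth = gen_regime_recording(seed=3)
    grid = make_windows(rec, 1000, 500)
    segs = label_windows(rec, grid, _label_rule())
    t_split = truth["volatile_span_s"][1]
    ones = [s for s in segs if s.label == "I"]
    twos = [s for s in segs if s.label == "II"]
    assert ones and twos
    assert all(s.span[1] <= t_split + 1000 for s in ones)
    assert all(s.span[0] >= t_split - 1000 for s in twos)


def test_all_noise_no_regime_ii(rng):
    rec = Recording(voltages=rng.normal(size=(1, 40_000))[None, :][0], sampling_rate=1.0)
    grid = make_windows(rec, 1000, 500)
    segs = label_windows(rec, grid, _label_rule())
    assert not any(s.label == "II" for s in segs)


def test_label_recovery_rate():
    """Fit-free window labels match generator truth in >= 95% of runs."""
    hits = 0
    n_runs = 20
    for seed in range(n_runs):
        rec, truth = gen_regime_recording(seed=seed)
        grid = make_windows(rec, 1000, 500)
        segs = label_windows(rec, grid, _label_rule())
        t_split = truth["volatile_span_s"][1]
        ok_i = any(s.label == "I" and s.span[1] <= t_split + 1000 for s in segs)
        ok_ii = any(s.label == "II" and s.span[0] >= t_split - 1000 for s in segs)
        hits += ok_i and ok_ii
    assert hits / n_runs >= 0.95


def test_baseline_return_threshold():
    fs = 1.0
    n = 2000
    base = np.zeros(n)
    onset, offset = 500.0, 600.0
    excursion = 50.0
    for final_frac, expected in ((0.05, True), (0.20, False)):
        x = base.copy()
        x[500:600] = excursion
        x[650:] = final_frac * excursion
        assert (
            baseline_return_satisfied(x, fs, onset, offset, tol=0.10)
            is expected
        )


def test_fit_based_segments_on_spiky_channel(rng):
    """End-to-end fit route: spikes with fast decays produce Regime I
    segments."""
    fs = 1.0
    x = rng.normal(0, 0.2, 60_000)
    for p in (15_000, 30_000, 45_000):
        t = np.arange(2000)
        x[p : p + 2000] += 30.0 * np.exp(-t / 200.0)
    segs = classify_decays(x, fs, ma_window=10_000, segment_samples=1000)
    assert segs
    assert all(s.source == "fit" for s in segs)
    assert any(s.label == "I" for s in segs)
    table = segments_to_table(segs)
    assert list(table.columns) == ["channel", "t_start_s", "t_end_s", "label", "tau_s", "source"]
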