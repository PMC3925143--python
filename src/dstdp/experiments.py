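"""Experiment drivers and distribution statistics.

These reproduce the emergent phenomena of the model from config presets:
equilibrium weight distributions (bimodal vs unimodal), AP-duration sweeps
of distribution shape and steady-state rate, input-rate sweeps, the
signal/noise selectivity protocol, and unbounded-run statistics.  Every
driver is a pure function of (config, seeds) and all stochastic claims are
evaluated as medians over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .exceptions import ParameterError
from .simulator import SimConfig, SimResult, run


def seed_stream(base_seed: int, tag: int, n: int) -> list[int]:
    """``n`` independent 31-bit seeds derived from (base_seed, tag)."""
    ss = np.random.SeedSequence([int(base_seed), int(tag)])
    return [int(s) for s in ss.generate_state(n, np.uint64) % (2 ** 31)]


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient ``(g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3)))``.

    Uses bias-corrected sample skewness ``g1`` and excess kurtosis ``g2``.
    Values above 5/9 (the uniform-distribution benchmark) indicate
    departure from unimodality.  Returns 0 for (near-)degenerate samples.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 4 or np.std(x) <= 1e-12 * max(1.0, abs(x.mean())):
        return 0.0
    g1 = sps.skew(x, bias=False)
    g2 = sps.kurtosis(x, fisher=True, bias=False)
    denom = g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g1 ** 2 + 1.0) / denom)


BIMODALITY_BENCHMARK = 5.0 / 9.0


@dataclass
class DistributionStats:
    """Summary of one equilibrium weight vector."""

    mean: float                      # nS
    std: float                       # nS
    hist_edges: np.ndarray           # in w / g_max
    hist_counts: np.ndarray
    bimodality_coefficient: float
    below_bound_fraction: float      # fraction of weights <= g_max
    max_weight: float                # nS
    equilibrated: bool = True

    @classmethod
    def from_weights(cls, w: np.ndarray, g_max: float, n_bins: int = 50,
                     equilibrated: bool = True) -> "DistributionStats":
        w = np.asarray(w, float)
        rel = w / g_max
        hi = max(1.0, float(rel.max()) + 1e-12)
        edges = np.linspace(0.0, hi, n_bins + 1)
        counts, _ = np.histogram(rel, bins=edges)
        return cls(mean=float(w.mean()), std=float(w.std()),
                   hist_edges=edges, hist_counts=counts,
                   bimodality_coefficient=bimodality_coefficient(w),
                   below_bound_fraction=float(np.mean(w <= g_max)),
                   max_weight=float(w.max()), equilibrated=equilibrated)


def is_equilibrated(result: SimResult, drift_per_100s: float = 0.01) -> bool:
    """Mean-weight drift below ``drift_per_100s`` over the last run quarter."""
    t = result.snapshot_times_ms / 1000.0
    means = result.weight_snapshots.mean(axis=1)
    q = t >= t[-1] * 0.75
    if q.sum() < 2:
        return True
    tq, mq = t[q], means[q]
    span_100s = (tq[-1] - tq[0]) / 100.0
    if span_100s <= 0 or means.mean() == 0:
        return True
    drift = abs(mq[-1] - mq[0]) / max(abs(mq.mean()), 1e-30)
    return drift / span_100s < drift_per_100s


def equilibrium_distribution(config: SimConfig, duration_s: float | None = None,
                             discard_s: float = 0.0) -> tuple[DistributionStats, SimResult]:
    """Run to (presumed) equilibrium and summarize the final weight vector.

    A failed drift criterion flags the result as non-equilibrated (which is
    the expected outcome for unbounded additive runs at short AP duration)
    rather than raising.
    """
    if duration_s is not None:
        config = replace(config, run=replace(config.run, duration_s=duration_s))
    if duration_s is not None and duration_s <= discard_s:
        raise ParameterError("duration must exceed the discarded transient")
    result = run(config)
    stats = DistributionStats.from_weights(
        result.final_weights, config.run.g_max,
        equilibrated=is_equilibrated(result))
    return stats, result


def per_synapse_temporal_std(result: SimResult, window_s: float) -> np.ndarray:
    """Std over time of each synaptic weight within the final ``window_s``."""
    t = result.snapshot_times_ms / 1000.0
    sel = t >= t[-1] - window_s
    return result.weight_snapshots[sel].std(axis=0)


@dataclass
class SweepResult:
    """Per-AP-duration statistics of an equilibrium sweep."""

    ap_durations: np.ndarray
    stats: list            # DistributionStats per duration (median-seed run)
    mean_w: np.ndarray     # nS, median across seeds
    std_w: np.ndarray      # nS, median across seeds
    rate: np.ndarray       # Hz, median across seeds
    temporal_std: np.ndarray  # nS, median per-synapse std, median across seeds


def ap_duration_sweep(base_config: SimConfig, durations, seeds,
                      duration_s: float | None = None,
                      rate_window_s: float = 200.0,
                      temporal_window_s: float = 1000.0) -> SweepResult:
    """Equilibrium statistics across an AP-duration grid.

    For each duration and seed: run, record mean/std of the final weights,
    the steady-state output rate (1-s bins over the final ``rate_window_s``)
    and the median per-synapse temporal std over the final
    ``temporal_window_s`` of snapshots.  Medians are taken across seeds.
    """
    durations = np.asarray(sorted(durations), float)
    if durations.size < 2:
        raise ParameterError("need at least two AP durations")
    mean_w, std_w, rate, tstd, stats = [], [], [], [], []
    for d in durations:
        cfg_d = base_config.with_ap_duration(float(d))
        if duration_s is not None:
            cfg_d = replace(cfg_d, run=replace(cfg_d.run, duration_s=duration_s))
        m, s, r, ts = [], [], [], []
        last_stats = None
        for seed in seeds:
            res = run(cfg_d.with_seed(seed))
            m.append(res.final_weights.mean())
            s.append(res.final_weights.std())
            r.append(res.steady_rate(rate_window_s))
            ts.append(np.median(per_synapse_temporal_std(res, temporal_window_s)))
            last_stats = DistributionStats.from_weights(
                res.final_weights, cfg_d.run.g_max,
                equilibrated=is_equilibrated(res))
        stats.append(last_stats)
        mean_w.append(np.median(m))
        std_w.append(np.median(s))
        rate.append(np.median(r))
        tstd.append(np.median(ts))
    return SweepResult(durations, stats, np.array(mean_w), np.array(std_w),
                       np.array(rate), np.array(tstd))


def rate_vs_input_sweep(base_config: SimConfig, exc_rates, seeds,
                        rate_window_s: float = 200.0) -> np.ndarray:
    """Median steady-state output rate per excitatory input rate.

    Weights re-equilibrate from the initial condition at each input level;
    the inhibitory rate stays at its configured value.
    """
    out = []
    for r_in in exc_rates:
        cfg = replace(base_config,
                      inputs=replace(base_config.inputs, rate_exc=float(r_in)))
        rates = [run(cfg.with_seed(s)).steady_rate(rate_window_s) for s in seeds]
        out.append(float(np.median(rates)))
    return np.asarray(out)


@dataclass
class SignalNoiseResult:
    """Phase-resolved output of the signal/noise protocol."""

    result: SimResult
    phase_bounds_s: tuple[float, float]      # (signal on, signal off)
    rate_noise_pre: float                    # Hz, equilibrated noise-only
    rate_signal: float                       # Hz, plateau phase
    rate_noise_post: float                   # Hz, decay phase (signal removed)
    weights_pre: np.ndarray                  # snapshot just before signal on
    weights_signal: np.ndarray               # snapshot just before signal off
    weights_post: np.ndarray                 # final weights


def signal_noise_experiment(config: SimConfig, signal_on_s: float,
                            signal_off_s: float,
                            tail_window_s: float = 100.0) -> SignalNoiseResult:
    """Three-phase protocol: noise-only, noise+signal, noise-only.

    The synchronous signal defined by ``config.inputs`` (``sync_rate``,
    ``sync_fraction``) is applied during ``[signal_on_s, signal_off_s)``.
    Phase rates are means of the 1-s rate trace over the last
    ``tail_window_s`` of each phase (so the pre-signal value is the
    equilibrated noise response and the in-signal value the plateau rate).
    """
    if not (0 < signal_on_s < signal_off_s < config.run.duration_s):
        raise ParameterError("phases must satisfy 0 < on < off < duration")
    cfg = replace(config, run=replace(config.run,
                                      signal_window_s=(signal_on_s, signal_off_s)))
    res = run(cfg)
    tr, bs = res.rate_trace, res.rate_bin_s
    b_on, b_off = int(signal_on_s / bs), int(signal_off_s / bs)
    k = max(1, int(tail_window_s / bs))
    t_snap = res.snapshot_times_ms / 1000.0
    i_pre = int(np.searchsorted(t_snap, signal_on_s, side="right")) - 1
    i_sig = int(np.searchsorted(t_snap, signal_off_s, side="right")) - 1
    return SignalNoiseResult(
        result=res, phase_bounds_s=(signal_on_s, signal_off_s),
        rate_noise_pre=float(tr[max(0, b_on - k):b_on].mean()),
        rate_signal=float(tr[max(0, b_off - k):b_off].mean()),
        rate_noise_post=float(tr[-k:].mean()),
        weights_pre=res.weight_snapshots[i_pre],
        weights_signal=res.weight_snapshots[i_sig],
        weights_post=res.final_weights,
    )


def unbounded_run_stats(base_config: SimConfig, durations, seeds,
                        duration_s: float = 1000.0):
    """Below-bound fraction and maximum weight of unbounded additive runs.

    Returns ``(durations, below_bound_fraction, max_weight)`` where the
    fraction counts final weights <= g_max (mean across seeds) and the
    maximum is the largest weight attained anywhere in each run (median
    across seeds).
    """
    durations = np.asarray(sorted(durations), float)
    frac, mx = [], []
    for d in durations:
        cfg = base_config.with_ap_duration(float(d))
        cfg = replace(cfg, run=replace(cfg.run, bounded=False,
                                       duration_s=duration_s))
        fr, mm = [], []
        for s in seeds:
            res = run(cfg.with_seed(s))
            fr.append(np.mean(res.final_weights <= cfg.run.g_max))
            mm.append(res.max_weight)
        frac.append(float(np.mean(fr)))
        mx.append(float(np.median(mm)))
    return durations, np.asarray(frac), np.asarray(mx)
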