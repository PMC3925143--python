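"""Presynaptic input generation.

The postsynaptic cell is driven by independent homogeneous Poisson trains
on ``n_exc`` excitatory and ``n_inh`` inhibitory synapses, discretized to
the simulation grid: in each bin of width ``dt`` every synapse spikes
independently with probability ``rate * dt`` (Bernoulli-per-bin, so at most
one background spike per synapse per bin).  Optionally, population-wide
synchronous events ("signal") occur with per-bin probability
``sync_rate * dt``; at each event a fixed subset of ``round(f * n_exc)``
excitatory synapses each receive one additional spike, flagged ``is_sync``.
Synchronous spikes are additive: a member synapse may carry both its
background spike and the synchronous spike in the same bin.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .exceptions import ParameterError, ResolutionError

EXC, INH = 0, 1
_POP_NAMES = np.array(["exc", "inh"])


@dataclass
class InputConfig:
    """Input-ensemble parameters (rates in Hz, dt in ms)."""

    n_exc: int = 1000
    n_inh: int = 200
    rate_exc: float = 10.0
    rate_inh: float = 10.0
    sync_rate: float = 0.0       # Hz, rate of synchronous events
    sync_fraction: float = 0.0   # fraction of excitatory synapses per event
    resample_sync: bool = False  # resample the synchronized subset per event
    seed: int = 0
    dt: float = 0.1              # ms

    def __post_init__(self):
        if self.n_exc <= 0 or self.n_inh < 0:
            raise ParameterError("synapse counts must be positive")
        if min(self.rate_exc, self.rate_inh, self.sync_rate) < 0:
            raise ParameterError("rates must be >= 0")
        if not (0.0 <= self.sync_fraction <= 1.0):
            raise ParameterError("sync_fraction must lie in [0, 1]")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")

    @property
    def n_sync(self) -> int:
        return int(round(self.sync_fraction * self.n_exc))


@dataclass
class SpikeRaster:
    """Timestamped presynaptic events on the simulation grid.

    Events are stored per population as parallel arrays of bin indices and
    synapse indices, sorted by bin; excitatory events additionally carry an
    ``is_sync`` flag.  ``time_ms = bin * dt``.
    """

    dt: float
    n_bins: int
    n_exc: int
    n_inh: int
    exc_bins: np.ndarray   # int32, nondecreasing
    exc_idx: np.ndarray    # int32
    exc_sync: np.ndarray   # bool
    inh_bins: np.ndarray   # int32, nondecreasing
    inh_idx: np.ndarray    # int32

    @property
    def duration_ms(self) -> float:
        return self.n_bins * self.dt

    @property
    def n_events(self) -> int:
        return self.exc_bins.size + self.inh_bins.size

    def exc_times_ms(self) -> np.ndarray:
        return self.exc_bins * self.dt

    def inh_counts_per_bin(self) -> np.ndarray:
        return np.bincount(self.inh_bins, minlength=self.n_bins).astype(np.int32)

    def to_frame(self) -> pd.DataFrame:
        """Unified 4-column event table (time_ms, index, population, is_sync)."""
        t = np.concatenate([self.exc_bins * self.dt, self.inh_bins * self.dt])
        idx = np.concatenate([self.exc_idx, self.inh_idx])
        pop = np.concatenate([np.zeros(self.exc_bins.size, np.uint8),
                              np.ones(self.inh_bins.size, np.uint8)])
        sync = np.concatenate([self.exc_sync,
                               np.zeros(self.inh_bins.size, bool)])
        order = np.argsort(t, kind="stable")
        return pd.DataFrame({"time_ms": t[order], "index": idx[order],
                             "population": _POP_NAMES[pop[order]],
                             "is_sync": sync[order].astype(int)})

    def save_tsv(self, path) -> None:
        """Write as a headered TSV (gzip if the path ends in .gz)."""
        df = self.to_frame()
        header = (f"# dt_ms={self.dt} n_bins={self.n_bins} "
                  f"n_exc={self.n_exc} n_inh={self.n_inh}\n")
        buf = io.StringIO()
        buf.write(header)
        df.to_csv(buf, sep="\t", index=False)
        data = buf.getvalue()
        if str(path).endswith(".gz"):
            import gzip
            with gzip.open(path, "wt") as fh:
                fh.write(data)
        else:
            with open(path, "w") as fh:
                fh.write(data)

    @classmethod
    def load_tsv(cls, path) -> "SpikeRaster":
        opener = open
        if str(path).endswith(".gz"):
            import gzip
            opener = gzip.open
        with opener(path, "rt") as fh:
            meta_line = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in meta_line.split())
            df = pd.read_csv(fh, sep="\t")
        dt = float(meta["dt_ms"])
        bins = np.rint(df["time_ms"].to_numpy() / dt).astype(np.int32)
        is_exc = (df["population"] == "exc").to_numpy()
        order_e = np.argsort(bins[is_exc], kind="stable")
        order_i = np.argsort(bins[~is_exc], kind="stable")
        return cls(
            dt=dt, n_bins=int(meta["n_bins"]), n_exc=int(meta["n_exc"]),
            n_inh=int(meta["n_inh"]),
            exc_bins=bins[is_exc][order_e],
            exc_idx=df["index"].to_numpy(np.int32)[is_exc][order_e],
            exc_sync=df["is_sync"].to_numpy(bool)[is_exc][order_e],
            inh_bins=bins[~is_exc][order_i],
            inh_idx=df["index"].to_numpy(np.int32)[~is_exc][order_i],
        )


@njit(cache=False)
def _fill_indices(counts, pool, n_syn):  # pragma: no cover - exercised via wrapper
    """Assign distinct synapse indices within each bin from a random pool.

    ``counts[b]`` spikes fall in bin ``b``; candidate indices are consumed
    from ``pool`` and re-drawn (from the pool) on within-bin collision.
    Returns (idx, consumed) with consumed = -1 if the pool ran out.
    """
    total = 0
    for b in range(counts.size):
        total += counts[b]
    idx = np.empty(total, np.int32)
    p = 0
    pos = 0
    for b in range(counts.size):
        k = counts[b]
        start = pos
        for j in range(k):
            placed = False
            while p < pool.size:
                cand = pool[p]
                p += 1
                dup = False
                for m in range(start, pos):
                    if idx[m] == cand:
                        dup = True
                        break
                if not dup:
                    idx[pos] = cand
                    placed = True
                    break
            if not placed:
                return idx, -1
            pos += 1
    return idx, p


def _bernoulli_events(rng, n_bins, n_syn, p):
    """Bin/index arrays for per-bin Bernoulli spiking on ``n_syn`` synapses.

    Equivalent in distribution to drawing each (synapse, bin) Bernoulli(p):
    the per-bin count is Binomial(n_syn, p) and, given the count, the firing
    synapses are a uniform random distinct subset.
    """
    counts = rng.binomial(n_syn, p, size=n_bins).astype(np.int32)
    total = int(counts.sum())
    margin = total // 32 + 64
    while True:
        pool = rng.integers(0, n_syn, size=total + margin, dtype=np.int32)
        idx, consumed = _fill_indices(counts, pool, n_syn)
        if consumed >= 0:
            break
        margin *= 4  # vanishingly rare unless p*n_syn is extreme
    bins = np.repeat(np.arange(n_bins, dtype=np.int32), counts)
    return bins, idx


def poisson_raster(config: InputConfig, duration_ms: float) -> SpikeRaster:
    """Independent Poisson background on all synapses for ``duration_ms``.

    Reproducible for a fixed ``config.seed``; raises
    :class:`ResolutionError` when ``rate * dt > 0.1`` (the per-bin Bernoulli
    approximation of the Poisson process would be too coarse).
    """
    if duration_ms <= 0:
        raise ParameterError("duration must be > 0")
    p_exc = config.rate_exc * config.dt * 1e-3
    p_inh = config.rate_inh * config.dt * 1e-3
    if max(p_exc, p_inh) > 0.1:
        raise ResolutionError("rate * dt exceeds 0.1; reduce dt")
    n_bins = int(round(duration_ms / config.dt))
    rng = np.random.default_rng(config.seed)
    exc_bins, exc_idx = _bernoulli_events(rng, n_bins, config.n_exc, p_exc)
    inh_bins, inh_idx = _bernoulli_events(rng, n_bins, config.n_inh, p_inh)
    return SpikeRaster(
        dt=config.dt, n_bins=n_bins, n_exc=config.n_exc, n_inh=config.n_inh,
        exc_bins=exc_bins, exc_idx=exc_idx,
        exc_sync=np.zeros(exc_bins.size, bool),
        inh_bins=inh_bins, inh_idx=inh_idx,
    )


def add_synchronous_events(raster: SpikeRaster, config: InputConfig,
                           t_start_ms: float = 0.0,
                           t_stop_ms: float | None = None) -> SpikeRaster:
    """Overlay Poisson-timed synchronous events on the excitatory raster.

    Event times are drawn per bin with probability ``sync_rate * dt`` inside
    ``[t_start_ms, t_stop_ms)``; at each event the synchronized subset
    (indices ``0 .. n_sync - 1`` by default, held fixed across the run so a
    raster plot shows the same rows carrying the signal; resampled per event
    when ``resample_sync``) receives one spike each.  Background spikes are
    left untouched.  Uses a seed stream separate from the background so the
    noise realization is identical with and without the signal.
    """
    m = config.n_sync
    if config.sync_rate <= 0 or m == 0:
        return raster
    p = config.sync_rate * raster.dt * 1e-3
    if p > 0.1:
        raise ResolutionError("sync_rate * dt exceeds 0.1; reduce dt")
    b0 = int(round(t_start_ms / raster.dt))
    b1 = raster.n_bins if t_stop_ms is None else int(round(t_stop_ms / raster.dt))
    b0, b1 = max(b0, 0), min(b1, raster.n_bins)
    rng = np.random.default_rng([config.seed, 0x5F])
    ev_bins = b0 + np.nonzero(rng.random(b1 - b0) < p)[0].astype(np.int32)
    if ev_bins.size == 0:
        return raster
    if config.resample_sync:
        members = np.concatenate([
            rng.choice(config.n_exc, size=m, replace=False).astype(np.int32)
            for _ in range(ev_bins.size)])
    else:
        members = np.tile(np.arange(m, dtype=np.int32), ev_bins.size)
    sync_bins = np.repeat(ev_bins, m)
    bins = np.concatenate([raster.exc_bins, sync_bins])
    idx = np.concatenate([raster.exc_idx, members])
    sync = np.concatenate([raster.exc_sync, np.ones(sync_bins.size, bool)])
    order = np.argsort(bins, kind="stable")
    return replace(raster, exc_bins=bins[order], exc_idx=idx[order],
                   exc_sync=sync[order])
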