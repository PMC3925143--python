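import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dstdp
from dstdp.experiments import seed_stream

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rate_runs():
    """Five-seed additive runs at short (0.1 ms) and long (2.0 ms) AP
    duration with default parameters — the basic rate-regulation protocol,
    shared across the steady-rate, input-sweep and bounds tests.  The
    short-AP arm equilibrates within 1000 s; the long-AP arm approaches its
    asymptotic rate much more slowly and is run for 3000 s."""
    seeds = seed_stream(2024, 1, 5)
    out = {}
    for d, dur in ((0.1, 1000.0), (2.0, 3000.0)):
        out[d] = [
            dstdp.run(dstdp.default_config("additive", d,
                                           duration_s=dur).with_seed(s))
            for s in seeds
        ]
    return out


@pytest.fixture()
def tiny_raster():
    """Hand-buildable raster factory for oracle-level checks."""
    def build(pre_events, n_exc=10, n_bins=10000, dt=0.1):
        pre_events = sorted(pre_events)
        bins = np.array([b for b, _ in pre_events], np.int32)
        idx = np.array([i for _, i in pre_events], np.int32)
        return dstdp.SpikeRaster(
            dt=dt, n_bins=n_bins, n_exc=n_exc, n_inh=2,
            exc_bins=bins, exc_idx=idx,
            exc_sync=np.zeros(bins.size, bool),
            inh_bins=np.empty(0, np.int32), inh_idx=np.empty(0, np.int32))
    return build
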