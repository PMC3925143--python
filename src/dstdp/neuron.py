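"""Conductance-based leaky integrate-and-fire neuron with spike-frequency
adaptation and an explicit action-potential duration.

Membrane dynamics between spikes::

    C dV/dt = g_L (E_L - V) + g_exc (E_exc - V) + g_inh (E_inh - V)
              + g_adapt (E_adapt - V)

When ``V`` crosses the threshold from below at ``t0`` the neuron emits a
spike: ``V`` is held at the AP voltage ``V_ap`` for ``t in (t0, t0 + d]``
and then reset to ``V_reset``.  No new threshold crossing can occur during
the clamp (absolute refractoriness of length ``d``).  The adaptation
conductance jumps by ``delta_g_adapt`` at ``t0`` and decays with
``tau_adapt``; total synaptic conductances jump instantaneously on each
presynaptic arrival and decay with ``tau_syn``.

This module is the plain-Python reference semantics, stepped one time bin
at a time; :mod:`dstdp.simulator` contains a compiled kernel with the same
per-bin update order (conductance jumps -> integrate/threshold -> end-of-bin
reset and exponential decays) that is validated against it in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import NumericalInstabilityError, ParameterError


@dataclass
class NeuronParams:
    """Electrophysiological constants (pF, nS, mV, ms).

    Defaults give a 20 ms membrane time constant (C / g_L = 200 pF / 10 nS).
    ``v_ap`` (the clamp voltage during the AP) and ``delta_g_adapt`` do not
    enter the plasticity rule, which reads only spike times and the AP
    duration; ``v_ap = 0`` is a generic AP peak, and ``delta_g_adapt = 1 nS``
    keeps adaptation visible but subdominant to the leak.
    """

    capacitance: float = 200.0       # pF
    g_leak: float = 10.0             # nS
    v_threshold: float = -54.0       # mV
    e_leak: float = -70.0            # mV
    v_reset: float = -60.0           # mV
    e_adapt: float = -70.0           # mV
    tau_adapt: float = 100.0         # ms
    delta_g_adapt: float = 1.0       # nS
    e_exc: float = 0.0               # mV
    e_inh: float = -70.0             # mV
    tau_syn: float = 5.0             # ms
    ap_duration: float = 2.0         # ms
    v_ap: float = 0.0                # mV
    g_inh: float = 0.5               # nS, fixed (non-plastic) inhibitory strength

    def __post_init__(self):
        if self.capacitance <= 0 or self.g_leak <= 0:
            raise ParameterError("capacitance and g_leak must be > 0")
        if self.tau_syn <= 0 or self.tau_adapt <= 0:
            raise ParameterError("tau_syn and tau_adapt must be > 0")
        if self.ap_duration <= 0:
            raise ParameterError("ap_duration must be > 0")
        if self.v_threshold <= self.v_reset:
            raise ParameterError("v_threshold must exceed v_reset")

    @property
    def tau_membrane(self) -> float:
        """Passive membrane time constant C / g_L, ms."""
        return self.capacitance / self.g_leak


@dataclass
class NeuronState:
    """Mutable integration state.

    ``ap_steps_left`` counts the remaining clamp bins; ``ap_active`` and
    ``ap_end_time`` expose the same information in wall-clock terms for the
    refractory policy and for plasticity bookkeeping.
    """

    v: float = -70.0                 # mV
    g_adapt: float = 0.0             # nS
    g_exc_total: float = 0.0         # nS
    g_inh_total: float = 0.0         # nS
    t: float = 0.0                   # ms, time at the *start* of the next bin
    ap_steps_left: int = 0
    ap_end_time: float = -math.inf   # ms
    last_spike_onset: float = -math.inf

    @property
    def ap_active(self) -> bool:
        return self.ap_steps_left > 0


def refractory_policy(state: NeuronState, t: float) -> bool:
    """Whether the neuron may cross threshold at time ``t``.

    False while the membrane is clamped at the AP voltage; the neuron
    cannot re-spike during its own action potential.
    """
    return not state.ap_active


def step(state: NeuronState, params: NeuronParams, dt: float,
         exc_weight_sum: float = 0.0, inh_spike_count: int = 0) -> tuple[NeuronState, bool]:
    """Advance the neuron by one bin of length ``dt`` ms (in place).

    ``exc_weight_sum`` is the summed conductance (nS) of excitatory spikes
    arriving in this bin; ``inh_spike_count`` the number of inhibitory
    arrivals (each contributes ``g_inh``).  Within the bin: conductances
    jump, the membrane integrates by exponential Euler with the post-jump
    conductances held constant, the threshold is tested, and at the end of
    the bin the AP-end reset (if due) and the exponential conductance
    decays are applied.  Returns ``(state, spiked)``.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if dt > params.ap_duration + 1e-12:
        raise ParameterError("dt must not exceed the AP duration")
    if exc_weight_sum < 0 or inh_spike_count < 0:
        raise ParameterError("synaptic arrivals must be non-negative")

    state.g_exc_total += exc_weight_sum
    state.g_inh_total += inh_spike_count * params.g_inh

    spiked = False
    if state.ap_steps_left == 0:
        g_tot = params.g_leak + state.g_exc_total + state.g_inh_total + state.g_adapt
        v_inf = (params.g_leak * params.e_leak
                 + state.g_exc_total * params.e_exc
                 + state.g_inh_total * params.e_inh
                 + state.g_adapt * params.e_adapt) / g_tot
        state.v = v_inf + (state.v - v_inf) * math.exp(-g_tot * dt / params.capacitance)
        if not math.isfinite(state.v):
            raise NumericalInstabilityError(dt)
        if state.v >= params.v_threshold:
            spiked = True
            state.v = params.v_ap
            state.g_adapt += params.delta_g_adapt
            nd = round(params.ap_duration / dt)
            state.ap_steps_left = nd
            state.last_spike_onset = state.t
            state.ap_end_time = state.t + nd * dt
    else:
        state.v = params.v_ap

    # end of bin: AP-end reset (the nd bins after the crossing bin are
    # clamped; the crossing bin itself does not count down), then decays
    if not spiked and state.ap_steps_left > 0:
        state.ap_steps_left -= 1
        if state.ap_steps_left == 0:
            state.v = params.v_reset
    dec_syn = math.exp(-dt / params.tau_syn)
    state.g_exc_total *= dec_syn
    state.g_inh_total *= dec_syn
    state.g_adapt *= math.exp(-dt / params.tau_adapt)
    state.t += dt
    return state, spiked
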