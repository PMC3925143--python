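# Model and methods

## The plasticity rule

`dstdp` simulates pairwise spike-timing-dependent plasticity in which the
duration `d` of the postsynaptic action potential (AP) enters the pairing
window explicitly.  For a pre/post pair at interval
`Δt = t_post_onset − t_pre` (positive when the presynaptic spike comes
first), the unit weight change is

```
Δw(Δt; d) =  +A₊ · exp(−Δt/τ₊)            Δt > 0          (causal LTP tail)
             +A₊                          −d ≤ Δt ≤ 0     (plateau: pre during the AP)
             −B(d) · exp(−(|Δt|−d)/τ₋)    Δt < −d         (LTD, anchored at the AP end)
```

with `A₊ = 0.005`, `τ₊ = τ₋ = 20 ms`.  The plateau height equals `A₊` by
continuity with the `Δt → 0⁺` limit, and both boundaries of the plateau are
closed (a pair at `Δt = 0` or `Δt = −d` is potentiation — a
potentiation-favoring tie-break).

The depression peak

```
B(d) = r · A₊ · (τ₊ + d) / τ₋
```

is the unique value that keeps the **area ratio** of the depression lobe to
the potentiation lobe (exponential tail plus plateau) equal to the learning
ratio `r` for *every* AP duration, so changing `d` does not covertly change
the LTP/LTD balance of the window itself.  `window_integral_ratio`
recomputes this ratio by adaptive quadrature and equals `r` to better than
1e−9 for `d ∈ [0, 5] ms`.  At `d = 0` the window reduces to the canonical
two-exponential kernel with depression amplitude `r·A₊` — with `r = 1.05`
exactly the slightly depression-dominant window of classic competitive
additive STDP.  `r` is therefore defined here as the depression/potentiation
area ratio; this direction is forced by the dynamics: only a
depression-dominant window yields competitive bimodal equilibria, low
regulated output rates, and (in the mixed mode, see below) a stable interior
fixed point.

Two update modes:

* **additive** (`r = 1.05`): `Δw_abs = unit · g_max` for both signs —
  weight-independent steps, competition, bimodal equilibria;
* **mixed** (`r = 2`): additive potentiation, multiplicative depression
  `Δw_abs = unit · w`.  With `r` defined at `w = g_max`, the effective
  depression/potentiation ratio is `r·w/g_max`; it crosses 1 at
  `w* ≈ g_max·τ₊/(r(τ₊+d))`, giving a stable unimodal equilibrium near
  `g_max/2` that shifts slightly left as `d` grows.

Bounded runs clip each weight to `[0, g_max]` after every event; unbounded
runs clip only at 0.

## Pairing registration during the AP clamp

All-to-all pairing is implemented, but **presynaptic spikes that arrive
while the postsynaptic membrane is clamped at the AP voltage are not
registered by the pairing machinery** (their synaptic conductance jump
still occurs).  This refractory gating is a deliberate model choice with a
mean-field justification: for homogeneous Poisson inputs, a fully credited
plateau is harvested at exactly the rate (`A₊·r_pre·R·d` per synapse per
second) that cancels the growth of `B(d)`, leaving the net drift
`−(r−1)·A₊·(τ₊+d)·r_pre·R` almost independent of `d` — AP duration would
then have nearly no emergent effect.  With the gate, the duration-scaled
depression is effective and all the AP-duration phenomena appear: the
bimodal→unimodal transition of the weight distribution, the collapse of the
noise-driven output rate from ~7 Hz to ~0.1 Hz between `d = 0.1` and
`2.0 ms`, the mixed-mode leftward shift of the equilibrium and its ~60–75%
rate drop, and the duration-dependent taming of unbounded runs.  The gate
is exposed as `RunConfig.plateau_pairing`; setting it `True` restores full
plateau crediting (useful for studying the cancellation itself), and the
pairing oracle honors the same switch.  The idealized window above — what a
controlled pairing experiment would measure — always contains the plateau.

## Neuron

Single-compartment conductance-based leaky integrate-and-fire with
spike-triggered adaptation:

```
C dV/dt = g_L(E_L−V) + g_exc(E_exc−V) + g_inh(E_inh−V) + g_adapt(E_adapt−V)
```

On an upward threshold crossing at `t0`: `V` is held at `V_ap` for
`t ∈ (t0, t0+d]`, then reset to `V_reset`; `g_adapt += Δg_adapt` at `t0`
and decays with `τ_adapt`; no re-crossing during the clamp.  Synaptic
conductances jump instantaneously per arriving spike (`w_i` excitatory,
fixed `g_inh` inhibitory) and decay with `τ_syn`.

## Parameters

| parameter | symbol | default | note |
|---|---|---|---|
| membrane capacitance | C | 200 pF | τ_m = C/g_L = 20 ms |
| leak conductance | g_L | 10 nS | |
| threshold / rest / reset | V_th, E_L, V_reset | −54 / −70 / −60 mV | |
| adaptation | E_adapt, τ_adapt, Δg_adapt | −70 mV, 100 ms, 1 nS | Δg chosen so adaptation is visible but subdominant (steady g_adapt ≈ 0.75 nS at 7.5 Hz) |
| AP voltage | V_ap | 0 mV | plasticity reads only spike times and d, so any suprathreshold value is equivalent |
| reversals | E_exc, E_inh | 0 / −70 mV | standard values |
| synaptic decay | τ_syn | 5 ms | |
| AP duration | d | 2.0 ms | "short" = 0.1 ms, "long" = 2.0 ms throughout |
| window | A₊, τ₊, τ₋, r | 0.005, 20 ms, 20 ms, 1.05 / 2 | |
| inputs | N_exc, N_inh, rates | 1000, 200, 10 Hz each | homogeneous Poisson |
| synchrony | λ, f | 10 Hz, 0.1 (off by default) | signal experiments |
| reference conductance | g_max | 0.15 nS | calibrated, see below |
| initial weights | w_init | g_max/2 | uniform single value |
| time step | dt | 0.1 ms | resolves the shortest AP |

**Calibration of `g_max`.**  The weight scale is not identifiable from the
window alone; it was set once by a one-dimensional sweep so that the
short-AP additive mode equilibrates at the reference output rate of
~7.5 Hz under the default 10-Hz inputs (measured: 6.9–8.1 Hz depending on
run length; asymptotic 5-seed median 6.9 Hz at 3000 s).  Every other
reported quantity is emergent at this value.  Much smaller `g_max` cannot
ignite from `w_init = g_max/2` (the network is then silent and plasticity
never starts); much larger values lose the near-threshold regime in which
rate regulation operates.

## Discretization and event semantics

Time is binned at `dt = 0.1 ms`.  Within a bin the order is: conductance
jumps (using start-of-bin weights) → exponential-Euler membrane update with
the post-jump conductances held constant → threshold test → postsynaptic
plasticity → presynaptic plasticity → end-of-bin AP reset and conductance
decays.  A presynaptic spike in the same bin as the AP onset therefore
pairs at `Δt = 0`.  The AP duration is resolved to `nd = round(d/dt)`
steps: the crossing bin plus `nd` clamped bins, with the plateau covering
pre-spike bins `[b0, b0+nd]` and the depression trace incremented at
`t0 + nd·dt`.  Poisson generation is Bernoulli-per-bin (probability
`rate·dt`, guarded to ≤ 0.1), which is the construction the synchronous
events also use.

Plasticity traces (`x_i` per synapse for LTP, scalar `y` for LTD) are
decayed analytically between events, so the trace implementation equals the
chronological all-pairs sum up to float rounding; `brute_force_weight_oracle`
recomputes final weights pair-by-pair (grouped per event, postsynaptic
before presynaptic within a bin) and agrees with the simulator to < 1e−10
(additive) / 1e−8 (mixed) relative error on 1-s instances.  Clipping is
applied after each event, preserving the pairwise semantics.  Weight
snapshots are recorded every 10 s, output rates in 1-s bins.

## What the generator emulates — and what it does not

Inputs are homogeneous Poisson trains, optionally overlaid with
Poisson-timed synchronous volleys on a fixed subset of excitatory synapses
(background and volley spikes are additive, so a member synapse can carry
both in one bin).  Real presynaptic populations have slow rate
fluctuations, pairwise correlations, oscillations and short-term dynamics,
none of which are modeled; passing tests therefore demonstrate the rule's
emergent behavior under stationary uncorrelated noise plus idealized
synchrony, not its behavior under naturalistic input statistics.

## Problem sizes used in the suite and the acceptance script

Quantitative claims are evaluated as medians over 3–5 seeds.  Additive-mode
steady-state rates use 3000-s runs: near threshold the output rate keeps
relaxing long after the mean weight has settled (e.g. 9.0 Hz at 1000 s
vs 6.9 Hz at 3000 s for short APs), so rate convergence decides the run
length.  Mixed-mode arms sit at a weight-dependent fixed point and use
1000-s (tests: 600-s) runs.  The distribution-shape sweep uses 2500-s runs
over `d ∈ {0.1, 0.5, 1.0, 2.0} ms`; unbounded-run statistics use the full
3000-s protocol (the runaway tail only develops after ~1500 s); the
input-rate sweep uses 2500-s runs per level; oracle-equivalence instances
are 1 s.

## Known limitations

* Equilibration from weight configurations whose total drive is
  subthreshold is impossible (no spikes, no plasticity): the model needs an
  igniting initial condition, and recovery after a strong perturbation
  (e.g. removal of a synchronous signal that has concentrated the weight
  mass) is bootstrap-limited and can take several thousand simulated
  seconds.
* The input-rate dependence of the additive short-AP mode rises overall
  (~7 → ~11 Hz from 10 → 50 Hz) but shows a shallow dip at 20 Hz in this
  parameterization.
* Sarle's bimodality coefficient with the 5/9 benchmark is a deterministic
  but blunt shape statistic; histograms (and Hartigan's dip test, available
  via scipy ecosystems) should be consulted for borderline cases.
* Single postsynaptic neuron only; inhibitory weights are fixed; no
  short-term plasticity, triplet terms, or voltage dependence.
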