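"""The duration-dependent STDP (dSTDP) pairing window.

The weight change for a single pre/post spike pair is a function of the
pairing interval ``delta_t = t_post_onset - t_pre`` (positive when the
presynaptic spike precedes the postsynaptic action-potential onset) and of
the postsynaptic AP duration ``d``:

* ``delta_t > 0``            — potentiation ``+A+ * exp(-delta_t / tau+)``;
* ``-d <= delta_t <= 0``     — potentiation plateau ``+A+`` (the presynaptic
  spike arrives while the postsynaptic AP is still ongoing);
* ``delta_t < -d``           — depression ``-B(d) * exp(-(|delta_t| - d) / tau-)``,
  anchored at the end of the AP.

``B(d) = r * A+ * (tau+ + d) / tau-`` is the unique depression peak that
keeps the ratio of the depression lobe area to the potentiation lobe area
(including the plateau) equal to the learning ratio ``r`` for every AP
duration, so lengthening the AP does not silently change the LTP/LTD
balance.  With ``d = 0`` and ``tau+ = tau-`` this reduces to the canonical
two-exponential window with depression amplitude ``r * A+`` (depression
dominant for ``r > 1``, the classic competitive additive regime).

Two update modes are supported:

* ``additive`` — weight steps of fixed absolute size ``unit * g_max`` for
  both signs (competition, bimodal equilibria);
* ``mixed``    — additive potentiation, multiplicative depression
  ``unit * w``.  With ``r`` defined at ``w = g_max``, the effective
  depression/potentiation ratio is ``r * w / g_max``: below ``g_max / r``
  potentiation wins, above it depression wins, which yields a stable
  unimodal equilibrium around ``g_max / r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad

from .exceptions import ParameterError, StateCorruptionError

ADDITIVE = "additive"
MIXED = "mixed"

#: Learning ratio defaults per update mode (depression/potentiation areas).
DEFAULT_RATIO = {ADDITIVE: 1.05, MIXED: 2.0}


@dataclass
class WindowParams:
    """Constants of the dSTDP kernel.

    Parameters
    ----------
    a_plus : maximum potentiation amplitude, as a fraction of ``g_max``.
    tau_plus, tau_minus : potentiation / depression time constants, ms.
    ap_duration : postsynaptic AP duration ``d``, ms.
    ratio : learning ratio ``r`` (depression area / potentiation area;
        in mixed mode evaluated at ``w = g_max``).  ``None`` selects the
        mode default (1.05 additive, 2 mixed).
    mode : ``"additive"`` or ``"mixed"``.
    """

    a_plus: float = 0.005
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    ap_duration: float = 2.0
    ratio: float | None = None
    mode: str = ADDITIVE

    def __post_init__(self):
        if self.mode not in (ADDITIVE, MIXED):
            raise ParameterError(f"unknown update mode {self.mode!r}")
        if self.ratio is None:
            self.ratio = DEFAULT_RATIO[self.mode]
        if not (self.a_plus > 0):
            raise ParameterError("a_plus must be > 0")
        if not (self.tau_plus > 0 and self.tau_minus > 0):
            raise ParameterError("time constants must be > 0")
        if not (self.ap_duration >= 0):
            raise ParameterError("ap_duration must be >= 0")
        if not (self.ratio > 0):
            raise ParameterError("ratio must be > 0")

    def with_duration(self, d: float) -> "WindowParams":
        return replace(self, ap_duration=d)


def depression_amplitude(params: WindowParams) -> float:
    """Peak depression ``B(d) = r * A+ * (tau+ + d) / tau-``.

    The potentiation lobe has area ``A+ * (tau+ + d)`` (exponential tail
    plus plateau); an exponential depression lobe of peak ``B`` has area
    ``B * tau-``.  Requiring depression/potentiation = ``r`` for every AP
    duration gives the closed form above.  Affine and strictly increasing
    in ``d``.
    """
    return params.ratio * params.a_plus * (params.tau_plus + params.ap_duration) / params.tau_minus


def window_value(delta_t, params: WindowParams):
    """Evaluate the pairing window at interval(s) ``delta_t`` (ms).

    Convention: ``delta_t = t_post_onset - t_pre``; positive means the
    presynaptic spike arrived first.  ``delta_t`` in ``[-d, 0]`` (the
    presynaptic spike lands during the AP, boundaries included) returns the
    plateau value ``+a_plus``.  Returns a unit weight change (fraction of
    ``g_max`` for potentiation; for depression the fraction is of ``g_max``
    in additive mode and of the current weight in mixed mode — see
    :func:`apply_update`).
    """
    dt = np.asarray(delta_t, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ParameterError("delta_t must be finite")
    b = depression_amplitude(params)
    out = np.empty_like(dt)
    ltp = dt > 0
    plateau = (dt <= 0) & (dt >= -params.ap_duration)
    ltd = dt < -params.ap_duration
    out[ltp] = params.a_plus * np.exp(-dt[ltp] / params.tau_plus)
    out[plateau] = params.a_plus
    # anchored at the AP end: exponent is -(|dt| - d) / tau-
    out[ltd] = -b * np.exp((dt[ltd] + params.ap_duration) / params.tau_minus)
    if np.isscalar(delta_t):
        return float(out)
    return out


def apply_update(w, unit_change, g_max: float, params: WindowParams, bounded: bool = True):
    """Apply a unit weight change to conductance ``w`` (nS).

    Additive mode scales both signs by ``g_max``; mixed mode scales
    depression by the current weight (multiplicative LTD, with the fixed
    point ``w = 0``).  The result is clipped to ``[0, g_max]`` when bounded,
    to ``[0, inf)`` otherwise.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise StateCorruptionError("negative synaptic weight")
    if not (g_max > 0):
        raise ParameterError("g_max must be > 0")
    u = np.asarray(unit_change, dtype=float)
    if params.mode == MIXED:
        delta = np.where(u >= 0, u * g_max, u * w)
    else:
        delta = u * g_max
    new = np.maximum(w + delta, 0.0)
    if bounded:
        new = np.minimum(new, g_max)
    if np.isscalar(unit_change) and new.ndim == 0:
        return float(new)
    return new


def window_integral_ratio(params: WindowParams, half_range: float | None = None) -> float:
    """Quadrature check of the LTP/LTD area normalization.

    Integrates the two lobes of :func:`window_value` over
    ``[-half_range, half_range]`` ms (default: 25 time constants plus the
    plateau, so truncation stays below 1e-10 of either lobe) and returns
    the absolute depression/potentiation area ratio, which equals the
    learning ratio ``r`` for every AP duration by construction.
    """
    if half_range is None:
        half_range = 25.0 * max(params.tau_plus, params.tau_minus) + params.ap_duration
    f = lambda t: window_value(float(t), params)
    kw = dict(epsabs=1e-14, epsrel=1e-12, limit=200)
    ltp_tail = quad(f, 0.0, half_range, **kw)[0]
    plateau = quad(f, -params.ap_duration, 0.0, **kw)[0] if params.ap_duration > 0 else 0.0
    ltd = quad(f, -half_range, -params.ap_duration, **kw)[0]
    return abs(ltd) / (ltp_tail + plateau)


def kernel_table(params: WindowParams, t_min: float = -100.0, t_max: float = 100.0,
                 step: float = 0.1) -> np.ndarray:
    """Tabulate the window as an ``(n, 2)`` array of (delta_t ms, unit change)."""
    ts = np.arange(t_min, t_max + step / 2, step)
    return np.column_stack([ts, window_value(ts, params)])
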