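"""Deterministic FN-synapse core.

The synapse stores a weight as the differential potential of two tunneling
junctions, ``Wd = (W+ - W-)/2``, and its usage history as the common mode,
``Wc = (W+ + W-)/2``.  Both junctions leak through a Fowler-Nordheim barrier
with voltage slew ``J(W) = (k1/k2) W^2 exp(-k2/W)``, which makes the unforced
common mode follow the closed form ``Wc(t) = k2 / ln(k1 t + k0)``.

Dynamics advance only while an input pulse is applied; between pulses the
floating gates are non-volatile.  One pulse of width ``dt`` therefore maps to
one discrete update

    Wd(n) = alpha(n) * Wd(n-1) + u(n),

where ``u(n)`` is the coupled differential input step and the decay factor

    alpha(n) = 1 - (1 + 2/ln(k1*dt*n + k0)) / (n + gamma),

with ``gamma = k0/(k1*dt)``, approaches 1 as usage accumulates: the synapse
stiffens with use (metaplasticity).  Two input conventions are provided:

``apply_pulse``
    the raw recursion above; ``x_pulse`` is added with unit gain (the
    level-step form, total capacitance collapsed onto the coupling cap).
``apply_input_pulse``
    a physical return-to-zero pulse: the input couples in, the elevated state
    decays for one pulse width, the input couples out.  The net imprint is
    ``(1 - alpha) * (x - Wd)``, i.e. proportional to pulse width and
    attenuated by usage — the experimentally observed write behaviour.

``junction_pulse`` integrates the two junctions exactly (each junction's ODE
is autonomous while the pulse top is flat), which exposes the exponential
dependence of the write size on pulse magnitude and supplies the per-junction
voltage drops that the stochastic single-electron model converts to Poisson
rates.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .params import DeviceParams

__all__ = [
    "SynapseState",
    "tunneling_slew",
    "wc_closed_form",
    "decay_alpha",
    "alpha_from_wc",
    "apply_pulse",
    "apply_input_pulse",
    "junction_pulse",
    "decay_rate_r",
    "optimal_flow",
    "write_energy",
]

#: Wc values above this ceiling are clipped when a modulation increment is
#: applied (safety limit of the restore path, in volts).
WC_CEILING = 9.0

_EXP_MAX = 700.0  # exp argument guard; K saturates instead of overflowing


def _exp_k(wc, k2: float):
    """exp(k2/Wc), the integration constant matching the current usage."""
    wc = np.asarray(wc, dtype=float)
    if np.any(wc <= 0):
        raise ValueError("Wc must be strictly positive")
    return np.exp(np.minimum(k2 / wc, _EXP_MAX))


def tunneling_slew(w, params: DeviceParams):
    """FN tunneling flow expressed as a voltage slew (V/s).

    ``J(W) = (k1/k2) * W^2 * exp(-k2/W)``; strictly increasing in ``W``.
    The node capacitance is folded into ``k1`` so that ``dWc/dt = -J(Wc)``
    integrates to the ``wc_closed_form`` trajectory.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("junction potential must be strictly positive")
    out = (params.k1 / params.k2) * w**2 * np.exp(-params.k2 / w)
    return float(out) if out.ndim == 0 else out


def wc_closed_form(t, params: DeviceParams):
    """Unforced common-mode trajectory ``Wc(t) = k2 / ln(k1*t + k0)``.

    ``t`` counts accumulated pulse-active time (s); ``Wc(0) = Wc0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = params.k2 / np.log(params.k1 * t + params.k0)
    return float(out) if out.ndim == 0 else out


def decay_alpha(n, params: DeviceParams):
    """Discrete weight-decay factor ``alpha(n)`` after ``n`` pulses.

    ``alpha(n) = 1 - (1 + 2/ln(k1*dt*n + k0)) * 1/(n + gamma)`` with
    ``gamma = k0/(k1*dt)``; lies in (0, 1) and increases with ``n``.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    kdt = params.k1 * params.dt_pulse
    ln = np.log(kdt * n + params.k0)
    out = 1.0 - (1.0 + 2.0 / ln) / (n + params.gamma())
    return float(out) if out.ndim == 0 else out


def alpha_from_wc(wc, params: DeviceParams, width: float | None = None):
    """Decay factor and post-pulse usage for one pulse starting at ``wc``.

    Returns ``(alpha, wc_after)``.  ``K = exp(k2/Wc)`` plays the role of
    ``k1*t + k0`` in the closed form, so a synapse whose usage has been
    restored by modulation simply behaves as a younger one.
    """
    width = params.dt_pulse if width is None else width
    if np.any(np.asarray(width) < 0):
        raise ValueError("pulse width must be non-negative")
    K_end = _exp_k(wc, params.k2) + params.k1 * width
    ln = np.log(K_end)
    alpha = 1.0 - (1.0 + 2.0 / ln) * (params.k1 * width / K_end)
    return alpha, params.k2 / ln


@dataclasses.dataclass
class SynapseState:
    """Dynamic state of one FN-synapse (or an array of synapses).

    ``w_plus``/``w_minus`` are the single source of truth; the weight ``wd``
    and usage ``wc`` are always recomputed from them.  Fields may be scalars
    or numpy arrays of a common shape.
    """

    w_plus: np.ndarray | float
    w_minus: np.ndarray | float
    n_updates: np.ndarray | int = 0

    @classmethod
    def fresh(cls, params: DeviceParams, shape: tuple[int, ...] | None = None) -> "SynapseState":
        """Zero-weight state at the initial usage potential Wc0."""
        if shape is None:
            return cls(w_plus=params.Wc0, w_minus=params.Wc0, n_updates=0)
        w = np.full(shape, params.Wc0, dtype=float)
        return cls(w_plus=w.copy(), w_minus=w.copy(), n_updates=np.zeros(shape, dtype=np.int64))

    @property
    def wd(self):
        """Stored weight (V): (W+ - W-)/2."""
        return (self.w_plus - self.w_minus) / 2.0

    @property
    def wc(self):
        """Usage indicator (V): (W+ + W-)/2."""
        return (self.w_plus + self.w_minus) / 2.0

    def copy(self) -> "SynapseState":
        return SynapseState(
            w_plus=np.copy(self.w_plus) if isinstance(self.w_plus, np.ndarray) else self.w_plus,
            w_minus=np.copy(self.w_minus) if isinstance(self.w_minus, np.ndarray) else self.w_minus,
            n_updates=np.copy(self.n_updates) if isinstance(self.n_updates, np.ndarray) else self.n_updates,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        def _plain(x):
            return x.tolist() if isinstance(x, np.ndarray) else x

        payload = json.dumps(
            {
                "w_plus": _plain(self.w_plus),
                "w_minus": _plain(self.w_minus),
                "n_updates": _plain(self.n_updates),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SynapseState":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)

        def _load(x, dtype):
            return np.asarray(x, dtype=dtype) if isinstance(x, list) else x

        return cls(
            w_plus=_load(d["w_plus"], float),
            w_minus=_load(d["w_minus"], float),
            n_updates=_load(d["n_updates"], np.int64),
        )


def _clip_wc(wc):
    over = np.asarray(wc) > WC_CEILING
    if np.any(over):
        warnings.warn(
            f"modulation increment drove Wc above the {WC_CEILING} V ceiling; clipped",
            RuntimeWarning,
            stacklevel=4,
        )
        wc = np.minimum(wc, WC_CEILING)
        if np.ndim(wc) == 0:
            wc = float(wc)
    return wc


def _rebuild(state: SynapseState, wd, wc, m_increment) -> SynapseState:
    if np.any(np.asarray(m_increment) < 0):
        raise ValueError("modulation increment must be non-negative")
    wc = _clip_wc(wc + m_increment)
    return SynapseState(w_plus=wc + wd, w_minus=wc - wd, n_updates=state.n_updates + 1)


def add_modulation(state: SynapseState, increment) -> SynapseState:
    """Raise the usage potential by a modulation increment (clipped at the
    ceiling, with a warning); the weight and update count are untouched."""
    if np.any(np.asarray(increment) < 0):
        raise ValueError("modulation increment must be non-negative")
    wd, wc = state.wd, _clip_wc(state.wc + increment)
    return SynapseState(w_plus=wc + wd, w_minus=wc - wd, n_updates=state.n_updates)


def apply_pulse(
    state: SynapseState,
    x_pulse,
    m_increment=0.0,
    params: DeviceParams | None = None,
    width: float | None = None,
) -> SynapseState:
    """One discrete update in the level-step convention.

    ``wd <- alpha * wd + x_pulse``; the usage advances by one pulse width of
    closed-form decay and is then raised by ``m_increment`` (clipped at the
    safety ceiling).  ``x_pulse`` is the differential input step
    ``vin(n) - vin(n-1)`` with unit coupling gain.
    """
    if params is None:
        raise TypeError("params is required")
    alpha, wc_new = alpha_from_wc(state.wc, params, width)
    wd_new = alpha * state.wd + x_pulse
    return _rebuild(state, wd_new, wc_new, m_increment)


def apply_input_pulse(
    state: SynapseState,
    v_in,
    params: DeviceParams,
    width: float | None = None,
    m_increment=0.0,
) -> SynapseState:
    """One physical return-to-zero input pulse of coupled amplitude ``v_in`` (V).

    The input couples onto the weight, the elevated state decays for one
    pulse width, and the input couples back out:

        wd <- alpha * (wd + u) - u  =  alpha * wd + (1 - alpha) * v_in

    with ``u = -v_in`` in the wiring convention where a positive pulse
    potentiates.  The imprint ``(1 - alpha) * (v_in - wd)`` shrinks as usage
    accumulates and drives ``wd`` toward ``v_in``: bounded, metaplastic
    writes.
    """
    alpha, wc_new = alpha_from_wc(state.wc, params, width)
    wd_new = alpha * state.wd + (1.0 - alpha) * v_in
    return _rebuild(state, wd_new, wc_new, m_increment)


def junction_pulse(
    state: SynapseState,
    x_volts,
    params: DeviceParams,
    width: float | None = None,
):
    """Exact per-junction integration of one flat-top pulse.

    The differential input ``+/- x/2`` couples onto the junctions with ratio
    ``Cc/CT``; while the top is flat each junction's ODE ``dW/dt = -J(W)`` is
    autonomous and integrates in closed form.  A positive ``x`` elevates
    ``W-`` (potentiation: ``Wd`` increases).

    Returns ``(new_state, drop_plus, drop_minus)`` where the drops are the
    tunneling-induced potential losses of each junction (>= 0), the quantity
    the stochastic model quantizes into electron counts.
    """
    width = params.dt_pulse if width is None else width
    couple = (params.Cc / params.CT) * np.asarray(x_volts, dtype=float) / 2.0
    u_plus = state.w_plus - couple
    u_minus = state.w_minus + couple
    if np.any(np.asarray(u_plus) <= 0) or np.any(np.asarray(u_minus) <= 0):
        raise ValueError("coupled junction potential must stay positive")
    k1w = params.k1 * width
    end_plus = params.k2 / np.log(_exp_k(u_plus, params.k2) + k1w)
    end_minus = params.k2 / np.log(_exp_k(u_minus, params.k2) + k1w)
    drop_plus = u_plus - end_plus
    drop_minus = u_minus - end_minus
    new = SynapseState(
        w_plus=end_plus + couple,
        w_minus=end_minus - couple,
        n_updates=state.n_updates + 1,
    )
    return new, drop_plus, drop_minus


def decay_rate_r(t, wc):
    """Discrete plasticity-decay diagnostic ``r(t) = -Wc''(t) / Wc'(t)``.

    ``t`` and ``wc`` are matched samples of a (strictly monotone) usage
    trajectory; central differences on the possibly non-uniform grid.
    Returns ``(t_interior, r)`` at the interior samples.  For the FN closed
    form ``t * r(t) -> 1``: the hallmark of a synapse whose memory decays at
    the optimal 1/t rate.
    """
    t = np.asarray(t, dtype=float)
    wc = np.asarray(wc, dtype=float)
    if t.shape != wc.shape or t.ndim != 1:
        raise ValueError("t and wc must be 1-D arrays of equal length")
    if t.size < 5:
        raise ValueError("need at least 5 samples to estimate curvature")
    d = np.diff(wc)
    if not (np.all(d < 0) or np.all(d > 0)):
        warnings.warn("trajectory is not strictly monotone", RuntimeWarning, stacklevel=2)
    d1 = np.gradient(wc, t)
    d2 = np.gradient(d1, t)
    # the outermost two samples inherit one-sided-difference error from the
    # repeated gradient; report strictly interior estimates only
    r = -d2[2:-2] / d1[2:-2]
    return t[2:-2], r


def optimal_flow(wc, beta):
    """Flow function ``J(Wc) = (1/beta) Wc^2 exp(-beta/Wc)`` (V/s).

    The unique functional form for which the usage trajectory satisfies the
    optimal ``r(t) = O(1/t)`` decay; identical to ``tunneling_slew`` for
    ``k1 = 1, k2 = beta``.
    """
    wc = np.asarray(wc, dtype=float)
    if np.any(wc <= 0) or beta <= 0:
        raise ValueError("wc and beta must be strictly positive")
    out = (1.0 / beta) * wc**2 * np.exp(-beta / wc)
    return float(out) if out.ndim == 0 else out


def write_energy(cc: float, x_volts: float) -> float:
    """Energy drawn from the input source to charge the coupling cap (J).

    ``E = (1/2) * Cc * X^2``.  A differential pulse applied as ``+/- X/2``
    on two coupling capacitors dissipates ``2 * write_energy(Cc, X/2)``.
    """
    if cc <= 0:
        raise ValueError("coupling capacitance must be strictly positive")
    return 0.5 * cc * float(x_volts) ** 2
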