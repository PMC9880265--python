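"""Poisson single-electron tunneling model.

At low tunneling-node potentials each synaptic update is carried by a
handful of electrons, so the continuous model must be replaced by a counting
process: during the n-th pulse the number of electrons crossing each
junction is Poisson with mean

    lambda+- = CT * dW+-_det / q,

where ``dW+-_det`` is the deterministic per-junction voltage drop for that
pulse (the junction-level closed-form step) and ``q/CT`` is the voltage
quantum of one electron (0.1 uV at CT = 1.6 pF).  Each sampled electron
decrements its junction by exactly ``q/CT``; the capacitive input coupling
is applied as in the deterministic model.  In the high-tunneling regime
(nodes around 7 V, thousands of electrons per pulse) the stochastic
trajectory concentrates on the deterministic one.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .device import SynapseState, junction_pulse
from .params import DeviceParams


@dataclasses.dataclass
class StochasticStepRecord:
    """Bookkeeping for one stochastic pulse (per junction)."""

    lambda_plus: np.ndarray | float
    lambda_minus: np.ndarray | float
    e_plus: np.ndarray | int
    e_minus: np.ndarray | int
    dW_plus: np.ndarray | float  # == -q * e_plus / CT, exactly
    dW_minus: np.ndarray | float


def expected_electrons(
    state: SynapseState,
    params: DeviceParams,
    x_pulse=0.0,
    width: float | None = None,
):
    """Expected electron counts (lambda_plus, lambda_minus) for one pulse.

    ``lambda = CT * dW_det / q`` with ``dW_det`` the deterministic drop of
    the junction over the pulse; ``lambda * q / CT`` recovers the drop
    exactly.
    """
    _, drop_plus, drop_minus = junction_pulse(state, x_pulse, params, width)
    scale = params.CT / params.q
    return drop_plus * scale, drop_minus * scale


def stochastic_step(
    state: SynapseState,
    x_pulse,
    rng: np.random.Generator | int,
    params: DeviceParams,
    width: float | None = None,
):
    """One pulse with Poisson-quantized tunneling.

    Returns ``(new_state, StochasticStepRecord)``; reproducible for a given
    seed or Generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lam_p, lam_m = expected_electrons(state, params, x_pulse, width)
    e_p = rng.poisson(lam_p)
    e_m = rng.poisson(lam_m)
    quantum = params.q / params.CT
    dW_p = -quantum * e_p
    dW_m = -quantum * e_m
    new = SynapseState(
        w_plus=state.w_plus + dW_p,
        w_minus=state.w_minus + dW_m,
        n_updates=state.n_updates + 1,
    )
    rec = StochasticStepRecord(
        lambda_plus=lam_p, lambda_minus=lam_m, e_plus=e_p, e_minus=e_m,
        dW_plus=dW_p, dW_minus=dW_m,
    )
    return new, rec


def run_pulse_train(
    n_pulses: int,
    params: DeviceParams,
    seed,
    amplitude: float = 4.0,
    wc_init: float | None = None,
    stochastic: bool = True,
    signs: np.ndarray | None = None,
    width: float | None = None,
):
    """Drive one synapse with a random +/- pulse train.

    Returns ``(wd_trajectory, records)`` with ``wd_trajectory`` of length
    ``n_pulses + 1`` (including the initial state).  With
    ``stochastic=False`` the same train is run through the deterministic
    junction model (the lambda -> infinity limit).
    """
    rng = np.random.default_rng(seed)
    if signs is None:
        signs = rng.choice([-1.0, 1.0], size=n_pulses)
    state = (
        SynapseState.fresh(params)
        if wc_init is None
        else SynapseState(w_plus=float(wc_init), w_minus=float(wc_init), n_updates=0)
    )
    wd = [float(state.wd)]
    records = []
    for n in range(n_pulses):
        x = amplitude * signs[n]
        if stochastic:
            state, rec = stochastic_step(state, x, rng, params, width)
            records.append(rec)
        else:
            # deterministic branch must not advance the rng: `signs` was
            # drawn up front so both branches see the same train
            state, _, _ = junction_pulse(state, x, params, width)
        wd.append(float(state.wd))
    return np.asarray(wd), records


def compare_to_deterministic(
    n_pulses: int,
    params: DeviceParams,
    seed,
    amplitude: float = 4.0,
    wc_init: float = 7.0,
    width: float | None = None,
) -> float:
    """Max |Wd_stoch - Wd_det| (V) over one identical pulse train.

    Both models start from the same zero-weight state at ``wc_init`` and see
    the same random +/- pulse sequence.
    """
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=n_pulses)
    wd_det, _ = run_pulse_train(
        n_pulses, params, seed, amplitude, wc_init, stochastic=False, signs=signs, width=width
    )
    wd_sto, _ = run_pulse_train(
        n_pulses, params, seed, amplitude, wc_init, stochastic=True, signs=signs, width=width
    )
    return float(np.max(np.abs(wd_sto - wd_det)))


def trace_to_csv(records: list[StochasticStepRecord], wd, wc, path) -> None:
    """Export a per-pulse stochastic trace (one synapse) as CSV."""
    import pandas as pd

    pd.DataFrame(
        {
            "pulse_index": np.arange(1, len(records) + 1),
            "lambda_plus": [r.lambda_plus for r in records],
            "e_plus": [r.e_plus for r in records],
            "lambda_minus": [r.lambda_minus for r in records],
            "e_minus": [r.e_minus for r in records],
            "Wd": np.asarray(wd)[1:],
            "Wc": np.asarray(wc)[1:],
        }
    ).to_csv(path, index=False)
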