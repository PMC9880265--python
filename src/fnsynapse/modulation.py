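"""Plasticity modulation: staircase restore of the usage potential.

Without modulation the usage potential Wc only ever decreases, so the network
consolidates monotonically and, at capacity, suffers a blackout: it can
neither recall old patterns nor store new ones.  A global staircase voltage
``Vmod(t) = sum_i m(i) * delta(t - iT)`` injected through a coupling
capacitor restores part of the per-update Wc drop and converts blackout into
graceful forgetting.  The step sizes tried here mirror the profiles of the
consolidation experiments:

m0  constant Vmod — zero increments (pure consolidation / EWC-like).
m1, m2, m3  increment = 3/4, 1/2, 1/4 of the network-mean |dWd| of the
    latest update (a single global broadcast signal).
m4  alternates between the m0 rule and the m1 rule every ``switch_period``
    updates (oscillatory capacity).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .device import WC_CEILING, _exp_k
from .params import DeviceParams

KINDS = ("m0_constant", "fraction_of_mean_dwd", "periodic_switch")


@dataclasses.dataclass
class ModulationProfile:
    """Rule producing the per-update modulation increments m(i) (V)."""

    kind: str = "m0_constant"
    fraction: float = 0.0
    switch_period: int = 250
    increments_log: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.switch_period < 1:
            raise ValueError("switch_period must be >= 1")

    @property
    def cumulative(self) -> float:
        """Final height of the Vmod staircase (V)."""
        return float(np.sum(self.increments_log))


def profile_preset(name: str, switch_period: int = 250) -> ModulationProfile:
    """The named profiles m0..m4 (and 'none' as an alias of m0)."""
    table = {
        "none": ModulationProfile("m0_constant"),
        "m0": ModulationProfile("m0_constant"),
        "m1": ModulationProfile("fraction_of_mean_dwd", fraction=0.75),
        "m2": ModulationProfile("fraction_of_mean_dwd", fraction=0.5),
        "m3": ModulationProfile("fraction_of_mean_dwd", fraction=0.25),
        "m4": ModulationProfile("periodic_switch", fraction=0.75, switch_period=switch_period),
    }
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"unknown modulation profile {name!r}") from None


def compute_increment(profile: ModulationProfile, mean_abs_dwd: float, update_index: int) -> float:
    """Modulation increment (V) for one update; appended to the profile log.

    ``mean_abs_dwd`` is the network-wide mean |dWd| of the latest update.
    For ``periodic_switch`` the rule alternates m0/m1 phases of
    ``switch_period`` updates each, starting in the m0 phase.
    """
    if mean_abs_dwd < 0:
        raise ValueError("mean_abs_dwd must be non-negative")
    if profile.kind == "m0_constant":
        inc = 0.0
    elif profile.kind == "fraction_of_mean_dwd":
        inc = profile.fraction * mean_abs_dwd
    else:  # periodic_switch
        phase = (int(update_index) // profile.switch_period) % 2
        inc = 0.0 if phase == 0 else 0.75 * mean_abs_dwd
    profile.increments_log.append(inc)
    return inc


def wc_with_modulation(
    wc_at_last_increment: float,
    elapsed_pulses: int,
    increment: float,
    params: DeviceParams,
    ceiling: float = WC_CEILING,
):
    """Usage potential after ``elapsed_pulses`` of decay plus one increment.

    Between increments Wc follows the closed form re-anchored at the last
    increment (``K = exp(k2/Wc)`` is the matching integration constant); at
    the increment instant Wc jumps up by ``increment``, clipped (with a
    warning) at the safety ceiling.
    """
    if elapsed_pulses < 0:
        raise ValueError("elapsed_pulses must be non-negative")
    wc = np.asarray(wc_at_last_increment, dtype=float)
    if np.any(wc <= 0):
        raise ValueError("Wc must be strictly positive")
    K = _exp_k(wc, params.k2) + params.k1 * params.dt_pulse * elapsed_pulses
    evolved = params.k2 / np.log(K)
    from .device import _rebuild, SynapseState  # reuse the clip-and-warn path

    anchor = SynapseState(w_plus=evolved, w_minus=evolved, n_updates=0)
    out = _rebuild(anchor, 0.0, evolved, increment).wc
    return float(out) if np.ndim(out) == 0 else out


def export_increments_csv(profile: ModulationProfile, path) -> None:
    """Write (update_index, increment_volts) rows for the applied staircase."""
    import pandas as pd

    pd.DataFrame(
        {
            "update_index": np.arange(1, len(profile.increments_log) + 1),
            "increment_volts": profile.increments_log,
        }
    ).to_csv(path, index=False)
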