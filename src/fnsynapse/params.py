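"""Device parameters, named presets, and config-file handling.

A Fowler-Nordheim (FN) synapse is a pair of floating-gate tunneling junctions.
Its behaviour is fixed by a handful of constants:

``k1`` (1/s) and ``k2`` (V)
    prefactor and barrier constant of the FN tunneling law, expressed in the
    voltage-slew convention ``J(W) = (k1/k2) W^2 exp(-k2/W)`` [V/s].  The
    physical current divided by the total node capacitance is folded into
    ``k1`` so that the common-mode closed form ``Wc(t) = k2/ln(k1 t + k0)``
    solves the node equation without carrying the capacitance around.
``Wc0`` (V) and ``k0 = exp(k2/Wc0)``
    initial common-mode (usage) potential and the corresponding integration
    constant.  ``gamma = k0/(k1*dt_pulse)`` is the effective initial age of
    the synapse measured in pulses; the retrieval signal of a stored pattern
    decays as 1/(n + gamma).
``Cc``, ``Cfg``, ``CT = Cc + Cfg`` (F)
    input coupling, floating-gate, and total node capacitance.  ``q/CT`` is
    the voltage quantum of a single tunneling electron (0.1 uV at 1.6 pF).
``dt_pulse`` (s)
    width of one input pulse; FN dynamics advance only while a pulse is
    applied, the state is non-volatile in between.
``A`` (m^2)
    junction area; retained for documentation, the stochastic model derives
    its Poisson rates from the deterministic voltage drop instead.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import yaml

ELECTRON_CHARGE = 1.602176634e-19  # C

_REL_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class DeviceParams:
    """Physical/behavioral constants of one FN-synapse."""

    k1: float = 1.0e16
    k2: float = 8.0 * math.log(1.0e19)  # ~349.99 V
    k0: float = 1.0e19
    Wc0: float = 8.0
    Cc: float = 200e-15
    Cfg: float = 1.4e-12
    dt_pulse: float = 0.25
    A: float = 1.0e-12
    q: float = ELECTRON_CHARGE

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k0", "Wc0", "Cc", "Cfg", "dt_pulse", "A", "q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DeviceParams.{name} must be strictly positive")
        if not math.isclose(self.k0, math.exp(self.k2 / self.Wc0), rel_tol=_REL_TOL):
            raise ValueError(
                "inconsistent initial condition: k0 must equal exp(k2/Wc0) "
                f"(got k0={self.k0:.6e}, exp(k2/Wc0)={math.exp(self.k2 / self.Wc0):.6e})"
            )
        g = self.gamma()
        if not math.isfinite(g) or g <= 0:
            raise ValueError("gamma = k0/(k1*dt_pulse) must be finite and positive")

    @property
    def CT(self) -> float:
        """Total tunneling-node capacitance Cc + Cfg (F)."""
        return self.Cc + self.Cfg

    def gamma(self) -> float:
        """Effective initial age of the synapse, in pulses: k0/(k1*dt_pulse)."""
        return self.k0 / (self.k1 * self.dt_pulse)

    def replace(self, **kwargs) -> "DeviceParams":
        return dataclasses.replace(self, **kwargs)

    def with_wc0(self, wc0: float) -> "DeviceParams":
        """Re-initialize at a different tunneling-node potential (k2 fixed)."""
        return self.replace(Wc0=wc0, k0=math.exp(self.k2 / wc0))

    def with_gamma(self, gamma: float) -> "DeviceParams":
        """Re-initialize so that k0/(k1*dt_pulse) equals ``gamma`` (k2 fixed)."""
        k0 = gamma * self.k1 * self.dt_pulse
        return self.replace(k0=k0, Wc0=self.k2 / math.log(k0))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["CT"] = self.CT
        d["gamma"] = self.gamma()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceParams":
        d = dict(d)
        d.pop("gamma", None)
        ct = d.pop("CT", None)
        p = cls(**d)
        if ct is not None and not math.isclose(ct, p.CT, rel_tol=_REL_TOL):
            raise ValueError("CT must equal Cc + Cfg")
        return p


def preset(name: str) -> DeviceParams:
    """Named device presets.

    ``default``   Wc0 = 8 V, gamma ~ 4000 (250 ms pulses).
    ``characterization``  100 ms pulses as used for single-device sweeps.
    ``gamma1`` / ``gamma2``  representative lower/higher effective-age settings
        (gamma = 2000 / 8000), obtained by re-initializing Wc0.
    ``high_regime``  tunneling nodes at ~7 V: large electron counts per pulse,
        the continuous deterministic model is accurate.
    ``low_regime``   tunneling nodes at ~6 V: a handful of electrons per pulse,
        single-electron stochastic territory.
    """
    base = DeviceParams()
    presets = {
        "default": lambda: base,
        "characterization": lambda: base.replace(dt_pulse=0.1),
        "gamma1": lambda: base.with_gamma(2.0e3),
        "gamma2": lambda: base.with_gamma(8.0e3),
        "high_regime": lambda: base.with_wc0(7.0),
        "low_regime": lambda: base.with_wc0(6.0),
    }
    try:
        return presets[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}") from None


PRESET_NAMES = ("default", "characterization", "gamma1", "gamma2", "high_regime", "low_regime")


def load_params(path: str | Path) -> DeviceParams:
    """Load DeviceParams from a YAML or JSON config file.

    The file may either name a preset (``preset: gamma1``) or give explicit
    fields; explicit fields override the preset's values.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    base = preset(data.pop("preset", "default"))
    data.pop("gamma", None)  # derived quantities re-checked after merging
    ct = data.pop("CT", None)
    if not data and ct is None:
        return base
    unknown = set(data) - {f.name for f in dataclasses.fields(DeviceParams)}
    if unknown:
        raise ValueError(f"unknown device parameter keys: {sorted(unknown)}")
    merged = dataclasses.asdict(base)
    merged.update(data)
    if ct is not None:
        merged["CT"] = ct
    return DeviceParams.from_dict(merged)


def save_params(params: DeviceParams, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
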