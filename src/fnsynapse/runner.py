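"""Experiment drivers: characterization sweeps and the experiment dispatcher.

Every run writes its numeric outputs (CSV/JSON) plus a metadata record
(config echo, seed, package version) so that any result can be replayed
from its artifacts alone.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import __version__
from .benchmark import DEFAULT_AMPLITUDE, monte_carlo_snr, retained_experiment
from .continual import Hyper, build_task_stream, train_stream, usage_histogram
from .device import SynapseState, junction_pulse
from .modulation import export_increments_csv, profile_preset
from .params import DeviceParams, load_params, preset
from .stochastic import compare_to_deterministic, run_pulse_train, trace_to_csv


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def characterize(
    params: DeviceParams,
    pulse_widths,
    pulse_magnitudes,
    fixed_magnitude: float = 4.0,
    fixed_width: float = 0.1,
) -> dict:
    """Single-device response sweeps.

    From a fresh synapse, measure the write size |dWd| of one pulse as a
    function of (a) pulse width at fixed magnitude — linear response — and
    (b) pulse magnitude at fixed width — exponential response (the coupled
    junction potential enters the tunneling exponent).  Returns the sweep
    tables and the fitted coefficients with R^2.
    """
    widths = np.asarray(pulse_widths, dtype=float)
    mags = np.asarray(pulse_magnitudes, dtype=float)
    if widths.size == 0 or mags.size == 0:
        raise ValueError("sweep lists must be non-empty")

    dwd_w = []
    for w in widths:
        s, _, _ = junction_pulse(SynapseState.fresh(params), fixed_magnitude, params, width=w)
        dwd_w.append(abs(float(s.wd)))
    dwd_m = []
    for m in mags:
        s, _, _ = junction_pulse(SynapseState.fresh(params), m, params, width=fixed_width)
        dwd_m.append(abs(float(s.wd)))
    dwd_w = np.asarray(dwd_w)
    dwd_m = np.asarray(dwd_m)

    slope, intercept = np.polyfit(widths, dwd_w, 1)
    lin_r2 = _r2(dwd_w, slope * widths + intercept)

    def expo(x, c, a, d):
        return c * np.exp(a * x) + d

    a0 = (params.Cc / params.CT) / 2.0 * params.k2 / params.Wc0**2
    popt, _ = curve_fit(expo, mags, dwd_m, p0=(dwd_m[0], a0, 0.0), maxfev=20000)
    exp_r2 = _r2(dwd_m, expo(mags, *popt))

    return {
        "width_sweep": pd.DataFrame({"width_s": widths, "dwd_volts": dwd_w}),
        "magnitude_sweep": pd.DataFrame({"magnitude_volts": mags, "dwd_volts": dwd_m}),
        "linear_fit": {"slope": float(slope), "intercept": float(intercept), "r2": float(lin_r2)},
        "exponential_fit": {
            "c": float(popt[0]), "a": float(popt[1]), "d": float(popt[2]), "r2": float(exp_r2),
        },
    }


@dataclasses.dataclass
class RunConfig:
    """One experiment run: which driver, which device, seed, and outputs."""

    experiment: str  # characterize | consolidate | modulate | stochastic | continual
    device_preset: str = "default"
    device_overrides: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"
    options: dict = dataclasses.field(default_factory=dict)

    def device(self) -> DeviceParams:
        p = preset(self.device_preset)
        if self.device_overrides:
            d = dataclasses.asdict(p)
            unknown = set(self.device_overrides) - set(d)
            if unknown:
                raise ValueError(f"unknown device parameter keys: {sorted(unknown)}")
            d.update(self.device_overrides)
            p = DeviceParams.from_dict(d)
        return p


EXPERIMENTS = ("characterize", "consolidate", "modulate", "stochastic", "continual")


def run_experiment(config: RunConfig) -> dict:
    """Dispatch one experiment and write its artifacts.

    Returns a summary dict (also written as ``<experiment>_meta.json``).
    """
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; choose from {EXPERIMENTS}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.device()
    opt = dict(config.options)
    summary: dict = {}

    if config.experiment == "characterize":
        widths = opt.get("pulse_widths") or list(np.linspace(0.01, 0.5, 20))
        mags = opt.get("pulse_magnitudes") or list(np.linspace(2.0, 6.0, 20))
        res = characterize(params, widths, mags)
        res["width_sweep"].to_csv(out / "width_sweep.csv", index=False)
        res["magnitude_sweep"].to_csv(out / "magnitude_sweep.csv", index=False)
        summary = {"linear_fit": res["linear_fit"], "exponential_fit": res["exponential_fit"]}

    elif config.experiment == "consolidate":
        trace = monte_carlo_snr(
            N=opt.get("N", 100),
            n_patterns=opt.get("patterns", 100),
            n_runs=opt.get("mc_runs", 1000),
            params=params,
            seed=config.seed,
            pulse_amplitude=opt.get("pulse_amplitude", DEFAULT_AMPLITUDE),
            track_p=opt.get("track_p", 1),
        )
        trace.to_frame().to_csv(out / "consolidate.csv", index=False)
        summary = {
            "N": trace.N, "n_runs": trace.n_runs, "gamma": trace.gamma,
            "final_snr_mc": float(trace.snr_mc[-1]),
            "final_snr_analytic": float(trace.snr_analytic[-1]),
        }

    elif config.experiment == "modulate":
        name = opt.get("profile", "m1")
        profile = None if name in ("none",) else profile_preset(
            name, switch_period=opt.get("switch_period", 250)
        )
        retained, result = retained_experiment(
            N=opt.get("N", 1000),
            n_patterns=opt.get("patterns", 2000),
            profile=profile,
            params=params,
            seed=config.seed,
            pulse_amplitude=opt.get("pulse_amplitude", DEFAULT_AMPLITUDE),
        )
        pd.DataFrame({"n": np.arange(1, retained.size + 1), "retained": retained}).to_csv(
            out / "retained.csv", index=False
        )
        if profile is not None:
            export_increments_csv(profile, out / "increments.csv")
        summary = {
            "profile": name, "max_retained": int(retained.max()),
            "final_retained": int(retained[-1]), "final_wc": float(result.wc_trajectory[-1]),
        }

    elif config.experiment == "stochastic":
        n_pulses = opt.get("pulses", 100)
        wc_init = opt.get("wc_init", 7.0)
        amplitude = opt.get("pulse_amplitude", 4.0)
        wd, recs = run_pulse_train(
            n_pulses, params, config.seed, amplitude=amplitude, wc_init=wc_init
        )
        wc = [wc_init] * (len(wd))  # common mode moves by < 1 uV in this regime
        trace_to_csv(recs, wd, wc, out / "stochastic_trace.csv")
        devs = [
            compare_to_deterministic(n_pulses, params, config.seed + i, amplitude, wc_init)
            for i in range(opt.get("n_seeds", 20))
        ]
        summary = {
            "max_deviation_volts": float(np.max(devs)),
            "median_deviation_volts": float(np.median(devs)),
            "n_seeds": opt.get("n_seeds", 20),
        }

    elif config.experiment == "continual":
        scheme = opt.get("scheme", "split")
        method = opt.get("method", "fn_sgd")
        stream = build_task_stream(opt.get("source", "synthetic"), scheme, seed=config.seed)
        hyper = Hyper(seed=config.seed, **opt.get("hyper", {}))
        am = train_stream(stream, method, hyper, device_params=params, record_usage=True)
        am.to_json(out / "accmatrix.json")
        if am.fn_weights is not None:
            rows = []
            for layer in range(len(am.fn_weights.states)):
                counts, edges = usage_histogram(am.fn_weights, layer)
                for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
                    rows.append({"layer": layer, "wc_lo": lo, "wc_hi": hi, "count": int(c)})
            pd.DataFrame(rows).to_csv(out / "wc_histograms.csv", index=False)
        summary = {"method": method, "scheme": scheme, "overall_average": am.overall_average}

    meta = {
        "experiment": config.experiment,
        "seed": config.seed,
        "version": __version__,
        "device": params.to_dict(),
        "options": {k: v for k, v in opt.items()},
        "summary": summary,
    }
    (out / f"{config.experiment}_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return meta
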