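"""Random binary pattern consolidation benchmark.

``n`` uncorrelated +/-1 patterns are imprinted, one pulse per synapse per
pattern, on a network of ``N`` FN-synapses that starts with zero weight.
The strength of the tracked pattern ``p`` after ``n`` patterns is measured
by the retrieval signal

    S(n, p) = (1/N) < sum_a Wd(a, n) * vin(a, p) >,

its noise by the cross-talk of the other stored patterns, and the memory
survives while SNR = S/nu exceeds a threshold (unity here).  For the FN
device the per-pattern retention coefficient is (1 - alpha(p)) * prod_j
alpha(j), whose magnitude is ~ 1/(n + gamma), giving the analytic power law

    S ~ 1/(n + gamma),   nu^2 ~ n / (N (n + gamma)^2),   SNR = sqrt(N / n):

memory lifetime and capacity scale linearly with network size and are
independent of the device constant gamma.

The Monte-Carlo driver reports two noise estimates: the ensemble standard
deviation of the retrieval signal (``nu_mc``) and the pooled per-pattern
noise ``sqrt((1/N) sum_i S_mc(n,i)^2)`` (``nu_pooled``), which matches the
analytic convention of including the tracked pattern's own term; ``snr_mc``
uses the latter so it is directly comparable to sqrt(N/n).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .device import SynapseState, add_modulation, alpha_from_wc, apply_input_pulse, decay_alpha
from .modulation import ModulationProfile, compute_increment
from .params import DeviceParams

#: Default pulse amplitude (V): the first imprint of a fresh synapse,
#: (1 - alpha(1)) * x, is then ~300 uV — the detectability criterion used
#: when initializing the hardware.
DEFAULT_AMPLITUDE = 1.15


@dataclasses.dataclass
class PatternEnsemble:
    """N x n matrix of +/-1 inputs plus the pulse encoding."""

    values: np.ndarray  # (N, n) of +/-1
    pulse_amplitude: float = DEFAULT_AMPLITUDE
    seed: int | None = None
    balanced: bool = False

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.values.shape[1]


def generate_patterns(
    N: int,
    n: int,
    seed=None,
    balanced: bool = False,
    pulse_amplitude: float = DEFAULT_AMPLITUDE,
) -> PatternEnsemble:
    """Draw an ensemble of uncorrelated random +/-1 patterns.

    ``balanced=True`` gives each synapse exactly n/2 potentiation and n/2
    depression pulses (a random permutation per row); note that this makes
    the entries of a row anticorrelated, which suppresses the tracked
    retrieval signal once n approaches the row length — the SNR experiments
    therefore default to i.i.d. patterns.
    """
    if N < 1 or n < 1:
        raise ValueError("N and n must be >= 1")
    rng = np.random.default_rng(seed)
    if balanced:
        if n % 2:
            raise ValueError("balanced patterns require an even number of patterns")
        row = np.concatenate([np.ones(n // 2, dtype=np.int8), -np.ones(n // 2, dtype=np.int8)])
        values = np.stack([rng.permutation(row) for _ in range(N)])
    else:
        values = rng.choice(np.array([-1, 1], dtype=np.int8), size=(N, n))
    return PatternEnsemble(values=values, pulse_amplitude=pulse_amplitude, seed=seed, balanced=balanced)


@dataclasses.dataclass
class ConsolidationResult:
    """Full trajectory of one consolidation run."""

    wd_history: np.ndarray  # (N, n) volts, after each pattern
    wc_trajectory: np.ndarray  # (n,) volts, after each pattern
    alphas: np.ndarray  # (n,) realized decay factors
    increments: np.ndarray  # (n,) applied modulation increments (V)


def run_consolidation(
    ensemble: PatternEnsemble,
    params: DeviceParams,
    profile: ModulationProfile | None = None,
) -> ConsolidationResult:
    """Imprint every pattern column with one pulse per synapse.

    All synapses start empty (zero weight at Wc0).  Every synapse receives a
    pulse for every pattern and the modulation signal is global, so the
    usage trajectory is shared across the network.  With a profile, the
    increment after each update is ``fraction x`` the network-mean |dWd| of
    that update.
    """
    N, n = ensemble.N, ensemble.n_patterns
    amp = ensemble.pulse_amplitude
    state = SynapseState.fresh(params, shape=(N,))
    wd_hist = np.empty((N, n))
    wc_traj = np.empty(n)
    alphas = np.empty(n)
    increments = np.zeros(n)
    for k in range(n):
        alphas[k] = alpha_from_wc(float(state.wc[0]), params)[0]
        wd_before = state.wd
        state = apply_input_pulse(state, amp * ensemble.values[:, k], params)
        if profile is not None:
            # modulation follows the differential update, sized from the
            # network-mean update magnitude of this very step
            mean_dwd = float(np.mean(np.abs(state.wd - wd_before)))
            inc = compute_increment(profile, mean_dwd, k)
            state = add_modulation(state, inc)
            increments[k] = inc
        wd_hist[:, k] = state.wd
        wc_traj[k] = float(state.wc[0])
    return ConsolidationResult(wd_hist, wc_traj, alphas, increments)


def retrieval_signal(weights_at_n, pattern_p, pulse_amplitude: float = 1.0) -> float:
    """``(1/N) sum_a Wd(a,n) * vin(a,p)`` with ``vin = amplitude * pattern``."""
    w = np.asarray(weights_at_n, dtype=float)
    v = np.asarray(pattern_p, dtype=float)
    if w.shape != v.shape:
        raise ValueError("weights and pattern must have equal length")
    return float(np.mean(w * pulse_amplitude * v))


def analytic_signal(n: int, p: int, params: DeviceParams):
    """Retention coefficient of pattern ``p`` after ``n`` patterns.

    Returns ``(exact, simplified)``: the exact product form
    ``(alpha(p+1) - 1) * prod_{j=p+2}^{n} alpha(j)`` (signed; the empty
    product is 1) and the simplified magnitude ``1/(n + gamma)``.  The two
    agree within ~10% because ``1 + 2/ln(k1*dt*n + k0) ~ 1`` for these
    parameter magnitudes.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if p > n:
        raise ValueError("p must not exceed n")
    exact = decay_alpha(p + 1, params) - 1.0
    if n >= p + 2:
        j = np.arange(p + 2, n + 1)
        exact *= float(np.exp(np.sum(np.log(decay_alpha(j, params)))))
    simplified = 1.0 / (n + params.gamma())
    return float(exact), float(simplified)


def analytic_noise(n: int, N: int, params: DeviceParams) -> float:
    """Cross-talk noise ``nu = sqrt(n/N) / (n + gamma)`` (tracked term included)."""
    if n < 1 or N < 1:
        raise ValueError("n and N must be >= 1")
    return float(np.sqrt(n / N) / (n + params.gamma()))


def analytic_snr(n, N) -> float | np.ndarray:
    """``SNR(n, p) = sqrt(N / n)``: independent of gamma and of the tracked p."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    out = np.sqrt(N / n)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class SNRTrace:
    """Monte-Carlo + analytic signal/noise/SNR curves for one tracked pattern."""

    n: np.ndarray  # observation times (number of patterns seen)
    s_mc: np.ndarray  # ensemble-mean retrieval signal (dimensionless)
    nu_mc: np.ndarray  # ensemble std of the retrieval signal
    nu_pooled: np.ndarray  # sqrt((1/N) sum_i S_mc(n,i)^2), analytic convention
    snr_mc: np.ndarray  # |s_mc| / nu_pooled
    s_analytic: np.ndarray
    nu_analytic: np.ndarray
    snr_analytic: np.ndarray
    gamma: float
    N: int
    n_runs: int
    track_p: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": self.n,
                "p": self.track_p,
                "S_analytic": self.s_analytic,
                "S_mc": self.s_mc,
                "nu_analytic": self.nu_analytic,
                "nu_mc": self.nu_mc,
                "nu_pooled": self.nu_pooled,
                "snr_analytic": self.snr_analytic,
                "snr_mc": self.snr_mc,
            }
        )


def monte_carlo_snr(
    N: int,
    n_patterns: int,
    n_runs: int,
    params: DeviceParams,
    seed=0,
    pulse_amplitude: float = DEFAULT_AMPLITUDE,
    track_p: int = 1,
    pooled_noise: bool = True,
) -> SNRTrace:
    """Monte-Carlo estimate of S, nu, SNR versus n for the tracked pattern.

    Simulates ``n_runs`` independent networks of ``N`` synapses.  Because no
    modulation is applied and every synapse is pulsed at every pattern, the
    usage trajectory is shared, so the per-step decay factors are the
    closed-form ``alpha(k)`` and the weight recursion is applied to the
    whole (runs x N) block at once (equivalent to iterating
    ``apply_input_pulse``; tested against it).

    With ``pooled_noise=False`` the pooled estimator is skipped (cheaper;
    ``snr_mc`` then falls back to the variance-based estimator with the
    tracked term added back: ``|S| / sqrt(var + S^2/N)``).
    """
    if not 1 <= track_p <= n_patterns:
        raise ValueError("track_p must lie in [1, n_patterns]")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, n_patterns + 1)
    alphas = decay_alpha(ks, params)
    R = np.zeros((n_runs, N), dtype=np.float64)
    ip = track_p - 1
    # the full pattern tensor is only needed for the pooled-noise estimator;
    # otherwise draw patterns on the fly and keep just the tracked column
    V = None
    if pooled_noise:
        V = rng.choice(np.array([-1.0, 1.0], dtype=np.float32), size=(n_runs, N, n_patterns))
    v_tracked = None

    s_sum = np.zeros(n_patterns)
    s_sqsum = np.zeros(n_patterns)
    pooled = np.full(n_patterns, np.nan)
    for k in range(n_patterns):
        a = alphas[k]
        if V is not None:
            v_k = V[:, :, k]
        else:
            v_k = rng.choice(np.array([-1.0, 1.0], dtype=np.float32), size=(n_runs, N))
        if k == ip:
            v_tracked = v_k
        # dimensionless weights: the pulse amplitude cancels from S/nu
        R = a * R + (1.0 - a) * v_k
        q_tracked = (R * v_tracked).mean(axis=1) if v_tracked is not None else np.zeros(n_runs)
        s_sum[k] = q_tracked.sum()
        s_sqsum[k] = (q_tracked**2).sum()
        if pooled_noise and k >= ip:
            # projections of every run's weights onto all patterns seen so far
            q_all = np.matmul(R[:, None, :].astype(np.float32), V[:, :, : k + 1]) / N
            s_all = q_all[:, 0, :].mean(axis=0)
            pooled[k] = float(np.sqrt(np.mean(s_all**2) * (k + 1) / N))

    s_mc = s_sum / n_runs
    var = s_sqsum / n_runs - s_mc**2
    nu_mc = np.sqrt(np.maximum(var, 0.0))
    if pooled_noise:
        nu_for_snr = pooled
    else:
        nu_for_snr = np.sqrt(np.maximum(var, 0.0) + s_mc**2 / N)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_mc = np.abs(s_mc) / nu_for_snr

    s_an = np.array([abs(analytic_signal(int(n), track_p, params)[0]) if n >= track_p else np.nan for n in ks])
    nu_an = np.array([analytic_noise(int(n), N, params) for n in ks])
    snr_an = analytic_snr(ks, N)
    return SNRTrace(
        n=ks, s_mc=np.abs(s_mc), nu_mc=nu_mc, nu_pooled=pooled, snr_mc=snr_mc,
        s_analytic=s_an, nu_analytic=nu_an, snr_analytic=np.asarray(snr_an),
        gamma=params.gamma(), N=N, n_runs=n_runs, track_p=track_p,
    )


def capacity_lifetime(
    N: int,
    params: DeviceParams,
    n_runs: int = 600,
    seed=0,
    n_max: int | None = None,
    pulse_amplitude: float = DEFAULT_AMPLITUDE,
) -> int:
    """Memory lifetime n*: first n at which the empirical SNR drops below 1.

    The analytic prediction is n* = N (SNR = sqrt(N/n)); the estimate uses
    the cheap variance-based SNR with the tracked term added back.
    """
    n_max = n_max or int(1.8 * N)
    trace = monte_carlo_snr(
        N, n_max, n_runs, params, seed=seed, pulse_amplitude=pulse_amplitude, pooled_noise=False
    )
    below = np.nonzero((trace.snr_mc < 1.0) & (trace.n >= 5))[0]
    if below.size == 0:
        raise RuntimeError(f"SNR never crossed 1 within n_max={n_max}; increase n_max")
    return int(trace.n[below[0]])


def modulated_snr_matrix(
    result: ConsolidationResult,
    N: int,
) -> np.ndarray:
    """SNR(n, p) for every pattern p and observation n from realized alphas.

    Uses the analytic retention coefficients of the realized (possibly
    modulated) decay sequence:  S(n,p) = (1-alpha_p) * prod_{j>p} alpha_j,
    nu^2(n) = (1/N) sum_{i<=n} S(n,i)^2.  Computed in the log domain; the
    (p, n) entry is SNR of pattern p at observation n (0 where p > n).
    """
    la = np.log(result.alphas)
    A = np.cumsum(la)  # A[k] = sum_{j<=k+1} ln alpha_j
    b = np.log1p(-result.alphas)  # ln(1 - alpha_p)
    v = 2.0 * (b - A)  # pattern-quality exponent, p = 1..n
    L = np.logaddexp.accumulate(v)  # ln sum_{i<=n} e^{v_i}
    n_tot = v.size
    # L(n) >= v_p for p <= n, so the exponent is bounded by ln(N)/2: no overflow
    snr = np.exp(0.5 * (np.log(N) + v[:, None] - L[None, :]))
    snr[np.tril_indices(n_tot, k=-1)] = 0.0  # pattern p does not exist before n = p
    return snr


def patterns_retained(snr_by_pattern: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Count, per observation time, the patterns whose SNR exceeds threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    m = np.asarray(snr_by_pattern, dtype=float)
    return (m > threshold).sum(axis=0)


def retained_experiment(
    N: int,
    n_patterns: int,
    profile: ModulationProfile | None,
    params: DeviceParams,
    seed=0,
    pulse_amplitude: float = DEFAULT_AMPLITUDE,
):
    """#patterns-retained versus time for one modulation profile.

    Returns ``(retained_counts, result)`` where ``retained_counts[k]`` is
    the number of stored patterns with SNR > 1 after k+1 updates.
    """
    ens = generate_patterns(N, n_patterns, seed=seed, pulse_amplitude=pulse_amplitude)
    result = run_consolidation(ens, params, profile)
    snr = modulated_snr_matrix(result, N)
    return patterns_retained(snr), result
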