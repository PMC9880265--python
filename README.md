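# fnsynapse

A behavioral simulator for **Fowler–Nordheim (FN) tunneling synapses**:
analog floating-gate memory elements whose *plasticity decays with usage at
the optimal ~1/t rate*, so that a network of them consolidates memories the
way theory says a bounded synapse should.

## Who this is for

Researchers in neuromorphic engineering and computational neuroscience who
want to study synaptic memory consolidation, metaplasticity, and continual
learning with a physically grounded device model — without fabricating the
device. Everything runs from parameters and synthetic inputs; no external
data is required.

## The model

An FN-synapse is a pair of floating-gate tunneling junctions with potentials
W⁺ and W⁻. The **weight** is the differential component and the **usage**
the common mode:

    Wd = (W⁺ − W⁻)/2,      Wc = (W⁺ + W⁻)/2.

Each junction leaks through an FN barrier with voltage slew
`J(W) = (k1/k2)·W²·exp(−k2/W)`, which makes the unforced usage follow

    Wc(t) = k2 / ln(k1·t + k0),        k0 = exp(k2/Wc0),

and gives the weight the discrete update rule (one input pulse of width Δt
per update, the state frozen in between):

    Wd(n) = α(n)·Wd(n−1) + u(n),
    α(n)  = 1 − (1 + 2/ln(k1·Δt·n + k0)) / (n + γ),      γ = k0/(k1·Δt).

Because `α(n) → 1` as usage accumulates, the synapse stiffens with use
(metaplasticity), and the effective decay rate satisfies `t·r(t) → 1` — the
signature of optimal memory retention. For a network of N synapses storing
n random ±1 patterns, the retrieval signal, cross-talk noise, and SNR of a
stored pattern follow

    S ≈ 1/(n+γ),    ν² ≈ n / (N·(n+γ)²),    SNR = √(N/n),

so memory lifetime and capacity scale linearly with N and are independent
of the device constant γ. A global modulation staircase `Vmod(t)` can
restore part of the per-update Wc drop, trading retention for graceful
forgetting; a Poisson single-electron variant covers the low-tunneling
regime; and a continual-learning harness backs every MLP weight with an
FN-synapse instance.

## Worked example

Imprint 100 random ±1 patterns on a network of 100 FN-synapses, tracking
the first pattern over 1000 Monte-Carlo repetitions:

```bash
fnsynapse consolidate --n 100 --patterns 100 --mc-runs 1000 --seed 1 --out demo
```

which prints the run summary and writes `demo/consolidate.csv`:

```
  n     S_mc    nu_mc   snr_mc  snr_analytic
  5 0.000262 0.000050 4.511339      4.472136
 25 0.000260 0.000122 2.009882      2.000000
 50 0.000255 0.000177 1.396950      1.414214
100 0.000253 0.000251 0.986886      1.000000
```

`S_mc` is the ensemble-mean retrieval signal of pattern 1 after n patterns
(dimensionless; ≈ 1/(n+γ) with γ = 4000), `nu_mc` the ensemble standard
deviation, and `snr_mc` the empirical SNR, which tracks the analytic
power law √(100/n) to within a few percent: the tracked memory's signal
fades as new patterns are written, crossing the retention threshold
(SNR = 1) at n ≈ N = 100 — capacity scales with network size.

Other entry points: `fnsynapse characterize` (write-size response sweeps),
`fnsynapse modulate` (patterns-retained under the m0–m4 plasticity-restore
profiles), `fnsynapse stochastic` (single-electron runs), and
`fnsynapse continual` (split/permuted task streams with FN-synapse, plain,
and EWC learners). The same functionality is available as a library; see
`fnsynapse.device`, `fnsynapse.benchmark`, `fnsynapse.continual`.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
numerical conventions, what the synthetic generators do and do not emulate,
and known limitations.
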