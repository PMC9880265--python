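# Methods

This note records the modelling assumptions, parameter choices, numerical
conventions, and known limitations of the simulator. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Device model

**State.** One FN-synapse is the pair of floating-gate potentials
(W⁺, W⁻); the stored weight Wd = (W⁺−W⁻)/2 and usage Wc = (W⁺+W⁻)/2 are
always derived from them (`SynapseState`). A fresh synapse has Wd = 0 and
Wc = Wc0.

**Units convention.** The tunneling flow is expressed directly as a voltage
slew, `J(W) = (k1/k2)·W²·exp(−k2/W)` in V/s: the physical current divided
by the total node capacitance C_T is folded into k1. This makes the slew
law and the closed-form usage trajectory `Wc(t) = k2/ln(k1·t + k0)`
mutually consistent without carrying C_T through the state equations.

**Discrete-time semantics.** Tunneling is negligible below ~5 V node
potential, so dynamics advance only while an input pulse holds the nodes
elevated; between pulses the state is non-volatile. One pulse of width Δt
therefore maps to exactly one discrete update, and the usage after any
history is summarized by the matching integration constant
`K = exp(k2/Wc)` (a synapse whose Wc has been restored by modulation is
indistinguishable from a younger one — this is what makes the modulation
rules well-defined).

**Two input conventions.**

* `apply_pulse` implements the raw level-step recursion
  `Wd(n) = α(n)·Wd(n−1) + u(n)` with unit input gain (the total capacitance
  collapsed onto the coupling capacitor). It is the form whose unrolled
  weighted sum the unit tests check to 1e−12 V.
* `apply_input_pulse` models a physical return-to-zero pulse: the input
  couples in, the elevated state decays for one pulse width, the input
  couples out, giving `Wd ← α·Wd + (1−α)·x·v`. Its imprint
  `(1−α)·(x·v − Wd)` is proportional to pulse width, attenuated by usage,
  and bounds the weight to |Wd| ≤ x. All pattern and learning experiments
  use this form: it is the one that reproduces the measured write behavior
  (linear in width, shrinking with usage) and the analytic
  signal/noise/SNR expressions with all n stored patterns carrying
  coefficients of magnitude ≈ 1/(n+γ). Taking the level-step form
  literally would give the most recent pattern a unit coefficient,
  inconsistent with the noise power n/(N(n+γ)²).
* `junction_pulse` integrates each junction's autonomous ODE exactly over a
  flat pulse top, with the physical coupling ratio Cc/C_T = 0.125. It
  exposes the exponential dependence of write size on pulse magnitude
  (which the linearized per-update form cannot) and supplies the
  per-junction voltage drops that the stochastic model quantizes.

**Decay-rate diagnostic.** `decay_rate_r` estimates r = −Wc″/Wc′ by
repeated `np.gradient` on a (possibly log-spaced) sampled trajectory and
discards two samples at each end, where the one-sided differences of the
repeated gradient are unreliable. For the FN trajectory |t·r(t) − 1| stays
below 0.05 for t ≥ 100·k0/k1 under the default parameters.

## Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| k1 | 1e16 s⁻¹ | slew prefactor; order of magnitude of the extracted device constants |
| k0 | 1e19 | integration constant at Wc0 (k0 = exp(k2/Wc0)) |
| Wc0 | 8.0 V | initial usage potential; hence k2 = Wc0·ln k0 ≈ 350 V |
| Δt | 250 ms | network-experiment pulse width (100 ms via the `characterization` preset) |
| γ = k0/(k1Δt) | 4000 | effective initial age in pulses |
| Cc | 200 fF | coupling capacitance (write energy ½·Cc·X²) |
| Cfg | 1.4 pF | chosen so C_T = 1.6 pF and q/C_T ≈ 0.1 µV per electron |
| pulse amplitude | 1.15 V | sets the first imprint (1−α(1))·x ≈ 300 µV, the detectability level used when initializing the hardware |
| Wc ceiling | 9.0 V | safety clip for the modulation restore path |
| A | 1e-12 m² | junction area; documentation only (see stochastic model) |

Presets `gamma1`/`gamma2` re-initialize Wc0 so that γ = 2000/8000
(representative values; the two SNR curves they produce are statistically
indistinguishable, as theory requires). `high_regime`/`low_regime` start
the nodes at 7 V / 6 V.

## Modulation

Profiles m0–m4 follow the staircase-restore idea: after each differential
update the usage is raised by an increment derived from the network-mean
|ΔWd| of that same update (a single global broadcast signal): m0 adds
nothing; m1/m2/m3 add ¾/½/¼ of the mean; m4 alternates between the m0 and
m1 rules every `switch_period` updates (default 250, configurable; the
first phase is m0). Increments are applied after the differential update,
never during it. Wc is clipped at the 9 V ceiling with a warning.

Operating regimes worth knowing: the restore-to-drop ratio scales as
(fraction)·(amplitude)·k2/Wc², so at the default 1.15 V amplitude the
m1–m3 profiles over-restore and Wc climbs — slowly at first, then
runaway — until it pins at the ceiling, where the network reaches a
steady forgetting state; with 2000 patterns m1 arrives early and m2 just
within the horizon, so their plateaus nearly coincide. At amplitudes
≲ 0.2 V the profiles instead equilibrate at distinct Wc levels below the
ceiling with distinct capacities. Both regimes avoid blackout; the
unmodulated network (m0) loses every stored pattern at once when n
reaches ≈ N.

## Memory benchmark

Patterns are i.i.d. uniform ±1 by default. Strictly balancing each
synapse's row (exactly n/2 of each sign) makes row entries anticorrelated
by −1/(n−1); because all retention coefficients are nearly equal when
γ ≫ n, that balancing suppresses the tracked signal by ≈ (n−1)/n·100% at
n equal to the row length, so the SNR experiments use the i.i.d. form
(balanced generation is available and tested).

Because every synapse is pulsed at every pattern and modulation is global,
the usage trajectory is shared network-wide; the Monte-Carlo driver
exploits this to update all runs × synapses as one array with the scalar
α(k) per step (verified against the element-wise device updates).

**Estimators.** The analytic noise ν² = n/(N(n+γ)²) deliberately includes
the tracked pattern's own term. The Monte-Carlo driver therefore reports
both the ensemble standard deviation of the retrieval signal (`nu_mc`) and
the pooled per-pattern noise `sqrt((1/N)·Σᵢ S_mc(n,i)²)` (`nu_pooled`),
and forms `snr_mc` from the convention that matches the analytic √(N/n)
(the pooled form where computed, otherwise variance plus S²/N). Using the
bare ensemble variance instead would report √(N/(n−1)) — more than 10%
above the analytic curve for n ≤ 10 purely as an estimator-convention
artifact. The pooled estimator's noise-floor bias is ≈ n/(N·runs) of ν²
(0.1% at the default sizes) and is left uncorrected.

Memory lifetime n\* is the first n ≥ 5 at which the empirical SNR drops
below 1. With 600 runs the estimator jitter on n\*/N is about ±8%, well
inside the 0.7–1.3 acceptance band. The modulated experiments compute
SNR(n, p) for all p analytically from the realized decay sequence
(log-domain cumulative sums; the tracked-term-inclusive noise), which is
deterministic given the simulated mean-|ΔWd| sequence.

## Stochastic single-electron model

Poisson rates are derived from the deterministic per-junction drops of the
junction-level step: λ± = C_T·ΔW±_det/q, one draw per junction per pulse.
This voltage-domain identification is exact by construction (λ·q/C_T
recovers the drop) and avoids needing the junction area and oxide
constants, which the parameterization does not pin down; A is retained in
`DeviceParams` for documentation but unused. Each sampled electron moves
its node by exactly q/C_T ≈ 0.1 µV, so charge bookkeeping is exact up to
float accumulation. Under the default constants the high-regime preset
(nodes at 7 V, 4 V pulses) yields a few electrons per pulse and a
stochastic-vs-deterministic trajectory deviation of a few µV over 100
pulses — far inside the 200 µV agreement bound; the genuinely
many-electron regime sits at the default Wc0 = 8 V (≈ 450 electrons per
pulse).

## Continual learning

The harness is a numpy MLP (ReLU hiddens, softmax head) with SGD, Adam,
and Adagrad optimizers and diagonal-Fisher EWC / online-EWC baselines
(penalty strength λ = 100 by default, a config knob echoed in the output
metadata; Fisher estimated from 200 per-sample gradients). No GPU or
external framework is used; the training loop must interleave per-parameter
synapse updates with optimizer steps, which rules out off-the-shelf
estimators.

**FN backing.** Every weight and bias owns a synapse. Synapses are
programmed to the network's random initialization (Wd = w/gain at Wc0).
A proposed step s becomes a pulse of width `pulse_gain·|s|` and sign
`sign(s)`; the realized update is `gain·(1−α)·(x·sign(s) − Wd)`. A seeded
calibration routine sets `pulse_gain` so a fresh synapse realizes its
requested step to within 10%. Weights are bounded to ±`weight_scale`
(default 0.25), and the per-step usage advance is |s|/weight_scale up to a
~4% logarithmic factor — after calibration this ratio is invariant to the
initial plasticity, so `weight_scale` is the single knob that sets how
fast parameters consolidate relative to how far training moves them.

**Synthetic stream.** Ten Gaussian-blob classes in 64 dimensions, centers
uniform on the sphere of radius 3 (typical pairwise distance 3√2 ≈ 4.2,
Bayes accuracy ≈ 98% with unit isotropic noise), 500 train / 100 test per
class, seeded. The split scheme yields five two-class tasks ([0,1], [2,3],
…) sharing one two-unit head; the permuted scheme presents ten fixed
feature permutations of the full problem (task 1 is the identity).
Defaults for this stream — SGD lr 0.3, 5 epochs, batch 32, hidden
100/100 — were set so that a single task trains past 95% accuracy in
seconds while each task accumulates enough usage for consolidation to
matter; image-scale runs should pass the MNIST-style settings
(1024-400-400-2, lr 1e-3, batch 128, 4 epochs) explicitly. The optimizer
is re-instantiated at each task boundary; FN-synapse state persists.

What the synthetic stream does *not* emulate: pixel-level structure and
vanishing-gradient depth effects of image data, label noise, class
imbalance, and the much longer per-task optimization of full-size
benchmarks. Passing the retention tests here shows the consolidation
mechanism orders the methods correctly at this scale, not that any
particular image-benchmark accuracy would be reproduced. Exact
image-benchmark accuracy values additionally depend on unpublished
hyper-parameters, so they are out of scope by design; the IDX adapter
(zero-padding 28×28 → 32×32, per-pixel standardization from train
statistics) is provided for users with local image data.

## Numerical choices

* `exp(k2/Wc)` is clamped at exp(700) — reachable only for Wc far below
  any operating point — so usage saturates instead of overflowing.
* Modulated SNR matrices are assembled in the log domain with
  `np.logaddexp.accumulate`; entries are bounded by √N, so no overflow.
* The empty product in the exact signal expression is 1, which makes the
  p = n value repeat the p = n−1 form; plots and tests treat n ≥ p+1 as
  the meaningful range, and |S| is reported (the raw coefficient is
  negative in the level-step convention, positive in the pulse
  convention).
* Random sources are `numpy.random.Generator` seeded per run; sub-seeds
  are derived with `SeedSequence`. Identical config + seed gives
  byte-identical CSV output.

## Known limitations

* Isothermal operation is assumed; k1, k2 drift with temperature on real
  devices.
* No transistor-level circuit effects: readout noise (~100 µV on the
  prototype), charge-pump programming, and hot-electron injection are not
  modelled; only their resulting constants appear as defaults.
* The stochastic model ignores correlated tunneling and shot-noise
  spectra; rates are per-pulse aggregates.
* Device mismatch is not simulated by default (a per-synapse multiplicative
  jitter on k1/k2 can be emulated by constructing per-synapse
  `DeviceParams`, but no turnkey hook is wired through the network
  harness).
* The cascade-model comparison curves are external references; the
  benchmark exposes `patterns_retained` on any SNR matrix so other models
  can be plugged in, but does not implement cascade internals.
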