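# Methods

## Model

`stdfa` simulates feed-forward spiking neural networks of leaky
integrate-and-fire (LIF) neurons on a fixed time grid (`dt = 1`, one
"biological time step"; all time constants are in units of that step). Each
neuron integrates a first-order synaptic current,

    tau_s dalpha_i/dt = -alpha_i + sum_j w_ij sum_f delta(t - t_j^f),
    tau_m du_i/dt     = -u_i + R alpha_i,           R = 1,

by forward Euler; a neuron whose potential reaches the threshold `nu` emits
at most one spike per step and resets to zero. There is no refractory
period: the spike-response view of the same dynamics restarts PSP
accumulation at the neuron's own last firing time, which the reset-to-zero
realizes exactly. Input-layer units are spike sources only.

Integrating the pair of linear ODEs gives the spike-response form: the
potential is a weighted sum, over pre-synaptic spikes, of the PSP kernel

    epsilon(s, t) = exp(-max(t-s,0)/tau_s) / (1 - tau_s/tau_m)
                    * [exp(-min(s,t)/tau_m) - exp(-min(s,t)/tau_s)] H(s) H(t),

where `t` is time since the pre-spike and `s` time since the post-neuron's
last firing. The normalization convention is the one in which the synaptic
impulse response carries a `1/tau_s` gain; the quadrature cross-check
(`psp_kernel_quadrature`) integrates exactly that convolution, and the two
agree to ~1e-15 on a 20x20 grid (asserted at 1e-3).

### S-PSP: the spike-train level quantity behind learning

The *spike-train level post-synaptic potential* `e_{i|j}` is the total
kernel contribution of pre-neuron `j`'s train to post-neuron `i`, sampled at
`i`'s firing times. The production path computes it online during the
forward pass with two traces per synapse,

    p <- (1 - 1/tau_s) p + (1/tau_s) * pre_spike      (synaptic trace)
    q <- (1 - 1/tau_m) q + p                          (membrane contribution)
    on post-fire:  e <- e + q;  q <- 0,

in that within-step order (pre injection, then `q`, then post-fire
handling), which also fixes the same-step pre/post case: the injection is
captured by `e` in the same step.

Two deliberate conventions:

* **Unit-gain membrane coupling.** The membrane recurrence is
  `u <- (1 - 1/tau_m) u + alpha`, with unit gain on the current, mirroring
  the `q` update. With synchronized resets this makes
  `u_i(t) = sum_j w_ij q_{i|j}(t)` an exact identity, so the firing count
  obeys `o_i ~= a_i / nu` with `a_i = sum_j w_ij e_{i|j}` by construction
  (`a_i/nu >= o_i` exactly, the slack being the supra-threshold overshoot at
  firing; measured at roughly 10-50% of the count in rate-driven regimes and
  documented rather than asserted tightly). The omitted `1/tau_m` Euler gain
  is absorbed into weight scale, exactly as the `1/tau_s`-normalized
  injection already is.
* **Before the first post-spike** the "previous firing time" is `-inf`, so
  contributions since trial start count toward the first firing; `s = +inf`
  in the closed-form kernel drops the restart decay factor.

The event-based double sum over recorded spike pairs exists as a reference
oracle in two modes: *discrete* (closed-form resummation of the Euler
recurrences; agrees with the online accumulator to ~1e-15 relative, asserted
at 1e-9) and *continuous* (the exponential kernel; the discrete value
converges to it at first order in `1/tau_s` when time constants and spike
spacings are scaled up together — the error halves per doubling in the
tests). Neither oracle is used in training.

## Learning rules

Training minimizes the rate-coded loss `E = 1/2 ||o - y||^2` on output
firing counts. Desired counts come from the class label: `hi` (default 35
per 100 steps) for the correct output neuron, `lo` (default 5) for the rest,
scaled with the horizon. Errors and updates:

    delta_o = (o - y)/nu                      output layer
    delta_k = B^k delta_o                     hidden layers (direct feedback)
    dw_ij   = eta * delta_i * e_{i|j},        w <- w - dw      (descent)

The output layer trains with `delta_o * e` directly. Hidden errors never
touch other layers' weights — credit assignment is depth-independent and
order-independent, which the tests assert exactly. Updates are per example
(online), no mini-batching, no momentum.

Feedback variants:

* `stdfa` — real-valued fixed random `B`, zero-mean uniform with half-width
  `sqrt(18) ~= 4.24`, chosen so its RMS matches the power-of-2 set's; this
  keeps `eta` comparable across variants.
* `stdfa2` — entries drawn uniformly from `{-4, -2, -1, 0, 1, 2, 4}` (zero
  included as a masked entry). Every feedback product is then a
  sign-corrected arithmetic shift; the float path uses `ldexp` and is
  bit-identical to the dense multiply, the fixed-point path shifts raw
  integers.
* `bp-baseline` — a symmetric-weight comparison rule
  `delta_i^k = (1/nu) sum_l delta_l^{k+1} w_li e_{l|i} / o_i` (0 for silent
  neurons). It applies the same dropped-perturbation simplification as the
  DFA derivation and substitutes the average `e/o` for the exact
  count-sensitivity of the S-PSP; it is a structural baseline for
  comparison, not a faithful reproduction of any published backprop rule.
* `frozen` — no updates; the no-learning control.

### Initialization and learning rate

The update `dw = eta * delta * e` is gated multiplicatively by the
post-neuron's own S-PSP: a neuron silent on every example has `e = 0`
everywhere, receives no update, and is an absorbing dead state. Zero-mean
output-layer initialization leaves roughly half the output neurons
under-driven and collapses entire networks for moderate `eta`. The package
therefore initializes the output layer non-negative uniform on
`[0, 2/sqrt(fan_in)]` — every output starts active and the error signal
prunes counts down — while hidden layers stay zero-mean uniform with
half-width `3/sqrt(fan_in)` (moderate initial firing; a few dead hidden
units are harmless).

The default learning rate `eta = 1e-5` was set from magnitude analysis: on
the default task `|delta|` reaches ~1e2 and `e` ~1e1, so `|dw|` stays at a
few percent of the weight scale; rates tenfold larger destabilize counts and
drive networks into the silent state.

## Fixed-point datapath

Quantized training emulates an integer hardware pipeline. Storage formats
(word/fraction bits): weights signed 17/12, S-PSP unsigned 11/6, membrane
potential signed 9/3. Time constants must be powers of 2 so decay by
`(1 - 1/tau)` is `raw - (raw >> log2 tau)`. Numerical choices, configurable
but defaulted as follows:

* quantization rounds to nearest, ties to even, and **saturates** (no
  overflow errors); shifts truncate, as shift registers do;
* synaptic-current accumulation uses a wider internal format (signed 24/12)
  before truncating down to the potential's 9/3 lattice, the way hardware
  accumulators are wider than storage;
* the error `delta` and the update `dw` are quantized to the weight format;
  weights live on the weight lattice, so quantized training is exactly
  reproducible integer arithmetic end to end (bit-identical across runs,
  asserted).

Costs of the coarse formats worth knowing: `e` saturates at 2047/64 ~= 32,
so very active synapses clip; potentials resolve to 1/8, so weak drives
below ~0.125 after truncation do not register; updates smaller than half the
weight resolution (2^-13) vanish, which stalls fine-tuning near convergence.
On the synthetic task these effects cost a few accuracy points relative to
the float path.

## Synthetic task and what it shows

`make_rate_task` generates an n-class task (defaults: 3 classes, 20 inputs,
T = 100, 10 examples per class): each class owns a template of
`n_inputs/n_classes` neurons, a fraction `overlap` (default 0.2) of which is
shared between all classes; template neurons fire at `peak_rate = 0.2` per
step, the rest at `base_rate = 0.02`, each example an independent Bernoulli
draw. The generator returns its templates, so tests can bound achievable
accuracy with an oracle template classifier independent of the learner.

What it emulates: rate-coded multi-class structure with class overlap and
Poisson-like trial noise. What it does not: the scale (hundreds of inputs,
tens of thousands of examples), temporal structure within a trial, and
example diversity of real benchmarks. In particular, with 30 fixed training
rasters a 20-30-3 network can and does partially memorize: training
accuracy reaches 100% in a handful of epochs while held-out accuracy on
freshly sampled examples is far lower and seed-dependent. Passing the
learning tests therefore demonstrates that the credit-assignment path
(random direct feedback on spike-train level quantities) optimizes the
training objective — not that the resulting nets generalize; generalization
at realistic scale is outside what this generator can certify.

Degenerate inputs are defined: an all-silent input yields silent layers,
zero S-PSPs everywhere, and (for `y > 0`) updates only where `e > 0`, i.e.
nowhere — silent networks do not train, which is why initialization
guarantees activity.

## Problem sizes and determinism

Default experiment sizes (20-30-3 network, 30 examples, T = 100, early
stopping once the accuracy target is reached) were chosen so a full
multi-rule, multi-seed comparison completes in seconds on one core while
still exercising every code path, including two-hidden-layer configurations
in the tests. Everything — data, initialization, feedback draws, shuffling —
flows from explicit integer seeds through `numpy` generators; reruns are
bit-identical, and the classification tie-break (equal counts) is the lowest
neuron index.

## Known limitations

* Memorization on the small default task (above); increase `n_per_class`
  for generalization studies.
* No axonal delays, no refractory period, no recurrence, single-spike-per-
  step — outside the implemented model family.
* The continuous-time oracle is for validation only; the simulator is
  fixed-step by design.
* The bp-baseline's `e/o` substitution makes it a structural, not exact,
  gradient rule.
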