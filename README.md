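# stdfa

Spike-train level direct feedback alignment (ST-DFA) for training
multi-layer spiking neural networks, with a hardware-friendly power-of-2
variant (ST-DFA-2) and a fixed-point emulation layer mirroring an FPGA
datapath.

## The problem

Backpropagation through a spiking network needs the transpose of every
forward weight matrix (weight transport) and a layer-by-layer backward
sweep — both biologically implausible and expensive in neuromorphic
hardware. Direct feedback alignment replaces the backward sweep: the output
error is projected straight to each hidden layer through a *fixed random*
matrix, so all hidden layers can update concurrently and no symmetric
weights exist anywhere.

This package implements that idea at the *spike-train level* for leaky
integrate-and-fire (LIF) networks trained against a rate-coded loss
`E = 1/2 ||o - y||²` on output firing counts:

    δᵒ = (o − y)/ν                         output layer
    δᵏ = Bᵏ δᵒ                             hidden layer k, Bᵏ fixed random
    Δw_ij = η · δᵢ · e_{i|j},   w ← w − Δw

The key quantity `e_{i|j}` is the **spike-train level post-synaptic
potential (S-PSP)**: the total PSP-kernel contribution of pre-neuron *j*'s
spike train to post-neuron *i*, sampled at *i*'s firing times,

    e_{i|j} = Σ_{t_i^f} Σ_{t_j^f} ε(t_i^f − t̂_i, t_i^f − t_j^f),

accumulated *online* during the forward pass with two per-synapse traces
(`p`, `q`) whose decays become arithmetic shifts when `τ_m`, `τ_s` are
powers of 2. In ST-DFA-2 the feedback entries are restricted to
`{−4, −2, −1, 0, 1, 2, 4}`, so every feedback multiply is a sign-corrected
shift — bit-identical to the dense product, in float and in fixed point.
The fixed-point layer emulates the hardware storage formats (weights signed
17-bit/12-frac, S-PSP unsigned 11-bit/6-frac, potential signed
9-bit/3-frac) so the accuracy cost of quantized on-chip training can be
measured in software.

Intended users: computational-neuroscience and neuromorphic-hardware
researchers who want a small, exactly reproducible reference implementation
of spike-train level DFA with its numerical conventions pinned down and
tested.

## Worked example

Train a 20-30-3 network with ST-DFA-2 on the built-in synthetic 3-class
rate task (20 inputs, 100 time steps, 20% template overlap, Poisson-sampled
spike trains):

```python
from stdfa import TrainConfig, RateTaskSpec, run_experiment

cfg = TrainConfig(rule="stdfa2", eta=1e-5, epochs=200, seed=0)
task = RateTaskSpec()  # 3 classes, 20 inputs, T=100, overlap 0.2
result = run_experiment(cfg, task, (20, 30, 3), stop_at_train_acc=95.0)

print(f"epochs run     : {result.epochs_run}")
print(f"train accuracy : {result.final_train_accuracy:.1f}%")
print(f"first epochs   : {[round(a, 1) for a in result.epoch_accuracies[:5]]}")
print(f"mean loss      : {result.epoch_losses[-1]:.1f}")
```

prints

```
epochs run     : 4
train accuracy : 100.0%
first epochs   : [20.0, 63.3, 90.0, 100.0]
mean loss      : 48.0
```

i.e. random direct feedback drives the training accuracy from the 33%
chance level to 100% in four passes over the data; the residual loss is the
squared mismatch between actual and desired spike counts that remains even
when the argmax is already correct. The same comparison from the command
line:

```bash
$ stdfa compare --shape 20-30-3 --rules stdfa,stdfa2,frozen --epochs 20 --seed 0 --eta 1e-5
stdfa        train=100.00% test= 63.33% epochs=20
stdfa2       train=100.00% test= 36.67% epochs=20
frozen       train=  6.67% test=  63.33% epochs=20
```

The frozen-weights control never leaves its initial (near-chance, very
seed-dependent) performance. Held-out accuracy on freshly sampled examples
is much lower than training accuracy at this tiny dataset size — the
default 30-example task is memorizable, a deliberate scale choice discussed
in `docs/methods.md`.

`stdfa train --checkpoint net.npz --log curve.csv ...`, `stdfa eval` and
`stdfa inspect` cover single runs, re-evaluation and checkpoint inspection;
`--quantize` switches any of them to the integer fixed-point datapath. An
IDX loader (`load_idx_images`) plus `center_crop` and `poisson_encode` let
user-supplied MNIST-format files drive the same pipeline; nothing is ever
downloaded.

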