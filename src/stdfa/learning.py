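"""ST-DFA learning: rate-coded loss, error feedback, and weight updates.

Training minimizes the rate-coded squared loss ``E = 1/2 ||o - y||^2``
between actual and desired output firing counts. The output-layer error is
``delta_o = (o - y)/nu``. Hidden-layer errors are obtained by *direct
feedback alignment*: a fixed random matrix ``B`` per hidden layer projects
``delta_o`` straight down, ``delta_k = B delta_o``, with no layer-by-layer
propagation and no weight transport. Weight updates are spike-train level,

    dw_ij = eta * delta_i * e_{i|j},    w <- w - dw,

with ``e_{i|j}`` the S-PSP accumulated during the forward pass.

Two feedback variants exist: real-valued random entries ("stdfa") and
entries restricted to a small signed power-of-2 set ("stdfa2"), for which
every feedback product is a sign-corrected arithmetic shift — the
hardware-friendly form. A symmetric-weight backprop baseline
(:func:`bp_hidden_error`) and a frozen-weights control are provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fixedpoint import WEIGHT_FORMAT, FixedPointFormat, QuantizedValue, quantize
from .neuron import Network, NeuronParams, forward_pass

__all__ = [
    "DEFAULT_POWER2_SET",
    "FeedbackMatrix",
    "TrainConfig",
    "TrainReport",
    "make_feedback",
    "init_network",
    "rate_loss",
    "target_counts",
    "output_error",
    "dfa_hidden_error",
    "dfa_hidden_error_fixed",
    "stdfa_weight_update",
    "bp_hidden_error",
    "train_example",
]

#: Signed power-of-2 feedback value set of the hardware-friendly variant.
DEFAULT_POWER2_SET = (-4, -2, -1, 0, 1, 2, 4)

#: Half-width of the uniform real-valued feedback distribution, chosen so its
#: second moment matches the default power-of-2 set's (mean square 42/7 = 6;
#: uniform(-a, a) has variance a^2/3, hence a = sqrt(18)).
REAL_FEEDBACK_SCALE = float(np.sqrt(3.0 * np.mean(np.square(DEFAULT_POWER2_SET))))


@dataclass(frozen=True)
class FeedbackMatrix:
    """Fixed random feedback weights of one hidden layer.

    ``b`` has shape ``(r_hidden, r_output)``; ``delta_hidden = b @ delta_o``.
    For the power-of-2 variant, ``shift_exponents`` and ``signs`` satisfy
    ``b = signs * 2**shift_exponents`` with ``signs == 0`` marking masked
    (zero) entries, so products reduce to shifts. Immutable after creation.
    """

    b: np.ndarray
    variant: str
    shift_exponents: np.ndarray | None = None
    signs: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.b.setflags(write=False)
        if self.variant == "power-of-2-set":
            if self.shift_exponents is None or self.signs is None:
                raise ValueError("power-of-2 variant needs shift_exponents and signs")
            recon = self.signs * np.exp2(self.shift_exponents)
            if not np.array_equal(recon, self.b):
                raise ValueError("b and (signs, shift_exponents) are inconsistent")


def make_feedback(
    shape: tuple[int, int],
    variant: str = "power-of-2-set",
    value_set=DEFAULT_POWER2_SET,
    scale: float | None = None,
    seed: int = 0,
) -> FeedbackMatrix:
    """Draw a fixed random feedback matrix, reproducible from ``seed``.

    ``power-of-2-set``: entries i.i.d. uniform over ``value_set``, whose
    nonzero members must all be signed powers of 2. ``real-gaussian`` /
    ``real-uniform``: zero-mean real entries with half-width / std ``scale``
    (default matched to the power-of-2 set's RMS so learning rates stay
    comparable across variants).
    """
    rng = np.random.default_rng(seed)
    if variant == "power-of-2-set":
        values = np.asarray(value_set, dtype=np.float64)
        if values.size == 0:
            raise ValueError("value_set must be nonempty")
        nz = values[values != 0]
        if nz.size and not np.all(np.log2(np.abs(nz)) % 1 == 0):
            raise ValueError("nonzero feedback values must be signed powers of 2")
        b = rng.choice(values, size=shape)
        signs = np.sign(b).astype(np.int64)
        m = np.zeros(shape, dtype=np.int64)
        nonzero = signs != 0
        m[nonzero] = np.log2(np.abs(b[nonzero])).astype(np.int64)
        return FeedbackMatrix(b=b, variant=variant, shift_exponents=m, signs=signs, seed=seed)
    if variant in ("real-uniform", "real-gaussian"):
        a = REAL_FEEDBACK_SCALE if scale is None else scale
        if variant == "real-uniform":
            b = rng.uniform(-a, a, size=shape)
        else:
            b = rng.normal(0.0, a, size=shape)
        return FeedbackMatrix(b=b, variant=variant, seed=seed)
    raise ValueError(f"unknown feedback variant {variant!r}")


def init_network(
    layer_sizes,
    seed: int = 0,
    params: NeuronParams | None = None,
    feedback_variant: str = "power-of-2-set",
    init_scale: float | None = None,
) -> Network:
    """Build a network with random weights and fixed feedback matrices.

    Hidden-layer weights are zero-mean uniform with half-width
    ``init_scale / sqrt(fan_in)``; output-layer weights are non-negative
    uniform on ``[0, 2/sqrt(fan_in)]``. The spike-train level update
    ``dw = eta * delta * e`` is gated multiplicatively by the post-neuron's
    own S-PSP, so a neuron that is silent on every example receives no
    update and can never recover; starting every output neuron with
    positive net drive removes that absorbing state, and the error signal
    then prunes counts down to their targets.
    """
    layer_sizes = tuple(int(s) for s in layer_sizes)
    params = params or NeuronParams()
    rng = np.random.default_rng(seed)
    scale = 3.0 if init_scale is None else init_scale
    n_conn = len(layer_sizes) - 1
    weights = []
    for k in range(n_conn):
        fan_in = layer_sizes[k]
        if k == n_conn - 1:
            w = rng.uniform(0.0, 1.0, size=(layer_sizes[k + 1], fan_in)) * (
                2.0 / np.sqrt(fan_in)
            )
        else:
            w = rng.uniform(-1.0, 1.0, size=(layer_sizes[k + 1], fan_in)) * (
                scale / np.sqrt(fan_in)
            )
        weights.append(w)
    n_out = layer_sizes[-1]
    feedback = [
        make_feedback(
            (layer_sizes[k + 1], n_out),
            variant=feedback_variant,
            seed=int(rng.integers(2**31)),
        )
        for k in range(len(layer_sizes) - 2)
    ]
    return Network(layer_sizes=layer_sizes, weights=weights, params=params, feedback=feedback)


def rate_loss(o, y) -> float:
    """Rate-coded squared loss ``E = 1/2 ||o - y||^2`` on firing counts."""
    o = np.asarray(o, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if o.shape != y.shape:
        raise ValueError(f"count vectors differ in shape: {o.shape} vs {y.shape}")
    return 0.5 * float(np.sum((o - y) ** 2))


def target_counts(label: int, n_out: int, T: int, hi: int = 35, lo: int = 5) -> np.ndarray:
    """Desired firing counts for a class label: ``hi`` for the correct output
    neuron, ``lo`` elsewhere, both scaled linearly with the horizon relative
    to a 100-step trial."""
    if not 0 <= label < n_out:
        raise ValueError(f"label {label} out of range for {n_out} outputs")
    if not hi > lo >= 0:
        raise ValueError("need hi > lo >= 0")
    y = np.full(n_out, round(lo * T / 100.0), dtype=np.int64)
    y[label] = round(hi * T / 100.0)
    return y


def output_error(o, y, nu: float) -> np.ndarray:
    """Output-layer error ``delta_i = (o_i - y_i) / nu``."""
    if nu <= 0:
        raise ValueError("threshold nu must be positive")
    return (np.asarray(o, dtype=np.float64) - np.asarray(y, dtype=np.float64)) / nu


def dfa_hidden_error(
    delta_o: np.ndarray, B: FeedbackMatrix, use_shifts: bool | None = None
) -> np.ndarray:
    """Hidden-layer error by direct feedback: ``delta_i = sum_l b_il delta_l``.

    With ``use_shifts`` (default: automatic for the power-of-2 variant) each
    product is realized as ``sign * ldexp(delta_l, m_il)`` — the float
    analogue of the hardware's sign-corrected arithmetic shift — which is
    bit-identical to the dense multiply because power-of-2 scaling is exact.
    """
    delta_o = np.asarray(delta_o, dtype=np.float64)
    if delta_o.shape != (B.b.shape[1],):
        raise ValueError(
            f"delta_o has shape {delta_o.shape}, feedback expects ({B.b.shape[1]},)"
        )
    if use_shifts is None:
        use_shifts = B.variant == "power-of-2-set"
    if use_shifts:
        if B.variant != "power-of-2-set":
            raise ValueError("shift path requires a power-of-2 feedback matrix")
        prods = B.signs * np.ldexp(
            np.broadcast_to(delta_o, B.b.shape), B.shift_exponents
        )
    else:
        prods = B.b * delta_o[np.newaxis, :]
    return prods.sum(axis=1)


def dfa_hidden_error_fixed(
    delta_o: QuantizedValue, B: FeedbackMatrix, use_shifts: bool = True
) -> QuantizedValue:
    """Fixed-point hidden error: integer shifts on the raw lattice values.

    Products accumulate in a wide integer register and the final sum
    saturates to ``delta_o``'s format, matching the hardware inner-product
    unit. The dense integer-multiply route (``use_shifts=False``) is
    bit-identical and serves as the cross-check.
    """
    if B.variant != "power-of-2-set":
        raise ValueError("fixed-point feedback requires the power-of-2 variant")
    raw = np.asarray(delta_o.raw, dtype=np.int64)
    if raw.shape != (B.b.shape[1],):
        raise ValueError("delta_o shape does not match feedback matrix")
    if use_shifts:
        shifted = np.left_shift(
            np.broadcast_to(raw, B.b.shape), B.shift_exponents
        )
        prods = B.signs * shifted
    else:
        prods = B.b.astype(np.int64) * raw[np.newaxis, :]
    total = prods.sum(axis=1)
    fmt = delta_o.fmt
    return QuantizedValue(np.clip(total, fmt.raw_min, fmt.raw_max), fmt)


def stdfa_weight_update(delta_k: np.ndarray, e: np.ndarray, eta: float) -> np.ndarray:
    """Weight-change matrix ``dw_ij = eta * delta_i * e_{i|j}``.

    The caller applies ``w <- w - dw`` (gradient descent on the rate loss).
    """
    delta_k = np.asarray(delta_k, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    if e.shape[0] != delta_k.shape[0]:
        raise ValueError("delta and S-PSP matrix do not conform")
    return eta * delta_k[:, np.newaxis] * e


def bp_hidden_error(
    delta_next: np.ndarray,
    W_next: np.ndarray,
    e_next: np.ndarray,
    o: np.ndarray,
    nu: float,
) -> np.ndarray:
    """Symmetric-weight backprop baseline error (comparison only).

    ``delta_i = (1/nu) sum_l delta_l^{k+1} w_li^{k+1} (e_{l|i}^{k+1}/o_i)``,
    with the ratio defined as 0 for silent neurons (``o_i = 0``). This uses
    the same simplification as the ST-DFA derivation (the post-spike-train
    perturbation term is dropped) and replaces the exact count-sensitivity of
    the S-PSP by the average ``e/o``; it is a structural baseline, not a
    faithful reproduction of any published backprop rule.
    """
    delta_next = np.asarray(delta_next, dtype=np.float64)
    o = np.asarray(o, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(o > 0, 1.0 / np.where(o > 0, o, 1.0), 0.0)
    contrib = delta_next[:, np.newaxis] * W_next * e_next  # (r_next, r_k)
    return contrib.sum(axis=0) * ratio / nu


@dataclass
class TrainConfig:
    """Configuration of per-example online training."""

    rule: str = "stdfa2"  # stdfa | stdfa2 | bp-baseline | frozen
    eta: float = 1e-5
    epochs: int = 200
    seed: int = 0
    hi: int = 35  # target count of the correct output neuron (per 100 steps)
    lo: int = 5  # target count of the other output neurons (per 100 steps)
    quantize: bool = False
    shuffle: bool = False
    weight_format: FixedPointFormat = field(default_factory=lambda: WEIGHT_FORMAT)

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not self.hi > self.lo >= 0:
            raise ValueError("need hi > lo >= 0")
        if self.rule not in ("stdfa", "stdfa2", "bp-baseline", "frozen"):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass
class TrainReport:
    """Loss and prediction of one training example."""

    loss: float
    output_counts: np.ndarray
    targets: np.ndarray
    predicted: int
    label: int

    @property
    def correct(self) -> bool:
        return self.predicted == self.label


def _hidden_deltas(net: Network, delta_o: np.ndarray, result, cfg: TrainConfig):
    """Per-hidden-layer error vectors under the configured rule.

    DFA rules touch only ``delta_o`` and each layer's own feedback matrix, so
    the hidden computations are order-independent (logically concurrent).
    """
    if cfg.rule in ("stdfa", "stdfa2"):
        use_shifts = cfg.rule == "stdfa2"
        if cfg.quantize:
            dq = quantize(delta_o, cfg.weight_format)
            return [
                dfa_hidden_error_fixed(dq, net.feedback[k], use_shifts=use_shifts).value
                for k in net.hidden_indices
            ]
        return [
            dfa_hidden_error(delta_o, net.feedback[k], use_shifts=use_shifts)
            for k in net.hidden_indices
        ]
    if cfg.rule == "bp-baseline":
        deltas: list[np.ndarray] = [None] * (net.n_layers - 1)
        delta_next = delta_o
        for k in reversed(range(net.n_layers - 1)):
            nu = net.layer_params(k).threshold
            delta_next = bp_hidden_error(
                delta_next, net.weights[k + 1], result.spsp[k + 1],
                result.counts[k + 1], nu,
            )
            deltas[k] = delta_next
        return deltas
    raise ValueError(f"rule {cfg.rule!r} computes no hidden errors")


def train_example(net: Network, input_spikes, label: int, cfg: TrainConfig) -> TrainReport:
    """One online training iteration: forward pass, errors, weight updates.

    The forward pass accumulates all S-PSPs; the output error is formed from
    the final firing counts; every hidden layer's ST-DFA update is computed
    from that same output error (no hidden layer sees another's update
    within the iteration); finally all updates are applied in place,
    ``w <- w - eta * delta (x) e``. Weights change per example, not per
    mini-batch. Prediction is argmax of output counts (lowest index wins
    ties).
    """
    result = forward_pass(net, input_spikes, quantized=cfg.quantize)
    o = result.output_counts
    T = result.spikes[0].shape[1]
    n_out = net.layer_sizes[-1]
    y = target_counts(label, n_out, T, hi=cfg.hi, lo=cfg.lo)
    loss = rate_loss(o, y)
    report = TrainReport(
        loss=loss, output_counts=o, targets=y,
        predicted=int(np.argmax(o)), label=label,
    )
    if cfg.rule == "frozen":
        return report

    nu_out = net.layer_params(net.n_layers - 1).threshold
    delta_o = output_error(o, y, nu_out)
    deltas = (
        _hidden_deltas(net, delta_o, result, cfg) if net.n_layers > 1 else []
    )
    deltas = list(deltas) + [delta_o]

    for k in range(net.n_layers):
        dw = stdfa_weight_update(deltas[k], result.spsp[k], cfg.eta)
        if cfg.quantize:
            fmt = cfg.weight_format
            w_raw = quantize(net.weights[k], fmt).raw
            dw_raw = quantize(dw, fmt).raw
            new_raw = np.clip(w_raw - dw_raw, fmt.raw_min, fmt.raw_max)
            net.weights[k] = new_raw.astype(np.float64) * fmt.resolution
        else:
            net.weights[k] = net.weights[k] - dw
    return report
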