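"""Discrete-time LIF/SRM neuron dynamics and the multi-layer forward pass.

The simulator advances a feed-forward spiking network on a fixed grid with
``dt = 1`` (one "biological time step"); membrane and synaptic time constants
are expressed in units of that step. Each neuron follows the leaky
integrate-and-fire model with a first-order synapse,

    tau_s dalpha/dt = -alpha + input,      tau_m du/dt = -u + R*alpha,

discretized by forward Euler. A neuron whose potential reaches the threshold
``nu`` emits a spike (at most one per step) and resets to zero; there is no
refractory period. ``R`` is fixed to 1 and absorbed into the synaptic
weights.

The membrane recurrence uses unit gain on the synaptic current
(``u <- (1 - 1/tau_m) u + alpha``), mirroring the per-synapse trace
recurrence of the online S-PSP accumulator (:mod:`stdfa.spsp`). With both
resets synchronized this makes the potential identically equal to the
weight-weighted sum of per-synapse traces, so the firing count ``o_i`` tracks
the total post-synaptic potential ``a_i = sum_j w_ij e_{i|j}`` through
``o_i ~= a_i / nu``.

Equivalently the potential can be written in spike-response form: a sum over
pre-synaptic spikes of the PSP kernel ``epsilon(s, t)``
(:func:`psp_kernel`), restarted at the neuron's own last firing time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fixedpoint import (
    ACCUMULATOR_FORMAT,
    POTENTIAL_FORMAT,
    SPSP_FORMAT,
    WEIGHT_FORMAT,
    FixedPointFormat,
    quantize,
)

__all__ = [
    "NeuronParams",
    "SpikeTrain",
    "LayerState",
    "Network",
    "ForwardResult",
    "psp_kernel",
    "lif_step",
    "forward_pass",
    "spikes_to_table",
    "table_to_spikes",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF/SRM neuron parameters, time constants in units of the step.

    Parameters
    ----------
    tau_m : float
        Membrane time constant. Must exceed ``tau_s`` (the PSP kernel's
        normalization divides by ``1 - tau_s/tau_m``).
    tau_s : float
        Synaptic (first-order current) time constant.
    threshold : float
        Firing threshold ``nu``.
    reset : float
        Potential assigned in the step a neuron fires.

    Defaults use power-of-2 time constants so the same parameters run on the
    shift-based fixed-point datapath.
    """

    tau_m: float = 16.0
    tau_s: float = 4.0
    threshold: float = 1.0
    reset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_m > self.tau_s > 0):
            raise ValueError(f"need tau_m > tau_s > 0, got {self.tau_m}, {self.tau_s}")
        if self.tau_m == self.tau_s:
            raise ValueError("tau_m == tau_s is singular (kernel normalization)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def tau_powers(self) -> tuple[int, int]:
        """``(log2 tau_m, log2 tau_s)``; raises unless both are powers of 2.

        Required by the hardware-emulation path, where decays are shifts.
        """
        pm, ps = math.log2(self.tau_m), math.log2(self.tau_s)
        if pm != int(pm) or ps != int(ps):
            raise ValueError(
                "hardware-emulation mode requires tau_m and tau_s to be "
                f"integer powers of 2, got {self.tau_m}, {self.tau_s}"
            )
        return int(pm), int(ps)


@dataclass
class SpikeTrain:
    """Firing time steps of one neuron over a trial of length ``horizon``."""

    times: np.ndarray
    horizon: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.horizon:
                raise ValueError("spike times must lie in [0, horizon)")

    @property
    def count(self) -> int:
        return int(self.times.size)

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.horizon, dtype=bool)
        dense[self.times] = True
        return dense

    @classmethod
    def from_dense(cls, dense: np.ndarray) -> "SpikeTrain":
        dense = np.asarray(dense, dtype=bool)
        return cls(np.flatnonzero(dense), dense.size)


@dataclass
class LayerState:
    """Per-neuron membrane potential, synaptic current and spike indicator."""

    u: np.ndarray
    alpha: np.ndarray
    fired: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "LayerState":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n, dtype=bool))


@dataclass
class Network:
    """Feed-forward SNN: layer sizes, weights, neuron parameters, feedback.

    ``weights[k]`` has shape ``(layer_sizes[k+1], layer_sizes[k])`` and feeds
    layer ``k+1``. Layer 0 is the input layer (spike sources only, no LIF
    dynamics). ``feedback[k]`` is the fixed random feedback matrix of hidden
    layer ``k+1`` (shape ``r_hidden x r_output``); the output layer has none.
    ``params`` may be one :class:`NeuronParams` shared by all layers or one
    per non-input layer.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    params: NeuronParams | Sequence[NeuronParams] = field(default_factory=NeuronParams)
    feedback: list | None = None

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if len(self.layer_sizes) < 2 or any(s <= 0 for s in self.layer_sizes):
            raise ValueError("network needs >= 2 layers of positive size")
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("need one weight matrix per non-input layer")
        for k, w in enumerate(self.weights):
            expect = (self.layer_sizes[k + 1], self.layer_sizes[k])
            if w.shape != expect:
                raise ValueError(f"weights[{k}] has shape {w.shape}, expected {expect}")

    @property
    def n_layers(self) -> int:
        """Number of non-input layers."""
        return len(self.layer_sizes) - 1

    @property
    def hidden_indices(self) -> range:
        """Indices (into ``weights``) of connections entering hidden layers."""
        return range(self.n_layers - 1)

    def layer_params(self, k: int) -> NeuronParams:
        """Parameters of non-input layer ``k`` (0-based among non-input)."""
        if isinstance(self.params, NeuronParams):
            return self.params
        return self.params[k]


def psp_kernel(s, t, params: NeuronParams):
    """Closed-form normalized PSP kernel ``epsilon(s, t)``.

    ``t`` is the time elapsed since the pre-synaptic spike and ``s`` the time
    elapsed since the post-synaptic neuron's last firing (``s = +inf`` before
    it has ever fired). Causality is enforced by Heaviside factors: the
    kernel vanishes for negative ``s`` or ``t``. Accepts scalars or arrays.
    """
    s = np.asarray(s, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    tau_m, tau_s = params.tau_m, params.tau_s
    heav = (s >= 0) & (t >= 0)
    mn = np.minimum(s, t)
    mn = np.where(heav, mn, 0.0)  # avoid exp overflow on negative args
    lead = np.maximum(t - s, 0.0)
    lead = np.where(np.isfinite(lead), lead, 0.0)  # s = +inf => no decay term
    out = (
        np.exp(-lead / tau_s)
        / (1.0 - tau_s / tau_m)
        * (np.exp(-mn / tau_m) - np.exp(-mn / tau_s))
    )
    out = np.where(heav, out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def lif_step(
    state: LayerState,
    weighted_input: np.ndarray,
    params: NeuronParams,
    dt: float = 1.0,
) -> LayerState:
    """One forward-Euler step of a LIF layer.

    The synaptic current decays by ``(1 - dt/tau_s)`` and receives the
    weighted input with gain ``dt/tau_s``; the potential decays by
    ``(1 - dt/tau_m)`` and integrates the updated current with unit gain.
    Neurons at or above threshold fire and reset in the same step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    alpha = (1.0 - dt / params.tau_s) * state.alpha + (dt / params.tau_s) * weighted_input
    u = (1.0 - dt / params.tau_m) * state.u + alpha
    fired = u >= params.threshold
    u = np.where(fired, params.reset, u)
    return LayerState(u=u, alpha=alpha, fired=fired)


@dataclass
class ForwardResult:
    """Spike trains, firing counts and accumulated S-PSPs of one trial.

    ``spikes[k]`` is the boolean raster ``(n_k, T)`` of layer ``k`` (layer 0
    is the input). ``spsp[k]`` holds the S-PSP matrix ``e_{i|j}`` of the
    connection into layer ``k+1``, same shape as ``weights[k]``. In quantized
    mode ``spsp_raw`` additionally carries the integer lattice values.
    """

    spikes: list[np.ndarray]
    counts: list[np.ndarray]
    spsp: list[np.ndarray]
    spsp_raw: list[np.ndarray] | None = None

    @property
    def output_counts(self) -> np.ndarray:
        return self.counts[-1]


def _as_dense_input(input_spikes, n_inputs: int, T: int | None) -> np.ndarray:
    if isinstance(input_spikes, (list, tuple)) and input_spikes and isinstance(
        input_spikes[0], SpikeTrain
    ):
        horizons = {st.horizon for st in input_spikes}
        if len(horizons) != 1:
            raise ValueError("input spike trains have mismatched horizons")
        dense = np.stack([st.to_dense() for st in input_spikes])
    else:
        dense = np.asarray(input_spikes, dtype=bool)
    if dense.ndim != 2 or dense.shape[0] != n_inputs:
        raise ValueError(f"input raster must be ({n_inputs}, T), got {dense.shape}")
    if T is not None and dense.shape[1] != T:
        raise ValueError("input horizon differs from requested T")
    if dense.shape[1] == 0:
        raise ValueError("trial length T must be positive")
    return dense


def forward_pass(
    net: Network,
    input_spikes,
    T: int | None = None,
    quantized: bool = False,
    weight_format: FixedPointFormat = WEIGHT_FORMAT,
    spsp_format: FixedPointFormat = SPSP_FORMAT,
    potential_format: FixedPointFormat = POTENTIAL_FORMAT,
    accumulator_format: FixedPointFormat = ACCUMULATOR_FORMAT,
) -> ForwardResult:
    """Simulate all layers for one trial, accumulating S-PSPs online.

    Layers are advanced one time step at a time from input to output; within
    a step, layer ``k`` sees layer ``k-1``'s spikes of the same step. For
    every synapse the online S-PSP accumulator runs alongside the membrane
    dynamics, so at the end of the trial ``spsp[k][i, j]`` equals the exact
    event-based S-PSP ``e_{i|j}`` of the discrete recurrences.

    With ``quantized=True`` the whole pass runs on the integer fixed-point
    datapath (weights, traces, potentials quantized to the given formats;
    decays as truncating shifts), which requires power-of-2 time constants.
    """
    input_spikes = _as_dense_input(input_spikes, net.layer_sizes[0], T)
    T = input_spikes.shape[1]

    if quantized:
        return _forward_quantized(
            net, input_spikes, T, weight_format, spsp_format,
            potential_format, accumulator_format,
        )

    L = net.n_layers
    states = [LayerState.zeros(n) for n in net.layer_sizes[1:]]
    p = [np.zeros(net.layer_sizes[k]) for k in range(L)]
    q = [np.zeros(w.shape) for w in net.weights]
    e = [np.zeros(w.shape) for w in net.weights]
    rasters = [input_spikes] + [
        np.zeros((n, T), dtype=bool) for n in net.layer_sizes[1:]
    ]

    for t in range(T):
        prev = input_spikes[:, t].astype(np.float64)
        for k in range(L):
            par = net.layer_params(k)
            states[k] = lif_step(states[k], net.weights[k] @ prev, par)
            fired = states[k].fired
            # online S-PSP: p update, then q, then post-fire capture/reset
            p[k] = (1.0 - 1.0 / par.tau_s) * p[k] + (1.0 / par.tau_s) * prev
            q[k] = (1.0 - 1.0 / par.tau_m) * q[k] + p[k]
            e[k][fired] += q[k][fired]
            q[k][fired] = 0.0
            rasters[k + 1][:, t] = fired
            prev = fired.astype(np.float64)

    counts = [r.sum(axis=1).astype(np.int64) for r in rasters]
    return ForwardResult(spikes=rasters, counts=counts, spsp=e)


def _forward_quantized(
    net: Network,
    input_spikes: np.ndarray,
    T: int,
    w_fmt: FixedPointFormat,
    e_fmt: FixedPointFormat,
    v_fmt: FixedPointFormat,
    acc_fmt: FixedPointFormat,
) -> ForwardResult:
    """Integer-only forward pass emulating the shift-based datapath."""
    L = net.n_layers
    w_raw = [quantize(w, w_fmt).raw for w in net.weights]
    nu_raw = [quantize(net.layer_params(k).threshold, v_fmt).raw for k in range(L)]
    powers = [net.layer_params(k).tau_powers() for k in range(L)]
    # synaptic injection 1/tau_s on the trace lattice; must be representable
    inj_raw = [quantize(1.0 / net.layer_params(k).tau_s, e_fmt).raw for k in range(L)]
    acc_shift = acc_fmt.frac_bits - v_fmt.frac_bits

    u = [np.zeros(n, dtype=np.int64) for n in net.layer_sizes[1:]]
    alpha = [np.zeros(n, dtype=np.int64) for n in net.layer_sizes[1:]]
    p = [np.zeros(net.layer_sizes[k], dtype=np.int64) for k in range(L)]
    q = [np.zeros(w.shape, dtype=np.int64) for w in net.weights]
    e = [np.zeros(w.shape, dtype=np.int64) for w in net.weights]
    rasters = [input_spikes] + [
        np.zeros((n, T), dtype=bool) for n in net.layer_sizes[1:]
    ]

    def sat(a, fmt):
        return np.clip(a, fmt.raw_min, fmt.raw_max)

    for t in range(T):
        prev = input_spikes[:, t].astype(np.int64)
        for k in range(L):
            pm, ps = powers[k]
            current = w_raw[k] @ prev  # wide integer accumulator, exact
            alpha[k] = sat(alpha[k] - (alpha[k] >> ps) + (current >> ps), acc_fmt)
            u[k] = sat(u[k] - (u[k] >> pm) + (alpha[k] >> acc_shift), v_fmt)
            fired = u[k] >= nu_raw[k]
            u[k][fired] = 0
            p[k] = sat(p[k] - (p[k] >> ps) + prev * inj_raw[k], e_fmt)
            q[k] = sat(q[k] - (q[k] >> pm) + p[k], e_fmt)
            e[k][fired] = sat(e[k][fired] + q[k][fired], e_fmt)
            q[k][fired] = 0
            rasters[k + 1][:, t] = fired
            prev = fired.astype(np.int64)

    counts = [r.sum(axis=1).astype(np.int64) for r in rasters]
    spsp = [ek.astype(np.float64) * e_fmt.resolution for ek in e]
    return ForwardResult(spikes=rasters, counts=counts, spsp=spsp, spsp_raw=e)


def spikes_to_table(raster: np.ndarray) -> np.ndarray:
    """Dense boolean raster ``(n, T)`` -> sparse ``(neuron, time)`` int table."""
    idx = np.argwhere(np.asarray(raster, dtype=bool))
    return idx.astype(np.int64)


def table_to_spikes(table: np.ndarray, n_neurons: int, T: int) -> np.ndarray:
    """Sparse ``(neuron, time)`` table -> dense boolean raster ``(n, T)``."""
    raster = np.zeros((n_neurons, T), dtype=bool)
    table = np.asarray(table, dtype=np.int64).reshape(-1, 2)
    raster[table[:, 0], table[:, 1]] = True
    return raster
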