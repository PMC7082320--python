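"""Spike-train level post-synaptic potential (S-PSP).

The S-PSP ``e_{i|j}`` is the total normalized PSP contribution of
pre-synaptic neuron ``j``'s spike train to post-synaptic neuron ``i``,
sampled at ``i``'s firing times with the kernel restarted at ``i``'s previous
firing:

    e_{i|j} = sum_{t_i^f} sum_{t_j^f} epsilon(t_i^f - that_i, t_i^f - t_j^f).

Two equivalent routes are provided:

* :func:`spsp_direct` — the event-based double sum over recorded spike
  times, in either ``"discrete"`` mode (the kernel induced by the simulator's
  own Euler recurrences, exact for the discrete system) or ``"continuous"``
  mode (the closed-form exponential kernel). Both exist as reference
  oracles; neither is the production path.
* :func:`spsp_online_step` — the per-step accumulator used during the
  forward pass. Two traces per synapse, a synaptic trace ``p`` and a
  membrane-contribution trace ``q``, are decayed and updated every step; when
  the post-neuron fires, ``q`` is banked into ``e`` and reset. On power-of-2
  time constants every multiply is a shift, which is how the hardware
  datapath realizes it.

In exact arithmetic the online accumulator and the discrete event-based sum
agree identically; in float64 they agree to ~1e-12 relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .neuron import NeuronParams, SpikeTrain, psp_kernel

__all__ = [
    "SPSPState",
    "spsp_online_step",
    "spsp_online_run",
    "spsp_direct",
    "psp_kernel_quadrature",
]


@dataclass
class SPSPState:
    """Per-synapse traces ``p``, ``q`` and accumulated S-PSP ``e``.

    ``p`` depends only on the pre-synaptic train and may be shared (via
    broadcasting) across all post-neurons of a layer; ``q`` and ``e`` are
    genuinely per-synapse because ``q`` resets at post-synaptic firings.
    """

    p: np.ndarray
    q: np.ndarray
    e: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "SPSPState":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape))


def spsp_online_step(
    state: SPSPState,
    pre_fired,
    post_fired,
    params: NeuronParams,
) -> SPSPState:
    """One step of the online S-PSP accumulator.

    Update order within a step: pre-spike injection into ``p``, then the
    ``q`` update, then post-fire handling (bank ``q`` into ``e`` and reset).
    A pre and post spike in the same step therefore both take effect: the
    injection is captured by ``e`` in that very step.

    ``pre_fired`` and ``post_fired`` are 0/1 indicators, scalar or arrays
    broadcastable against the state.
    """
    pre = np.asarray(pre_fired, dtype=np.float64)
    post = np.asarray(post_fired, dtype=np.float64)
    p = (1.0 - 1.0 / params.tau_s) * state.p + (1.0 / params.tau_s) * pre
    q = (1.0 - 1.0 / params.tau_m) * state.q + p
    e = state.e + post * q
    q = q * (1.0 - post)
    return SPSPState(p=p, q=q, e=e)


def spsp_online_run(pre: SpikeTrain, post: SpikeTrain, params: NeuronParams) -> float:
    """Run the online accumulator over a full trial for one synapse."""
    if pre.horizon != post.horizon:
        raise ValueError("pre and post trains must share the same horizon")
    pre_d = pre.to_dense()
    post_d = post.to_dense()
    state = SPSPState.zeros(())
    for t in range(pre.horizon):
        state = spsp_online_step(state, float(pre_d[t]), float(post_d[t]), params)
    return float(state.e)


def _discrete_pair_kernel(
    t_post: int, t_pre: int, t_prev_post: int | None, params: NeuronParams
) -> float:
    """Contribution of one (pre, post) spike pair under the Euler recurrences.

    Closed-form resummation of the discrete traces: with decay factors
    ``a = 1 - 1/tau_m`` and ``b = 1 - 1/tau_s``, a pre spike at ``t_pre``
    contributes to ``q`` at the post firing ``t_post`` (with ``q`` last reset
    at ``t_prev_post``)

        (1/tau_s) * sum_{t' = max(t_pre, t_prev_post + 1)}^{t_post}
                     a**(t_post - t') * b**(t' - t_pre).
    """
    if t_pre > t_post:
        return 0.0
    lower = t_pre if t_prev_post is None else max(t_pre, t_prev_post + 1)
    if lower > t_post:
        return 0.0
    a = 1.0 - 1.0 / params.tau_m
    b = 1.0 - 1.0 / params.tau_s
    tprime = np.arange(lower, t_post + 1)
    terms = a ** (t_post - tprime) * b ** (tprime - t_pre)
    return float(terms.sum() / params.tau_s)


def spsp_direct(
    pre: SpikeTrain,
    post: SpikeTrain,
    params: NeuronParams,
    mode: str = "discrete",
) -> float:
    """Event-based S-PSP: the double sum over recorded spike pairs.

    ``mode="discrete"`` evaluates the kernel induced by the simulator's own
    Euler recurrences and matches :func:`spsp_online_run` exactly (up to
    float round-off). ``mode="continuous"`` evaluates the closed-form
    exponential kernel :func:`stdfa.neuron.psp_kernel`; the discrete value
    converges to it (first order in ``1/tau_s``) as time constants and spike
    spacings grow.

    Before the post-neuron's first firing its "previous firing time" is taken
    as ``-inf``, so all contributions since trial start count toward the
    first spike.
    """
    if pre.horizon != post.horizon:
        raise ValueError("pre and post trains must share the same horizon")
    if mode not in ("discrete", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    total = 0.0
    prev: int | None = None
    for t_post in post.times:
        t_post = int(t_post)
        for t_pre in pre.times:
            t_pre = int(t_pre)
            if mode == "discrete":
                total += _discrete_pair_kernel(t_post, t_pre, prev, params)
            else:
                s = np.inf if prev is None else float(t_post - prev)
                total += psp_kernel(s, float(t_post - t_pre), params)
        prev = t_post
    return total


def psp_kernel_quadrature(s: float, t: float, params: NeuronParams) -> float:
    """Numerical evaluation of the kernel's defining convolution integral.

    Integrates the membrane impulse response against the normalized
    first-order synaptic response ``(1/tau_s) exp(-(t - t')/tau_s)`` over the
    window since the last post-synaptic firing:

        epsilon(s, t) = (1/tau_s) * int_0^s exp(-t'/tau_m)
                                     exp(-(t - t')/tau_s) H(t - t') dt'.

    Independent cross-check for the closed form; not used in simulation.
    """
    if s <= 0 or t <= 0:
        return 0.0
    upper = min(s, t)  # Heaviside kills the integrand beyond t
    val, _ = quad(
        lambda tp: np.exp(-tp / params.tau_m) * np.exp(-(t - tp) / params.tau_s),
        0.0,
        upper,
        epsabs=1e-14,
        epsrel=1e-12,
    )
    return val / params.tau_s
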