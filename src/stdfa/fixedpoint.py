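"""Fixed-point number formats and shift arithmetic.

Emulates the integer datapath of a digital (FPGA-style) spiking neural
processor so quantized training can be exercised in software and its accuracy
cost measured. A :class:`FixedPointFormat` describes a lattice
``{k * 2**-frac_bits}`` over the signed or unsigned integer range of
``total_bits``; a :class:`QuantizedValue` stores raw integers on that lattice.

Default storage formats (word length / fraction length):

========================  =======================
synaptic weight ``w``     signed 17-bit / 12-frac
S-PSP ``e``               unsigned 11-bit / 6-frac
membrane potential ``v``  signed 9-bit / 3-frac
========================  =======================

Decay by ``(1 - 1/tau)`` with ``tau`` a power of 2 is realized as
``raw - (raw >> log2(tau))`` (truncating arithmetic shift); multiplication by
a signed power-of-2 feedback weight is realized as a sign-corrected left
shift. Both are bit-exact integer operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FixedPointFormat",
    "QuantizedValue",
    "WEIGHT_FORMAT",
    "SPSP_FORMAT",
    "POTENTIAL_FORMAT",
    "ACCUMULATOR_FORMAT",
    "quantize",
    "dequantize",
    "shift_decay",
    "shift_mul",
]


@dataclass(frozen=True)
class FixedPointFormat:
    """Word length, fraction length and signedness of a quantized scalar.

    The representable values are ``raw * 2**-frac_bits`` with ``raw`` in
    ``[-2**(total_bits-1), 2**(total_bits-1) - 1]`` when signed, and
    ``[0, 2**total_bits - 1]`` when unsigned.
    """

    total_bits: int
    frac_bits: int
    signed: bool = True

    def __post_init__(self) -> None:
        if not (self.total_bits >= self.frac_bits >= 0):
            raise ValueError(
                f"need total_bits >= frac_bits >= 0, got "
                f"{self.total_bits}/{self.frac_bits}"
            )

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1)) if self.signed else 0

    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1 if self.signed else (1 << self.total_bits) - 1

    @property
    def resolution(self) -> float:
        """Lattice spacing, one unit in the last place."""
        return 2.0 ** -self.frac_bits

    @property
    def max_value(self) -> float:
        return self.raw_max * self.resolution

    @property
    def min_value(self) -> float:
        return self.raw_min * self.resolution


#: Default storage formats of the emulated hardware datapath.
WEIGHT_FORMAT = FixedPointFormat(17, 12, signed=True)
SPSP_FORMAT = FixedPointFormat(11, 6, signed=False)
POTENTIAL_FORMAT = FixedPointFormat(9, 3, signed=True)
#: Wider internal format for synaptic-current accumulation before the
#: membrane add; hardware accumulators are wider than storage.
ACCUMULATOR_FORMAT = FixedPointFormat(24, 12, signed=True)


@dataclass
class QuantizedValue:
    """Integer raw representation(s) plus the format interpreting them."""

    raw: np.ndarray
    fmt: FixedPointFormat

    @property
    def value(self) -> np.ndarray:
        """Real value(s) ``raw * 2**-frac_bits``."""
        return np.asarray(self.raw, dtype=np.float64) * self.fmt.resolution


def _saturate(raw: np.ndarray, fmt: FixedPointFormat) -> np.ndarray:
    return np.clip(raw, fmt.raw_min, fmt.raw_max)


def quantize(x, fmt: FixedPointFormat) -> QuantizedValue:
    """Round ``x`` to the nearest lattice point (ties to even), saturating.

    Out-of-range inputs clamp to the format's extreme representable values;
    there is no overflow error.
    """
    scaled = np.asarray(x, dtype=np.float64) * (1 << fmt.frac_bits)
    raw = np.rint(scaled).astype(np.int64)  # rint: round-half-to-even
    return QuantizedValue(_saturate(raw, fmt), fmt)


def dequantize(q: QuantizedValue) -> np.ndarray:
    return q.value


def shift_decay(q: QuantizedValue, tau_power: int) -> QuantizedValue:
    """Multiply by ``(1 - 2**-tau_power)`` as ``raw - (raw >> tau_power)``.

    This is the hardware decay step for a time constant ``tau = 2**tau_power``;
    the right shift truncates (floor division), matching shift registers.
    """
    raw = np.asarray(q.raw, dtype=np.int64)
    return QuantizedValue(raw - (raw >> tau_power), q.fmt)


def shift_mul(x: QuantizedValue, m: int, sign: int) -> QuantizedValue:
    """Multiply by ``sign * 2**m`` as a sign-corrected left shift.

    ``sign`` of 0 emulates the zero-mask skip for masked feedback entries.
    Results saturate to ``x``'s format.
    """
    if m < 0:
        raise ValueError("shift exponent m must be >= 0")
    raw = np.asarray(x.raw, dtype=np.int64)
    if sign == 0:
        out = np.zeros_like(raw)
    else:
        out = sign * (raw << m)
    return QuantizedValue(_saturate(out, x.fmt), x.fmt)
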