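"""Dimensionality reduction of squiggle traces.

Pipeline (in order): optional sample duplication, optional centering,
inverse discrete wavelet transform (the trace is interpreted as a
coefficient vector, coarsest approximation block first), clamping to
``[lo, hi]`` and integer quantization into a ``2**s``-code register with
the top code reserved as an out-of-range sentinel.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import _dwt
from .signal_io import SquiggleSignal

__all__ = [
    "TransformedSignal",
    "QuantizedSignal",
    "duplicate_samples",
    "inverse_dwt",
    "forward_dwt",
    "clamp_quantize",
    "required_register_size",
    "reduce_squiggle",
]

logger = logging.getLogger(__name__)

DEFAULT_CLAMP = (-25.0, 25.0)
DEFAULT_LEVELS = 2
DEFAULT_FILTER = "la8"


@dataclasses.dataclass(frozen=True)
class TransformedSignal:
    """Output of the (inverse) wavelet transform."""

    values: np.ndarray
    levels: int
    filter_id: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("transformed values must be finite")
        object.__setattr__(self, "values", arr)


@dataclasses.dataclass(frozen=True)
class QuantizedSignal:
    """Clamped integer codes plus the register geometry.

    In-range value ``v`` maps to code ``round(v - lo)``; anything outside
    ``[lo, hi]`` maps to the sentinel, the largest code of the register.
    """

    codes: np.ndarray
    s: int
    sentinel: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.size and (codes.min() < 0 or codes.max() >= (1 << self.s)):
            raise ValueError("codes must lie in [0, 2^s)")
        if not 0 <= self.sentinel < (1 << self.s):
            raise ValueError("sentinel must lie in [0, 2^s)")
        object.__setattr__(self, "codes", codes)

    @property
    def in_range_mask(self) -> np.ndarray:
        return self.codes != self.sentinel

    def to_values(self) -> np.ndarray:
        """Map in-range codes back to (quantized) values; sentinel -> NaN."""
        vals = self.codes.astype(float) + self.lo
        vals[~self.in_range_mask] = np.nan
        return vals


def duplicate_samples(signal: SquiggleSignal) -> SquiggleSignal:
    """Record every reading twice: ``[a, b] -> [a, a, b, b]``."""
    return SquiggleSignal(np.repeat(signal.readings, 2))


def _truncate(values: np.ndarray, levels: int) -> np.ndarray:
    block = 1 << levels
    keep = (values.size // block) * block
    if keep != values.size:
        logger.info("truncating signal from %d to %d samples (multiple of 2^%d)",
                    values.size, keep, levels)
    return values[:keep]


def inverse_dwt(signal, levels: int = DEFAULT_LEVELS, filter_id: str = DEFAULT_FILTER) -> TransformedSignal:
    """Inverse transform, treating the input as a coefficient vector.

    Input length is truncated to the largest multiple of ``2**levels``;
    output length equals the (truncated) input length.  Inverted exactly
    by :func:`forward_dwt`.
    """
    values = signal.readings if isinstance(signal, SquiggleSignal) else np.asarray(signal, dtype=float)
    values = _truncate(np.asarray(values, dtype=float), levels)
    out = _dwt.waverec(values, levels, filter_id)
    return TransformedSignal(out, levels, filter_id)


def forward_dwt(values, levels: int = DEFAULT_LEVELS, filter_id: str = DEFAULT_FILTER) -> np.ndarray:
    """Forward transform (coefficient vector out); mirror of inverse_dwt."""
    if isinstance(values, TransformedSignal):
        values = values.values
    values = _truncate(np.asarray(values, dtype=float), levels)
    return _dwt.wavedec(values, levels, filter_id)


def required_register_size(num_values: int) -> int:
    """Smallest ``s`` with ``2**s >= num_values``."""
    if num_values < 1:
        raise ValueError("num_values must be >= 1")
    return max(0, int(num_values - 1).bit_length())


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.where(values >= 0, np.floor(values + 0.5), np.ceil(values - 0.5))


def clamp_quantize(values, lo: float = DEFAULT_CLAMP[0], hi: float = DEFAULT_CLAMP[1]) -> QuantizedSignal:
    """Clamp to ``[lo, hi]`` and quantize to integer codes.

    Rounding is half-away-from-zero.  ``s`` is sized for the in-range
    codes plus one sentinel; the sentinel is the largest code ``2**s - 1``.
    """
    if isinstance(values, TransformedSignal):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size and not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if not lo < hi:
        raise ValueError("need lo < hi")
    num_in_range = int(round(hi - lo)) + 1
    s = required_register_size(num_in_range + 1)  # +1 for the sentinel
    sentinel = (1 << s) - 1
    codes = np.rint(_round_half_away(values) - lo).astype(np.int64)
    out_of_range = (values < lo) | (values > hi)
    codes[out_of_range] = sentinel
    return QuantizedSignal(codes, s, sentinel, float(lo), float(hi))


def reduce_squiggle(
    signal: SquiggleSignal,
    *,
    duplicate: bool = True,
    center: bool = True,
    levels: int = DEFAULT_LEVELS,
    filter_id: str = DEFAULT_FILTER,
    lo: float = DEFAULT_CLAMP[0],
    hi: float = DEFAULT_CLAMP[1],
) -> tuple[QuantizedSignal, TransformedSignal]:
    """Full reduction pipeline: duplicate -> center -> inverse DWT -> clamp.

    Centering (subtracting the mean before the orthogonal transform)
    removes the DC offset of the raw current scale; without it the
    transform output would sit on the raw-current scale rather than in a
    small band around zero.
    """
    sig = duplicate_samples(signal) if duplicate else signal
    values = np.asarray(sig.readings, dtype=float)
    if center and values.size:
        values = values - values.mean()
    transformed = inverse_dwt(values, levels=levels, filter_id=filter_id)
    return clamp_quantize(transformed, lo, hi), transformed
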