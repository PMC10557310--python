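"""Reliability and sizing mathematics for the detector circuits.

Covers three models: multiplicative accuracy accumulation over a
serialized register (``w**s``), exact binomial majority-vote decoding
over replicated qubits (ties on even replica counts count as failure),
and linear breadth/depth/volume scaling from the measured per-one-bit
circuit constants (breadth 4 qubits, transpiled depth 40 gates).
"""

from __future__ import annotations

import dataclasses
from math import comb

__all__ = [
    "NoiseParams",
    "ResourceEstimate",
    "register_accuracy",
    "majority_vote_error",
    "estimate_resources",
    "DEFAULT_WORST_ACCURACY",
    "UNIT_BREADTH",
    "UNIT_DEPTH",
]

DEFAULT_WORST_ACCURACY = 0.57  # worst measured per-unit accuracy
UNIT_BREADTH = 4   # qubits per one-bit arithmetic unit
UNIT_DEPTH = 40    # transpiled gates per one-bit arithmetic unit


@dataclasses.dataclass(frozen=True)
class NoiseParams:
    """Per-unit accuracy ``w`` (error ``e = 1 - w``) and replica count."""

    w: float
    n_rep: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")

    @property
    def e(self) -> float:
        return 1.0 - self.w


@dataclasses.dataclass(frozen=True)
class ResourceEstimate:
    """Linear circuit-size totals for an ``s``-bit register."""

    s: int
    unit_breadth: int = UNIT_BREADTH
    unit_depth: int = UNIT_DEPTH

    @property
    def breadth(self) -> int:
        return self.unit_breadth * self.s

    @property
    def depth(self) -> int:
        return self.unit_depth * self.s

    @property
    def volume(self) -> int:
        return self.unit_breadth * self.unit_depth * self.s

    def as_dict(self) -> dict[str, int]:
        return {"s": self.s, "breadth": self.breadth, "depth": self.depth,
                "volume": self.volume}


def register_accuracy(w: float, s: int) -> float:
    """Accuracy of ``s`` serialized one-bit units, each accurate w.p. ``w``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if s < 1:
        raise ValueError("s must be >= 1")
    return w ** s

def majority_vote_error(e: float, n_rep: int) -> float:
    """Failure probability of majority decoding over ``n_rep`` replicas.

    Exact binomial tail ``P(X >= ceil(n_rep / 2))`` for
    ``X ~ Binomial(n_rep, e)``: the vote fails when at least half the
    replicas err, so ties on even ``n_rep`` count as failure.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError("e must lie in [0, 1]")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    threshold = (n_rep + 1) // 2  # ceil(n/2)
    w = 1.0 - e
    return float(sum(comb(n_rep, k) * e ** k * w ** (n_rep - k)
                     for k in range(threshold, n_rep + 1)))


def estimate_resources(s: int, unit_breadth: int = UNIT_BREADTH,
                       unit_depth: int = UNIT_DEPTH) -> ResourceEstimate:
    """Breadth/depth/volume totals for an ``s``-bit register pipeline."""
    if s < 1:
        raise ValueError("s must be >= 1")
    return ResourceEstimate(int(s), int(unit_breadth), int(unit_depth))
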