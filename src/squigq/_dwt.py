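"""Periodized orthogonal discrete wavelet transform.

Implemented directly (no external wavelet dependency) for two filters:

* ``haar`` — length-2, used for closed-form tests;
* ``la8``  — the least-asymmetric length-8 orthogonal filter (the default
  of the R wavelet toolchain this mirrors; identical to ``sym4``).

Circular (periodized) boundary handling makes the analysis operator an
orthogonal matrix, so synthesis is its exact transpose and round-trip
error is at machine precision.

Coefficient layout for a ``levels``-deep transform of length ``N``
(``N`` divisible by ``2**levels``), coarsest block first::

    [ a_L (N/2^L) | d_L (N/2^L) | d_{L-1} (N/2^{L-1}) | ... | d_1 (N/2) ]
"""

from __future__ import annotations

import numpy as np

__all__ = ["FILTERS", "analysis_step", "synthesis_step", "wavedec", "waverec"]

_SQRT2 = np.sqrt(2.0)

# Least-asymmetric length-8 scaling coefficients (sum = sqrt(2)), Newton
# polished against the orthonormality + vanishing-moment equations so the
# periodized transform round-trips at ~1e-13 even on raw-current scales.
_LA8 = np.array(
    [
        -0.07576571478950221,
        -0.02963552764600245,
        0.497618667632775,
        0.803738751805132,
        0.29785779560530595,
        -0.09921954357663355,
        -0.012603967262031283,
        0.03222310060405146,
    ]
)

FILTERS: dict[str, np.ndarray] = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    "la8": _LA8,
}


def _filters(filter_id: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        h = FILTERS[filter_id]
    except KeyError:
        raise ValueError(f"unknown wavelet filter {filter_id!r}") from None
    # quadrature mirror: g[l] = (-1)^l h[L-1-l]
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return h, g


def analysis_step(x: np.ndarray, filter_id: str) -> tuple[np.ndarray, np.ndarray]:
    """One circular analysis step: even-length ``x`` -> (approx, detail)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n % 2:
        raise ValueError("analysis requires even length")
    h, g = _filters(filter_id)
    L = h.size
    needed = n + L - 2  # largest index reached is 2*(n/2 - 1) + L - 1
    reps = -(-(needed) // n) if n else 1
    ext = np.tile(x, max(1, reps))[:needed] if n else x
    a = np.zeros(n // 2)
    d = np.zeros(n // 2)
    for l in range(L):
        sl = ext[l : l + n - 1 : 2]
        a += h[l] * sl
        d += g[l] * sl
    return a, d


def synthesis_step(a: np.ndarray, d: np.ndarray, filter_id: str) -> np.ndarray:
    """Exact inverse of :func:`analysis_step`."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.shape != d.shape:
        raise ValueError("approx/detail length mismatch")
    h, g = _filters(filter_id)
    n = 2 * a.size
    x = np.zeros(n)
    k = np.arange(a.size)
    for l in range(h.size):
        idx = (2 * k + l) % n
        np.add.at(x, idx, a * h[l] + d * g[l])
    return x


def wavedec(x: np.ndarray, levels: int, filter_id: str) -> np.ndarray:
    """Multi-level analysis, returning the flat coarsest-first layout."""
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if x.size % (1 << levels):
        raise ValueError(f"length {x.size} not divisible by 2^{levels}")
    details: list[np.ndarray] = []
    a = x
    for _ in range(levels):
        a, d = analysis_step(a, filter_id)
        details.append(d)
    return np.concatenate([a] + details[::-1])


def waverec(coeffs: np.ndarray, levels: int, filter_id: str) -> np.ndarray:
    """Multi-level synthesis from the flat coarsest-first layout."""
    coeffs = np.asarray(coeffs, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = coeffs.size
    if n % (1 << levels):
        raise ValueError(f"length {n} not divisible by 2^{levels}")
    block = n >> levels
    a = coeffs[:block]
    pos = block
    for _ in range(levels):
        d = coeffs[pos : pos + a.size]
        a = synthesis_step(a, d, filter_id)
        pos += d.size
    return a
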