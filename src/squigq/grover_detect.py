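"""Grover-amplified quantum feature detectors.

The searchable object is the superposition of value pairs drawn from a
window of ``n`` quantized values:

* ramp detection pairs consecutive values ``(v[i+1], v[i])``;
* near-to-constant pairs the center value with each neighbor.

An explicit index register of ``a = max(1, ceil(log2(n-1)))`` qubits
addresses the ``n - 1`` pairs (unused branches carry zero amplitude).
Each oracle computes its violation predicate with reversible borrow
arithmetic, kicks the phase back off a flag qubit prepared as
``(|0> - |1>)/sqrt(2)``, and uncomputes its workspace.  The diffusion
operator reflects about the full prepared state, so the closed-form
Grover rotation holds exactly for any occupied-branch count.

A measured candidate index is always re-checked classically against the
single pair it names; the decision is "feature present" only when no
verified violating pair was found across the iteration schedule.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np

from .features import FeatureParams
from .reversible_core import (
    Circuit,
    MeasurementHistogram,
    bitstring,
    simulate_sparse,
    _borrow_chain,
    _constant_borrow_chain,
)

__all__ = [
    "WindowEncoding",
    "build_pair_superposition",
    "build_increase_oracle",
    "build_decrease_oracle",
    "build_near_constant_oracle",
    "oracle_marked_set",
    "grover_search",
    "grover_marked_mass",
    "detect_feature_quantum",
    "QuantumDetection",
    "quantum_window_classifier",
]


@dataclasses.dataclass(frozen=True)
class WindowEncoding:
    """Register layout shared by preparation and oracle circuits.

    Layout (LSB-first qubit indices): index register, minuend register,
    subtrahend register, then oracle workspace (difference register, two
    borrow chains, abs helper, mark qubit) and the phase-kickback flag.
    """

    n: int
    s: int
    pairs: tuple[tuple[int, int], ...]  # (minuend, subtrahend) per index

    @property
    def num_pairs(self) -> int:
        return len(self.pairs)

    @property
    def a(self) -> int:
        return max(1, (self.num_pairs - 1).bit_length())

    @property
    def index(self) -> tuple[int, ...]:
        return tuple(range(self.a))

    @property
    def minuend(self) -> tuple[int, ...]:
        return tuple(range(self.a, self.a + self.s))

    @property
    def subtrahend(self) -> tuple[int, ...]:
        return tuple(range(self.a + self.s, self.a + 2 * self.s))

    @property
    def diff(self) -> tuple[int, ...]:
        return tuple(range(self.a + 2 * self.s, self.a + 3 * self.s))

    @property
    def borrows1(self) -> tuple[int, ...]:
        return tuple(range(self.a + 3 * self.s, self.a + 4 * self.s))

    @property
    def borrows2(self) -> tuple[int, ...]:
        base = self.a + 4 * self.s
        return tuple(range(base, base + self.s + 1))

    @property
    def abs_helper(self) -> int:
        return self.a + 5 * self.s + 1

    @property
    def mark(self) -> int:
        return self.a + 5 * self.s + 2

    @property
    def flag(self) -> int:
        return self.a + 5 * self.s + 3

    @property
    def qubit_count(self) -> int:
        return self.a + 5 * self.s + 4


def _controlled_on_pattern(circ: Circuit, controls: Sequence[int], pattern: int,
                           body: Callable[[], None]) -> None:
    """Run ``body`` with 0-valued controls wrapped in X sandwiches."""
    zeros = [q for k, q in enumerate(controls) if not (pattern >> k) & 1]
    for q in zeros:
        circ.x(q)
    body()
    for q in zeros:
        circ.x(q)


def _prepare_uniform(circ: Circuit, qubits: Sequence[int], m: int,
                     controls: tuple[int, ...] = (), pattern: int = 0) -> None:
    """Uniform superposition over the first ``m`` states of ``qubits``.

    Recursive RY tree on qubits MSB-first; full subtrees become plain
    Hadamards.  ``controls``/``pattern`` carry the branch condition.
    """
    k = len(qubits)
    if m < 1 or m > (1 << k):
        raise ValueError("m out of range for register width")
    if m == 1:
        return  # branch stays |0...0>
    msb = qubits[-1]
    if m == (1 << k):  # full subtree: Hadamard everything
        for q in qubits:
            _controlled_on_pattern(
                circ, controls, pattern,
                lambda q=q: circ.append(_gate("H", q, controls)))
        return
    m0 = min(m, 1 << (k - 1))
    m1 = m - m0
    theta = 2.0 * math.atan2(math.sqrt(m1), math.sqrt(m0))
    if theta != 0.0:
        _controlled_on_pattern(
            circ, controls, pattern,
            lambda: circ.append(_gate("RY", msb, controls, theta)))
    lower = qubits[:-1]
    if lower:
        _prepare_uniform(circ, lower, m0, controls + (msb,), pattern)
        if m1 > 0:
            _prepare_uniform(circ, lower, m1, controls + (msb,),
                             pattern | (1 << len(controls)))


def _gate(kind: str, target: int, controls: Sequence[int], theta: float | None = None):
    from .reversible_core import Gate
    if kind == "RY":
        return Gate("RY", target, tuple(controls), theta)
    return Gate(kind, target, tuple(controls))


def build_pair_superposition(
    window: Sequence[int],
    s: int,
    mode: str = "consecutive",
    center: int | None = None,
) -> tuple[Circuit, WindowEncoding]:
    """State preparation: uniform index register + multiplexed pair load.

    After simulation the non-workspace part of the state is exactly
    ``(1/sqrt(n-1)) * sum_i |i>|minuend_i>|subtrahend_i>`` with the flag
    qubit in ``(|0> - |1>)/sqrt(2)``.
    """
    values = [int(v) for v in window]
    n = len(values)
    if n < 2:
        raise ValueError("window needs at least 2 values")
    if any(not 0 <= v < (1 << s) for v in values):
        raise ValueError(f"window values must lie in [0, 2^{s})")
    if mode == "consecutive":
        pairs = tuple((values[i + 1], values[i]) for i in range(n - 1))
    elif mode == "center":
        c = n // 2 if center is None else center
        if not 0 <= c < n:
            raise ValueError("center index out of range")
        pairs = tuple((values[c], values[i]) for i in range(n) if i != c)
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    enc = WindowEncoding(n, s, pairs)
    circ = Circuit(enc.qubit_count, {
        "index": enc.index, "minuend": enc.minuend, "subtrahend": enc.subtrahend,
        "flag": (enc.flag,),
    })
    # flag -> (|0> - |1>)/sqrt(2)
    circ.x(enc.flag)
    circ.h(enc.flag)
    _prepare_uniform(circ, enc.index, enc.num_pairs)
    for i, (hi, lo) in enumerate(pairs):
        def load(i=i, hi=hi, lo=lo) -> None:
            for j in range(s):
                if (hi >> j) & 1:
                    circ.mcx(enc.index, enc.minuend[j])
                if (lo >> j) & 1:
                    circ.mcx(enc.index, enc.subtrahend[j])
        _controlled_on_pattern(circ, enc.index, i, load)
    return circ, enc


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def _kickback_oracle(enc: WindowEncoding, compute: Circuit) -> Circuit:
    """compute -> CX(mark, flag) -> uncompute."""
    circ = Circuit(enc.qubit_count)
    circ.extend(compute)
    circ.cx(enc.mark, enc.flag)
    circ.extend(compute.inverse())
    return circ


def _mark_or(circ: Circuit, q1: int, q2: int, mark: int) -> None:
    """mark ^= (q1 OR q2), for a fresh |0> mark qubit."""
    circ.x(q1)
    circ.x(q2)
    circ.ccx(q1, q2, mark)
    circ.x(q2)
    circ.x(q1)
    circ.x(mark)


def _ramp_compute(enc: WindowEncoding, incr: int, reverse: bool) -> Circuit:
    circ = Circuit(enc.qubit_count)
    a, b = (enc.subtrahend, enc.minuend) if reverse else (enc.minuend, enc.subtrahend)
    _borrow_chain(circ, a, b, enc.diff, enc.borrows1)
    _constant_borrow_chain(circ, enc.diff, incr, enc.borrows2[: enc.s])
    # violation iff the pair difference went negative OR fell short of incr
    _mark_or(circ, enc.borrows1[-1], enc.borrows2[enc.s - 1], enc.mark)
    return circ


def build_increase_oracle(incr: int, s: int, encoding: WindowEncoding) -> Circuit:
    """Phase-flips pair components with ``minuend - subtrahend < incr``."""
    if not 0 < incr < (1 << (s - 1)):
        raise ValueError("incr must satisfy 0 < incr < 2^(s-1)")
    return _kickback_oracle(encoding, _ramp_compute(encoding, incr, reverse=False))


def build_decrease_oracle(incr: int, s: int, encoding: WindowEncoding) -> Circuit:
    """Phase-flips pair components with ``subtrahend - minuend < incr``."""
    if not 0 < incr < (1 << (s - 1)):
        raise ValueError("incr must satisfy 0 < incr < 2^(s-1)")
    return _kickback_oracle(encoding, _ramp_compute(encoding, incr, reverse=True))


def _abs_inline(circ: Circuit, wires: Sequence[int], helper: int) -> None:
    """Two's-complement |.| on ``wires`` (MSB = sign) with a sign helper."""
    sign = wires[-1]
    circ.cx(sign, helper)
    for w in wires:
        circ.cx(helper, w)
    for j in range(len(wires) - 1, 0, -1):
        circ.mcx((helper,) + tuple(wires[:j]), wires[j])
    circ.cx(helper, wires[0])


def build_near_constant_oracle(
    epsilon: int,
    s: int,
    encoding: WindowEncoding,
    allow_general: bool = False,
) -> Circuit:
    """Phase-flips pair components with ``|minuend - subtrahend| >= epsilon``.

    For ``epsilon = 2**k`` the test is the leading-zero check: any set bit
    among positions ``k..s`` of the (s+1)-bit absolute difference marks a
    violation.  Other epsilons are rejected unless ``allow_general`` is
    set, in which case a borrow comparator is used instead.
    """
    epsilon = int(epsilon)
    if not 0 < epsilon < (1 << (s - 1)):
        raise ValueError("epsilon must satisfy 0 < epsilon < 2^(s-1)")
    power_of_two = epsilon & (epsilon - 1) == 0
    if not power_of_two and not allow_general:
        raise ValueError("epsilon must be a power of two (or pass allow_general)")
    enc = encoding
    compute = Circuit(enc.qubit_count)
    _borrow_chain(compute, enc.minuend, enc.subtrahend, enc.diff, enc.borrows1)
    signed = enc.diff + (enc.borrows1[-1],)  # (s+1)-bit two's-complement diff
    _abs_inline(compute, signed, enc.abs_helper)
    if power_of_two:
        k = epsilon.bit_length() - 1
        high = signed[k:]
        for w in high:
            compute.x(w)
        compute.mcx(high, enc.mark)  # mark = all-high-bits-zero
        for w in high:
            compute.x(w)
        compute.x(enc.mark)  # mark = some high bit set = violation
    else:
        _constant_borrow_chain(compute, signed, epsilon, enc.borrows2)
        compute.cx(enc.borrows2[-1], enc.mark)
        compute.x(enc.mark)  # violation iff |diff| >= epsilon (no borrow)
    return _kickback_oracle(enc, compute)


def oracle_marked_set(oracle: Circuit, encoding: WindowEncoding) -> set[int]:
    """Extract the marked pair indices by classical phase tracking.

    Oracles are X-family permutations plus kickbacks onto the flag; a
    basis component picks up a ``-1`` phase exactly when a satisfied
    X-gate targets the flag.  Each occupied index branch is propagated
    once.
    """
    marked: set[int] = set()
    for i, (hi, lo) in enumerate(encoding.pairs):
        bits = i | (hi << encoding.minuend[0]) | (lo << encoding.subtrahend[0])
        phase = 1
        for gate in oracle.gates:
            if gate.kind != "X":
                raise ValueError("phase tracking requires an X-family oracle")
            satisfied = all((bits >> c) & 1 for c in gate.controls)
            if not satisfied:
                continue
            if gate.target == encoding.flag:
                phase = -phase
            else:
                bits ^= 1 << gate.target
        if phase < 0:
            marked.add(i)
    return marked


# ---------------------------------------------------------------------------
# Grover search
# ---------------------------------------------------------------------------

def grover_marked_mass(m: int, big_m: int, iterations: int) -> float:
    """Closed-form marked probability mass after ``iterations`` rounds."""
    if not 0 <= m <= big_m:
        raise ValueError("need 0 <= m <= M")
    if m == 0:
        return 0.0
    theta = math.asin(math.sqrt(m / big_m))
    return math.sin((2 * iterations + 1) * theta) ** 2


def _diffusion(prep: Circuit) -> Circuit:
    """Reflection about the prepared state: prep^-1, flip |0...0>, prep."""
    q = prep.qubit_count
    circ = Circuit(q)
    circ.extend(prep.inverse())
    for i in range(q):
        circ.x(i)
    circ.mcz(tuple(range(q - 1)), q - 1)
    for i in range(q):
        circ.x(i)
    circ.extend(prep)
    return circ


def index_distribution(amps: dict[int, complex], encoding: WindowEncoding) -> dict[int, float]:
    """Marginal measurement distribution of the index register."""
    mask = (1 << encoding.a) - 1
    dist: dict[int, float] = {}
    for basis, amp in amps.items():
        i = basis & mask
        dist[i] = dist.get(i, 0.0) + abs(amp) ** 2
    return dist


def grover_final_state(
    state_prep: Circuit,
    oracle: Circuit,
    iterations: int,
) -> dict[int, complex]:
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    amps = simulate_sparse(state_prep, 0)
    if iterations:
        step = Circuit(state_prep.qubit_count)
        step.extend(oracle)
        step.extend(_diffusion(state_prep))
        for _ in range(iterations):
            amps = simulate_sparse(step, amps)
    return amps


def grover_search(
    state_prep: Circuit,
    oracle: Circuit,
    iterations: int,
    shots: int = 1024,
    seed: int | None = None,
    encoding: WindowEncoding | None = None,
) -> tuple[int, MeasurementHistogram]:
    """Run prep + ``iterations`` Grover rounds, measure the index register.

    Returns the most frequently measured index and the full histogram
    (bitstrings of the index register width).
    """
    if encoding is None:
        raise ValueError("encoding is required to locate the index register")
    amps = grover_final_state(state_prep, oracle, iterations)
    dist = index_distribution(amps, encoding)
    hist = _sample_index_histogram(dist, encoding.a, shots, seed)
    return int(hist.most_frequent(), 2), hist


def _sample_index_histogram(
    dist: dict[int, float], a: int, shots: int, seed: int | None
) -> MeasurementHistogram:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, probs)
    counts = {bitstring(k, a): int(c) for k, c in zip(keys, draws) if c}
    return MeasurementHistogram(counts, shots)


# ---------------------------------------------------------------------------
# decision procedure
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class QuantumDetection:
    """Outcome of one quantum feature decision."""

    decision: bool
    kind: str
    counterexample: int | None
    histograms: tuple[MeasurementHistogram, ...]
    iterations_schedule: tuple[int, ...]


def _pair_violates(kind: str, pair: tuple[int, int], params: FeatureParams) -> bool:
    hi, lo = pair
    if kind == "increase":
        return hi - lo < params.incr
    if kind == "decrease":
        return lo - hi < params.incr
    if kind == "constant":
        return abs(hi - lo) >= params.epsilon
    raise ValueError(kind)


def _build_oracle(kind: str, params: FeatureParams, s: int, enc: WindowEncoding) -> Circuit:
    if kind == "increase":
        return build_increase_oracle(int(params.incr), s, enc)
    if kind == "decrease":
        return build_decrease_oracle(int(params.incr), s, enc)
    if kind == "constant":
        eps = int(params.epsilon)
        return build_near_constant_oracle(eps, s, enc,
                                          allow_general=eps & (eps - 1) != 0)
    raise ValueError(kind)


def _iteration_schedule(num_pairs: int, rounds: int) -> tuple[int, ...]:
    """Iteration counts per repeat: single-marked optimum, then 1, then 0.

    The trailing 0 (preparation only, uniform over occupied branches)
    guards against marked fractions where amplification overshoots; every
    measured candidate is classically verified, so extra rounds can only
    tighten the decision.
    """
    j_star = int(math.floor((math.pi / 4.0) * math.sqrt(num_pairs)))
    schedule: list[int] = []
    for j in (j_star, 1, 0):
        if j not in schedule:
            schedule.append(j)
    return tuple(schedule[:max(1, rounds)])


def _detect_single(
    window: Sequence[int],
    kind: str,
    params: FeatureParams,
    s: int,
    shots: int,
    seed: int,
    rounds: int,
    cache: dict | None,
) -> QuantumDetection:
    mode = "center" if kind == "constant" else "consecutive"
    center = params.center_index() if kind == "constant" else None
    values = [int(v) for v in window]
    n = len(values)
    if mode == "center":
        pairs = tuple((values[center], values[i]) for i in range(n) if i != center)
    else:
        pairs = tuple((values[i + 1], values[i]) for i in range(n - 1))
    big_m = len(pairs)
    schedule = _iteration_schedule(big_m, rounds)
    histograms: list[MeasurementHistogram] = []
    violations: set[int] = set()
    for r, j in enumerate(schedule):
        dist = _cached_index_distribution(
            values, kind, params, s, j, cache, mode, center)
        hist = _sample_index_histogram(dist, max(1, (big_m - 1).bit_length()),
                                       shots, seed + 7919 * r)
        histograms.append(hist)
        for key in hist.counts:
            i = int(key, 2)
            if i < big_m and _pair_violates(kind, pairs[i], params):
                violations.add(i)
    counterexample = min(violations) if violations else None
    return QuantumDetection(
        decision=not violations,
        kind=kind,
        counterexample=counterexample,
        histograms=tuple(histograms),
        iterations_schedule=schedule,
    )


def _cached_index_distribution(
    values: list[int],
    kind: str,
    params: FeatureParams,
    s: int,
    iterations: int,
    cache: dict | None,
    mode: str,
    center: int | None,
) -> dict[int, float]:
    """Final Grover index distribution, via full circuit simulation.

    With a shared ``cache`` dict, results are memoized on the violation
    pattern of the window's pairs: for this construction the index
    marginal depends only on which branches the oracle marks (oracle
    soundness itself is covered by exhaustive phase-tracking tests).
    """
    key = None
    if cache is not None:
        if mode == "center":
            pairs = tuple((values[center], values[i])
                          for i in range(len(values)) if i != center)
        else:
            pairs = tuple((values[i + 1], values[i]) for i in range(len(values) - 1))
        mask = 0
        for i, p in enumerate(pairs):
            if _pair_violates(kind, p, params):
                mask |= 1 << i
        key = (kind, len(pairs), s, iterations, mask,
               float(params.incr), float(params.epsilon))
        if key in cache:
            return cache[key]
    prep, enc = build_pair_superposition(values, s, mode=mode, center=center)
    oracle = _build_oracle(kind, params, s, enc)
    amps = grover_final_state(prep, oracle, iterations)
    dist = index_distribution(amps, enc)
    if cache is not None:
        cache[key] = dist
    return dist


def detect_feature_quantum(
    window: Sequence[int],
    kind: str,
    params: FeatureParams,
    s: int,
    shots: int = 1024,
    seed: int = 0,
    rounds: int = 3,
    cache: dict | None = None,
) -> QuantumDetection:
    """Quantum decision for one window and one feature kind.

    Peak/valley decisions are the conjunction of a half-window increase
    and a half-window decrease detection (in the appropriate order).
    Deterministic under a fixed seed.
    """
    if kind in ("constant", "increase", "decrease"):
        return _detect_single(window, kind, params, s, shots, seed, rounds, cache)
    if kind not in ("peak", "valley"):
        raise ValueError(f"unknown feature kind {kind!r}")
    values = [int(v) for v in window]
    if len(values) % 2 or len(values) < 4:
        raise ValueError("peak/valley windows need even length >= 4")
    h = len(values) // 2
    half_params = dataclasses.replace(params, n=h)
    first_kind = "increase" if kind == "peak" else "decrease"
    second_kind = "decrease" if kind == "peak" else "increase"
    first = _detect_single(values[:h], first_kind, half_params, s, shots, seed, rounds, cache)
    second = _detect_single(values[h:], second_kind, half_params, s, shots,
                            seed + 104729, rounds, cache)
    counterexample = first.counterexample
    if counterexample is None and second.counterexample is not None:
        counterexample = h + second.counterexample
    return QuantumDetection(
        decision=first.decision and second.decision,
        kind=kind,
        counterexample=counterexample,
        histograms=first.histograms + second.histograms,
        iterations_schedule=first.iterations_schedule,
    )


def quantum_window_classifier(
    s: int,
    shots: int = 1024,
    seed: int = 0,
    rounds: int = 3,
    cache: dict | None = None,
) -> Callable:
    """A window -> kinds function backed by the quantum detectors.

    Plugs into :func:`squigq.features.scan_features` as ``detector``.
    """

    def classify(window, params: FeatureParams) -> list[str]:
        values = [int(v) for v in np.asarray(window)]
        kinds = []
        for kind in ("constant", "increase", "decrease"):
            det = detect_feature_quantum(values, kind, params, s, shots, seed,
                                         rounds, cache)
            if det.decision:
                kinds.append(kind)
        if len(values) % 2 == 0 and len(values) >= 4:
            for kind in ("peak", "valley"):
                det = detect_feature_quantum(values, kind, params, s, shots,
                                             seed, rounds, cache)
                if det.decision:
                    kinds.append(kind)
        return kinds

    return classify
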