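"""Reversible-circuit simulation and arithmetic building blocks.

Gates are ``X``, ``H``, ``Z`` and ``RY`` with an arbitrary (possibly
empty) set of positive controls, which covers CNOT/Toffoli and the
multi-controlled X/Z used by the detectors.  Qubit 0 is the least
significant bit; bitstrings are printed most-significant-first.

Two simulation engines share the same gate semantics:

* a dense statevector (vector of ``2**q`` complex amplitudes), capped at
  ``MAX_DENSE_QUBITS``;
* a sparse dictionary of nonzero amplitudes, used for the wide but
  low-support detector circuits.

Arithmetic blocks are synthesized from their truth functions over
{X, CX, CCX} and verified exhaustively by the test-suite: the one-bit
full subtractor (difference ``q1 - q2`` with borrow-in/borrow-out), the
ripple borrow subtractor over two ``s``-bit registers, and the
two's-complement absolute value with a sign helper qubit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Gate",
    "Circuit",
    "QuantumState",
    "MeasurementHistogram",
    "MAX_DENSE_QUBITS",
    "simulate",
    "simulate_sparse",
    "measure",
    "full_subtractor_result",
    "full_subtractor_carry",
    "build_subtractor_result_circuit",
    "build_subtractor_carry_circuit",
    "build_ripple_subtractor",
    "build_abs_circuit",
    "apply_bitflip_noise",
]

MAX_DENSE_QUBITS = 24

_GATE_KINDS = ("X", "H", "Z", "RY")


@dataclasses.dataclass(frozen=True)
class Gate:
    """One gate: ``kind`` on ``target``, conditioned on all ``controls``."""

    kind: str
    target: int
    controls: tuple[int, ...] = ()
    param: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        controls = tuple(sorted(self.controls))
        if self.target in controls:
            raise ValueError("target must not be a control")
        if len(set(controls)) != len(controls):
            raise ValueError("duplicate control qubits")
        if (self.kind == "RY") != (self.param is not None):
            raise ValueError("param is required for RY and only RY")
        object.__setattr__(self, "controls", controls)

    @property
    def qubits(self) -> tuple[int, ...]:
        return self.controls + (self.target,)

    def inverse(self) -> "Gate":
        if self.kind == "RY":
            return Gate("RY", self.target, self.controls, -self.param)
        return self

    def is_permutation(self) -> bool:
        """True if the gate maps basis states to basis states (no phase)."""
        return self.kind == "X"


class Circuit:
    """An ordered gate list over ``qubit_count`` qubits.

    ``registers`` is an optional name -> qubit-index-tuple map carried for
    serialization and bookkeeping only.
    """

    def __init__(self, qubit_count: int, registers: Mapping[str, Sequence[int]] | None = None):
        if qubit_count < 1:
            raise ValueError("qubit_count must be >= 1")
        self.qubit_count = int(qubit_count)
        self.gates: list[Gate] = []
        self.registers: dict[str, tuple[int, ...]] = {
            name: tuple(idx) for name, idx in (registers or {}).items()
        }

    # -- builder helpers ---------------------------------------------------
    def append(self, gate: Gate) -> "Circuit":
        for q in gate.qubits:
            if not 0 <= q < self.qubit_count:
                raise ValueError(f"qubit index {q} out of range (width {self.qubit_count})")
        self.gates.append(gate)
        return self

    def x(self, t: int) -> "Circuit":
        return self.append(Gate("X", t))

    def h(self, t: int) -> "Circuit":
        return self.append(Gate("H", t))

    def z(self, t: int) -> "Circuit":
        return self.append(Gate("Z", t))

    def ry(self, theta: float, t: int, controls: Iterable[int] = ()) -> "Circuit":
        return self.append(Gate("RY", t, tuple(controls), float(theta)))

    def cx(self, c: int, t: int) -> "Circuit":
        return self.append(Gate("X", t, (c,)))

    def ccx(self, c1: int, c2: int, t: int) -> "Circuit":
        return self.append(Gate("X", t, (c1, c2)))

    def mcx(self, controls: Iterable[int], t: int) -> "Circuit":
        return self.append(Gate("X", t, tuple(controls)))

    def cz(self, c: int, t: int) -> "Circuit":
        return self.append(Gate("Z", t, (c,)))

    def mcz(self, controls: Iterable[int], t: int) -> "Circuit":
        return self.append(Gate("Z", t, tuple(controls)))

    def extend(self, other: "Circuit") -> "Circuit":
        if other.qubit_count > self.qubit_count:
            raise ValueError("cannot extend with a wider circuit")
        self.gates.extend(other.gates)
        return self

    def inverse(self) -> "Circuit":
        inv = Circuit(self.qubit_count, self.registers)
        inv.gates = [g.inverse() for g in reversed(self.gates)]
        return inv

    @property
    def breadth(self) -> int:
        return self.qubit_count

    @property
    def depth(self) -> int:
        """Longest dependency chain: gates sharing a qubit are ordered."""
        frontier = [0] * self.qubit_count
        for g in self.gates:
            level = 1 + max(frontier[q] for q in g.qubits)
            for q in g.qubits:
                frontier[q] = level
        return max(frontier, default=0)

    def is_permutation(self) -> bool:
        return all(g.is_permutation() for g in self.gates)

    # -- serialization -----------------------------------------------------
    def to_text(self) -> str:
        header = {"qubit_count": self.qubit_count, "registers": {
            k: list(v) for k, v in self.registers.items()}}
        lines = ["#%json " + json.dumps(header, sort_keys=True)]
        for g in self.gates:
            name = g.kind
            if g.kind in ("X", "Z"):
                name = {0: g.kind, 1: "C" + g.kind, 2: "CC" + g.kind}.get(
                    len(g.controls), "MC" + g.kind)
            elif g.controls:
                name = "MC" + g.kind
            parts = [name]
            if g.kind == "RY":
                parts.append(repr(g.param))
            parts += [str(q) for q in g.controls] + [str(g.target)]
            lines.append(" ".join(parts))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Circuit":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("#%json "):
            raise ValueError("missing circuit metadata header")
        meta = json.loads(lines[0][len("#%json "):])
        circ = cls(meta["qubit_count"], meta.get("registers", {}))
        for ln in lines[1:]:
            if ln.startswith("#"):
                continue
            parts = ln.split()
            name = parts[0]
            base = name.lstrip("MC") if name.startswith("MC") else name.lstrip("C")
            if base not in _GATE_KINDS:
                raise ValueError(f"unknown gate {name!r}")
            rest = parts[1:]
            param = None
            if base == "RY":
                param = float(rest[0])
                rest = rest[1:]
            qubits = [int(tok) for tok in rest]
            circ.append(Gate(base, qubits[-1], tuple(qubits[:-1]), param))
        return circ

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "Circuit":
        with open(path) as fh:
            return cls.from_text(fh.read())


# ---------------------------------------------------------------------------
# states and measurement
# ---------------------------------------------------------------------------

def _parse_initial(initial: str | int, qubit_count: int) -> int:
    if isinstance(initial, str):
        if len(initial) != qubit_count or set(initial) - {"0", "1"}:
            raise ValueError(f"initial bitstring must be {qubit_count} chars of 0/1")
        return int(initial, 2)  # MSB-first string
    idx = int(initial)
    if not 0 <= idx < (1 << qubit_count):
        raise ValueError("initial index out of range")
    return idx


def bitstring(index: int, qubit_count: int) -> str:
    return format(index, f"0{qubit_count}b")


@dataclasses.dataclass
class QuantumState:
    """Dense complex amplitude vector of length ``2**qubit_count``."""

    amplitudes: np.ndarray
    qubit_count: int

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=complex)
        if amp.size != 1 << self.qubit_count:
            raise ValueError("amplitude vector has wrong length")
        self.amplitudes = amp

    @property
    def norm(self) -> float:
        return float(np.sqrt(np.sum(np.abs(self.amplitudes) ** 2)))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2

    def nonzero(self, tol: float = 1e-12) -> dict[str, complex]:
        return {
            bitstring(i, self.qubit_count): complex(a)
            for i, a in enumerate(self.amplitudes)
            if abs(a) > tol
        }


@dataclasses.dataclass(frozen=True)
class MeasurementHistogram:
    """Counts per measured bitstring over a fixed number of shots."""

    counts: dict[str, int]
    shots: int

    def __post_init__(self) -> None:
        if self.shots < 1:
            raise ValueError("shots must be >= 1")
        if sum(self.counts.values()) != self.shots:
            raise ValueError("counts must sum to shots")

    def most_frequent(self) -> str:
        return max(sorted(self.counts), key=lambda k: self.counts[k])

    def frequency(self, key: str) -> float:
        return self.counts.get(key, 0) / self.shots


# ---------------------------------------------------------------------------
# dense engine
# ---------------------------------------------------------------------------

def _apply_gate_dense(state: np.ndarray, gate: Gate, qubit_count: int) -> None:
    idx = np.arange(state.size)
    cmask = 0
    for c in gate.controls:
        cmask |= 1 << c
    tmask = 1 << gate.target
    sel0 = np.flatnonzero(((idx & cmask) == cmask) & ((idx & tmask) == 0))
    sel1 = sel0 | tmask
    if gate.kind == "X":
        state[sel0], state[sel1] = state[sel1].copy(), state[sel0].copy()
    elif gate.kind == "Z":
        state[sel1] *= -1.0
    elif gate.kind == "H":
        a, b = state[sel0].copy(), state[sel1].copy()
        inv = 1.0 / math.sqrt(2.0)
        state[sel0] = (a + b) * inv
        state[sel1] = (a - b) * inv
    elif gate.kind == "RY":
        a, b = state[sel0].copy(), state[sel1].copy()
        c, s = math.cos(gate.param / 2), math.sin(gate.param / 2)
        state[sel0] = c * a - s * b
        state[sel1] = s * a + c * b
    else:  # pragma: no cover
        raise ValueError(gate.kind)


def simulate(circuit: Circuit, initial: str | int = 0) -> QuantumState:
    """Noiseless dense statevector evolution from a classical bitstring."""
    q = circuit.qubit_count
    if q > MAX_DENSE_QUBITS:
        raise ValueError(
            f"dense simulation capped at {MAX_DENSE_QUBITS} qubits (asked for {q}); "
            "use simulate_sparse")
    state = np.zeros(1 << q, dtype=complex)
    state[_parse_initial(initial, q)] = 1.0
    for gate in circuit.gates:
        _apply_gate_dense(state, gate, q)
    return QuantumState(state, q)


# ---------------------------------------------------------------------------
# sparse engine
# ---------------------------------------------------------------------------

_SPARSE_TOL = 1e-14


def _apply_gate_sparse(amps: dict[int, complex], gate: Gate) -> dict[int, complex]:
    cmask = 0
    for c in gate.controls:
        cmask |= 1 << c
    tmask = 1 << gate.target
    if gate.kind == "X":
        out: dict[int, complex] = {}
        for i, a in amps.items():
            out[i ^ tmask if (i & cmask) == cmask else i] = a
        return out
    if gate.kind == "Z":
        for i in amps:
            if (i & cmask) == cmask and (i & tmask):
                amps[i] = -amps[i]
        return amps
    # branching gates (H, RY)
    if gate.kind == "H":
        m00 = m01 = m10 = 1.0 / math.sqrt(2.0)
        m11 = -m00
    else:
        c, s = math.cos(gate.param / 2), math.sin(gate.param / 2)
        m00, m01, m10, m11 = c, -s, s, c
    out = {}
    for i, a in amps.items():
        if (i & cmask) != cmask:
            out[i] = out.get(i, 0.0) + a
            continue
        i0, i1 = i & ~tmask, i | tmask
        if i & tmask:
            out[i0] = out.get(i0, 0.0) + m01 * a
            out[i1] = out.get(i1, 0.0) + m11 * a
        else:
            out[i0] = out.get(i0, 0.0) + m00 * a
            out[i1] = out.get(i1, 0.0) + m10 * a
    return {i: a for i, a in out.items() if abs(a) > _SPARSE_TOL}


def simulate_sparse(
    circuit: Circuit,
    initial: str | int | dict[int, complex] = 0,
) -> dict[int, complex]:
    """Sparse statevector evolution; returns {basis index: amplitude}."""
    if isinstance(initial, dict):
        amps = dict(initial)
    else:
        amps = {_parse_initial(initial, circuit.qubit_count): 1.0 + 0.0j}
    for gate in circuit.gates:
        amps = _apply_gate_sparse(amps, gate)
    return amps


def measure(
    state: QuantumState | dict[int, complex],
    shots: int = 1024,
    seed: int | None = None,
    qubit_count: int | None = None,
) -> MeasurementHistogram:
    """Multinomial sampling from squared amplitude magnitudes."""
    if shots < 1:
        raise ValueError("shots must be >= 1")
    if isinstance(state, QuantumState):
        keys = np.arange(state.amplitudes.size)
        probs = state.probabilities()
        q = state.qubit_count
    else:
        if qubit_count is None:
            raise ValueError("qubit_count required for sparse states")
        keys = np.array(sorted(state), dtype=np.int64)
        probs = np.array([abs(state[k]) ** 2 for k in keys])
        q = qubit_count
    total = probs.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"state is not normalized (sum p = {total})")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, probs / total)
    counts = {bitstring(int(k), q): int(c) for k, c in zip(keys, draws) if c}
    return MeasurementHistogram(counts, shots)


# ---------------------------------------------------------------------------
# arithmetic truth functions and circuits
# ---------------------------------------------------------------------------

def full_subtractor_result(carry_in: int, q1: int, q2: int) -> int:
    """Difference bit of ``q1 - q2 - carry_in``: XOR of the three inputs."""
    return (carry_in ^ q1 ^ q2) & 1


def full_subtractor_carry(carry_in: int, q1: int, q2: int) -> int:
    """Borrow-out of ``q1 - q2 - carry_in``: majority(NOT q1, q2, carry_in)."""
    a, b, c = 1 - (q1 & 1), q2 & 1, carry_in & 1
    return int(a + b + c >= 2)


def build_subtractor_result_circuit() -> Circuit:
    """4 qubits: carry_in=0, q1=1, q2=2, result=3 (|0> initialized)."""
    circ = Circuit(4, {"carry_in": (0,), "q1": (1,), "q2": (2,), "result": (3,)})
    circ.cx(0, 3).cx(1, 3).cx(2, 3)
    return circ


def build_subtractor_carry_circuit() -> Circuit:
    """4 qubits: carry_in=0, q1=1, q2=2, carry_out=3 (|0> initialized).

    majority(a,b,c) = ab XOR ac XOR bc, with ``a = NOT q1`` realized by an
    X sandwich around the Toffolis that use q1.
    """
    circ = Circuit(4, {"carry_in": (0,), "q1": (1,), "q2": (2,), "carry_out": (3,)})
    circ.x(1)
    circ.ccx(1, 2, 3)
    circ.ccx(1, 0, 3)
    circ.x(1)
    circ.ccx(2, 0, 3)
    return circ


def _borrow_chain(circ: Circuit, a: Sequence[int], b: Sequence[int],
                  result: Sequence[int] | None, borrows: Sequence[int]) -> None:
    """Ripple ``a - b``: per-bit XOR difference + majority borrow.

    ``result`` may be None to compute borrows only.  ``borrows[i]`` must
    be fresh |0> qubits; ``borrows[-1]`` ends as the final borrow
    (1 iff a < b as unsigned integers).
    """
    s = len(a)
    for i in range(s):
        prev = borrows[i - 1] if i else None
        if result is not None:
            r = result[i]
            circ.cx(a[i], r)
            circ.cx(b[i], r)
            if prev is not None:
                circ.cx(prev, r)
        # borrow_i = majority(NOT a_i, b_i, borrow_{i-1})
        circ.x(a[i])
        circ.ccx(a[i], b[i], borrows[i])
        if prev is not None:
            circ.ccx(a[i], prev, borrows[i])
        circ.x(a[i])
        if prev is not None:
            circ.ccx(b[i], prev, borrows[i])


def build_ripple_subtractor(s: int) -> Circuit:
    """Two's-complement subtraction of two ``s``-bit registers.

    Layout (LSB first): a = [0..s), b = [s..2s), result = [2s..3s),
    borrow chain = [3s..4s).  For classical inputs the result register
    holds ``(a - b) mod 2**s`` and the final borrow qubit ``4s - 1`` is 1
    iff ``a < b``; superposed inputs work by linearity.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    regs = {
        "a": tuple(range(s)),
        "b": tuple(range(s, 2 * s)),
        "result": tuple(range(2 * s, 3 * s)),
        "borrows": tuple(range(3 * s, 4 * s)),
        "borrow": (4 * s - 1,),
    }
    circ = Circuit(4 * s, regs)
    _borrow_chain(circ, regs["a"], regs["b"], regs["result"], regs["borrows"])
    return circ


def _constant_borrow_chain(circ: Circuit, t: Sequence[int], k: int,
                           borrows: Sequence[int]) -> None:
    """Borrows of ``t - k`` for a classical constant ``k``.

    Final borrow qubit is 1 iff ``t < k`` (unsigned).
    """
    s = len(t)
    for i in range(s):
        k_i = (k >> i) & 1
        prev = borrows[i - 1] if i else None
        if prev is None:
            if k_i:  # borrow = NOT t_0
                circ.cx(t[i], borrows[i])
                circ.x(borrows[i])
            # k_i == 0: borrow stays 0
        elif k_i:  # borrow = NOT t_i OR prev = NOT(t_i AND NOT prev)
            circ.x(prev)
            circ.ccx(t[i], prev, borrows[i])
            circ.x(prev)
            circ.x(borrows[i])
        else:  # borrow = NOT t_i AND prev
            circ.x(t[i])
            circ.ccx(t[i], prev, borrows[i])
            circ.x(t[i])


def build_abs_circuit(s: int) -> Circuit:
    """Two's-complement absolute value of an ``s``-bit register.

    Register = qubits [0..s) (bit ``s-1`` is the sign), helper = qubit
    ``s`` (|0> initialized; ends up holding the original sign).  Negative
    inputs are bit-complemented and incremented; the most negative value
    maps to itself.
    """
    if s < 2:
        raise ValueError("s must be >= 2")
    regs = {"register": tuple(range(s)), "helper": (s,)}
    circ = Circuit(s + 1, regs)
    helper = s
    circ.cx(s - 1, helper)
    for i in range(s):
        circ.cx(helper, i)
    # controlled +1 on the register (MSB-down carry cascade)
    for j in range(s - 1, 0, -1):
        circ.mcx((helper,) + tuple(range(j)), j)
    circ.cx(helper, 0)
    return circ


def twos_complement_abs(x: int, s: int) -> int:
    """Classical oracle: |x| in s-bit two's complement (most negative fixed)."""
    if not 0 <= x < (1 << s):
        raise ValueError("x out of register range")
    signed = x - (1 << s) if x >= (1 << (s - 1)) else x
    return abs(signed) & ((1 << s) - 1)


# ---------------------------------------------------------------------------
# bit-flip noise channel
# ---------------------------------------------------------------------------

def noisy_trajectories(
    circuit: Circuit,
    flip_prob: float,
    shots: int = 1024,
    seed: int | None = None,
    initial: str | int = 0,
) -> np.ndarray:
    """Raw Monte-Carlo trajectory outcomes, one row of bits per shot.

    Column 0 is the most significant qubit, matching printed bitstrings.
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    if not circuit.is_permutation():
        raise ValueError("bit-flip trajectories require a permutation circuit "
                         "(X-family gates only)")
    q = circuit.qubit_count
    start = _parse_initial(initial, q)
    bits = np.zeros((shots, q), dtype=np.uint8)
    for i in range(q):
        bits[:, (q - 1) - i] = (start >> i) & 1  # column 0 = MSB for output
    rng = np.random.default_rng(seed)
    col = lambda qubit: (q - 1) - qubit
    for gate in circuit.gates:
        if gate.controls:
            ok = np.all(bits[:, [col(c) for c in gate.controls]] == 1, axis=1)
        else:
            ok = np.ones(shots, dtype=bool)
        bits[ok, col(gate.target)] ^= 1
        if flip_prob > 0.0:
            touched = [col(c) for c in gate.qubits]
            flips = rng.random((shots, len(touched))) < flip_prob
            bits[:, touched] ^= flips.astype(np.uint8)
    return bits


def apply_bitflip_noise(
    circuit: Circuit,
    flip_prob: float,
    shots: int = 1024,
    seed: int | None = None,
    initial: str | int = 0,
) -> MeasurementHistogram:
    """Monte-Carlo trajectories with per-gate, per-touched-qubit bit flips.

    Only defined for permutation (classical reversible) circuits, which
    all the arithmetic blocks are; with ``flip_prob == 0`` this reduces
    exactly to noiseless simulate + measure.
    """
    bits = noisy_trajectories(circuit, flip_prob, shots, seed, initial)
    counts: dict[str, int] = {}
    for row in bits:
        key = "".join("1" if b else "0" for b in row)
        counts[key] = counts.get(key, 0) + 1
    return MeasurementHistogram(counts, shots)
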