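import itertools
import math

import numpy as np
import pytest

from squigq import reversible_core as rc

INV_SQRT2 = 1.0 / math.sqrt(2.0)


def single_output(state):
    nz = state.nonzero()
    assert len(nz) == 1, nz
    return next(iter(nz))


class TestGateAndCircuit:
    def test_target_cannot_be_control(self):
        with pytest.raises(ValueError):
            rc.Gate("X", 1, (1,))

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            rc.Gate("T", 0)

    def test_ry_needs_param(self):
        with pytest.raises(ValueError):
            rc.Gate("RY", 0)
        with pytest.raises(ValueError):
            rc.Gate("X", 0, param=1.0)

    def test_index_out_of_range(self):
        circ = rc.Circuit(2)
        with pytest.raises(ValueError):
            circ.x(2)

    def test_depth_counts_longest_chain(self):
        circ = rc.Circuit(3)
        circ.x(0).x(1).x(0).cx(0, 2)
        # qubit 0 sees X, X, CX -> chain of 3
        assert circ.depth == 3
        assert circ.breadth == 3

    def test_serialization_roundtrip(self):
        circ = rc.Circuit(4, {"data": (0, 1), "out": (3,)})
        circ.x(0).h(1).z(2).cx(0, 1).ccx(0, 1, 2).mcx((0, 1, 2), 3)
        circ.mcz((0, 2), 3).ry(0.7853981633974483, 2, controls=(1,))
        text = circ.to_text()
        back = rc.Circuit.from_text(text)
        assert back.qubit_count == 4
        assert back.registers == circ.registers
        assert back.gates == circ.gates
        assert back.to_text() == text

    def test_file_roundtrip(self, tmp_path):
        circ = rc.build_ripple_subtractor(2)
        p = tmp_path / "sub2.qc"
        circ.save(p)
        assert rc.Circuit.load(p).gates == circ.gates


class TestSimulate:
    def test_x_flips(self):
        state = rc.simulate(rc.Circuit(1).x(0), "0")
        assert state.nonzero() == {"1": (1 + 0j)}

    def test_hadamard_balanced(self):
        state = rc.simulate(rc.Circuit(1).h(0), "0")
        np.testing.assert_allclose(state.amplitudes, [INV_SQRT2, INV_SQRT2], atol=1e-12)

    def test_hadamard_twice_restores(self):
        state = rc.simulate(rc.Circuit(1).h(0).h(0), "0")
        np.testing.assert_allclose(state.amplitudes, [1.0, 0.0], atol=1e-12)

    def test_width_cap(self):
        with pytest.raises(ValueError, match="dense"):
            rc.simulate(rc.Circuit(rc.MAX_DENSE_QUBITS + 1), 0)

    def test_norm_preserved_random_circuit(self, rng):
        circ = rc.Circuit(10)
        for _ in range(1000):
            kind = rng.choice(["X", "H", "Z", "RY"])
            qubits = rng.choice(10, size=3, replace=False)
            if kind == "RY":
                circ.ry(rng.uniform(0, 2 * np.pi), int(qubits[0]),
                        controls=[int(q) for q in qubits[1:]])
            else:
                circ.append(rc.Gate(kind, int(qubits[0]),
                                    tuple(int(q) for q in qubits[1:])))
        state = rc.simulate(circ, 0)
        assert abs(state.norm - 1.0) < 1e-9

    def test_reversibility(self, rng):
        circ = rc.Circuit(6)
        for _ in range(200):
            kind = rng.choice(["X", "H", "Z", "RY"])
            qubits = rng.choice(6, size=2, replace=False)
            if kind == "RY":
                circ.ry(rng.uniform(0, 2 * np.pi), int(qubits[0]), (int(qubits[1]),))
            else:
                circ.append(rc.Gate(kind, int(qubits[0]), (int(qubits[1]),)))
        full = rc.Circuit(6)
        full.extend(circ)
        full.extend(circ.inverse())
        state = rc.simulate(full, 0b101010)
        expected = np.zeros(64)
        expected[0b101010] = 1.0
        np.testing.assert_allclose(state.amplitudes, expected, atol=1e-9)

    def test_sparse_matches_dense(self, rng):
        circ = rc.Circuit(8)
        for _ in range(120):
            kind = rng.choice(["X", "H", "Z"])
            qubits = rng.choice(8, size=2, replace=False)
            circ.append(rc.Gate(kind, int(qubits[0]), (int(qubits[1]),)))
        dense = rc.simulate(circ, 3)
        sparse = rc.simulate_sparse(circ, 3)
        vec = np.zeros(256, dtype=complex)
        for idx, amp in sparse.items():
            vec[idx] = amp
        np.testing.assert_allclose(vec, dense.amplitudes, atol=1e-9)


class TestMeasure:
    def test_basis_state_all_shots(self):
        state = rc.simulate(rc.Circuit(2).x(0), 0)
        hist = rc.measure(state, shots=1024, seed=0)
        assert hist.counts == {"01": 1024}

    def test_balanced_within_binomial_bound(self):
        state = rc.simulate(rc.Circuit(1).h(0), 0)
        hist = rc.measure(state, shots=10_000, seed=1)
        sigma = math.sqrt(10_000 * 0.25)
        assert abs(hist.counts["0"] - 5000) < 5 * sigma

    def test_deterministic_under_seed(self):
        state = rc.simulate(rc.Circuit(3).h(0).h(1).h(2), 0)
        a = rc.measure(state, shots=500, seed=42)
        b = rc.measure(state, shots=500, seed=42)
        assert a.counts == b.counts

    def test_unnormalized_rejected(self):
        bad = rc.QuantumState(np.array([1.0, 1.0], dtype=complex), 1)
        with pytest.raises(ValueError, match="normal"):
            rc.measure(bad, shots=10)


class TestSubtractorUnits:
    TABLE = [  # (carry_in, q1, q2) -> (result, new_carry)
        ((0, 0, 0), (0, 0)),
        ((0, 0, 1), (1, 1)),
        ((0, 1, 0), (1, 0)),
        ((0, 1, 1), (0, 0)),
        ((1, 0, 0), (1, 1)),
        ((1, 0, 1), (0, 1)),
        ((1, 1, 0), (0, 0)),
        ((1, 1, 1), (1, 1)),
    ]

    @pytest.mark.parametrize("inputs,expected", TABLE)
    def test_truth_functions(self, inputs, expected):
        c, q1, q2 = inputs
        assert rc.full_subtractor_result(c, q1, q2) == expected[0]
        assert rc.full_subtractor_carry(c, q1, q2) == expected[1]

    @pytest.mark.parametrize("inputs,expected", TABLE)
    def test_circuits_match_truth_functions(self, inputs, expected):
        c, q1, q2 = inputs
        init = f"0{q2}{q1}{c}"  # MSB-first: output q3, q2, q1, q0
        out = single_output(rc.simulate(rc.build_subtractor_result_circuit(), init))
        assert int(out[0]) == expected[0]
        out = single_output(rc.simulate(rc.build_subtractor_carry_circuit(), init))
        assert int(out[0]) == expected[1]

    def test_result_is_xor_identity(self):
        for c, q1, q2 in itertools.product(range(2), repeat=3):
            assert rc.full_subtractor_result(c, q1, q2) == (c ^ q1 ^ q2)


class TestRippleSubtractor:
    @pytest.mark.parametrize("s", [1, 2, 3])
    def test_exhaustive_against_classical(self, s):
        circ = rc.build_ripple_subtractor(s)
        mask = (1 << s) - 1
        for a, b in itertools.product(range(1 << s), repeat=2):
            state = rc.simulate(circ, a | (b << s))
            idx = int(single_output(state), 2)
            result = (idx >> (2 * s)) & mask
            borrow = (idx >> (4 * s - 1)) & 1
            assert result == (a - b) % (1 << s)
            assert borrow == (1 if a < b else 0)

    def test_self_subtraction_is_zero(self):
        s = 3
        circ = rc.build_ripple_subtractor(s)
        for a in range(1 << s):
            idx = int(single_output(rc.simulate(circ, a | (a << s))), 2)
            assert (idx >> (2 * s)) & ((1 << s) - 1) == 0
            assert (idx >> (4 * s - 1)) & 1 == 0

    def test_spec_examples_s3(self):
        circ = rc.build_ripple_subtractor(3)
        idx = int(single_output(rc.simulate(circ, 5 | (3 << 3))), 2)
        assert (idx >> 6) & 7 == 2 and (idx >> 11) & 1 == 0
        idx = int(single_output(rc.simulate(circ, 3 | (5 << 3))), 2)
        assert (idx >> 6) & 7 == 0b110 and (idx >> 11) & 1 == 1  # -2, borrow

    def test_superposed_inputs_by_linearity(self):
        # put register a of width 2 into superposition over {0..3}, b = 1
        s = 2
        circ = rc.Circuit(4 * s)
        circ.h(0).h(1)
        circ.x(s)  # b = 1
        circ.extend(rc.build_ripple_subtractor(s))
        state = rc.simulate(circ, 0)
        nz = state.nonzero()
        assert len(nz) == 4
        for key, amp in nz.items():
            idx = int(key, 2)
            a = idx & 3
            result = (idx >> (2 * s)) & 3
            assert result == (a - 1) % 4
            assert abs(abs(amp) - 0.5) < 1e-12


class TestAbsCircuit:
    @pytest.mark.parametrize("s", [2, 3, 4])
    def test_exhaustive_against_twos_complement(self, s):
        circ = rc.build_abs_circuit(s)
        for x in range(1 << s):
            idx = int(single_output(rc.simulate(circ, x)), 2)
            assert idx & ((1 << s) - 1) == rc.twos_complement_abs(x, s)

    def test_positive_unchanged(self):
        idx = int(single_output(rc.simulate(rc.build_abs_circuit(3), 0b011)), 2)
        assert idx & 7 == 0b011

    def test_negative_three_becomes_three(self):
        idx = int(single_output(rc.simulate(rc.build_abs_circuit(3), 0b101)), 2)
        assert idx & 7 == 0b011

    def test_most_negative_fixed_point(self):
        idx = int(single_output(rc.simulate(rc.build_abs_circuit(3), 0b100)), 2)
        assert idx & 7 == 0b100

    def test_oracle_validation(self):
        with pytest.raises(ValueError):
            rc.twos_complement_abs(8, 3)


class TestBitflipNoise:
    def test_p_zero_matches_noiseless(self):
        circ = rc.build_subtractor_result_circuit()
        hist = rc.apply_bitflip_noise(circ, 0.0, shots=256, seed=0, initial="0011")
        expected = single_output(rc.simulate(circ, "0011"))
        assert hist.counts == {expected: 256}

    def test_out_of_range_rejected(self):
        circ = rc.Circuit(1).x(0)
        with pytest.raises(ValueError):
            rc.apply_bitflip_noise(circ, 1.5, shots=10)

    def test_non_permutation_rejected(self):
        circ = rc.Circuit(1).h(0)
        with pytest.raises(ValueError, match="permutation"):
            rc.apply_bitflip_noise(circ, 0.1, shots=10)

    def test_accuracy_decays_with_flip_probability(self):
        circ = rc.build_subtractor_result_circuit()
        expected = single_output(rc.simulate(circ, "0011"))
        freqs = [
            rc.apply_bitflip_noise(circ, p, shots=10_000, seed=5,
                                   initial="0011").frequency(expected)
            for p in (0.0, 0.02, 0.05, 0.1)
        ]
        assert freqs[0] == 1.0
        assert all(a >= b for a, b in zip(freqs, freqs[1:]))

    def test_half_flip_deep_circuit_is_uniform(self):
        circ = rc.Circuit(1)
        for _ in range(50):
            circ.x(0)
        hist = rc.apply_bitflip_noise(circ, 0.5, shots=10_000, seed=2)
        sigma = math.sqrt(10_000 * 0.25)
        assert abs(hist.counts.get("0", 0) - 5000) < 5 * sigma
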