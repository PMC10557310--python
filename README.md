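# squigq

Quantum-assisted feature extraction for Nanopore squiggle traces.

A squiggle is the time-ordered sequence of integer current readings a
nanopore sequencer emits. This package implements, end to end and fully
simulated:

- **`squigq.signal_io`** — plain-text trace and feature-call I/O, plus a
  deterministic synthetic-trace generator with planted, annotated
  features (constant stretches, sharp ramps, peaks, valleys).
- **`squigq.preprocess`** — dimensionality reduction: sample duplication,
  a periodized orthogonal (inverse) discrete wavelet transform (`haar`
  and the least-asymmetric length-8 filter `la8`, implemented
  in-package), clamping to `[-25, 25]` and quantization into a
  `2**s`-code register with a reserved out-of-range sentinel.
- **`squigq.features`** — classical detectors for the four feature
  classes (near-to-constant within `epsilon`; every step `>= incr` /
  `<= -incr`; peak/valley as ramp-up/ramp-down half-windows) and a
  sliding-window scanner that merges hits into interval calls.
- **`squigq.reversible_core`** — a dense + sparse statevector simulator
  over {X, H, Z, RY} with arbitrary control sets, the one-bit full
  subtractor (difference and borrow), a ripple borrow subtractor over
  two `s`-bit registers, a two's-complement absolute-value circuit, and
  a Monte-Carlo bit-flip noise channel for permutation circuits.
- **`squigq.grover_detect`** — quantum feature detectors: an indexed
  superposition of value pairs, reversible threshold / leading-zero
  oracles with phase kickback, Grover amplification with exact
  closed-form behaviour, and a verified decision procedure.
- **`squigq.analysis`** — reliability and sizing models: `w**s` register
  accuracy accumulation, exact binomial majority-vote decoding error
  (ties fail), and breadth/depth/volume estimates from the per-one-bit
  constants (breadth 4, transpiled depth 40).

## Command line

```sh
# synthesize a trace with planted features
squigq simulate --plan plan.yaml --sd 2.0 --seed 7 --out signal.tsv --truth truth.tsv

# reduce it (duplicate -> inverse DWT levels=2 -> clamp [-25,25] -> quantize)
squigq preprocess --in signal.tsv --out quantized.tsv --report report.json

# classical detection
squigq detect --in signal.tsv --mode classical --n 4 --incr 8 --epsilon 3 --out calls.tsv

# quantum detection on small-alphabet codes
squigq detect --in codes.tsv --mode quantum --n 4 --incr 3 --epsilon 2 --s 5 \
    --shots 1024 --seed 11 --out calls.tsv --evidence evidence.json

# run a serialized reversible circuit
squigq circuit run --circuit sub3.qc --init 101011 --shots 1024 --seed 1 --noise 0.0

# sizing and reliability models
squigq resources --register-size 6
squigq error-model --accuracy 0.57 --register-size 9 --replicas 16 --json
```

A plan file is a YAML list of segments:

```yaml
segments:
  - {kind: constant, length: 120, level: 450}
  - {kind: peak, length: 8, level: 450, slope: 8}
```

Every command accepts `--config file.yaml` (flat keys mirroring the
flags; explicit flags win) and writes a `<out>.manifest.json` recording
the effective parameters and seeds, so reruns are byte-identical.

## Conventions

- Intervals are 0-based, half-open `[start, end)`.
- Qubit 0 is the least significant bit; bitstrings print MSB-first.
- Near-constant comparison is strict (`< epsilon`); ramp comparison is
  non-strict (`>= incr`). Both boundaries are pinned by tests.
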