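"""Squiggle trace I/O and synthetic trace generation.

A squiggle is a time-ordered sequence of integer current readings.  The
exchange format is deliberately plain: one value per line, ``#`` comment
lines allowed.  Feature annotations/calls travel as TSV with 0-based,
half-open ``[start, end)`` intervals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FEATURE_KINDS",
    "SquiggleSignal",
    "FeatureAnnotation",
    "SegmentSpec",
    "SyntheticSpec",
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "generate_squiggle",
    "continuous_plan",
]

FEATURE_KINDS = ("constant", "increase", "decrease", "peak", "valley")

DEFAULT_RAW_RANGE = (300, 700)


class SignalParseError(ValueError):
    """Raised when a trace file contains a malformed token."""


@dataclasses.dataclass(frozen=True)
class SquiggleSignal:
    """An integer (or real, once transformed) current trace."""

    readings: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.readings)
        if arr.ndim != 1:
            raise ValueError("readings must be one-dimensional")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("readings must be finite")
        object.__setattr__(self, "readings", arr)

    @property
    def length(self) -> int:
        return int(self.readings.size)

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SquiggleSignal):
            return NotImplemented
        return np.array_equal(self.readings, other.readings)


@dataclasses.dataclass(frozen=True, order=True)
class FeatureAnnotation:
    """A ``[start, end)`` interval labelled with a feature kind."""

    start: int
    end: int
    kind: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def overlaps(self, other: "FeatureAnnotation") -> bool:
        return self.start < other.end and other.start < self.end


@dataclasses.dataclass(frozen=True)
class SegmentSpec:
    """One piece of a synthetic trace plan.

    ``slope`` is the per-sample step: positive for ``increase``, negative
    for ``decrease``, and the (positive) ramp magnitude for ``peak`` /
    ``valley``.  ``level`` is the starting value of the segment.
    """

    kind: str
    length: int
    level: float
    slope: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length < 0:
            raise ValueError("segment length must be >= 0")
        if self.kind == "increase" and self.slope <= 0:
            raise ValueError("increase segments need slope > 0")
        if self.kind == "decrease" and self.slope >= 0:
            raise ValueError("decrease segments need slope < 0")
        if self.kind in ("peak", "valley"):
            if self.slope <= 0:
                raise ValueError("peak/valley segments need slope > 0")
            if self.length % 2:
                raise ValueError("peak/valley segments need even length")


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """A full synthetic trace: segment plan + additive noise + seed."""

    segments: tuple[SegmentSpec, ...]
    noise_sd: float = 0.0
    seed: int = 0
    value_range: tuple[float, float] = DEFAULT_RAW_RANGE

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError("value_range must satisfy lo < hi")

    @property
    def total_length(self) -> int:
        return sum(seg.length for seg in self.segments)


def _segment_values(seg: SegmentSpec) -> np.ndarray:
    i = np.arange(seg.length, dtype=float)
    if seg.kind == "constant":
        return np.full(seg.length, float(seg.level))
    if seg.kind in ("increase", "decrease"):
        return seg.level + seg.slope * i
    # peak: strictly up for length/2 steps, then strictly down; valley is
    # the mirror image.  The two halves each satisfy the ramp definition.
    h = seg.length // 2
    sign = 1.0 if seg.kind == "peak" else -1.0
    up = seg.level + sign * seg.slope * np.arange(h, dtype=float)
    top = up[-1] if h else seg.level
    down = top - sign * seg.slope * np.arange(1, h + 1, dtype=float)
    return np.concatenate([up, down])


def generate_squiggle(spec: SyntheticSpec) -> tuple[SquiggleSignal, list[FeatureAnnotation]]:
    """Emit a deterministic synthetic trace plus its planted annotations.

    Noise is additive Gaussian, rounded to integer and clipped to the
    configured value range; with ``noise_sd == 0`` the output is exactly
    the piecewise plan (rounded to integers).
    """
    rng = np.random.default_rng(spec.seed)
    pieces: list[np.ndarray] = []
    annotations: list[FeatureAnnotation] = []
    pos = 0
    for seg in spec.segments:
        vals = _segment_values(seg)
        pieces.append(vals)
        if seg.length:
            annotations.append(FeatureAnnotation(pos, pos + seg.length, seg.kind))
        pos += seg.length
    clean = np.concatenate(pieces) if pieces else np.empty(0)
    if spec.noise_sd > 0:
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    lo, hi = spec.value_range
    readings = np.clip(np.rint(clean), lo, hi).astype(np.int64)
    return SquiggleSignal(readings), annotations


def continuous_plan(
    kinds: Sequence[str],
    const_len: int,
    feat_len: int,
    level: float,
    slope: float,
) -> tuple[SegmentSpec, ...]:
    """Interleave constant stretches with features, without level jumps.

    Every feature segment starts at the value the previous segment ended
    on, so segment boundaries themselves carry no spurious steps.
    """
    segs = [SegmentSpec("constant", const_len, level)]
    cur = float(level)
    for kind in kinds:
        if kind == "increase":
            segs.append(SegmentSpec(kind, feat_len, cur, slope))
            cur += slope * (feat_len - 1)
        elif kind == "decrease":
            segs.append(SegmentSpec(kind, feat_len, cur, -slope))
            cur -= slope * (feat_len - 1)
        elif kind == "peak":
            segs.append(SegmentSpec(kind, feat_len, cur, slope))
            cur -= slope
        elif kind == "valley":
            segs.append(SegmentSpec(kind, feat_len, cur, slope))
            cur += slope
        else:
            raise ValueError(f"continuous_plan cannot place kind {kind!r}")
        segs.append(SegmentSpec("constant", const_len, cur))
    return tuple(segs)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_token(token: str, lineno: int) -> float:
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        raise SignalParseError(f"line {lineno}: malformed value {token!r}") from None


def read_signal(path: str | Path, dialect: str = "one-per-line", column: int = 0) -> SquiggleSignal:
    """Read a trace: one value per line, or one TSV column.

    Empty files yield an empty signal.  A malformed token raises
    :class:`SignalParseError` naming the offending line.
    """
    if dialect not in ("one-per-line", "tsv-column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    values: list[float] = []
    all_int = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line if dialect == "one-per-line" else line.split("\t")[column]
            v = _parse_token(token, lineno)
            all_int = all_int and isinstance(v, int)
            values.append(v)
    dtype = np.int64 if all_int else np.float64
    return SquiggleSignal(np.asarray(values, dtype=dtype))


def write_signal(signal: SquiggleSignal | Sequence[float], path: str | Path) -> None:
    """Write one value per line; reals keep 17 significant digits."""
    arr = signal.readings if isinstance(signal, SquiggleSignal) else np.asarray(signal)
    with open(path, "w") as fh:
        if np.issubdtype(arr.dtype, np.integer):
            for v in arr:
                fh.write(f"{int(v)}\n")
        else:
            for v in arr:
                fh.write(f"{float(v):.17g}\n")


def write_annotations(annotations: Iterable[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#start\tend\tkind\tscore\n")
        for a in annotations:
            fh.write(f"{a.start}\t{a.end}\t{a.kind}\t{a.score:g}\n")


def read_annotations(path: str | Path) -> list[FeatureAnnotation]:
    out: list[FeatureAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SignalParseError(f"line {lineno}: expected >= 3 columns")
            start, end, kind = int(parts[0]), int(parts[1]), parts[2]
            score = float(parts[3]) if len(parts) > 3 else 1.0
            out.append(FeatureAnnotation(start, end, kind, score))
    return out
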