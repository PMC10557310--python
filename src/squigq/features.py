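"""Classical detectors for the four squiggle feature classes.

Definitions (on a window of ``n`` consecutive values):

* near-to-constant — every neighbor differs from the center value by
  strictly less than ``epsilon``;
* sharp increase — every consecutive difference is ``>= incr``
  (decrease: ``<= -incr``);
* peak — sharp increase on the first ``n/2`` values, sharp decrease on
  the last ``n/2`` (valley: the mirror image).

Boundary conventions are deliberate and pinned by tests: the constant
test is strict (``< epsilon``), the ramp test is non-strict (``>= incr``).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .signal_io import FeatureAnnotation, SquiggleSignal

__all__ = [
    "FeatureParams",
    "is_near_constant",
    "is_sharp_increase",
    "is_sharp_decrease",
    "is_peak",
    "is_valley",
    "scan_features",
    "match_calls",
]

NEIGHBOR_MODES = ("left", "right", "centered")


@dataclasses.dataclass(frozen=True)
class FeatureParams:
    """Detector thresholds.

    n : window length (>= 2; even for peak/valley).
    epsilon : near-constant tolerance (strictly greater differences fail).
    incr : minimum significant per-step increase.
    neighbor_mode : where the near-constant center sits — ``left`` means
        neighbors precede the center, ``right`` means they follow it,
        ``centered`` splits them half/half.
    """

    n: int
    epsilon: float
    incr: float
    neighbor_mode: str = "centered"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.incr <= 0:
            raise ValueError("incr must be > 0")
        if self.neighbor_mode not in NEIGHBOR_MODES:
            raise ValueError(f"unknown neighbor_mode {self.neighbor_mode!r}")

    def center_index(self) -> int:
        if self.neighbor_mode == "left":
            return self.n - 1
        if self.neighbor_mode == "right":
            return 0
        return self.n // 2


def is_near_constant(window: Sequence[float], center: int, epsilon: float) -> bool:
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    if not 0 <= center < w.size:
        raise ValueError("center index out of range")
    return bool(np.all(np.abs(w - w[center]) < epsilon))


def is_sharp_increase(window: Sequence[float], incr: float) -> bool:
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("window must have length >= 2")
    return bool(np.all(np.diff(w) >= incr))


def is_sharp_decrease(window: Sequence[float], incr: float) -> bool:
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("window must have length >= 2")
    return bool(np.all(np.diff(w) <= -incr))


def is_peak(window: Sequence[float], incr: float) -> bool:
    w = np.asarray(window, dtype=float)
    if w.size % 2 or w.size < 4:
        raise ValueError("peak window must have even length >= 4")
    h = w.size // 2
    return is_sharp_increase(w[:h], incr) and is_sharp_decrease(w[h:], incr)


def is_valley(window: Sequence[float], incr: float) -> bool:
    w = np.asarray(window, dtype=float)
    if w.size % 2 or w.size < 4:
        raise ValueError("valley window must have even length >= 4")
    h = w.size // 2
    return is_sharp_decrease(w[:h], incr) and is_sharp_increase(w[h:], incr)


def classify_window(window: Sequence[float], params: FeatureParams) -> list[str]:
    """All feature kinds that fire on one window (peaks need even n)."""
    kinds: list[str] = []
    w = np.asarray(window, dtype=float)
    if is_near_constant(w, params.center_index(), params.epsilon):
        kinds.append("constant")
    if is_sharp_increase(w, params.incr):
        kinds.append("increase")
    if is_sharp_decrease(w, params.incr):
        kinds.append("decrease")
    if w.size % 2 == 0 and w.size >= 4:
        if is_peak(w, params.incr):
            kinds.append("peak")
        if is_valley(w, params.incr):
            kinds.append("valley")
    return kinds


WindowDetector = Callable[[np.ndarray, FeatureParams], list[str]]


def _merge_runs(hits: list[tuple[int, int, str]]) -> list[FeatureAnnotation]:
    """Merge overlapping same-kind window hits into maximal intervals."""
    merged: list[FeatureAnnotation] = []
    by_kind: dict[str, list[tuple[int, int]]] = {}
    for start, end, kind in hits:
        by_kind.setdefault(kind, []).append((start, end))
    for kind, intervals in by_kind.items():
        intervals.sort()
        cur_s, cur_e = intervals[0]
        for s0, e0 in intervals[1:]:
            if s0 <= cur_e:  # overlapping or adjacent windows
                cur_e = max(cur_e, e0)
            else:
                merged.append(FeatureAnnotation(cur_s, cur_e, kind))
                cur_s, cur_e = s0, e0
        merged.append(FeatureAnnotation(cur_s, cur_e, kind))
    return sorted(merged)


def scan_features(
    signal: SquiggleSignal,
    params: FeatureParams,
    detector: WindowDetector | None = None,
) -> list[FeatureAnnotation]:
    """Slide the detectors along the trace and emit merged interval calls.

    ``detector`` defaults to the classical :func:`classify_window`; the
    quantum backend plugs in here.  Peak/valley hits suppress increase /
    decrease hits whose windows they contain.
    """
    if detector is None:
        detector = classify_window
    values = np.asarray(signal.readings, dtype=float)
    n = params.n
    if n > values.size:
        raise ValueError(f"window n={n} exceeds signal length {values.size}")
    hits: list[tuple[int, int, str]] = []
    for start in range(values.size - n + 1):
        window = values[start : start + n]
        for kind in detector(window, params):
            hits.append((start, start + n, kind))
    pv = [(s, e) for s, e, k in hits if k in ("peak", "valley")]
    if pv:
        hits = [
            (s, e, k)
            for s, e, k in hits
            if k in ("peak", "valley", "constant")
            or not any(ps <= s and e <= pe for ps, pe in pv)
        ]
    return _merge_runs(hits)


def match_calls(
    calls: Sequence[FeatureAnnotation],
    truth: Sequence[FeatureAnnotation],
) -> tuple[float, float]:
    """(precision, recall) with same-kind overlap as the match criterion."""
    if not calls and not truth:
        return 1.0, 1.0
    matched_calls = sum(
        1 for c in calls if any(c.kind == t.kind and c.overlaps(t) for t in truth)
    )
    matched_truth = sum(
        1 for t in truth if any(c.kind == t.kind and c.overlaps(t) for c in calls)
    )
    precision = matched_calls / len(calls) if calls else 1.0
    recall = matched_truth / len(truth) if truth else 1.0
    return precision, recall
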