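"""Episode-based evaluation of FoG detectors.

Window-based scoring inflates both true positives (long episodes span many
windows) and true negatives (patients sit or lie still for long stretches).
The episode-based protocol counters both: each ground-truth FoG episode is
scored once, as detected (TP) or missed (FN); each detection that overlaps
no episode is one FP; and the parts of a session free of both episodes and
detections are segmented into true-negative units with a 30 s cap — a clean
span of length L contributes ``floor(L/30)`` TNs plus one more if the
remainder exceeds 5 s (a 40 s activity-free span therefore counts 2 TN,
a 4 s gap none).

Intervals are half-open ``[start, end)`` in seconds; boundary contact is not
overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import WINDOW_DURATION_S, WINDOW_STRIDE_S

TN_MAX_SPAN_S = 30.0
TN_MIN_REMAINDER_S = 5.0
_TOL = 1e-9


class IntervalSet:
    """Ordered, non-overlapping half-open intervals on the session time axis."""

    def __init__(self, intervals):
        arr = np.asarray(list(intervals), dtype=float).reshape(-1, 2)
        if len(arr):
            arr = arr[np.argsort(arr[:, 0])]
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError("intervals must have end > start")
            if np.any(arr[1:, 0] < arr[:-1, 1] - _TOL):
                raise ValueError("intervals must not overlap")
        self.intervals = arr

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and np.array_equal(
            self.intervals, other.intervals
        )

    def total_duration(self) -> float:
        if not len(self):
            return 0.0
        return float((self.intervals[:, 1] - self.intervals[:, 0]).sum())

    def overlaps(self, start: float, end: float) -> bool:
        """True if any interval intersects [start, end) with positive measure."""
        return any(s < end - _TOL and start < e - _TOL for s, e in self.intervals)

    def to_csv(self, path: str | Path, label: str = "fog") -> None:
        pd.DataFrame(
            {
                "start_s": self.intervals[:, 0] if len(self) else [],
                "end_s": self.intervals[:, 1] if len(self) else [],
                "label": label,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = "fog") -> "IntervalSet":
        df = pd.read_csv(path)
        if label is not None and "label" in df.columns:
            df = df[df["label"] == label]
        return cls(df[["start_s", "end_s"]].to_numpy(dtype=float))


class EpisodeSet(IntervalSet):
    """Ground-truth FoG episode intervals for one session."""


class DetectionSet(IntervalSet):
    """Detector output intervals (merged runs of positive windows)."""


@dataclass
class ConfusionCounts:
    """Episode-level confusion counts; TP+FN equals the number of truth episodes."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass
class Metrics:
    """Sensitivity, specificity and their geometric mean.

    A metric whose denominator is zero (no truth episodes, or no negative
    opportunity) is undefined and reported as ``None`` — never as 0.
    """

    sensitivity: float | None
    specificity: float | None
    geometric_mean: float | None


def windows_to_detections(
    start_times: np.ndarray,
    decisions: np.ndarray,
    window_duration_s: float = WINDOW_DURATION_S,
    stride_s: float = WINDOW_STRIDE_S,
) -> DetectionSet:
    """Merge maximal runs of consecutive positive windows into intervals.

    Windows are consecutive when their start times differ by one stride; a
    run's interval is the union of its windows' spans, so a single positive
    window yields a 3.2 s detection.
    """
    start_times = np.asarray(start_times, dtype=float)
    decisions = np.asarray(decisions, dtype=bool)
    if start_times.shape != decisions.shape:
        raise ValueError("start_times and decisions length mismatch")
    intervals = []
    run_start = None
    prev_t = None
    for t, d in zip(start_times, decisions):
        if d:
            if run_start is not None and t - prev_t <= stride_s + _TOL:
                prev_t = t
            else:
                if run_start is not None:
                    intervals.append((run_start, prev_t + window_duration_s))
                run_start, prev_t = t, t
        else:
            if run_start is not None:
                intervals.append((run_start, prev_t + window_duration_s))
                run_start = None
    if run_start is not None:
        intervals.append((run_start, prev_t + window_duration_s))
    return DetectionSet(intervals)


def _clean_spans(
    truth: IntervalSet, detections: IntervalSet, session_span: tuple[float, float]
) -> list[tuple[float, float]]:
    """Maximal sub-spans of the session free of both episodes and detections."""
    lo, hi = session_span
    events = sorted(
        [(max(s, lo), min(e, hi)) for s, e in list(truth) + list(detections) if e > lo and s < hi]
    )
    spans = []
    cursor = lo
    for s, e in events:
        if s > cursor + _TOL:
            spans.append((cursor, s))
        cursor = max(cursor, e)
    if hi > cursor + _TOL:
        spans.append((cursor, hi))
    return spans


def tn_count(span_length_s: float) -> int:
    """TN units contributed by one clean span of the given length.

    ``floor(L/30)`` full units, plus one for a remainder strictly longer
    than 5 s.
    """
    if span_length_s < 0:
        raise ValueError("span length must be non-negative")
    k = math.floor((span_length_s + _TOL) / TN_MAX_SPAN_S)
    remainder = span_length_s - k * TN_MAX_SPAN_S
    return k + (1 if remainder > TN_MIN_REMAINDER_S + _TOL else 0)


def count_confusion(
    truth: EpisodeSet,
    detections: DetectionSet,
    session_span: tuple[float, float],
) -> ConfusionCounts:
    """Episode-level confusion counts for one session.

    TP/FN are scored per truth episode (overlapped by at least one detection
    or not); FP per detection overlapping no truth episode — a detection
    spanning two episodes contributes to both episodes' TP status, and
    multiple detections inside one episode still yield a single TP.  TN
    units come from segmenting clean spans.
    """
    lo, hi = session_span
    if hi <= lo:
        raise ValueError("session span must have positive length")
    clipped = []
    for s, e in detections:
        # up to one output sample of overhang is a resampling rounding
        # artefact and is clipped; anything larger is a caller error
        if s < lo - 0.05 or e > hi + 0.05:
            raise ValueError(f"detection [{s}, {e}) outside session span")
        clipped.append((max(s, lo), min(e, hi)))
    detections = DetectionSet(clipped)
    tp = sum(1 for s, e in truth if detections.overlaps(s, e))
    fn = len(truth) - tp
    fp = sum(1 for s, e in detections if not truth.overlaps(s, e))
    tn = sum(tn_count(e - s) for s, e in _clean_spans(truth, detections, session_span))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def score_sessions(
    start_times: np.ndarray,
    decisions: np.ndarray,
    truth: EpisodeSet,
    session_spans: list[tuple[float, float]],
    window_duration_s: float = WINDOW_DURATION_S,
    stride_s: float = WINDOW_STRIDE_S,
) -> ConfusionCounts:
    """Episode-level counts for window decisions spread over several sessions.

    Windows and truth episodes are partitioned by session span before run
    merging and TN segmentation, so detections and clean spans never bridge
    the gap between sessions.
    """
    start_times = np.asarray(start_times, dtype=float)
    decisions = np.asarray(decisions, dtype=bool)
    total = ConfusionCounts()
    for lo, hi in session_spans:
        mask = (start_times >= lo - _TOL) & (start_times < hi - _TOL)
        det = windows_to_detections(
            start_times[mask], decisions[mask], window_duration_s, stride_s
        )
        # a window starting just inside the span extends up to one window
        # duration past it (e.g. across a personal-split boundary); the
        # part beyond the span is scored by the complementary evaluation
        det = DetectionSet(
            [(max(s, lo), min(e, hi)) for s, e in det if max(s, lo) < min(e, hi)]
        )
        span_truth = EpisodeSet(
            [(s, e) for s, e in truth if s >= lo - _TOL and e <= hi + _TOL]
        )
        total = total + count_confusion(span_truth, det, (lo, hi))
    return total


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), and GM = √(Sens·Spec)."""
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else None
    gm = math.sqrt(sens * spec) if sens is not None and spec is not None else None
    return Metrics(sensitivity=sens, specificity=spec, geometric_mean=gm)


def geometric_mean(sensitivity: float, specificity: float) -> float:
    """√(sensitivity · specificity), on whatever scale the inputs share."""
    return math.sqrt(sensitivity * specificity)


def summarize_methods(cells: dict[tuple[str, str], tuple[float, float]]) -> pd.DataFrame:
    """Summary table for {(method, mode): (sensitivity, specificity)} cells.

    Adds the geometric mean per cell and is the basis for the method/mode
    contrasts (personalised − generic per method; SVM − baseline per mode).
    Inputs and outputs are in percent.
    """
    rows = []
    for (method, mode), (sens, spec) in cells.items():
        rows.append(
            {
                "method": method,
                "mode": mode,
                "sensitivity_pct": sens,
                "specificity_pct": spec,
                "geometric_mean_pct": geometric_mean(sens, spec),
            }
        )
    return pd.DataFrame(rows)


def gm_contrasts(summary: pd.DataFrame) -> dict[str, float]:
    """Geometric-mean deltas between the four method/mode cells (percent)."""
    gm = {
        (r["method"], r["mode"]): r["geometric_mean_pct"]
        for _, r in summary.iterrows()
    }
    out = {}
    if ("svm", "personalized") in gm and ("svm", "generic") in gm:
        out["svm_personalized_minus_generic"] = (
            gm[("svm", "personalized")] - gm[("svm", "generic")]
        )
    if ("svm", "generic") in gm and ("mbfa", "generic") in gm:
        out["generic_svm_minus_mbfa"] = gm[("svm", "generic")] - gm[("mbfa", "generic")]
    if ("svm", "personalized") in gm and ("mbfa", "personalized") in gm:
        out["personalized_svm_minus_mbfa"] = (
            gm[("svm", "personalized")] - gm[("mbfa", "personalized")]
        )
    if ("mbfa", "personalized") in gm and ("mbfa", "generic") in gm:
        out["mbfa_personalized_minus_generic"] = (
            gm[("mbfa", "personalized")] - gm[("mbfa", "generic")]
        )
    return out
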