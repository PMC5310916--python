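"""Freeze-index threshold baseline (Moore–Bächlin style) for FoG detection.

For each analysis window the power spectral density (squared DFT magnitudes)
of one acceleration channel is summed over the walking band WB (0.5–3 Hz)
and the freezing band FB (3–8 Hz).  The freeze index FI = FB/WB quantifies
trembling relative to locomotion; the power index PI = WB + FB gates out
windows with no movement at all.  A window is flagged FoG when FI > FTH and
PI > PTH.

The two thresholds are optimised on a 9×9 grid (0 to 4 in steps of 0.5) by
maximising pooled Sensitivity·Specificity under the constraint that both
exceed 70%, in a leave-one-patient-out fashion; a personalised variant
blends the pooled leave-one-out surface with the test subject's own
half-session surface before optimising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import (
    ConfusionCounts,
    DetectionSet,
    EpisodeSet,
    score_sessions,
    windows_to_detections,
)
from .features import BAND_FREEZE, BAND_WALK, Spectrum, band_bins, stft
from .preprocess import FS_TARGET, WindowSeries

logger = logging.getLogger(__name__)

FI_EPS = 1e-12
DEFAULT_THRESHOLD_GRID = tuple(float(x) for x in np.arange(0.0, 4.0 + 1e-9, 0.5))
MIN_SENSITIVITY = 0.70
MIN_SPECIFICITY = 0.70


@dataclass
class MBFAParams:
    """Decision thresholds and band configuration for the baseline detector."""

    fth: float = 1.0
    pth: float = 1.0
    walking_band: tuple[float, float] = BAND_WALK
    freezing_band: tuple[float, float] = BAND_FREEZE
    channel: str = "modulus"
    constrained: bool = True  # False when the 70%/70% feasibility fallback fired

    def __post_init__(self) -> None:
        if self.fth < 0 or self.pth < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class MBFAWindowOutput:
    fi: float
    pi: float
    decision: bool
    start_time: float


def freeze_power_index(
    window: np.ndarray,
    params: MBFAParams | None = None,
    fs: float = FS_TARGET,
) -> tuple[float, float]:
    """Freeze index and power index of one window.

    PSD is the squared DFT magnitude of the selected channel; WB and FB sum
    it over the band bins; FI = FB/(WB + ε) with ε = 1e−12 guarding rest
    windows, PI = WB + FB.
    """
    params = params or MBFAParams()
    spec = stft(np.asarray(window, dtype=float), fs)
    psd = spec.magnitude(params.channel) ** 2
    wb = float(psd[band_bins(*params.walking_band, fs, spec.n)].sum())
    fb = float(psd[band_bins(*params.freezing_band, fs, spec.n)].sum())
    return fb / (wb + FI_EPS), wb + fb


def window_outputs(
    series: WindowSeries, params: MBFAParams | None = None
) -> list[MBFAWindowOutput]:
    """FI/PI and threshold decisions for every window of a recording."""
    params = params or MBFAParams()
    out = []
    for w, t in zip(series.windows, series.start_times):
        fi, pi = freeze_power_index(w, params, series.fs)
        out.append(
            MBFAWindowOutput(
                fi=fi,
                pi=pi,
                decision=(fi > params.fth) and (pi > params.pth),
                start_time=float(t),
            )
        )
    return out


def detect(series: WindowSeries, params: MBFAParams) -> DetectionSet:
    """Run the threshold detector and merge positive windows into intervals."""
    outs = window_outputs(series, params)
    return windows_to_detections(
        np.array([o.start_time for o in outs]),
        np.array([o.decision for o in outs]),
        series.duration_s,
        series.stride_s,
    )


@dataclass
class ThresholdGridEval:
    """Confusion counts of one subject's data over the full threshold grid.

    ``counts[i][j]`` holds the episode-level counts at ``(fth_grid[i],
    pth_grid[j])`` — the Eval_k surface the grid optimisers pool.
    """

    fth_grid: tuple[float, ...]
    pth_grid: tuple[float, ...]
    counts: list[list[ConfusionCounts]] = field(repr=False, default_factory=list)


def evaluate_grid(
    fi: np.ndarray,
    pi: np.ndarray,
    start_times: np.ndarray,
    truth: EpisodeSet,
    session_spans: list[tuple[float, float]],
    grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
    window_duration_s: float | None = None,
    stride_s: float | None = None,
) -> ThresholdGridEval:
    """Episode-level confusion counts at every (FTH, PTH) grid point.

    ``session_spans`` lists the time extents of the underlying sessions so
    clean-span TN segmentation never bridges a between-session gap.
    """
    from .preprocess import WINDOW_DURATION_S, WINDOW_STRIDE_S

    window_duration_s = window_duration_s or WINDOW_DURATION_S
    stride_s = stride_s or WINDOW_STRIDE_S
    fi = np.asarray(fi, dtype=float)
    pi = np.asarray(pi, dtype=float)
    start_times = np.asarray(start_times, dtype=float)
    counts = []
    for fth in grid:
        row = []
        for pth in grid:
            decisions = (fi > fth) & (pi > pth)
            row.append(
                score_sessions(
                    start_times, decisions, truth, session_spans,
                    window_duration_s, stride_s,
                )
            )
        counts.append(row)
    return ThresholdGridEval(fth_grid=tuple(grid), pth_grid=tuple(grid), counts=counts)


def _pooled_sens_spec(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    return sens, spec


def _argmax_product(
    surface: dict[tuple[float, float], tuple[float | None, float | None]],
) -> tuple[float, float, bool]:
    """Grid point maximising Sens·Spec under the 70%/70% constraint.

    Grid points with an undefined metric are skipped.  If no point satisfies
    the constraint, falls back to the unconstrained argmax (logged).  Ties
    resolve to the smallest FTH, then the smallest PTH.
    """
    feasible, unconstrained = [], []
    for (fth, pth), (sens, spec) in surface.items():
        if sens is None or spec is None:
            logger.warning(
                "grid point (FTH=%s, PTH=%s) has undefined sens/spec; skipped",
                fth, pth,
            )
            continue
        item = (sens * spec, -fth, -pth)
        unconstrained.append((item, fth, pth))
        if sens > MIN_SENSITIVITY and spec > MIN_SPECIFICITY:
            feasible.append((item, fth, pth))
    if not unconstrained:
        raise ValueError("no grid point has defined sensitivity and specificity")
    pool = feasible
    constrained = True
    if not pool:
        logger.warning(
            "no threshold pair reaches sensitivity and specificity > 70%%; "
            "falling back to the unconstrained argmax"
        )
        pool = unconstrained
        constrained = False
    _, fth, pth = max(pool, key=lambda it: it[0])
    return fth, pth, constrained


def grid_search_generic(
    cohort_evals: dict[str, ThresholdGridEval], test_subject: str
) -> MBFAParams:
    """Leave-one-patient-out threshold selection.

    Confusion counts are summed over every subject except ``test_subject``;
    pooled sensitivity and specificity are computed per grid point and the
    constrained product argmax returned.
    """
    train = {k: v for k, v in cohort_evals.items() if k != test_subject}
    if not train:
        raise ValueError("cohort contains no training subjects")
    ref = next(iter(train.values()))
    surface = {}
    for i, fth in enumerate(ref.fth_grid):
        for j, pth in enumerate(ref.pth_grid):
            pooled = ConfusionCounts()
            for ev in train.values():
                pooled = pooled + ev.counts[i][j]
            surface[(fth, pth)] = _pooled_sens_spec(pooled)
    fth, pth, ok = _argmax_product(surface)
    return MBFAParams(fth=fth, pth=pth, constrained=ok)


def personalize_thresholds(
    cohort_evals: dict[str, ThresholdGridEval],
    test_subject: str,
    half_eval: ThresholdGridEval,
    weights: tuple[float, float],
    convention: str = "as_printed",
) -> MBFAParams:
    """Personalised threshold selection blending pooled and own-half surfaces.

    The blended surface is ``Sens(PM) = Sens(LOO)·w_t + Sens(half)·w_20``
    (likewise for specificity) — the weight attachment exactly as published,
    which pairs w_t (the large, cohort-side weight) with the pooled term.
    ``convention='swapped'`` exchanges the two weights instead; no attempt is
    made to arbitrate the published intent.
    """
    w_t, w_20 = weights
    if convention == "swapped":
        w_t, w_20 = w_20, w_t
    elif convention != "as_printed":
        raise ValueError(f"unknown weight convention {convention!r}")
    train = {k: v for k, v in cohort_evals.items() if k != test_subject}
    if not train:
        raise ValueError("cohort contains no training subjects")
    ref = next(iter(train.values()))
    surface = {}
    for i, fth in enumerate(ref.fth_grid):
        for j, pth in enumerate(ref.pth_grid):
            pooled = ConfusionCounts()
            for ev in train.values():
                pooled = pooled + ev.counts[i][j]
            loo_sens, loo_spec = _pooled_sens_spec(pooled)
            h_sens, h_spec = _pooled_sens_spec(half_eval.counts[i][j])
            if None in (loo_sens, loo_spec, h_sens, h_spec):
                surface[(fth, pth)] = (None, None)
                continue
            surface[(fth, pth)] = (
                loo_sens * w_t + h_sens * w_20,
                loo_spec * w_t + h_spec * w_20,
            )
    fth, pth, ok = _argmax_product(surface)
    return MBFAParams(fth=fth, pth=pth, constrained=ok)
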