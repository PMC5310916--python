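"""Freeze-index baseline: FI/PI computation and threshold optimisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogbench.evaluation import ConfusionCounts
from fogbench.mbfa import (
    DEFAULT_THRESHOLD_GRID,
    MBFAParams,
    ThresholdGridEval,
    freeze_power_index,
    grid_search_generic,
    personalize_thresholds,
)

from conftest import cosine_window

X_PARAMS = MBFAParams(channel="x")


class TestFreezePowerIndex:
    def test_zero_window(self):
        fi, pi = freeze_power_index(np.zeros((128, 3)), X_PARAMS)
        assert fi == 0.0
        assert pi == 0.0
        assert not (fi > 0.5 and pi > 0.5)

    def test_freeze_band_cosine(self):
        # bin 20 = 6.25 Hz: FB = (N/2)^2 = 4096, WB ~ 0 -> FI explodes
        fi, pi = freeze_power_index(cosine_window(bin_index=20), X_PARAMS)
        assert pi == pytest.approx(4096.0, rel=1e-9)
        assert fi >= 1e6

    def test_walking_band_cosine(self):
        # bin 4 = 1.25 Hz: WB = 4096, FB ~ 0
        fi, pi = freeze_power_index(cosine_window(bin_index=4), X_PARAMS)
        assert pi == pytest.approx(4096.0, rel=1e-9)
        assert fi <= 1e-6

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fi_scale_invariant_pi_quadratic(self, c):
        w = cosine_window(bin_index=20, amplitude=0.3)
        w[:, 0] += 0.1 * np.cos(2 * np.pi * 4 * np.arange(128) / 128)
        fi1, pi1 = freeze_power_index(w, X_PARAMS)
        fi2, pi2 = freeze_power_index(c * w, X_PARAMS)
        assert fi2 == pytest.approx(fi1, rel=1e-6)
        assert pi2 == pytest.approx(c**2 * pi1, rel=1e-6)

    def test_decision_monotone_in_thresholds(self):
        w = cosine_window(bin_index=20, amplitude=0.05)
        fi, pi = freeze_power_index(w, X_PARAMS)
        previous = True
        for fth in DEFAULT_THRESHOLD_GRID:
            decision = (fi > fth) and (pi > 1.0)
            assert not (decision and not previous)  # never flips back on
            previous = decision


def _grid_eval_from_fn(fn) -> ThresholdGridEval:
    grid = DEFAULT_THRESHOLD_GRID
    counts = [[fn(fth, pth) for pth in grid] for fth in grid]
    return ThresholdGridEval(fth_grid=grid, pth_grid=grid, counts=counts)


def _separable_counts(fth: float, pth: float) -> ConfusionCounts:
    """FoG windows all at FI=3, PI=2; clean signal below 0.5 on either index."""
    detects_fog = (fth < 3) and (pth < 2)
    flags_clean = (fth < 0.5) and (pth < 0.5)
    return ConfusionCounts(
        tp=4 if detects_fog else 0,
        fn=0 if detects_fog else 4,
        fp=6 if flags_clean else 0,
        tn=0 if flags_clean else 6,
    )


class TestGridSearchGeneric:
    def test_grid_has_81_candidate_pairs(self):
        assert len(DEFAULT_THRESHOLD_GRID) ** 2 == 81
        np.testing.assert_allclose(DEFAULT_THRESHOLD_GRID,
                                   np.arange(0, 4.5, 0.5))

    def test_separable_cohort_reaches_perfect_pooled_product(self):
        evals = {f"s{i}": _grid_eval_from_fn(_separable_counts) for i in range(4)}
        params = grid_search_generic(evals, "s0")
        assert params.constrained
        # separating region: fth < 3 and 0.5 <= pth < 2 (or fth >= 0.5);
        # ties resolve to the smallest FTH then smallest PTH -> (0, 0.5)
        assert (params.fth, params.pth) == (0.0, 0.5)
        gi = {g: i for i, g in enumerate(DEFAULT_THRESHOLD_GRID)}
        chosen = evals["s1"].counts[gi[params.fth]][gi[params.pth]]
        assert chosen.fn == 0 and chosen.fp == 0

    def test_held_out_subject_counts_are_ignored(self):
        def garbage(fth, pth):
            return ConfusionCounts(tp=0, fn=9, fp=9, tn=0)

        evals = {f"s{i}": _grid_eval_from_fn(_separable_counts) for i in range(4)}
        evals_poisoned = dict(evals)
        evals_poisoned["s0"] = _grid_eval_from_fn(garbage)
        p1 = grid_search_generic(evals, "s0")
        p2 = grid_search_generic(evals_poisoned, "s0")
        assert (p1.fth, p1.pth) == (p2.fth, p2.pth)

    def test_empty_cohort_rejected(self):
        evals = {"s0": _grid_eval_from_fn(_separable_counts)}
        with pytest.raises(ValueError):
            grid_search_generic(evals, "s0")

    def test_infeasible_constraint_falls_back_unconstrained(self):
        # sensitivity never exceeds 50%: constraint infeasible everywhere
        def weak(fth, pth):
            detects = (fth < 3) and (pth < 2)
            return ConfusionCounts(tp=2 if detects else 0, fn=2 if detects else 4,
                                   fp=0, tn=6)

        evals = {f"s{i}": _grid_eval_from_fn(weak) for i in range(3)}
        params = grid_search_generic(evals, "s0")
        assert not params.constrained


class TestPersonalizeThresholds:
    def test_degenerate_weights_reduce_to_generic(self):
        evals = {f"s{i}": _grid_eval_from_fn(_separable_counts) for i in range(4)}
        half = _grid_eval_from_fn(
            lambda f, p: ConfusionCounts(tp=0, fn=5, fp=5, tn=0)
        )
        generic = grid_search_generic(evals, "s0")
        personal = personalize_thresholds(evals, "s0", half, weights=(1.0, 0.0))
        assert (personal.fth, personal.pth) == (generic.fth, generic.pth)

    def test_identical_surfaces_blend_to_same_selection(self):
        evals = {f"s{i}": _grid_eval_from_fn(_separable_counts) for i in range(4)}
        pooled = _grid_eval_from_fn(
            lambda f, p: ConfusionCounts(
                tp=sum(_separable_counts(f, p).tp for _ in range(3)),
                fn=sum(_separable_counts(f, p).fn for _ in range(3)),
                fp=sum(_separable_counts(f, p).fp for _ in range(3)),
                tn=sum(_separable_counts(f, p).tn for _ in range(3)),
            )
        )
        for w in [(0.9, 0.1), (0.5, 0.5), (0.2, 0.8)]:
            p = personalize_thresholds(evals, "s0", pooled, weights=w)
            g = grid_search_generic(evals, "s0")
            assert (p.fth, p.pth) == (g.fth, g.pth)

    def test_two_point_blend_arithmetic_by_hand(self):
        # hand-built surfaces: LOO (sens, spec) and half (sens, spec) known
        # at each grid point; blended product computed with 4-cell arithmetic
        def loo_fn(fth, pth):
            if (fth, pth) == (0.5, 0.5):
                return ConfusionCounts(tp=9, fn=1, fp=2, tn=8)  # 0.9 / 0.8
            return ConfusionCounts(tp=8, fn=2, fp=1, tn=9)      # 0.8 / 0.9

        def half_fn(fth, pth):
            if (fth, pth) == (0.5, 0.5):
                return ConfusionCounts(tp=3, fn=7, fp=0, tn=10)  # 0.3 / 1.0
            return ConfusionCounts(tp=10, fn=0, fp=5, tn=5)      # 1.0 / 0.5

        evals = {"s0": _grid_eval_from_fn(loo_fn), "s1": _grid_eval_from_fn(loo_fn)}
        half = _grid_eval_from_fn(half_fn)
        w_t, w_20 = 0.75, 0.25
        # blended at (0.5, 0.5): sens 0.9*0.75+0.3*0.25=0.75, spec 0.8*0.75+1.0*0.25=0.85
        #   -> product 0.6375, feasible
        # everywhere else:       sens 0.8*0.75+1.0*0.25=0.85, spec 0.9*0.75+0.5*0.25=0.80
        #   -> product 0.68, feasible and larger
        params = personalize_thresholds(evals, "s0", half, weights=(w_t, w_20),
                                        convention="as_printed")
        # ties resolve to smallest thresholds; the winning region excludes
        # (0.5, 0.5) so the smallest grid point overall wins: (0, 0)
        assert (params.fth, params.pth) == (0.0, 0.0)

    def test_swapped_convention_exchanges_weights(self):
        def loo_fn(fth, pth):
            return ConfusionCounts(tp=9, fn=1, fp=1, tn=9)

        def half_fn(fth, pth):
            if fth <= 1.0:
                return ConfusionCounts(tp=10, fn=0, fp=0, tn=10)
            return ConfusionCounts(tp=0, fn=10, fp=10, tn=0)

        evals = {"s0": _grid_eval_from_fn(loo_fn), "s1": _grid_eval_from_fn(loo_fn)}
        half = _grid_eval_from_fn(half_fn)
        asp = personalize_thresholds(evals, "s0", half, weights=(0.99, 0.01),
                                     convention="as_printed")
        swp = personalize_thresholds(evals, "s0", half, weights=(0.99, 0.01),
                                     convention="swapped")
        # as-printed attaches the large weight to the pooled surface (flat),
        # swapped attaches it to the half surface: both still feasible, and
        # both must pick a point in the half's preferred low-threshold region
        # because the blend there is strictly larger
        assert swp.fth <= 1.0
        assert asp.fth <= 1.0
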