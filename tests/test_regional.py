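"""Region classification: worked examples, properties and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfoveit import regional
from hfoveit.core import (
    AerationMap,
    AnalysisError,
    LungMask,
    StepMaps,
    VentilationMap,
)


def grid32(fill=0.0):
    return np.full((32, 32), float(fill))


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no array tricks)
# ---------------------------------------------------------------------------

def lung_mask_oracle(aer_n, aer_ref, thr=0.20):
    rows, cols = aer_n.shape
    max_diff = max(
        aer_n[r][c] - aer_ref[r][c] for r in range(rows) for c in range(cols)
    )
    mask = np.zeros((rows, cols), dtype=bool)
    if max_diff <= 0:
        return mask
    for r in range(rows):
        for c in range(cols):
            if aer_n[r][c] - aer_ref[r][c] > thr * max_diff:
                mask[r][c] = True
    return mask


def od_mask_oracle(aer_lower, aer_higher, lung_lower, thr=0.20):
    rows, cols = aer_lower.shape
    max_diff = max(
        aer_higher[r][c] - aer_lower[r][c]
        for r in range(rows)
        for c in range(cols)
    )
    mask = np.zeros((rows, cols), dtype=bool)
    if max_diff <= 0:
        return mask
    for r in range(rows):
        for c in range(cols):
            limited = aer_higher[r][c] - aer_lower[r][c] < thr * max_diff
            if limited and lung_lower[r][c]:
                mask[r][c] = True
    return mask


class TestCoV:
    def test_uniform_map_is_fifty_percent(self):
        assert regional.cov(VentilationMap(grid32(1.0))) == pytest.approx(50.0)

    def test_single_most_dorsal_pixel_is_hundred(self):
        v = grid32()
        v[31, 5] = 2.0
        assert regional.cov(VentilationMap(v)) == pytest.approx(100.0)

    def test_two_pixel_weighted_mean(self):
        # weight 1 at y=0 and weight 3 at y=1 -> 3/4 of the way dorsal
        v = grid32()
        v[0, 0] = 1.0
        v[31, 0] = 3.0
        assert regional.cov(VentilationMap(v)) == pytest.approx(75.0)

    def test_all_zero_map_is_undefined(self):
        with pytest.raises(AnalysisError, match="zero"):
            regional.cov(VentilationMap(grid32()))

    @settings(derandomize=True, max_examples=50)
    @given(
        scale=st.floats(0.1, 100.0),
        seed=st.integers(0, 10_000),
    )
    def test_scale_invariance_and_flip_antisymmetry(self, scale, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.0, 1.0, size=(32, 32)) + 1e-6
        c = regional.cov(VentilationMap(v))
        assert regional.cov(VentilationMap(scale * v)) == pytest.approx(c)
        assert regional.cov(VentilationMap(v[::-1].copy())) == pytest.approx(
            100.0 - c
        )


class TestLungMask:
    def test_threshold_selects_large_differences(self):
        ref = grid32()
        aer = grid32()
        aer[0, 0], aer[0, 1], aer[0, 2] = 10.0, 1.0, 5.0
        mask = regional.lung_mask(AerationMap(aer), AerationMap(ref))
        expected = np.zeros((32, 32), dtype=bool)
        expected[0, 0] = expected[0, 2] = True  # diffs > 0.2 * 10 = 2
        np.testing.assert_array_equal(mask.mask, expected)

    def test_identical_maps_give_empty_mask(self):
        aer = AerationMap(grid32(3.0))
        assert regional.lung_mask(aer, aer).count == 0

    def test_uniform_positive_difference_gives_full_mask(self):
        mask = regional.lung_mask(
            AerationMap(grid32(5.0)), AerationMap(grid32(2.0))
        )
        assert mask.count == 32 * 32

    @settings(derandomize=True, max_examples=300)
    @given(seed=st.integers(0, 10**6))
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        aer_n = rng.normal(size=(4, 4))
        aer_ref = rng.normal(size=(4, 4))
        got = regional.lung_mask(AerationMap(aer_n), AerationMap(aer_ref))
        np.testing.assert_array_equal(got.mask, lung_mask_oracle(aer_n, aer_ref))


class TestOverdistension:
    def test_limited_change_pixel_in_lung_is_overdistended(self):
        lower, higher = grid32(), grid32()
        higher[0, 0], higher[0, 1] = 10.0, 1.0
        lung = np.zeros((32, 32), dtype=bool)
        lung[0, 0] = lung[0, 1] = True
        mask, count = regional.overdistension_mask(
            AerationMap(lower), AerationMap(higher), LungMask(lung)
        )
        assert count == 1 and mask[0, 1] and not mask[0, 0]

    def test_uniform_large_increase_gives_empty_mask(self):
        lung = LungMask(np.ones((32, 32), dtype=bool))
        _, count = regional.overdistension_mask(
            AerationMap(grid32(0.0)), AerationMap(grid32(10.0)), lung
        )
        assert count == 0

    def test_pixel_outside_lung_not_overdistended(self):
        lower, higher = grid32(), grid32()
        higher[0, 0], higher[0, 1] = 10.0, 1.0
        lung = np.zeros((32, 32), dtype=bool)
        lung[0, 0] = True  # the limited-change pixel is not lung
        _, count = regional.overdistension_mask(
            AerationMap(lower), AerationMap(higher), LungMask(lung)
        )
        assert count == 0

    def test_no_gain_anywhere_gives_empty_mask(self):
        lung = LungMask(np.ones((32, 32), dtype=bool))
        _, count = regional.overdistension_mask(
            AerationMap(grid32(5.0)), AerationMap(grid32(5.0)), lung
        )
        assert count == 0

    @settings(derandomize=True, max_examples=300)
    @given(seed=st.integers(0, 10**6))
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        lower = rng.normal(size=(4, 4))
        higher = rng.normal(size=(4, 4))
        lung = rng.random((4, 4)) < 0.6
        got, _ = regional.overdistension_mask(
            AerationMap(lower), AerationMap(higher), LungMask(lung)
        )
        np.testing.assert_array_equal(got, od_mask_oracle(lower, higher, lung))


class TestRecruitable:
    def test_identical_masks_give_empty(self):
        m = LungMask(np.eye(32, dtype=bool))
        _, count = regional.recruitable_mask(m, m)
        assert count == 0

    def test_empty_current_returns_highest(self):
        high = LungMask(np.eye(32, dtype=bool))
        _, count = regional.recruitable_mask(
            high, LungMask(np.zeros((32, 32), dtype=bool))
        )
        assert count == 32

    def test_set_difference(self):
        high = np.zeros((32, 32), dtype=bool)
        high[0, 0] = high[0, 1] = high[0, 2] = True
        cur = np.zeros((32, 32), dtype=bool)
        cur[0, 1] = True
        mask, count = regional.recruitable_mask(LungMask(high), LungMask(cur))
        assert count == 2 and mask[0, 0] and mask[0, 2] and not mask[0, 1]


class TestRatio:
    @pytest.mark.parametrize(
        "od,rec,expected", [(8, 1, 8.0), (0, 5, 0.0), (0, 0, None), (3, 0, None)]
    )
    def test_ratio_and_degenerate_cases(self, od, rec, expected):
        assert regional.od_recruit_ratio(od, rec) == expected


class TestAnalyzeSeries:
    def _steps_from_maps(self, maps, mpaws):
        return [
            StepMaps(
                step_index=k,
                mpaw=p,
                aeration=AerationMap(a, mpaw=p),
                ventilation=VentilationMap(np.abs(a) + 1.0, mpaw=p),
            )
            for k, (p, a) in enumerate(zip(mpaws, maps))
        ]

    def test_two_identical_steps_degenerate(self):
        a = grid32(4.0)
        steps = self._steps_from_maps([a, a], [24.0, 21.0])
        out = regional.analyze_series(steps)
        for s in out:
            assert s.regions.n_recruitable == 0
        # no pixel gains aeration at the higher step -> vacuous criterion
        assert out[0].regions.n_overdistended == 0
        assert out[1].regions.n_overdistended is None

    def test_single_step_returns_cov_only(self):
        steps = self._steps_from_maps([grid32(1.0)], [24.0])
        out = regional.analyze_series(steps)
        assert out[0].regions is None
        assert out[0].cov_pct == pytest.approx(50.0)

    def test_lowest_step_has_no_overdistension_value(self, compact_steps):
        out = regional.analyze_series(compact_steps)
        assert out[-1].regions.n_overdistended is None
        assert all(s.regions.n_overdistended is not None for s in out[:-1])

    def test_mask_set_invariants_hold_on_phantom(self, compact_steps):
        out = regional.analyze_series(compact_steps)
        highest = out[0].lung
        for k, s in enumerate(out):
            r = s.regions
            assert 0 <= r.n_recruitable <= 1024
            assert r.n_recruitable == int(r.recruitable.sum())
            # recruitable pixels are never lung at the current step
            assert not np.any(r.recruitable & s.lung.mask)
            if r.overdistended is not None:
                assert r.n_overdistended == int(r.overdistended.sum())
                # overdistended pixels lie in the lung mask of the lower
                # step of the pair
                assert np.all(
                    out[k + 1].lung.mask[r.overdistended]
                )
                assert not np.any(r.overdistended & r.recruitable)

    def test_recruitable_zero_at_highest_step(self, compact_steps):
        out = regional.analyze_series(compact_steps)
        assert out[0].regions.n_recruitable == 0

    def test_unordered_steps_rejected(self, compact_steps):
        with pytest.raises(AnalysisError, match="decreasing"):
            regional.analyze_series(list(reversed(compact_steps)))
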