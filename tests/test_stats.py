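"""Contingency log-odds, border enrichment, set dynamics, FRAP."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

from eladkit.genome import GenomeModel
from eladkit.hic import TadPartition
from eladkit.signal import Peak, PeakSet
from eladkit.stats import (
    binarize_feature,
    border_enrichment_pvalue,
    de_target_overlap,
    feature_landmark_log_odds,
    frap_normalize,
    timepoint_dynamics,
)


def _fisher_by_enumeration(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration: sum the
    probabilities of every table with the same margins whose probability
    does not exceed the observed one (tiny relative slack for float ties)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sp_stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def _table_result(a, b, c, d):
    f = np.array([True] * (a + b) + [False] * (c + d))
    l = np.array([True] * a + [False] * b + [True] * c + [False] * d)
    return feature_landmark_log_odds(f, l)


class TestLogOdds:
    def test_independent_table_is_null(self):
        r = _table_result(20, 20, 10, 10)
        assert r.log_odds == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_nine_fold_odds_example(self):
        r = _table_result(30, 10, 10, 30)
        assert math.exp(r.log_odds) == pytest.approx(9.0)
        assert r.log_odds == pytest.approx(math.log(9), abs=1e-12)
        assert r.p_value == pytest.approx(
            _fisher_by_enumeration(30, 10, 10, 30), rel=1e-10
        )

    def test_zero_cell_is_continuity_corrected(self):
        r = _table_result(0, 10, 10, 30)
        assert math.isfinite(r.log_odds)
        expected = math.log((0.5 * 30.5) / (10.5 * 10.5))
        assert r.log_odds == pytest.approx(expected)
        assert 0 < r.p_value <= 1

    def test_matches_enumeration_over_margin_grid(self):
        """Exhaustive check over small tables plus a margins ≤ 50 sample."""
        rng = np.random.default_rng(0)
        tables = [
            (a, b, c, n - a - b - c)
            for n in range(2, 16)
            for a in range(n + 1)
            for b in range(n - a + 1)
            for c in range(n - a - b + 1)
        ]
        tables += [tuple(int(x) for x in rng.integers(0, 26, 4))
                   for _ in range(400)]
        for a, b, c, d in tables:
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            r = _table_result(a, b, c, d)
            assert r.p_value == pytest.approx(
                _fisher_by_enumeration(a, b, c, d), rel=1e-10
            ), (a, b, c, d)

    def test_degenerate_landmark_errors(self):
        f = np.array([True, False, True])
        with pytest.raises(ValueError):
            feature_landmark_log_odds(f, np.array([True, True, True]))
        with pytest.raises(ValueError):
            feature_landmark_log_odds(f, np.array([False, False, False]))


def test_binarize_feature_any_overlap_and_min_fraction():
    ivs = {"chr1": np.array([[50, 150], [900, 1000]])}
    bins = binarize_feature(ivs, "chr1", 10, 100)
    assert bins.tolist() == [True, True] + [False] * 7 + [True]
    strict = binarize_feature(ivs, "chr1", 10, 100, min_fraction=0.6)
    assert strict.tolist() == [False, False] + [False] * 7 + [True]


@pytest.fixture
def border_world():
    """1.2-Mb genome, 4 borders of 30 kb each → border fraction 0.10."""
    genome = GenomeModel([("chr1", 1_200_000)])
    part = TadPartition("chr1", 10_000, np.zeros(120),
                        [(10, 5.0), (40, 5.0), (70, 5.0), (100, 5.0)])
    return genome, part


class TestBorderEnrichment:
    def _peaks(self, starts):
        return PeakSet("c", [Peak("chr1", int(s), int(s) + 100, 1, 2)
                             for s in sorted(starts)])

    def test_exact_binomial_tail(self, border_world):
        genome, part = border_world
        border_starts = [95_000 + i * 1000 for i in range(10)] + \
                        [395_000 + i * 1000 for i in range(10)] + \
                        [695_000 + i * 1000 for i in range(10)]
        outside = [200_000 + i * 2000 for i in range(70)]
        p, fold, obs, n = border_enrichment_pvalue(
            self._peaks(border_starts + outside), part, genome
        )
        assert (obs, n) == (30, 100)
        assert fold == pytest.approx(3.0)
        assert p == sp_stats.binom.sf(29, 100, 0.1)

    def test_null_center_p_at_least_half(self, border_world):
        genome, part = border_world
        # exactly the expected proportion: 2 of 20 peaks in borders
        starts = [95_000, 395_000] + [200_000 + i * 3000 for i in range(18)]
        p, fold, obs, n = border_enrichment_pvalue(self._peaks(starts), part, genome)
        assert (obs, n) == (2, 20)
        assert p >= 0.5

    def test_zero_peaks(self, border_world):
        genome, part = border_world
        p, fold, obs, n = border_enrichment_pvalue(PeakSet("c", []), part, genome)
        assert (p, fold, obs, n) == (1.0, 0.0, 0, 0)

    def test_permutation_agrees_with_binomial(self, border_world):
        genome, part = border_world
        rng = np.random.default_rng(5)
        starts = np.concatenate([
            rng.integers(0, 1_199_000, 60),
            rng.integers(95_000, 125_000, 15),  # extra mass at one border
        ])
        starts = np.unique(starts // 200 * 200)
        peaks = self._peaks(starts)
        p_bin, *_ = border_enrichment_pvalue(peaks, part, genome, "binomial")
        p_perm, *_ = border_enrichment_pvalue(peaks, part, genome, "permutation",
                                              n_permutations=4000, seed=1)
        assert 0.1 <= p_perm / p_bin <= 10  # same order of magnitude


class TestDynamics:
    def test_identical_sets(self):
        s = set(range(100))
        d = timepoint_dynamics({"a": s, "b": set(s), "c": set(s)})
        assert d.maintained == 100 and d.maintained_pct == 100
        assert d.changed == 0 and d.changed_pct == 0

    def test_disjoint_sets(self):
        d = timepoint_dynamics({
            "a": set(range(10)), "b": set(range(10, 25)), "c": set(range(25, 30))
        })
        assert d.maintained == 0
        assert d.changed == d.union_size == 30

    def test_venn_regions_sum_to_union(self, rng):
        sets = {c: set(rng.choice(300, 120, replace=False).tolist())
                for c in ("a", "b", "c")}
        d = timepoint_dynamics(sets)
        assert sum(d.venn.values()) == d.union_size
        assert d.maintained + d.changed == d.union_size

    def test_published_cardinalities_reproduce_percentages(self):
        """Sets built with |∩| = 2933 and |∪| = 10350 give 28% maintained
        and 7417 (72%) changed."""
        core = set(range(2933))
        rest = list(range(2933, 10_350))
        third = len(rest) // 3
        sets = {
            "t0": core | set(rest[:2 * third]),
            "t1": core | set(rest[third:]),
            "t2": core | set(rest[:third]) | set(rest[2 * third:]),
        }
        d = timepoint_dynamics(sets)
        assert d.union_size == 10_350
        assert d.maintained == 2933 and d.maintained_pct == 28
        assert d.changed == 7417 and d.changed_pct == 72


class TestDeOverlap:
    def test_disjoint(self):
        assert de_target_overlap({1, 2}, {3, 4}) == (0, 0.0, 0.0, False)

    def test_published_fraction(self):
        targets = set(range(4454))
        de = set(range(1872)) | {10_000 + i for i in range(500)}
        ov, pct_t, _, _ = de_target_overlap(de, targets)
        assert ov == 1872
        assert round(pct_t) == 42

    def test_empty_targets_flagged(self):
        ov, pct_t, pct_d, empty = de_target_overlap({1}, set())
        assert empty and pct_t == 0.0

    def test_random_sets_match_membership_oracle(self, rng):
        a = set(rng.choice(100, 40, replace=False).tolist())
        b = set(rng.choice(100, 30, replace=False).tolist())
        ov, pct_t, pct_d, _ = de_target_overlap(a, b)
        expected = sum(1 for x in b if x in a)
        assert ov == expected
        assert pct_t == pytest.approx(100 * expected / len(b))
        assert pct_d == pytest.approx(100 * expected / len(a))


class TestFrap:
    def test_identity_and_full_bleach(self):
        assert frap_normalize(110, 10, 110, 110, 10, 110) == pytest.approx(1.0)
        assert frap_normalize(10, 10, 110, 110, 10, 110) == pytest.approx(0.0)

    def test_worked_example(self):
        assert frap_normalize(60, 10, 110, 110, 10, 110) == pytest.approx(0.5)

    @given(st.floats(0.01, 100), st.floats(20, 90))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, roi_b):
        base = frap_normalize(roi_b, 10, 110, 100, 10, 110)
        scaled = frap_normalize(roi_b * scale, 10 * scale, 110 * scale,
                                100 * scale, 10 * scale, 110 * scale)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_denominator_names_roi(self):
        with pytest.raises(ZeroDivisionError, match="ROI_nb"):
            frap_normalize(60, 10, 10, 110, 10, 110)
        with pytest.raises(ZeroDivisionError, match="pbROI_nb"):
            frap_normalize(60, 10, 110, 110, 10, 10)

    def test_per_frame_series(self):
        series = frap_normalize(np.array([10.0, 35.0, 60.0]), 10, 110,
                                110, 10, 110)
        assert np.allclose(series, [0.0, 0.25, 0.5])
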