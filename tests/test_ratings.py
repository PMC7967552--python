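"""Expert-rating aggregation, ICC(2,1), Spearman summary, concordance."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import alcpolicy as ap
from alcpolicy.ratings import RatingItem, RatingMatrix

from conftest import icc_oracle


def matrix(values, **kw):
    values = np.asarray(values, dtype=float)
    items = [RatingItem(f"e{i}") for i in range(values.shape[0])]
    raters = [f"r{j}" for j in range(values.shape[1])]
    return RatingMatrix(items, raters, values, **kw)


class TestMeans:
    def test_uniform_and_spread(self):
        assert ap.mean_ratings(matrix([[5, 5], [5, 5]])).tolist() == [5.0, 5.0]
        assert ap.mean_ratings(matrix([[2, 4, 6, 8, 10], [0, 0, 0, 0, 5]]))[0] == 6.0

    def test_antisymmetric(self):
        assert ap.mean_ratings(matrix([[0, 10], [10, 0]])).tolist() == [5.0, 5.0]

    def test_missing_cells_flagged_then_averaged(self):
        m = matrix([[4, np.nan], [6, 8]], allow_missing=True)
        assert not m.complete
        assert ap.mean_ratings(m).tolist() == [4.0, 7.0]

    def test_missing_rejected_by_default(self):
        with pytest.raises(ValueError, match="missing"):
            matrix([[4, np.nan], [6, 8]])


class TestSelectDates:
    def make_events(self, n):
        return [
            ap.PolicyEvent(
                event_id=f"e{i}",
                enactment_date=dt.date(2008 + i, 1, 1),
                measures=(
                    ap.PolicyMeasure(
                        domain="taxation_price", direction="restrictive", population="general"
                    ),
                ),
            )
            for i in range(n)
        ]

    def test_threshold_is_inclusive(self):
        events = self.make_events(2)
        m = matrix([[5, 5], [4, 4]])
        assert ap.select_dates(m, events) == {dt.date(2008, 1, 1)}

    def test_all_zero_selects_nothing(self):
        assert ap.select_dates(matrix([[0, 0], [0, 0]]), self.make_events(2)) == set()

    def test_unknown_event_errors(self):
        with pytest.raises(ValueError, match="unknown event"):
            ap.select_dates(matrix([[5, 5], [5, 5]]), self.make_events(1))

    def test_grouping_takes_max_over_items_at_a_date(self):
        events = self.make_events(1)
        items = [RatingItem("e0", 0), RatingItem("e0", 1)]
        m = RatingMatrix(items, ["a", "b"], [[1.0, 2.0], [8.0, 9.0]])
        assert ap.select_dates(m, events) == {dt.date(2008, 1, 1)}

    @given(threshold_lo=st.floats(0, 10), threshold_hi=st.floats(0, 10))
    def test_monotone_in_threshold(self, threshold_lo, threshold_hi):
        lo, hi = sorted([threshold_lo, threshold_hi])
        events = self.make_events(3)
        m = matrix([[2, 3], [5, 6], [9, 10]])
        assert ap.select_dates(m, events, hi) <= ap.select_dates(m, events, lo)


class TestICC:
    def test_frozen_small_example_matches_oracle(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        res = ap.icc(matrix(x))
        assert res.estimate == pytest.approx(2.0 / 3.0, abs=1e-12)  # oracle value
        assert res.estimate == pytest.approx(icc_oracle(x), abs=1e-10)

    def test_identical_raters_give_one(self):
        x = np.tile([[1.0], [4.0], [7.0], [9.0]], (1, 4))
        res = ap.icc(matrix(x))
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_constant_offset_between_raters_penalized(self):
        x = np.array([[1.0, 3.0], [4.0, 6.0], [7.0, 9.0], [2.0, 4.0]])
        assert ap.icc(matrix(x)).estimate < 1.0

    def test_degenerate_matrix_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            ap.icc(matrix([[5.0, 5.0], [5.0, 5.0]]))

    def test_ci_brackets_estimate_and_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x = np.clip(np.round(rng.normal(5, 2, size=(12, 4))), 0, 10)
        res = ap.icc(matrix(x))
        assert res.ci_low <= res.estimate <= res.ci_high
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 4),
                "raters": np.tile(np.arange(4), 12),
                "scores": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, "targets", "raters", "scores").set_index("Type")
        assert res.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]  # pingouin rounds bounds to 2 dp
        assert res.ci_low == pytest.approx(lo, abs=0.011)
        assert res.ci_high == pytest.approx(hi, abs=0.011)

    @given(
        x=hnp.arrays(
            float,
            st.tuples(st.integers(3, 8), st.integers(3, 6)),
            elements=st.integers(0, 20).map(lambda v: v / 2.0),
        )
    )
    def test_matches_brute_force_oracle(self, x):
        if np.ptp(x) == 0:
            return
        res_oracle = icc_oracle(x)
        try:
            res = ap.icc(matrix(x))
        except ValueError:
            return  # degenerate denominator; oracle undefined too
        assert res.estimate == pytest.approx(res_oracle, abs=1e-10)

    @given(shift=st.integers(0, 6))
    def test_invariant_under_common_constant(self, shift):
        x = np.array([[1.0, 2.0], [4.0, 3.0], [3.0, 4.0], [2.0, 2.0]])
        base = ap.icc(matrix(x)).estimate
        shifted = ap.icc(matrix(x + shift)).estimate  # stays within [0, 10]
        assert shifted == pytest.approx(base, abs=1e-10)


class TestSpearman:
    def test_identical_and_reversed_raters(self):
        m = matrix([[1, 1, 9], [5, 5, 5.5], [9, 9, 1]])
        res = ap.spearman_summary(m)
        rho = {frozenset((a, b)): r for a, b, r in res.pairs}
        assert rho[frozenset(("r0", "r1"))] == pytest.approx(1.0)
        assert rho[frozenset(("r0", "r2"))] == pytest.approx(-1.0)

    def test_constant_rater_excluded_and_flagged(self):
        m = matrix([[1, 5], [2, 5], [3, 5]])
        with pytest.raises(ValueError, match="no rater pair"):
            ap.spearman_summary(m)
        m = matrix([[1, 5, 2], [2, 5, 4], [3, 5, 9]])
        res = ap.spearman_summary(m)
        assert ("r0", "r1") in res.excluded_pairs and ("r1", "r2") in res.excluded_pairs
        assert len(res.pairs) == 1

    def test_median_iqr_match_rank_based_recomputation(self):
        rng = np.random.default_rng(11)
        signal = rng.uniform(0, 10, 21)
        x = np.clip(np.round(signal[:, None] + rng.normal(0, 2, (21, 5))), 0, 10)
        res = ap.spearman_summary(matrix(x))

        # independent recomputation: Pearson correlation of average ranks
        from scipy.stats import rankdata

        rhos = []
        for i in range(5):
            for j in range(i + 1, 5):
                ri, rj = rankdata(x[:, i]), rankdata(x[:, j])
                rhos.append(np.corrcoef(ri, rj)[0, 1])
        assert res.median == pytest.approx(np.median(rhos), abs=1e-12)
        q1, q3 = np.percentile(rhos, [25, 75])
        assert res.iqr == pytest.approx(q3 - q1, abs=1e-12)

    @given(seed=st.integers(0, 50))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.uniform(0, 10, (8, 3)))
        if any(np.ptp(x[:, j]) == 0 for j in range(3)):
            return
        res = ap.spearman_summary(matrix(x))
        y = x.copy()
        y[:, 0] = np.round(y[:, 0] * 0.9)  # monotone (non-strict rounding kept mild)
        if np.ptp(y[:, 0]) == 0 or len(np.unique(y[:, 0])) != len(np.unique(x[:, 0])):
            return
        res2 = ap.spearman_summary(matrix(y))
        assert res2.median == pytest.approx(res.median, abs=1e-12)


class TestConcordance:
    def test_partition_properties(self, assignments):
        tier_dates = {
            dt.date(2008, 1, 1), dt.date(2009, 1, 1), dt.date(2014, 4, 1),
            dt.date(2017, 3, 1), dt.date(2018, 1, 1),
        }
        expert = tier_dates | {dt.date(2015, 3, 1), dt.date(2016, 1, 1)}
        conc = ap.concordance(expert, assignments)
        assert conc.in_both == tier_dates
        assert conc.expert_only == {dt.date(2015, 3, 1), dt.date(2016, 1, 1)}
        assert conc.criteria_only == frozenset()
        assert conc.expert_superset

    def test_identical_and_disjoint(self, assignments):
        tier_dates = frozenset(
            a.enactment_date for a in assignments if a.tier.value in ("tier1", "tier2_only")
        )
        same = ap.concordance(tier_dates, assignments)
        assert same.expert_only == same.criteria_only == frozenset()
        disjoint = ap.concordance({dt.date(1999, 1, 1)}, assignments)
        assert disjoint.in_both == frozenset()
        assert not disjoint.expert_superset


def test_ratings_csv_round_trip(tmp_path):
    m = matrix([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    path = tmp_path / "ratings.csv"
    from alcpolicy.ratings import read_ratings_csv, write_ratings_csv

    write_ratings_csv(m, path)
    again = read_ratings_csv(path)
    assert [it.event_id for it in again.items] == [it.event_id for it in m.items]
    assert np.array_equal(again.values, m.values)
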