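import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scalorank import (
    TIER_LABELS,
    assign_class,
    build_class_scheme,
    rank_regions,
    sturges_width,
    tier_summary,
)
from scalorank.scoring import AggregateScores
from scalorank.classify import rank_and_summarize


@pytest.fixture
def fars_scheme():
    """The published Fars-province scheme: endpoints 33/89.4, N = 21."""
    return build_class_scheme(33.0, 89.4, N=21)


class TestSturgesWidth:
    def test_published_inputs(self):
        assert sturges_width(56.4, 21) == pytest.approx(10.5159, abs=5e-4)

    def test_log10_anchor(self):
        assert sturges_width(10, 10) == pytest.approx(10 / 4.3)

    @given(
        st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
        st.integers(min_value=2, max_value=10**6),
    )
    @settings(deadline=None)
    def test_matches_formula_reimplementation(self, R, N):
        assert sturges_width(R, N) == pytest.approx(R / (1 + 3.3 * math.log10(N)))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sturges_width(0, 21)
        with pytest.raises(ValueError):
            sturges_width(10, 1)


class TestBuildClassScheme:
    def test_reproduces_published_lower_bounds(self, fars_scheme):
        assert fars_scheme.lower_bounds == [33.0, 43.5, 54.0, 64.5, 75.0]

    def test_top_interval_absorbs_remainder(self, fars_scheme):
        low, high = fars_scheme.interval(4)
        assert (low, high) == (75.0, 89.4)
        assert high - low > fars_scheme.params.width  # wider than one Sturges step

    def test_paper_style_interval_rendering(self, fars_scheme):
        assert fars_scheme.interval_display(4) == "(89.4-75)"
        assert fars_scheme.interval_display(3) == "(74.9-64.5)"
        assert fars_scheme.interval_display(0) == "(43.4-33)"

    def test_contiguous_coverage_simple_inputs(self):
        scheme = build_class_scheme(0, 5, N=10, decimals=3)
        for k in range(4):
            assert scheme.interval(k)[1] == scheme.interval(k + 1)[0]
        assert scheme.interval(0)[0] == 0
        assert scheme.interval(4)[1] == 5

    def test_rounding_collision_raises(self):
        # width rounds to 0 at 1 decimal => bounds cannot increase
        with pytest.raises(ValueError, match="decimals"):
            build_class_scheme(0, 0.1, N=100, decimals=1)

    @given(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        st.floats(min_value=5, max_value=500, allow_nan=False),
        # N >= 9 keeps four Sturges steps inside the range so five tiers fit
        st.integers(min_value=9, max_value=1000),
    )
    @settings(deadline=None, max_examples=60)
    def test_partition_on_fine_grid(self, lo, R, N):
        """Every admissible score falls in exactly one half-open interval."""
        scheme = build_class_scheme(lo, lo + R, N, decimals=3)
        grid = np.linspace(scheme.lower_bounds[0], scheme.score_max, 201)
        for s in grid:
            memberships = [
                k
                for k in range(5)
                if (
                    scheme.interval(k)[0] <= s < scheme.interval(k)[1]
                    or (k == 4 and s == scheme.score_max)
                )
            ]
            assert len(memberships) == 1
            assert assign_class(s, scheme) == TIER_LABELS[memberships[0]]


class TestAssignClass:
    def test_headline_scores(self, fars_scheme):
        assert assign_class(85, fars_scheme) == "development"
        assert assign_class(36, fars_scheme) == "under_development"

    def test_shared_boundary_goes_to_upper_tier(self, fars_scheme):
        assert assign_class(43.5, fars_scheme) == "less_development"
        assert assign_class(43.499, fars_scheme) == "under_development"

    def test_out_of_range_named_in_error(self, fars_scheme):
        with pytest.raises(ValueError, match="90.0"):
            assign_class(90.0, fars_scheme)
        with pytest.raises(ValueError, match="32.0"):
            assign_class(32.0, fars_scheme)


def make_aggregates(totals: dict[str, int], n_indicators=30):
    s = pd.Series(totals, name="total_score")
    clusters = pd.DataFrame({"institutional": s})
    return AggregateScores(
        cluster_scores=clusters, total=s, bounds=(n_indicators, 4 * n_indicators)
    )


class TestRankAndSummarize:
    def test_competition_ranking_with_ties(self, fars_scheme):
        agg = make_aggregates({"a": 80, "b": 70, "c": 70, "d": 50})
        ranked = rank_regions(agg.total, fars_scheme)
        assert [(c.region, c.rank) for c in ranked] == [
            ("a", 1), ("b", 2), ("c", 2), ("d", 4),
        ]
        # sorted by total descending
        assert [c.total_score for c in ranked] == sorted(
            [c.total_score for c in ranked], reverse=True
        )

    def test_tier_monotone_in_total(self, fars_scheme, rng):
        totals = {f"r{i}": int(t) for i, t in enumerate(rng.integers(33, 90, 40))}
        ranked = rank_regions(make_aggregates(totals).total, fars_scheme)
        order = {lab: k for k, lab in enumerate(TIER_LABELS)}
        tiers = [order[c.tier] for c in ranked]  # ranked best-first
        assert tiers == sorted(tiers, reverse=True)

    def test_ranking_matches_independent_sort(self, fars_scheme, rng):
        totals = {f"r{i}": int(t) for i, t in enumerate(rng.integers(33, 90, 25))}
        ranked = rank_regions(make_aggregates(totals).total, fars_scheme)
        by_region = {c.region: c.rank for c in ranked}
        for r, t in totals.items():
            assert by_region[r] == 1 + sum(u > t for u in totals.values())

    def test_tier_percentages_published_counts(self, fars_scheme):
        # 22 regions split 7/4/8/2/1 from the top tier down
        totals = (
            [80] * 7 + [70] * 4 + [60] * 8 + [50] * 2 + [40]
        )
        agg = make_aggregates({f"r{i}": t for i, t in enumerate(totals)})
        _, tiers = rank_and_summarize(agg, fars_scheme)
        assert tiers["count"].tolist() == [7, 4, 8, 2, 1]
        assert tiers["percent"].tolist() == [31.82, 18.18, 36.36, 9.09, 4.55]
        assert round(tiers["percent"].iloc[0], 1) == 31.8

    def test_single_region_is_rank_one_full_tier(self, fars_scheme):
        agg = make_aggregates({"only": 60})
        classified, tiers = rank_and_summarize(agg, fars_scheme)
        assert classified[0].rank == 1
        assert tiers.loc[tiers["count"] > 0, "percent"].tolist() == [100.0]

    def test_percent_conservation(self, fars_scheme, rng):
        for _ in range(10):
            n = int(rng.integers(1, 60))
            totals = {f"r{i}": int(t) for i, t in enumerate(rng.integers(33, 90, n))}
            _, tiers = rank_and_summarize(make_aggregates(totals), fars_scheme)
            assert tiers["percent"].sum() == pytest.approx(100.0, abs=0.25)
            assert tiers["count"].sum() == n
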