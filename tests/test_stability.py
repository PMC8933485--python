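import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, norm

from phantomrad.radiomics.manifest import CANONICAL_NAMES
from phantomrad.stability import (
    StabilityReport,
    StudyDesign,
    compute_stability_report,
    discriminative_percentage,
    rank_features,
    stability_percentage,
    topk_count,
    topk_overlap,
    wilcoxon_W,
)


class TestWilcoxonW:
    def test_identical_constant_samples(self):
        assert wilcoxon_W([5, 5, 5, 5], [5, 5, 5, 5]).W == 0.0

    def test_extremal_separation_exact_value(self):
        # U = 0, mean 4.5, sd sqrt(5.25) -> |z| = 4.5/sqrt(5.25)
        r = wilcoxon_W([1, 2, 3], [4, 5, 6])
        assert r.W == pytest.approx(4.5 / np.sqrt(5.25))
        assert round(r.W, 3) == 1.964

    def test_brute_force_extremal_u(self):
        # exhaustive check: of all 20 label assignments of ranks 1..6 into
        # two triples, [1,2,3] vs [4,5,6] attains the extremal rank sum
        ranks = [1, 2, 3, 4, 5, 6]
        sums = [
            sum(c) for c in itertools.combinations(ranks, 3)
        ]
        assert len(sums) == 20
        assert min(sums) == 1 + 2 + 3

    def test_swap_invariance(self, rng):
        a, b = rng.random(8), rng.random(5)
        assert wilcoxon_W(a, b).W == pytest.approx(wilcoxon_W(b, a).W)

    def test_matches_scipy_asymptotic_pvalue(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 1, rng.integers(3, 12))
            w = wilcoxon_W(a, b).W
            p = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            ).pvalue
            assert 2 * norm.sf(w) == pytest.approx(p, rel=1e-10)

    def test_tie_correction_applied(self):
        # heavy ties shrink the variance; scipy agrees
        a = [1, 1, 2, 2]
        b = [2, 2, 3, 3]
        w = wilcoxon_W(a, b).W
        p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                         use_continuity=False).pvalue
        assert 2 * norm.sf(w) == pytest.approx(p, rel=1e-10)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            wilcoxon_W([1], [2, 3])

    @given(
        # integer-valued samples so the affine transform cannot create or
        # destroy ties through float rounding
        a=st.lists(st.integers(-100, 100).map(float), min_size=3, max_size=8),
        b=st.lists(st.integers(-100, 100).map(float), min_size=3, max_size=8),
        scale=st.floats(0.1, 10),
        shift=st.floats(-50, 50),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_transform_invariance(self, a, b, scale, shift):
        w0 = wilcoxon_W(a, b).W
        ta = [scale * x + shift for x in a]
        tb = [scale * x + shift for x in b]
        assert wilcoxon_W(ta, tb).W == pytest.approx(w0, abs=1e-9)

    @given(
        a=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10),
        b=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_nonnegative_and_finite(self, a, b):
        r = wilcoxon_W(a, b)
        assert r.W >= 0
        assert np.isfinite(r.W)


def _table(rows):
    return pd.DataFrame(rows)


def _synth_table(rng, n_groups=8, n_reps=3, rois=None, feature_fn=None):
    """Synthetic feature table with a single feature column 'f'."""
    if rois is None:
        rois = [
            ("liver_1", "normal_liver"),
            ("liver_2", "normal_liver"),
            ("cyst_1", "cyst"),
            ("cyst_2", "cyst"),
            ("hemangioma", "hemangioma"),
            ("metastasis", "metastasis"),
        ]
    rows = []
    for g in range(n_groups):
        for rep in range(n_reps):
            for roi, cls in rois:
                value = feature_fn(g, rep, roi, cls) if feature_fn else rng.random()
                rows.append(
                    {
                        "group": str(g + 1),
                        "repetition": rep,
                        "roi": roi,
                        "tissue_class": cls,
                        "f": value,
                    }
                )
    return _table(rows)


class TestStabilityPercentage:
    def test_identical_constant_groups_fully_stable(self, rng):
        table = _synth_table(rng, feature_fn=lambda g, r, roi, c: 1.0)
        pct, _, total = stability_percentage(table, ["f"])
        assert pct["f"] == 100.0

    def test_denominator_is_pairs_times_rois(self, rng):
        table = _synth_table(rng, n_groups=8)
        _, _, total = stability_percentage(table, ["f"])
        assert total == 28 * 6  # C(8,2) pairs x 6 ROIs

    def test_separated_group_means_unstable(self, rng):
        table = _synth_table(
            rng, feature_fn=lambda g, r, roi, c: 100.0 * g + rng.normal(0, 0.01)
        )
        pct, _, _ = stability_percentage(table, ["f"])
        assert pct["f"] < 5.0

    def test_missing_cells_warn_and_excluded(self, rng):
        table = _synth_table(rng, n_groups=3)
        table = table[~((table["group"] == "2") & (table["roi"] == "cyst_1"))]
        with pytest.warns(UserWarning, match="excluded"):
            _, _, total = stability_percentage(table, ["f"])
        # cyst_1 contributes only C(2,2 groups)=1 pair instead of 3
        assert total == 3 * 5 + 1

    def test_single_group_rejected(self, rng):
        table = _synth_table(rng, n_groups=2)
        table = table[table["group"] == "1"]
        with pytest.raises(ValueError, match="2 groups"):
            stability_percentage(table, ["f"])


class TestDiscriminativePercentage:
    def test_identical_class_distributions_low(self, rng):
        table = _synth_table(rng, n_reps=5,
                             feature_fn=lambda g, r, roi, c: rng.random())
        pct, _, _ = discriminative_percentage(table, ["f"])
        assert pct["f"] < 30.0

    def test_denominator_class_pairs_times_groups(self, rng):
        table = _synth_table(rng, n_groups=8)
        _, _, total = discriminative_percentage(table, ["f"])
        assert total == 6 * 8  # C(4,2) class pairs x 8 groups

    def test_disjoint_class_supports_fully_discriminative(self, rng):
        offsets = {"normal_liver": 0.0, "cyst": 100.0, "hemangioma": 200.0,
                   "metastasis": 300.0}
        table = _synth_table(
            rng, n_reps=5,
            feature_fn=lambda g, r, roi, c: offsets[c] + rng.random(),
        )
        pct, _, _ = discriminative_percentage(table, ["f"])
        assert pct["f"] == 100.0

    def test_single_class_rejected(self, rng):
        table = _synth_table(rng)
        table = table[table["tissue_class"] == "cyst"]
        with pytest.raises(ValueError, match="classes"):
            discriminative_percentage(table, ["f"])


def _report(stab: dict, disc: dict) -> StabilityReport:
    return StabilityReport(
        stability=pd.Series(stab),
        discriminative=pd.Series(disc),
        stability_breakdown=pd.DataFrame(),
        discriminative_breakdown=pd.DataFrame(),
    )


class TestRanking:
    def test_all_equal_percentages_use_name_order(self):
        names = ["b", "a", "c"]
        rep = _report({n: 50.0 for n in names}, {n: 0.0 for n in names})
        assert rank_features(rep, "stability") == ["a", "b", "c"]

    def test_top_feature_first(self):
        rep = _report({"a": 0.0, "b": 100.0, "c": 0.0}, {"a": 0.0, "b": 0.0, "c": 0.0})
        assert rank_features(rep, "stability")[0] == "b"

    def test_top10_lengths(self, rng):
        stab = {f: float(rng.integers(0, 101)) for f in CANONICAL_NAMES}
        disc = {f: float(rng.integers(0, 101)) for f in CANONICAL_NAMES}
        rep = _report(stab, disc)
        assert len(rank_features(rep, "stability")[:10]) == 10
        assert len(rank_features(rep, "discriminative")[:10]) == 10

    def test_unknown_axis_rejected(self):
        rep = _report({"a": 0.0}, {"a": 0.0})
        with pytest.raises(ValueError, match="axis"):
            rank_features(rep, "both")

    def test_percentages_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 100"):
            _report({"a": 120.0}, {"a": 0.0})


class TestTopkOverlap:
    def test_ten_percent_of_86_is_9(self):
        assert topk_count(0.10, 86) == 9

    def test_round_half_up(self):
        assert topk_count(0.5, 5) == 3  # 2.5 rounds up
        assert topk_count(0.05, 86) == 4  # 4.3 rounds down

    def test_identical_rankings_full_overlap(self):
        ranking = list(CANONICAL_NAMES)
        curve = topk_overlap(ranking, ranking)
        assert (curve["overlap_pct"] == 100.0).all()

    def test_random_rankings_match_baseline_at_half(self, rng):
        # Monte-Carlo permutation null: mean overlap ~ 50% at fraction 0.5
        universe = [f"f{i}" for i in range(86)]
        overlaps = []
        for _ in range(1000):
            a = list(rng.permutation(universe))
            b = list(rng.permutation(universe))
            k = topk_count(0.5, 86)
            overlaps.append(len(set(a[:k]) & set(b[:k])) / k * 100)
        assert np.mean(overlaps) == pytest.approx(50.0, abs=2.0)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            topk_overlap(["a", "b"], ["a", "c"])

    def test_baseline_column(self):
        curve = topk_overlap(list("abcdefghij"), list("abcdefghij"),
                             fractions=[0.1, 0.5, 1.0])
        np.testing.assert_allclose(
            curve["random_baseline_pct"], [10.0, 50.0, 100.0]
        )


class TestStudyDesign:
    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            StudyDesign(groups=[("1", "sirt", 150)])

    def test_requires_two_repetitions(self):
        with pytest.raises(ValueError, match="repetitions"):
            StudyDesign(
                groups=[("1", "sirt", 150), ("2", "fbp", 150)], repetitions=1
            )

    def test_unique_group_ids(self):
        with pytest.raises(ValueError, match="unique"):
            StudyDesign(groups=[("1", "sirt", 150), ("1", "fbp", 150)])

    def test_seeds_within_group(self):
        d = StudyDesign(
            groups=[("1", "sirt", 150), ("2", "fbp", 150)],
            repetitions=3,
            base_seed=7,
        )
        assert d.seeds_for_group(0) == [7, 8, 9]


class TestQualitativeHeadline:
    def test_constructed_design_shows_low_stability_high_discrimination(self, rng):
        # class means far apart AND group-dependent drift: discriminative
        # power should be high while stability is low
        offsets = {"normal_liver": 0.0, "cyst": 500.0, "hemangioma": 1000.0,
                   "metastasis": 1500.0}
        table = _synth_table(
            rng, n_reps=5,
            feature_fn=lambda g, r, roi, c: offsets[c] + 30.0 * g
            + rng.normal(0, 0.5),
        )
        report = compute_stability_report(table, ["f"])
        assert report.discriminative["f"] > report.stability["f"]
        assert report.discriminative["f"] > 90.0
        assert report.stability["f"] < 20.0
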