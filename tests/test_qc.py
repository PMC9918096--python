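"""QC and normalization: CPM, hemolysis rule, detection sets, prevalence, PCA."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirseed import (cpm_normalize, hemolysis_qc, detection_sets,
                     prevalence_filter, pca_summary)


class TestCpm:
    def test_simple_proportions(self):
        counts = pd.DataFrame({"s1": [1, 3, 6]}, index=["a", "b", "c"])
        cpm = cpm_normalize(counts)
        np.testing.assert_allclose(cpm["s1"], [100_000, 300_000, 600_000])

    def test_equal_counts_split_evenly(self):
        counts = pd.DataFrame(np.full((8, 3), 5),
                              index=[f"m{i}" for i in range(8)],
                              columns=list("xyz"))
        cpm = cpm_normalize(counts)
        np.testing.assert_allclose(cpm.to_numpy(), 1e6 / 8)

    def test_columns_sum_to_one_million(self, random_counts):
        cpm = cpm_normalize(random_counts + 1)   # avoid zero totals
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6)

    def test_scale_invariance(self, random_counts):
        counts = random_counts + 1
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 7
        pd.testing.assert_series_equal(cpm_normalize(counts)["s0"],
                                       cpm_normalize(scaled)["s0"])

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            cpm_normalize(counts)


class TestHemolysisQc:
    def _meta(self, a414, vol_ok=None):
        n = len(a414)
        return pd.DataFrame({
            "a414": a414,
            "plasma_volume_ok": vol_ok if vol_ok is not None else [True] * n,
        }, index=[f"s{i}" for i in range(n)])

    def test_strictly_below_threshold_qualifies(self):
        res = hemolysis_qc(self._meta([0.24]))
        assert res.qualified.iloc[0]

    def test_threshold_value_is_hemolyzed(self):
        res = hemolysis_qc(self._meta([0.25]))
        assert not res.qualified.iloc[0]

    def test_insufficient_volume_disqualifies(self):
        res = hemolysis_qc(self._meta([0.1], vol_ok=[False]))
        assert not res.qualified.iloc[0]

    def test_attrition_percentage(self):
        # 115 qualified of 150 reports 77%
        a414 = [0.1] * 115 + [0.3] * 35
        res = hemolysis_qc(self._meta(a414))
        assert res.n_qualified == 115
        assert res.pct_qualified == 77

    def test_percentage_equals_rounded_ratio(self, rng):
        a414 = rng.uniform(0.05, 0.4, 60)
        res = hemolysis_qc(self._meta(a414))
        expected = math.floor(100 * res.n_qualified / res.n_total + 0.5)
        assert res.pct_qualified == expected

    def test_missing_a414_flagged_unevaluable(self):
        res = hemolysis_qc(self._meta([0.1, np.nan]))
        assert res.unevaluable == ["s1"]
        assert res.n_total == 2
        res2 = hemolysis_qc(self._meta([0.1, np.nan]),
                            exclude_unevaluable_from_denominator=True)
        assert res2.n_total == 1


class TestDetectionSets:
    def test_planted_pattern_recovered(self):
        counts = pd.DataFrame(0, index=["only_a", "only_b", "shared", "absent"],
                              columns=["a1", "a2", "b1", "b2"])
        counts.loc["only_a", "a1"] = 3
        counts.loc["only_b", "b2"] = 1
        counts.loc["shared"] = [1, 0, 2, 0]
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        sets = detection_sets(counts, groups)
        assert sets.group_sets["A"] == {"only_a", "shared"}
        assert sets.group_sets["B"] == {"only_b", "shared"}
        assert sets.intersections[frozenset({"A", "B"})] == {"shared"}
        assert sets.exclusive("A") == {"only_a"}
        assert sets.union() == {"only_a", "only_b", "shared"}

    def test_identical_groups_intersect_fully(self, random_counts):
        groups = pd.Series("G1", index=random_counts.columns[:6]).combine_first(
            pd.Series("G2", index=random_counts.columns[6:]))
        dup = random_counts.copy()
        dup[random_counts.columns[6:]] = random_counts[
            random_counts.columns[:6]].to_numpy()
        sets = detection_sets(dup, groups)
        assert sets.intersections[frozenset({"G1", "G2"})] == \
            sets.group_sets["G1"] == sets.group_sets["G2"]

    def test_empty_group_warns(self, random_counts):
        groups = pd.Series("A", index=random_counts.columns)
        groups = pd.concat([groups, pd.Series({"ghost": "B"})])
        with pytest.warns(UserWarning, match="no samples"):
            sets = detection_sets(random_counts, groups)
        assert sets.group_sets["B"] == set()


class TestPrevalenceFilter:
    def test_always_present_kept(self, random_counts):
        kept = prevalence_filter(random_counts + 1, min_count=1,
                                 min_fraction=1.0)
        assert len(kept) == len(random_counts)

    def test_seven_of_ten_dropped_at_80_percent(self):
        row = [1] * 7 + [0] * 3
        counts = pd.DataFrame([row], index=["m"], columns=[f"s{i}"
                                                           for i in range(10)])
        assert len(prevalence_filter(counts, min_fraction=0.8)) == 0
        assert len(prevalence_filter(counts, min_fraction=0.7)) == 1

    def test_matches_brute_force_row_scan(self, random_counts):
        min_count, min_fraction = 2, 0.6
        kept = prevalence_filter(random_counts, min_count, min_fraction)
        need = math.ceil(min_fraction * random_counts.shape[1])
        expected = [i for i, row in random_counts.iterrows()
                    if sum(v >= min_count for v in row) >= need]
        assert list(kept.index) == expected

    @given(frac_lo=st.floats(0.1, 0.5), frac_hi=st.floats(0.5, 1.0))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_fraction(self, frac_lo, frac_hi):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(0.8, size=(30, 10)))
        lo = set(prevalence_filter(counts, min_fraction=frac_lo).index)
        hi = set(prevalence_filter(counts, min_fraction=frac_hi).index)
        assert hi <= lo

    def test_invalid_fraction_rejected(self, random_counts):
        with pytest.raises(ValueError):
            prevalence_filter(random_counts, min_fraction=0.0)


class TestPca:
    def test_duplicate_samples_get_identical_scores(self, random_counts):
        cpm = cpm_normalize(random_counts + 1)
        dup = pd.concat([cpm, cpm.add_suffix("_copy")], axis=1)
        res = pca_summary(dup)
        np.testing.assert_allclose(res.scores.loc["s0"],
                                   res.scores.loc["s0_copy"], atol=1e-8)

    def test_rank_one_matrix_explained_by_pc1(self):
        base = np.linspace(1, 5, 10)
        cpm = pd.DataFrame(np.outer(base, [1.0, 2.0, 3.0, 4.0]))
        res = pca_summary(cpm, log_transform=False)
        assert res.pct_variance[0] > 99.9

    def test_eigenvalues_match_direct_eigendecomposition(self):
        x = np.array([[2.0, 1.0, 0.5], [1.0, 3.0, 1.5], [0.5, 1.5, 4.0],
                      [1.0, 0.0, 2.0]])
        cpm = pd.DataFrame(x.T)       # 3 miRNAs x 4 samples
        res = pca_summary(cpm, log_transform=False)
        xc = x - x.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        np.testing.assert_allclose(res.pct_variance,
                                   evals / evals.sum() * 100, atol=1e-8)

    def test_variance_percentages_non_increasing_and_bounded(self, random_counts):
        res = pca_summary(cpm_normalize(random_counts + 1))
        assert np.all(np.diff(res.pct_variance) <= 1e-9)
        assert res.pct_variance.sum() <= 100 + 1e-6

    def test_constant_matrix_handled(self):
        cpm = pd.DataFrame(np.full((5, 4), 250_000.0))
        res = pca_summary(cpm)
        assert np.allclose(res.pct_variance, 0)
        assert np.allclose(res.scores, 0)
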