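"""Fidelity scores, distribution tests, non-uniform entropy, score utility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfprivacy import (
    ConfigurationError,
    contingency_similarity,
    correlation_similarity,
    ks_complement,
    nue_similarity,
    overall_quality,
    score_utility,
    tvd_complement,
)
from hfprivacy.anonymize import NYHA_HIERARCHY, Hierarchy
from hfprivacy.scores import CoxScore
from hfprivacy.utility import cohens_d, compare_variables

from conftest import bool_spec, cont_spec, make_schema, ord_spec, table_from_dict


def ecdf_sup_distance(x, y):
    """Brute-force sup distance between two empirical CDFs."""
    grid = np.concatenate([x, y])
    fx = np.array([(np.asarray(x) <= g).mean() for g in grid])
    fy = np.array([(np.asarray(y) <= g).mean() for g in grid])
    return np.max(np.abs(fx - fy))


class TestKsComplement:
    def test_identical_samples(self):
        assert ks_complement([1, 2, 3], [1, 2, 3]) == 1.0

    def test_disjoint_supports(self):
        assert ks_complement([1, 2], [10, 20]) == pytest.approx(0.0)

    def test_half_overlap_matches_brute_force(self):
        x, y = [1, 2, 3, 4], [3, 4, 5, 6]
        assert ecdf_sup_distance(x, y) == pytest.approx(0.5)
        assert ks_complement(x, y) == pytest.approx(0.5)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        st.lists(st.floats(-50, 50), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_and_symmetric(self, x, y):
        assert ks_complement(x, y) == pytest.approx(1 - ecdf_sup_distance(x, y), abs=1e-9)
        assert ks_complement(x, y) == pytest.approx(ks_complement(y, x), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            ks_complement([], [1.0])


class TestTvdComplement:
    def test_identical(self):
        assert tvd_complement({"A": 0.5, "B": 0.5}, {"A": 0.5, "B": 0.5}) == 1.0

    def test_total_disagreement(self):
        assert tvd_complement({"A": 1.0}, {"B": 1.0}) == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        assert tvd_complement({"A": 0.5, "B": 0.5}, {"A": 0.75, "B": 0.25}) == pytest.approx(0.75)

    def test_symmetry_and_rejects_unnormalized(self):
        r, s = {"A": 0.3, "B": 0.7}, {"A": 0.6, "B": 0.4}
        assert tvd_complement(r, s) == tvd_complement(s, r)
        with pytest.raises(ConfigurationError):
            tvd_complement({"A": 0.5}, {"A": 1.0})


class TestCorrelationSimilarity:
    @pytest.mark.parametrize(
        "rr,rs,expected", [(0.4, 0.4, 1.0), (1.0, -1.0, 0.0), (0.5, 0.1, 0.8)]
    )
    def test_formula(self, rr, rs, expected):
        assert correlation_similarity(rr, rs) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            correlation_similarity(1.5, 0.0)


class TestContingencySimilarity:
    def test_identical(self):
        j = {("a", "x"): 0.5, ("a", "y"): 0.5}
        assert contingency_similarity(j, j) == 1.0

    def test_disjoint(self):
        assert contingency_similarity({("a", "x"): 1.0}, {("b", "y"): 1.0}) == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        r = {("a", "x"): 0.5, ("a", "y"): 0.5}
        s = {("a", "x"): 0.25, ("a", "y"): 0.75}
        assert contingency_similarity(r, s) == pytest.approx(0.75)
        assert contingency_similarity(s, r) == pytest.approx(0.75)


MIXED = make_schema(
    cont_spec("x", 0, 100), cont_spec("y", 0, 100), bool_spec("b"),
)


class TestOverallQuality:
    def test_table_vs_itself_is_exactly_one(self, small_cohort):
        rep = overall_quality(small_cohort, small_cohort)
        assert rep.overall == 1.0
        assert all(v == 1.0 for v in rep.shapes.values())
        assert all(v == 1.0 for v in rep.pairs.values())

    def test_single_continuous_column_equals_ks_complement(self):
        schema = make_schema(cont_spec("x", 0, 10))
        a = table_from_dict(schema, {"x": [1.0, 2.0, 3.0, 4.0]})
        b = table_from_dict(schema, {"x": [3.0, 4.0, 5.0, 6.0]})
        rep = overall_quality(a, b)
        assert rep.overall == pytest.approx(0.5)
        assert not rep.pairs

    def test_component_count_and_mean_recomputed(self):
        rng = np.random.default_rng(1)
        a = table_from_dict(
            MIXED,
            {"x": rng.uniform(0, 100, 80), "y": rng.uniform(0, 100, 80), "b": list(rng.random(80) < 0.5)},
        )
        b = table_from_dict(
            MIXED,
            {"x": rng.uniform(0, 100, 80), "y": rng.uniform(0, 100, 80), "b": list(rng.random(80) < 0.7)},
        )
        rep = overall_quality(a, b)
        assert len(rep.shapes) == 3 and len(rep.pairs) == 3
        components = list(rep.shapes.values()) + list(rep.pairs.values())
        assert rep.overall == pytest.approx(np.mean(components))
        assert all(0.0 <= v <= 1.0 for v in components)

    def test_no_shared_columns_rejected(self):
        a = table_from_dict(make_schema(cont_spec("x", 0, 10)), {"x": [1.0]})
        b = table_from_dict(make_schema(cont_spec("z", 0, 10)), {"z": [1.0]})
        with pytest.raises(ConfigurationError):
            overall_quality(a, b)


class TestCompareVariables:
    def test_identical_tables(self, small_cohort):
        stats_ = compare_variables(small_cohort, small_cohort)
        for name, entry in stats_.per_variable.items():
            if entry["test"] == "ks":
                assert entry["cohens_d"] == 0.0
                assert entry["p"] >= 0.99
            else:
                assert entry["p"] == pytest.approx(1.0)

    def test_effect_size_consistency(self):
        rng = np.random.default_rng(2)
        schema = make_schema(cont_spec("x", -1000, 1000))
        a = table_from_dict(schema, {"x": rng.normal(0, 1, 20000)})
        b = table_from_dict(schema, {"x": rng.normal(0.5, 1, 20000)})
        d = compare_variables(a, b).per_variable["x"]["cohens_d"]
        assert abs(d) == pytest.approx(0.5, abs=0.05)

    def test_pooled_sd_zero_flagged(self):
        assert cohens_d([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert np.isnan(cohens_d([1.0, 1.0], [2.0, 2.0]))

    def test_generalized_labels_treated_as_categories(self):
        schema = make_schema(ord_spec("g", {"I": 0.5, "II": 0.5}))
        a = table_from_dict(schema, {"g": ["I", "II"] * 20})
        b = table_from_dict(schema, {"g": ["I/II"] * 40})
        entry = compare_variables(a, b).per_variable["g"]
        assert entry["test"] == "chi2"
        assert entry["p"] < 0.05


class TestNueSimilarity:
    def test_no_generalization_is_one(self):
        col = pd.Series(["I", "II", "III", "IV"])
        assert nue_similarity(col, col.copy()) == 1.0

    def test_full_suppression_is_zero(self):
        col = pd.Series(["I", "II", "III", "IV"])
        anon = pd.Series([np.nan] * 4)
        assert nue_similarity(col, anon) == pytest.approx(0.0)

    def test_hand_computed_eight_record_toy(self):
        # counts I:2 II:2 III:2 IV:2; full generalization to I/II, III/IV:
        # per-record loss -log2(2/4) = 1 bit -> total 8;
        # max loss -log2(2/8) = 2 bits each -> 16; similarity 1 - 8/16 = 0.5
        col = pd.Series(["I", "I", "II", "II", "III", "III", "IV", "IV"])
        anon = col.map(NYHA_HIERARCHY)
        assert nue_similarity(col, anon) == pytest.approx(0.5)

    def test_monotone_under_coarser_generalization(self):
        col = pd.Series(["I", "I", "II", "II", "III", "III", "IV", "IV"])
        partial = col.copy()
        partial[:4] = partial[:4].map(NYHA_HIERARCHY)
        full = col.map(NYHA_HIERARCHY)
        suppressed = pd.Series([np.nan] * 8)
        s_partial = nue_similarity(col, partial)
        s_full = nue_similarity(col, full)
        s_supp = nue_similarity(col, suppressed)
        assert 1.0 >= s_partial >= s_full >= s_supp == pytest.approx(0.0)

    def test_unexplainable_value_rejected(self):
        with pytest.raises(ConfigurationError):
            nue_similarity(pd.Series(["I", "II"]), pd.Series(["I", "weird"]))


SCORE = CoxScore(
    name="toy",
    covariates=[{"variable": "x", "transform": "linear", "coefficient": 0.05, "center": 50.0}],
    baseline_survival={1: 0.9},
)


class TestScoreUtility:
    def _table(self, values):
        schema = make_schema(cont_spec("x", 0, 100))
        return table_from_dict(schema, {"x": values})

    def test_identical_tables_zero_effect(self):
        rng = np.random.default_rng(3)
        t = self._table(rng.uniform(20, 80, 200))
        rep = score_utility(t, t.copy(), SCORE)
        assert rep.cohens_d == 0.0
        assert rep.ks_statistic == 0.0

    def test_ecdf_export_is_nondecreasing_zero_to_one(self):
        rng = np.random.default_rng(4)
        rep = score_utility(
            self._table(rng.uniform(20, 80, 150)),
            self._table(rng.uniform(20, 80, 150)),
            SCORE,
        )
        for _, grp in rep.ecdf.groupby("table"):
            e = grp["ecdf"].to_numpy()
            assert (np.diff(e) >= 0).all()
            assert e[-1] == pytest.approx(1.0)

    def test_location_shift_recovered_in_cohens_d(self):
        rng = np.random.default_rng(5)
        base = rng.normal(50, 8, 20000).clip(1, 99)
        shifted = (base + 4.0).clip(1, 99)
        rep = score_utility(self._table(base), self._table(shifted), SCORE)
        # expected d computed from the actual score values
        from hfprivacy.scores import score_table

        a = score_table(self._table(base), SCORE).values
        b = score_table(self._table(shifted), SCORE).values
        expected = cohens_d(a, b)
        assert rep.cohens_d == pytest.approx(expected, rel=1e-9)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        shift_d = (a.mean() - b.mean()) / pooled
        assert rep.cohens_d == pytest.approx(shift_d, rel=0.1)
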