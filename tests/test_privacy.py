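"""Splits, Gower distance, attack risks, normalization, DCR metrics."""

import numpy as np
import pandas as pd
import pytest

from hfprivacy import (
    AttackConfig,
    CohortTable,
    ConfigurationError,
    GeneratorConfig,
    dcr_metrics,
    generate_cohort,
    gower_distance,
    inference_risk,
    linkage_risk,
    normalize_risk,
    repeat_assessment,
    singling_out_risk,
    split_train_control,
)
from hfprivacy.privacy import gower_matrix

from conftest import bool_spec, cont_spec, make_schema, ord_spec, table_from_dict


def cohort(n, seed, missing=0.0):
    return generate_cohort(
        config=GeneratorConfig(n_records=n, seed=seed, missingness_rate=missing)
    )


class TestSplit:
    def test_even_split(self):
        sp = split_train_control(cohort(100, 1), seed=2)
        assert sp.training.n_rows == 50 and sp.control.n_rows == 50

    def test_odd_split_sizes_differ_by_one(self):
        sp = split_train_control(cohort(101, 1), seed=2)
        assert {sp.training.n_rows, sp.control.n_rows} == {50, 51}

    def test_partition_disjoint_and_complete(self):
        t = cohort(60, 3)
        sp = split_train_control(t, seed=4)
        merged = pd.concat([sp.training.df, sp.control.df]).sort_values(
            list(t.df.columns)
        )
        assert len(merged) == 60

    def test_same_seed_identical(self):
        t = cohort(50, 5)
        a, b = split_train_control(t, 6), split_train_control(t, 6)
        assert a.training.equals(b.training) and a.control.equals(b.control)

    def test_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            split_train_control(cohort(2, 1).__class__(
                cohort(2, 1).schema, cohort(2, 1).df.iloc[:1]
            ), 1)


MIX = make_schema(
    cont_spec("x", 0, 10), bool_spec("b"), ord_spec("g", {"a": 0.5, "b": 0.5})
)


class TestGower:
    def test_identical_records_zero(self):
        t = table_from_dict(MIX, {"x": [3.0], "b": [True], "g": ["a"]})
        assert gower_distance(t.df.iloc[0], t.df.iloc[0], MIX) == 0.0

    def test_full_categorical_mismatch_is_one(self):
        schema = make_schema(bool_spec("b"), ord_spec("g", {"a": 0.5, "b": 0.5}))
        t = table_from_dict(schema, {"b": [True, False], "g": ["a", "b"]})
        assert gower_distance(t.df.iloc[0], t.df.iloc[1], schema) == 1.0

    def test_half_range_contribution(self):
        t = table_from_dict(
            MIX, {"x": [0.0, 5.0], "b": [True, True], "g": ["a", "a"]}
        )
        assert gower_distance(t.df.iloc[0], t.df.iloc[1], MIX) == pytest.approx(0.5 / 3)

    def test_both_missing_excluded_one_sided_mismatch(self):
        t = table_from_dict(
            MIX, {"x": [np.nan, np.nan], "b": [True, True], "g": ["a", np.nan]}
        )
        # x excluded, b matches (0), g one-sided missing (1) -> mean over 2
        assert gower_distance(t.df.iloc[0], t.df.iloc[1], MIX) == pytest.approx(0.5)

    def test_matrix_matches_pairwise_function(self):
        t = cohort(15, 7)
        m = gower_matrix(t, t)
        for i in (0, 3, 7):
            for j in (1, 4, 9):
                assert m[i, j] == pytest.approx(
                    gower_distance(t.df.iloc[i], t.df.iloc[j], t.schema), abs=1e-12
                )
        assert np.allclose(np.diag(m), 0.0)


class TestNormalizeRisk:
    @pytest.mark.parametrize(
        "a,c,expected", [(0.3, 0.3, 0.0), (1.0, 0.0, 1.0), (0.5, 0.2, 0.375)]
    )
    def test_formula(self, a, c, expected):
        assert normalize_risk(a, c) == pytest.approx(expected)

    def test_degenerate_control(self):
        assert normalize_risk(1.0, 1.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_risk(1.2, 0.0)


class TestSinglingOut:
    def test_verbatim_copy_high_risk(self):
        t = cohort(400, 11)
        sp = split_train_control(t, 12)
        protected = sp.training  # total leak: protected = training
        cfg = AttackConfig(n_attacks=100, repetitions=1, mode="singling_out_multi")
        est = singling_out_risk(protected, sp.training, sp.control, cfg, seed=13)
        assert est.risk > 0.5

    @pytest.mark.parametrize("mode", ["singling_out_uni", "singling_out_multi"])
    def test_null_calibration_independent_protected(self, mode):
        training, control = (
            split_train_control(cohort(400, 14), 15).training,
            split_train_control(cohort(400, 14), 15).control,
        )
        protected = cohort(200, 999)
        cfg = AttackConfig(n_attacks=100, repetitions=10, mode=mode, seed=16)
        est = repeat_assessment(
            lambda s: singling_out_risk(protected, training, control, cfg, s), cfg
        )
        assert est.risk < 0.1

    def test_zero_attacks_rejected(self):
        with pytest.raises(ConfigurationError):
            AttackConfig(n_attacks=0)

    def test_bad_mode_rejected(self):
        t = cohort(40, 1)
        cfg = AttackConfig(mode="linkage")
        with pytest.raises(ConfigurationError):
            singling_out_risk(t, t, t, cfg, 1)


class TestLinkage:
    def test_copy_of_training_links_perfectly(self):
        t = cohort(120, 17)
        sp = split_train_control(t, 18)
        cfg = AttackConfig(n_attacks=50, repetitions=1)
        est = linkage_risk(sp.training, sp.training, sp.control, None, cfg, seed=19)
        assert est.attack_rate == 1.0
        assert est.risk > 0.9

    def test_null_calibration(self):
        sp = split_train_control(cohort(400, 20), 21)
        protected = cohort(200, 888)
        cfg = AttackConfig(n_attacks=100, repetitions=10, seed=22)
        est = repeat_assessment(
            lambda s: linkage_risk(protected, sp.training, sp.control, None, cfg, s),
            cfg,
        )
        assert est.risk < 0.1

    def test_empty_aux_set_rejected(self):
        t = cohort(40, 23)
        with pytest.raises(ConfigurationError):
            linkage_risk(t, t, t, ([], t.schema.names), AttackConfig(), 1)

    def test_nearest_tie_resolved_to_lowest_index(self):
        # two identical protected records: argmin must return index 0
        t = table_from_dict(
            MIX, {"x": [1.0, 1.0, 9.0], "b": [True, True, False], "g": ["a", "a", "b"]}
        )
        target = table_from_dict(MIX, {"x": [1.0], "b": [True], "g": ["a"]})
        d = gower_matrix(target, t)
        assert d.argmin(axis=1)[0] == 0


class TestInference:
    def test_copy_of_training_perfect_inference(self):
        t = cohort(120, 24)
        sp = split_train_control(t, 25)
        aux = [n for n in t.schema.names if n != "lvef"]
        cfg = AttackConfig(n_attacks=50, repetitions=1)
        est = inference_risk(sp.training, sp.training, sp.control, aux, "lvef", cfg, 26)
        assert est.attack_rate == 1.0

    def test_independent_secret_low_risk(self):
        sp = split_train_control(cohort(300, 27), 28)
        protected = cohort(150, 777)
        aux = [n for n in protected.schema.names if n != "haemoglobin"]
        cfg = AttackConfig(n_attacks=100, repetitions=10, seed=29)
        est = repeat_assessment(
            lambda s: inference_risk(
                protected, sp.training, sp.control, aux, "haemoglobin", cfg, s
            ),
            cfg,
        )
        assert est.risk < 0.1

    def test_tolerance_monotonicity(self):
        t = cohort(200, 30)
        sp = split_train_control(t, 31)
        protected = cohort(100, 32)
        aux = [n for n in t.schema.names if n != "sodium"]
        rates = []
        for tol in (0.0, 0.05):
            cfg = AttackConfig(n_attacks=100, repetitions=1, tolerance=tol)
            est = inference_risk(protected, sp.training, sp.control, aux, "sodium", cfg, 33)
            rates.append(est.attack_rate)
        assert rates[0] <= rates[1]

    def test_secret_in_aux_rejected(self):
        t = cohort(40, 34)
        with pytest.raises(ConfigurationError):
            inference_risk(t, t, t, t.schema.names, "lvef", AttackConfig(), 1)

    def test_constant_secret_degenerate(self):
        t = cohort(40, 35)
        t.df["diabetes"] = True
        aux = [n for n in t.schema.names if n != "diabetes"]
        est = inference_risk(t, t, t, aux, "diabetes", AttackConfig(), 1)
        assert est.risk == 0.0 and "degenerate_secret" in est.flags


class TestRepeatAssessment:
    def test_single_repetition_zero_sd(self):
        cfg = AttackConfig(n_attacks=10, repetitions=1)
        est = repeat_assessment(
            lambda s: singling_out_risk(
                cohort(50, 36), cohort(50, 37), cohort(50, 38),
                AttackConfig(n_attacks=10, mode="singling_out_uni"), s,
            ),
            cfg,
        )
        assert est.sd == 0.0

    def test_mean_is_arithmetic_mean_and_deterministic_sd_zero(self):
        calls = []

        def fake_attack(seed):
            from hfprivacy.privacy import RiskEstimate

            calls.append(seed)
            return RiskEstimate(0.25, 0.0, [0.25], 0.3, 0.1)

        cfg = AttackConfig(n_attacks=1, repetitions=5)
        est = repeat_assessment(fake_attack, cfg)
        assert est.risk == pytest.approx(0.25)
        assert est.sd == 0.0
        assert est.per_repetition == [0.25] * 5
        assert len(set(calls)) == 5  # distinct sub-seeds


class TestDcr:
    def test_protected_subset_of_training(self):
        t = cohort(200, 39)
        sp = split_train_control(t, 40)
        rep = dcr_metrics(sp.training, sp.training, sp.control)
        assert rep.share == 1.0
        assert rep.median_dcr_training == 0.0

    def test_swap_symmetry(self):
        a, b, p = cohort(150, 41), cohort(150, 42), cohort(150, 43)
        fwd = dcr_metrics(p, a, b)
        rev = dcr_metrics(p, b, a)
        assert fwd.share == pytest.approx(1.0 - rev.share)
        assert fwd.median_dcr_ratio == pytest.approx(1.0 / rev.median_dcr_ratio)

    def test_empty_protected_rejected(self):
        t = cohort(10, 44)
        empty = CohortTable(t.schema, t.df.iloc[:0])
        with pytest.raises(ConfigurationError):
            dcr_metrics(empty, t, t)


def test_protection_never_increases_constructed_leak_risk():
    """Copy -> anonymized -> combined: multivariate singling-out risk on a
    constructed total-leak scenario is non-increasing along the chain."""
    from hfprivacy import AnonConfig, ProtectionMethod, clean, protect, score_subset

    t = generate_cohort(config=GeneratorConfig(n_records=700, seed=45))
    sub = score_subset(clean(t), "BioHF")
    sp = split_train_control(sub, 46)
    cfg = AttackConfig(n_attacks=150, repetitions=3, mode="singling_out_multi", seed=47)

    def risk_of(protected):
        return repeat_assessment(
            lambda s: singling_out_risk(protected, sp.training, sp.control, cfg, s),
            cfg,
        ).risk

    copy_risk = risk_of(sp.training)
    anon, _ = protect(sp.training, ProtectionMethod("anonymize"), seed=48)
    comb, _ = protect(sp.training, ProtectionMethod("combined"), seed=48)
    assert copy_risk >= risk_of(anon)
    assert copy_risk >= risk_of(comb)
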