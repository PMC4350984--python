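"""Partitioning, confusion/diagnostics, stratified audit estimation."""

import numpy as np
import pandas as pd
import pytest

from radrole.evaluation import (
    AGREE,
    DISAGREE,
    AuditDesign,
    ConfusionMatrix,
    PartitionSpec,
    assign_audit_strata,
    audit_confusion_by_stratum,
    confusion_matrix,
    diagnostic_metrics,
    population_quality_report,
    split_dataset,
    stratified_audit_sample,
    stratified_estimates,
)
from radrole.records import CURATIVE, PALLIATIVE
from radrole.synthdata import SynthConfig, generate_records


class TestSplitDataset:
    def test_partition_is_disjoint_and_exhaustive(self):
        df = pd.DataFrame({"x": range(10)})
        train, valid, test = split_dataset(df, PartitionSpec(seed=1))
        assert len(train) + len(valid) + len(test) == 10
        assert set(train.index) | set(valid.index) | set(test.index) == set(range(10))

    def test_same_seed_identical(self):
        df = pd.DataFrame({"x": range(100)})
        a = split_dataset(df, PartitionSpec(seed=7))
        b = split_dataset(df, PartitionSpec(seed=7))
        for left, right in zip(a, b):
            assert list(left.index) == list(right.index)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            PartitionSpec(fractions=(0.5, 0.3, 0.3))

    def test_mean_train_share_near_forty_percent(self):
        df = pd.DataFrame({"x": range(100)})
        shares = [
            len(split_dataset(df, PartitionSpec(seed=s))[0]) / 100 for s in range(200)
        ]
        se = np.sqrt(0.4 * 0.6 / (100 * 200))
        assert abs(np.mean(shares) - 0.40) < 3 * se


class TestConfusion:
    def test_identity_predictions(self):
        cm = confusion_matrix(["C", "P", "C"], ["C", "P", "C"])
        assert cm.accuracy == 1.0
        assert cm.rate_c_to_p == 0.0 and cm.rate_p_to_c == 0.0

    def test_count_arithmetic(self):
        cm = ConfusionMatrix(n_cc=90, n_cp=10, n_pc=0, n_pp=0)
        assert cm.accuracy == pytest.approx(0.90)
        assert cm.rate_c_to_p == pytest.approx(0.10)

    def test_rates_and_accuracy_sum_to_one(self):
        rng = np.random.default_rng(3)
        pred = rng.choice(["C", "P"], 500)
        ref = rng.choice(["C", "P"], 500)
        cm = confusion_matrix(pred, ref)
        assert cm.accuracy + cm.rate_c_to_p + cm.rate_p_to_c == pytest.approx(1.0)
        # direct-count oracle
        assert cm.accuracy == pytest.approx((pred == ref).mean())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["C"], ["C", "P"])

    def test_wilson_ci_contains_point_and_shrinks(self):
        small = ConfusionMatrix(n_cc=45, n_cp=5, n_pc=0, n_pp=0)
        big = ConfusionMatrix(n_cc=900, n_cp=100, n_pc=0, n_pp=0)
        for cm in (small, big):
            lo, hi = cm.accuracy_ci()
            assert lo <= cm.accuracy <= hi
        w_small = np.diff(small.accuracy_ci())[0]
        w_big = np.diff(big.accuracy_ci())[0]
        assert w_big < w_small


class TestDiagnostics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(n_cc=50, n_cp=0, n_pc=0, n_pp=50)
        metrics = diagnostic_metrics(cm)
        assert all(m.value == 1.0 for m in metrics.values())

    def test_arithmetic_example(self):
        cm = ConfusionMatrix(n_cc=97, n_cp=3, n_pc=16, n_pp=84)
        metrics = diagnostic_metrics(cm)
        assert metrics["sensitivity"].value == pytest.approx(0.84)
        assert metrics["specificity"].value == pytest.approx(0.97)

    def test_all_curative_policy(self):
        cm = confusion_matrix(["C"] * 10, ["C"] * 7 + ["P"] * 3)
        metrics = diagnostic_metrics(cm)
        assert metrics["sensitivity"].value == 0.0
        assert metrics["specificity"].value == 1.0
        assert metrics["ppv"] is None  # zero denominator -> undefined

    def test_ci_contains_point(self):
        cm = ConfusionMatrix(n_cc=80, n_cp=20, n_pc=10, n_pp=90)
        for m in diagnostic_metrics(cm).values():
            assert m.ci_low <= m.value <= m.ci_high


def one_record_audit_frame(n, classifier_error, intent_error, seed):
    """One record per patient with independent classifier and intent
    errors; the binary labels make any double error an agreement."""
    rng = np.random.default_rng(seed)
    truth = np.where(rng.random(n) < 0.3, "P", "C")
    flip = lambda labels, rate: np.where(
        rng.random(n) < rate, np.where(labels == "C", "P", "C"), labels
    )
    return pd.DataFrame(
        {
            "record_id": np.arange(n),
            "patient_id": [f"q{i}" for i in range(n)],
            "treat_date": pd.Timestamp("2006-01-01"),
            "centre": "C1",
            "true_role": truth,
            "trr_label": flip(truth, classifier_error),
            "intent_flag": flip(truth, intent_error),
        }
    )


def _stratified_frame(n_patients=400, seed=0, **config_kw):
    config = SynthConfig(n_patients=n_patients, seed=seed, **config_kw)
    df = generate_records(config)
    # a deliberately imperfect classifier standing in for the tree: dose cut
    df["trr_label"] = np.where(df["fraction_size"].fillna(250.0) >= 277.0, "P", "C")
    return df


class TestAuditSampling:
    def test_census_returns_whole_population(self):
        df = _stratified_frame(80)
        design = AuditDesign(strata_by=("agreement",), n_per_stratum=10**9, seed=0)
        df = assign_audit_strata(df, design)
        sample, table = stratified_audit_sample(df, design)
        assert len(sample) == len(df)
        assert (sample["weight"] == 1.0).all()
        assert table["N_patients"].sum() == df["patient_id"].nunique()

    def test_exact_stratum_allocations(self):
        df = _stratified_frame(120)
        design = AuditDesign(strata_by=("agreement",), n_per_stratum=4, seed=1)
        df = assign_audit_strata(df, design)
        sample, table = stratified_audit_sample(df, design)
        per = sample.groupby("audit_stratum")["patient_id"].nunique()
        assert (per == 4).all()
        assert (table["n_patients"] == 4).all()

    def test_fixed_seed_reproducible(self):
        df = _stratified_frame(100)
        design = AuditDesign(strata_by=("centre", "agreement"), n_per_stratum=3, seed=9)
        df = assign_audit_strata(df, design)
        a, _ = stratified_audit_sample(df, design)
        b, _ = stratified_audit_sample(df, design)
        assert list(a["record_id"]) == list(b["record_id"])

    def test_oversized_request_rejected(self):
        df = _stratified_frame(30)
        design = AuditDesign(strata_by=("agreement",), n_per_stratum={AGREE: 10**6}, seed=0)
        df = assign_audit_strata(df, design)
        with pytest.raises(ValueError):
            stratified_audit_sample(df, design)


class TestStratifiedEstimates:
    def test_single_stratum_reduces_to_pooled(self):
        counts = pd.DataFrame(
            [{"weight": 1.0, "n_cc": 80, "n_cp": 20, "n_pc": 10, "n_pp": 90}]
        )
        est = stratified_estimates(counts)
        pooled = diagnostic_metrics(ConfusionMatrix(80, 20, 10, 90))
        assert est.sensitivity.value == pytest.approx(pooled["sensitivity"].value)
        assert est.specificity.value == pytest.approx(pooled["specificity"].value)
        assert est.ppv.value == pytest.approx(pooled["ppv"].value)
        assert est.npv.value == pytest.approx(pooled["npv"].value)

    def test_two_stratum_hand_example(self):
        # (N=900,n=90,TP=30,FN=10) and (N=100,n=50,TP=20,FN=20)
        counts = pd.DataFrame(
            [
                {"weight": 10.0, "n_cc": 0, "n_cp": 0, "n_pc": 10, "n_pp": 30},
                {"weight": 2.0, "n_cc": 0, "n_cp": 0, "n_pc": 20, "n_pp": 20},
            ]
        )
        est = stratified_estimates(counts)
        assert est.sensitivity.value == pytest.approx(340 / 480)

    def test_scaling_all_population_sizes_invariant(self):
        counts = pd.DataFrame(
            [
                {"weight": 5.0, "n_cc": 40, "n_cp": 5, "n_pc": 8, "n_pp": 30},
                {"weight": 2.0, "n_cc": 25, "n_cp": 9, "n_pc": 3, "n_pp": 50},
            ]
        )
        doubled = counts.assign(weight=counts["weight"] * 2)
        a, b = stratified_estimates(counts), stratified_estimates(doubled)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(a, name).value == pytest.approx(getattr(b, name).value)

    def test_equal_weights_match_pooled(self):
        counts = pd.DataFrame(
            [
                {"weight": 3.0, "n_cc": 40, "n_cp": 5, "n_pc": 8, "n_pp": 30},
                {"weight": 3.0, "n_cc": 25, "n_cp": 9, "n_pc": 3, "n_pp": 50},
            ]
        )
        est = stratified_estimates(counts)
        pooled = diagnostic_metrics(ConfusionMatrix(65, 14, 11, 80))
        assert est.sensitivity.value == pytest.approx(pooled["sensitivity"].value)
        assert est.npv.value == pytest.approx(pooled["npv"].value)

    def test_recovers_population_values_on_synthetic_data(self):
        df = _stratified_frame(2500, seed=5)
        design = AuditDesign(strata_by=("agreement",), n_per_stratum=150, seed=2)
        df = assign_audit_strata(df, design)
        sample, _ = stratified_audit_sample(df, design)
        counts = audit_confusion_by_stratum(sample, "true_role", "trr_label")
        est = stratified_estimates(counts)
        # population truth by direct counting
        tp = ((df["true_role"] == "P") & (df["trr_label"] == "P")).sum()
        fn = ((df["true_role"] == "P") & (df["trr_label"] == "C")).sum()
        tn = ((df["true_role"] == "C") & (df["trr_label"] == "C")).sum()
        fp = ((df["true_role"] == "C") & (df["trr_label"] == "P")).sum()
        true_sens, true_spec = tp / (tp + fn), tn / (tn + fp)
        from _oracles import mc_se_weighted_ratio

        for est_m, truth, target in (
            (est.sensitivity, true_sens, "P"),
            (est.specificity, true_spec, "C"),
        ):
            se = mc_se_weighted_ratio(df, sample, "true_role", "trr_label", target=target)
            assert abs(est_m.value - truth) <= 3 * se


class TestQualityReport:
    def _report(self, df, design):
        df = assign_audit_strata(df, design)
        sample, _ = stratified_audit_sample(df, design)
        return df, sample, population_quality_report(df, sample, truth_col="true_role")

    @staticmethod
    def _value(report, metric, method):
        row = report[(report["metric"] == metric) & (report["method"] == method)]
        return float(row["value"].iloc[0])

    def test_noiseless_perfect_classifier(self):
        df = generate_records(
            SynthConfig(
                n_patients=150,
                seed=3,
                intent_flip_rate=0.0,
                intent_missing_rate=0.0,
                missing_rates={"fraction_size": 0.0, "body_region_group": 0.0,
                               "site_group": 0.0, "days_from_first": 0.0},
            )
        )
        df["trr_label"] = df["true_role"]
        design = AuditDesign(strata_by=("agreement",), n_per_stratum=10**9, seed=0)
        _, _, report = self._report(df, design)
        for method in ("classification_rules", "intent_flag"):
            assert self._value(report, "% correct", method) == pytest.approx(100.0)
            assert self._value(report, "% incorrect", method) == pytest.approx(0.0)
            assert self._value(report, "% missing", method) == pytest.approx(0.0)

    def test_five_percent_flips_complete_intent(self):
        df = _stratified_frame(
            2000, seed=8, intent_flip_rate=0.05, intent_missing_rate=0.0
        )
        design = AuditDesign(strata_by=("agreement",), n_per_stratum=10**9, seed=0)
        _, _, report = self._report(df, design)
        incorrect = self._value(report, "% incorrect", "intent_flag")
        n = len(df)
        se = 100 * np.sqrt(0.05 * 0.95 / n)
        assert abs(incorrect - 5.0) < 3 * se
        assert self._value(report, "% missing", "intent_flag") == 0.0

    def test_rows_sum_to_hundred(self):
        df = _stratified_frame(600, seed=10)
        design = AuditDesign(strata_by=("agreement",), n_per_stratum=50, seed=4)
        _, _, report = self._report(df, design)
        for method in ("classification_rules", "intent_flag"):
            total = sum(
                self._value(report, m, method)
                for m in ("% correct", "% incorrect", "% missing")
            )
            assert total == pytest.approx(100.0)

    def test_disagreement_only_audit_overstates_success(self):
        # census audits make the comparison deterministic: the targeted
        # design assumes agreement records correct, so agree-but-both-wrong
        # records inflate % correct. One record per patient isolates the
        # estimator mechanism from within-patient clustering.
        df = one_record_audit_frame(
            n=20_000, classifier_error=0.03, intent_error=0.05, seed=12
        )
        full_design = AuditDesign(strata_by=("agreement",), n_per_stratum=10**9, seed=0)
        df = assign_audit_strata(df, full_design)
        full_sample, _ = stratified_audit_sample(df, full_design)
        full_report = population_quality_report(df, full_sample, truth_col="true_role")

        n_disagree = df.loc[df["audit_stratum"] == DISAGREE, "patient_id"].nunique()
        targeted = AuditDesign(
            strata_by=("agreement",), n_per_stratum={DISAGREE: n_disagree}, seed=0
        )
        targeted_sample, _ = stratified_audit_sample(df, targeted)
        targeted_report = population_quality_report(
            df, targeted_sample, truth_col="true_role",
            assume_unaudited_agreement_correct=True,
        )
        both_wrong_in_agree = (
            (df["audit_stratum"] == AGREE)
            & (df["trr_label"] != df["true_role"])
        ).sum()
        assert both_wrong_in_agree > 0  # the mechanism of the bias
        for method in ("classification_rules", "intent_flag"):
            assert self._value(targeted_report, "% correct", method) > self._value(
                full_report, "% correct", method
            )
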