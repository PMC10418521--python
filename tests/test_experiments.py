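"""Split construction, model fitting, bootstrap aggregation and the
inflation report."""

import numpy as np
import pandas as pd
import pytest

from fcleak.experiments import (
    fit_predict,
    inflation_report,
    make_random_scan_split,
    make_scan_double_dip_split,
    make_subject_disjoint_split,
    make_window_double_dip_split,
    null_metric,
    run_bootstrap,
    run_cross_cohort,
)
from fcleak.synthetic import SynthConfig, generate_fc_cohort
from fcleak.types import ExperimentResult, SplitSpec, vectors_to_frame


def _toy_table(n_subjects=10, scans=2, windows=None):
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n_subjects):
        for s in range(scans):
            wins = range(windows) if windows else [-1]
            for w in wins:
                rows.append({"subject_id": f"sub{i:02d}", "scan_id": f"scan{s:02d}",
                             "window_index": w, "ROI0_ROI1": rng.uniform(-1, 1)})
    return pd.DataFrame(rows)


class TestSplits:
    def test_subject_disjoint_counts(self):
        split = make_subject_disjoint_split(_toy_table(10, 2), 0.2, seed=0)
        assert len(split.test_units) == 4
        assert len({u[0] for u in split.test_units}) == 2
        assert not {u[0] for u in split.train_units} & {u[0] for u in split.test_units}

    def test_subject_disjoint_deterministic(self):
        t = _toy_table(10, 2)
        a = make_subject_disjoint_split(t, seed=42)
        b = make_subject_disjoint_split(t, seed=42)
        assert a.train_units == b.train_units and a.test_units == b.test_units

    def test_subject_test_frequency(self):
        t = _toy_table(10, 2)
        counts = {f"sub{i:02d}": 0 for i in range(10)}
        for seed in range(100):
            for u in make_subject_disjoint_split(t, seed=seed).test_units:
                counts[u[0]] += 1
        freqs = np.array(list(counts.values())) / 200.0  # 2 units per draw
        assert np.all((freqs > 0.08) & (freqs < 0.35))
        assert np.mean(freqs) == pytest.approx(0.2)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="5 subjects"):
            make_subject_disjoint_split(_toy_table(4, 2))

    def test_scan_double_dip(self):
        split = make_scan_double_dip_split(_toy_table(50, 2))
        assert len(split.train_units) == len(split.test_units) == 50
        assert {u[0] for u in split.train_units} == {u[0] for u in split.test_units}
        assert not set(split.train_units) & set(split.test_units)
        assert all(u[1] == "scan00" for u in split.train_units)

    def test_scan_double_dip_three_scans(self):
        t = _toy_table(6, 3)
        split = make_scan_double_dip_split(t)
        per_subject_train = pd.Series([u[0] for u in split.train_units]).value_counts()
        assert (per_subject_train == 2).all()
        per_subject_test = pd.Series([u[0] for u in split.test_units]).value_counts()
        assert (per_subject_test == 1).all()

    def test_scan_double_dip_needs_multiscan(self):
        with pytest.raises(ValueError, match="two or more"):
            make_scan_double_dip_split(_toy_table(5, 1))

    def test_window_double_dip_interleaves(self):
        split = make_window_double_dip_split(_toy_table(5, 1, windows=4))
        assert all(u[2] in (0, 2) for u in split.train_units)
        assert all(u[2] in (1, 3) for u in split.test_units)
        assert {u[0] for u in split.train_units} == {u[0] for u in split.test_units}

    def test_window_double_dip_single_window_errors(self):
        with pytest.raises(ValueError, match="single window"):
            make_window_double_dip_split(_toy_table(5, 1, windows=1))

    def test_random_scan_split(self):
        split = make_random_scan_split(_toy_table(10, 2), 0.2, seed=1)
        assert split.leakage_mode == "scan_shuffled"
        assert len(split.test_units) == 4

    def test_split_spec_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitSpec([("s1", "a", -1)], [("s1", "a", -1)], "scan_shuffled")

    def test_split_spec_rejects_leaky_disjoint(self):
        with pytest.raises(ValueError, match="both sides"):
            SplitSpec([("s1", "a", -1)], [("s1", "b", -1)], "subject_disjoint")


class TestFitPredict:
    def test_noiseless_phenotype_is_learned(self):
        cfg = SynthConfig(n_subjects=30, n_rois=10, seed=8,
                          alpha_fingerprint=0, sigma_session=0, beta_phenotype=2.0)
        vectors, cohort = generate_fc_cohort(cfg)
        fc = vectors_to_frame(vectors)
        split = make_subject_disjoint_split(fc, seed=0)
        acc, _ = fit_predict(fc, cohort, split, "classification", seed=0)
        rmse, _ = fit_predict(fc, cohort, split, "regression", seed=0)
        assert acc == 1.0
        assert rmse < 0.1

    def test_permuted_labels_give_chance_accuracy(self, small_fc_table):
        fc, cohort = small_fc_table
        rng = np.random.default_rng(11)
        accs = []
        for seed in range(5):
            shuffled = cohort.copy()
            perm = rng.permutation(cohort["subject_id"].unique())
            remap = dict(zip(cohort["subject_id"].unique(), perm))
            pheno = cohort.drop_duplicates("subject_id").set_index("subject_id")
            shuffled["phenotype_bin"] = [int(pheno.loc[remap[s], "phenotype_bin"]) for s in shuffled["subject_id"]]
            shuffled["phenotype_cont"] = [float(pheno.loc[remap[s], "phenotype_cont"]) for s in shuffled["subject_id"]]
            split = make_subject_disjoint_split(fc, seed=seed)
            accs.append(fit_predict(fc, shuffled, split, "classification", seed=seed)[0])
        # 5 seeds x 8 test scans: binomial around 0.5
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / (5 * 8))

    def test_single_class_training_rejected(self, small_fc_table):
        fc, cohort = small_fc_table
        degenerate = cohort.copy()
        degenerate["phenotype_bin"] = 1
        split = make_subject_disjoint_split(fc, seed=0)
        with pytest.raises(ValueError, match="single class"):
            fit_predict(fc, degenerate, split, "classification")

    def test_scaler_uses_train_statistics_only(self, small_fc_table):
        from sklearn.preprocessing import StandardScaler

        fc, cohort = small_fc_table
        split = make_subject_disjoint_split(fc, seed=3)
        edge_cols = [c for c in fc.columns if c.startswith("ROI")]
        indexed = fc.set_index(["subject_id", "scan_id", "window_index"])
        x_train = indexed.loc[split.train_units, edge_cols].to_numpy()
        scaler = StandardScaler().fit(x_train)
        # a scaler fit on train rows alone reproduces the pipeline's view of
        # the test data: test rows never enter the normalization
        x_all = indexed.loc[split.train_units + split.test_units, edge_cols].to_numpy()
        leaky = StandardScaler().fit(x_all)
        assert not np.allclose(scaler.mean_, leaky.mean_)

    def test_missing_units_rejected(self, small_fc_table):
        fc, cohort = small_fc_table
        split = SplitSpec([("ghost", "scan00", -1)], [("sub00", "scan00", -1)], "scan_shuffled")
        with pytest.raises(KeyError, match="missing"):
            fit_predict(fc, cohort, split, "classification")


class TestNullMetric:
    def _cohort(self, labels, conts=None):
        n = len(labels)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "scan_id": "a",
            "phenotype_cont": conts if conts is not None else np.linspace(-1, 1, n),
            "phenotype_bin": labels,
        })

    def test_balanced_labels(self):
        cohort = self._cohort([0, 1] * 10)
        units = [(f"s{i}", "a", -1) for i in range(20)]
        split = SplitSpec(units[:10], units[10:], "scan_shuffled")
        assert null_metric(cohort, split, "classification") == pytest.approx(0.5)

    def test_imbalanced_labels(self):
        # train majority is 1 (60/40); test is the same composition
        labels = [1] * 6 + [0] * 4 + [1] * 6 + [0] * 4
        cohort = self._cohort(labels)
        units = [(f"s{i}", "a", -1) for i in range(20)]
        split = SplitSpec(units[:10], units[10:], "scan_shuffled")
        assert null_metric(cohort, split, "classification") == pytest.approx(0.6)

    def test_regression_null_is_train_mean_rmse(self):
        rng = np.random.default_rng(5)
        conts = rng.standard_normal(20)
        cohort = self._cohort([0, 1] * 10, conts)
        units = [(f"s{i}", "a", -1) for i in range(20)]
        split = SplitSpec(units[:10], units[10:], "scan_shuffled")
        expected = np.sqrt(np.mean((conts[10:] - conts[:10].mean()) ** 2))
        assert null_metric(cohort, split, "regression") == pytest.approx(expected)


class TestBootstrapAndCrossCohort:
    def test_iteration_count_and_determinism(self, small_fc_table):
        fc, cohort = small_fc_table
        res = run_bootstrap(fc, cohort, make_subject_disjoint_split,
                            "classification", n_iterations=3, base_seed=5)
        assert len(res.per_iteration_metric) == 3
        assert len(res.chosen_hyperparameter) == 3
        res2 = run_bootstrap(fc, cohort, make_subject_disjoint_split,
                             "classification", n_iterations=3, base_seed=5)
        assert res.per_iteration_metric == res2.per_iteration_metric

    def test_mean_consistent_with_higher_replication(self, small_fc_table):
        fc, cohort = small_fc_table
        short = run_bootstrap(fc, cohort, make_subject_disjoint_split,
                              "classification", n_iterations=5, base_seed=0)
        long = run_bootstrap(fc, cohort, make_subject_disjoint_split,
                             "classification", n_iterations=15, base_seed=100)
        spread = max(short.metric_sd, long.metric_sd, 1e-6)
        assert abs(short.metric_mean - long.metric_mean) <= spread

    def test_cross_cohort_no_signal_is_chance(self):
        base = dict(n_subjects=25, n_rois=10, beta_phenotype=0.0)
        a = SynthConfig(seed=1, structure_seed=7, **base)
        b = SynthConfig(seed=2, structure_seed=7, **base)
        fa, ca = generate_fc_cohort(a)
        fb, cb = generate_fc_cohort(b)
        res = run_cross_cohort(vectors_to_frame(fa), ca, vectors_to_frame(fb), cb,
                               "classification")
        assert abs(res.metric_mean - 0.5) < 3 * np.sqrt(0.25 / res.n_test)

    def test_cross_cohort_transfers_phenotype_signal(self):
        base = dict(n_subjects=25, n_rois=10, beta_phenotype=2.0,
                    alpha_fingerprint=0.5, sigma_session=0.3)
        a = SynthConfig(seed=1, structure_seed=7, **base)
        b = SynthConfig(seed=2, structure_seed=7, **base)
        fa, ca = generate_fc_cohort(a)
        fb, cb = generate_fc_cohort(b)
        res = run_cross_cohort(vectors_to_frame(fa), ca, vectors_to_frame(fb), cb,
                               "classification")
        assert res.metric_mean > 0.8

    def test_cross_cohort_feature_mismatch(self):
        a = SynthConfig(n_subjects=25, n_rois=10, seed=1)
        b = SynthConfig(n_subjects=25, n_rois=12, seed=2)
        fa, ca = generate_fc_cohort(a)
        fb, cb = generate_fc_cohort(b)
        with pytest.raises(ValueError, match="mismatch"):
            run_cross_cohort(vectors_to_frame(fa), ca, vectors_to_frame(fb), cb,
                             "classification")


class TestInflationReport:
    @staticmethod
    def _result(task, mean, arm):
        return ExperimentResult(task=task, arm=arm, per_iteration_metric=[mean],
                                metric_mean=mean, metric_sd=0.0, n_train=1, n_test=1)

    def test_classification_percentage_points(self):
        legit = self._result("classification", 0.61, "legitimate")
        dd = self._result("classification", 0.86, "double_dip")
        row = inflation_report(legit, dd, 0.51)
        assert row["improvement_pct"] == pytest.approx(25.0)

    def test_regression_relative_to_null(self):
        legit = self._result("regression", 5.92, "legitimate")
        dd = self._result("regression", 4.97, "double_dip")
        row = inflation_report(legit, dd, 7.68)
        assert row["improvement_pct"] == pytest.approx(12.4, abs=0.05)

    def test_equal_arms_give_zero(self):
        legit = self._result("classification", 0.7, "legitimate")
        dd = self._result("classification", 0.7, "double_dip")
        assert inflation_report(legit, dd, 0.5)["improvement_pct"] == 0.0

    def test_task_mismatch_rejected(self):
        legit = self._result("classification", 0.7, "legitimate")
        dd = self._result("regression", 0.7, "double_dip")
        with pytest.raises(ValueError, match="task"):
            inflation_report(legit, dd, 0.5)
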