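"""Leakage experiments: null, legitimate and double-dipping arms.

The three arms mirror a results table with columns *null model*, *best
(legitimate) prediction* and *double-dipping prediction*:

* legitimate — subjects partitioned 80/20, all of a subject's scans or
  windows on one side (no identity leakage possible);
* scan double-dip — each subject's first scan in train, second in test,
  so a model can exploit the subject fingerprint instead of phenotype
  signal;
* window double-dip — the same exploit through non-overlapping dFC
  windows of a single scan (even windows train, odd test);
* scan shuffled — scans assigned to sides at random, landing between the
  legitimate and double-dip extremes;
* cross-cohort — train on one cohort, test on another, the mitigation:
  fingerprints cannot transfer across disjoint subject pools.

Models are deliberately simple: logistic regression (classification
accuracy) and ridge regression (RMSE), features standardized with
train-set statistics only, regularization strength picked on a
powers-of-ten grid by inner 5-fold cross-validation on the training set.
"Bootstrap" aggregation is Monte-Carlo re-splitting: n_iterations
independent 80/20 re-splits (deterministic split makers vary only the
inner-CV folds across iterations).
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import accuracy_score, mean_squared_error
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .types import (
    ExperimentResult,
    SplitSpec,
    UNIT_COLUMNS,
    units_of,
    validate_cohort,
)

__all__ = [
    "HYPERPARAM_GRID",
    "make_subject_disjoint_split",
    "make_scan_double_dip_split",
    "make_window_double_dip_split",
    "make_random_scan_split",
    "fit_predict",
    "null_metric",
    "run_bootstrap",
    "run_cross_cohort",
    "inflation_report",
]

#: powers-of-ten regularization grid (ridge alpha / inverse logistic C)
HYPERPARAM_GRID = 10.0 ** np.arange(-4, 5)

N_ITERATIONS_DEFAULT = 20
TEST_FRACTION_DEFAULT = 0.2
INNER_CV_FOLDS = 5

SEED_MOD = 2**31


# ---------------------------------------------------------------------------
# split construction


def make_subject_disjoint_split(
    fc_table: pd.DataFrame,
    test_fraction: float = TEST_FRACTION_DEFAULT,
    seed: int = 0,
) -> SplitSpec:
    """Random subject-level 80/20 partition; all units of a subject together."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    units = units_of(fc_table)
    subjects = sorted({u[0] for u in units})
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects for a subject-disjoint split")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(subjects)))
    n_test = min(max(n_test, 1), len(subjects) - 1)
    test_subjects = set(rng.choice(subjects, size=n_test, replace=False))
    train = [u for u in units if u[0] not in test_subjects]
    test = [u for u in units if u[0] in test_subjects]
    return SplitSpec(train, test, leakage_mode="subject_disjoint", seed=seed)


def make_scan_double_dip_split(fc_table: pd.DataFrame) -> SplitSpec:
    """Each subject's first scan (lexicographic) to train, second to test.

    Subjects with more than two scans contribute the extras to train;
    single-scan subjects are excluded.  Deterministic.
    """
    units = units_of(fc_table)
    by_subject: dict = {}
    for u in units:
        by_subject.setdefault(u[0], []).append(u)
    train, test = [], []
    for subject in sorted(by_subject):
        scans = sorted(by_subject[subject], key=lambda u: (u[1], u[2]))
        if len(scans) < 2:
            continue
        train.append(scans[0])
        test.append(scans[1])
        train.extend(scans[2:])
    if not test:
        raise ValueError("no subject has two or more scans")
    return SplitSpec(train, test, leakage_mode="scan_double_dip", seed=None)


def make_window_double_dip_split(fc_table: pd.DataFrame) -> SplitSpec:
    """Even window_index to train, odd to test (deterministic interleave)."""
    units = units_of(fc_table)
    windows_per_scan: dict = {}
    for u in units:
        if u[2] < 0:
            raise ValueError(f"unit {u} is not window-level (window_index < 0)")
        windows_per_scan.setdefault((u[0], u[1]), []).append(u)
    short = [k for k, v in windows_per_scan.items() if len(v) < 2]
    if short:
        raise ValueError(f"scan(s) with a single window: {short[:3]}")
    train = [u for u in units if u[2] % 2 == 0]
    test = [u for u in units if u[2] % 2 == 1]
    return SplitSpec(train, test, leakage_mode="window_double_dip", seed=None)


def make_random_scan_split(
    fc_table: pd.DataFrame,
    test_fraction: float = TEST_FRACTION_DEFAULT,
    seed: int = 0,
) -> SplitSpec:
    """Random unit-level 80/20 split, ignoring subject identity.

    Some subjects straddle both sides, so the result sits between the
    subject-disjoint and double-dip extremes.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    units = units_of(fc_table)
    if len(units) < 5:
        raise ValueError("too few units for a random split")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(units)))
    n_test = min(max(n_test, 1), len(units) - 1)
    idx = rng.permutation(len(units))
    test_idx = set(idx[:n_test].tolist())
    train = [u for k, u in enumerate(units) if k not in test_idx]
    test = [u for k, u in enumerate(units) if k in test_idx]
    return SplitSpec(train, test, leakage_mode="scan_shuffled", seed=seed)


# ---------------------------------------------------------------------------
# model fitting


def _assemble(fc_table: pd.DataFrame, cohort: pd.DataFrame, units: Sequence[tuple], task: str):
    validate_cohort(cohort)
    edge_cols = [c for c in fc_table.columns if c not in UNIT_COLUMNS]
    indexed = fc_table.set_index(UNIT_COLUMNS)
    missing = [u for u in units if u not in indexed.index]
    if missing:
        raise KeyError(f"split units missing from fc_table: {missing[:3]}")
    x = indexed.loc[list(units), edge_cols].to_numpy(dtype=float)
    pheno_col = "phenotype_bin" if task == "classification" else "phenotype_cont"
    pheno = cohort.drop_duplicates("subject_id").set_index("subject_id")[pheno_col]
    try:
        y = pheno.loc[[u[0] for u in units]].to_numpy()
    except KeyError as exc:
        raise KeyError(f"subject missing from cohort table: {exc}") from exc
    return x, y


def fit_predict(
    fc_table: pd.DataFrame,
    cohort: pd.DataFrame,
    split: SplitSpec,
    task: str,
    seed: int = 0,
) -> Tuple[float, float]:
    """Fit the arm's model on the train side, score it on the test side.

    Features are standardized with train statistics only (the scaler
    lives inside the CV pipeline, so inner folds are clean too).
    Regularization strength comes from the powers-of-ten grid via inner
    5-fold CV on the training set; the model is then refit on the full
    training set.

    Returns (test accuracy | test RMSE, chosen hyperparameter).
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    x_train, y_train = _assemble(fc_table, cohort, split.train_units, task)
    x_test, y_test = _assemble(fc_table, cohort, split.test_units, task)
    cv_seed = int(seed) % SEED_MOD

    if task == "classification":
        counts = np.unique(y_train, return_counts=True)[1]
        if counts.size < 2:
            raise ValueError("training set contains a single class")
        if counts.min() < 2:
            raise ValueError("training set needs >= 2 samples per class")
        # tiny cohorts: inner folds cannot exceed the rarer class count
        folds = min(INNER_CV_FOLDS, int(counts.min()))
        model = LogisticRegression(max_iter=2000)
        param_grid = {"model__C": HYPERPARAM_GRID}
        cv = StratifiedKFold(folds, shuffle=True, random_state=cv_seed)
        scoring = "accuracy"
    else:
        folds = min(INNER_CV_FOLDS, len(y_train))
        model = Ridge()
        param_grid = {"model__alpha": HYPERPARAM_GRID}
        cv = KFold(folds, shuffle=True, random_state=cv_seed)
        scoring = "neg_root_mean_squared_error"

    pipe = Pipeline([("scale", StandardScaler()), ("model", model)])
    search = GridSearchCV(pipe, param_grid, cv=cv, scoring=scoring, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        search.fit(x_train, y_train)
        y_pred = search.predict(x_test)
    if task == "classification":
        metric = float(accuracy_score(y_test, y_pred))
    else:
        metric = float(np.sqrt(mean_squared_error(y_test, y_pred)))
    chosen = float(next(iter(search.best_params_.values())))
    return metric, chosen


def null_metric(cohort: pd.DataFrame, split: SplitSpec, task: str) -> float:
    """Baseline: majority train class frequency in test, or RMSE of the train mean."""
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    pheno_col = "phenotype_bin" if task == "classification" else "phenotype_cont"
    pheno = (
        validate_cohort(cohort)
        .drop_duplicates("subject_id")
        .set_index("subject_id")[pheno_col]
    )
    y_train = pheno.loc[[u[0] for u in split.train_units]].to_numpy()
    y_test = pheno.loc[[u[0] for u in split.test_units]].to_numpy()
    if task == "classification":
        majority = pd.Series(y_train).mode().iloc[0]
        return float(np.mean(y_test == majority))
    return float(np.sqrt(np.mean((y_test - y_train.mean()) ** 2)))


def run_bootstrap(
    fc_table: pd.DataFrame,
    cohort: pd.DataFrame,
    split_maker: Callable[..., SplitSpec],
    task: str,
    n_iterations: int = N_ITERATIONS_DEFAULT,
    base_seed: int = 0,
    arm: str = "legitimate",
) -> ExperimentResult:
    """Monte-Carlo re-splitting: n_iterations splits, one fit each.

    ``split_maker(fc_table, seed=...)`` builds the split; deterministic
    makers (the double-dip ones take no seed) are called without it, so
    iterations then differ only in the inner-CV fold shuffle.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    metrics, hyperparams = [], []
    n_train = n_test = 0
    for it in range(n_iterations):
        seed = (int(base_seed) + it) % SEED_MOD
        try:
            split = split_maker(fc_table, seed=seed)
        except TypeError:
            split = split_maker(fc_table)
        metric, hp = fit_predict(fc_table, cohort, split, task, seed=seed)
        metrics.append(metric)
        hyperparams.append(hp)
        n_train, n_test = len(split.train_units), len(split.test_units)
    return ExperimentResult.from_iterations(
        task=task,
        arm=arm,
        metrics=metrics,
        n_train=n_train,
        n_test=n_test,
        hyperparameters=hyperparams,
    )


def run_cross_cohort(
    fc_table_a: pd.DataFrame,
    cohort_a: pd.DataFrame,
    fc_table_b: pd.DataFrame,
    cohort_b: pd.DataFrame,
    task: str,
    seed: int = 0,
) -> ExperimentResult:
    """Train on all of cohort A, test on all of cohort B.

    The mitigation arm: subject fingerprints cannot transfer across
    disjoint cohorts, so any accuracy above null reflects phenotype
    signal.  No split randomness; recorded as a legitimate arm.
    """
    edges_a = [c for c in fc_table_a.columns if c not in UNIT_COLUMNS]
    edges_b = [c for c in fc_table_b.columns if c not in UNIT_COLUMNS]
    if edges_a != edges_b:
        raise ValueError("cohorts have mismatched feature columns")
    units_a = units_of(fc_table_a)
    units_b = units_of(fc_table_b)
    # disambiguate any subject-id collisions between the two pools
    tag = lambda units, t: [(f"{t}:{s}", c, w) for s, c, w in units]
    fc_a = fc_table_a.copy()
    fc_a["subject_id"] = "A:" + fc_a["subject_id"].astype(str)
    fc_b = fc_table_b.copy()
    fc_b["subject_id"] = "B:" + fc_b["subject_id"].astype(str)
    co_a = cohort_a.copy()
    co_a["subject_id"] = "A:" + co_a["subject_id"].astype(str)
    co_b = cohort_b.copy()
    co_b["subject_id"] = "B:" + co_b["subject_id"].astype(str)
    fc = pd.concat([fc_a, fc_b], ignore_index=True)
    co = pd.concat([co_a, co_b], ignore_index=True)
    split = SplitSpec(
        tag(units_a, "A"), tag(units_b, "B"), leakage_mode="cross_cohort", seed=seed
    )
    metric, hp = fit_predict(fc, co, split, task, seed=seed)
    return ExperimentResult.from_iterations(
        task=task,
        arm="legitimate",
        metrics=[metric],
        n_train=len(units_a),
        n_test=len(units_b),
        hyperparameters=[hp],
    )


def inflation_report(
    legit: ExperimentResult, dd: ExperimentResult, null: float
) -> dict:
    """One results-table row: null / legitimate / double-dip / improvement.

    Classification improvement is the double-dip minus legitimate mean
    accuracy in percentage points.  Regression improvement is the RMSE
    reduction relative to the null-model RMSE,
    100 * (legit - dd) / null, the convention that reproduces published
    improvement percentages from their printed RMSEs.
    """
    if legit.task != dd.task:
        raise ValueError(f"task mismatch: {legit.task} vs {dd.task}")
    if legit.task == "classification":
        improvement = 100.0 * (dd.metric_mean - legit.metric_mean)
    else:
        if null <= 0:
            raise ValueError("null RMSE must be positive")
        improvement = 100.0 * (legit.metric_mean - dd.metric_mean) / null
    return {
        "task": legit.task,
        "null": float(null),
        "legitimate_mean": legit.metric_mean,
        "legitimate_sd": legit.metric_sd,
        "double_dip_mean": dd.metric_mean,
        "double_dip_sd": dd.metric_sd,
        "improvement_pct": float(improvement),
    }
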