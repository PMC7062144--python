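"""Metrics, cross-validation harness, feature pre-selection, learner comparison.

Generalisation is estimated by repeated stratified k-fold cross-validation
(10 x 10-fold for classification, 20 x 5-fold for regression by convention).
Every data-dependent step — SD filtering, Mann-Whitney ranking, threshold
fitting — is learned inside the training folds only, so the harness is
leak-free by construction.  Learners are compared with a paired t-test over
the per-split test metrics; pairs that are not significantly different
(p >= 0.05) are considered equivalent.

Comparator learners (elastic-net logistic regression, random forest, linear
SVM) are thin adapters over scikit-learn; only the adapter contract — fit on
a training matrix/target, predict on a test matrix — belongs to this
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, enet_path
from sklearn.metrics import (f1_score, precision_score, recall_score,
                             roc_auc_score)
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .data_io import (AbundanceMatrix, SampleTarget, ValidationError,
                      filter_low_sd)
from .models import (CLASSIFICATION_METRICS, REGRESSION_METRICS, ModelError,
                     predict, score_samples)


class UndefinedMetricError(ValidationError):
    """The requested metric is undefined on this input (e.g. AUC, one class)."""


# -- metrics ----------------------------------------------------------------


def compute_metric(y_true, y_pred_or_score, metric: str,
                   positive_class: str | None = None) -> float:
    """Standard metric definitions on aligned vectors.

    AUC expects scores (rank statistic, ties give 0.5); the other
    classification metrics expect labels.  ``ser`` is the standard error of
    the residuals divided by the target's standard deviation.
    """
    if metric in REGRESSION_METRICS:
        y_true = np.asarray(y_true, dtype=float)
        y_hat = np.asarray(y_pred_or_score, dtype=float)
        if metric == "r2":
            ss_res = float(((y_true - y_hat) ** 2).sum())
            ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
            return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if metric == "spearman_rho":
            return float(stats.spearmanr(y_true, y_hat).statistic)
        resid = y_true - y_hat
        sd = y_true.std(ddof=1)
        return float(resid.std(ddof=1) / sd) if sd > 0 else 0.0

    if metric not in CLASSIFICATION_METRICS:
        raise ModelError(f"unknown metric {metric!r}")
    y_true = np.asarray([str(v) for v in np.asarray(y_true).ravel()], dtype=object)
    labels = sorted(set(y_true))
    pos = str(positive_class) if positive_class is not None else labels[-1]
    if metric == "auc":
        if len(labels) < 2:
            raise UndefinedMetricError("AUC undefined with a single observed class")
        scores = np.asarray(y_pred_or_score, dtype=float)
        return float(roc_auc_score((y_true == pos).astype(int), scores))
    y_hat = np.asarray([str(v) for v in np.asarray(y_pred_or_score).ravel()],
                       dtype=object)
    if metric == "accuracy":
        return float((y_true == y_hat).mean())
    fn = {"f1": f1_score, "precision": precision_score, "recall": recall_score}[metric]
    return float(fn(y_true, y_hat, pos_label=pos, zero_division=0,
                    labels=sorted(set(y_true) | set(y_hat))))


# -- univariate pre-selection -----------------------------------------------


def mann_whitney_rank(m: AbundanceMatrix, y: SampleTarget) -> pd.DataFrame:
    """Rank features by two-sided Mann-Whitney association with the class.

    Returns a DataFrame (feature, U, p, effect, direction) ordered by p
    ascending, ties by |effect - 0.5| descending, then feature name.  The
    effect is U/(n1*n2), the probability that a positive-class sample
    outranks a negative one (0.5 = no shift); ``direction`` is the class with
    the greater mean rank.  Used to pre-select top features for RF/SVM
    comparators and to seed the GA.
    """
    if y.kind != "binary_class":
        raise ValidationError("Mann-Whitney ranking requires a binary target")
    mask = y.positive_mask()
    pos_label = y.resolved_positive()
    neg_label = [c for c in y.classes if c != pos_label][0]
    xa = m.values[:, mask]
    xb = m.values[:, ~mask]
    n1, n2 = xa.shape[1], xb.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided",
                                 method="asymptotic")
    U = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # all-tie features: no evidence
    effect = U / (n1 * n2)
    tab = pd.DataFrame({
        "feature": m.feature_ids,
        "U": U,
        "p": p,
        "effect": effect,
        "direction": np.where(effect >= 0.5, pos_label, neg_label),
    })
    tab["_shift"] = np.abs(tab["effect"] - 0.5)
    tab = tab.sort_values(["p", "_shift", "feature"],
                          ascending=[True, False, True], kind="mergesort")
    return tab.drop(columns="_shift").reset_index(drop=True)


# -- cross-validation -------------------------------------------------------


@dataclass
class CVResult:
    """Per-split generalisation estimates for one learner."""

    learner_name: str
    n_folds: int
    n_repeats: int
    metric: str
    seed: int
    values: np.ndarray
    test_indices: list = field(default_factory=list)
    models: list = field(default_factory=list)  # selected BTR model per split
    fbms: list = field(default_factory=list)    # FBM per split (BTR learners)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_folds * self.n_repeats:
            raise ValidationError(
                f"{self.values.size} values for a "
                f"{self.n_repeats}x{self.n_folds} scheme"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v in enumerate(self.values):
            rows.append({"split_id": i, "repeat": i // self.n_folds,
                         "fold": i % self.n_folds, "metric": self.metric,
                         "value": v, "learner": self.learner_name})
        return pd.DataFrame(rows)


def cross_validate(m: AbundanceMatrix, y: SampleTarget, learner,
                   scheme: tuple[int, int] = (10, 10), seed: int = 0,
                   metric: str = "accuracy") -> CVResult:
    """Repeated stratified k-fold CV of any learner honouring the adapter
    contract (``fit(m_train, y_train)``, ``predict(m_test)``, optionally
    ``decision_scores(m_test)`` for AUC and ``set_split_seed(int)``).

    ``scheme`` is (n_folds, n_repeats); class proportions are preserved
    within one sample per fold.  Returns one test-metric value per split —
    a 10 x 10 scheme yields exactly 100 estimates.
    """
    n_folds, n_repeats = scheme
    if y.kind != "binary_class":
        raise ValidationError("the CV harness currently supports binary targets")
    if m.n_samples < n_folds:
        raise ValidationError("fewer samples than folds")
    labels = np.asarray(y.values)
    counts = pd.Series(labels).value_counts()
    if counts.min() < n_folds:
        raise ValidationError(
            f"class {counts.idxmin()!r} has {counts.min()} samples, "
            f"fewer than {n_folds} folds"
        )
    splitter = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats,
                                       random_state=seed)
    values, test_sets, models, fbms = [], [], [], []
    X_dummy = np.zeros((m.n_samples, 1))
    for i, (tr, te) in enumerate(splitter.split(X_dummy, labels)):
        if hasattr(learner, "set_split_seed"):
            learner.set_split_seed(int((seed * 9973 + i) % (2 ** 31)))
        m_tr, y_tr = m.subset_samples(tr), y.subset(tr)
        m_te, y_te = m.subset_samples(te), y.subset(te)
        learner.fit(m_tr, y_tr)
        if metric == "auc":
            pred = learner.decision_scores(m_te)
        else:
            pred = learner.predict(m_te)
        values.append(compute_metric(y_te.values, pred, metric,
                                     positive_class=y.resolved_positive()))
        test_sets.append(np.asarray(te))
        models.append(getattr(learner, "model_", None))
        fbms.append(getattr(learner, "fbm_", None))
    return CVResult(getattr(learner, "name", type(learner).__name__),
                    n_folds, n_repeats, metric, seed, np.asarray(values),
                    test_indices=test_sets, models=models, fbms=fbms)


def heldout_splits(m: AbundanceMatrix, y: SampleTarget,
                   result: CVResult) -> list[tuple[AbundanceMatrix, SampleTarget]]:
    """Reconstruct each split's held-out (matrix, target) pair."""
    return [(m.subset_samples(te), y.subset(te)) for te in result.test_indices]


def compare_learners(a: CVResult, b: CVResult) -> tuple[float, float, str]:
    """Paired t-test over per-split metric differences.

    Requires identical schemes, seeds and split assignments.  Returns
    (t, p, verdict) with verdict in {a_better, b_better, equivalent};
    equivalent iff p >= 0.05.  Zero-variance differences short-circuit:
    all-zero means equivalent, a constant non-zero difference is decisive.
    """
    if (a.n_folds, a.n_repeats, a.seed, a.metric) != \
            (b.n_folds, b.n_repeats, b.seed, b.metric):
        raise ValidationError("CV results use different schemes or seeds")
    if len(a.test_indices) and len(b.test_indices):
        for ta, tb in zip(a.test_indices, b.test_indices):
            if not np.array_equal(ta, tb):
                raise ValidationError("CV results use different split assignments")
    diff = a.values - b.values
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.0, 1.0, "equivalent"
        t = np.inf if diff[0] > 0 else -np.inf
        return float(t), 0.0, "a_better" if diff[0] > 0 else "b_better"
    t, p = stats.ttest_rel(a.values, b.values)
    if p >= 0.05:
        return float(t), float(p), "equivalent"
    return float(t), float(p), "a_better" if diff.mean() > 0 else "b_better"


# -- learner adapters -------------------------------------------------------


class BTRLearner:
    """Adapter: evolutionary BTR search + penalized selection + FBM.

    ``fit`` optionally SD-filters the training matrix, evolves per-k islands,
    keeps the penalized winner in ``model_`` and the family of best models in
    ``fbm_``; ``predict`` re-applies the training preprocessing to the test
    matrix by feature name.
    """

    def __init__(self, language: str = "bin", k_min: int = 1, k_max: int = 5,
                 population_size: int = 200, generations: int = 100,
                 mutation_rate: float = 0.2, crossover_rate: float = 0.8,
                 elite_fraction: float = 0.1, lambda_penalty: float = 0.01,
                 p_level: float = 0.05, sd_filter: bool = False,
                 fitness_metric: str = "accuracy", seed: int = 0):
        self.language = language
        self.k_min, self.k_max = k_min, k_max
        self.population_size = population_size
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.crossover_rate = crossover_rate
        self.elite_fraction = elite_fraction
        self.lambda_penalty = lambda_penalty
        self.p_level = p_level
        self.sd_filter = sd_filter
        self.fitness_metric = fitness_metric
        self.seed = seed
        self.name = f"btr_{language}"

    def set_split_seed(self, seed: int) -> None:
        self.seed = seed

    def fit(self, m: AbundanceMatrix, y: SampleTarget) -> "BTRLearner":
        from .search import SearchConfig, evolve, prepare_data
        from .selection import extract_fbm, penalized_select

        data = m
        if self.sd_filter:
            data, _ = filter_low_sd(data)
        cfg = SearchConfig(language=self.language, k_min=self.k_min,
                           k_max=min(self.k_max, data.n_features),
                           population_size=self.population_size,
                           generations=self.generations,
                           mutation_rate=self.mutation_rate,
                           crossover_rate=self.crossover_rate,
                           elite_fraction=self.elite_fraction,
                           seed=self.seed, fitness_metric=self.fitness_metric)
        pop = evolve(data, y, cfg)
        self.population_ = pop
        self.model_ = penalized_select(pop, self.lambda_penalty)
        self.fbm_ = extract_fbm(pop, n_train=data.n_samples, p_level=self.p_level)
        return self

    def _prepared(self, m: AbundanceMatrix) -> AbundanceMatrix:
        from .search import prepare_data

        return prepare_data(m, self.language)

    def predict(self, m: AbundanceMatrix) -> np.ndarray:
        return predict(self.model_, self._prepared(m))

    def decision_scores(self, m: AbundanceMatrix) -> np.ndarray:
        s = score_samples(self.model_, self._prepared(m))
        return s if self.model_.direction == "score_greater" else -s


class _SklearnAdapter:
    """Shared plumbing: matrix transposition, optional MW top-k selection."""

    name = "sklearn"

    def __init__(self, mw_top_k: int | None = None, seed: int = 0):
        self.mw_top_k = mw_top_k
        self.seed = seed

    def set_split_seed(self, seed: int) -> None:
        self.seed = seed

    def _select(self, m: AbundanceMatrix, y: SampleTarget) -> list[str]:
        if self.mw_top_k is None:
            return list(m.feature_ids)
        tab = mann_whitney_rank(m, y)
        return list(tab["feature"].head(self.mw_top_k))

    def _X(self, m: AbundanceMatrix) -> np.ndarray:
        idx = [m.feature_index(f) for f in self.features_]
        return m.values[idx, :].T

    def fit(self, m: AbundanceMatrix, y: SampleTarget):
        self.features_ = self._select(m, y)
        self.estimator_ = self._make()
        self.estimator_.fit(self._X(m), np.asarray(y.values, dtype=object))
        return self

    def predict(self, m: AbundanceMatrix) -> np.ndarray:
        return self.estimator_.predict(self._X(m))

    def decision_scores(self, m: AbundanceMatrix) -> np.ndarray:
        est = self.estimator_
        if hasattr(est, "decision_function"):
            return est.decision_function(self._X(m))
        return est.predict_proba(self._X(m))[:, -1]


class ENetLearner(_SklearnAdapter):
    """Elastic-net logistic regression (mixing 0.5, a lasso/ridge compromise).

    When ``max_features`` is set, the first features to enter the
    regularization path (computed with ``enet_path`` on a +/-1-coded
    response, a linear surrogate for the logistic path) are kept before the
    final fit — mirroring how an embedded path yields a model of a fixed
    size.
    """

    name = "enet"

    def __init__(self, l1_ratio: float = 0.5, C: float = 1.0,
                 max_features: int | None = None, seed: int = 0):
        super().__init__(mw_top_k=None, seed=seed)
        self.l1_ratio = l1_ratio
        self.C = C
        self.max_features = max_features

    def _make(self):
        return LogisticRegression(solver="saga", l1_ratio=self.l1_ratio,
                                  C=self.C, max_iter=5000,
                                  random_state=self.seed)

    def _select(self, m: AbundanceMatrix, y: SampleTarget) -> list[str]:
        if self.max_features is None or self.max_features >= m.n_features:
            return list(m.feature_ids)
        X = m.values.T
        resp = np.where(y.positive_mask(), 1.0, -1.0)
        _, coefs, _ = enet_path(X, resp, l1_ratio=self.l1_ratio, alphas=100)
        entry_alpha = np.full(m.n_features, np.inf)
        for j in range(m.n_features):
            nz = np.nonzero(coefs[j] != 0)[0]
            if nz.size:
                entry_alpha[j] = nz[0]  # earlier entry = stronger feature
        order = np.lexsort((np.arange(m.n_features), entry_alpha))
        return [m.feature_ids[i] for i in order[:self.max_features]]


class RandomForestLearner(_SklearnAdapter):
    """Random forest (500 trees), optionally on MW-pre-selected features."""

    name = "rf"

    def __init__(self, n_estimators: int = 500, mw_top_k: int | None = None,
                 seed: int = 0):
        super().__init__(mw_top_k=mw_top_k, seed=seed)
        self.n_estimators = n_estimators

    def _make(self):
        return RandomForestClassifier(n_estimators=self.n_estimators,
                                      random_state=self.seed)


class SVMLearner(_SklearnAdapter):
    """Linear-kernel SVM, optionally on MW-pre-selected features."""

    name = "svmlin"

    def __init__(self, C: float = 1.0, mw_top_k: int | None = None,
                 seed: int = 0):
        super().__init__(mw_top_k=mw_top_k, seed=seed)
        self.C = C

    def _make(self):
        return SVC(kernel="linear", C=self.C, random_state=self.seed)


class MajorityLearner:
    """Baseline: always predict the training majority class."""

    name = "majority"

    def fit(self, m: AbundanceMatrix, y: SampleTarget) -> "MajorityLearner":
        vals, counts = np.unique(np.asarray(y.values, dtype=object),
                                 return_counts=True)
        # deterministic tie-break: lexicographically smaller label
        self.label_ = sorted(vals[counts == counts.max()])[0]
        return self

    def predict(self, m: AbundanceMatrix) -> np.ndarray:
        return np.full(m.n_samples, self.label_, dtype=object)

    def decision_scores(self, m: AbundanceMatrix) -> np.ndarray:
        return np.zeros(m.n_samples)
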