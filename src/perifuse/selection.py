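"""Feature-reduction and modelling chain.

The chain mirrors standard deep-learning-radiomics practice:

1. PCA of the raw deep features to 32 components (fitted on training rows
   only; for feature-level fusion each region block gets its own PCA to 32
   and the blocks are concatenated, keeping region contributions symmetric);
2. two-sided Mann-Whitney U filter at p < 0.05;
3. Pearson redundancy pruning at |r| >= 0.9, visiting features in ascending
   p-value order so the more class-associated member of a correlated pair
   survives;
4. LASSO (L1-penalized logistic path, penalty chosen by stratified 10-fold
   cross-validated deviance);
5. a logistic classifier evaluated by ROC/AUC at a Youden-optimal threshold
   frozen on the training cohort, with stratified-bootstrap 95% CIs and a
   stratified 5-fold CV AUC on training.

Every fitted quantity (centering, p-values, correlations, penalty,
classifier, threshold) is a function of training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .errors import ParameterError
from .metrics import MetricsReport, auc_score, evaluate_at_threshold, youden_threshold

DEFAULT_PCA_COMPONENTS = 32
DEFAULT_MWU_ALPHA = 0.05
DEFAULT_PEARSON_R = 0.9
DEFAULT_LASSO_FOLDS = 10
_LASSO_CS = np.logspace(-3, 2, 30)


@dataclass
class FeatureMatrix:
    """Cases x features with per-feature provenance."""

    values: np.ndarray
    case_ids: list[str]
    labels: np.ndarray
    feature_names: list[str]
    region_tags: list[str]
    stage: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ParameterError("feature matrix must be 2-D")
        n, p = self.values.shape
        if len(self.case_ids) != n or len(self.labels) != n:
            raise ParameterError("case_ids/labels must align with matrix rows")
        if len(self.feature_names) != p or len(self.region_tags) != p:
            raise ParameterError("feature metadata must align with matrix columns")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("feature matrix contains non-finite values")
        if not np.isin(self.labels, (0, 1)).all():
            raise ParameterError("labels must be binary 0/1")

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, idx, stage: str) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            case_ids=list(self.case_ids),
            labels=self.labels.copy(),
            feature_names=[self.feature_names[i] for i in idx],
            region_tags=[self.region_tags[i] for i in idx],
            stage=stage,
        )


@dataclass
class SelectionReport:
    """Feature counts surviving each stage, p-values and the LASSO path."""

    n_input: int
    n_after_pca: int
    n_after_mwu: int
    n_after_pearson: int
    n_after_lasso: int
    p_values: dict[str, float] = field(default_factory=dict)
    penalty_path: list[float] = field(default_factory=list)
    chosen_penalty: float | None = None
    surviving_features: list[str] = field(default_factory=list)

    def __post_init__(self):
        counts = [self.n_input, self.n_after_pca, self.n_after_mwu,
                  self.n_after_pearson, self.n_after_lasso]
        if any(a < b for a, b in zip(counts, counts[1:])) or counts[-1] < 0:
            raise ParameterError(f"selection counts must be non-increasing, got {counts}")


def pca_reduce(
    train: FeatureMatrix,
    apply_to: FeatureMatrix | None,
    n_components: int = DEFAULT_PCA_COMPONENTS,
) -> tuple[FeatureMatrix, FeatureMatrix | None, PCA]:
    """Centering + orthonormal projection fitted on training rows only.

    Both matrices are projected onto ``min(n_components, n_train - 1,
    n_features)`` components. Region-aware reduction for feature-level fusion
    is handled by :func:`pca_reduce_by_region`.
    """
    if train.n_cases < 2:
        raise ParameterError("PCA requires >= 2 training rows")
    if apply_to is not None and apply_to.n_features != train.n_features:
        raise ParameterError(
            f"apply_to has {apply_to.n_features} features, train has {train.n_features}"
        )
    k = min(n_components, train.n_cases - 1, train.n_features)
    pca = PCA(n_components=k, svd_solver="auto", random_state=0)
    train_vals = pca.fit_transform(train.values)
    tag = train.region_tags[0] if len(set(train.region_tags)) == 1 else "all"
    names = [f"{tag}_pca_{i:02d}" for i in range(k)]
    out_train = FeatureMatrix(
        train_vals, list(train.case_ids), train.labels.copy(), names, [tag] * k, stage="pca"
    )
    out_apply = None
    if apply_to is not None:
        out_apply = FeatureMatrix(
            pca.transform(apply_to.values),
            list(apply_to.case_ids),
            apply_to.labels.copy(),
            names,
            [tag] * k,
            stage="pca",
        )
    return out_train, out_apply, pca


def pca_reduce_by_region(
    train: FeatureMatrix,
    apply_to: FeatureMatrix | None,
    n_components: int = DEFAULT_PCA_COMPONENTS,
) -> tuple[FeatureMatrix, FeatureMatrix | None]:
    """Per-region PCA (32 components each) concatenated in region order."""
    regions = list(dict.fromkeys(train.region_tags))
    train_blocks, apply_blocks = [], []
    for region in regions:
        cols = [i for i, tag in enumerate(train.region_tags) if tag == region]
        tr = train.select_columns(cols, stage="raw")
        ap = apply_to.select_columns(cols, stage="raw") if apply_to is not None else None
        tr_red, ap_red, _ = pca_reduce(tr, ap, n_components)
        train_blocks.append(tr_red)
        apply_blocks.append(ap_red)
    return _hstack(train_blocks), (_hstack(apply_blocks) if apply_to is not None else None)


def _hstack(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    return FeatureMatrix(
        np.hstack([b.values for b in blocks]),
        list(blocks[0].case_ids),
        blocks[0].labels.copy(),
        sum((b.feature_names for b in blocks), []),
        sum((b.region_tags for b in blocks), []),
        stage="pca",
    )


def mwu_filter(
    matrix: FeatureMatrix, alpha: float = DEFAULT_MWU_ALPHA
) -> tuple[FeatureMatrix, np.ndarray]:
    """Two-sided Mann-Whitney U filter: keep features with p strictly < alpha.

    Constant features carry no class information; they are assigned p = 1 and
    dropped. Returns the filtered matrix and the p-value of *every* input
    feature (aligned with the input columns).
    """
    y = matrix.labels
    if len(np.unique(y)) < 2:
        raise ParameterError("Mann-Whitney filter requires both classes present")
    p_values = np.ones(matrix.n_features)
    for j in range(matrix.n_features):
        col = matrix.values[:, j]
        if np.ptp(col) == 0:
            continue
        p_values[j] = stats.mannwhitneyu(
            col[y == 0], col[y == 1], alternative="two-sided"
        ).pvalue
    keep = np.flatnonzero(p_values < alpha)
    return matrix.select_columns(keep, stage="mwu"), p_values


def pearson_prune(
    matrix: FeatureMatrix, p_values, r_threshold: float = DEFAULT_PEARSON_R
) -> FeatureMatrix:
    """Greedy redundancy pruning at |Pearson r| >= threshold.

    Features are visited in ascending p-value order (ties broken by original
    column order); a feature is kept iff its |r| with every already-kept
    feature is strictly below the threshold, so no kept pair is redundant.
    """
    p_values = np.asarray(p_values, dtype=float)
    if len(p_values) != matrix.n_features:
        raise ParameterError("p_values must align with matrix columns")
    if matrix.n_features == 0:
        return matrix
    order = np.argsort(p_values, kind="stable")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(matrix.values.T)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    kept: list[int] = []
    for j in order:
        if all(abs(corr[j, k]) < r_threshold for k in kept):
            kept.append(int(j))
    kept.sort()
    return matrix.select_columns(kept, stage="pearson")


def lasso_select(
    matrix: FeatureMatrix,
    folds: int = DEFAULT_LASSO_FOLDS,
    seed: int = 0,
    upstream_counts: dict[str, int] | None = None,
    p_values: dict[str, float] | None = None,
) -> tuple[FeatureMatrix, SelectionReport]:
    """L1-penalized logistic feature selection with stratified k-fold CV.

    The penalty is chosen over a log-spaced grid by minimum mean CV deviance;
    surviving features have nonzero coefficients at the chosen penalty. If
    the L1 path zeroes everything, the single feature with the largest
    absolute coefficient along the path (falling back to the first column)
    is retained so the downstream classifier always has an input.
    """
    y = matrix.labels
    if matrix.n_cases < folds:
        raise ParameterError(f"need >= {folds} cases for {folds}-fold CV, got {matrix.n_cases}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ParameterError(
            f"stratified {folds}-fold CV needs >= {folds} cases per class, got {counts.tolist()}"
        )
    scaler = StandardScaler().fit(matrix.values)
    x = scaler.transform(matrix.values)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=_LASSO_CS,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=500,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    coef = model.coef_.ravel()
    keep = np.flatnonzero(coef != 0)
    if keep.size == 0:
        keep = np.array([int(np.argmax(np.abs(coef))) if np.any(coef) else 0])
    selected = matrix.select_columns(keep, stage="lasso")
    up = upstream_counts or {}
    report = SelectionReport(
        n_input=up.get("n_input", matrix.n_features),
        n_after_pca=up.get("n_after_pca", matrix.n_features),
        n_after_mwu=up.get("n_after_mwu", matrix.n_features),
        n_after_pearson=matrix.n_features,
        n_after_lasso=len(keep),
        p_values=p_values or {},
        penalty_path=[float(1.0 / c) for c in _LASSO_CS],
        chosen_penalty=float(1.0 / model.C_[0]),
        surviving_features=list(selected.feature_names),
    )
    return selected, report


@dataclass
class ChainParams:
    pca_components: int = DEFAULT_PCA_COMPONENTS
    mwu_alpha: float = DEFAULT_MWU_ALPHA
    pearson_r: float = DEFAULT_PEARSON_R
    lasso_folds: int = DEFAULT_LASSO_FOLDS


def run_selection_chain(
    train: FeatureMatrix,
    test: FeatureMatrix | None,
    params: ChainParams | None = None,
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix | None, SelectionReport]:
    """PCA -> Mann-Whitney -> Pearson -> LASSO, fitted on training rows only.

    If the Mann-Whitney filter leaves no feature, the single smallest-p
    feature is carried forward (the chain must hand the classifier at least
    one column; documented degenerate-input policy).
    """
    params = params or ChainParams()
    n_input = train.n_features
    tr_pca, te_pca = pca_reduce_by_region(train, test, params.pca_components)
    tr_mwu, p_all = mwu_filter_or_best(tr_pca, params.mwu_alpha)
    p_kept = np.array([p_all[tr_pca.feature_names.index(n)] for n in tr_mwu.feature_names])
    tr_pruned = pearson_prune(tr_mwu, p_kept, params.pearson_r)
    p_pruned = {n: float(p_all[tr_pca.feature_names.index(n)]) for n in tr_pruned.feature_names}
    tr_sel, report = lasso_select(
        tr_pruned,
        folds=params.lasso_folds,
        seed=seed,
        upstream_counts={
            "n_input": n_input,
            "n_after_pca": tr_pca.n_features,
            "n_after_mwu": tr_mwu.n_features,
        },
        p_values=p_pruned,
    )
    te_sel = None
    if test is not None:
        cols = [te_pca.feature_names.index(n) for n in tr_sel.feature_names]
        te_sel = te_pca.select_columns(cols, stage="lasso")
    return tr_sel, te_sel, report


def mwu_filter_or_best(
    matrix: FeatureMatrix, alpha: float = DEFAULT_MWU_ALPHA
) -> tuple[FeatureMatrix, np.ndarray]:
    """Mann-Whitney filter that keeps the single best feature when nothing
    passes the alpha threshold (degenerate-input policy for the chain)."""
    filtered, p_values = mwu_filter(matrix, alpha)
    if filtered.n_features == 0:
        filtered = matrix.select_columns([int(np.argmin(p_values))], stage="mwu")
    return filtered, p_values


@dataclass
class FittedModel:
    """Standardizer + logistic classifier + frozen operating threshold."""

    scaler: StandardScaler
    classifier: LogisticRegression
    threshold: float
    feature_names: list[str]

    def scores(self, matrix: FeatureMatrix) -> np.ndarray:
        if matrix.feature_names != self.feature_names:
            raise ParameterError("feature space mismatch between train and test")
        return self.classifier.predict_proba(self.scaler.transform(matrix.values))[:, 1]


def fit_and_evaluate(
    train: FeatureMatrix,
    test: FeatureMatrix | None,
    cv_folds: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[MetricsReport, MetricsReport | None, FittedModel]:
    """Fit the logistic classifier on train and evaluate both cohorts.

    The operating threshold maximizes Youden's index on training scores and
    is reused unchanged on the test cohort. 95% CIs are stratified-bootstrap
    percentile intervals; the training report additionally carries the mean
    stratified ``cv_folds``-fold cross-validated AUC.
    """
    if test is not None and test.feature_names != train.feature_names:
        raise ParameterError("train and test must share the selected feature space")
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ParameterError("training cohort must contain both classes")
    scaler = StandardScaler().fit(train.values)
    clf = LogisticRegression(max_iter=1000)
    clf.fit(scaler.transform(train.values), y)
    model = FittedModel(scaler, clf, threshold=0.0, feature_names=list(train.feature_names))
    train_scores = model.scores(train)
    model.threshold = youden_threshold(y, train_scores)

    train_report = evaluate_at_threshold(y, train_scores, model.threshold, n_boot, seed)
    train_report.cv_auc = _cv_auc(train, cv_folds, seed)

    test_report = None
    if test is not None:
        test_scores = model.scores(test)
        test_report = evaluate_at_threshold(
            test.labels, test_scores, model.threshold, n_boot, seed + 1
        )
    return train_report, test_report, model


def _cv_auc(train: FeatureMatrix, cv_folds: int, seed: int) -> float:
    """Mean stratified k-fold cross-validated AUC of the classifier."""
    y = train.labels
    if np.bincount(y, minlength=2).min() < cv_folds:
        return float("nan")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr_idx, va_idx in cv.split(train.values, y):
        scaler = StandardScaler().fit(train.values[tr_idx])
        clf = LogisticRegression(max_iter=1000)
        clf.fit(scaler.transform(train.values[tr_idx]), y[tr_idx])
        scores = clf.predict_proba(scaler.transform(train.values[va_idx]))[:, 1]
        aucs.append(auc_score(y[va_idx], scores))
    return float(np.nanmean(aucs))
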