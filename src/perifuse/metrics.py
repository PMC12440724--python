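"""ROC metrics: AUC, Youden operating point, bootstrap CIs, paired DeLong test.

AUC is computed by its defining statistic — the probability that a random
positive case outscores a random negative case, with ties counted 1/2 — which
also supplies the per-case structural components the DeLong variance needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError


def _split_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ParameterError("labels and scores length mismatch")
    if not np.isin(labels, (0, 1)).all():
        raise ParameterError("labels must be binary 0/1")
    return scores[labels == 1], scores[labels == 0]


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise concordance components: V10 per positive, V01 per negative."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def auc_score(labels, scores) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    pos, neg = _split_scores(labels, scores)
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


def youden_threshold(labels, scores) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1.

    Candidate thresholds are the observed scores (prediction rule:
    ``score >= threshold``); among maximizers the highest threshold (most
    specific operating point) is returned, for determinism.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)[::-1]
    pred = scores[None, :] >= thresholds[:, None]
    n_pos = max(int((labels == 1).sum()), 1)
    n_neg = max(int((labels == 0).sum()), 1)
    tpr = (pred & (labels == 1)).sum(axis=1) / n_pos
    fpr = (pred & (labels == 0)).sum(axis=1) / n_neg
    return float(thresholds[int(np.argmax(tpr - fpr))])


def confusion_metrics(labels, scores, threshold: float) -> dict[str, float]:
    """Accuracy, sensitivity and specificity at ``score >= threshold``."""
    labels = np.asarray(labels, dtype=int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    pos = labels == 1
    neg = labels == 0
    return {
        "accuracy": float((pred == labels).mean()),
        "sensitivity": float((pred[pos] == 1).mean()) if pos.any() else float("nan"),
        "specificity": float((pred[neg] == 0).mean()) if neg.any() else float("nan"),
    }


@dataclass
class MetricsReport:
    """Performance of one model on one cohort at a fixed operating point."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    n_cases: int
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    cv_auc: float | None = None

    def as_row(self) -> dict[str, float]:
        row = {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "n_cases": self.n_cases,
        }
        for metric, (lo, hi) in self.ci95.items():
            row[f"{metric}_ci_lo"] = lo
            row[f"{metric}_ci_hi"] = hi
        if self.cv_auc is not None:
            row["cv_auc"] = self.cv_auc
        return row

    def format_auc(self) -> str:
        """AUC with its 95% CI, e.g. ``0.837 (95%CI 0.759-0.916)``."""
        if "auc" in self.ci95:
            lo, hi = self.ci95["auc"]
            return f"{self.auc:.3f} (95%CI {lo:.3f}-{hi:.3f})"
        return f"{self.auc:.3f}"


def evaluate_at_threshold(
    labels, scores, threshold: float, n_boot: int = 1000, seed: int = 0
) -> MetricsReport:
    """Full MetricsReport at a fixed threshold with stratified bootstrap CIs.

    Resampling is stratified by class (percentile CIs over ``n_boot``
    replicates); with ``n_boot=0`` or a single-class cohort the CIs are
    suppressed (the latter with a warning).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    report = MetricsReport(
        auc=auc_score(labels, scores),
        threshold=threshold,
        n_cases=len(labels),
        **confusion_metrics(labels, scores, threshold),
    )
    single_class = len(np.unique(labels)) < 2
    if single_class:
        warnings.warn("single-class cohort: confidence intervals suppressed")
        return report
    if n_boot <= 0:
        return report
    rng = np.random.default_rng(np.random.SeedSequence([0xB007, seed]))
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    samples = {"auc": [], "accuracy": [], "sensitivity": [], "specificity": []}
    for _ in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_pos, size=len(idx_pos), replace=True),
            rng.choice(idx_neg, size=len(idx_neg), replace=True),
        ])
        lb, sc = labels[take], scores[take]
        samples["auc"].append(auc_score(lb, sc))
        for key, val in confusion_metrics(lb, sc, threshold).items():
            samples[key].append(val)
    for key, vals in samples.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        report.ci95[key] = (float(lo), float(hi))
    return report


def delong_variance(labels, scores) -> float:
    """DeLong variance estimate of a single AUC."""
    pos, neg = _split_scores(labels, scores)
    v10, v01 = _placements(pos, neg)
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        return float("nan")
    return float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)


def compare_auc_paired(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired AUC difference with a DeLong variance estimate.

    Returns ``(delta_auc, p_value)`` where ``delta_auc = AUC(a) - AUC(b)``
    and the two-sided p-value comes from the normal approximation with the
    paired (covariance-adjusted) DeLong variance. Identical score vectors
    give delta 0, p 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ParameterError("paired comparison requires identical case sets")
    pos_a, neg_a = _split_scores(labels, scores_a)
    pos_b, neg_b = _split_scores(labels, scores_b)
    v10_a, v01_a = _placements(pos_a, neg_a)
    v10_b, v01_b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    delta = auc_a - auc_b
    m, n = len(pos_a), len(neg_a)
    if m < 2 or n < 2:
        raise ParameterError("need >= 2 cases in each class")
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 1e-16:
        return delta, 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(2.0 * stats.norm.sf(abs(z)))
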