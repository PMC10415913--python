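"""Per-rule gene-signature classification.

Each rule is scored by training a nearest-shrunken-centroid classifier
on the expression values of the rule's participating genes, under
stratified 10-fold cross-validation repeated several times. Reported
metrics: mean/SD accuracy, specificity and sensitivity across repeats,
and AUC from the pooled class-posterior scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from omicsrules.discretize import item_gene
from omicsrules.mining import Rule
from omicsrules.preprocess import PairedOmics


class EvaluateError(ValueError):
    pass


@dataclass
class RuleEvaluation:
    rule_label: str
    accuracy: float
    accuracy_sd: float
    specificity: float
    specificity_sd: float
    sensitivity: float
    sensitivity_sd: float
    auc: float
    overall_error_sd: float


class NearestShrunkenCentroid:
    """Nearest shrunken centroids with soft-thresholded class centroids.

    Standardized centroid deviations d_kj = (xbar_kj - xbar_j) /
    (m_k (s_j + s0)) are soft-thresholded by ``delta``; the discriminant
    for class k is the standardized squared distance to the shrunken
    centroid minus 2 log prior, and posteriors follow from exp(-delta/2).
    """

    def __init__(self, delta: float = 0.0):
        self.delta = delta

    def fit(self, x: np.ndarray, y: np.ndarray) -> "NearestShrunkenCentroid":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        n, p = x.shape
        overall = x.mean(axis=0)
        k = len(self.classes_)
        within_ss = np.zeros(p)
        centroids = np.zeros((k, p))
        counts = np.zeros(k)
        for idx, cls in enumerate(self.classes_):
            xc = x[y == cls]
            counts[idx] = len(xc)
            centroids[idx] = xc.mean(axis=0)
            within_ss += ((xc - centroids[idx]) ** 2).sum(axis=0)
        dof = max(n - k, 1)
        s = np.sqrt(within_ss / dof)
        s0 = np.median(s)
        m = np.sqrt(1.0 / counts + 1.0 / n)
        d = (centroids - overall) / (m[:, None] * (s + s0))
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.delta, 0.0)
        self.overall_ = overall
        self.scale_ = s + s0
        self.centroids_ = overall + m[:, None] * (s + s0) * d_shrunk
        self.priors_ = counts / n
        return self

    def decision(self, x: np.ndarray) -> np.ndarray:
        """Per-class discriminant scores (lower = closer)."""
        x = np.asarray(x, dtype=float)
        scores = np.empty((x.shape[0], len(self.classes_)))
        for idx in range(len(self.classes_)):
            z = (x - self.centroids_[idx]) / self.scale_
            scores[:, idx] = (z**2).sum(axis=1) - 2.0 * np.log(self.priors_[idx])
        return scores

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        scores = self.decision(x)
        logp = -0.5 * scores
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmin(self.decision(x), axis=1)]


def _select_delta(
    x: np.ndarray, y: np.ndarray, deltas: np.ndarray, rng: np.random.Generator
) -> float:
    """Pick the shrinkage by an internal 3-fold CV, largest delta that
    attains the best accuracy (prefer sparser centroids on ties)."""
    if len(np.unique(y)) < 2:
        return 0.0
    n_splits = min(3, np.bincount(y).min())
    if n_splits < 2:
        return 0.0
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                         random_state=int(rng.integers(2**31 - 1)))
    accs = np.zeros(len(deltas))
    for train, test in cv.split(x, y):
        for i, delta in enumerate(deltas):
            model = NearestShrunkenCentroid(delta=delta).fit(x[train], y[train])
            accs[i] += float(np.mean(model.predict(x[test]) == y[test]))
    best = accs.max()
    return float(deltas[np.nonzero(accs >= best - 1e-12)[0][-1]])


def evaluate_rule(
    omics: PairedOmics,
    rule: Rule,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    include_methylation: bool = False,
) -> RuleEvaluation:
    """Repeated stratified k-fold CV of the rule's gene signature.

    Class 1 is treated as positive for sensitivity/specificity. AUC is
    computed from the positive-class posteriors pooled across the folds
    of all repeats.
    """
    genes = sorted({item_gene(it) for it in rule.items})
    missing = [g for g in genes if g not in omics.gene_ids]
    if missing:
        raise EvaluateError(f"rule genes missing from data: {missing}")
    sub = omics.subset_genes(genes)
    x = sub.expression.T
    if include_methylation:
        x = np.hstack([x, sub.methylation.T])
    y = sub.labels
    if len(np.unique(y)) < 2:
        raise EvaluateError("both classes must be present")
    rng = np.random.default_rng(seed)
    n_splits = min(folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise EvaluateError("not enough samples per class for cross-validation")
    deltas = np.linspace(0.0, 2.0, 9)
    acc_reps, spec_reps, sens_reps = [], [], []
    pooled_scores, pooled_truth = [], []
    for _ in range(repeats):
        cv = StratifiedKFold(
            n_splits=n_splits, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tp = tn = fp = fn = 0
        for train, test in cv.split(x, y):
            delta = _select_delta(x[train], y[train], deltas, rng)
            model = NearestShrunkenCentroid(delta=delta).fit(x[train], y[train])
            pred = model.predict(x[test])
            proba = model.predict_proba(x[test])
            pos_col = int(np.nonzero(model.classes_ == 1)[0][0])
            pooled_scores.extend(proba[:, pos_col])
            pooled_truth.extend(y[test])
            tp += int(np.sum((pred == 1) & (y[test] == 1)))
            tn += int(np.sum((pred == 0) & (y[test] == 0)))
            fp += int(np.sum((pred == 1) & (y[test] == 0)))
            fn += int(np.sum((pred == 0) & (y[test] == 1)))
        acc_reps.append((tp + tn) / (tp + tn + fp + fn))
        sens_reps.append(tp / (tp + fn) if tp + fn else np.nan)
        spec_reps.append(tn / (tn + fp) if tn + fp else np.nan)
    acc = np.asarray(acc_reps)
    auc = float(roc_auc_score(pooled_truth, pooled_scores))
    return RuleEvaluation(
        rule_label=rule.label(),
        accuracy=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=1)) if repeats > 1 else 0.0,
        specificity=float(np.nanmean(spec_reps)),
        specificity_sd=float(np.nanstd(spec_reps, ddof=1)) if repeats > 1 else 0.0,
        sensitivity=float(np.nanmean(sens_reps)),
        sensitivity_sd=float(np.nanstd(sens_reps, ddof=1)) if repeats > 1 else 0.0,
        auc=auc,
        overall_error_sd=float((1.0 - acc).std(ddof=1)) if repeats > 1 else 0.0,
    )


def roc_points(omics: PairedOmics, rule: Rule, folds: int = 10, seed: int = 0):
    """Pooled-CV ROC curve points (fpr, tpr, thresholds) plus the
    Youden-J optimal threshold."""
    evaluation_scores, truth = _pooled_scores(omics, rule, folds, seed)
    fpr, tpr, thresholds = roc_curve(truth, evaluation_scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    return fpr, tpr, thresholds, float(thresholds[best])


def _pooled_scores(omics: PairedOmics, rule: Rule, folds: int, seed: int):
    genes = sorted({item_gene(it) for it in rule.items})
    sub = omics.subset_genes(genes)
    x, y = sub.expression.T, sub.labels
    rng = np.random.default_rng(seed)
    n_splits = min(folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                         random_state=int(rng.integers(2**31 - 1)))
    scores, truth = [], []
    for train, test in cv.split(x, y):
        model = NearestShrunkenCentroid().fit(x[train], y[train])
        proba = model.predict_proba(x[test])
        pos_col = int(np.nonzero(model.classes_ == 1)[0][0])
        scores.extend(proba[:, pos_col])
        truth.extend(y[test])
    return np.asarray(scores), np.asarray(truth)


def summarize_rules(rows: np.ndarray | list, decimals: int | None = None) -> np.ndarray:
    """Column-wise arithmetic mean of per-rule metric rows.

    ``rows`` is an (n_rules x n_metrics) array (or list of equal-length
    sequences). With ``decimals`` the means are rounded half-up to that
    many places — matching how summary rows are conventionally printed.
    """
    arr = np.asarray(rows, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise EvaluateError("nothing to summarize")
    means = arr.mean(axis=0)
    if decimals is not None:
        means = round_half_up(means, decimals)
    return means


def round_half_up(values: np.ndarray, decimals: int) -> np.ndarray:
    """Decimal rounding with ties away from zero (not banker's).

    Uses exact decimal arithmetic on the shortest repr of each float so
    printed values like 0.85075 round to 0.8508 as a human would.
    """
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-decimals)
    # pre-quantize at 12 decimals so accumulated float error (e.g. a mean
    # of exact decimals landing at 0.9084999999999999) does not flip a tie
    guard = Decimal(1).scaleb(-max(decimals + 4, 12))
    scalar = np.isscalar(values) or np.ndim(values) == 0
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    out = np.array(
        [
            float(
                Decimal(repr(float(v)))
                .quantize(guard, rounding=ROUND_HALF_UP)
                .quantize(quantum, rounding=ROUND_HALF_UP)
            )
            for v in arr
        ]
    )
    return out[0] if scalar else out
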