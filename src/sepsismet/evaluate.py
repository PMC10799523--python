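"""ROC/AUC comparison of mortality predictors.

Scores come from unpenalised least-squares fits (in-sample fitted values,
matching the all-observations fitting convention of small cohorts — an
optimistic evaluation, so a cross-validated mode is also provided), from a
penalised metabolite model, or from single markers. AUC uses the
rank/Mann-Whitney formulation (ties count half), which equals the
trapezoidal area under the empirical curve; confidence intervals are DeLong
by default with a stratified-bootstrap alternative.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "linear_score",
    "roc_auc",
    "auc_ci",
    "roc_with_ci",
    "cv_linear_scores",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "thresholds": [float(t) for t in self.thresholds],
            "sensitivity": [float(s) for s in self.sensitivity],
            "specificity": [float(s) for s in self.specificity],
        }


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels.astype(int)


def linear_score(
    design: np.ndarray, outcome: np.ndarray, features: list[int] | None = None
) -> np.ndarray:
    """In-sample fitted values of an unpenalised OLS fit as risk scores.

    ``features`` selects design columns (all by default). Rank-deficient
    designs fall back to the minimum-norm solution with a warning; fitted
    values are unaffected by the choice of solution within the column space.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if features is not None:
        X = X[:, features]
    y = np.asarray(outcome, dtype=float)
    A = np.column_stack([np.ones(X.shape[0]), X])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("collinear design: using the minimum-norm solution")
    return A @ beta


def cv_linear_scores(
    design: np.ndarray, outcome: np.ndarray, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Held-out OLS scores (k-fold), the honest counterpart of linear_score."""
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    scores = np.empty(n)
    for part in np.array_split(idx, k):
        tr = np.setdiff1d(idx, part)
        A_tr = np.column_stack([np.ones(tr.size), X[tr]])
        beta, *_ = np.linalg.lstsq(A_tr, y[tr], rcond=None)
        scores[part] = np.column_stack([np.ones(part.size), X[part]]) @ beta
    return scores


def roc_auc(scores, labels) -> RocCurve:
    """Empirical ROC curve and AUC (concordant pairs + half the ties).

    Thresholds sit at midpoints between adjacent distinct scores, with
    sentinels beyond the extremes so the curve spans (0,0) to (1,1) in
    (1-specificity, sensitivity) space.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # midranks
    rank_sum_pos = float(ranks[labels == 1].sum())
    u_pos = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    auc = u_pos / (n_pos * n_neg)

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    for i, t in enumerate(thresholds):
        sens[i] = np.mean(pos_scores >= t)
        spec[i] = np.mean(neg_scores < t)
    order = np.argsort(-thresholds)  # high threshold first: (0,1) -> (1,0)
    return RocCurve(
        thresholds=thresholds[order],
        sensitivity=sens[order],
        specificity=spec[order],
        auc=float(auc),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _delong_ci(scores: np.ndarray, labels: np.ndarray, level: float) -> tuple[float, float]:
    """Normal-theory CI from DeLong structural components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i); V01 symmetric
    v10 = np.array([(np.sum(neg < x) + 0.5 * np.sum(neg == x)) / n for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m for x in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0:
        warnings.warn("zero DeLong variance (perfect separation): degenerate CI")
        return float(auc), float(auc)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    seed: int = 0,
    n_boot: int = 2000,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% (by default) confidence interval for the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if labels.sum() < 2 or (labels.size - labels.sum()) < 2:
        raise ValueError("need at least 2 members per class")
    if method == "delong":
        return _delong_ci(scores, labels, level)
    if method != "bootstrap":
        raise ValueError("method must be 'delong' or 'bootstrap'")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos_idx, pos_idx.size, replace=True)
        ineg = rng.choice(neg_idx, neg_idx.size, replace=True)
        s = np.concatenate([scores[ip], scores[ineg]])
        l = np.concatenate([np.ones(ip.size, int), np.zeros(ineg.size, int)])
        aucs[b] = roc_auc(s, l).auc
    alpha = (1 - level) / 2
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def roc_with_ci(scores, labels, method: str = "delong", seed: int = 0) -> RocCurve:
    """Convenience wrapper: curve, AUC and CI in one object."""
    curve = roc_auc(scores, labels)
    curve.ci_low, curve.ci_high = auc_ci(scores, labels, method=method, seed=seed)
    curve.ci_method = method
    return curve
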