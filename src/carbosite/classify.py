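"""Gaussian-kernel SVM classification and imbalance-aware evaluation.

The classifier is the standard soft-margin SVM dual with the Gaussian
kernel K(x, z) = exp(-||x - z||^2 / (2 sigma^2)); the dual is solved by
libsvm (via scikit-learn), the multipliers and support vectors are
extracted, and the bias b* is recomputed as y_j - sum_i alpha_i y_i
K(x_i, x_j) averaged over the free support vectors (0 < alpha < C).
Scores are the signed decision values sum_i alpha_i y_i K(x_i, x) + b*.

Evaluation reports sensitivity TP/P, specificity TN/N and the pairwise
AUC: the fraction of (positive, negative) score pairs that are correctly
ordered, ties counted 1/2 — identical to the normalised Mann-Whitney U.

Cross-validation is stratified; all fitting (scaling, attention
selection, GAN training, the SVM) sees only the training split of each
fold. Within a fold the rebalance+train cycle can be repeated n_repeats
times with distinct sub-seeds, retaining the model with the best
training-split AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import FeatureMatrix
from .seq_features import minmax_scale

__all__ = [
    "SvmModel",
    "EvalReport",
    "CvResult",
    "gaussian_kernel",
    "default_sigma",
    "train_svm",
    "predict",
    "evaluate",
    "cross_validate",
]


def gaussian_kernel(x, z, sigma: float) -> float:
    """exp(-||x - z||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x, z = np.asarray(x, dtype=float), np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    return float(np.exp(-np.sum((x - z) ** 2) / (2.0 * sigma**2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma**2))


def default_sigma(X: np.ndarray) -> float:
    """Scale heuristic: sigma = sqrt(d * mean column variance / 2).

    Equivalent to scikit-learn's gamma='scale' under gamma = 1/(2 sigma^2).
    """
    v = float(np.mean(np.var(X, axis=0)))
    return float(np.sqrt(max(X.shape[1] * v, 1e-12) / 2.0))


@dataclass
class SvmModel:
    support_vectors: np.ndarray
    alphas: np.ndarray  # KKT multipliers alpha*_i in [0, C]
    labels: np.ndarray  # +/-1 per support vector
    bias: float
    C: float
    sigma: float

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        K = _kernel_matrix(np.atleast_2d(X), self.support_vectors, self.sigma)
        return K @ (self.alphas * self.labels) + self.bias


def _to_pm1(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    out = np.where(y > 0, 1, -1)
    if np.unique(out).size < 2:
        raise ValueError("both classes must be present")
    return out


def train_svm(train: FeatureMatrix, C: float = 1.0, sigma: float | None = None) -> SvmModel:
    """Solve the Gaussian-kernel SVM dual and extract the KKT solution."""
    if C <= 0:
        raise ValueError("C must be positive")
    y = _to_pm1(train.y)
    X = train.X
    if sigma is None:
        sigma = default_sigma(X)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    gamma = 1.0 / (2.0 * sigma**2)
    clf = SVC(C=C, kernel="rbf", gamma=gamma).fit(X, y)
    dual = clf.dual_coef_.ravel()  # alpha_i * y_i on support vectors
    sv = clf.support_vectors_
    sv_y = np.sign(dual).astype(int)
    alphas = np.abs(dual)

    # Bias via the KKT condition on free support vectors, averaged.
    free = (alphas > 1e-8) & (alphas < C - 1e-8 * C)
    if np.any(free):
        K = _kernel_matrix(sv[free], sv, sigma)
        bias = float(np.mean(sv_y[free] - K @ (alphas * sv_y)))
    else:  # all SVs at bound; fall back to the solver's intercept
        bias = float(clf.intercept_[0])
    return SvmModel(support_vectors=sv, alphas=alphas, labels=sv_y,
                    bias=bias, C=C, sigma=float(sigma))


def predict(model: SvmModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Signed decision scores and their sign as +/-1 labels (0 -> +1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {model.support_vectors.shape[1]}, "
            f"got {X.shape[1]}"
        )
    scores = model.decision_scores(X)
    return np.where(scores >= 0, 1, -1), scores


@dataclass
class EvalReport:
    sen: float
    spe: float
    auc: float
    TP: int
    TN: int
    P: int
    N: int
    P_score: np.ndarray = field(repr=False, default=None)
    N_score: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("sen", "spe", "auc", "TP", "TN", "P", "N")}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def csv_row(self, method: str, residue: str, ir: float) -> str:
        return f"{method},{residue},{ir:g},{self.sen:.4f},{self.spe:.4f},{self.auc:.4f}"


def pairwise_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Fraction of correctly ordered (positive, negative) pairs; ties 1/2."""
    p = np.asarray(pos_scores, dtype=float)[:, None]
    n = np.asarray(neg_scores, dtype=float)[None, :]
    wins = (p > n).sum() + 0.5 * (p == n).sum()
    return float(wins / (p.size * n.size))


def evaluate(labels, scores) -> EvalReport:
    """Score a set of predictions: Sen, Spe and pairwise AUC.

    ``labels`` are the true classes (+1/-1 or 1/0); ``scores`` are
    signed decision values — a score >= 0 predicts positive.
    """
    y = _to_pm1(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != y.shape:
        raise ValueError("labels and scores must align")
    pos, neg = scores[y == 1], scores[y == -1]
    TP = int((pos >= 0).sum())
    TN = int((neg < 0).sum())
    return EvalReport(
        sen=TP / pos.size, spe=TN / neg.size, auc=pairwise_auc(pos, neg),
        TP=TP, TN=TN, P=pos.size, N=neg.size, P_score=pos, N_score=neg,
    )


@dataclass
class CvResult:
    folds: list[EvalReport]
    sen: float
    spe: float
    auc: float
    best_model: SvmModel
    best_train_auc: float

    def to_dict(self) -> dict:
        return {
            "sen": self.sen, "spe": self.spe, "auc": self.auc,
            "best_train_auc": self.best_train_auc,
            "folds": [f.to_dict() for f in self.folds],
        }


def cross_validate(
    data: FeatureMatrix,
    rebalancer=None,
    C: float = 1.0,
    sigma: float | None = None,
    n_folds: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold CV with per-fold rebalancing and model selection.

    ``rebalancer`` is None (no resampling) or a callable
    ``(train: FeatureMatrix, seed: int) -> FeatureMatrix`` applied to the
    scaled training split only; the held-out fold is never touched by
    scaling fits, attention selection or GAN training. The fold result
    is the report of the repeat with the best training-split AUC; the
    aggregate is the mean over folds, and ``best_model`` is the overall
    best-training-AUC model (for application to an external test set).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = np.asarray(data.y)
    if np.bincount(y, minlength=2).min() < n_folds:
        raise ValueError(
            "a fold would have no samples of one class; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds, best_model, best_auc = [], None, -np.inf
    for f, (tr, te) in enumerate(skf.split(data.X, y)):
        if data.scaling_state == "raw":
            train, (test,) = minmax_scale(data.subset(tr), [data.subset(te)])
        else:  # inputs already live in [0, 1]
            train, test = data.subset(tr), data.subset(te)
        fold_best = None
        for r in range(n_repeats):
            sub_seed = (seed + 100_003 * f + 131 * r) % (2**31)
            fit_set = rebalancer(train, sub_seed) if rebalancer is not None else train
            model = train_svm(fit_set, C=C, sigma=sigma)
            tr_auc = evaluate(_to_pm1(train.y), model.decision_scores(train.X)).auc
            if fold_best is None or tr_auc > fold_best[0]:
                fold_best = (tr_auc, model)
        tr_auc, model = fold_best
        folds.append(evaluate(_to_pm1(test.y), model.decision_scores(test.X)))
        if tr_auc > best_auc:
            best_auc, best_model = tr_auc, model
    return CvResult(
        folds=folds,
        sen=float(np.mean([f.sen for f in folds])),
        spe=float(np.mean([f.spe for f in folds])),
        auc=float(np.mean([f.auc for f in folds])),
        best_model=best_model,
        best_train_auc=float(best_auc),
    )
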