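"""Cluster transfer to independent cohorts and In-Group-Proportion validation.

A discovery-cohort clustering is transferred to validation patients by an
L1-penalized multinomial logistic classifier (LASSO). Its out-of-sample
discriminability is estimated by repeated stratified cross-validation with
the Hand–Till multi-class AUC; when working in burden space the mechanism
autoencoders are refit inside every training fold so test folds never leak
into encoder training. Coherence of the transferred stratification is
measured by the In-Group Proportion (IGP): the fraction of validation
patients whose Euclidean nearest neighbour in the discovery cohort carries
the same cluster label, with significance from a permutation test that
shuffles the discovery labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .burden import BurdenEncoder, EncoderSpec

__all__ = [
    "TransferClassifier",
    "fit_transfer_classifier",
    "cross_validate",
    "assign_clusters",
    "IGPResult",
    "igp",
    "igp_permutation_test",
]


def _default_lambda_grid(X: np.ndarray, y: np.ndarray, n_values: int = 30) -> np.ndarray:
    """Log-spaced L1 strengths spanning [1e-4, 1e2] of the max-gradient scale."""
    classes = np.unique(y)
    n = len(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    prior = Y.mean(axis=0)
    grad = X.T @ (Y - prior) / n
    lam_max = max(float(np.abs(grad).max()), 1e-12)
    return lam_max * np.logspace(2, -4, n_values)


class TransferClassifier(BaseEstimator, ClassifierMixin):
    """L1-penalized multinomial logistic cluster classifier.

    The penalty strength is chosen from ``lambda_grid`` (auto-scaled when
    None) by inner stratified cross-validated deviance. Features are
    standardized internally. At very large penalties all non-intercept
    coefficients vanish and predictions collapse to the class priors.
    """

    def __init__(
        self,
        lambda_grid: np.ndarray | None = None,
        inner_folds: int = 5,
        max_iter: int = 5000,
        random_state: int = 0,
    ):
        self.lambda_grid = lambda_grid
        self.inner_folds = inner_folds
        self.max_iter = max_iter
        self.random_state = random_state

    def _model(
        self, lam: float, n: int, warm_start: bool = False, tol: float = 1e-4
    ) -> LogisticRegression:
        return LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / max(n * lam, 1e-12),
            solver="saga",
            max_iter=self.max_iter,
            tol=tol,
            warm_start=warm_start,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 members")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        grid = (
            np.asarray(self.lambda_grid, dtype=float)
            if self.lambda_grid is not None
            else _default_lambda_grid(Xs, y)
        )
        folds = min(self.inner_folds, counts.min())
        if folds >= 2:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.random_state)
            dev = np.zeros(len(grid))
            order = np.argsort(grid)[::-1]  # strongest penalty first, warm-started path
            for tr, te in cv.split(Xs, y):
                m = self._model(grid[order[0]], len(tr), warm_start=True)
                for i in order:
                    m.set_params(C=1.0 / max(len(tr) * grid[i], 1e-12))
                    m.fit(Xs[tr], y[tr])
                    dev[i] += log_loss(y[te], m.predict_proba(Xs[te]), labels=classes)
            best = int(np.argmin(dev))
            self.cv_deviance_ = dev / folds
        else:
            best = len(grid) // 2
            self.cv_deviance_ = None
        self.lambda_ = float(grid[best])
        self.lambda_grid_ = grid
        self.model_ = self._model(self.lambda_, len(y), tol=1e-6).fit(Xs, y)
        if np.abs(self.model_.coef_).max() < 1e-10:
            # fully shrunk model: the intercept-only optimum is the log prior
            # (saga stalls here because coefficient steps are clipped to zero)
            priors = np.array([(y == c).mean() for c in self.model_.classes_])
            logp = np.log(priors)
            self.model_.coef_[:] = 0.0
            self.model_.intercept_ = (
                logp - logp.mean()
                if len(priors) > 2
                else np.array([logp[1] - logp[0]])
            )
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self.scaler_.transform(np.asarray(X, dtype=float)))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_transfer_classifier(
    features, labels, lambda_grid=None, seed: int = 0
) -> TransferClassifier:
    """Fit the LASSO cluster classifier; lambda chosen by inner CV deviance."""
    clf = TransferClassifier(lambda_grid=lambda_grid, random_state=seed)
    return clf.fit(np.asarray(features, dtype=float), np.asarray(labels))


def hand_till_auc(y_true, proba, classes) -> float:
    """Hand–Till multi-class AUC: average of all pairwise one-vs-one AUCs.

    Reduces to the ordinary AUC when there are two classes.
    """
    proba = np.asarray(proba, dtype=float)
    if len(classes) == 2:
        return float(roc_auc_score(y_true == classes[1], proba[:, 1]))
    return float(
        roc_auc_score(y_true, proba, multi_class="ovo", average="macro", labels=classes)
    )


def cross_validate(
    features,
    labels,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    genotypes: pd.DataFrame | None = None,
    grouping=None,
    encoder_spec: EncoderSpec | None = None,
) -> float:
    """Mean Hand–Till multi-class AUC over repeated stratified CV.

    With ``genotypes`` + ``grouping`` given, the classifier works in burden
    space and the per-mechanism autoencoders are refit on each training fold
    (burden features of held-out patients come from fold-trained encoders);
    otherwise ``features`` are used as-is. AUC is computed per repeat on the
    pooled held-out predictions, then averaged over repeats.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")
    burden_mode = genotypes is not None and grouping is not None
    X_fixed = None if burden_mode else np.asarray(features, dtype=float)
    n = len(y)
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    aucs = []
    proba_pool = np.zeros((n, len(classes)))
    fold_count = 0
    for tr, te in rskf.split(np.zeros(n), y):
        if burden_mode:
            spec = encoder_spec or EncoderSpec()
            enc = BurdenEncoder(
                grouping=grouping,
                bottleneck_dim=spec.bottleneck_dim,
                sparsity_weight=spec.sparsity_weight,
                ridge=spec.ridge,
                learning_rate=spec.learning_rate,
                max_epochs=spec.max_epochs,
                tol=spec.tol,
                standardize=spec.standardize,
                random_state=spec.seed,
            ).fit(genotypes.iloc[tr])
            Xtr = enc.transform(genotypes.iloc[tr]).to_numpy()
            Xte = enc.transform(genotypes.iloc[te]).to_numpy()
        else:
            Xtr, Xte = X_fixed[tr], X_fixed[te]
        clf = TransferClassifier(random_state=seed).fit(Xtr, y[tr])
        proba = clf.predict_proba(Xte)
        # align columns to the global class order
        order = [list(clf.classes_).index(c) for c in classes]
        proba_pool[te] = proba[:, order]
        fold_count += 1
        if fold_count % folds == 0:  # one repeat complete
            aucs.append(hand_till_auc(y, proba_pool, classes))
            proba_pool = np.zeros((n, len(classes)))
    return float(np.mean(aucs))


def assign_clusters(model: TransferClassifier, validation_features):
    """Predicted labels and class probabilities for validation patients."""
    proba = model.predict_proba(np.asarray(validation_features, dtype=float))
    labels = model.classes_[np.argmax(proba, axis=1)]
    return labels, proba


@dataclass
class IGPResult:
    """In-Group Proportion per cluster and overall, plus permutation p-values."""

    per_cluster: dict  # label -> IGP in [0, 1] (NaN if the cluster is empty)
    overall: float
    nn_labels: np.ndarray  # discovery label of each validation patient's NN
    nn_indices: np.ndarray
    predicted_labels: np.ndarray
    discovery_labels: np.ndarray
    n_perm: int | None = None
    p_overall: float | None = None
    p_per_cluster: dict = field(default_factory=dict)


def igp(
    validation_features,
    predicted_labels,
    discovery_features,
    discovery_labels,
) -> IGPResult:
    """In-Group Proportion of a transferred clustering.

    For every validation patient, find the Euclidean nearest discovery
    patient (ties break to the lowest patient index). A cluster's IGP is the
    fraction of its validation patients whose nearest neighbour shares the
    label; the overall IGP pools all validation patients. IGP near 1 means
    the validation data distribution is coherent with the discovery
    clustering; near 0 means disagreement.
    """
    Xv = np.atleast_2d(np.asarray(validation_features, dtype=float))
    Xd = np.atleast_2d(np.asarray(discovery_features, dtype=float))
    pred = np.asarray(predicted_labels)
    disc = np.asarray(discovery_labels)
    if len(disc) != Xd.shape[0] or len(pred) != Xv.shape[0]:
        raise ValueError("label lengths do not match feature rows")
    D = cdist(Xv, Xd)
    nn = np.argmin(D, axis=1)  # argmin returns the lowest index on ties
    nn_labels = disc[nn]
    agree = nn_labels == pred
    per_cluster = {}
    import warnings

    for lab in np.unique(disc):
        mask = pred == lab
        if mask.sum() == 0:
            warnings.warn(f"cluster {lab!r}: no validation patients; IGP undefined", stacklevel=2)
            per_cluster[lab] = float("nan")
        else:
            per_cluster[lab] = float(agree[mask].mean())
    return IGPResult(
        per_cluster=per_cluster,
        overall=float(agree.mean()),
        nn_labels=nn_labels,
        nn_indices=nn,
        predicted_labels=pred,
        discovery_labels=disc,
    )


def igp_permutation_test(result: IGPResult, n_perm: int = 1000, seed: int = 0) -> IGPResult:
    """Permutation p-values for an IGP result.

    Discovery cluster labels are uniformly permuted and the IGP recomputed
    (nearest neighbours are fixed, only their labels change). The add-one
    estimator p = (1 + #{perm ≥ observed}) / (n_perm + 1) avoids p = 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    disc = result.discovery_labels
    nn = result.nn_indices
    pred = result.predicted_labels
    labels = np.unique(disc)
    ge_overall = 0
    ge_cluster = {lab: 0 for lab in labels}
    cluster_masks = {lab: pred == lab for lab in labels}
    for _ in range(n_perm):
        perm = rng.permutation(disc)
        nn_lab = perm[nn]
        agree = nn_lab == pred
        if agree.mean() >= result.overall:
            ge_overall += 1
        for lab in labels:
            mask = cluster_masks[lab]
            if mask.sum() == 0:
                continue
            obs = result.per_cluster[lab]
            if not np.isnan(obs) and agree[mask].mean() >= obs:
                ge_cluster[lab] += 1
    result.n_perm = n_perm
    result.p_overall = (1 + ge_overall) / (n_perm + 1)
    result.p_per_cluster = {
        lab: (1 + ge_cluster[lab]) / (n_perm + 1)
        for lab in labels
        if not np.isnan(result.per_cluster.get(lab, float("nan")))
    }
    return result
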