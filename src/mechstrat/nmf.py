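"""Sparse non-negative matrix factorization (multiplicative updates, L1 on loadings).

Factorizes a non-negative patients × mechanisms matrix X ≈ A·S where A
(patients × k) softly assigns patients to clusters and S (k × mechanisms)
sparsely maps mechanisms to clusters. The objective

    ||X − A·S||_F² + sparsity · Σ|S|

is minimized by alternating Lee–Seung-style multiplicative updates; the L1
term enters the S update denominator, which keeps the objective monotonically
non-increasing. Hard per-run labels are the row-wise argmax of A (ties break
to the lowest cluster index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["SparseNMF", "FactorizationResult", "snmf"]

_EPS = 1e-12


@dataclass
class FactorizationResult:
    """One sNMF fit: factors, objective trace and hard labels."""

    X: np.ndarray
    k: int
    A: np.ndarray  # patients x k, soft assignment
    S: np.ndarray  # k x mechanisms, sparse loadings
    objective: float
    objective_history: list[float]
    iterations: int

    @property
    def labels(self) -> np.ndarray:
        """Hard cluster per patient: argmax over A rows (ties → lowest index)."""
        return np.argmax(self.A, axis=1)

    @property
    def squared_error(self) -> float:
        return float(np.linalg.norm(self.X - self.A @ self.S) ** 2)


class SparseNMF(BaseEstimator, TransformerMixin):
    """Sparse NMF estimator (sklearn-style).

    ``fit_transform(X)`` returns the patient coefficient matrix A;
    ``components_`` holds the sparse mechanism loading matrix S.
    """

    def __init__(
        self,
        n_components: int = 4,
        sparsity: float = 0.01,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.sparsity = sparsity
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.isfinite(X).all():
            raise ValueError("X must be finite")
        if (X < 0).any():
            raise ValueError("X must be non-negative")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_components > X.shape[0]:
            raise ValueError("n_components cannot exceed the number of patients")
        if self.sparsity < 0:
            raise ValueError("sparsity must be >= 0")
        return X

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = self._validate(X)
        n, m = X.shape
        k = self.n_components
        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(max(X.mean(), _EPS) / k)
        A = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
        S = rng.uniform(_EPS, 1.0, size=(k, m)) * scale

        def objective(A, S):
            return float(
                np.linalg.norm(X - A @ S) ** 2 + self.sparsity * np.abs(S).sum()
            )

        history = [objective(A, S)]
        it = 0
        for it in range(1, self.max_iter + 1):
            # A-update (plain Frobenius multiplicative rule)
            A *= (X @ S.T) / (A @ (S @ S.T) + _EPS)
            # S-update with the L1 term in the denominator
            S *= (A.T @ X) / ((A.T @ A) @ S + self.sparsity + _EPS)
            obj = objective(A, S)
            history.append(obj)
            prev = history[-2]
            if abs(prev - obj) <= self.tol * max(abs(prev), _EPS):
                break
        self.components_ = S
        self.objective_ = history[-1]
        self.objective_history_ = history
        self.n_iter_ = it
        self.reconstruction_err_ = float(np.linalg.norm(X - A @ S) ** 2)
        self._A = A
        self._X = X
        return A

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X) -> np.ndarray:
        """Project new rows onto fixed loadings S by multiplicative updates on A."""
        check_is_fitted(self, "components_")
        X = self._validate(X)
        S = self.components_
        rng = np.random.default_rng(self.random_state)
        A = rng.uniform(_EPS, 1.0, size=(X.shape[0], S.shape[0]))
        for _ in range(self.max_iter):
            A_new = A * (X @ S.T) / (A @ (S @ S.T) + _EPS)
            if np.max(np.abs(A_new - A)) <= self.tol:
                A = A_new
                break
            A = A_new
        return A

    def result(self) -> FactorizationResult:
        check_is_fitted(self, "components_")
        return FactorizationResult(
            X=self._X,
            k=self.n_components,
            A=self._A,
            S=self.components_,
            objective=self.objective_,
            objective_history=self.objective_history_,
            iterations=self.n_iter_,
        )


def snmf(
    X,
    k: int,
    sparsity: float = 0.01,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> FactorizationResult:
    """One sparse NMF run; see :class:`SparseNMF`."""
    model = SparseNMF(
        n_components=k, sparsity=sparsity, max_iter=max_iter, tol=tol, random_state=seed
    )
    model.fit(X)
    return model.result()
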