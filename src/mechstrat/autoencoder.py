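"""Sparse autoencoder for per-mechanism SNP burden scores.

One tiny network per mechanism: standardized dosages → sigmoid bottleneck
(default width 1) → linear decoder. The bottleneck activation is the burden
score, bounded in [0, 1] by construction, which also guarantees the
non-negativity required by the downstream matrix factorization. Sparsity is
an L1 penalty on the encoder weights; a small ridge term makes the optimum
unique when SNP columns are collinear (e.g. perfect LD duplicates), so
contribution weights of interchangeable SNPs agree.

Training is full-batch Adam on

    mean squared reconstruction error
    + sparsity_weight * ||W_enc||_1
    + ridge * (||W_enc||_2^2 + ||W_dec||_2^2)

with a relative-loss stopping tolerance. A fit that fails to beat the
all-mean reconstruction is retried once from a fresh seed. All-constant
input marks the encoder degenerate: it scores every patient 0.5 and reports
uniform SNP contributions.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["SparseAutoencoder"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SparseAutoencoder(BaseEstimator, TransformerMixin):
    """Single-hidden-layer sparse autoencoder with a bounded bottleneck.

    Parameters
    ----------
    bottleneck_dim : int, default 1
        Width of the sigmoid bottleneck. The burden score is the mean
        bottleneck activation (the activation itself when width is 1).
    sparsity_weight : float, default 1e-3
        L1 penalty on encoder weights.
    ridge : float, default 1e-3
        Small L2 penalty on all weights (uniqueness under collinearity).
    learning_rate, max_epochs, tol
        Full-batch Adam step size, epoch cap, and relative-loss tolerance.
    standardize : bool, default True
        Standardize each input column to zero mean / unit variance before
        encoding (constant columns become all-zero).
    random_state : int or None
        Seed for weight initialization.

    Attributes
    ----------
    w_enc_ : (n_features, bottleneck_dim) encoder weights
    w_dec_ : (bottleneck_dim, n_features) decoder weights
    degenerate_ : True when the input carried no variance
    reconstruction_error_ : final mean squared reconstruction error
    baseline_error_ : error of the all-mean reconstruction
    """

    def __init__(
        self,
        bottleneck_dim: int = 1,
        sparsity_weight: float = 1e-3,
        ridge: float = 1e-3,
        learning_rate: float = 0.05,
        max_epochs: int = 800,
        tol: float = 1e-6,
        standardize: bool = True,
        max_retries: int = 1,
        random_state: int | None = None,
    ):
        self.bottleneck_dim = bottleneck_dim
        self.sparsity_weight = sparsity_weight
        self.ridge = ridge
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.tol = tol
        self.standardize = standardize
        self.max_retries = max_retries
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _prepare(self, X: np.ndarray, fitting: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if fitting:
            # per-column mode imputation for missing dosages
            modes = np.zeros(X.shape[1])
            for j in range(X.shape[1]):
                col = X[:, j]
                obs = col[~np.isnan(col)]
                if obs.size:
                    vals, counts = np.unique(obs, return_counts=True)
                    modes[j] = vals[np.argmax(counts)]
            self.modes_ = modes
        X = np.where(np.isnan(X), self.modes_[None, :], X)
        if fitting:
            self.means_ = X.mean(axis=0) if X.shape[0] else np.zeros(X.shape[1])
            sd = X.std(axis=0) if X.shape[0] else np.zeros(X.shape[1])
            self.scales_ = np.where(sd > 0, sd, 1.0)
            self.constant_ = sd == 0
        if self.standardize:
            X = (X - self.means_[None, :]) / self.scales_[None, :]
            X[:, self.constant_] = 0.0
        return X

    def _loss_and_grads(self, Xs, W1, b1, W2, b2):
        n, d = Xs.shape
        Z = _sigmoid(Xs @ W1 + b1)  # (n, h)
        Xhat = Z @ W2 + b2  # (n, d)
        R = Xhat - Xs
        mse = float(np.mean(R**2))
        loss = (
            mse
            + self.sparsity_weight * float(np.abs(W1).sum())
            + self.ridge * float((W1**2).sum() + (W2**2).sum())
        )
        dXhat = 2.0 * R / (n * d)
        gb2 = dXhat.sum(axis=0)
        gW2 = Z.T @ dXhat + 2.0 * self.ridge * W2
        dZ = dXhat @ W2.T
        dA = dZ * Z * (1.0 - Z)
        gW1 = Xs.T @ dA + self.sparsity_weight * np.sign(W1) + 2.0 * self.ridge * W1
        gb1 = dA.sum(axis=0)
        return loss, mse, (gW1, gb1, gW2, gb2)

    def _train_once(self, Xs: np.ndarray, seed: int):
        rng = np.random.default_rng(seed)
        n, d = Xs.shape
        h = self.bottleneck_dim
        W1 = rng.normal(0.0, 1.0 / np.sqrt(max(d, 1)), size=(d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, 0.1, size=(h, d))
        b2 = np.zeros(d)
        params = [W1, b1, W2, b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        prev_loss = np.inf
        mse = np.inf
        history = []
        for t in range(1, self.max_epochs + 1):
            loss, mse, grads = self._loss_and_grads(Xs, *params)
            history.append(loss)
            if np.isfinite(prev_loss) and abs(prev_loss - loss) <= self.tol * max(
                abs(prev_loss), 1e-12
            ):
                break
            prev_loss = loss
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g**2
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                params[i] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return params, mse, history

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        if self.bottleneck_dim < 1:
            raise ValueError("bottleneck_dim must be >= 1")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be >= 0")
        Xs = self._prepare(X, fitting=True)
        self.n_features_in_ = Xs.shape[1]
        if Xs.shape[1] < 1:
            raise ValueError("need at least one SNP column")
        self.degenerate_ = bool(self.constant_.all()) or Xs.shape[0] < 2
        if self.degenerate_:
            h, d = self.bottleneck_dim, Xs.shape[1]
            self.w_enc_ = np.zeros((d, h))
            self.b_enc_ = np.zeros(h)
            self.w_dec_ = np.zeros((h, d))
            self.b_dec_ = np.zeros(d)
            self.reconstruction_error_ = 0.0
            self.baseline_error_ = 0.0
            self.loss_history_ = []
            return self
        baseline = float(np.mean((Xs - Xs.mean(axis=0)) ** 2))
        seed = 0 if self.random_state is None else int(self.random_state)
        best = None
        for attempt in range(self.max_retries + 1):
            params, mse, history = self._train_once(Xs, seed + 1000003 * attempt)
            if best is None or mse < best[1]:
                best = (params, mse, history)
            if mse <= baseline:
                break
        else:
            warnings.warn(
                "autoencoder did not beat the all-mean reconstruction after retries",
                stacklevel=2,
            )
        (W1, b1, W2, b2), mse, history = best
        # canonical orientation: a burden score must increase with aggregate
        # risk-allele dosage. Flipping a sigmoid unit (z -> 1 - z) leaves the
        # reconstruction loss unchanged (W2 -> -W2 absorbs it), so orient each
        # unit to correlate positively with the mean imputed dosage.
        Ximp = np.where(np.isnan(np.asarray(X, dtype=float)), self.modes_[None, :], X)
        ref = np.asarray(Ximp, dtype=float).mean(axis=1)
        if np.std(ref) > 0:
            Z = _sigmoid(Xs @ W1 + b1)
            for j in range(Z.shape[1]):
                if np.std(Z[:, j]) == 0:
                    continue
                if np.corrcoef(ref, Z[:, j])[0, 1] < 0:
                    b2 = b2 + W2[j]
                    W1[:, j] *= -1.0
                    b1[j] *= -1.0
                    W2[j] *= -1.0
        self.w_enc_, self.b_enc_, self.w_dec_, self.b_dec_ = W1, b1, W2, b2
        self.reconstruction_error_ = mse
        self.baseline_error_ = baseline
        self.loss_history_ = history
        return self

    def transform(self, X) -> np.ndarray:
        """Burden score per patient, in [0, 1]; shape (n_patients,)."""
        check_is_fitted(self, "w_enc_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} SNP columns, got {X.shape[1]}"
            )
        if X.shape[0] == 0:
            return np.zeros(0)
        if self.degenerate_:
            return np.full(X.shape[0], 0.5)
        Xs = self._prepare(X, fitting=False)
        Z = _sigmoid(Xs @ self.w_enc_ + self.b_enc_)
        return Z.mean(axis=1) if self.bottleneck_dim > 1 else Z[:, 0]

    @property
    def contributions_(self) -> np.ndarray:
        """Relative SNP contributions |w| / Σ|w|, non-negative, summing to 1."""
        check_is_fitted(self, "w_enc_")
        w = np.abs(self.w_enc_).sum(axis=1)
        total = w.sum()
        if self.degenerate_ or total == 0:
            warnings.warn("degenerate encoder: uniform contributions", stacklevel=2)
            return np.full(self.n_features_in_, 1.0 / self.n_features_in_)
        return w / total

    def to_dict(self) -> dict:
        """JSON-serializable weight dump."""
        check_is_fitted(self, "w_enc_")
        return {
            "bottleneck_dim": self.bottleneck_dim,
            "degenerate": self.degenerate_,
            "w_enc": self.w_enc_.tolist(),
            "b_enc": self.b_enc_.tolist(),
            "w_dec": self.w_dec_.tolist(),
            "b_dec": self.b_dec_.tolist(),
            "means": self.means_.tolist(),
            "scales": self.scales_.tolist(),
            "constant": self.constant_.tolist(),
            "modes": self.modes_.tolist(),
            "standardize": self.standardize,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SparseAutoencoder":
        enc = cls(bottleneck_dim=payload["bottleneck_dim"], standardize=payload["standardize"])
        enc.w_enc_ = np.asarray(payload["w_enc"], dtype=float)
        enc.b_enc_ = np.asarray(payload["b_enc"], dtype=float)
        enc.w_dec_ = np.asarray(payload["w_dec"], dtype=float)
        enc.b_dec_ = np.asarray(payload["b_dec"], dtype=float)
        enc.means_ = np.asarray(payload["means"], dtype=float)
        enc.scales_ = np.asarray(payload["scales"], dtype=float)
        enc.constant_ = np.asarray(payload["constant"], dtype=bool)
        enc.modes_ = np.asarray(payload["modes"], dtype=float)
        enc.degenerate_ = bool(payload["degenerate"])
        enc.n_features_in_ = enc.w_enc_.shape[0]
        return enc
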