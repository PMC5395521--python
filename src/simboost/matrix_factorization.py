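"""Regularized matrix factorization of the partially observed affinity matrix.

The observed affinities are approximated as ``M[i, j] ~ p_i . q_j`` with drug
factors ``P`` (rank x n_drugs) and target factors ``Q`` (rank x n_targets)
fitted by stochastic gradient descent on

    sum_{(i,j) observed} (m_ij - p_i . q_j)^2 + lambda (||p_i||^2 + ||q_j||^2)

The latent columns double as Type-3 features for the boosted-tree model, and
``P^T Q`` is the linear matrix-factorization baseline predictor.

SGD visits the observed cells in a seeded-shuffled order once per epoch and
applies the per-cell update (learning rate eta, error e = m_ij - p_i.q_j)::

    p_i += eta * (e * q_j - lambda * p_i)
    q_j += eta * (e * p_i - lambda * q_j)

i.e. the half-scaled gradient with the constant 2 absorbed into eta.
"""

from __future__ import annotations

import json

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .data_io import AffinityMatrix
from .errors import ConfigError, NumericalError

__all__ = ["MatrixFactorization", "factorize", "predict_mf", "latent_features"]


@njit(cache=False)
def _sgd_epoch(P, Q, rows, cols, vals, order, lr, lam):  # pragma: no cover - jitted
    rank = P.shape[0]
    for idx in order:
        i = rows[idx]
        j = cols[idx]
        e = vals[idx]
        for r in range(rank):
            e -= P[r, i] * Q[r, j]
        for r in range(rank):
            p = P[r, i]
            q = Q[r, j]
            P[r, i] = p + lr * (e * q - lam * p)
            Q[r, j] = q + lr * (e * p - lam * q)


class MatrixFactorization(BaseEstimator):
    """SGD matrix factorization of an :class:`~simboost.data_io.AffinityMatrix`.

    Parameters
    ----------
    rank : latent dimension k.
    reg_lambda : L2 penalty weight on the factor columns.
    learning_rate : SGD step size.
    n_epochs : full passes over the observed cells.
    init_scale : factors are initialised N(0, init_scale / sqrt(rank)).
    seed : drives initialisation and the per-epoch shuffle.

    Attributes (after ``fit``)
    --------------------------
    P_ : (rank, n_drugs) drug factors.
    Q_ : (rank, n_targets) target factors.
    objective_history_ : regularized objective after each epoch.
    drug_ids_, target_ids_ : id lists of the training matrix.
    """

    def __init__(self, rank: int = 10, reg_lambda: float = 0.01,
                 learning_rate: float = 0.01, n_epochs: int = 100,
                 init_scale: float = 0.1, seed: int = 0):
        self.rank = rank
        self.reg_lambda = reg_lambda
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.init_scale = init_scale
        self.seed = seed

    def fit(self, m_train: AffinityMatrix) -> "MatrixFactorization":
        if self.rank < 1:
            raise ConfigError("rank must be >= 1")
        if self.n_epochs < 1:
            raise ConfigError("n_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.reg_lambda < 0:
            raise ConfigError("reg_lambda must be >= 0")
        rows, cols = np.nonzero(m_train.observed)
        if len(rows) == 0:
            raise ConfigError("training matrix has no observed cells")
        vals = m_train.values[rows, cols]
        rows = rows.astype(np.int64)
        cols = cols.astype(np.int64)

        rng = np.random.default_rng(self.seed)
        sd = self.init_scale / np.sqrt(self.rank)
        P = rng.normal(0.0, sd, size=(self.rank, m_train.n_drugs))
        Q = rng.normal(0.0, sd, size=(self.rank, m_train.n_targets))

        history = []
        for _ in range(self.n_epochs):
            order = rng.permutation(len(vals)).astype(np.int64)
            _sgd_epoch(P, Q, rows, cols, vals, order,
                       self.learning_rate, self.reg_lambda)
            obj = self._objective(P, Q, rows, cols, vals)
            if not np.isfinite(obj):
                raise NumericalError(
                    "matrix factorization diverged (non-finite objective); "
                    "try a smaller learning_rate")
            history.append(obj)

        self.P_ = P
        self.Q_ = Q
        self.objective_history_ = np.array(history)
        self.drug_ids_ = list(m_train.drug_ids)
        self.target_ids_ = list(m_train.target_ids)
        return self

    def _objective(self, P, Q, rows, cols, vals) -> float:
        pred = np.einsum("ri,ri->i", P[:, rows], Q[:, cols])
        sq = np.sum((vals - pred) ** 2)
        reg = self.reg_lambda * (np.sum(P[:, rows] ** 2) + np.sum(Q[:, cols] ** 2))
        return float(sq + reg)

    def predict_full(self) -> np.ndarray:
        """Full n_drugs x n_targets prediction matrix ``P^T Q``."""
        self._check_fitted()
        return self.P_.T @ self.Q_

    def predict_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Predictions for individual (drug index, target index) cells."""
        self._check_fitted()
        return np.einsum("ri,ri->i", self.P_[:, rows], self.Q_[:, cols])

    def latent_features(self, drug_id: str, target_id: str) -> np.ndarray:
        """Concatenated drug and target factor columns (length 2 * rank)."""
        self._check_fitted()
        try:
            i = self.drug_ids_.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None
        try:
            j = self.target_ids_.index(target_id)
        except ValueError:
            raise KeyError(f"unknown target id: {target_id!r}") from None
        return np.concatenate([self.P_[:, i], self.Q_[:, j]])

    def _check_fitted(self) -> None:
        if not hasattr(self, "P_"):
            raise ConfigError("MatrixFactorization instance is not fitted")

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        payload = {
            "params": self.get_params(),
            "drug_ids": self.drug_ids_,
            "target_ids": self.target_ids_,
            "P": self.P_.tolist(),
            "Q": self.Q_.tolist(),
            "objective_history": self.objective_history_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "MatrixFactorization":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(**payload["params"])
        model.P_ = np.array(payload["P"])
        model.Q_ = np.array(payload["Q"])
        model.objective_history_ = np.array(payload["objective_history"])
        model.drug_ids_ = payload["drug_ids"]
        model.target_ids_ = payload["target_ids"]
        return model


def factorize(m_train: AffinityMatrix, rank: int = 10, reg_lambda: float = 0.01,
              learning_rate: float = 0.01, n_epochs: int = 100,
              seed: int = 0) -> MatrixFactorization:
    """Functional wrapper around :class:`MatrixFactorization`."""
    return MatrixFactorization(rank=rank, reg_lambda=reg_lambda,
                               learning_rate=learning_rate, n_epochs=n_epochs,
                               seed=seed).fit(m_train)


def predict_mf(model: MatrixFactorization) -> np.ndarray:
    return model.predict_full()


def latent_features(model: MatrixFactorization, drug_id: str,
                    target_id: str) -> np.ndarray:
    return model.latent_features(drug_id, target_id)
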