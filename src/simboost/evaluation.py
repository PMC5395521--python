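"""Metrics and the repeated cross-validation protocol.

Metrics: RMSE on the continuous predictions; concordance index (CI, the
probability that two randomly drawn pairs with different true affinities are
predicted in the correct order, prediction ties counting 1/2); AUC and AUPR
after binarizing the *true* affinities at the dataset threshold -- the models
always predict continuous values and the threshold is applied after
prediction, never at training time.

Protocol: k-fold cross validation where the folds are built so that every
target's observed cells span at least two folds (no target is ever seen only
in training or only in testing), repeated with fresh fold seeds; one pooled
value per metric per repetition, reported as mean +/- sd over repetitions.
Within each fold, matrix factorization and every feature are rebuilt from the
training folds only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .boosting import SimBoostQuantRegressor, SimBoostRegressor
from .data_io import AffinityMatrix, SimilarityMatrix, binarize
from .errors import ConfigError, DataFormatError
from .feature_assembly import PairFeaturizer

__all__ = [
    "rmse",
    "concordance_index",
    "auc_aupr",
    "FoldAssignment",
    "build_folds",
    "MetricsReport",
    "cross_validate",
]

#: Maximum allowed difference between fold sizes after balancing.
FOLD_SIZE_SLACK = 1


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ConfigError("rmse requires equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def concordance_index(y, yhat) -> float:
    """CI over all index pairs with different labels; prediction ties count 1/2.

    Chunked O(n^2) enumeration of the definition (exact, no approximation).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ConfigError("concordance_index requires two equal-length vectors")
    if np.all(y == y[0]):
        raise ConfigError("concordance_index is undefined when all labels are equal")
    n = len(y)
    num = 0.0
    den = 0
    chunk = 512
    for i0 in range(0, n, chunk):
        dy = y[i0:i0 + chunk, None] - y[None, :]
        du = yhat[i0:i0 + chunk, None] - yhat[None, :]
        valid = dy != 0
        num += np.sum(valid & (du * dy > 0)) + 0.5 * np.sum(valid & (du == 0))
        den += int(valid.sum())
    return num / den


def auc_aupr(labels, scores) -> tuple[float, float]:
    """ROC AUC (rank statistic, tie-corrected) and step-wise AUPR.

    AUPR is computed as average precision (step-wise integration of the
    precision-recall curve, no interpolation).
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ConfigError("auc_aupr requires both classes to be present")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


@dataclass
class FoldAssignment:
    """Partition of the observed cells into folds.

    ``cells`` is an (n_obs, 2) array of (drug index, target index); ``folds``
    the fold index of each cell.
    """

    n_folds: int
    cells: np.ndarray
    folds: np.ndarray
    seed: int

    def test_cells(self, fold: int) -> np.ndarray:
        return self.cells[self.folds == fold]

    def train_cells(self, fold: int) -> np.ndarray:
        return self.cells[self.folds != fold]


def build_folds(observed_mask: np.ndarray, n_folds: int = 5, seed: int = 0,
                enforce_drug_constraint: bool = False) -> FoldAssignment:
    """Build folds so every target's observations span >= 2 distinct folds.

    Per target, its observed cells are shuffled and dealt round-robin starting
    at a random offset (so any target with >= 2 cells automatically spans >= 2
    folds); global fold sizes are then balanced by moves that preserve the
    constraint, down to a max-min gap of ``FOLD_SIZE_SLACK``.
    """
    observed_mask = np.asarray(observed_mask, dtype=bool)
    if n_folds < 2:
        raise ConfigError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    n_drugs, n_targets = observed_mask.shape

    per_target = observed_mask.sum(axis=0)
    deficient = np.nonzero(per_target < 2)[0]
    if deficient.size:
        raise DataFormatError(
            f"targets with < 2 observed cells cannot satisfy the fold "
            f"constraint: target indices {deficient.tolist()}")

    cells = []
    folds = []
    for j in range(n_targets):
        drugs = np.nonzero(observed_mask[:, j])[0]
        rng.shuffle(drugs)
        offset = int(rng.integers(n_folds))
        for r, i in enumerate(drugs):
            cells.append((i, j))
            folds.append((offset + r) % n_folds)
    cells = np.array(cells)
    folds = np.array(folds)

    _balance_folds(cells, folds, n_folds, rng)

    if enforce_drug_constraint:
        _enforce_drug_spread(cells, folds, n_folds, rng)

    return FoldAssignment(n_folds, cells, folds, seed)


def _target_fold_counts(cells, folds, n_folds, n_targets):
    counts = np.zeros((n_targets, n_folds), dtype=int)
    np.add.at(counts, (cells[:, 1], folds), 1)
    return counts


def _balance_folds(cells, folds, n_folds, rng) -> None:
    """Move cells from the largest to the smallest fold while every move keeps
    the source cell's target spanning >= 2 folds."""
    n_targets = cells[:, 1].max() + 1
    counts = _target_fold_counts(cells, folds, n_folds, n_targets)
    sizes = np.bincount(folds, minlength=n_folds)
    for _ in range(len(folds)):
        big = int(np.argmax(sizes))
        small = int(np.argmin(sizes))
        if sizes[big] - sizes[small] <= FOLD_SIZE_SLACK:
            break
        candidates = np.nonzero(folds == big)[0]
        rng.shuffle(candidates)
        moved = False
        for idx in candidates:
            t = cells[idx, 1]
            spans = int((counts[t] > 0).sum())
            # moving the cell must leave its target spanning >= 2 folds
            if counts[t, big] == 1:
                new_spans = spans - 1 + (0 if counts[t, small] > 0 else 1)
            else:
                new_spans = spans + (0 if counts[t, small] > 0 else 1)
            if new_spans < 2:
                continue
            counts[t, big] -= 1
            counts[t, small] += 1
            folds[idx] = small
            sizes[big] -= 1
            sizes[small] += 1
            moved = True
            break
        if not moved:
            break


def _enforce_drug_spread(cells, folds, n_folds, rng) -> None:
    """Best-effort repair so every drug with >= 2 cells spans >= 2 folds."""
    n_targets = cells[:, 1].max() + 1
    counts = _target_fold_counts(cells, folds, n_folds, n_targets)
    for drug in np.unique(cells[:, 0]):
        idxs = np.nonzero(cells[:, 0] == drug)[0]
        if len(idxs) < 2 or len(set(folds[idxs])) >= 2:
            continue
        current = folds[idxs[0]]
        others = [f for f in range(n_folds) if f != current]
        rng.shuffle(others)
        repaired = False
        for idx in idxs:
            t = cells[idx, 1]
            for dest in others:
                spans = int((counts[t] > 0).sum())
                if counts[t, current] == 1:
                    new_spans = spans - 1 + (0 if counts[t, dest] > 0 else 1)
                else:
                    new_spans = spans + (0 if counts[t, dest] > 0 else 1)
                if new_spans >= 2:
                    counts[t, current] -= 1
                    counts[t, dest] += 1
                    folds[idx] = dest
                    repaired = True
                    break
            if repaired:
                break
        if not repaired:
            raise DataFormatError(
                f"could not spread drug index {int(drug)} over >= 2 folds")


@dataclass
class MetricsReport:
    """Mean +/- sd of each metric over repetitions, per model."""

    models: dict  # model -> metric -> {"mean": float, "sd": float, "values": [...]}
    n_repetitions: int
    n_folds: int
    seed: int

    METRICS = ("RMSE", "AUC", "AUPR", "CI")

    def to_json(self) -> str:
        return json.dumps({
            "n_repetitions": self.n_repetitions,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "models": self.models,
        }, indent=2)

    def to_table(self) -> str:
        """Human-readable table: rows = models, columns = metrics, mean +/- sd."""
        width = max(len(m) for m in self.models) + 2
        header = "".join(f"{m:>16}" for m in self.METRICS)
        lines = [f"{'model':<{width}}{header}"]
        for model, metrics in self.models.items():
            cells = "".join(
                f"{metrics[m]['mean']:.3f} ± {metrics[m]['sd']:.3f}".rjust(16)
                for m in self.METRICS)
            lines.append(f"{model:<{width}}{cells}")
        return "\n".join(lines)


def _mask_out(m: AffinityMatrix, cells: np.ndarray) -> AffinityMatrix:
    """Copy of m with the given cells turned unobserved."""
    out = m.copy()
    out.values[cells[:, 0], cells[:, 1]] = np.nan
    out.observed[cells[:, 0], cells[:, 1]] = False
    return out


def cross_validate(m: AffinityMatrix, d_sim: SimilarityMatrix,
                   t_sim: SimilarityMatrix, models=("simboost", "mf"),
                   n_folds: int = 5, n_repetitions: int = 10, seed: int = 0,
                   binarize_threshold: float = 7.0, direction: str = ">=",
                   featurizer_params: dict | None = None,
                   boost_params: dict | None = None,
                   quant_params: dict | None = None) -> MetricsReport:
    """Repeated constrained cross-validation of the requested models.

    Models: ``"simboost"`` (squared loss), ``"simboost-quant"`` (interval
    midpoint), ``"mf"`` (the matrix-factorization baseline, reusing the
    factorization fitted for the Type-3 features).  Per repetition the held-out
    predictions of all folds are pooled before computing each metric.
    """
    featurizer_params = dict(featurizer_params or {})
    boost_params = dict(boost_params or {})
    quant_params = dict(quant_params or {})
    unknown = set(models) - {"simboost", "simboost-quant", "mf"}
    if unknown:
        raise ConfigError(f"unknown models: {sorted(unknown)}")

    raw: dict[str, dict[str, list[float]]] = {
        mod: {met: [] for met in MetricsReport.METRICS} for mod in models}

    for rep in range(n_repetitions):
        rep_seed = seed + rep
        fold_assign = build_folds(m.observed, n_folds=n_folds, seed=rep_seed)
        y_true: list[np.ndarray] = []
        preds: dict[str, list[np.ndarray]] = {mod: [] for mod in models}

        for fold in range(n_folds):
            test = fold_assign.test_cells(fold)
            train = fold_assign.train_cells(fold)
            m_train = _mask_out(m, test)
            fold_seed = (rep_seed * n_folds + fold) % (2 ** 31 - 1)

            fz = PairFeaturizer(**featurizer_params, seed=fold_seed)
            fz.fit((m_train, d_sim, t_sim))
            train_pairs = [(m.drug_ids[i], m.target_ids[j]) for i, j in train]
            test_pairs = [(m.drug_ids[i], m.target_ids[j]) for i, j in test]
            X_train = fz.transform(train_pairs)
            X_test = fz.transform(test_pairs)
            y_train = m.values[train[:, 0], train[:, 1]]
            y_true.append(m.values[test[:, 0], test[:, 1]])

            if "simboost" in models:
                reg = SimBoostRegressor(**boost_params, seed=fold_seed)
                reg.fit(X_train, y_train)
                preds["simboost"].append(reg.predict(X_test))
            if "simboost-quant" in models:
                qreg = SimBoostQuantRegressor(**quant_params, seed=fold_seed)
                qreg.fit(X_train, y_train)
                preds["simboost-quant"].append(qreg.predict(X_test))
            if "mf" in models:
                preds["mf"].append(
                    fz.mf_model_.predict_cells(test[:, 0], test[:, 1]))

        y = np.concatenate(y_true)
        labels = _binary_labels(y, binarize_threshold, direction)
        for mod in models:
            yhat = np.concatenate(preds[mod])
            raw[mod]["RMSE"].append(rmse(y, yhat))
            raw[mod]["CI"].append(concordance_index(y, yhat))
            scores = yhat if direction == ">=" else -yhat
            auc, aupr = auc_aupr(labels, scores)
            raw[mod]["AUC"].append(auc)
            raw[mod]["AUPR"].append(aupr)

    summary = {
        mod: {
            met: {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1))
                  if len(vals) > 1 else 0.0, "values": [float(v) for v in vals]}
            for met, vals in mets.items()}
        for mod, mets in raw.items()}
    return MetricsReport(summary, n_repetitions, n_folds, seed)


def _binary_labels(y: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    if direction == ">=":
        return y >= threshold
    if direction == "<=":
        return y <= threshold
    raise ConfigError("direction must be '>=' or '<='")
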