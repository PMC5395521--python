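"""Per-pair feature vectors: Type-1 + Type-2 per entity, Type-3 per pair.

For a pair (d_i, t_j) the feature vector is the concatenation, in fixed order,
of five blocks:

* Type 1 of d_i and of t_j: observation count (``n.obs``), mean similarity to
  all entities of the same kind including self (``ave.sim``), histogram of the
  similarity row over equal-width bins on [0, 1] (``hist.sim``), and mean
  observed affinity (``ave.val``).
* Type 2 of d_i and of t_j, computed on the thresholded similarity graph:
  degree (``num.nb``), top-k neighbour similarities (``k.sim``), unweighted and
  similarity-weighted means of the neighbours' Type-1 vectors (``k.ave.feat``,
  ``k.w.ave.feat``), and node scores ``bt``, ``cl``, ``ev``, ``pr``.
* Type 3 of the pair: matrix-factorization latent columns (``mf``),
  read-across averages ``d.t.ave`` / ``t.d.ave``, and the drug and target
  node scores on the bipartite affinity network (``d.t.bt`` ... ``d.t.pr``).

Statistics undefined for an entity (e.g. ``ave.val`` of a drug with no
training observation) are NaN -- the missing marker the gradient-boosted trees
route natively -- never an imputed constant.

All features derive from the *training* observations, D and T only: held-out
affinities cannot leak into any feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import AffinityMatrix, SimilarityMatrix
from .errors import ConfigError, DataFormatError
from .graph_features import (build_bipartite_graph, build_similarity_graph,
                             knn_summary, node_centralities,
                             pair_network_averages)
from .matrix_factorization import MatrixFactorization

__all__ = ["FeatureSchema", "PairFeaturizer", "type1_features", "assemble"]

_CENTRALITY_KEYS = ("bt", "cl", "ev", "pr")


@dataclass
class FeatureSchema:
    """Ordered feature layout shared by every pair of a run."""

    blocks: list[tuple[str, int]]
    names: list[str]

    @property
    def total_length(self) -> int:
        return len(self.names)


def _type1_names(n_bins: int) -> list[str]:
    return (["n.obs", "ave.sim"]
            + [f"hist.sim.{b + 1}" for b in range(n_bins)]
            + ["ave.val"])


def _build_schema(n_bins: int, k: int, mf_rank: int) -> FeatureSchema:
    t1 = _type1_names(n_bins)
    names: list[str] = []
    blocks: list[tuple[str, int]] = []

    def add(block: str, cols: list[str]) -> None:
        blocks.append((block, len(cols)))
        names.extend(cols)

    add("type1.drug", [f"d.{c}" for c in t1])
    add("type1.target", [f"t.{c}" for c in t1])
    for side in ("d", "t"):
        t2 = ([f"{side}.num.nb"]
              + [f"{side}.k.sim.{r + 1}" for r in range(k)]
              + [f"{side}.k.ave.feat.{c}" for c in t1]
              + [f"{side}.k.w.ave.feat.{c}" for c in t1]
              + [f"{side}.{c}" for c in _CENTRALITY_KEYS])
        add(f"type2.{'drug' if side == 'd' else 'target'}", t2)
    t3 = ([f"mf.d.{r + 1}" for r in range(mf_rank)]
          + [f"mf.t.{r + 1}" for r in range(mf_rank)]
          + ["d.t.ave", "t.d.ave"]
          + [f"d.t.{c}.drug" for c in _CENTRALITY_KEYS]
          + [f"d.t.{c}.target" for c in _CENTRALITY_KEYS])
    add("type3.pair", t3)
    return FeatureSchema(blocks, names)


def type1_features(m_train: AffinityMatrix, s: SimilarityMatrix, entity_id: str,
                   n_bins: int, axis: str) -> np.ndarray:
    """Type-1 vector for one drug (``axis='drug'``) or target (``axis='target'``)."""
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    sim_row = s.row(entity_id)
    if axis == "drug":
        i = m_train.drug_index(entity_id)
        obs = m_train.observed[i]
        vals = m_train.values[i, obs]
    elif axis == "target":
        j = m_train.target_index(entity_id)
        obs = m_train.observed[:, j]
        vals = m_train.values[obs, j]
    else:
        raise ConfigError("axis must be 'drug' or 'target'")
    hist, _ = np.histogram(sim_row, bins=np.linspace(0.0, 1.0, n_bins + 1))
    ave_val = float(vals.mean()) if vals.size else np.nan
    return np.concatenate([
        [float(obs.sum()), float(sim_row.mean())],
        hist.astype(float),
        [ave_val],
    ])


class PairFeaturizer(BaseEstimator, TransformerMixin):
    """Fit the feature-engineering state on (M_train, D, T); transform pairs.

    Parameters
    ----------
    sim_threshold : similarity above which an edge exists in the Type-2 graphs.
    knn_k : number of nearest neighbours for the k-NN summaries.
    n_bins : similarity-histogram bins on [0, 1].
    mf_rank, mf_reg_lambda, mf_learning_rate, mf_n_epochs : matrix-factorization
        hyperparameters for the Type-3 latent features.
    seed : drives matrix-factorization initialisation and shuffling.

    ``fit`` takes the triple ``(M_train, D, T)``; ``transform`` takes a list of
    ``(drug_id, target_id)`` pairs and returns a DataFrame whose columns follow
    ``schema_.names``.
    """

    def __init__(self, sim_threshold: float = 0.5, knn_k: int = 5,
                 n_bins: int = 10, mf_rank: int = 10,
                 mf_reg_lambda: float = 0.01, mf_learning_rate: float = 0.01,
                 mf_n_epochs: int = 100, seed: int = 0):
        self.sim_threshold = sim_threshold
        self.knn_k = knn_k
        self.n_bins = n_bins
        self.mf_rank = mf_rank
        self.mf_reg_lambda = mf_reg_lambda
        self.mf_learning_rate = mf_learning_rate
        self.mf_n_epochs = mf_n_epochs
        self.seed = seed

    def fit(self, data: tuple[AffinityMatrix, SimilarityMatrix, SimilarityMatrix],
            y=None) -> "PairFeaturizer":
        m_train, d_sim, t_sim = data
        if d_sim.ids != m_train.drug_ids:
            raise DataFormatError("drug similarity ids do not match affinity drug ids")
        if t_sim.ids != m_train.target_ids:
            raise DataFormatError("target similarity ids do not match affinity target ids")
        self.m_train_ = m_train
        self.d_sim_ = d_sim
        self.t_sim_ = t_sim

        self.drug_graph_ = build_similarity_graph(d_sim, self.sim_threshold)
        self.target_graph_ = build_similarity_graph(t_sim, self.sim_threshold)

        self.type1_drug_ = {d: type1_features(m_train, d_sim, d, self.n_bins, "drug")
                            for d in m_train.drug_ids}
        self.type1_target_ = {t: type1_features(m_train, t_sim, t, self.n_bins, "target")
                              for t in m_train.target_ids}

        drug_cent = node_centralities(self.drug_graph_)
        target_cent = node_centralities(self.target_graph_)
        self.type2_drug_ = {
            d: self._type2_vector(d_sim, self.drug_graph_, self.type1_drug_,
                                  drug_cent, d)
            for d in m_train.drug_ids}
        self.type2_target_ = {
            t: self._type2_vector(t_sim, self.target_graph_, self.type1_target_,
                                  target_cent, t)
            for t in m_train.target_ids}

        self.mf_model_ = MatrixFactorization(
            rank=self.mf_rank, reg_lambda=self.mf_reg_lambda,
            learning_rate=self.mf_learning_rate, n_epochs=self.mf_n_epochs,
            seed=self.seed).fit(m_train)

        bipartite = build_bipartite_graph(m_train)
        self.bipartite_scores_ = node_centralities(bipartite)

        self.schema_ = _build_schema(self.n_bins, self.knn_k, self.mf_rank)
        return self

    def _type2_vector(self, s, graph, type1_table, centralities, node) -> np.ndarray:
        knn = knn_summary(s, graph, node, self.knn_k, type1_table)
        cent = centralities[node]
        return np.concatenate([
            [float(knn["num_nb"])],
            knn["k_sim"],
            knn["k_ave_feat"],
            knn["k_w_ave_feat"],
            [cent[c] for c in _CENTRALITY_KEYS],
        ])

    def _type3_vector(self, drug_id: str, target_id: str) -> np.ndarray:
        mf = self.mf_model_.latent_features(drug_id, target_id)
        d_t_ave, t_d_ave = pair_network_averages(
            self.m_train_, self.drug_graph_, self.target_graph_,
            drug_id, target_id)
        dc = self.bipartite_scores_[("drug", drug_id)]
        tc = self.bipartite_scores_[("target", target_id)]
        return np.concatenate([
            mf, [d_t_ave, t_d_ave],
            [dc[c] for c in _CENTRALITY_KEYS],
            [tc[c] for c in _CENTRALITY_KEYS],
        ])

    def transform(self, pairs: list[tuple[str, str]]) -> pd.DataFrame:
        if not hasattr(self, "schema_"):
            raise ConfigError("PairFeaturizer instance is not fitted")
        unknown = [(d, t) for d, t in pairs
                   if d not in self.type1_drug_ or t not in self.type1_target_]
        if unknown:
            raise KeyError(f"unknown drug/target ids in pairs: {unknown}")
        rows = np.empty((len(pairs), self.schema_.total_length))
        for r, (d, t) in enumerate(pairs):
            rows[r] = np.concatenate([
                self.type1_drug_[d], self.type1_target_[t],
                self.type2_drug_[d], self.type2_target_[t],
                self._type3_vector(d, t),
            ])
        index = pd.MultiIndex.from_tuples(pairs, names=["drug", "target"])
        return pd.DataFrame(rows, index=index, columns=self.schema_.names)

    def labels(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """Observed training affinities for the given pairs (NaN if unobserved)."""
        m = self.m_train_
        return np.array([
            m.values[m.drug_index(d), m.target_index(t)] for d, t in pairs
        ])


def assemble(m_train: AffinityMatrix, d_sim: SimilarityMatrix,
             t_sim: SimilarityMatrix, pairs: list[tuple[str, str]],
             **featurizer_params) -> tuple[FeatureSchema, pd.DataFrame]:
    """One-shot featurization: fit a :class:`PairFeaturizer` and transform pairs."""
    fz = PairFeaturizer(**featurizer_params).fit((m_train, d_sim, t_sim))
    return fz.schema_, fz.transform(pairs)
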