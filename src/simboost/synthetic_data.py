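"""Synthetic (M, D, T) triples with the structure read-across methods assume.

Real kinase-panel benchmarks share three statistical features this generator
reproduces: (1) a partially observed affinity matrix whose signal is low-rank
plus a non-linear component; (2) cluster-structured drug-drug and
target-target similarity matrices in [0, 1] with unit diagonal (compounds come
in chemical series, kinases in families); (3) a long right tail in the
affinity distribution with a spike at a non-binding baseline (the assay
detection floor).

Drugs and targets are assigned to clusters; each entity's latent vector is its
cluster centroid plus Gaussian jitter.  The noiseless affinity for pair (i, j)
with latent vectors u, v and per-entity main effects a_i, b_j is

    baseline + a_i + b_j + softplus(u . v) + nonlinear_weight * sin(u . v)
        + idiosyncratic terms

The main effects emulate promiscuous targets and sticky compounds -- the
dominant signal in real panels, which read-across features (per-entity average
affinity) capture directly -- while the softplus/sin terms add low-rank and
non-linear interaction structure.  The idiosyncratic terms carry per-entity
interaction quirks that similarities cannot predict (they are only learnable
from an entity's own observations), so sparse entities are genuinely harder --
the premise of interval widths shrinking with observation count.  Similarities are cosine similarities of the
latent vectors rescaled from [-1, 1] to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AffinityMatrix, SimilarityMatrix
from .errors import ConfigError, NumericalError

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset"]

_MAX_MASK_REDRAWS = 100


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a small sparse kinase selectivity panel: 100 compounds,
    60 targets, 25% of cells measured with long-tailed per-entity observation
    counts, affinities on a pK-like scale with a non-binding baseline of 5 and
    assay noise of 0.3 log units.
    """

    n_drugs: int = 100
    n_targets: int = 60
    latent_rank: int = 5
    n_drug_clusters: int = 5
    n_target_clusters: int = 4
    density: float = 0.25
    obs_heterogeneity: float = 0.8  # log-normal sd of per-entity observation propensity
    noise_sd: float = 0.3
    nonlinear_weight: float = 1.0
    baseline: float = 5.0
    entity_effect_sd: float = 0.5  # sd of per-drug / per-target main effects
    idiosyncrasy: float = 0.4  # sd of entity-idiosyncratic interaction terms
    cluster_spread: float = 0.3  # sd of per-entity jitter around the centroid
    seed: int = 0

    def validate(self) -> None:
        if self.n_drugs < 1 or self.n_targets < 1:
            raise ConfigError("n_drugs and n_targets must be >= 1")
        if not (1 <= self.latent_rank <= min(self.n_drugs, self.n_targets)):
            raise ConfigError("latent_rank must be in [1, min(n_drugs, n_targets)]")
        if not (1 <= self.n_drug_clusters <= self.n_drugs):
            raise ConfigError("n_drug_clusters must be in [1, n_drugs]")
        if not (1 <= self.n_target_clusters <= self.n_targets):
            raise ConfigError("n_target_clusters must be in [1, n_targets]")
        if not (0.0 < self.density <= 1.0):
            raise ConfigError("density must be in (0, 1]")
        if min(self.noise_sd, self.nonlinear_weight, self.cluster_spread,
               self.entity_effect_sd, self.obs_heterogeneity,
               self.idiosyncrasy) < 0:
            raise ConfigError("noise_sd, nonlinear_weight, cluster_spread, "
                              "entity_effect_sd, obs_heterogeneity and "
                              "idiosyncrasy must be >= 0")


@dataclass
class GroundTruth:
    """Noiseless affinities and the latent structure behind a synthetic dataset."""

    true_values: np.ndarray            # n_drugs x n_targets, noiseless
    drug_latents: np.ndarray           # n_drugs x latent_rank
    target_latents: np.ndarray         # n_targets x latent_rank
    drug_effects: np.ndarray           # additive main effect per drug
    target_effects: np.ndarray         # additive main effect per target
    drug_clusters: np.ndarray          # cluster index per drug
    target_clusters: np.ndarray        # cluster index per target


def _softplus(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(x))
    return np.logaddexp(0.0, x)


def _cluster_latents(rng: np.random.Generator, n: int, n_clusters: int,
                     rank: int, spread: float) -> tuple[np.ndarray, np.ndarray]:
    centroids = rng.normal(0.0, 1.0, size=(n_clusters, rank))
    assignment = rng.permutation(np.arange(n) % n_clusters)
    latents = centroids[assignment] + rng.normal(0.0, spread, size=(n, rank))
    return latents, assignment


def _cosine_similarity_matrix(latents: np.ndarray, ids: list[str]) -> SimilarityMatrix:
    norms = np.linalg.norm(latents, axis=1)
    norms[norms == 0] = 1.0
    unit = latents / norms[:, None]
    cos = unit @ unit.T
    sim = (np.clip(cos, -1.0, 1.0) + 1.0) / 2.0
    sim = 0.5 * (sim + sim.T)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, ids)


def _draw_mask(rng: np.random.Generator, shape: tuple[int, int], density: float,
               heterogeneity: float) -> np.ndarray:
    """Per-cell Bernoulli mask with per-entity observation propensities.

    Each drug and target carries a log-normal propensity so per-entity
    observation counts are long-tailed, as in real panels (a few heavily
    assayed entities, many sparsely tested ones).  The cell probability is the
    global density scaled by the normalised propensity product.  Entities left
    with fewer than two observations are topped up with forced draws (real
    benchmarks likewise guarantee a minimum per-entity coverage by filtering),
    so the cross-validation fold constraint always holds.
    """
    n_rows, n_cols = shape
    min_row = min(2, n_cols)
    min_col = min(2, n_rows)
    if density >= 1.0:
        return np.ones(shape, dtype=bool)
    for _ in range(_MAX_MASK_REDRAWS):
        row_prop = rng.lognormal(0.0, heterogeneity, size=n_rows) if heterogeneity > 0 \
            else np.ones(n_rows)
        col_prop = rng.lognormal(0.0, heterogeneity, size=n_cols) if heterogeneity > 0 \
            else np.ones(n_cols)
        prob = density * np.outer(row_prop, col_prop)
        # renormalise after clipping so the realised density matches `density`
        target_total = density * prob.size
        for _ in range(20):
            prob = np.clip(prob * (target_total / prob.sum()), 0.0, 1.0)
            if abs(prob.sum() - target_total) < 0.5:
                break
        mask = rng.random(shape) < prob
        for i in np.nonzero(mask.sum(axis=1) < min_row)[0]:
            missing = np.nonzero(~mask[i])[0]
            add = rng.choice(missing, size=min_row - int(mask[i].sum()), replace=False)
            mask[i, add] = True
        for j in np.nonzero(mask.sum(axis=0) < min_col)[0]:
            missing = np.nonzero(~mask[:, j])[0]
            add = rng.choice(missing, size=min_col - int(mask[:, j].sum()), replace=False)
            mask[add, j] = True
        if (mask.sum(axis=1).min() >= min_row and mask.sum(axis=0).min() >= min_col):
            return mask
    raise NumericalError(
        f"could not satisfy the >=2-observations-per-entity constraint at "
        f"density {density} after {_MAX_MASK_REDRAWS} attempts"
    )


def generate_dataset(cfg: SyntheticConfig) -> tuple[
        AffinityMatrix, SimilarityMatrix, SimilarityMatrix, GroundTruth]:
    """Generate one (M, D, T, ground truth) quadruple.

    A fixed seed yields bitwise-identical output: all randomness flows through
    a single ``numpy.random.default_rng(cfg.seed)`` stream.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    drug_latents, drug_clusters = _cluster_latents(
        rng, cfg.n_drugs, cfg.n_drug_clusters, cfg.latent_rank, cfg.cluster_spread)
    target_latents, target_clusters = _cluster_latents(
        rng, cfg.n_targets, cfg.n_target_clusters, cfg.latent_rank, cfg.cluster_spread)

    drug_effects = rng.normal(0.0, cfg.entity_effect_sd, size=cfg.n_drugs)
    target_effects = rng.normal(0.0, cfg.entity_effect_sd, size=cfg.n_targets)

    dot = drug_latents @ target_latents.T
    true_values = (cfg.baseline + drug_effects[:, None] + target_effects[None, :]
                   + _softplus(dot) + cfg.nonlinear_weight * np.sin(dot))
    if cfg.idiosyncrasy > 0:
        # entity-idiosyncratic interaction structure, independent of D and T:
        # random per-target (per-drug) loadings on the partner's latents, so it
        # is learnable only from the entity's own observed cells
        t_load = rng.normal(size=(cfg.n_targets, cfg.latent_rank))
        d_load = rng.normal(size=(cfg.n_drugs, cfg.latent_rank))
        g = drug_latents @ t_load.T
        h = d_load @ target_latents.T
        true_values += cfg.idiosyncrasy * (g / g.std() + h / h.std())

    mask = _draw_mask(rng, (cfg.n_drugs, cfg.n_targets), cfg.density,
                      cfg.obs_heterogeneity)
    noise = rng.normal(0.0, cfg.noise_sd, size=true_values.shape) if cfg.noise_sd > 0 \
        else np.zeros_like(true_values)
    values = np.where(mask, true_values + noise, np.nan)

    width_d = len(str(cfg.n_drugs))
    width_t = len(str(cfg.n_targets))
    drug_ids = [f"d{i + 1:0{width_d}d}" for i in range(cfg.n_drugs)]
    target_ids = [f"t{j + 1:0{width_t}d}" for j in range(cfg.n_targets)]

    m = AffinityMatrix(values, mask, drug_ids, target_ids)
    d_sim = _cosine_similarity_matrix(drug_latents, drug_ids)
    t_sim = _cosine_similarity_matrix(target_latents, target_ids)
    gt = GroundTruth(true_values, drug_latents, target_latents,
                     drug_effects, target_effects,
                     drug_clusters, target_clusters)
    return m, d_sim, t_sim, gt
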