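"""PCA with a cumulative-variance cutoff and 4-D UMAP feature extraction.

PCA is run on the min–max normalized matrix with column centering
(covariance PCA — normalization has already equalized scales); the number
of retained components is the smallest k whose cumulative explained
variance reaches the threshold (default 95%). UMAP embeds the normalized
matrix into four features ("Feature 1"–"Feature 4") with a 5-neighbor
graph and zero minimum embedding distance; given a seed the embedding is
deterministic, but coordinates are meaningful only up to the algorithm's
stochasticity, so downstream checks compare cluster recovery, never raw
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DomainError
from .preprocess import FeatureMatrix

__all__ = ["PCAResult", "EmbeddingMatrix", "pca_fit", "umap_embed",
           "UMAP_N_COMPONENTS", "UMAP_N_NEIGHBORS", "UMAP_MIN_DIST"]

UMAP_N_COMPONENTS = 4
UMAP_N_NEIGHBORS = 5
UMAP_MIN_DIST = 0.0


@dataclass
class PCAResult:
    """Loadings (p×k), scores (N×k), per-component explained-variance
    ratios over the k retained components, their cumulative sum, and the
    full-spectrum ratios for diagnostics."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    cumulative: float
    all_ratios: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class EmbeddingMatrix:
    """N×4 UMAP features plus the hyperparameters and seed that made them."""

    features: pd.DataFrame
    sample_meta: pd.DataFrame
    hyperparameters: dict
    seed: int


def pca_fit(
    M: FeatureMatrix,
    variance_threshold: float = 0.95,
    use_correlation: bool = False,
) -> PCAResult:
    """Principal components of the (centered) normalized feature matrix.

    k is the smallest component count whose cumulative explained variance
    is ≥ ``variance_threshold``; rank-deficient input retains at most the
    rank, with a warning. Each loading column is sign-fixed so its
    largest-magnitude element is positive. ``use_correlation`` switches to
    correlation-matrix PCA (columns additionally scaled to unit variance).
    """
    X = M.values.to_numpy(dtype=float)
    if use_correlation:
        stds = X.std(axis=0, ddof=1)
        if np.any(stds == 0):
            raise DomainError("correlation PCA undefined with constant columns")
        X = X / stds
    model = PCA(n_components=None)
    scores_full = model.fit_transform(X)
    ratios = model.explained_variance_ratio_
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    if rank < X.shape[1]:
        warnings.warn(
            f"input is rank-deficient (rank {rank} < {X.shape[1]} columns); "
            f"at most {rank} informative components exist",
            stacklevel=2,
        )
        k = min(k, rank)

    loadings = model.components_[:k].T  # p×k
    scores = scores_full[:, :k]
    # reproducible sign convention: dominant element of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    pc_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=M.values.columns, columns=pc_names),
        scores=pd.DataFrame(scores, columns=pc_names),
        explained_variance_ratio=ratios[:k].copy(),
        cumulative=float(cum[k - 1]),
        all_ratios=ratios.copy(),
    )


def umap_embed(M: FeatureMatrix, seed: int = 42) -> EmbeddingMatrix:
    """Embed the normalized matrix into 4 UMAP features.

    Hyperparameters: n_components=4, n_neighbors=5, min_dist=0. The seed
    is recorded on the result and makes repeated runs identical.
    """
    import umap  # deferred: numba compilation is slow to import

    X = M.values.to_numpy(dtype=float)
    if X.shape[0] < UMAP_N_NEIGHBORS + 1:
        raise DomainError(
            f"UMAP needs at least {UMAP_N_NEIGHBORS + 1} samples, got {X.shape[0]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=UMAP_N_COMPONENTS,
            n_neighbors=UMAP_N_NEIGHBORS,
            min_dist=UMAP_MIN_DIST,
            random_state=seed,
        )
        emb = reducer.fit_transform(X)
    features = pd.DataFrame(
        emb, columns=[f"Feature{i + 1}" for i in range(UMAP_N_COMPONENTS)]
    )
    return EmbeddingMatrix(
        features=features,
        sample_meta=M.sample_meta.reset_index(drop=True),
        hyperparameters={
            "n_components": UMAP_N_COMPONENTS,
            "n_neighbors": UMAP_N_NEIGHBORS,
            "min_dist": UMAP_MIN_DIST,
        },
        seed=seed,
    )
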