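"""Fuzzy C-means with genetic-algorithm centroid initialization.

The model minimizes the fuzzified within-cluster scatter

    J = Σ_j Σ_i  u_ij^m  ||x_j − v_i||²,    m > 1,

by the standard alternating stationarity updates

    u_ij = 1 / Σ_k (d_ij / d_kj)^(2/(m−1)),
    v_i  = Σ_j u_ij^m x_j / Σ_j u_ij^m.

Plain FCM seeds centroids with randomly chosen samples, which can leave
the iteration in a poor basin; the GA variant instead evolves real-valued
chromosomes (flattened C×d centroid candidates) against a
nearest-centroid distance fitness and hands the best individual to FCM as
the initial centroids.  Four model variants mirror the comparison the
pipeline is built around: FCM on all 15 parameters, ChlF-FCM on the four
chilling-sensitive parameters (Fv/Fm, Fo, Y(NO), qP), PCA-FCM on the
retained principal components, and UMAP-GA-FCM on the four UMAP features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chlf import FEATURE_NAMES
from .dimred import pca_fit, umap_embed
from .errors import DomainError
from .preprocess import FeatureMatrix

__all__ = [
    "FCMConfig", "FCMState", "GAConfig", "ClassificationResult",
    "fcm_fit", "fcm_objective", "memberships_for_centroids",
    "random_init_centroids", "ga_optimize_centroids", "assign_classes",
    "run_variant", "VARIANTS", "CHLF_SUBSET", "SEVERITY_NAMES",
]

#: The four chilling-sensitive parameters used by the ChlF-FCM variant,
#: in their stated order.
CHLF_SUBSET = ("Fv_Fm", "Fo", "Y_NO", "qP")

SEVERITY_NAMES = ("unstressed", "slight", "moderate", "severe")

VARIANTS = ("FCM", "ChlF-FCM", "PCA-FCM", "UMAP-GA-FCM")


@dataclass
class FCMConfig:
    n_clusters: int = 4
    fuzzifier: float = 2.0  # m > 1
    tol: float = 1e-5       # max-abs membership change to declare convergence
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.fuzzifier <= 1:
            raise DomainError(f"fuzzifier m must be > 1, got {self.fuzzifier}")
        if self.n_clusters < 2:
            raise DomainError(f"need at least 2 clusters, got {self.n_clusters}")


@dataclass
class GAConfig:
    population_size: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    generations: int = 50
    elitism: int = 1
    seed: int = 0
    fitness: str = "crisp"  # "crisp" nearest-centroid SSQ or "fuzzy" Eq-style J

    def __post_init__(self) -> None:
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{name} must be in [0,1], got {p}")
        if self.fitness not in ("crisp", "fuzzy"):
            raise DomainError(f"unknown fitness kind: {self.fitness!r}")


@dataclass
class FCMState:
    membership: np.ndarray          # N×C, rows sum to 1
    centroids: np.ndarray           # C×d
    objective_trajectory: np.ndarray  # J per update cycle, prefixed by J_init
    initial_error: float
    iterations: int
    converged: bool


@dataclass
class ClassificationResult:
    class_labels: np.ndarray        # N ints in {0..3}
    cluster_to_class: dict[int, int]
    memberships: np.ndarray         # N×C, columns in *class* order
    severity_names: tuple[str, ...] = SEVERITY_NAMES


def _sq_distances(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """N×C matrix of squared Euclidean distances."""
    diff = X[:, None, :] - V[None, :, :]
    return np.einsum("ncd,ncd->nc", diff, diff)


def memberships_for_centroids(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix induced by fixed centroids (the U-update).

    A sample coincident with a centroid gets membership 1 there (and 0
    elsewhere), avoiding the division by zero distance.
    """
    d2 = _sq_distances(X, V)
    zero = d2 <= 0.0
    U = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** -power  # (1/d²)^(1/(m-1))
        U = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():
        U[hit] = 0.0
        # ties (sample equidistant-zero to several centroids) split evenly
        U[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    return U


def fcm_objective(X: np.ndarray, U: np.ndarray, V: np.ndarray, m: float) -> float:
    """The fuzzified within-cluster scatter J(U, V)."""
    return float((U ** m * _sq_distances(X, V)).sum())


def fcm_fit(X: np.ndarray, config: FCMConfig, init_centroids: np.ndarray) -> FCMState:
    """Alternating FCM optimization from explicit initial centroids.

    ``initial_error`` is J evaluated at the initial centroids with the
    memberships they induce, before any centroid update (the "initial
    movement error" of the variant comparison).  The objective is recorded
    after every full (U, V) update cycle; iteration stops when the
    max-abs membership change drops below ``tol`` or at ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DomainError("X must be a 2-D matrix")
    if np.isnan(X).any():
        raise DomainError("X contains NaN")
    V = np.array(init_centroids, dtype=float, copy=True)
    if V.shape[1] != X.shape[1]:
        raise DomainError(
            f"centroid dimension {V.shape[1]} != data dimension {X.shape[1]}"
        )
    if len(np.unique(V, axis=0)) != len(V):
        raise DomainError("initial centroids must be distinct")

    m = config.fuzzifier
    U = memberships_for_centroids(X, V, m)
    initial_error = fcm_objective(X, U, V, m)
    trajectory = [initial_error]

    converged = False
    iterations = 0
    for _ in range(config.max_iter):
        Um = U ** m
        weights = Um.sum(axis=0)
        if np.any(weights == 0):
            # dead cluster: keep its previous centroid
            V_new = V.copy()
            ok = weights > 0
            V_new[ok] = (Um.T[ok] @ X) / weights[ok, None]
        else:
            V_new = (Um.T @ X) / weights[:, None]
        U_new = memberships_for_centroids(X, V_new, m)
        iterations += 1
        trajectory.append(fcm_objective(X, U_new, V_new, m))
        delta = float(np.abs(U_new - U).max())
        U, V = U_new, V_new
        if delta < config.tol:
            converged = True
            break

    return FCMState(
        membership=U,
        centroids=V,
        objective_trajectory=np.asarray(trajectory),
        initial_error=initial_error,
        iterations=iterations,
        converged=converged,
    )


def random_init_centroids(X: np.ndarray, C: int, rng: np.random.Generator) -> np.ndarray:
    """Plain-FCM initialization: C distinct samples drawn as centroids."""
    X = np.asarray(X, dtype=float)
    uniq = np.unique(X, axis=0)
    if len(uniq) < C:
        raise DomainError(f"fewer than {C} distinct samples to seed centroids")
    idx = rng.choice(len(uniq), size=C, replace=False)
    return uniq[idx].copy()


def _fitness(X: np.ndarray, pop: np.ndarray, C: int, d: int, kind: str, m: float) -> np.ndarray:
    """Fitness of each chromosome: 1/(1 + distortion)."""
    out = np.empty(len(pop))
    for i, chrom in enumerate(pop):
        V = chrom.reshape(C, d)
        d2 = _sq_distances(X, V)
        if kind == "crisp":
            distortion = float(d2.min(axis=1).sum())
        else:
            U = memberships_for_centroids(X, V, m)
            distortion = float((U ** m * d2).sum())
        out[i] = 1.0 / (1.0 + distortion)
    return out


def ga_optimize_centroids(
    X: np.ndarray,
    C: int,
    ga: GAConfig,
    fuzzifier: float = 2.0,
) -> np.ndarray:
    """Evolve initial centroids for FCM with a real-valued GA.

    Chromosomes are flattened C×d centroid candidates sampled uniformly
    within per-column data ranges.  Fitness is 1/(1 + Σ_j min_i ||x_j −
    v_i||²) (crisp nearest-centroid distortion; a fuzzy-J variant is
    selectable).  Fitness-proportionate (roulette) selection with elitism,
    arithmetic crossover, and per-gene Gaussian mutation with σ = 0.1 ×
    column range.  Returns the best chromosome of the final population as
    a C×d centroid matrix.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if C > n:
        raise DomainError(f"cannot place {C} centroids with only {n} samples")
    rng = np.random.default_rng(ga.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    genes = C * d

    pop = rng.uniform(np.tile(lo, C), np.tile(hi, C), size=(ga.population_size, genes))
    fit = _fitness(X, pop, C, d, ga.fitness, fuzzifier)

    for _ in range(ga.generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: ga.elitism]].copy()

        probs = fit / fit.sum()
        parents_idx = rng.choice(len(pop), size=ga.population_size, p=probs)
        children = pop[parents_idx].copy()

        # arithmetic crossover on consecutive pairs
        for a in range(0, ga.population_size - 1, 2):
            if rng.random() < ga.crossover_prob:
                lam = rng.random()
                pa, pb = children[a].copy(), children[a + 1].copy()
                children[a] = lam * pa + (1 - lam) * pb
                children[a + 1] = (1 - lam) * pa + lam * pb

        # per-gene Gaussian mutation, σ = 0.1 × column range
        mask = rng.random(children.shape) < ga.mutation_prob
        noise = rng.normal(0.0, 1.0, children.shape) * (0.1 * np.tile(span, C))
        children = children + mask * noise

        children[: ga.elitism] = elite
        pop = children
        fit = _fitness(X, pop, C, d, ga.fitness, fuzzifier)

    best = pop[int(np.argmax(fit))].reshape(C, d)
    # nudge coincident centroids apart so FCM's distinctness precondition holds
    if len(np.unique(best, axis=0)) < C:
        best = best + rng.normal(0.0, 1e-9, best.shape)
    return best


def ga_fitness_history(
    X: np.ndarray, C: int, ga: GAConfig, fuzzifier: float = 2.0
) -> np.ndarray:
    """Best fitness per generation (diagnostic; non-decreasing under
    elitism).  Mirrors :func:`ga_optimize_centroids` exactly."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(ga.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    genes = C * d
    pop = rng.uniform(np.tile(lo, C), np.tile(hi, C), size=(ga.population_size, genes))
    fit = _fitness(X, pop, C, d, ga.fitness, fuzzifier)
    history = [float(fit.max())]
    for _ in range(ga.generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: ga.elitism]].copy()
        probs = fit / fit.sum()
        parents_idx = rng.choice(len(pop), size=ga.population_size, p=probs)
        children = pop[parents_idx].copy()
        for a in range(0, ga.population_size - 1, 2):
            if rng.random() < ga.crossover_prob:
                lam = rng.random()
                pa, pb = children[a].copy(), children[a + 1].copy()
                children[a] = lam * pa + (1 - lam) * pb
                children[a + 1] = (1 - lam) * pa + lam * pb
        mask = rng.random(children.shape) < ga.mutation_prob
        noise = rng.normal(0.0, 1.0, children.shape) * (0.1 * np.tile(span, C))
        children = children + mask * noise
        children[: ga.elitism] = elite
        pop = children
        fit = _fitness(X, pop, C, d, ga.fitness, fuzzifier)
        history.append(float(fit.max()))
    return np.asarray(history)


def assign_classes(state: FCMState, severity_proxy: np.ndarray) -> ClassificationResult:
    """Order clusters by decreasing cluster-mean severity proxy (default
    proxy is each sample's Fv/Fm) and map them to severity classes 0–3
    (unstressed → severe).  Ties broken by cluster index; hard labels are
    the argmax memberships.
    """
    U = state.membership
    C = U.shape[1]
    proxy = np.asarray(severity_proxy, dtype=float)
    if len(proxy) != U.shape[0]:
        raise DomainError("severity proxy length != sample count")
    hard = U.argmax(axis=1)
    means = np.full(C, -np.inf)
    for c in range(C):
        members = hard == c
        if members.any():
            means[c] = proxy[members].mean()
    n_nonempty = int(np.isfinite(means).sum())
    if n_nonempty < C:
        warnings.warn(
            f"only {n_nonempty} of {C} clusters are non-empty; "
            "classes assigned to non-empty clusters only",
            stacklevel=2,
        )
    # healthy (high Fv/Fm) first; ties → lower cluster index less severe
    order = sorted(range(C), key=lambda c: (-means[c], c))
    cluster_to_class = {cluster: cls for cls, cluster in enumerate(order)}
    labels = np.array([cluster_to_class[c] for c in hard])
    memberships_by_class = U[:, order]
    return ClassificationResult(
        class_labels=labels,
        cluster_to_class=cluster_to_class,
        memberships=memberships_by_class,
    )


def _scale01(X: np.ndarray) -> np.ndarray:
    """Column-wise min–max scaling of a model input representation.

    Every variant's input is mapped onto [0,1] per column before
    clustering, so the fuzzified objectives (and hence the initial
    movement errors) of different representations are on comparable
    scales.  Degenerate (constant) columns map to 0."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def run_variant(
    M: FeatureMatrix,
    variant: str,
    seed: int,
    severity_proxy: np.ndarray | None = None,
    fcm_config: FCMConfig | None = None,
    ga_config: GAConfig | None = None,
    pca_threshold: float = 0.95,
) -> tuple[ClassificationResult, dict]:
    """Run one model variant over a preprocessed (normalized) matrix.

    Input representation per variant: ``FCM`` — all 15 parameters;
    ``ChlF-FCM`` — Fv/Fm, Fo, Y(NO), qP; ``PCA-FCM`` — the retained PCs;
    ``UMAP-GA-FCM`` — the four UMAP features with GA-optimized initial
    centroids (the other variants draw random sample centroids).  Each
    representation is column-wise min–max scaled (see :func:`_scale01`)
    so objectives are comparable across variants.

    Returns the classification plus a diagnostics dict with the initial
    movement error, iteration count, objective trajectory, and seeds.
    """
    if variant not in VARIANTS:
        raise DomainError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    fcm_config = fcm_config or FCMConfig()
    rng = np.random.default_rng(seed)

    if variant == "FCM":
        X = M.values[list(FEATURE_NAMES)].to_numpy(dtype=float)
    elif variant == "ChlF-FCM":
        X = M.values[list(CHLF_SUBSET)].to_numpy(dtype=float)
    elif variant == "PCA-FCM":
        X = _scale01(pca_fit(M, variance_threshold=pca_threshold).scores.to_numpy(dtype=float))
    else:  # UMAP-GA-FCM
        X = _scale01(umap_embed(M, seed=seed).features.to_numpy(dtype=float))

    if variant == "UMAP-GA-FCM":
        ga_config = ga_config or GAConfig(seed=seed)
        init = ga_optimize_centroids(X, fcm_config.n_clusters, ga_config,
                                     fuzzifier=fcm_config.fuzzifier)
    else:
        init = random_init_centroids(X, fcm_config.n_clusters, rng)

    state = fcm_fit(X, fcm_config, init)
    if severity_proxy is None:
        severity_proxy = M.values["Fv_Fm"].to_numpy(dtype=float)
    result = assign_classes(state, severity_proxy)
    diagnostics = {
        "variant": variant,
        "seed": seed,
        "n_samples": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "initial_error": state.initial_error,
        "iterations": state.iterations,
        "converged": bool(state.converged),
        "objective_trajectory": state.objective_trajectory.tolist(),
        "fcm_config": {
            "n_clusters": fcm_config.n_clusters,
            "fuzzifier": fcm_config.fuzzifier,
            "tol": fcm_config.tol,
            "max_iter": fcm_config.max_iter,
        },
    }
    if variant == "UMAP-GA-FCM":
        diagnostics["ga_config"] = {
            "population_size": ga_config.population_size,
            "crossover_prob": ga_config.crossover_prob,
            "mutation_prob": ga_config.mutation_prob,
            "generations": ga_config.generations,
            "elitism": ga_config.elitism,
            "seed": ga_config.seed,
            "fitness": ga_config.fitness,
        }
    return result, diagnostics
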