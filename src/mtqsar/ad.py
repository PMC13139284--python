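"""Applicability domain by k-NN Tanimoto distances, plus validated
t-SNE chemical-space projections.

The domain is defined on the training set's mean k-nearest-neighbor
Tanimoto distances (k = 3 by default, self-distances excluded): the
threshold is the 95% quantile of that in-sample distribution -- the
upper edge of the dense core of the training space -- and a query is
inside the domain when its mean k-NN distance does not exceed it.

Projection validation sweeps t-SNE over a perplexity x seed grid and
scores every run by trustworthiness (neighborhood preservation),
Procrustes disparity against a per-perplexity reference run (geometric
stability across initializations), and silhouette (cluster coherence).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from sklearn.manifold import TSNE
from sklearn.manifold import trustworthiness as _sk_trustworthiness
from sklearn.metrics import silhouette_score

from .featurize import tanimoto_distance_matrix

DEFAULT_K = 3
DEFAULT_COVERAGE = 0.95
DEFAULT_KS = tuple(range(3, 30, 2))
DEFAULT_PERPLEXITIES = (10, 20, 30, 40, 50)
DEFAULT_SEEDS = (0, 42, 99)


@dataclasses.dataclass
class ADModel:
    """Fitted applicability domain: training fingerprints, neighbor
    count k, and the coverage-quantile distance threshold (linear
    interpolation between order statistics)."""

    training_fps: np.ndarray
    k: int
    threshold: float
    coverage: float
    training_distances: np.ndarray
    quantile_method: str = "linear"


def _cross_distances(query_fps: np.ndarray, training_fps: np.ndarray) -> np.ndarray:
    """(n_query, n_train) Tanimoto distances."""
    Q = np.asarray(query_fps, dtype=np.float64)
    T = np.asarray(training_fps, dtype=np.float64)
    inter = Q @ T.T
    union = Q.sum(axis=1)[:, None] + T.sum(axis=1)[None, :] - inter
    sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return np.clip(1.0 - sim, 0.0, 1.0)


def knn_mean_distance(
    query_fp: np.ndarray, training_fps: np.ndarray, k: int = DEFAULT_K
) -> float:
    """Mean of the k smallest Tanimoto distances from one query to the
    training set (out-of-sample: the query is not a training member)."""
    training_fps = np.atleast_2d(training_fps)
    if not 1 <= k <= training_fps.shape[0]:
        raise ValueError(f"k={k} exceeds available neighbors "
                         f"({training_fps.shape[0]})")
    d = _cross_distances(np.atleast_2d(query_fp), training_fps)[0]
    return float(np.sort(d)[:k].mean())


def insample_knn_distances(training_fps: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """Per-compound mean k-NN distance within the training set, with the
    zero self-distance excluded."""
    n = training_fps.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} requires a training set of > k compounds")
    D = tanimoto_distance_matrix(np.asarray(training_fps))
    D = D + np.diag(np.full(n, np.inf))  # exclude self
    part = np.partition(D, k - 1, axis=1)[:, :k]
    return part.mean(axis=1)


def k_sweep(
    training_fps: np.ndarray, ks: Sequence[int] = DEFAULT_KS
) -> pd.DataFrame:
    """Mean and variance of the in-sample mean-k-NN distance for each k.

    The mean is non-decreasing in k by construction (each increment adds
    an order statistic no smaller than those before it); this is
    asserted on the result.
    """
    n = np.asarray(training_fps).shape[0]
    if n <= max(ks):
        raise ValueError(f"training set of {n} too small for k={max(ks)}")
    D = tanimoto_distance_matrix(np.asarray(training_fps))
    D = D + np.diag(np.full(n, np.inf))
    Dsorted = np.sort(D, axis=1)
    rows = []
    for k in ks:
        per_compound = Dsorted[:, :k].mean(axis=1)
        rows.append(dict(k=int(k), mean=float(per_compound.mean()),
                         variance=float(per_compound.var(ddof=1))))
    table = pd.DataFrame(rows)
    assert np.all(np.diff(table["mean"]) >= -1e-12), \
        "mean k-NN distance must be non-decreasing in k"
    return table


def fit_threshold(
    training_fps: np.ndarray, k: int = DEFAULT_K,
    coverage: float = DEFAULT_COVERAGE,
    distances: np.ndarray | None = None,
) -> ADModel:
    """Fit the applicability domain threshold as the coverage quantile
    of the in-sample mean-k-NN distance distribution.

    ``distances`` overrides the in-sample computation with a precomputed
    distance sample (the fingerprints are then only stored for later
    classification).
    """
    training_fps = np.asarray(training_fps)
    if training_fps.shape[0] < 20:
        raise ValueError("need >= 20 training compounds to fit a threshold")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    dists = (np.asarray(distances, dtype=float) if distances is not None
             else insample_knn_distances(training_fps, k))
    threshold = float(np.quantile(dists, coverage, method="linear"))
    if threshold == 0.0:
        warnings.warn("degenerate training set: all k-NN distances zero, "
                      "threshold 0", stacklevel=2)
    return ADModel(training_fps=training_fps, k=k, threshold=threshold,
                   coverage=coverage, training_distances=dists)


def classify(ad: ADModel, query_fps: np.ndarray) -> pd.DataFrame:
    """Inside/outside labels plus audit distances for query compounds;
    inside means mean k-NN distance <= threshold (boundary inclusive)."""
    query_fps = np.atleast_2d(np.asarray(query_fps))
    D = _cross_distances(query_fps, ad.training_fps)
    part = np.partition(D, ad.k - 1, axis=1)[:, :ad.k]
    dists = part.mean(axis=1)
    return pd.DataFrame(
        dict(mean_knn_distance=dists, inside_ad=dists <= ad.threshold)
    )


def classify_insample(ad: ADModel) -> pd.DataFrame:
    """Inside/outside labels for the training compounds themselves,
    using the in-sample mean k-NN distances (self-distance excluded)
    that the threshold was fitted on."""
    d = ad.training_distances
    return pd.DataFrame(
        dict(mean_knn_distance=d, inside_ad=d <= ad.threshold)
    )


# -- chemical-space projection ----------------------------------------------

def tsne_project(
    distances: np.ndarray, perplexity: float, seed: int, max_iter: int = 1000
) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of a precomputed distance matrix."""
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not perplexity < n:
        raise ValueError(f"perplexity {perplexity} infeasible for n={n}")
    method = "barnes_hut" if n >= 4 * perplexity else "exact"
    tsne = TSNE(
        n_components=2, metric="precomputed", init="random",
        perplexity=perplexity, random_state=seed, method=method,
        max_iter=max_iter,
    )
    emb = tsne.fit_transform(D)
    if not np.all(np.isfinite(emb)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return emb


def trustworthiness(
    distances: np.ndarray, embedding: np.ndarray, n_neighbors: int = 5
) -> float:
    """Neighborhood-preservation score in [0, 1]: penalizes embedding
    neighbors that are not original-space neighbors, weighted by their
    original-rank excess."""
    D = np.asarray(distances, dtype=float)
    if not n_neighbors < D.shape[0] / 2:
        raise ValueError("n_neighbors must be < n/2")
    return float(_sk_trustworthiness(D, np.asarray(embedding),
                                     n_neighbors=n_neighbors,
                                     metric="precomputed"))


def procrustes_disparity(reference: np.ndarray, candidate: np.ndarray) -> float:
    """Residual sum of squared differences after optimal translation,
    uniform scaling, and rotation/reflection (standard Procrustes
    statistic on unit-norm centered configurations)."""
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape:
        raise ValueError("embeddings must have equal shapes")
    if np.allclose(cand, cand.mean(axis=0)) or np.allclose(ref, ref.mean(axis=0)):
        raise ValueError("degenerate (all-coincident) embedding")
    _, _, disparity = _scipy_procrustes(ref, cand)
    return float(disparity)


def silhouette(embedding: np.ndarray, labels: Sequence) -> float:
    """Cluster-coherence score in [-1, 1] of the embedding under the
    given labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires >= 2 distinct labels")
    return float(silhouette_score(np.asarray(embedding), labels))


@dataclasses.dataclass
class ProjectionReport:
    perplexity: float
    seed: int
    trustworthiness: float
    procrustes_disparity: float | None   # None for each group's reference run
    silhouette: float
    trustworthy_flag: bool
    stable_flag: bool
    is_reference: bool
    embedding: np.ndarray = dataclasses.field(repr=False, default=None)


def validate_projections(
    distances: np.ndarray,
    labels: Sequence,
    perplexities: Sequence[float] = DEFAULT_PERPLEXITIES,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    trust_threshold: float = 0.99,
    disparity_threshold: float = 0.01,
    n_neighbors: int = 5,
    max_iter: int = 1000,
) -> tuple[list[ProjectionReport], ProjectionReport]:
    """Full perplexity x seed sweep with quantitative validation.

    Within each perplexity group the lowest-seed run is the Procrustes
    reference (its disparity is absent); the others are aligned to it.
    ``trustworthy_flag`` is per run (trustworthiness >= threshold);
    ``stable_flag`` is shared by the group and true only when every
    non-reference run's disparity is <= the disparity threshold.  The
    selected configuration maximizes the rank-sum of trustworthiness,
    -disparity and silhouette among trustworthy non-reference runs.
    """
    reports: list[ProjectionReport] = []
    for perp in perplexities:
        group: list[ProjectionReport] = []
        ref_emb = None
        for i, seed in enumerate(sorted(seeds)):
            emb = tsne_project(distances, perp, seed, max_iter=max_iter)
            tw = trustworthiness(distances, emb, n_neighbors=n_neighbors)
            sil = silhouette(emb, labels)
            if i == 0:
                ref_emb, disp, is_ref = emb, None, True
            else:
                disp, is_ref = procrustes_disparity(ref_emb, emb), False
            group.append(ProjectionReport(
                perplexity=perp, seed=seed, trustworthiness=tw,
                procrustes_disparity=disp, silhouette=sil,
                trustworthy_flag=tw >= trust_threshold, stable_flag=False,
                is_reference=is_ref, embedding=emb,
            ))
        stable = all(
            r.procrustes_disparity <= disparity_threshold
            for r in group if not r.is_reference
        )
        for r in group:
            r.stable_flag = stable
        reports.extend(group)

    candidates = [
        r for r in reports if not r.is_reference and r.trustworthy_flag
    ]
    if not candidates:
        candidates = [r for r in reports if not r.is_reference]

    def _ranks(values, reverse):
        order = sorted(range(len(values)), key=lambda i: values[i],
                       reverse=reverse)
        ranks = [0] * len(values)
        for rank, i in enumerate(order):
            ranks[i] = rank
        return ranks

    tw_rank = _ranks([r.trustworthiness for r in candidates], reverse=True)
    disp_rank = _ranks([r.procrustes_disparity for r in candidates],
                       reverse=False)
    sil_rank = _ranks([r.silhouette for r in candidates], reverse=True)
    totals = [t + d + s for t, d, s in zip(tw_rank, disp_rank, sil_rank)]
    best_i = min(
        range(len(candidates)),
        key=lambda i: (totals[i], candidates[i].perplexity, candidates[i].seed),
    )
    return reports, candidates[best_i]


def reports_to_frame(reports: list[ProjectionReport]) -> pd.DataFrame:
    """Projection reports as a delimited-text-ready table (one row per
    perplexity x seed; reference rows carry an empty disparity)."""
    return pd.DataFrame([
        dict(perplexity=r.perplexity, seed=r.seed,
             trustworthiness=r.trustworthiness,
             procrustes_disparity=(np.nan if r.procrustes_disparity is None
                                   else r.procrustes_disparity),
             silhouette=r.silhouette, trustworthy_flag=r.trustworthy_flag,
             stable_flag=r.stable_flag, is_reference=r.is_reference)
        for r in reports
    ])
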