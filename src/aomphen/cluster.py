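"""PCA projection, quality filtering, Gaussian-mixture clustering, profiling.

Principal components are derived from the training-split embeddings only and
applied to all embeddings. Low-quality periods (below the population median
data quality, i.e. the 1st and 2nd quartiles) are removed before clustering.
A Gaussian mixture is fitted on the top PCs across a range of component
counts and covariance families, selected by BIC; responsibilities are
hardened to cluster labels by maximum responsibility. Clusters are
characterized by CCS diagnosis prevalence in the year before the index
date, mean z-scored most-recent measurements, and temporal presence rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.mixture import GaussianMixture

from aomphen.cohort import PreAOMPeriod
from aomphen.errors import ConfigError
from aomphen.featurize import Normalizer, compute_presence_rates, static_transform

DEFAULT_N_PCS = 40


@dataclass
class PCModel:
    """Train-fold principal axes: centered eigendecomposition of covariance."""

    eigenvectors: np.ndarray  # (H, H), columns ordered by decreasing eigenvalue
    eigenvalues: np.ndarray
    train_means: np.ndarray
    n_components_kept: int = DEFAULT_N_PCS

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class GMMModel:
    model: GaussianMixture
    n_components: int
    covariance_type: str
    responsibilities: np.ndarray  # (n, K)
    selection_trace: pd.DataFrame = field(repr=False)  # k, covariance_type, bic


def fit_pca(train_embeddings: np.ndarray, n_components_kept: int = DEFAULT_N_PCS) -> PCModel:
    """Eigendecomposition of the training-embedding covariance matrix.

    Test data never influences the axes; when the embedding dimension is
    below ``n_components_kept`` all dimensions are kept.
    """
    E = np.asarray(train_embeddings, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ConfigError("need at least 2 training embeddings")
    means = E.mean(axis=0)
    cov = np.cov(E - means, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    return PCModel(
        eigenvectors=vecs[:, order],
        eigenvalues=vals,
        train_means=means,
        n_components_kept=min(n_components_kept, E.shape[1]),
    )


def project(embeddings: np.ndarray, pc_model: PCModel, k: int | None = None) -> np.ndarray:
    """PC scores: centered embeddings rotated onto the first k axes."""
    k = pc_model.n_components_kept if k is None else k
    if k > pc_model.eigenvectors.shape[1]:
        raise ConfigError(f"k={k} exceeds embedding dimension {pc_model.eigenvectors.shape[1]}")
    return (np.asarray(embeddings, dtype=float) - pc_model.train_means) @ pc_model.eigenvectors[:, :k]


def filter_by_quality(quality: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Keep periods with quality >= the population median (drops Q1-Q2).

    Ties at the median are retained (the conservative reading of removing
    the two lowest quartiles). Returns (retained rows, threshold used).
    """
    threshold = float(quality["quality"].median())
    return quality[quality["quality"] >= threshold], threshold


def fit_gmm(
    pc_scores: np.ndarray,
    k_range: range | list[int] = range(1, 16),
    seed: int = 0,
    covariance_types: tuple[str, ...] = ("full", "diag"),
    n_init: int = 3,
    reg_covar: float = 1e-6,
) -> GMMModel:
    """Fit candidate mixtures and select (K, covariance family) by BIC."""
    S = np.asarray(pc_scores, dtype=float)
    ks = list(k_range)
    if S.shape[0] <= max(ks):
        raise ConfigError("need more samples than the largest candidate K")
    trace = []
    best = None
    for ct in covariance_types:
        for k in ks:
            gm = GaussianMixture(
                n_components=k, covariance_type=ct, n_init=n_init,
                random_state=seed, reg_covar=reg_covar,
            ).fit(S)
            bic = gm.bic(S)
            trace.append(dict(k=k, covariance_type=ct, bic=bic, converged=gm.converged_))
            if best is None or bic < best[0]:
                best = (bic, gm, k, ct)
    _, gm, k, ct = best
    return GMMModel(
        model=gm,
        n_components=k,
        covariance_type=ct,
        responsibilities=gm.predict_proba(S),
        selection_trace=pd.DataFrame(trace),
    )


def assign_clusters(gmm: GMMModel) -> np.ndarray:
    """Harden responsibilities: argmax, ties broken by lowest cluster index."""
    return np.argmax(gmm.responsibilities, axis=1)


def tsne_embed(pc_scores: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE coordinates of the PC scores; visualization only."""
    from sklearn.manifold import TSNE

    S = np.asarray(pc_scores, dtype=float)
    if S.shape[0] <= 3 * perplexity:
        raise ConfigError("need n > 3 * perplexity samples for t-SNE")
    return TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca").fit_transform(S)


@dataclass
class ClusterProfile:
    cluster: int
    n_periods: int
    ccs_prevalence: pd.Series
    meas_zmeans: pd.Series
    presence: pd.DataFrame = field(repr=False)


def _heatmap_order(matrix: np.ndarray, method: str = "complete") -> np.ndarray:
    if matrix.shape[0] < 3:
        return np.arange(matrix.shape[0])
    return leaves_list(linkage(matrix, method=method, metric="euclidean"))


def profile_clusters(
    labels: np.ndarray,
    periods: list[PreAOMPeriod],
    measurements: pd.DataFrame,
    diagnoses: pd.DataFrame,
    ccs_ids: list[int],
    normalizer: Normalizer,
) -> tuple[list[ClusterProfile], dict[str, pd.DataFrame]]:
    """Characterize clusters against raw events.

    Per cluster: prevalence of each CCS category among its periods (any
    diagnosis within 365 days before the index day), mean z-scored
    most-recent measurement values, and temporal presence rates. Also
    returns heatmap-ready matrices with rows/columns ordered by hierarchical
    clustering (complete linkage, Euclidean distance).
    """
    labels = np.asarray(labels)
    if len(labels) != len(periods):
        raise ConfigError("one label per period required")
    profiles: list[ClusterProfile] = []
    prev_rows, z_rows, index = [], [], []
    for cl in sorted(set(labels.tolist())):
        members = [p for p, l in zip(periods, labels) if l == cl]
        if not members:
            warnings.warn(f"cluster {cl} is empty; excluded from profiles", stacklevel=2)
            continue
        prev = np.zeros(len(ccs_ids))
        zsum = np.zeros(len(normalizer.feature_ids))
        zcnt = np.zeros(len(normalizer.feature_ids))
        for p in members:
            dv = diagnoses[
                (diagnoses["person_id"] == p.person_id)
                & (diagnoses["day"] >= p.index_day - 365)
                & (diagnoses["day"] < p.index_day)
            ]
            seen = set(dv["ccs_id"].unique())
            prev += np.array([1.0 if c in seen else 0.0 for c in ccs_ids])
            sv = static_transform(p, measurements, diagnoses, ccs_ids, normalizer)
            obs = sv.mask[: len(normalizer.feature_ids)] == 1.0
            zsum[obs] += sv.values[: len(normalizer.feature_ids)][obs]
            zcnt[obs] += 1
        prev /= len(members)
        with np.errstate(invalid="ignore"):
            zmean = np.where(zcnt > 0, zsum / np.maximum(zcnt, 1), np.nan)
        presence = compute_presence_rates(members, measurements, "feature_id")
        profiles.append(
            ClusterProfile(
                cluster=int(cl),
                n_periods=len(members),
                ccs_prevalence=pd.Series(prev, index=[f"ccs_{c}" for c in ccs_ids]),
                meas_zmeans=pd.Series(zmean, index=[f"meas_{f}" for f in normalizer.feature_ids]),
                presence=presence,
            )
        )
        prev_rows.append(prev)
        z_rows.append(zmean)
        index.append(f"cluster_{cl}")
    prevalence = pd.DataFrame(prev_rows, index=index, columns=[f"ccs_{c}" for c in ccs_ids])
    zmeans = pd.DataFrame(z_rows, index=index, columns=[f"meas_{f}" for f in normalizer.feature_ids])
    heatmaps = {}
    for name, mat in (("prevalence", prevalence), ("zmeans", zmeans.fillna(0.0))):
        ro = _heatmap_order(mat.to_numpy())
        co = _heatmap_order(mat.to_numpy().T)
        heatmaps[name] = mat.iloc[ro, co]
    return profiles, heatmaps
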