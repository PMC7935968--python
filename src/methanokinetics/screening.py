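"""Nutrient-demand correlation stage: standardize, impute, PCA, k-means.

The screening matrix holds one row per strain x medium observation with the
response variables (OD_max, turnover_max, MER_max) and medium covariates
(salt, sulfate, sulfur, ammonium, phosphate, cysteine concentrations),
possibly with missing entries.  The pipeline is

    iterative-PCA imputation -> column standardization -> PCA
    -> k-means on the first two components -> cluster summaries

Cluster quality is reported as between_SS / total_SS in percent, the
standard k-means decomposition (between + within = total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ScreeningMatrix",
    "ImputationReport",
    "PCAResult",
    "ClusterResult",
    "standardize",
    "impute_iterative_pca",
    "pca",
    "kmeans_first2pcs",
    "cluster_summary",
    "run_screening",
]


@dataclass
class ScreeningMatrix:
    """Strains x variables table with optional per-row metadata.

    ``data`` holds the numeric variables (NaN marks a missing entry);
    ``metadata`` holds categorical descriptors (taxonomy, temperature
    group, medium id, ...) aligned on the same index.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        numeric = self.data.select_dtypes(include=[np.number])
        if numeric.shape[1] != self.data.shape[1]:
            bad = [c for c in self.data.columns if c not in numeric.columns]
            raise ValueError(f"non-numeric data columns: {bad}")
        frac_missing = self.data.isna().mean()
        too_sparse = frac_missing[frac_missing > 0.5]
        if len(self.data.columns) - len(too_sparse) < 2:
            raise ValueError("fewer than 2 columns with <=50% missing entries")
        if self.metadata is not None and not self.data.index.equals(self.metadata.index):
            raise ValueError("metadata index does not match data index")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ImputationReport:
    iterations: int
    converged: bool
    n_imputed: int


@dataclass
class PCAResult:
    scores: np.ndarray  # rows x components
    loadings: np.ndarray  # variables x components
    variance_fractions: np.ndarray
    columns: list[str]


@dataclass
class ClusterResult:
    """k-means result on the first two principal components."""

    labels: np.ndarray
    centroids: np.ndarray  # k x 2, in PC1-PC2 space
    between_ss_over_total_ss: float  # percent
    within_ss: float
    total_ss: float
    pc_variance_fractions: np.ndarray | None = None
    imputation: ImputationReport | None = None
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.k = int(self.centroids.shape[0])


def standardize(matrix: ScreeningMatrix) -> ScreeningMatrix:
    """Column-wise (x - mean) / sd over observed entries (sample sd, ddof=1)."""
    data = matrix.data.copy()
    for col in data.columns:
        observed = data[col].dropna()
        sd = observed.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        data[col] = (data[col] - observed.mean()) / sd
    return ScreeningMatrix(data, matrix.metadata)


def impute_iterative_pca(
    matrix: ScreeningMatrix,
    ncomp: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[ScreeningMatrix, ImputationReport]:
    """Complete missing entries by regularized iterative PCA.

    Missing cells start at their column means; each iteration centers the
    matrix, reconstructs it at rank ``ncomp`` from a truncated SVD and
    re-substitutes the reconstruction into the missing cells only, until
    the largest change on an imputed cell falls below ``tol``.  The
    retained singular values are shrunk by the noise variance estimated
    from the discarded components (lambda_k -> lambda_k - sigma^2), which
    keeps the fit from chasing noise through the missing cells; on exactly
    low-rank data the shrinkage vanishes and the truth is recovered.
    Observed entries are never altered.
    """
    x = matrix.values.copy()
    mask = np.isnan(x)
    n_missing = int(mask.sum())
    if n_missing == 0:
        return matrix, ImputationReport(iterations=0, converged=True, n_imputed=0)
    if mask.all(axis=0).any():
        col = matrix.data.columns[mask.all(axis=0)][0]
        raise ValueError(f"column {col!r} is entirely missing; cannot impute")
    if not 0 < ncomp < min(x.shape):
        raise ValueError(f"ncomp={ncomp} must lie in (0, min(n_rows, n_cols))")

    col_means = np.nanmean(x, axis=0)
    x[mask] = np.take(col_means, np.where(mask)[1])

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = x.mean(axis=0)
        centered = x - mu
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        lam = s**2 / max(x.shape[0] - 1, 1)
        sigma2 = lam[ncomp:].mean() if lam.size > ncomp else 0.0
        shrink = np.where(lam[:ncomp] > 0, np.maximum(lam[:ncomp] - sigma2, 0.0) / np.where(lam[:ncomp] > 0, lam[:ncomp], 1.0), 0.0)
        recon = (u[:, :ncomp] * (s[:ncomp] * shrink)) @ vt[:ncomp] + mu
        delta = np.abs(recon[mask] - x[mask]).max()
        x[mask] = recon[mask]
        if delta < tol:
            converged = True
            break

    completed = pd.DataFrame(x, index=matrix.data.index, columns=matrix.data.columns)
    return (
        ScreeningMatrix(completed, matrix.metadata),
        ImputationReport(iterations=it, converged=converged, n_imputed=n_missing),
    )


def pca(matrix: ScreeningMatrix) -> PCAResult:
    """Principal components of a standardized, complete matrix.

    SVD of the column-centered data; variance fractions are the normalized
    squared singular values.  Sign convention: each component is flipped so
    its largest-magnitude loading is positive, making results deterministic
    across platforms.
    """
    x = matrix.values
    if np.isnan(x).any():
        raise ValueError("PCA requires a complete matrix; impute first")
    if x.shape[0] < 3:
        raise ValueError(f"PCA needs at least 3 rows, got {x.shape[0]}")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    var = s**2
    fractions = var / var.sum() if var.sum() > 0 else var
    return PCAResult(
        scores=scores,
        loadings=vt.T,
        variance_fractions=fractions,
        columns=list(matrix.data.columns),
    )


def kmeans_first2pcs(
    scores: np.ndarray,
    k: int = 4,
    seed: int = 0,
    n_init: int = 25,
) -> ClusterResult:
    """Lloyd k-means on PC1-PC2, best of ``n_init`` seeded restarts.

    Reports between_SS / total_SS as a percentage (0% at k=1, 100% when
    every distinct point is its own centroid).
    """
    pts = np.asarray(scores, dtype=float)[:, :2]
    n_distinct = np.unique(pts, axis=0).shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(pts)
    within = float(km.inertia_)
    total = float(((pts - pts.mean(axis=0)) ** 2).sum())
    between = total - within
    pct = 100.0 * between / total if total > 0 else 0.0
    return ClusterResult(
        labels=labels,
        centroids=km.cluster_centers_,
        between_ss_over_total_ss=pct,
        within_ss=within,
        total_ss=total,
    )


def cluster_summary(result: ClusterResult, matrix: ScreeningMatrix) -> pd.DataFrame:
    """Per-cluster medians of the numeric variables plus metadata composition.

    Clusters that ended up empty still get a row (count 0) so the table
    always has ``k`` rows.
    """
    if len(result.labels) != len(matrix.data):
        raise ValueError("labels do not align with matrix rows")
    rows = []
    for c in range(result.k):
        in_c = result.labels == c
        row: dict = {"cluster": c + 1, "count": int(in_c.sum())}
        sub = matrix.data.loc[in_c]
        for col in matrix.data.columns:
            row[f"median_{col}"] = float(sub[col].median()) if in_c.any() else float("nan")
        if matrix.metadata is not None:
            meta = matrix.metadata.loc[in_c]
            for col in matrix.metadata.columns:
                counts = meta[col].value_counts()
                row[f"{col}_composition"] = (
                    ";".join(f"{k_}:{v}" for k_, v in sorted(counts.items())) if in_c.any() else ""
                )
        rows.append(row)
    return pd.DataFrame(rows)


def run_screening(
    matrix: ScreeningMatrix,
    k: int = 4,
    seed: int = 0,
    ncomp: int = 2,
    n_init: int = 25,
) -> tuple[ClusterResult, PCAResult, pd.DataFrame]:
    """Full pipeline: impute -> standardize -> PCA -> k-means -> summary."""
    completed, report = impute_iterative_pca(matrix, ncomp=ncomp)
    standardized = standardize(completed)
    components = pca(standardized)
    clusters = kmeans_first2pcs(components.scores, k=k, seed=seed, n_init=n_init)
    clusters.pc_variance_fractions = components.variance_fractions
    clusters.imputation = report
    summary = cluster_summary(clusters, completed)
    return clusters, components, summary
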