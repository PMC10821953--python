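"""Expression normalization, specificity statistics and stage clustering.

Implements FPKM -> TPM conversion (per-column normalization to 1e6),
male-specificity z-scores from replicate SDs, min-max normalized z-scores,
the tissue-specificity index tau, row-standardized spermatogenesis stage
profiles with PCA + k-means clustering, and rank-correlation trend tests of
gene properties against origination-branch age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ExpressionMatrix",
    "fpkm_to_tpm",
    "filter_expressed",
    "male_specificity_zscore",
    "normalize_zscores",
    "tau_specificity",
    "scale_stage_profiles",
    "pca_reduce",
    "kmeans_stage_clusters",
    "order_clusters_by_stage",
    "age_trend_tests",
]

STAGE_NAMES = (
    "early_spermatogonia",
    "late_spermatogonia",
    "early_spermatocytes",
    "late_spermatocytes",
    "early_spermatids",
    "late_spermatids",
)


@dataclass
class ExpressionMatrix:
    """Gene x tissue expression values with optional sex means and replicate SDs."""

    values: pd.DataFrame  # genes in rows, tissues in columns
    unit: str = "FPKM"  # FPKM | TPM
    male_mean: pd.Series | None = None
    female_mean: pd.Series | None = None
    male_sd: pd.Series | None = None
    female_sd: pd.Series | None = None

    def __post_init__(self):
        if self.unit not in ("FPKM", "TPM"):
            raise ValueError("unit must be FPKM or TPM")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be >= 0")


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: per tissue column, value / column-sum * 1e6."""
    if matrix.unit != "FPKM":
        raise ValueError(f"matrix unit is {matrix.unit}, expected FPKM")
    colsum = matrix.values.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"all-zero tissue columns cannot be normalized: {list(zero.index)}")
    tpm = matrix.values / colsum * 1e6
    return ExpressionMatrix(
        values=tpm,
        unit="TPM",
        male_mean=matrix.male_mean,
        female_mean=matrix.female_mean,
        male_sd=matrix.male_sd,
        female_sd=matrix.female_sd,
    )


def filter_expressed(matrix: ExpressionMatrix, min_tpm: float = 0.1) -> ExpressionMatrix:
    """Keep genes whose maximum expression strictly exceeds ``min_tpm`` TPM."""
    if matrix.unit != "TPM":
        raise ValueError("filter operates on TPM values")
    keep = matrix.values.max(axis=1) > min_tpm
    idx = matrix.values.index[keep]
    sub = lambda s: None if s is None else s.loc[s.index.intersection(idx)]
    return ExpressionMatrix(
        values=matrix.values.loc[idx],
        unit="TPM",
        male_mean=sub(matrix.male_mean),
        female_mean=sub(matrix.female_mean),
        male_sd=sub(matrix.male_sd),
        female_sd=sub(matrix.female_sd),
    )


def male_specificity_zscore(male_mean, female_mean, male_sd, female_sd):
    """Raw male-bias z: (male - female) / sqrt(sd_male^2 + sd_female^2)."""
    male_mean = np.asarray(male_mean, dtype=float)
    female_mean = np.asarray(female_mean, dtype=float)
    male_sd = np.asarray(male_sd, dtype=float)
    female_sd = np.asarray(female_sd, dtype=float)
    if (male_sd < 0).any() or (female_sd < 0).any():
        raise ValueError("SDs must be >= 0")
    denom = np.sqrt(male_sd**2 + female_sd**2)
    if (denom == 0).any():
        raise ZeroDivisionError("both replicate SDs are zero for some gene")
    out = (male_mean - female_mean) / denom
    return float(out) if out.ndim == 0 else out


def normalize_zscores(raw):
    """Min-max normalization of a z-score vector onto [0, 1]."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant z-score vector")
    return (raw - lo) / (hi - lo)


def tau_specificity(expression) -> float:
    """Tissue-specificity index tau = sum(1 - x_i/x_max) / (N - 1).

    0 for perfectly uniform expression, 1 for single-tissue expression.
    Invariant under positive rescaling of the profile.
    """
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least 2 tissues")
    if (x < 0).any():
        raise ValueError("expression must be >= 0")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def scale_stage_profiles(stage_matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize stage profiles (per-gene mean 0, SD 1; SD floored)."""
    vals = stage_matrix.values.astype(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd = np.maximum(sd, 1e-12)
    return pd.DataFrame(
        (vals - mean) / sd, index=stage_matrix.index, columns=stage_matrix.columns
    )


def pca_reduce(
    scaled: pd.DataFrame | np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered PCA; returns (coordinates, explained-variance fractions).

    Rank deficiency below ``n_components`` pads coordinates and fractions
    with zeros (with a warning) so downstream shapes stay stable.
    """
    x = scaled.values if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    n_eff = max(1, min(n_components, rank, min(x.shape)))
    pca = PCA(n_components=n_eff, svd_solver="full")
    coords = pca.fit_transform(x)
    evr = pca.explained_variance_ratio_
    if coords.shape[1] < n_components:
        import warnings

        warnings.warn(
            f"rank {rank} below {n_components} components; padding with zeros"
        )
        pad = n_components - coords.shape[1]
        coords = np.hstack([coords, np.zeros((coords.shape[0], pad))])
        evr = np.concatenate([evr, np.zeros(pad)])
    return coords, evr


def kmeans_stage_clusters(
    coordinates: np.ndarray, k: int = 4, seed: int | None = 0, n_init: int = 50
) -> np.ndarray:
    """k-means labels (0-based) with k-means++ restarts, best inertia kept."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape[0] < k:
        raise ValueError("need at least k points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(coordinates)


def order_clusters_by_stage(labels: np.ndarray, scaled: pd.DataFrame) -> np.ndarray:
    """Renumber clusters 1..k by ascending expression-weighted mean stage.

    Each cluster's centroid (in scaled space, shifted to be nonnegative) is
    reduced to a weighted mean stage index; clusters peaking early get low
    numbers.  Ties are broken by the centroid's argmax stage.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    vals = scaled.values if isinstance(scaled, pd.DataFrame) else np.asarray(scaled)
    stages = np.arange(1, vals.shape[1] + 1, dtype=float)
    keys = []
    for lab in uniq:
        centroid = vals[labels == lab].mean(axis=0)
        w = centroid - centroid.min()
        if w.sum() > 0:
            mean_stage = float((stages * w).sum() / w.sum())
        else:
            mean_stage = float(np.argmax(centroid) + 1)
        keys.append((mean_stage, int(np.argmax(centroid)), lab))
    ranking = {lab: r + 1 for r, (_, _, lab) in enumerate(sorted(keys))}
    return np.array([ranking[lab] for lab in labels])


def age_trend_tests(
    table: pd.DataFrame, property_name: str, branch_col: str = "branch"
) -> dict[str, float]:
    """Kendall tau-b and Spearman rho of a gene property against branch age.

    Branch indices are heavily tied across genes, hence the tie-corrected
    tau-b variant.  Two-sided p-values; scipy switches to exact enumeration
    for small untied samples and the normal/t approximation otherwise.
    """
    sub = table[[branch_col, property_name]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 genes with branch and property")
    x = sub[branch_col].astype(float).values
    y = sub[property_name].astype(float).values
    if np.all(y == y[0]) or np.all(x == x[0]):
        raise ValueError("undefined correlation for a constant column")
    kt = stats.kendalltau(x, y, variant="b")
    sp = stats.spearmanr(x, y)
    return {
        "kendall_tau": float(kt.statistic),
        "kendall_p": float(kt.pvalue),
        "spearman_rho": float(sp.statistic),
        "spearman_p": float(sp.pvalue),
        "n": int(len(sub)),
    }
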