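"""Foldability and structural-ensemble metrics.

Per-residue confidence (pLDDT, 0-100) profiles are classified into
well / partially / not folded using the published thresholds: well-folded
requires mean pLDDT > 80 *and* more than 90% of residues confidently
predicted (pLDDT > 70); partially folded requires more than 30% confident
residues *or* a confident run longer than 50 residues; everything else is
not folded.  All thresholds are strict.

Structural ensembles (equal-length backbone coordinate sets) are compared
by TM-score after Kabsch superposition with iterative subset refinement;
ensemble convergence is the mean pairwise TM-score times 100.  Conformation
ensembles are clustered by the density-peaks algorithm on a pairwise
distance matrix (backbone RMSD by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlddtProfile",
    "FoldabilityResult",
    "FoldabilityParams",
    "StructureModel",
    "ConformationClustering",
    "classify_foldability",
    "kabsch_superpose",
    "tm_score",
    "tm_d0",
    "select_low_energy",
    "ensemble_convergence",
    "rmsd_matrix",
    "density_peaks_cluster",
    "representative_models",
    "novel_fold_flag",
]


@dataclass(frozen=True)
class PlddtProfile:
    gene: str
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.size < 1:
            raise ValueError("pLDDT profile must have at least one residue")
        if scores.min() < 0 or scores.max() > 100:
            raise ValueError("pLDDT scores must lie in [0, 100]")


@dataclass(frozen=True)
class FoldabilityParams:
    """Classifier thresholds; all comparisons are strict."""

    well_mean: float = 80.0
    confident_plddt: float = 70.0
    well_p_confident: float = 0.90
    partial_p_confident: float = 0.30
    partial_run: int = 50


@dataclass(frozen=True)
class FoldabilityResult:
    gene: str
    foldability: str  # well_folded | partially_folded | not_folded
    mean_plddt: float
    p_confident: float
    max_confident_run: int


@dataclass(frozen=True)
class StructureModel:
    model_id: int
    coords: np.ndarray  # (L, 3) backbone coordinates, Angstrom
    energy: float | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (L, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")


@dataclass
class ConformationClustering:
    labels: np.ndarray  # 1..k per model
    centers: np.ndarray  # k model indices, ordered by gamma
    rho: np.ndarray
    delta: np.ndarray


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        if run > best:
            best = run
    return best


def classify_foldability(
    profile: PlddtProfile, params: FoldabilityParams = FoldabilityParams()
) -> FoldabilityResult:
    """Well / partially / not folded call from a per-residue confidence profile."""
    scores = profile.scores
    confident = scores > params.confident_plddt
    mean = float(scores.mean())
    p_conf = float(confident.mean())
    run = _longest_run(confident)
    if mean > params.well_mean and p_conf > params.well_p_confident:
        cls = "well_folded"
    elif p_conf > params.partial_p_confident or run > params.partial_run:
        cls = "partially_folded"
    else:
        cls = "not_folded"
    return FoldabilityResult(profile.gene, cls, mean, p_conf, run)


def kabsch_superpose(
    a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD proper rotation R and translation t mapping ``b`` onto ``a``.

    Returns (R, t, rmsd) with ``a ~ b @ R.T + t``.  Reflections are
    corrected to proper rotations (det +1).  Near-degenerate (collinear)
    inputs produce a warning and a best-effort result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("inputs must be equal-shape (L, 3) arrays")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 paired points")
    if weights is None:
        weights = np.ones(a.shape[0])
    w = weights / weights.sum()
    ca = (w[:, None] * a).sum(axis=0)
    cb = (w[:, None] * b).sum(axis=0)
    aa = a - ca
    bb = b - cb
    h = (w[:, None] * bb).T @ aa
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        warnings.warn("ill-conditioned superposition (near-collinear points)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    moved = b @ rot.T + t
    rmsd = float(np.sqrt(((moved - a) ** 2).sum(axis=1).mean()))
    return rot, t, rmsd


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale; floored at 0.5 A for very short chains."""
    if l_norm < 1:
        raise ValueError("normalization length must be >= 1")
    return max(0.5, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8) if l_norm > 15 else 0.5


def tm_score(
    a: np.ndarray, b: np.ndarray, l_norm: int | None = None, max_iter: int = 20
) -> float:
    """TM-score of index-paired structures after refined superposition.

    Starts from a Kabsch fit on all residues, then iteratively re-superposes
    on the subset with d_i < d0 until the subset stabilizes (at most
    ``max_iter`` rounds); the score is evaluated over *all* residues with
    the final superposition:  (1/L_norm) * sum 1 / (1 + (d_i/d0)^2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("structures must have equal length for index pairing")
    n = a.shape[0]
    if l_norm is None:
        l_norm = n
    d0 = tm_d0(l_norm)
    rot, t, _ = kabsch_superpose(a, b)
    prev_subset = None
    for _ in range(max_iter):
        moved = b @ rot.T + t
        d = np.sqrt(((moved - a) ** 2).sum(axis=1))
        subset = d < d0
        if subset.sum() < 3 or (prev_subset is not None and np.array_equal(subset, prev_subset)):
            break
        prev_subset = subset
        rot, t, _ = kabsch_superpose(a[subset], b[subset])
    moved = b @ rot.T + t
    d = np.sqrt(((moved - a) ** 2).sum(axis=1))
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def select_low_energy(models: list[StructureModel], k: int = 20) -> list[StructureModel]:
    """The ``k`` lowest-potential-energy models; energy ties broken by model id."""
    if any(m.energy is None for m in models):
        raise ValueError("all models need potential energies")
    if k > len(models):
        raise ValueError("k exceeds ensemble size")
    return sorted(models, key=lambda m: (m.energy, m.model_id))[:k]


def ensemble_convergence(coords: np.ndarray | list[np.ndarray]) -> float:
    """Mean pairwise TM-score of an ensemble, scaled to (0, 100].

    The normalization length is the (shared) chain length, so the value is
    directly comparable with percentage-scaled per-residue confidence.
    """
    coords = [np.asarray(c, dtype=float) for c in coords]
    if len(coords) < 2:
        raise ValueError("need at least 2 models")
    lengths = {c.shape[0] for c in coords}
    if len(lengths) != 1:
        raise ValueError("all models must share one chain length")
    total = 0.0
    npairs = 0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            total += tm_score(coords[i], coords[j])
            npairs += 1
    return 100.0 * total / npairs


def rmsd_matrix(coords: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Symmetric pairwise backbone RMSD matrix after Kabsch superposition."""
    coords = [np.asarray(c, dtype=float) for c in coords]
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(coords[i], coords[j])
            out[i, j] = out[j, i] = r
    return out


def default_dc(distances: np.ndarray) -> float:
    """Density cutoff heuristic: 2nd percentile of off-diagonal distances."""
    n = distances.shape[0]
    off = distances[~np.eye(n, dtype=bool)]
    return float(np.percentile(off, 2.0))


def density_peaks_cluster(
    distances: np.ndarray, k: int, d_c: float | None = None
) -> ConformationClustering:
    """Density-peaks clustering on a pairwise distance matrix.

    Density rho_i counts neighbors within ``d_c``; separation delta_i is the
    distance to the nearest point of higher density (the global peak takes
    the maximum distance).  The ``k`` points maximizing gamma = rho * delta
    become cluster centers; the rest inherit the label of their nearest
    higher-density neighbor, assigned in decreasing density order.  Density
    ties are broken by index so the ordering is total.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if distances.shape != (n, n) or not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(distances) != 0) or np.any(distances < 0):
        raise ValueError("distance matrix must be nonnegative with zero diagonal")
    if not 1 <= k <= n:
        raise ValueError("k must lie in [1, n]")
    if d_c is None:
        d_c = default_dc(distances)
    offdiag = ~np.eye(n, dtype=bool)
    rho = ((distances < d_c) & offdiag).sum(axis=1).astype(float)

    # total order: higher rho first, then lower index
    order = np.lexsort((np.arange(n), -rho))
    delta = np.empty(n)
    nn_higher = np.full(n, -1)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = distances[i].max()
            continue
        higher = order[:pos]
        j = higher[np.argmin(distances[i, higher])]
        delta[i] = distances[i, j]
        nn_higher[i] = j
    gamma = rho * delta
    centers = np.lexsort((np.arange(n), -gamma))[:k]
    labels = np.zeros(n, dtype=int)
    for rank_idx, c in enumerate(centers):
        labels[c] = rank_idx + 1
    for i in order:
        if labels[i] == 0:
            labels[i] = labels[nn_higher[i]]
    return ConformationClustering(
        labels=labels, centers=np.array(centers), rho=rho, delta=delta
    )


def representative_models(
    clustering: ConformationClustering, models: list[StructureModel]
) -> tuple[list[StructureModel], StructureModel]:
    """Cluster-center models ordered by cluster size; the top center is the
    refined representative.  Size ties are broken by center model id."""
    sizes = {
        lab: int((clustering.labels == lab).sum())
        for lab in range(1, len(clustering.centers) + 1)
    }
    ordered = sorted(
        range(1, len(clustering.centers) + 1),
        key=lambda lab: (-sizes[lab], models[clustering.centers[lab - 1]].model_id),
    )
    reps = [models[clustering.centers[lab - 1]] for lab in ordered]
    return reps, reps[0]


def novel_fold_flag(max_tm_to_reference_set: float) -> bool:
    """True when no reference structure reaches TM-score 0.5 (strict)."""
    if not 0.0 < max_tm_to_reference_set <= 1.0:
        raise ValueError("TM-score must lie in (0, 1]")
    return max_tm_to_reference_set < 0.5
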