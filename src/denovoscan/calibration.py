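"""Score calibration against random-sequence expectation.

Spliced-alignment scores of a protein query against genomic DNA only become
interpretable relative to what *random* sequence pairs of the same size
achieve.  This module simulates random protein/DNA pairs, summarizes the
best-local-score distribution per protein length N by its Mean and SD, fits
both as two-phase exponential decays in N,

    S(N) = S0 + SpanFast * exp(-KFast * N) + SpanSlow * exp(-KSlow * N)

with SpanFast = (S0 - Smin) * PercentFast/100 and
SpanSlow = (S0 - Smin) * (1 - PercentFast/100), and converts an observed
score into a one-tailed Gaussian p-value for the hypothesis that query and
target are unrelated.  A region whose coding-potential score is significant
at p <= 1e-6 (default) is called genic.

The spliced aligner itself is a local dynamic programme with codon matches
(BLOSUM62), affine gaps in both sequences, and a flat intron penalty for
DNA jumps of at least 40 nt; see :mod:`denovoscan._dp`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import lmfit
from scipy.stats import norm
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from ._dp import dp_best_score, dp_scores_batch, dp_matrices

__all__ = [
    "AA_ALPHABET",
    "DEFAULT_AA_FREQS",
    "DEFAULT_GC",
    "ScoringParams",
    "ScoreResult",
    "DecayFit",
    "CalibrationTable",
    "FitError",
    "random_protein",
    "random_dna",
    "spliced_align_score",
    "score_random_batch",
    "build_calibration",
    "fit_two_phase_decay",
    "predict_mean_sd",
    "genic_pvalue",
    "is_genic",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# Amino-acid usage of the D. melanogaster proteome (approximate), alphabetical
# one-letter order; renormalized at import.
DEFAULT_AA_FREQS = np.array(
    [
        0.0753, 0.0191, 0.0525, 0.0647, 0.0348,  # A C D E F
        0.0629, 0.0272, 0.0492, 0.0568, 0.0899,  # G H I K L
        0.0237, 0.0490, 0.0553, 0.0519, 0.0553,  # M N P Q R
        0.0811, 0.0571, 0.0587, 0.0100, 0.0297,  # S T V W Y
    ]
)
DEFAULT_AA_FREQS /= DEFAULT_AA_FREQS.sum()

#: genome-wide GC of D. melanogaster protein-coding sequence (approximate)
DEFAULT_GC = 0.54

#: default protein-length grid for calibration
DEFAULT_LENGTH_GRID = (15, 20, 25, 50, 75, 100, 200, 500, 1000)

#: epsilon floor for predicted SDs (score units)
SD_EPSILON = 1e-6


def _build_scoring_tables(stop_score: float) -> tuple[np.ndarray, np.ndarray]:
    """(20 x 21) substitution matrix (last column = stop) and codon->column map."""
    blosum = substitution_matrices.load("BLOSUM62")
    smat = np.empty((20, 21))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            smat[i, j] = blosum[a][b]
        smat[i, 20] = stop_score
    table = CodonTable.unambiguous_dna_by_id[1]
    codon2col = np.empty(64, dtype=np.int64)
    for i0, b0 in enumerate(_BASES):
        for i1, b1 in enumerate(_BASES):
            for i2, b2 in enumerate(_BASES):
                codon = b0 + b1 + b2
                idx = i0 * 16 + i1 * 4 + i2
                if codon in table.stop_codons:
                    codon2col[idx] = 20
                else:
                    codon2col[idx] = _AA_INDEX[table.forward_table[codon]]
    return smat, codon2col


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the surrogate spliced aligner (substitution-matrix units)."""

    gap_open: float = 11.0
    gap_extend: float = 1.0
    intron_penalty: float = 8.0
    min_intron: int = 40
    stop_score: float = -6.0

    def tables(self) -> tuple[np.ndarray, np.ndarray]:
        key = ("_tables", self.stop_score)
        cached = _TABLE_CACHE.get(key)
        if cached is None:
            cached = _build_scoring_tables(self.stop_score)
            _TABLE_CACHE[key] = cached
        return cached


_TABLE_CACHE: dict = {}


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of one spliced alignment."""

    score: float
    protein_length: int
    n_introns: int
    aligned_fraction: float

    def __post_init__(self):
        if self.n_introns < 0:
            raise ValueError("n_introns must be >= 0")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction must lie in [0, 1]")


class FitError(RuntimeError):
    """Two-phase decay fit failed to converge; carries the best attempt."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


def protein_to_indices(protein: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in protein], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-standard amino acid {exc} in protein") from exc


def dna_to_codon_columns(dna: str, codon2col: np.ndarray) -> np.ndarray:
    base = np.array([_BASE_INDEX[b] for b in dna], dtype=np.int64)
    if base.size < 3:
        raise ValueError("DNA must be at least 3 nt")
    cidx = base[:-2] * 16 + base[1:-1] * 4 + base[2:]
    return codon2col[cidx]


def random_protein(n: int, aa_freqs=None, rng=None) -> str:
    """Random protein of length ``n`` with i.i.d. residues drawn from ``aa_freqs``."""
    if n < 1:
        raise ValueError("protein length must be >= 1")
    rng = np.random.default_rng(rng)
    freqs = DEFAULT_AA_FREQS if aa_freqs is None else np.asarray(aa_freqs, float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("aa_freqs must sum to 1")
    idx = rng.choice(20, size=n, p=freqs)
    return "".join(AA_ALPHABET[i] for i in idx)


def random_dna(n: int, gc: float = DEFAULT_GC, rng=None) -> str:
    """Random DNA of length 3*(n + 300) at the given GC content.

    ``n`` is the *protein* length the sequence is sized for: the target is
    long enough to host the full coding region plus flanking sequence.
    """
    if n < 1:
        raise ValueError("protein length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=3 * (n + 300), p=p)
    return "".join(_BASES[i] for i in idx)


def _traceback(hh, pp, dd, ii, params: ScoringParams) -> tuple[int, int]:
    """(n_introns, n_matched) along one optimal local path."""
    i, j = np.unravel_index(np.argmax(hh), hh.shape)
    n_intron = 0
    n_match = 0
    tol = 1e-9
    state = "H"
    while True:
        if state == "H":
            v = hh[i, j]
            if v <= tol:
                break
            if abs(v - pp[i, j]) < tol:
                state = "P"
                continue
            if abs(v - dd[i, j]) < tol:
                state = "D"
                continue
            if abs(v - ii[i, j]) < tol:
                n_intron += 1
                target = v + params.intron_penalty
                jprev = -1
                for jj in range(j - params.min_intron, -1, -1):
                    if abs(hh[i, jj] - target) < tol:
                        jprev = jj
                        break
                if jprev < 0:  # pragma: no cover - numerical guard
                    break
                j = jprev
                continue
            # codon match
            n_match += 1
            i, j = i - 1, j - 3
            continue
        if state == "P":
            v = pp[i, j]
            if abs(v - (hh[i - 1, j] - params.gap_open)) < tol:
                i, state = i - 1, "H"
            else:
                i = i - 1
            continue
        # state == "D"
        v = dd[i, j]
        if abs(v - (hh[i, j - 3] - params.gap_open)) < tol:
            j, state = j - 3, "H"
        else:
            j = j - 3
    return n_intron, n_match


def spliced_align_score(
    protein: str, dna: str, params: ScoringParams | None = None
) -> ScoreResult:
    """Best local spliced-alignment score of ``protein`` against ``dna``.

    Deterministic; the empty alignment scores 0 (local floor).  The returned
    :class:`ScoreResult` also reports the number of introns and the fraction
    of protein residues aligned along one optimal path.
    """
    if not protein or not dna:
        raise ValueError("protein and DNA must be non-empty")
    if len(dna) < 3:
        raise ValueError("DNA must be at least 3 nt")
    params = params or ScoringParams()
    smat, codon2col = params.tables()
    pidx = protein_to_indices(protein)
    caa = dna_to_codon_columns(dna, codon2col)
    hh, pp, dd, ii = dp_matrices(
        pidx, caa, smat, params.gap_open, params.gap_extend,
        params.intron_penalty, params.min_intron,
    )
    score = float(hh.max())
    if score <= 0.0:
        return ScoreResult(0.0, len(protein), 0, 0.0)
    n_intron, n_match = _traceback(hh, pp, dd, ii, params)
    return ScoreResult(score, len(protein), n_intron, n_match / len(protein))


def score_only(protein: str, dna: str, params: ScoringParams | None = None) -> float:
    """Fast path: best local score without traceback."""
    params = params or ScoringParams()
    smat, codon2col = params.tables()
    return float(
        dp_best_score(
            protein_to_indices(protein),
            dna_to_codon_columns(dna, codon2col),
            smat,
            params.gap_open,
            params.gap_extend,
            params.intron_penalty,
            params.min_intron,
        )
    )


def score_random_batch(
    n: int,
    n_reps: int,
    aa_freqs=None,
    gc: float = DEFAULT_GC,
    params: ScoringParams | None = None,
    rng=None,
) -> np.ndarray:
    """Scores of ``n_reps`` independent random protein/DNA pairs at length ``n``."""
    rng = np.random.default_rng(rng)
    params = params or ScoringParams()
    freqs = DEFAULT_AA_FREQS if aa_freqs is None else np.asarray(aa_freqs, float)
    smat, codon2col = params.tables()
    m = 3 * (n + 300)
    pmat = rng.choice(20, size=(n_reps, n), p=freqs).astype(np.int64)
    pbase = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base = rng.choice(4, size=(n_reps, m), p=pbase).astype(np.int64)
    cidx = base[:, :-2] * 16 + base[:, 1:-1] * 4 + base[:, 2:]
    cmat = codon2col[cidx]
    return dp_scores_batch(
        pmat, cmat, smat, params.gap_open, params.gap_extend,
        params.intron_penalty, params.min_intron,
    )


@dataclass
class DecayFit:
    """Fitted two-phase decay: S(N) = S0 + SpanFast e^(-KFast N) + SpanSlow e^(-KSlow N).

    ``s0`` is the large-N plateau and ``smin`` the other asymptotic anchor of
    the span; the spans may take either sign, so the curve can decay toward
    or rise toward the plateau.  ``percent_fast`` is in [0, 100] and
    KFast >= KSlow >= 0 by construction.
    """

    s0: float
    smin: float
    percent_fast: float
    k_fast: float
    k_slow: float
    rss: float = 0.0

    @property
    def span_fast(self) -> float:
        return (self.s0 - self.smin) * self.percent_fast * 0.01

    @property
    def span_slow(self) -> float:
        return (self.s0 - self.smin) * (1.0 - self.percent_fast * 0.01)

    def predict(self, n) -> np.ndarray | float:
        n = np.asarray(n, dtype=float)
        out = (
            self.s0
            + self.span_fast * np.exp(-self.k_fast * n)
            + self.span_slow * np.exp(-self.k_slow * n)
        )
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DecayFit":
        return cls(**d)


def _two_phase(n, s0, smin, percent_fast, k_fast, ratio):
    k_slow = k_fast * ratio
    span = s0 - smin
    sf = span * percent_fast * 0.01
    ss = span * (1.0 - percent_fast * 0.01)
    return s0 + sf * np.exp(-k_fast * n) + ss * np.exp(-k_slow * n)


def fit_two_phase_decay(x, y, n_starts: int = 8) -> DecayFit:
    """Least-squares two-phase decay fit with multi-start over decay rates.

    The constraint KFast >= KSlow >= 0 is enforced by parameterizing
    KSlow = KFast * ratio with ratio in [0, 1].  The objective is multimodal
    in the rates, hence log-spaced multi-starts; the best residual sum of
    squares wins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points to fit a two-phase decay")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be strictly increasing")
    yrange = float(y.max() - y.min())
    model = lmfit.Model(_two_phase, independent_vars=["n"])
    best = None
    kf_starts = np.geomspace(3e-3, 0.3, max(2, n_starts // 2))
    for kf0 in kf_starts:
        for r0 in (0.05, 0.5):
            params = model.make_params(
                s0=float(y[-1]),
                smin=float(y[0]),
                percent_fast=dict(value=60.0, min=0.0, max=100.0),
                k_fast=dict(value=float(kf0), min=0.0),
                ratio=dict(value=float(r0), min=0.0, max=1.0),
            )
            try:
                res = model.fit(y, params, n=x)
            except Exception:  # pragma: no cover - lmfit internal failure
                continue
            rss = float(np.sum(res.residual**2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        raise FitError("two-phase decay fit failed for every start")
    rss, res = best
    p = res.params
    fit = DecayFit(
        s0=float(p["s0"].value),
        smin=float(p["smin"].value),
        percent_fast=float(p["percent_fast"].value),
        k_fast=float(p["k_fast"].value),
        k_slow=float(p["k_fast"].value * p["ratio"].value),
        rss=rss,
    )
    # sanity: the fit must not be worse than the flat model, except for
    # genuinely flat data where both are equivalent
    flat_rss = float(np.sum((y - y.mean()) ** 2))
    if yrange > 0 and rss > flat_rss * 1.001:
        raise FitError("two-phase decay fit did not beat the flat model", fit)
    return fit


@dataclass
class CalibrationTable:
    """Per-length Mean/SD of random spliced-alignment scores plus decay fits."""

    length_grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_reps: int
    mean_fit: DecayFit
    sd_fit: DecayFit
    gc: float = DEFAULT_GC
    params: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self):
        self.length_grid = np.asarray(self.length_grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd < 0):
            raise ValueError("SD must be >= 0 at every grid point")
        if not np.all(np.diff(self.length_grid) > 0):
            raise ValueError("length grid must be strictly increasing")

    def to_json(self, path=None) -> str:
        doc = {
            "length_grid": self.length_grid.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n_reps": self.n_reps,
            "gc": self.gc,
            "scoring_params": asdict(self.params),
            "mean_fit": self.mean_fit.to_dict(),
            "sd_fit": self.sd_fit.to_dict(),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationTable":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            length_grid=np.array(doc["length_grid"]),
            mean=np.array(doc["mean"]),
            sd=np.array(doc["sd"]),
            n_reps=int(doc["n_reps"]),
            mean_fit=DecayFit.from_dict(doc["mean_fit"]),
            sd_fit=DecayFit.from_dict(doc["sd_fit"]),
            gc=float(doc.get("gc", DEFAULT_GC)),
            params=ScoringParams(**doc.get("scoring_params", {})),
        )


def build_calibration(
    length_grid=DEFAULT_LENGTH_GRID,
    n_reps: int = 1000,
    aa_freqs=None,
    gc: float = DEFAULT_GC,
    params: ScoringParams | None = None,
    rng=None,
) -> CalibrationTable:
    """Simulate random pairs on a length grid and fit Mean(N) and SD(N)."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(rng)
    params = params or ScoringParams()
    grid = np.asarray(sorted(length_grid), dtype=int)
    means = np.empty(grid.size)
    sds = np.empty(grid.size)
    for k, n in enumerate(grid):
        scores = score_random_batch(int(n), n_reps, aa_freqs, gc, params, rng)
        means[k] = scores.mean()
        sds[k] = scores.std(ddof=1)
    mean_fit = fit_two_phase_decay(grid, means)
    sd_fit = fit_two_phase_decay(grid, sds)
    return CalibrationTable(
        length_grid=grid.astype(float),
        mean=means,
        sd=sds,
        n_reps=n_reps,
        mean_fit=mean_fit,
        sd_fit=sd_fit,
        gc=gc,
        params=params,
    )


def predict_mean_sd(table: CalibrationTable, n: int) -> tuple[float, float]:
    """Random-expectation Mean and SD for a protein of length ``n``.

    The SD is floored at a small epsilon so downstream z-scores stay finite.
    """
    if n < 1:
        raise ValueError("protein length must be >= 1")
    mean = float(table.mean_fit.predict(n))
    sd = max(float(table.sd_fit.predict(n)), SD_EPSILON)
    return mean, sd


def genic_pvalue(score: float, n: int, table: CalibrationTable) -> float:
    """One-tailed Gaussian upper-tail p-value of ``score`` at length ``n``."""
    mean, sd = predict_mean_sd(table, n)
    return float(norm.sf((score - mean) / sd))


def is_genic(p: float, threshold: float = 1e-6) -> bool:
    """Significance call; the threshold is inclusive (p <= threshold)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return p <= threshold
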