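"""Numba kernels for the local spliced-alignment dynamic programme.

The recurrence aligns a protein query against genomic DNA with four moves:

* codon match       (i, j) -> (i+1, j+3)  scored by a substitution matrix
                                           (stop codons carry a fixed penalty)
* protein gap       (i, j) -> (i+1, j)    affine (open/extend)
* DNA codon gap     (i, j) -> (i, j+3)    affine (open/extend)
* intron            (i, j) -> (i, j+g)    flat penalty, any g >= min_intron

Local (Smith-Waterman) semantics: every cell is floored at zero and the
alignment score is the global maximum over all cells.  The per-row intron
move is serviced by a running prefix maximum, giving O(N*M) time and O(M)
memory for score-only evaluation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def dp_best_score(pidx, caa, smat, gap_open, gap_ext, intron_penalty, min_intron):
    """Best local score for one protein (aa indices) vs one DNA (codon-aa codes)."""
    n = pidx.shape[0]
    m = caa.shape[0] + 2  # DNA length; codons start at 0 .. m-3
    hprev = np.zeros(m + 1)
    hcur = np.zeros(m + 1)
    prow = np.full(m + 1, NEG)
    drow = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        runmax = NEG
        ai = pidx[i - 1]
        for j in range(m + 1):
            p = hprev[j] - gap_open
            if prow[j] - gap_ext > p:
                p = prow[j] - gap_ext
            prow[j] = p
            d = NEG
            if j >= 3:
                d = hcur[j - 3] - gap_open
                if drow[j - 3] - gap_ext > d:
                    d = drow[j - 3] - gap_ext
            drow[j] = d
            if j >= min_intron and hcur[j - min_intron] > runmax:
                runmax = hcur[j - min_intron]
            h = 0.0
            if j >= 3:
                mm = hprev[j - 3] + smat[ai, caa[j - 3]]
                if mm > h:
                    h = mm
            if p > h:
                h = p
            if d > h:
                h = d
            if runmax - intron_penalty > h:
                h = runmax - intron_penalty
            hcur[j] = h
            if h > best:
                best = h
        tmp = hprev
        hprev = hcur
        hcur = tmp
    return best


@njit(cache=True)
def dp_scores_batch(pmat, cmat, smat, gap_open, gap_ext, intron_penalty, min_intron):
    """Score a batch of independent (protein, DNA) pairs of equal sizes."""
    n = pmat.shape[0]
    out = np.empty(n)
    for r in range(n):
        out[r] = dp_best_score(
            pmat[r], cmat[r], smat, gap_open, gap_ext, intron_penalty, min_intron
        )
    return out


@njit(cache=True)
def dp_matrices(pidx, caa, smat, gap_open, gap_ext, intron_penalty, min_intron):
    """Full DP matrices (H, P, D, I) for traceback of a single pair."""
    n = pidx.shape[0]
    m = caa.shape[0] + 2
    hh = np.zeros((n + 1, m + 1))
    pp = np.full((n + 1, m + 1), NEG)
    dd = np.full((n + 1, m + 1), NEG)
    ii = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        runmax = NEG
        ai = pidx[i - 1]
        for j in range(m + 1):
            p = hh[i - 1, j] - gap_open
            if pp[i - 1, j] - gap_ext > p:
                p = pp[i - 1, j] - gap_ext
            pp[i, j] = p
            if j >= 3:
                d = hh[i, j - 3] - gap_open
                if dd[i, j - 3] - gap_ext > d:
                    d = dd[i, j - 3] - gap_ext
                dd[i, j] = d
            if j >= min_intron and hh[i, j - min_intron] > runmax:
                runmax = hh[i, j - min_intron]
            ii[i, j] = runmax - intron_penalty
            h = 0.0
            if j >= 3:
                mm = hh[i - 1, j - 3] + smat[ai, caa[j - 3]]
                if mm > h:
                    h = mm
            if pp[i, j] > h:
                h = pp[i, j]
            if dd[i, j] > h:
                h = dd[i, j]
            if ii[i, j] > h:
                h = ii[i, j]
            hh[i, j] = h
    return hh, pp, dd, ii
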