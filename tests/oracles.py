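"""Independent brute-force oracles used to cross-check the implementations.

Each oracle is written from the operation's definition with no shared code
paths: direct maxima instead of state chaining for the aligner, direct rule
application for the identification funnel, position-by-position scanning
for ORFs, all-pairs loops for peak proximity, and the quaternion (Horn)
method for superposition.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM = substitution_matrices.load("BLOSUM62")
_STOPS = {"TAA", "TAG", "TGA"}
NEG = -1e30


def oracle_spliced_score(protein, dna, gap_open=11.0, gap_ext=1.0,
                         intron_penalty=8.0, min_intron=40, stop_score=-6.0):
    """Naive O(N*M^2) evaluation of the local spliced-alignment DP."""
    n, m = len(protein), len(dna)

    def sub(a, j):
        codon = dna[j:j + 3]
        if codon in _STOPS:
            return stop_score
        return float(_BLOSUM[a][str(Seq(codon).translate())])

    h = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(m + 1):
            cands = [0.0]
            if j >= 3:
                cands.append(h[i - 1, j - 3] + sub(protein[i - 1], j - 3))
            # protein gap of t residues, direct maximum
            for t in range(1, i + 1):
                cands.append(h[i - t, j] - gap_open - (t - 1) * gap_ext)
            # DNA codon gap of t codons
            for t in range(1, j // 3 + 1):
                cands.append(h[i, j - 3 * t] - gap_open - (t - 1) * gap_ext)
            # intron jump of any g >= min_intron
            for jp in range(0, j - min_intron + 1):
                cands.append(h[i, jp] - intron_penalty)
            h[i, j] = max(cands)
            best = max(best, h[i, j])
    return best


ORTHOLOGS = {"annotated_ortholog", "unannotated_ortholog"}


def oracle_candidate_decision(profile, arthropod_hit=False,
                              reliable_distant=False, validated_distant=False):
    """Direct rule evaluation of the identification funnel on one profile.

    ``profile``: dict branch -> hit-class string.  Returns (status, branch).
    """
    if all(c == "no_alignment" for c in profile.values()):
        return "not_aligned", None
    orth = [b for b, c in profile.items() if c in ORTHOLOGS]
    if not orth:
        return "rejected_no_nongenic_support", None
    br = max(orth)
    if not any(c == "nongenic" for b, c in profile.items() if b > br):
        return "rejected_no_nongenic_support", br
    if arthropod_hit:
        return "rejected_arthropod_homolog", br
    if reliable_distant or validated_distant:
        return "rejected_distant_homolog", br
    return "candidate", br


def oracle_find_orfs(seq, min_len=75):
    """Position-by-position six-frame ORF scan; returns {(start, end, strand)}."""
    seq = seq.upper()
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        n = len(s)
        for pos in range(n - 2):
            if s[pos:pos + 3] != "ATG":
                continue
            for stop in range(pos + 3, n - 2, 3):
                if s[stop:stop + 3] in _STOPS:
                    end = stop + 3
                    if end - pos >= min_len:
                        if strand == "+":
                            out.add((pos, end, "+"))
                        else:
                            out.add((n - end, n - pos, "-"))
                    break
    return out


def oracle_peak_proximity(gene, peaks, window=500):
    """All-pairs window count / nearest distance for one gene.

    ``gene``: (start, end); ``peaks``: list of (start, end, score).
    Returns (count, mean_intensity_or_nan, distance).
    """
    gs, ge = gene
    ws, we = max(0, gs - window), ge + window
    in_win = [p for p in peaks if p[0] < we and p[1] > ws]
    count = len(in_win)
    mean_int = float(np.mean([p[2] for p in in_win])) if in_win else float("nan")
    dist = float("inf")
    for ps, pe, _ in peaks:
        if ps < ge and pe > gs:
            dist = 0.0
            break
        gap = gs - pe if pe <= gs else ps - ge
        dist = min(dist, float(gap))
    return count, mean_int, dist


def oracle_quaternion_rmsd(a, b):
    """Least-RMSD via Horn's quaternion method (independent of SVD Kabsch)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = bc.T @ ac
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (ac**2).sum() + (bc**2).sum()
    msd = max(0.0, (e0 - 2.0 * lam)) / a.shape[0]
    return float(np.sqrt(msd))


def oracle_kendall_tau_b(x, y):
    """O(n^2) pair enumeration of tie-corrected Kendall's tau-b."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def oracle_spearman(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
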