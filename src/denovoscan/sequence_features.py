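"""Sequence composition, codon usage, ORF scanning and peak proximity.

Coordinates are 0-based half-open throughout (BED convention); minus-strand
ORFs are reported on the forward genomic axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.Data import CodonTable

__all__ = [
    "CodonUsageTable",
    "OrfRecord",
    "gc_content",
    "codon_gc_by_aa",
    "build_codon_usage",
    "optimal_codon_fraction",
    "find_orfs",
    "peak_proximity",
]

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
#: synonymous codons per amino acid, alphabetical
SYNONYMOUS = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    SYNONYMOUS.setdefault(aa, []).append(codon)


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); Ns are excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    c = Counter(seq.upper())
    denom = c["A"] + c["C"] + c["G"] + c["T"]
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (c["G"] + c["C"]) / denom


def _iter_codons(cds: str):
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    for k in range(0, len(cds), 3):
        yield cds[k : k + 3]


def _translatable(cds: str) -> bool:
    """No internal stops; a trailing stop codon is allowed and dropped."""
    if len(cds) % 3 != 0:
        return False
    codons = list(_iter_codons(cds))
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    return all(c in _TABLE.forward_table for c in codons)


def _coding_codons(cds: str) -> list[str]:
    codons = list(_iter_codons(cds))
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    return codons


def codon_gc_by_aa(cds_set) -> dict[str, float]:
    """Per-amino-acid GC fraction pooled over all codon occurrences.

    Untranslatable CDS records are skipped with a log message.
    """
    gc_counts: Counter = Counter()
    base_counts: Counter = Counter()
    for name, cds in _named(cds_set):
        if not _translatable(cds):
            logger.warning("skipping untranslatable CDS %s", name)
            continue
        for codon in _coding_codons(cds):
            aa = _TABLE.forward_table[codon]
            gc_counts[aa] += codon.count("G") + codon.count("C")
            base_counts[aa] += 3
    return {aa: gc_counts[aa] / base_counts[aa] for aa in base_counts}


def _named(cds_set):
    if isinstance(cds_set, dict):
        return cds_set.items()
    return ((f"cds_{i}", s) for i, s in enumerate(cds_set))


@dataclass
class CodonUsageTable:
    """Codon counts, the optimal (most frequent) codon per amino acid, and
    the per-amino-acid GC fraction of the codons actually used."""

    counts: dict[str, int]
    optimal: dict[str, str]
    gc_by_aa: dict[str, float]

    def optimal_for(self, aa: str) -> str | None:
        return self.optimal.get(aa)


def build_codon_usage(cds_set) -> CodonUsageTable:
    """Tally synonymous codon usage; optimal = argmax count, ties alphabetical."""
    counts: Counter = Counter()
    for name, cds in _named(cds_set):
        if not _translatable(cds):
            logger.warning("skipping untranslatable CDS %s", name)
            continue
        counts.update(_coding_codons(cds))
    optimal = {}
    for aa, codons in SYNONYMOUS.items():
        observed = [(counts[c], c) for c in codons if counts[c] > 0]
        if not observed:
            continue  # amino acid never observed; optimal undefined
        top = max(c for c, _ in observed)
        best_codon = sorted(c for n, c in observed if n == top)[0]
        optimal[aa] = best_codon
    return CodonUsageTable(
        counts=dict(counts), optimal=optimal, gc_by_aa=codon_gc_by_aa(cds_set)
    )


def optimal_codon_fraction(cds: str, table: CodonUsageTable) -> float:
    """Fraction of a CDS's codons that are their amino acid's optimal codon."""
    codons = _coding_codons(cds)
    if not codons:
        raise ValueError("empty CDS")
    hits = sum(
        1
        for c in codons
        if table.optimal_for(_TABLE.forward_table[c]) == c
    )
    return hits / len(codons)


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on the forward genomic axis, 0-based half-open.

    ``length`` includes the stop codon; ``frame`` is 0..2 on the reported
    strand; ``nested`` marks internal in-frame starts sharing a parent stop.
    """

    start: int
    end: int
    strand: str
    frame: int
    length: int
    nested: bool

    def __post_init__(self):
        if self.length != self.end - self.start:
            raise ValueError("length must equal end - start")
        if self.length % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


def _scan_strand(seq: str, min_len: int, include_nested: bool):
    """Yield (start, end, frame, nested) on one strand's local coordinates."""
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG":
                starts.append(pos)
            elif codon in _STOPS:
                end = pos + 3
                for rank, s in enumerate(starts):
                    length = end - s
                    if length >= min_len:
                        yield s, end, frame, rank > 0
                    if not include_nested:
                        break
                starts = []


def find_orfs(
    seq: str, min_len: int = 75, include_nested: bool = True
) -> list[OrfRecord]:
    """All ORFs (ATG .. in-frame stop, stop included) of length >= ``min_len``
    across all six frames.  With ``include_nested`` every internal in-frame
    ATG starts its own record; records are deduplicated by (start, end,
    strand) and sorted by genomic position.
    """
    seq = seq.upper()
    n = len(seq)
    seen = set()
    out: list[OrfRecord] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for start, end, frame, nested in _scan_strand(s, min_len, include_nested):
            if strand == "+":
                gstart, gend = start, end
            else:
                gstart, gend = n - end, n - start
            key = (gstart, gend, strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                OrfRecord(gstart, gend, strand, frame, end - start, nested)
            )
    out.sort(key=lambda r: (r.start, r.end, r.strand))
    return out


def peak_proximity(
    genes: pd.DataFrame, peaks: pd.DataFrame, window: int = 500
) -> pd.DataFrame:
    """Peak counts / intensities near genes and distance to the nearest peak.

    ``genes`` needs columns (gene, contig, start, end); ``peaks`` needs
    (contig, start, end) plus an optional ``score`` intensity column.  The
    flanking window is [start - window, end + window) clamped at zero.
    Distance is the edge gap to the *gene span* (0 when overlapping);
    genes on contigs without peaks get distance +inf and count 0.
    """
    has_score = "score" in peaks.columns
    known = set(genes["contig"])
    for contig in set(peaks["contig"]) - known:
        logger.warning("peaks on unknown contig %s skipped", contig)
    by_contig = {c: df.sort_values("start") for c, df in peaks.groupby("contig")}
    rows = []
    for g in genes.itertuples(index=False):
        sub = by_contig.get(g.contig)
        if sub is None or sub.empty:
            rows.append(
                {"gene": g.gene, "peak_count": 0, "mean_intensity": math.nan,
                 "distance": math.inf}
            )
            continue
        ps = sub["start"].values
        pe = sub["end"].values
        wstart = max(0, g.start - window)
        wend = g.end + window
        in_window = (ps < wend) & (pe > wstart)
        count = int(in_window.sum())
        if has_score and count:
            mean_int = float(sub["score"].values[in_window].mean())
        else:
            mean_int = math.nan
        overlap = (ps < g.end) & (pe > g.start)
        if overlap.any():
            dist = 0.0
        else:
            left = g.start - pe[pe <= g.start]
            right = ps[ps >= g.end] - g.end
            cands = np.concatenate([left, right])
            dist = float(cands.min()) if cands.size else math.inf
        rows.append(
            {"gene": g.gene, "peak_count": count, "mean_intensity": mean_int,
             "distance": dist}
        )
    return pd.DataFrame(rows)
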