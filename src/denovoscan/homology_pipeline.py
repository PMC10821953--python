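"""De novo gene identification from syntenic and homology evidence.

The identification workflow walks each focal-species gene through a funnel:

1. the gene must be covered by the whole-genome alignment in at least one
   outgroup species (syntenic hits exist);
2. the furthest branch carrying an annotated or unannotated ortholog is the
   inferred origination branch Br_i;
3. at least one branch beyond Br_i must carry a *non-genic* hit — the
   ancestral non-coding sequence a de novo gene requires;
4. no homolog may exist in the distant arthropod outgroups;
5. no reliable homolog (two independent searches agreeing at E <= 0.001)
   may exist in species beyond Br_i;
6. no validated unannotated homolog (spliced-alignment gene prediction with
   canonical start/stop, no frameshifts, matching exon count) may exist
   beyond Br_i.

Genes surviving all stages are de novo candidates with origination branch
Br_i and an intergenic/intragenic birthplace flag.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, genic_pvalue

__all__ = [
    "HitClass",
    "CandidateStatus",
    "RawSyntenicRecord",
    "GenePrediction",
    "GeneRecord",
    "Thresholds",
    "classify_syntenic_hit",
    "infer_furthest_ortholog_branch",
    "has_outgroup_nongenic_support",
    "consensus_homolog_filter",
    "validate_unannotated_homolog",
    "classify_genomic_context",
    "call_de_novo_candidates",
    "PROFILE_SEARCHES",
    "SEARCH_NAMES",
]

SEARCH_NAMES = frozenset({"blastp", "jackhmmer_a", "jackhmmer_b", "tblastn"})
#: iterative profile searches subject to the best-domain false-positive filter
PROFILE_SEARCHES = frozenset({"jackhmmer_a", "jackhmmer_b"})


class HitClass(str, enum.Enum):
    ANNOTATED_ORTHOLOG = "annotated_ortholog"
    UNANNOTATED_ORTHOLOG = "unannotated_ortholog"
    NONGENIC = "nongenic"
    AMBIGUOUS = "ambiguous"
    NO_ALIGNMENT = "no_alignment"

    @property
    def is_ortholog(self) -> bool:
        return self in (HitClass.ANNOTATED_ORTHOLOG, HitClass.UNANNOTATED_ORTHOLOG)


class CandidateStatus(str, enum.Enum):
    CANDIDATE = "candidate"
    NOT_ALIGNED = "not_aligned"
    REJECTED_NO_NONGENIC_SUPPORT = "rejected_no_nongenic_support"
    REJECTED_ARTHROPOD_HOMOLOG = "rejected_arthropod_homolog"
    REJECTED_DISTANT_HOMOLOG = "rejected_distant_homolog"


class MalformedRecordError(ValueError):
    """A raw evidence record carries an inconsistent combination of fields."""


@dataclass(frozen=True)
class Thresholds:
    """All identification cutoffs, defaulting to the published constants."""

    blastp_evalue: float = 0.05
    genic_pvalue: float = 1e-6
    consensus_evalue: float = 0.001
    best_domain_evalue: float = 1e-5
    arthropod_evalue: float = 0.05
    tblastn_evalue: float = 1.0


@dataclass(frozen=True)
class RawSyntenicRecord:
    """One (gene, species) liftover outcome before classification.

    Exactly one evidence kind must be present: an annotated overlap with a
    blastp E-value, an unannotated region with a gene-prediction score (or a
    precomputed genic p-value), or no alignment at all.
    """

    gene: str
    species: str
    branch: int
    aligned: bool = True
    annotated: bool | None = None
    evalue: float | None = None
    score: float | None = None
    protein_length: int | None = None
    pvalue: float | None = None


@dataclass(frozen=True)
class GenePrediction:
    """A spliced-alignment gene-structure prediction in an outgroup genome."""

    gene: str
    species: str
    has_start: bool
    has_stop: bool
    frameshifts: int
    n_exons: int


@dataclass(frozen=True)
class GeneRecord:
    """A focal-species query gene."""

    gene: str
    contig: str = ""
    start: int = 0  # 0-based half-open
    end: int = 0
    strand: str = "+"
    cds: str = ""
    protein: str = ""
    n_exons: int = 1
    ortholog_exon_counts: tuple[int, ...] = ()


def classify_syntenic_hit(
    record: RawSyntenicRecord,
    calibration: CalibrationTable | None = None,
    thresholds: Thresholds = Thresholds(),
) -> HitClass:
    """Classify one liftover outcome into an ortholog / non-genic call.

    Annotated overlaps are orthologs when their blastp E-value clears the
    cutoff, ambiguous otherwise.  Unannotated regions are unannotated
    orthologs when their coding potential is significant against the random
    calibration, non-genic otherwise.
    """
    if not record.aligned:
        if record.annotated is not None or record.evalue is not None or (
            record.score is not None or record.pvalue is not None
        ):
            raise MalformedRecordError(
                f"{record.gene}/{record.species}: unaligned record carries evidence"
            )
        return HitClass.NO_ALIGNMENT
    if record.annotated is None:
        raise MalformedRecordError(
            f"{record.gene}/{record.species}: aligned record missing annotation flag"
        )
    if record.annotated:
        if record.evalue is None or record.score is not None or record.pvalue is not None:
            raise MalformedRecordError(
                f"{record.gene}/{record.species}: annotated overlap needs an E-value only"
            )
        if record.evalue < thresholds.blastp_evalue:
            return HitClass.ANNOTATED_ORTHOLOG
        return HitClass.AMBIGUOUS
    if record.evalue is not None:
        raise MalformedRecordError(
            f"{record.gene}/{record.species}: unannotated region with blastp E-value"
        )
    if record.pvalue is not None:
        p = record.pvalue
    elif record.score is not None and record.protein_length is not None:
        if calibration is None:
            raise MalformedRecordError(
                f"{record.gene}/{record.species}: score given but no calibration table"
            )
        p = genic_pvalue(record.score, record.protein_length, calibration)
    else:
        raise MalformedRecordError(
            f"{record.gene}/{record.species}: unannotated region without score or p-value"
        )
    if p <= thresholds.genic_pvalue:
        return HitClass.UNANNOTATED_ORTHOLOG
    return HitClass.NONGENIC


def infer_furthest_ortholog_branch(profile: Mapping[int, HitClass]) -> int | None:
    """Furthest branch carrying an (annotated or unannotated) ortholog.

    Patchy presence is tolerated: intermediate non-genic branches between
    two ortholog-bearing branches are read as secondary losses, and the
    furthest ortholog still defines the origination branch.  Returns ``None``
    when no branch carries an ortholog.
    """
    if not profile:
        raise ValueError("empty hit-class profile")
    ortholog_branches = [b for b, c in profile.items() if c.is_ortholog]
    return max(ortholog_branches) if ortholog_branches else None


def has_outgroup_nongenic_support(profile: Mapping[int, HitClass], br_i: int) -> bool:
    """True iff at least one branch beyond ``br_i`` carries a non-genic hit."""
    if br_i not in profile:
        raise ValueError(f"branch {br_i} not covered by profile")
    return any(c is HitClass.NONGENIC for b, c in profile.items() if b > br_i)


def consensus_homolog_filter(
    evidence: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> tuple[bool, pd.DataFrame]:
    """Two-search consensus for a reliable distant homolog.

    ``evidence`` holds rows for one gene, already restricted to subject
    species more distant than the inferred origination branch, with columns
    ``subject_species``, ``search``, ``evalue`` and (for profile searches)
    ``best_domain_evalue``.  Profile-search rows whose best single-domain
    E-value exceeds the false-positive cutoff are discarded first.  A
    reliable homolog exists when some subject species is supported by at
    least two distinct searches, each at E <= the consensus cutoff.
    """
    if evidence.empty:
        return False, evidence
    ev = evidence.copy()
    if "best_domain_evalue" in ev.columns:
        bad = ev["search"].isin(PROFILE_SEARCHES) & (
            ev["best_domain_evalue"].fillna(0.0) > thresholds.best_domain_evalue
        )
        ev = ev[~bad]
    ev = ev[ev["evalue"] <= thresholds.consensus_evalue]
    if ev.empty:
        return False, ev
    counts = ev.groupby("subject_species")["search"].nunique()
    reliable_species = counts[counts >= 2].index
    support = ev[ev["subject_species"].isin(reliable_species)]
    return len(reliable_species) > 0, support


def validate_unannotated_homolog(
    prediction: GenePrediction, query: GeneRecord
) -> bool:
    """Gene-structure sanity check for a putative unannotated distant homolog.

    Requires a canonical start and stop codon, zero frameshifts, and an exon
    count matching the query or any of its recorded orthologs.
    """
    allowed_exons = {query.n_exons, *query.ortholog_exon_counts}
    return (
        prediction.has_start
        and prediction.has_stop
        and prediction.frameshifts == 0
        and prediction.n_exons in allowed_exons
    )


def classify_genomic_context(
    gene: GeneRecord, annotation: Iterable[GeneRecord]
) -> str:
    """``intragenic`` iff the gene's span overlaps any *other* annotated gene.

    Overlap is strand-blind and computed on 0-based half-open spans, so
    abutting genes (end == start) do not overlap.
    """
    for other in annotation:
        if other.gene == gene.gene or other.contig != gene.contig:
            continue
        if gene.start < other.end and other.start < gene.end:
            return "intragenic"
    return "intergenic"


#: ordered funnel stages as recorded in ``filters_passed``
FUNNEL_STAGES = (
    "aligned",
    "ortholog_branch",
    "outgroup_nongenic",
    "no_arthropod_homolog",
    "no_consensus_distant_homolog",
    "tblastn_validation",
)


def _classify_profiles(
    hits: pd.DataFrame,
    calibration: CalibrationTable | None,
    thresholds: Thresholds,
) -> dict[str, dict[int, HitClass]]:
    """Per-gene branch -> HitClass profiles, collapsing species within branches.

    An ortholog in any species of a branch marks the branch as orthologous;
    failing that, a non-genic hit in any species marks it non-genic; then
    ambiguous; an entirely unaligned branch is no-alignment.
    """
    rank = {
        HitClass.ANNOTATED_ORTHOLOG: 4,
        HitClass.UNANNOTATED_ORTHOLOG: 4,
        HitClass.NONGENIC: 3,
        HitClass.AMBIGUOUS: 2,
        HitClass.NO_ALIGNMENT: 1,
    }
    profiles: dict[str, dict[int, HitClass]] = {}
    for row in hits.itertuples(index=False):
        rec = RawSyntenicRecord(
            gene=row.gene,
            species=row.species,
            branch=int(row.branch),
            aligned=bool(row.aligned),
            annotated=(None if pd.isna(row.annotated) else bool(row.annotated)),
            evalue=(None if pd.isna(row.evalue) else float(row.evalue)),
            score=(None if pd.isna(row.score) else float(row.score)),
            protein_length=(
                None if pd.isna(row.protein_length) else int(row.protein_length)
            ),
            pvalue=(
                None
                if "pvalue" not in hits.columns or pd.isna(row.pvalue)
                else float(row.pvalue)
            ),
        )
        cls = classify_syntenic_hit(rec, calibration, thresholds)
        prof = profiles.setdefault(rec.gene, {})
        prev = prof.get(rec.branch)
        if prev is None or rank[cls] > rank[prev]:
            prof[rec.branch] = cls
    return profiles


def call_de_novo_candidates(
    hits: pd.DataFrame,
    evidence: pd.DataFrame | None = None,
    arthropod_evidence: pd.DataFrame | None = None,
    calibration: CalibrationTable | None = None,
    predictions: Sequence[GenePrediction] = (),
    genes: Mapping[str, GeneRecord] | None = None,
    annotation: Sequence[GeneRecord] = (),
    branch_of_species: Mapping[str, int] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Run the identification funnel over all genes in the hit table.

    Parameters mirror the evidence sources: ``hits`` is the per-(gene,
    species) syntenic table; ``evidence`` the distant-homolog search rows
    (with a ``subject_branch`` column or a ``branch_of_species`` map);
    ``arthropod_evidence`` rows of (gene, evalue) against the distant
    arthropod outgroups; ``predictions`` validated-homolog candidates from
    translated searches beyond Br_i.  Returns one row per gene with the
    final status, inferred branch, genomic context and the ordered stage
    outcomes.
    """
    required = {"gene", "species", "branch", "aligned", "annotated",
                "evalue", "score", "protein_length"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    for name, df, keycol in (
        ("evidence", evidence, "gene"),
        ("arthropod_evidence", arthropod_evidence, "gene"),
    ):
        if df is not None and not df.empty:
            unknown = set(df[keycol]) - set(hits["gene"])
            if unknown:
                raise ValueError(
                    f"{name} table references unknown genes: {sorted(unknown)[:5]}"
                )

    profiles = _classify_profiles(hits, calibration, thresholds)
    genes = genes or {}
    ann_list = list(annotation)
    pred_by_gene: dict[str, list[GenePrediction]] = {}
    for p in predictions:
        pred_by_gene.setdefault(p.gene, []).append(p)

    rows = []
    for gene_id in sorted(profiles):
        profile = profiles[gene_id]
        stages: list[str] = []
        status = None
        br_i: int | None = None

        aligned = any(c is not HitClass.NO_ALIGNMENT for c in profile.values())
        stages.append(f"aligned:{'pass' if aligned else 'fail'}")
        if not aligned:
            status = CandidateStatus.NOT_ALIGNED

        if status is None:
            br_i = infer_furthest_ortholog_branch(profile)
            stages.append(f"ortholog_branch:{br_i if br_i is not None else 'none'}")
            if br_i is None:
                status = CandidateStatus.REJECTED_NO_NONGENIC_SUPPORT

        if status is None:
            ok = has_outgroup_nongenic_support(profile, br_i)
            stages.append(f"outgroup_nongenic:{'pass' if ok else 'fail'}")
            if not ok:
                status = CandidateStatus.REJECTED_NO_NONGENIC_SUPPORT

        if status is None:
            arth_hit = False
            if arthropod_evidence is not None and not arthropod_evidence.empty:
                sub = arthropod_evidence[arthropod_evidence["gene"] == gene_id]
                arth_hit = bool((sub["evalue"] < thresholds.arthropod_evalue).any())
            stages.append(f"no_arthropod_homolog:{'fail' if arth_hit else 'pass'}")
            if arth_hit:
                status = CandidateStatus.REJECTED_ARTHROPOD_HOMOLOG

        if status is None:
            reliable = False
            if evidence is not None and not evidence.empty:
                sub = evidence[evidence["gene"] == gene_id]
                if "subject_branch" in sub.columns:
                    sub = sub[sub["subject_branch"] > br_i]
                elif branch_of_species is not None:
                    sb = sub["subject_species"].map(branch_of_species)
                    sub = sub[sb.fillna(np.inf) > br_i]
                reliable, _ = consensus_homolog_filter(sub, thresholds)
            stages.append(
                f"no_consensus_distant_homolog:{'fail' if reliable else 'pass'}"
            )
            if reliable:
                status = CandidateStatus.REJECTED_DISTANT_HOMOLOG

        if status is None:
            query = genes.get(gene_id, GeneRecord(gene=gene_id))
            validated = any(
                validate_unannotated_homolog(p, query)
                for p in pred_by_gene.get(gene_id, [])
            )
            stages.append(f"tblastn_validation:{'fail' if validated else 'pass'}")
            if validated:
                status = CandidateStatus.REJECTED_DISTANT_HOMOLOG

        if status is None:
            status = CandidateStatus.CANDIDATE

        context = ""
        if gene_id in genes and ann_list:
            context = classify_genomic_context(genes[gene_id], ann_list)
        rows.append(
            {
                "gene": gene_id,
                "status": status.value,
                "branch": br_i if br_i is not None else pd.NA,
                "context": context,
                "filters_passed": ";".join(stages),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "status", "branch", "context", "filters_passed"])
    out["branch"] = out["branch"].astype("Int64")
    return out


def funnel_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Reconstruct the identification funnel from per-gene stage outcomes."""
    total = len(calls)
    counts = {"input": total}
    survivors = calls
    checks = (
        ("aligned", "aligned:pass"),
        ("with_ortholog_branch", "ortholog_branch:"),
        ("with_outgroup_nongenic", "outgroup_nongenic:pass"),
        ("no_arthropod_homolog", "no_arthropod_homolog:pass"),
        ("no_consensus_distant_homolog", "no_consensus_distant_homolog:pass"),
        ("tblastn_validated", "tblastn_validation:pass"),
    )
    for name, token in checks:
        if name == "with_ortholog_branch":
            mask = survivors["filters_passed"].str.contains(
                r"ortholog_branch:\d", regex=True
            )
        else:
            mask = survivors["filters_passed"].str.contains(token, regex=False)
        survivors = survivors[mask]
        counts[name] = int(len(survivors))
    counts["candidates"] = int((calls["status"] == "candidate").sum())
    return counts
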