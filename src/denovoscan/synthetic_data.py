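"""Synthetic datasets with planted ground truth for the whole pipeline.

The generator emulates the study design the identification workflow assumes:
a focal species nested inside a ladder of outgroup branches (Br_1 closest,
Br_n deepest), genes planted either as *de novo* births on a known branch or
as ancient genes with deep homology; per-species syntenic evidence with
ortholog decay and non-genic outgroup hits; homology-search E-value tables;
per-residue confidence (pLDDT) profiles from three foldability archetypes;
helix-like and coil-like 3D ensembles; a 27-tissue expression matrix with
planted male-biased genes; and 6-stage testis profiles drawn from four
archetype templates.

All randomness flows from a single integer seed through per-component,
per-gene substreams, so outputs are reproducible byte-for-byte and stable
under reordering of genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_AA_FREQS,
    DEFAULT_GC,
    CalibrationTable,
    predict_mean_sd,
)
from .expression_metrics import ExpressionMatrix, STAGE_NAMES
from .homology_pipeline import GeneRecord
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "LadderTree",
    "SimulatedDataset",
    "generate_species_tree",
    "simulate_gene_histories",
    "simulate_homolog_evidence",
    "simulate_plddt_profiles",
    "simulate_structure_ensemble",
    "simulate_expression",
    "simulate",
    "write_outputs",
    "DEFAULT_STAGE_ARCHETYPES",
]

_BASES = "ACGT"

#: four spermatogenesis stage-profile templates (rows), peaking from early
#: to late across the six ordered germline stages (columns)
DEFAULT_STAGE_ARCHETYPES = np.array(
    [
        [2.0, 1.5, 0.5, 0.2, 0.1, 0.1],
        [0.5, 1.5, 2.0, 1.0, 0.3, 0.2],
        [0.2, 0.5, 1.0, 2.0, 1.5, 0.5],
        [0.1, 0.1, 0.3, 0.8, 1.5, 2.0],
    ]
)

TISSUE_NAMES = tuple(
    ["testis"] + [f"tissue_{i:02d}" for i in range(1, 27)]
)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic dataset.

    Defaults emulate the real study's shape: a 9-branch outgroup ladder,
    500 genes of which 30% are de novo births, foldability archetype
    frequencies matching the published class proportions, and E-value
    distributions that separate true homologs from unrelated pairs cleanly
    at the default thresholds.
    """

    n_branches: int = 9
    n_genes: int = 500
    frac_de_novo: float = 0.3
    branch_weights: np.ndarray | None = None  # origination probability per branch
    aa_freqs: np.ndarray = field(default_factory=lambda: DEFAULT_AA_FREQS.copy())
    gc_content: float = DEFAULT_GC
    # log10 E-value ranges
    evalue_true_homolog: tuple[float, float] = (-30.0, -6.0)
    evalue_unrelated: tuple[float, float] = (-2.0, 2.0)
    #: fraction of within-branch orthologs left unannotated
    frac_unannotated: float = 0.2
    #: beyond the origination branch: probability a species shows a non-genic
    #: hit (the rest are unaligned)
    p_outgroup_nongenic: float = 0.8
    #: probability a de novo gene draws a spurious (above-threshold)
    #: arthropod hit row per arthropod species
    p_arthropod_spurious: float = 0.2
    #: noise knob: probability a de novo gene gets a *sub-threshold*
    #: contaminating arthropod hit (0 = clean evidence)
    frac_arthropod_contamination: float = 0.0
    n_arthropod_species: int = 8
    frac_intragenic_de_novo: float = 0.3
    frac_intragenic_other: float = 0.1
    #: (well, partial, none) archetype probabilities
    fold_probs_de_novo: tuple[float, float, float] = (0.06, 0.54, 0.40)
    fold_probs_other: tuple[float, float, float] = (0.50, 0.40, 0.10)
    frac_male_biased_de_novo: float = 0.6
    frac_male_biased_other: float = 0.1
    expression_archetypes: np.ndarray = field(
        default_factory=lambda: DEFAULT_STAGE_ARCHETYPES.copy()
    )
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_branches < 2:
            raise ValueError("need at least 2 branches")
        for name in (
            "frac_de_novo",
            "gc_content",
            "frac_unannotated",
            "p_outgroup_nongenic",
            "p_arthropod_spurious",
            "frac_arthropod_contamination",
            "frac_intragenic_de_novo",
            "frac_intragenic_other",
            "frac_male_biased_de_novo",
            "frac_male_biased_other",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.branch_weights is None:
            # plantable branches only: a birth on the deepest branch has no
            # outgroup left to witness the ancestral non-coding state
            w = np.zeros(self.n_branches)
            w[: self.n_branches - 1] = 1.0 / (self.n_branches - 1)
            self.branch_weights = w
        else:
            self.branch_weights = np.asarray(self.branch_weights, dtype=float)
        if len(self.branch_weights) != self.n_branches:
            raise ValueError("branch_weights must have one entry per branch")
        if abs(self.branch_weights.sum() - 1.0) > 1e-9:
            raise ValueError("branch_weights must sum to 1")
        self.aa_freqs = np.asarray(self.aa_freqs, dtype=float)
        if abs(self.aa_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("aa_freqs must sum to 1")
        for probs in (self.fold_probs_de_novo, self.fold_probs_other):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("fold archetype probabilities must sum to 1")
        self.expression_archetypes = np.asarray(self.expression_archetypes, float)
        if self.expression_archetypes.shape[1] != 6:
            raise ValueError("expression archetypes must cover 6 stages")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Splittable substream: one generator per (component, gene, ...) key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class LadderTree:
    """A pure ladder: branch i separates the focal taxon from outgroup i."""

    n_branches: int
    focal: str = "sp0"

    @property
    def species(self) -> list[str]:
        return [self.focal] + [f"sp{i}" for i in range(1, self.n_branches + 1)]

    def branch_of_species(self) -> dict[str, int]:
        return {f"sp{i}": i for i in range(1, self.n_branches + 1)}

    def to_newick(self) -> str:
        inner = f"{self.focal}:1"
        for i in range(1, self.n_branches + 1):
            inner = f"({inner},sp{i}:1)Br_{i}:1"
        return inner[: -2] + ";"


def generate_species_tree(n_branches: int) -> LadderTree:
    """Ladder species tree with the focal taxon at the tip of the comb."""
    if n_branches < 2:
        raise ValueError("need at least 2 branches")
    return LadderTree(n_branches=n_branches)


def _random_cds(protein_len: int, gc: float, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + stop, at approximately the given GC."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < protein_len:
        c = "".join(_BASES[i] for i in rng.choice(4, size=3, p=p))
        if c not in stops:
            codons.append(c)
    codons.append(("TAA", "TAG", "TGA")[rng.integers(3)])
    return "".join(codons)


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds[:-3]).translate())


def simulate_gene_histories(
    config: SimulationConfig,
    calibration: CalibrationTable | None = None,
):
    """Plant gene origination histories and emit the syntenic-hit table.

    Returns ``(genes, annotation, hits, truth)``: the query gene records,
    background annotation used for genomic-context calls, the per (gene,
    species) raw syntenic table, and the planted-truth frame.  When a
    calibration table is supplied, unannotated regions carry spliced-
    alignment *scores* consistent with their planted genic p-values (via the
    inverse Gaussian), so the downstream pipeline re-derives the p-values
    itself; otherwise the p-values are emitted directly.
    """
    seed = config.seed
    nb = config.n_branches
    truth_rows = []
    genes: dict[str, GeneRecord] = {}
    annotation: list[GeneRecord] = []
    hit_rows = []
    slot = 20_000

    for gi in range(config.n_genes):
        gid = f"g{gi:04d}"
        rng = _rng(seed, 1, gi)
        is_de_novo = rng.random() < config.frac_de_novo
        if is_de_novo:
            branch = int(rng.choice(nb, p=config.branch_weights)) + 1
            plen = int(np.clip(np.round(np.exp(rng.normal(np.log(130), 0.45))), 70, 600))
            intragenic = rng.random() < config.frac_intragenic_de_novo
            male_biased = rng.random() < config.frac_male_biased_de_novo
            fold = rng.choice(("well", "partial", "none"), p=config.fold_probs_de_novo)
        else:
            branch = None
            plen = int(np.clip(np.round(np.exp(rng.normal(np.log(420), 0.55))), 100, 2000))
            intragenic = rng.random() < config.frac_intragenic_other
            male_biased = rng.random() < config.frac_male_biased_other
            fold = rng.choice(("well", "partial", "none"), p=config.fold_probs_other)
        expr_archetype = int(rng.integers(config.expression_archetypes.shape[0])) + 1

        cds = _random_cds(plen, config.gc_content, rng)
        protein = _translate(cds)
        base = gi * slot
        bg = GeneRecord(
            gene=f"bg{gi:04d}", contig="chr_sim", start=base + 2_000,
            end=base + 8_000, strand="+",
        )
        annotation.append(bg)
        glen = len(cds)
        if intragenic:
            gstart = base + 4_000
        else:
            gstart = base + 12_000
        rec = GeneRecord(
            gene=gid, contig="chr_sim", start=gstart, end=gstart + glen,
            strand="+", cds=cds, protein=protein, n_exons=1 + int(rng.integers(3)),
        )
        genes[gid] = rec
        truth_rows.append(
            {
                "gene": gid,
                "origin_branch": branch if is_de_novo else "ancient",
                "context": "intragenic" if intragenic else "intergenic",
                "fold_archetype": fold,
                "expr_archetype": expr_archetype,
                "male_biased": bool(male_biased),
                "protein_length": plen,
            }
        )

        # syntenic evidence per branch species
        furthest = branch if is_de_novo else nb
        got_nongenic = False
        for b in range(1, nb + 1):
            sp = f"sp{b}"
            row = {
                "gene": gid, "species": sp, "branch": b, "aligned": True,
                "annotated": np.nan, "evalue": np.nan, "score": np.nan,
                "protein_length": plen, "pvalue": np.nan,
            }
            if b <= furthest:
                if rng.random() < config.frac_unannotated:
                    row["annotated"] = False
                    row["pvalue"] = 10.0 ** rng.uniform(-12, -8)
                else:
                    row["annotated"] = True
                    row["evalue"] = 10.0 ** rng.uniform(*config.evalue_true_homolog)
            else:
                if rng.random() < config.p_outgroup_nongenic:
                    row["annotated"] = False
                    row["pvalue"] = rng.uniform(0.0, 1.0)
                    got_nongenic = True
                else:
                    row["aligned"] = False
            hit_rows.append(row)
        if is_de_novo and furthest < nb and not got_nongenic:
            # a plantable candidate needs at least one non-genic witness
            row = hit_rows[-(nb - furthest)]
            row["aligned"] = True
            row["annotated"] = False
            row["pvalue"] = rng.uniform(0.0, 1.0)

    hits = pd.DataFrame(hit_rows)
    if calibration is not None:
        mask = hits["pvalue"].notna()
        for idx in hits.index[mask]:
            n = int(hits.at[idx, "protein_length"])
            mean, sd = predict_mean_sd(calibration, n)
            z = norm.isf(hits.at[idx, "pvalue"])
            hits.at[idx, "score"] = mean + z * sd
        hits.loc[mask, "pvalue"] = np.nan
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return genes, annotation, hits, truth


SEARCHES = ("blastp", "jackhmmer_a", "jackhmmer_b")


def simulate_homolog_evidence(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distant-homolog and arthropod search tables consistent with the truth.

    Ancient genes receive true-homolog E-values in at least two independent
    searches against subjects beyond every branch, and real arthropod hits.
    De novo genes only draw unrelated-range E-values (never passing the
    consensus cutoff), and arthropod rows conditioned above the exclusion
    threshold unless the contamination knob is turned up.
    """
    ev_rows = []
    arth_rows = []
    lo_u, hi_u = config.evalue_unrelated
    arth_floor = math.log10(0.05)
    for gi, (gid, row) in enumerate(truth.iterrows()):
        rng = _rng(config.seed, 2, gi)
        ancient = row["origin_branch"] == "ancient"
        if ancient:
            n_sub = 1 + int(rng.integers(2))
            for s in range(n_sub):
                subject = f"distant_sp{s}"
                for search in SEARCHES[: 2 + int(rng.integers(2))]:
                    ev_rows.append(
                        {
                            "gene": gid,
                            "subject_species": subject,
                            "subject_branch": config.n_branches + 1,
                            "search": search,
                            "evalue": 10.0 ** rng.uniform(*config.evalue_true_homolog),
                            "best_domain_evalue": 10.0 ** rng.uniform(-20, -8),
                        }
                    )
            for a in range(config.n_arthropod_species):
                if rng.random() < 0.6:
                    arth_rows.append(
                        {
                            "gene": gid,
                            "species": f"arth_{a}",
                            "evalue": 10.0 ** rng.uniform(*config.evalue_true_homolog),
                        }
                    )
        else:
            # spurious, non-consensus rows only
            for search in SEARCHES:
                if rng.random() < 0.3:
                    ev_rows.append(
                        {
                            "gene": gid,
                            "subject_species": f"distant_sp{int(rng.integers(3))}",
                            "subject_branch": config.n_branches + 1,
                            "search": search,
                            "evalue": 10.0 ** rng.uniform(lo_u, hi_u),
                            "best_domain_evalue": 10.0 ** rng.uniform(-4, 2),
                        }
                    )
            for a in range(config.n_arthropod_species):
                if rng.random() < config.p_arthropod_spurious:
                    arth_rows.append(
                        {
                            "gene": gid,
                            "species": f"arth_{a}",
                            "evalue": 10.0 ** rng.uniform(arth_floor, hi_u),
                        }
                    )
            if rng.random() < config.frac_arthropod_contamination:
                arth_rows.append(
                    {
                        "gene": gid,
                        "species": f"arth_{int(rng.integers(config.n_arthropod_species))}",
                        "evalue": 10.0 ** rng.uniform(-10, -2),
                    }
                )
    cols_ev = ["gene", "subject_species", "subject_branch", "search", "evalue",
               "best_domain_evalue"]
    cols_ar = ["gene", "species", "evalue"]
    evidence = pd.DataFrame(ev_rows, columns=cols_ev)
    arthropod = pd.DataFrame(arth_rows, columns=cols_ar)
    return evidence, arthropod


def simulate_plddt_profiles(
    truth: pd.DataFrame, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Per-residue confidence profiles from the planted foldability archetypes.

    well: i.i.d. N(88, 4); partial: one contiguous confident segment of
    max(60, 0.4 L) residues at N(80, 4) over an N(45, 8) background;
    none: N(40, 8).  All scores clipped to [0, 100].
    """
    out = {}
    for gi, (gid, row) in enumerate(truth.iterrows()):
        rng = _rng(config.seed, 3, gi)
        L = int(row["protein_length"])
        arch = row["fold_archetype"]
        if arch == "well":
            scores = rng.normal(88, 4, L)
        elif arch == "partial":
            seg = max(60, int(round(0.4 * L)))
            seg = min(seg, L)
            start = int(rng.integers(0, L - seg + 1))
            scores = rng.normal(45, 8, L)
            scores[start : start + seg] = rng.normal(80, 4, seg)
        else:
            scores = rng.normal(40, 8, L)
        out[gid] = np.clip(scores, 0.0, 100.0)
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def ideal_helix(length: int, rise: float = 1.5, turn_deg: float = 100.0,
                radius: float = 2.3) -> np.ndarray:
    """CA trace of an ideal alpha helix."""
    i = np.arange(length)
    t = np.deg2rad(turn_deg) * i
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * i])


def _self_avoiding_walk(length: int, rng: np.random.Generator,
                        step: float = 3.8, min_dist: float = 3.0) -> np.ndarray:
    coords = np.zeros((length, 3))
    for i in range(1, length):
        for _ in range(100):
            d = rng.normal(size=3)
            d *= step / np.linalg.norm(d)
            cand = coords[i - 1] + d
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)) >= min_dist:
                coords[i] = cand
                break
        else:  # extremely rare; accept the clash rather than loop forever
            coords[i] = cand
    return coords


def simulate_structure_ensemble(
    archetype: str,
    n_models: int,
    length: int = 100,
    noise: float = 0.5,
    rng=None,
) -> np.ndarray:
    """Coordinate ensembles: perturbed ideal helices or random coils.

    ``well`` models share one ideal helix backbone perturbed per model by
    Gaussian noise and an arbitrary rigid motion; ``none`` models are
    independent self-avoiding random walks.  Returns (n_models, length, 3).
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    if archetype not in ("well", "none"):
        raise ValueError("archetype must be 'well' or 'none'")
    rng = np.random.default_rng(rng)
    out = np.empty((n_models, length, 3))
    base = ideal_helix(length)
    for m in range(n_models):
        if archetype == "well":
            coords = base + rng.normal(0, noise, (length, 3)) if noise > 0 else base.copy()
        else:
            coords = _self_avoiding_walk(length, rng)
        rot = _random_rotation(rng)
        out[m] = coords @ rot.T + rng.uniform(-20, 20, 3)
    return out


def simulate_expression(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """27-tissue FPKM matrix with sex means/SDs, plus the stage matrix.

    Male-biased planted genes are testis-dominant and at least 4x higher in
    the male whole body than in the female; unbiased genes share one sex
    level so their z-scores are centered at zero.  The stage matrix holds
    the male-biased genes, each drawn from its planted archetype template
    with multiplicative noise.
    """
    genes = list(truth.index)
    n_t = len(TISSUE_NAMES)
    vals = np.empty((len(genes), n_t))
    male_mean = np.empty(len(genes))
    female_mean = np.empty(len(genes))
    male_sd = np.empty(len(genes))
    female_sd = np.empty(len(genes))
    stage_rows = {}
    archetypes = config.expression_archetypes
    for gi, gid in enumerate(genes):
        rng = _rng(config.seed, 4, gi)
        base = float(np.exp(rng.normal(np.log(8), 0.8)))
        biased = bool(truth.at[gid, "male_biased"])
        if biased:
            profile = base * 0.02 * np.exp(rng.normal(0, 0.3, n_t))
            profile[0] = base * 25 * np.exp(rng.normal(0, 0.2))  # testis
            m_true = base * float(rng.uniform(5, 12))
            f_true = base
        else:
            profile = base * np.exp(rng.normal(0, 0.3, n_t))
            m_true = f_true = base
        vals[gi] = profile
        reps_m = np.abs(rng.normal(m_true, 0.15 * m_true + 0.05, config.n_replicates))
        reps_f = np.abs(rng.normal(f_true, 0.15 * f_true + 0.05, config.n_replicates))
        male_mean[gi] = reps_m.mean()
        female_mean[gi] = reps_f.mean()
        male_sd[gi] = reps_m.std(ddof=1)
        female_sd[gi] = reps_f.std(ddof=1)
        if biased:
            template = archetypes[int(truth.at[gid, "expr_archetype"]) - 1]
            stage_rows[gid] = template * np.exp(rng.normal(0, 0.15, 6))
    idx = pd.Index(genes, name="gene")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(vals, index=idx, columns=list(TISSUE_NAMES)),
        unit="FPKM",
        male_mean=pd.Series(male_mean, index=idx),
        female_mean=pd.Series(female_mean, index=idx),
        male_sd=pd.Series(male_sd, index=idx),
        female_sd=pd.Series(female_sd, index=idx),
    )
    stage = pd.DataFrame.from_dict(
        stage_rows, orient="index", columns=list(STAGE_NAMES)
    )
    stage.index.name = "gene"
    return matrix, stage


def simulate_atac_peaks(
    genes: dict[str, GeneRecord], truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """BED-style ATAC peaks enriched near de novo gene starts."""
    rows = []
    contig_end = max(g.end for g in genes.values()) + 10_000
    for gi, (gid, row) in enumerate(truth.iterrows()):
        rng = _rng(config.seed, 5, gi)
        g = genes[gid]
        if row["origin_branch"] != "ancient" and rng.random() < 0.8:
            center = int(rng.integers(g.start - 400, g.end + 400))
            start = max(0, center - 150)
            rows.append(
                {"contig": g.contig, "start": start, "end": start + 300,
                 "name": f"peak_{gid}", "score": float(rng.uniform(50, 1000))}
            )
    bg_rng = _rng(config.seed, 5, 10**6)
    for k in range(len(genes) // 2):
        start = int(bg_rng.integers(0, contig_end))
        rows.append(
            {"contig": "chr_sim", "start": start, "end": start + 300,
             "name": f"peak_bg{k}", "score": float(bg_rng.uniform(50, 1000))}
        )
    return pd.DataFrame(rows).sort_values(["start", "name"]).reset_index(drop=True)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: LadderTree
    genes: dict[str, GeneRecord]
    annotation: list[GeneRecord]
    hits: pd.DataFrame
    evidence: pd.DataFrame
    arthropod: pd.DataFrame
    truth: pd.DataFrame
    plddt: dict[str, np.ndarray]
    expression: ExpressionMatrix
    stage: pd.DataFrame
    peaks: pd.DataFrame


def simulate(
    config: SimulationConfig | None = None,
    calibration: CalibrationTable | None = None,
) -> SimulatedDataset:
    """Generate a complete dataset with planted ground truth."""
    config = config or SimulationConfig()
    tree = generate_species_tree(config.n_branches)
    genes, annotation, hits, truth = simulate_gene_histories(config, calibration)
    evidence, arthropod = simulate_homolog_evidence(truth, config)
    plddt = simulate_plddt_profiles(truth, config)
    expression, stage = simulate_expression(truth, config)
    peaks = simulate_atac_peaks(genes, truth, config)
    return SimulatedDataset(
        config=config, tree=tree, genes=genes, annotation=annotation,
        hits=hits, evidence=evidence, arthropod=arthropod, truth=truth,
        plddt=plddt, expression=expression, stage=stage, peaks=peaks,
    )


def write_outputs(ds: SimulatedDataset, outdir) -> None:
    """Serialize a dataset to standard formats (FASTA/GFF3/newick/TSV/BED/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fh:
        for gid in sorted(ds.genes):
            fh.write(f">{gid}\n{ds.genes[gid].protein}\n")
    with open(outdir / "cds.fasta", "w") as fh:
        for gid in sorted(ds.genes):
            fh.write(f">{gid}\n{ds.genes[gid].cds}\n")
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(ds.tree.to_newick() + "\n")
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in sorted(ds.annotation, key=lambda r: r.start) + [
            ds.genes[g] for g in sorted(ds.genes)
        ]:
            # GFF3 is 1-based inclusive
            fh.write(
                f"{rec.contig}\tsim\tgene\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\tID={rec.gene}\n"
            )
    ds.hits.to_csv(outdir / "syntenic_hits.tsv", sep="\t", index=False)
    ds.evidence.to_csv(outdir / "homolog_evidence.tsv", sep="\t", index=False)
    ds.arthropod.to_csv(outdir / "arthropod_evidence.tsv", sep="\t", index=False)
    with open(outdir / "plddt.tsv", "w") as fh:
        fh.write("gene\tresidue_index\tplddt\n")
        for gid in sorted(ds.plddt):
            for i, v in enumerate(ds.plddt[gid], start=1):
                fh.write(f"{gid}\t{i}\t{v:.3f}\n")
    expr = ds.expression
    expr.values.to_csv(outdir / "expression_fpkm.tsv", sep="\t")
    pd.DataFrame(
        {
            "male_mean": expr.male_mean,
            "female_mean": expr.female_mean,
            "male_sd": expr.male_sd,
            "female_sd": expr.female_sd,
        }
    ).to_csv(outdir / "sex_expression.tsv", sep="\t")
    ds.stage.to_csv(outdir / "stage_profiles.tsv", sep="\t")
    with open(outdir / "peaks.bed", "w") as fh:
        for p in ds.peaks.itertuples(index=False):
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.1f}\n")
    truth = ds.truth.reset_index().to_dict(orient="records")
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"config": _config_doc(ds.config), "genes": truth}, fh, indent=1)


def _config_doc(config: SimulationConfig) -> dict:
    doc = asdict(config)
    for k, v in doc.items():
        if isinstance(v, np.ndarray):
            doc[k] = v.tolist()
    return doc


def write_pdb_ensemble(coords: np.ndarray, path) -> None:
    """Write an (n_models, L, 3) CA ensemble as a multi-MODEL PDB file."""
    with open(path, "w") as fh:
        for m, model in enumerate(coords, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (x, y, z) in enumerate(model, start=1):
                fh.write(
                    f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
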