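"""End-to-end orchestration: calibrate, scan, characterize, report.

``run_pipeline`` drives the full analysis over a dataset (typically a
synthetic one with planted truth): build or load a score calibration, run
the identification funnel, classify foldability, score expression
specificity, compute sequence features, and join everything into one
per-gene report plus a funnel summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as calib
from . import expression_metrics as em
from . import homology_pipeline as hp
from . import sequence_features as sf
from . import structure_metrics as sm
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FunnelReport", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """All thresholds (defaulting to the published constants) plus run knobs."""

    thresholds: hp.Thresholds = field(default_factory=hp.Thresholds)
    min_tpm: float = 0.1
    fold_params: sm.FoldabilityParams = field(default_factory=sm.FoldabilityParams)
    peak_window: int = 500
    k_stage_clusters: int = 4
    calibration_grid: tuple[int, ...] = calib.DEFAULT_LENGTH_GRID
    calibration_reps: int = 300
    seed: int = 0

    def validate(self):
        t = self.thresholds
        for name in ("blastp_evalue", "genic_pvalue", "consensus_evalue",
                     "best_domain_evalue", "arthropod_evalue", "tblastn_evalue"):
            if getattr(t, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.min_tpm < 0 or self.peak_window < 0:
            raise ValueError("min_tpm and peak_window must be nonnegative")


@dataclass
class FunnelReport:
    counts: dict[str, int]
    per_branch: dict[int, int]

    def __post_init__(self):
        vals = list(self.counts.values())
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("funnel counts must be non-increasing")


def run_pipeline(
    config: PipelineConfig | None = None,
    dataset: sd.SimulatedDataset | None = None,
    calibration_table: calib.CalibrationTable | None = None,
) -> tuple[pd.DataFrame, FunnelReport, pd.DataFrame]:
    """Execute every stage over ``dataset`` and join a per-gene report.

    Returns (candidate calls, funnel report, per-gene property table).
    When no dataset is given, a default synthetic one is generated from the
    config seed; when no calibration table is given, one is built with the
    config's grid and rep count.
    """
    config = config or PipelineConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    if calibration_table is None:
        logger.info("stage calibration: grid=%s reps=%d",
                    config.calibration_grid, config.calibration_reps)
        calibration_table = calib.build_calibration(
            config.calibration_grid, config.calibration_reps, rng=rng
        )
    if dataset is None:
        dataset = sd.simulate(
            sd.SimulationConfig(seed=config.seed), calibration=calibration_table
        )

    logger.info("stage scan: %d genes", len(dataset.genes))
    calls = hp.call_de_novo_candidates(
        hits=dataset.hits,
        evidence=dataset.evidence,
        arthropod_evidence=dataset.arthropod,
        calibration=calibration_table,
        genes=dataset.genes,
        annotation=dataset.annotation,
        thresholds=config.thresholds,
    )
    counts = hp.funnel_counts(calls)
    cand = calls[calls["status"] == "candidate"]
    per_branch = cand.groupby("branch", observed=True).size()
    funnel = FunnelReport(
        counts=counts,
        per_branch={int(k): int(v) for k, v in per_branch.items()},
    )

    logger.info("stage foldability: %d profiles", len(dataset.plddt))
    fold_rows = []
    for gid in sorted(dataset.plddt):
        res = sm.classify_foldability(
            sm.PlddtProfile(gid, dataset.plddt[gid]), config.fold_params
        )
        fold_rows.append(
            {"gene": gid, "foldability": res.foldability,
             "mean_plddt": res.mean_plddt, "p_confident": res.p_confident,
             "max_confident_run": res.max_confident_run}
        )
    fold = pd.DataFrame(fold_rows).set_index("gene")

    logger.info("stage expression")
    tpm = em.fpkm_to_tpm(dataset.expression)
    tpm = em.filter_expressed(tpm, config.min_tpm)
    z = em.male_specificity_zscore(
        tpm.male_mean, tpm.female_mean, tpm.male_sd, tpm.female_sd
    )
    znorm = em.normalize_zscores(z)
    tau = tpm.values.apply(lambda r: em.tau_specificity(r.values), axis=1)
    expr = pd.DataFrame(
        {"zscore": pd.Series(np.asarray(z), index=tpm.values.index),
         "zscore_norm": pd.Series(np.asarray(znorm), index=tpm.values.index),
         "tau": tau}
    )
    expr.index.name = "gene"

    logger.info("stage features")
    cds_set = {g: rec.cds for g, rec in dataset.genes.items()}
    usage = sf.build_codon_usage(cds_set)
    feat_rows = []
    for gid in sorted(dataset.genes):
        rec = dataset.genes[gid]
        feat_rows.append(
            {"gene": gid, "gc": sf.gc_content(rec.cds),
             "optimal_codon_fraction": sf.optimal_codon_fraction(rec.cds, usage)}
        )
    feats = pd.DataFrame(feat_rows).set_index("gene")
    gene_spans = pd.DataFrame(
        [{"gene": g, "contig": r.contig, "start": r.start, "end": r.end}
         for g, r in sorted(dataset.genes.items())]
    )
    prox = sf.peak_proximity(gene_spans, dataset.peaks, config.peak_window)
    prox = prox.set_index("gene")

    report = (
        calls.set_index("gene")
        .join(fold, how="left")
        .join(expr, how="left")
        .join(feats, how="left")
        .join(prox, how="left")
        .reset_index()
    )
    return calls, funnel, report


def write_report(
    outdir,
    calls: pd.DataFrame,
    funnel: FunnelReport,
    report: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> None:
    """TSV master table + JSON funnel + a log of every threshold used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    report.to_csv(outdir / "per_gene_report.tsv", sep="\t", index=False)
    with open(outdir / "funnel.json", "w") as fh:
        json.dump(
            {"counts": funnel.counts,
             "per_branch": {str(k): v for k, v in funnel.per_branch.items()}},
            fh, indent=1,
        )
    if config is not None:
        doc = {
            "thresholds": asdict(config.thresholds),
            "min_tpm": config.min_tpm,
            "fold_params": asdict(config.fold_params),
            "peak_window": config.peak_window,
            "k_stage_clusters": config.k_stage_clusters,
            "calibration_grid": list(config.calibration_grid),
            "calibration_reps": config.calibration_reps,
            "seed": config.seed,
        }
        with open(outdir / "run_config.json", "w") as fh:
            json.dump(doc, fh, indent=1)
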