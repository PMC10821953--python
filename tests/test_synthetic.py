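"""Synthetic dataset generator: trees, histories, archetypes, determinism."""

import numpy as np
import pandas as pd
import pytest
from io import StringIO

from Bio import Phylo

from denovoscan import synthetic_data as sd
from denovoscan import structure_metrics as sm
from denovoscan.structure_metrics import PlddtProfile
from denovoscan.homology_pipeline import HitClass, classify_syntenic_hit, RawSyntenicRecord


class TestSpeciesTree:
    def test_smallest_ladder(self):
        tree = sd.generate_species_tree(2)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["sp0", "sp1", "sp2"]
        # focal nested deepest: sp0 and sp1 are siblings inside the sp2 split
        depths = parsed.depths(unit_branch_lengths=True)
        terminal_depth = {t.name: d for t, d in depths.items() if t.name and t.name.startswith("sp")}
        assert terminal_depth["sp0"] > terminal_depth["sp2"]

    def test_nine_branch_depth_ordering(self):
        tree = sd.generate_species_tree(9)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert len(parsed.get_terminals()) == 10
        depths = {
            t.name: d
            for t, d in parsed.depths(unit_branch_lengths=True).items()
            if t.is_terminal()
        }
        for i in range(1, 9):
            assert depths[f"sp{i}"] > depths[f"sp{i+1}"]

    def test_newick_round_trip(self):
        tree = sd.generate_species_tree(5)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        names = [t.name for t in parsed.get_terminals()]
        reparsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert names == [t.name for t in reparsed.get_terminals()]

    def test_too_few_branches_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_species_tree(1)


class TestConfigValidation:
    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(frac_de_novo=1.5)

    def test_branch_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(n_branches=3, branch_weights=[0.5, 0.2, 0.1])

    def test_aa_freqs_checked(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(aa_freqs=np.full(20, 0.1))


class TestGeneHistories:
    def test_planted_branch_controls_hit_classes(self):
        cfg = sd.SimulationConfig(n_genes=60, frac_de_novo=1.0, seed=5)
        _, _, hits, truth = sd.simulate_gene_histories(cfg)
        for gid, row in truth.iterrows():
            b = int(row["origin_branch"])
            sub = hits[hits["gene"] == gid].set_index("branch")
            for br in range(1, cfg.n_branches + 1):
                rec = sub.loc[br]
                cls = classify_syntenic_hit(
                    RawSyntenicRecord(
                        gene=gid, species=f"sp{br}", branch=br,
                        aligned=bool(rec["aligned"]),
                        annotated=None if pd.isna(rec["annotated"]) else bool(rec["annotated"]),
                        evalue=None if pd.isna(rec["evalue"]) else rec["evalue"],
                        pvalue=None if pd.isna(rec["pvalue"]) else rec["pvalue"],
                    )
                )
                if br <= b:
                    assert cls.is_ortholog
                else:
                    assert cls in (HitClass.NONGENIC, HitClass.NO_ALIGNMENT)

    def test_every_planted_gene_has_outgroup_nongenic(self):
        cfg = sd.SimulationConfig(n_genes=100, frac_de_novo=1.0, seed=6)
        _, _, hits, truth = sd.simulate_gene_histories(cfg)
        for gid, row in truth.iterrows():
            b = int(row["origin_branch"])
            sub = hits[(hits["gene"] == gid) & (hits["branch"] > b)]
            nongenic = sub["pvalue"].notna() & (sub["pvalue"] > 1e-6)
            assert nongenic.any()

    def test_no_de_novo_means_all_ancient(self):
        cfg = sd.SimulationConfig(n_genes=30, frac_de_novo=0.0, seed=7)
        _, _, hits, truth = sd.simulate_gene_histories(cfg)
        assert (truth["origin_branch"] == "ancient").all()
        # every branch of every gene carries ortholog evidence
        orth = hits["evalue"].notna() | (hits["pvalue"] < 1e-6)
        assert orth.all()

    def test_fixed_seed_reproducible(self):
        cfg = sd.SimulationConfig(n_genes=25, seed=11)
        a = sd.simulate_gene_histories(cfg)
        b = sd.simulate_gene_histories(cfg)
        pd.testing.assert_frame_equal(a[2], b[2])
        pd.testing.assert_frame_equal(a[3], b[3])
        assert {g: r.cds for g, r in a[0].items()} == {g: r.cds for g, r in b[0].items()}

    def test_protein_matches_cds(self):
        cfg = sd.SimulationConfig(n_genes=5, seed=1)
        genes, _, _, truth = sd.simulate_gene_histories(cfg)
        from Bio.Seq import Seq

        for gid, rec in genes.items():
            assert str(Seq(rec.cds).translate()).rstrip("*") == rec.protein
            assert len(rec.protein) == truth.at[gid, "protein_length"]


class TestHomologEvidence:
    def test_ancient_genes_have_consensus_support(self):
        cfg = sd.SimulationConfig(n_genes=40, frac_de_novo=0.0, seed=2)
        _, _, _, truth = sd.simulate_gene_histories(cfg)
        evidence, _ = sd.simulate_homolog_evidence(truth, cfg)
        for gid in truth.index:
            sub = evidence[(evidence["gene"] == gid) & (evidence["evalue"] <= 1e-5)]
            assert sub.groupby("subject_species")["search"].nunique().max() >= 2

    def test_de_novo_genes_have_no_consensus_homolog(self):
        cfg = sd.SimulationConfig(n_genes=40, frac_de_novo=1.0, seed=3)
        _, _, _, truth = sd.simulate_gene_histories(cfg)
        evidence, arthropod = sd.simulate_homolog_evidence(truth, cfg)
        assert not (evidence["evalue"] <= 0.001).any()
        assert not (arthropod["evalue"] < 0.05).any()

    def test_evalues_positive_and_finite(self):
        cfg = sd.SimulationConfig(n_genes=50, seed=4)
        _, _, _, truth = sd.simulate_gene_histories(cfg)
        evidence, arthropod = sd.simulate_homolog_evidence(truth, cfg)
        for df in (evidence, arthropod):
            assert (df["evalue"] > 0).all() and np.isfinite(df["evalue"]).all()


class TestPlddtArchetypes:
    def classify_fraction(self, archetype, n=300, seed=0):
        cfg = sd.SimulationConfig(n_genes=n, seed=seed)
        truth = pd.DataFrame(
            {"fold_archetype": [archetype] * n,
             "protein_length": np.random.default_rng(seed).integers(70, 400, n)},
            index=[f"g{i:04d}" for i in range(n)],
        )
        profiles = sd.simulate_plddt_profiles(truth, cfg)
        calls = [
            sm.classify_foldability(PlddtProfile(g, p)).foldability
            for g, p in profiles.items()
        ]
        return calls

    def test_well_archetype_classified_well(self):
        calls = self.classify_fraction("well")
        assert calls.count("well_folded") / len(calls) >= 0.99

    def test_none_archetype_classified_not_folded(self):
        calls = self.classify_fraction("none")
        assert all(c == "not_folded" for c in calls)

    def test_partial_archetype_classified_partial(self):
        calls = self.classify_fraction("partial")
        assert calls.count("partially_folded") / len(calls) >= 0.99

    def test_scores_bounded(self):
        cfg = sd.SimulationConfig(n_genes=20, seed=8)
        _, _, _, truth = sd.simulate_gene_histories(cfg)
        for p in sd.simulate_plddt_profiles(truth, cfg).values():
            assert p.min() >= 0 and p.max() <= 100


class TestStructureEnsembles:
    def test_identical_models_fully_converge(self):
        ens = sd.simulate_structure_ensemble("well", 4, length=60, noise=0.0, rng=0)
        assert sm.ensemble_convergence(ens) == pytest.approx(100.0, abs=1e-6)

    def test_coil_below_helix(self):
        for seed in range(3):
            helix = sd.simulate_structure_ensemble("well", 5, length=100, rng=seed)
            coil = sd.simulate_structure_ensemble("none", 5, length=100, rng=seed)
            assert sm.ensemble_convergence(coil) < sm.ensemble_convergence(helix)

    def test_coordinates_finite_and_shapes_equal(self):
        ens = sd.simulate_structure_ensemble("none", 3, length=50, rng=1)
        assert ens.shape == (3, 50, 3)
        assert np.isfinite(ens).all()

    def test_too_few_models_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_structure_ensemble("well", 1)


class TestExpressionSimulation:
    @pytest.fixture(scope="class")
    @staticmethod
    def dataset():
        cfg = sd.SimulationConfig(n_genes=200, seed=9)
        _, _, _, truth = sd.simulate_gene_histories(cfg)
        matrix, stage = sd.simulate_expression(truth, cfg)
        return cfg, truth, matrix, stage

    def test_fpkm_nonnegative(self, dataset):
        _, _, matrix, _ = dataset
        assert (matrix.values.values >= 0).all()

    def test_male_biased_genes_exceed_4x(self, dataset):
        _, truth, matrix, _ = dataset
        biased = truth.index[truth["male_biased"]]
        ratio = matrix.male_mean[biased] / matrix.female_mean[biased]
        assert (ratio >= 4).mean() > 0.95

    def test_unbiased_zscores_center_at_zero(self, dataset):
        from denovoscan.expression_metrics import male_specificity_zscore

        _, truth, matrix, _ = dataset
        idx = truth.index[~truth["male_biased"]]
        z = male_specificity_zscore(
            matrix.male_mean[idx], matrix.female_mean[idx],
            matrix.male_sd[idx], matrix.female_sd[idx],
        )
        assert abs(np.mean(z)) < 0.2

    def test_testis_specific_profile_high_tau(self, dataset):
        from denovoscan.expression_metrics import tau_specificity

        _, truth, matrix, _ = dataset
        biased = truth.index[truth["male_biased"]]
        taus = [tau_specificity(matrix.values.loc[g].values) for g in biased]
        assert np.min(taus) > 0.9

    def test_stage_matrix_covers_male_biased_genes(self, dataset):
        _, truth, _, stage = dataset
        assert set(stage.index) == set(truth.index[truth["male_biased"]])


class TestClassBalance:
    def test_archetype_frequencies_within_binomial_ci(self):
        cfg = sd.SimulationConfig(n_genes=2000, seed=10)
        _, _, _, truth = sd.simulate_gene_histories(cfg)
        n = len(truth)
        p = cfg.frac_de_novo
        observed = (truth["origin_branch"] != "ancient").sum()
        half = 2.576 * np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) < half
        de_novo = truth[truth["origin_branch"] != "ancient"]
        for arch, p_arch in zip(("well", "partial", "none"), cfg.fold_probs_de_novo):
            obs = (de_novo["fold_archetype"] == arch).sum()
            m = len(de_novo)
            assert abs(obs - m * p_arch) < 2.576 * np.sqrt(m * p_arch * (1 - p_arch)) + 1


class TestOutputs:
    def test_write_outputs_round_trip(self, tmp_path):
        cfg = sd.SimulationConfig(n_genes=12, seed=12)
        ds = sd.simulate(cfg)
        sd.write_outputs(ds, tmp_path)
        for name in ("proteins.fasta", "cds.fasta", "tree.nwk", "genes.gff3",
                     "syntenic_hits.tsv", "homolog_evidence.tsv", "plddt.tsv",
                     "expression_fpkm.tsv", "sex_expression.tsv", "peaks.bed",
                     "truth.json"):
            assert (tmp_path / name).exists(), name
        hits = pd.read_csv(tmp_path / "syntenic_hits.tsv", sep="\t")
        assert len(hits) == 12 * cfg.n_branches
        from Bio import SeqIO

        prots = list(SeqIO.parse(tmp_path / "proteins.fasta", "fasta"))
        assert len(prots) == 12

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = sd.SimulationConfig(n_genes=10, seed=13)
        sd.write_outputs(sd.simulate(cfg), tmp_path / "a")
        sd.write_outputs(sd.simulate(cfg), tmp_path / "b")
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name
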