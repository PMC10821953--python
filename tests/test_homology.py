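"""Identification funnel: hit classification, branch inference, filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from denovoscan import homology_pipeline as hp
from denovoscan.homology_pipeline import (
    CandidateStatus,
    GenePrediction,
    GeneRecord,
    HitClass,
    RawSyntenicRecord,
)

from oracles import oracle_candidate_decision

CLASS_FIELDS = {
    "annotated_ortholog": dict(annotated=True, evalue=1e-10),
    "ambiguous": dict(annotated=True, evalue=0.5),
    "unannotated_ortholog": dict(annotated=False, pvalue=1e-9),
    "nongenic": dict(annotated=False, pvalue=0.4),
    "no_alignment": dict(aligned=False),
}


def record_for(cls, gene="g", species="sp1", branch=1):
    return RawSyntenicRecord(gene=gene, species=species, branch=branch,
                             **CLASS_FIELDS[cls])


def hits_frame(profiles):
    """profiles: dict gene -> dict branch -> class string."""
    rows = []
    for gene, prof in profiles.items():
        for b, cls in prof.items():
            f = CLASS_FIELDS[cls]
            rows.append(
                {"gene": gene, "species": f"sp{b}", "branch": b,
                 "aligned": f.get("aligned", True),
                 "annotated": f.get("annotated", np.nan),
                 "evalue": f.get("evalue", np.nan),
                 "score": np.nan, "protein_length": 100,
                 "pvalue": f.get("pvalue", np.nan)}
            )
    return pd.DataFrame(rows)


class TestClassifySyntenicHit:
    @pytest.mark.parametrize("cls", list(CLASS_FIELDS))
    def test_each_class_rule(self, cls):
        assert hp.classify_syntenic_hit(record_for(cls)) == HitClass(cls)

    def test_annotated_boundary_is_strict(self):
        rec = RawSyntenicRecord("g", "sp1", 1, annotated=True, evalue=0.05)
        assert hp.classify_syntenic_hit(rec) == HitClass.AMBIGUOUS

    def test_genic_pvalue_boundary_inclusive(self):
        rec = RawSyntenicRecord("g", "sp1", 1, annotated=False, pvalue=1e-6)
        assert hp.classify_syntenic_hit(rec) == HitClass.UNANNOTATED_ORTHOLOG

    def test_score_route_uses_calibration(self, tiny_calib_table):
        from denovoscan.calibration import predict_mean_sd

        mean, sd = predict_mean_sd(tiny_calib_table, 100)
        strong = RawSyntenicRecord("g", "sp1", 1, annotated=False,
                                   score=mean + 8 * sd, protein_length=100)
        weak = RawSyntenicRecord("g", "sp1", 1, annotated=False,
                                 score=mean, protein_length=100)
        assert hp.classify_syntenic_hit(strong, tiny_calib_table) == \
            HitClass.UNANNOTATED_ORTHOLOG
        assert hp.classify_syntenic_hit(weak, tiny_calib_table) == HitClass.NONGENIC

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(aligned=False, evalue=1e-4),
            dict(annotated=True),
            dict(annotated=True, evalue=1e-4, pvalue=0.5),
            dict(annotated=False),
            dict(annotated=False, evalue=1e-4),
        ],
    )
    def test_malformed_records_rejected(self, kwargs):
        rec = RawSyntenicRecord("g", "sp1", 1, **kwargs)
        with pytest.raises(hp.MalformedRecordError):
            hp.classify_syntenic_hit(rec)


class TestBranchInference:
    def test_contiguous_profile(self):
        prof = {b: HitClass.ANNOTATED_ORTHOLOG for b in range(1, 5)}
        prof.update({b: HitClass.NONGENIC for b in range(5, 10)})
        assert hp.infer_furthest_ortholog_branch(prof) == 4

    def test_patchy_profile_takes_furthest(self):
        prof = {b: HitClass.NONGENIC for b in range(1, 10)}
        prof[2] = HitClass.ANNOTATED_ORTHOLOG
        prof[7] = HitClass.UNANNOTATED_ORTHOLOG
        assert hp.infer_furthest_ortholog_branch(prof) == 7

    def test_no_ortholog_returns_none(self):
        prof = {b: HitClass.NONGENIC for b in range(1, 10)}
        assert hp.infer_furthest_ortholog_branch(prof) is None

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            hp.infer_furthest_ortholog_branch({})

    def test_adding_deeper_ortholog_never_decreases_branch(self):
        rng = np.random.default_rng(0)
        classes = list(HitClass)
        for _ in range(50):
            prof = {b: classes[rng.integers(5)] for b in range(1, 8)}
            base = hp.infer_furthest_ortholog_branch(prof)
            if base is None:
                continue
            prof2 = dict(prof)
            b2 = int(rng.integers(1, 8))
            prof2[b2] = HitClass.ANNOTATED_ORTHOLOG
            assert hp.infer_furthest_ortholog_branch(prof2) >= base


class TestOutgroupSupport:
    def test_nongenic_beyond_branch(self):
        prof = {b: HitClass.ANNOTATED_ORTHOLOG for b in range(1, 5)}
        prof.update({b: HitClass.NO_ALIGNMENT for b in range(5, 10)})
        prof[6] = HitClass.NONGENIC
        assert hp.has_outgroup_nongenic_support(prof, 4)

    def test_all_unaligned_outgroups(self):
        prof = {b: HitClass.ANNOTATED_ORTHOLOG for b in range(1, 5)}
        prof.update({b: HitClass.NO_ALIGNMENT for b in range(5, 10)})
        assert not hp.has_outgroup_nongenic_support(prof, 4)

    def test_deepest_branch_has_no_outgroup(self):
        prof = {b: HitClass.ANNOTATED_ORTHOLOG for b in range(1, 10)}
        assert not hp.has_outgroup_nongenic_support(prof, 9)

    def test_out_of_range_branch(self):
        with pytest.raises(ValueError):
            hp.has_outgroup_nongenic_support({1: HitClass.NONGENIC}, 5)


def ev(gene="g", subject="X", search="blastp", evalue=1e-4, bde=np.nan):
    return {"gene": gene, "subject_species": subject, "search": search,
            "evalue": evalue, "best_domain_evalue": bde}


class TestConsensusFilter:
    def test_two_searches_agree(self):
        rows = pd.DataFrame([ev(search="blastp", evalue=1e-4),
                             ev(search="jackhmmer_a", evalue=5e-4, bde=1e-8)])
        reliable, support = hp.consensus_homolog_filter(rows)
        assert reliable and len(support) == 2

    def test_single_search_insufficient(self):
        rows = pd.DataFrame([ev(search="blastp", evalue=1e-20)])
        assert not hp.consensus_homolog_filter(rows)[0]

    def test_cutoff_enforced(self):
        rows = pd.DataFrame([ev(search="blastp", evalue=0.01),
                             ev(search="jackhmmer_a", evalue=0.01, bde=1e-8)])
        assert not hp.consensus_homolog_filter(rows)[0]

    def test_best_domain_filter_removes_profile_false_positives(self):
        rows = pd.DataFrame([ev(search="blastp", evalue=1e-4),
                             ev(search="jackhmmer_a", evalue=1e-4, bde=1e-3)])
        assert not hp.consensus_homolog_filter(rows)[0]

    def test_two_subjects_single_search_each(self):
        rows = pd.DataFrame([ev(subject="X", search="blastp", evalue=1e-6),
                             ev(subject="Y", search="jackhmmer_a", evalue=1e-6,
                                bde=1e-8)])
        assert not hp.consensus_homolog_filter(rows)[0]


class TestValidateUnannotatedHomolog:
    QUERY = GeneRecord(gene="q", n_exons=3, ortholog_exon_counts=(2, 4))

    def test_all_criteria_met(self):
        pred = GenePrediction("q", "s", True, True, 0, 3)
        assert hp.validate_unannotated_homolog(pred, self.QUERY)

    def test_frameshift_fails(self):
        pred = GenePrediction("q", "s", True, True, 1, 3)
        assert not hp.validate_unannotated_homolog(pred, self.QUERY)

    def test_ortholog_exon_count_accepted(self):
        pred = GenePrediction("q", "s", True, True, 0, 4)
        assert hp.validate_unannotated_homolog(pred, self.QUERY)

    def test_unmatched_exon_count_fails(self):
        pred = GenePrediction("q", "s", True, True, 0, 7)
        assert not hp.validate_unannotated_homolog(pred, self.QUERY)


class TestGenomicContext:
    def mk(self, gene, start, end, contig="c1"):
        return GeneRecord(gene=gene, contig=contig, start=start, end=end)

    def test_nested_gene_is_intragenic(self):
        g = self.mk("a", 1000, 1500)
        ann = [self.mk("b", 500, 5000)]
        assert hp.classify_genomic_context(g, ann) == "intragenic"

    def test_distant_gene_is_intergenic(self):
        g = self.mk("a", 1000, 1500)
        ann = [self.mk("b", 20_000, 30_000)]
        assert hp.classify_genomic_context(g, ann) == "intergenic"

    def test_abutting_half_open_is_intergenic(self):
        g = self.mk("a", 1000, 1500)
        ann = [self.mk("b", 1500, 2000), self.mk("c", 500, 1000)]
        assert hp.classify_genomic_context(g, ann) == "intergenic"

    def test_self_overlap_ignored(self):
        g = self.mk("a", 1000, 1500)
        assert hp.classify_genomic_context(g, [g]) == "intergenic"


class TestCallPipeline:
    def test_arthropod_rejection(self):
        profiles = {"g": {1: "annotated_ortholog", 2: "nongenic", 3: "nongenic"}}
        hits = hits_frame(profiles)
        arth = pd.DataFrame([{"gene": "g", "species": "a1", "evalue": 1e-30}])
        calls = hp.call_de_novo_candidates(hits, arthropod_evidence=arth)
        assert calls.loc[0, "status"] == "rejected_arthropod_homolog"

    def test_inconsistent_keys_rejected(self):
        hits = hits_frame({"g": {1: "annotated_ortholog"}})
        arth = pd.DataFrame([{"gene": "phantom", "species": "a1", "evalue": 1e-30}])
        with pytest.raises(ValueError, match="phantom"):
            hp.call_de_novo_candidates(hits, arthropod_evidence=arth)

    def test_exhaustive_three_branch_oracle(self):
        classes = list(CLASS_FIELDS)
        for combo in itertools.product(classes, repeat=3):
            prof = {b + 1: c for b, c in enumerate(combo)}
            calls = hp.call_de_novo_candidates(hits_frame({"g": prof}))
            want_status, want_branch = oracle_candidate_decision(prof)
            assert calls.loc[0, "status"] == want_status, prof
            got_branch = calls.loc[0, "branch"]
            assert (pd.isna(got_branch) and want_branch is None) or \
                got_branch == want_branch

    def test_sampled_five_branch_oracle(self):
        classes = list(CLASS_FIELDS)
        rng = np.random.default_rng(17)
        profiles = {}
        expected = {}
        for k in range(300):
            prof = {b: classes[rng.integers(5)] for b in range(1, 6)}
            gid = f"g{k:03d}"
            profiles[gid] = prof
            expected[gid] = oracle_candidate_decision(prof)
        calls = hp.call_de_novo_candidates(hits_frame(profiles)).set_index("gene")
        for gid, (status, branch) in expected.items():
            assert calls.loc[gid, "status"] == status
            got = calls.loc[gid, "branch"]
            assert (pd.isna(got) and branch is None) or got == branch

    def test_adding_distant_homolog_never_promotes(self):
        prof = {1: "annotated_ortholog", 2: "nongenic", 3: "nongenic"}
        hits = hits_frame({"g": prof})
        base = hp.call_de_novo_candidates(hits)
        assert base.loc[0, "status"] == "candidate"
        evidence = pd.DataFrame(
            [dict(ev(evalue=1e-6), subject_branch=9),
             dict(ev(search="jackhmmer_a", evalue=1e-6, bde=1e-8),
                  subject_branch=9)]
        )
        with_hom = hp.call_de_novo_candidates(hits, evidence=evidence)
        assert with_hom.loc[0, "status"] == "rejected_distant_homolog"

    def test_funnel_counts_non_increasing(self):
        rng = np.random.default_rng(3)
        classes = list(CLASS_FIELDS)
        profiles = {
            f"g{k}": {b: classes[rng.integers(5)] for b in range(1, 6)}
            for k in range(100)
        }
        calls = hp.call_de_novo_candidates(hits_frame(profiles))
        counts = hp.funnel_counts(calls)
        vals = list(counts.values())
        assert all(a >= b for a, b in zip(vals, vals[1:]))
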