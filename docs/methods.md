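# Methods

## Overview

`denovoscan` implements a desk-scale, fully testable version of a de novo
gene identification and characterization analysis for a focal insect genome
nested in a ladder of outgroup species. The pipeline has five analytic
layers — score calibration, the identification funnel, foldability and
ensemble structure metrics, expression-specificity statistics, and sequence
features — plus a synthetic-data generator that plants ground truth for all
of them. Heavy external computations of the original study design
(whole-genome alignment, BLAST/jackhmmer searches, structure prediction,
molecular dynamics) are treated as *inputs*: their outputs arrive as tables,
and the generator emulates their statistical shape.

## Score calibration against random expectation

A protein query spliced-aligned against genomic DNA always achieves *some*
positive local score, and the best random score grows with protein length N.
To decide whether an unannotated syntenic region has genuine coding
potential, the package simulates random protein/DNA pairs — proteins drawn
i.i.d. from the focal proteome's amino-acid frequencies, DNA of length
3·(N+300) at the genome's coding GC content — and summarizes the best-score
distribution per N by its mean and standard deviation. Both are fitted as
two-phase exponential decays

    S(N) = S0 + SpanFast·e^(−KFast·N) + SpanSlow·e^(−KSlow·N),
    SpanFast = (S0 − Smin)·PercentFast/100,
    SpanSlow = (S0 − Smin)·(1 − PercentFast/100),

with KFast ≥ KSlow ≥ 0 enforced by the parameterization KSlow = KFast·r,
r ∈ [0, 1], and PercentFast ∈ [0, 100]. Because the objective is multimodal
in the rates, the fit (lmfit least squares) uses eight log-spaced
multi-starts and keeps the best residual sum of squares. The spans are
*not* constrained in sign: for a mean curve that rises toward its plateau
S0 (the case here — longer random pairs reach higher best local scores),
Smin exceeds S0 and both spans are negative. An observed score is converted
to a one-tailed Gaussian upper-tail p-value at the fitted Mean(N) and SD(N)
(SD floored at 1e-6 score units), and a region is called genic at
p ≤ 1e-6 (inclusive boundary).

The true null of a local-alignment maximum is heavier-tailed than Gaussian
(extreme-value shaped), so the nominal 1e-6 call is anti-conservative in
principle; empirically the false-positive rate on fresh random pairs stays
near 1e-4 or below at all tested lengths, which the acceptance checks bound
at 1e-3.

### The surrogate spliced aligner

The original analysis delegates spliced alignment to external gene-structure
predictors; reimplementing those is out of scope, and the calibration
framework — not the aligner — is the contribution. The package therefore
ships a deliberately simple, exhaustively verifiable local DP over
(protein index i, DNA index j) with four moves: codon match (i+1, j+3)
scored by BLOSUM62 with stop codons at −6; protein gap (i+1, j) and DNA
codon gap (i, j+3), both affine at open 11 / extend 1; and an intron jump
(i, j+g) for any g ≥ 40 nt at a flat penalty of 8, which is the "penalty
for introducing splicing sites" the calibration must capture. Cells are
floored at zero and the score is the global maximum (Smith–Waterman
semantics). The intron move is serviced by a running prefix maximum per
protein row, giving O(N·M) time; the hot loop is compiled with numba.
No splice-site dinucleotide (GT..AG) requirement is imposed. Tests compare
the production DP against a naive evaluator that takes direct maxima over
all gap and intron extents on small instances.

## Identification funnel

Per (gene, species) liftover outcomes are classified as: annotated ortholog
(annotated overlap, blastp E < 0.05), ambiguous (annotated overlap,
E ≥ 0.05 — counted neither as ortholog nor as non-genic support),
unannotated ortholog (unannotated region, genic p ≤ 1e-6), non-genic hit
(unannotated, p > 1e-6), or no alignment. With several species per branch,
an ortholog in any species marks the branch orthologous; failing that, a
non-genic hit in any species marks it non-genic.

The origination branch Br_i is the furthest branch carrying an ortholog;
patchy profiles (ortholog at Br2 and Br7 with non-genic hits between) are
read as secondary losses and resolve to the furthest ortholog. A candidate
must then have (1) at least one non-genic hit beyond Br_i (the ancestral
non-coding witness), (2) no arthropod-outgroup homolog at E < 0.05, (3) no
reliable distant homolog — some subject species supported by at least two
distinct searches at E ≤ 0.001, after discarding profile-search rows whose
best single-domain E-value exceeds 1e-5 — and (4) no validated unannotated
distant homolog, where validation requires a canonical start and stop, zero
frameshifts, and an exon count matching the query or one of its recorded
orthologs. Stages run in that order and the first failure is recorded, so
the funnel counts are auditable from the per-gene stage outcomes. Genes
with no ortholog-bearing branch at all cannot be assigned an origination
branch and are filed with the no-nongenic-support rejections.

Genomic context is intragenic iff the gene's span overlaps any *other*
annotated gene's span on either strand, under 0-based half-open
coordinates (abutting spans do not overlap); GFF3 I/O converts from
1-based inclusive coordinates at the boundary.

## Structure metrics

Foldability classes from per-residue confidence (pLDDT ∈ [0, 100]):
well-folded iff mean pLDDT > 80 and more than 90% of residues confident
(pLDDT > 70); else partially folded iff more than 30% confident residues or
a confident run longer than 50; else not folded. All thresholds are strict,
so a mean of exactly 80 or a run of exactly 50 falls to the lower class,
and the classifier is monotone in every residue's score.

TM-score uses index pairing (ensemble members share a sequence), an initial
Kabsch superposition on all residues, then up to 20 rounds of
re-superposition on the subset with d_i < d0 until the subset stabilizes;
the final score is (1/L_norm)·Σ 1/(1+(d_i/d0)²) over all residues, with
d0 = max(0.5, 1.24·(L_norm−15)^{1/3} − 1.8) and the 0.5 Å floor covering
L_norm ≤ 21 where the cube-root formula degenerates. Kabsch uses SVD with
reflection correction (det +1); near-collinear inputs warn and return the
best effort. Ensemble convergence is the mean pairwise TM-score × 100, the
percent scale making it directly comparable with pLDDT; when potential
energies are available the 20 lowest-energy models are selected first, and
ensembles supplied without energies are used whole.

Conformation clustering follows the density-peaks algorithm on a pairwise
backbone-RMSD matrix (the metric is a package choice; the source analysis
clusters MD conformations without naming one): ρ_i counts neighbors within
d_c (default: the 2nd percentile of off-diagonal distances), δ_i is the
distance to the nearest higher-density point (maximum distance for the
global peak), centers are the top k by γ = ρ·δ, and remaining points
inherit the label of their nearest higher-density neighbor in decreasing
density order. Density ties are broken by index so the ordering is total.
Representatives are the cluster centers ordered by cluster size, the top
one serving as the refined model; a fold is flagged potentially novel when
its maximum TM-score against a reference set is strictly below 0.5.

## Expression statistics

FPKM → TPM divides each tissue column by its sum and scales to 1e6 (unit
tags prevent double conversion); genes are kept when their maximum TPM
strictly exceeds 0.1. Male specificity is
z = (TPM_male − TPM_female)/√(sd_male² + sd_female²) from whole-body
replicate SDs, min-max normalized onto [0, 1] across genes. Tissue
specificity is tau = Σ(1 − x_i/x_max)/(N−1) on the raw (unlogged) TPM
vector over 27 tissues. Stage profiles over the six spermatogenesis stages
are row-standardized ("scaled" is not given a formula in the source;
per-gene standardization is the standard choice for amplitude-free
clustering and makes the operation idempotent), reduced by column-centered
PCA to three components, clustered by k-means (k-means++ with 50 restarts,
fixed seed), and renumbered 1..4 by ascending expression-weighted mean
stage of the cluster centroids (argmax stage breaks ties), so cluster #1
always peaks earliest. Age trends use tie-corrected Kendall tau-b — branch
indices are heavily tied, tau-a would be misleading — and Spearman rho on
average ranks, two-sided.

## Sequence features

GC content excludes Ns from the denominator. Codon usage pools codon
counts over translatable CDS records (untranslatable records are skipped
with a log message); the optimal codon per amino acid is the most frequent,
ties broken alphabetically. The ORF scanner covers all six frames; an ORF
is ATG..in-frame stop with the stop included in the length, kept at
length ≥ 75 nt — the stated threshold ("longer than 75 nt, coding 25
amino acids") is internally ambiguous since 75 nt is 24 residues plus the
stop, and the inclusive reading keeps a single clean rule behind a
`min_len` knob. Nested in-frame ATGs sharing a parent stop produce their
own records. Peak proximity counts peaks overlapping the gene span ±500 bp
(window anchored on the span, not the TSS), averages their intensity, and
reports the edge gap to the nearest peak under half-open coordinates
(0 when overlapping, +inf when the contig has no peaks).

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: a 9-branch ladder
(one species per branch; the branch logic collapses each branch to one
evidence slot), 500 genes, 30% de novo, foldability archetype frequencies
(6/54/40% for de novo genes) matching the published class proportions, and
clean E-value separation — log10 E uniform on [−30, −6] for true homologs
and [−2, 2] for unrelated pairs, so the 0.001 consensus cutoff separates
them perfectly. Origination branches default to uniform over branches
1..8: a birth on the deepest branch has no outgroup left to witness the
ancestral non-coding state and is undetectable by construction, so it is
not planted. Spurious arthropod rows for de novo genes are drawn at or
above the 0.05 exclusion threshold ("clean evidence"); a contamination
knob plants sub-threshold arthropod hits for robustness studies.
Protein lengths are log-normal (median ≈130 for de novo genes, ≈420
otherwise, floored at 70 so the partially-folded archetype's 60-residue
confident segment fits). pLDDT archetypes sit several SDs from every
classification threshold, so the planted classes are unambiguous: the
partial archetype's confident segment spans max(60, 0.4·L) residues, which
keeps its confident fraction above 30% at all lengths without approaching
the well-folded thresholds (its mean stays near 59). Male-biased genes are
testis-dominant with male whole-body means 5–12× female; replicate means
and SDs come from 4 simulated replicates at 15% CV. Stage profiles are
drawn from four fixed templates peaking at successive stages, with 15%
multiplicative noise.

All randomness flows from one integer seed through per-component, per-gene
`SeedSequence` spawn keys, so outputs are byte-identical across runs and
stable under gene reordering.

The generator does *not* simulate sequence evolution under a substitution
model, alignment-block structure, assembly or annotation error, expression
count noise, or correlated evidence failures across species. Passing tests
therefore demonstrate that the *rules and statistics* are implemented
correctly and recover planted truth under the stated noise — not that the
thresholds would achieve the same sensitivity/specificity on real genomes.

## Problem sizes and numerical choices

Test and acceptance runs use 200–1000 random simulations per grid length
(the calibration machinery is agnostic to the count; tolerances in tests
are CLT-scaled to the rep count used) and a length grid of 15–500 for
fitting, with the full 15–1000 grid exercised in the decay-recovery check.
The false-positive audit scores 10,000 fresh pairs per length at N ∈
{25, 100, 500}. Degenerate inputs are handled explicitly: flat data fit
exactly (both spans vanish), constant stage rows standardize to zero,
rank-deficient PCA pads with zeros and warns, and the SD floor keeps
z-scores finite. Fit failures raise with the best attempt attached rather
than returning silently.

## Known limitations

* The surrogate aligner is not Genewise/Spaln: absolute score scales are
  not comparable to those tools, only the calibration logic transfers.
* The Gaussian tail model is anti-conservative for extreme quantiles of a
  local-alignment null; the 1e-6 nominal level is an operating point, not
  an exact error rate.
* Iterative profile-search curation (manual HMM pruning between jackhmmer
  rounds) is modeled only as the best-domain E-value filter.
* The density-peaks assignment is greedy by density order, as in the
  original algorithm; it does not optimize a global objective.
* Welch-style unequal-variance testing is used wherever group means are
  compared in examples; the source analyses do not state the variant.
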