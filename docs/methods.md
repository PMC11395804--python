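# Methods

This note documents the models and procedures implemented in `pangenefam`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical and design choices a maintainer would
want recorded. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. Syntelog-group construction

**Anchors.** Input is a similarity table (gene_a, gene_b, score) from any
aligner; the package never computes alignments for this step. Per genome
pair, a pair survives when each gene's score is within a factor *c* of that
gene's best score against the partner genome. *c* = 1 is strict
reciprocal-best; the default *c* = 0.9 keeps near-best hits so both copies of
a tandem array can anchor to the same partner. Same-genome similarity rows
are excluded from anchoring but retained as tandem evidence (below).

**Collinear chaining.** Anchors carry gene ranks (ordinal positions along
the chromosome). Chains maximize summed anchor score under a weighted
longest-monotone-subsequence recurrence: a predecessor must precede on genome
A, be monotone on genome B (increasing = `same`, decreasing = `inverted`
orientation), and lie within `max_gap` ranks on both genomes. Blocks are
extracted best-score-first; each anchor joins at most one block; blocks with
fewer than `min_block` anchors are discarded. Defaults `max_gap` = 10,
`min_block` = 5 are common collinearity settings and configurable. The DP is
O(n²) per genome pair and is verified against exhaustive chain enumeration on
small anchor sets in the test suite.

**Tandem recovery.** Strictly monotone chains cannot hold two anchors that
compete for one partner rank, so tandem copies would fall out of their block.
Two mechanisms reattach them: (i) an unchained anchor that shares an endpoint
with a chained anchor, with its other endpoint within `max_intervening` + 1
ranks of the chained anchor's corresponding endpoint, is attached to the
graph; (ii) same-genome similarity pairs between rank-adjacent genes are
added as edges, which also keeps tandem arrays of *private* genes (which have
no cross-genome anchors at all) in a single group.

**Grouping and conflict resolution.** Genes are nodes and in-block anchors
weighted edges; connected components are SG candidates. Within a component a
genome may contribute several genes only when they form one tandem array
(transitive closure of "separated by ≤ `max_intervening` intervening
genes", default 1). Otherwise the array with the largest total anchor weight
to the rest of the component is kept (ties by lexicographic gene id) and the
remainder re-seeded as private singletons. This greedy selection realizes
the one-slot-per-genome-plus-tandems semantics; an exact per-genome-pair
maximum-weight matching would differ only in multi-genome conflict webs that
the noiseless and low-noise regimes exercised here do not produce.

**Occupancy classes.** With occupancy *m* of *K* genomes: core iff *m = K*;
private iff *m = 1* (and *K* > 1); softcore iff *m/K* > 9/10 evaluated in
exact rational arithmetic; dispensable otherwise. The strict "over 90%"
boundary gives softcore occupancy {25, 26} at K = 27 and makes softcore
infeasible for some K (e.g., K = 10, where no integer lies in (9, 10)); the
generator treats a requested-but-infeasible class as a configuration error
rather than silently reassigning it.

**Accumulation curves.** For each random genome ordering, pan(m) counts SGs
present in ≥ 1 of the first m genomes and core(m) those present in all m;
means and standard deviations over orderings are reported. Pan is
non-decreasing and core non-increasing per ordering by construction.

## 2. Family annotation

Seed members require ≥ 1 N-terminal and ≥ 1 C-terminal domain hit each with
e-value ≤ 1e-5 (inclusive — the conventional reading of "threshold").
Membership propagates to every SG co-member of a seed; propagation is
idempotent, and domain evidence takes precedence when a gene is both a seed
and a co-member. Typicality requires both domains: one-domain genes are
atypical, matching the truncation mechanism in which one terminus is lost;
the alternative reading (atypical only when *both* domains are missing) is a
switch (`require_both=False`).

Subfamily labels are assigned by the highest global-identity labeled
reference (identity = identical columns over aligned columns, gap-penalized
global alignment), with a 0.30 identity floor below which members stay
`unassigned`. This is a deliberate stand-in for tree-based subfamily
assignment (alignment + phylogeny pipelines are out of scope); users with
tree-derived labels can substitute them directly. Doubly-truncated fragments
retaining only a middle portion legitimately fall below the floor.

The family PAV matrix reports per-SG, per-genome status from member
typicality: `absent`, `typical`, `atypical`, or `both`; private counts tally
family SGs with occupancy 1. Typical-vs-atypical length comparisons use a
one-sided Mann–Whitney U (atypical shorter) on CDS and gene lengths, with an
explicit empty result when either group is empty.

## 3. Nei–Gojobori Ka/Ks

Inputs are gapless, stop-free, codon-aligned sequence pairs (codon
back-threading of protein alignments is upstream). Per codon, each position
contributes (number of synonymous one-step changes)/3 to S, with
stop-creating changes counted nonsynonymous; S + N = 3L identically. S is
averaged over the two sequences (standard NG86). Differences are averaged
over all k! single-step orderings between differing codons; pathways passing
through a stop are excluded, with all pathways used if every one hits a stop
(the common implementation convention — the choice is isolated in one
function and switchable). Both proportions get the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as saturated rather than
extrapolated. ω = dN/dS is reported as missing (never infinity) when dS = 0,
and excluded from distributions; a flag marks ω < 4 for reporting filters.
The implementation is property-tested against an independent pathway
enumeration oracle and cross-checked against Biopython's NG86 routine.

## 4. Variant consequences

Gene models are strand-aware with 0-based half-open internal coordinates
(GFF3/VCF conversion happens only at I/O). Classes follow Sequence
Ontology / Ensembl-VEP conventions, since the upstream tool being emulated
uses them with default parameters: splice donor = first 2 intronic bases at
an intron's 5′ end and acceptor = last 2 at its 3′ end (transcription
orientation); splice region = 1–3 exonic or 3–8 intronic bases from a
junction excluding donor/acceptor bases; intron, coding sequence, 5′/3′ UTR;
upstream/downstream within 5 kb of the transcript on the appropriate strand
side. When several classes apply the primary call is the most severe under
the fixed precedence acceptor = donor > region > coding > UTR > intron >
up/downstream, with all classes retained. Only SNVs are fully supported;
indels are classified by start position. One canonical transcript per gene
is assumed. Classification is involutive under coordinate mirroring with
strand flip, which the suite checks exhaustively on synthetic genes.

## 5. Expression and coexpression

FPKM(g, s) = counts · 10⁹ / (length(g) · total(s)). The differential
stage is a deliberately simple DESeq2-style stand-in — median-of-ratios size
factors, log2 fold-change of normalized means with pseudocount 1, Welch
t-test per gene on log2(normalized + 1), Benjamini–Hochberg adjustment — and
applies the thresholds |log2FC| > 1 and FDR < 0.05. Externally produced DE
tables can be substituted; the thresholds, not the test engine, are the
analysis-defining element here.

Correlations are Pearson on log2(FPKM + 1) (the standard coexpression
transform; raw FPKM is a switch). For gene i, partners are ranked 1..n−1 by
descending correlation with ties broken by gene id; MR(i, j) =
√(rank_i(j)·rank_j(i)) is symmetric and ≥ 1 with equality iff the genes are
mutual top partners. Edge weights are the exponential decay e^−(MR−1)/x for
x ∈ {5, 10, 25, 50, 100}; the printed formula in the source methodology is
sign-ambiguous, and the decaying form is used because an increasing form
would make the "> 0.01" retention filter vacuous (the sign is a config
flag). Edges are kept iff PCC > 0 *and* weight > 0.01.

Modules come from a ClusterONE-style greedy: seeds in descending
weighted-degree order grow/shrink by single-node moves maximizing
cohesiveness f(V) = w_in/(w_in + w_bound + p·|V|) with penalty p = 2,
overlapping results (overlap score |A∩B|²/(|A||B|) ≥ 0.8) are merged,
sets smaller than 3 dropped, and modules retained iff a one-sided
Mann–Whitney test of internal vs boundary edge weights gives p < 0.1. All
tie-breaks are lexicographic, so results are deterministic.

**Known limitation — intruder absorption.** With an n-sample experiment, a
background gene's chance correlation with a planted module's shared latent
factor has standard deviation ≈ 1/√n; the maximum over B background genes
grows like √(2 ln B)/√n. At n = 24 and B = 200 this is ≈ 0.55, so one to a
few background genes correlate ≈ 0.45 with *every* module gene, obtain small
mutual ranks to all of them, and measurably increase module cohesiveness
when absorbed. Any faithful cohesiveness maximizer therefore tends to report
the planted module plus one or more such genes under these conditions; the
planted genes themselves are recovered together and the module is highly
significant, but exact gene-for-gene recovery should not be expected at this
sample size and background count.

## 6. Synthetic-data generator

The generator emulates the study design end to end: a configurable number of
genomes, each a single chromosome of ranked genes; SGs planted with
occupancy drawn from the class's feasible occupancy set; members of one SG
at matching ranks, with optional local-swap rearrangement noise; tandem
copies inserted at rank + 1 and recorded in the same SG.

Sequences evolve by proposal–acceptance codon evolution: Poisson(branch ·
L) proposals uniform over one-step nucleotide changes; synonymous proposals
always accepted, nonsynonymous accepted with probability min(ω, 1),
stop-creating proposals rejected — so realized dN/dS matches ω in
expectation for ω ≤ 1 with trivial math, which is what estimator-recovery
tests need. Default branch length 0.3 proposed substitutions per codon gives
pS ≈ 0.1, comfortably below saturation. Family SG ancestors derive from six
labeled subfamily reference ancestors; members are truncated (5′, 3′ or
both thirds of the CDS removed) with the configured probability, which
deletes the corresponding domain hit and marks the gene atypical. Every
family SG keeps at least one domain-complete member, since an SG with no
seed could never be found by domain evidence plus propagation — the truth
would otherwise be unrecoverable by construction, for the real analysis as
much as for this one. Planted ancestral CDS lengths decrease from core to
private so feature summaries have a known ordering.

Variants are sampled per class in proportion to configured rates, uniformly
within the focal gene's positions of that class (regions derived by interval
arithmetic with the fixed precedence applied, independently of the
classifier's offset logic). Expression counts are negative-binomial
(dispersion 0.05) around log-normal means; module genes share a latent
factor giving pairwise log-scale correlation equal to the configured level;
DEG genes get the configured fold-change between conditions (half up, half
down). The per-sample biological log-SD defaults to 1.0; DEG-recovery runs
use 0.3 as the low-noise condition. All randomness flows from one master
seed through named substreams (crc32 of the artifact name), so identical
configs give byte-identical files and any artifact regenerates in isolation.

Not emulated: read-level sequencing, indels in codon evolution, realistic
intergenic or intronic sequence content, assembly gaps (absence always means
true absence), multi-transcript genes, and genuinely overlapping gene
models. Passing recovery tests therefore demonstrates correctness of the
algorithms under planted structure, not robustness to annotation or
assembly artifacts in real data.

## 7. Sizes and determinism

Test and acceptance runs use desk-scale problem sizes chosen to exercise
every code path with comfortable statistical margins: 4–12 genomes, 40–208
genes per genome, 500-codon / 200-replicate estimator-recovery simulations,
5,000-variant consequence checks, 50-replicate DEG runs. The full suite and
the acceptance script are deterministic given their seeds; the pipeline
manifest records sha256 checksums per stage, and re-running an identical
config reproduces identical checksums.
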