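# Methods

This note documents the models and procedures `cobscreen` implements, the
parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Marker catalog

The screening set is eleven cobalamin (cob/cbi) pathway families chosen
for broad distribution across both biosynthesis routes — cobA_cysG
(TIGR01469), cobI_cbiL (TIGR01467), cobJ_cbiH (TIGR01466), cobM_cbiF
(TIGR01465), cbiT_cobL (TIGR02469), cbiE_cobL (TIGR02467), cbiC_cobH
(PF02570), cbiA_cobB (TIGR00379), cbiB_cobD (TIGR00380), cbiP_cobQ
(TIGR00313), cobS (TIGR00317) — plus three universally conserved
ribosomal-protein families (PF00164, PF00828, PF00380) used as a
community-abundance baseline. Gene labels join the aerobic/anaerobic
nomenclature with an underscore where the routes share a homologous
enzyme. Accession version suffixes ("PF02570.10") are stripped on both
sides of every match, since hit files may carry any minor version.

Two label sets live beside the member list because genome-level analyses
read the full annotation vocabulary, not just the screening markers:
route-diagnostic genes (aerobic-specific: cobG, cobF and the CobN/S/T
chelatase subunits, written `cobS_chelatase`/`cobT_chelatase` because the
chelatase subunits are different enzymes from the TIGR00317 cobalamin
synthase labelled plain `cobS`; anaerobic-specific: cbiX, cbiG, cbiD) and
the completeness indicators (cbiA_cobB, cbiC_cobH, cobT). Stage
assignments (early = uroporphyrinogen III → cobyrinic acid a,c-diamide;
late = onward to the cofactor) are catalog metadata only; no computation
that affects results consumes them.

## Genome-level profiling

Presence/absence is literal: family *f* is present in genome *g* iff the
annotation carries ≥ 1 gene labelled *f*. The conservation score of *f* is
the fraction of supplied genomes possessing it; the set of genomes over
which it is computed is the caller's choice (e.g. restrict to archaea
before calling), never baked in.

**Route call.** With *a* = anaerobic-specific genes present and *b* =
aerobic-specific genes present: `anaerobic` if a ≥ 2 and a > b; `aerobic`
if b ≥ 2 and b > a; `none` if a = b = 0; `ambiguous` otherwise. Requiring
two diagnostic genes makes the call robust to a single annotation dropout
without over-calling from one gene; known anaerobic producers carry all
three anaerobic-specific genes, so the rule has a one-gene margin.
`complete_likely` is true when **any one** of the three indicator genes is
present — the published heuristic is "any of", not "all of". CbiJ is
deliberately never consulted: it is absent from known archaeal producers
and would penalize genuinely complete archaeal pathways.

**Synteny.** Clusters are maximal runs of pathway-labelled genes, per
replicon in start-coordinate order, in which consecutive pathway genes are
separated by at most `max_gap` non-pathway genes (default 2 — tolerant of
small ORFs and annotation noise while keeping the planted 6- and 4-gene
fixture clusters, separated by ≥ 20 decoys, distinct). Distance is counted
in intervening genes, not base pairs, for robustness to annotation
density; strand is recorded but not constrained. Runs of length 1 are not
clusters. Between clusters, similarity is `score = J · O`: Jaccard of the
label sets times the fraction of shared label pairs whose relative order
agrees (1 when ≤ 1 label is shared; repeated labels compared at first
occurrence). The pair set makes the score symmetric by construction.
Cross-genome families are single-linkage components over edges with
score ≥ `min_score`, reported when they span ≥ `min_genomes` genomes, with
the longest member's order as consensus (ties: lexicographically smallest
genome id). The detection procedure and scoring function are this
package's own constructions; the underlying biology is simply that the
early-pathway six-gene and late-pathway four-gene clusters recur with
conserved order across ammonia-oxidizing archaeal genomes.

## Metagenome screening

Inputs are the text formats the upstream tools write: hmmsearch
per-sequence "tblout" (the per-domain "domtblout" dialect is also parsed;
the full-sequence E-value governs filtering in both) and BLAST
`-outfmt 6`. The screening threshold is E ≤ 1 × 10⁻⁶, **boundary
inclusive** — "threshold of 10⁻⁶" is read as the largest accepted value,
and the boundary case is pinned by tests so the convention is auditable.

Each ORF resolves to at most one marker family (smallest E-value, then
largest bit score, then lexicographically smallest accession). One family
per ORF prevents an ORF from counting in two marker categories, which
would break Σ_t D_t = 1. Taxonomy comes from the top BLAST match among
hits passing the same threshold (smallest E, then largest bit score, then
earliest file position — BLAST lists better hits first); the label is the
lineage name at the reporting rank, default phylum, with an option to
split Proteobacteria to class to mirror the mixed phylum/class reporting
convention of marine surveys. Unknown subjects, truncated lineages,
missing BLAST evidence and no-passing-hit cases all yield "Unclassified"
— a counted category, never an error.

## Contribution statistics

The per-taxon contribution is the pooled proportion

    D_t = Σ_g h(g, t) / N,   N = Σ_g Σ_t h(g, t)

over the eleven markers. The pooled reading ("combined data for the 11
marker genes", with the same per-category total denominator as the
single-gene frequency profiles) guarantees Σ_t D_t = 1; the alternative —
an unweighted mean of per-gene profiles — is available behind
`method="mean"` since the defining formula's source presentation is
ambiguous, but the pooled form is the default and the documented reading.

The small-sample filter n < 10 applies to whichever denominator is being
formed: per-gene n for single-gene profiles, combined N for D_t, and the
ribosomal profiles under the same rule. Filtered quantities report the
sentinel `insufficient` rather than a number. Over-representation is
`D_t(cob)/D_t(ribo)` per sample and pooled; a zero ribosomal share yields
a missing value, not infinity. Taxa below a display fraction collapse into
"Other" at export time only — arithmetic is always lossless.

## Ecotype clustering

Samples are clustered on Manhattan (L1) distances between D_t profiles
with Ward's method in the `ward.D` sense: the Lance–Williams update

    d(k, i∪j) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) − n_k d(i,j)] / (n_i+n_j+n_k)

applied to the dissimilarities as supplied (this is what R's `hclust`
does with `method="ward.D"` on a Manhattan distance object; `ward.D2`,
which squares inside the update, is an option). Implementation note: the
package feeds √d to scipy's Ward linkage and squares the returned
heights, which is algebraically the ward.D recurrence on d itself; the
test suite checks the merge sequence and heights against an independent
naive Lance–Williams implementation. ward.D on arbitrary dissimilarities
can in principle produce height inversions; they are recorded (and clamped
to zero branch lengths in Newick export), not forbidden.

The number of clusters is chosen automatically by maximizing mean
silhouette width over k ∈ [2, min(10, n−1)] on the same distance matrix
(ties to the smallest k) — a deterministic surrogate for cutting a
dendrogram by eye. Cluster ids are numbered by first appearance in sample
order, so partitions are invariant to input permutation up to relabeling.
Clusters are labelled from their mean profile: one initial when a taxon
reaches the dominance threshold (0.50), "+"-joined initials for taxa at
the co-dominance threshold (0.25), else "mixed"; both thresholds and the
taxon→initial map (Thaumarchaeota→T, Proteobacteria→P, Cyanobacteria→C,
first letter otherwise) are configurable.

## Correlation screening

Plain sample Pearson correlations, pairwise-complete over missing
metadata with a minimum of 5 pairs (pooled surveys have heterogeneous
metadata; listwise deletion would discard most samples). Constant vectors
and under-paired columns report `insufficient`. No p-values and no
multiple-testing correction are attached — the output is a screening view
with an |r| > 0.25 display filter, and the full matrix is always retained
beside it. Calendar months enter correlations through
cos(2π·month/12) (maximal mid-winter), with the raw month kept for
grouped summaries; per-study grouped analysis repeats the screen within
each study to remove between-study methodological variation.

A note on taxon-vs-taxon correlations: because D_t rows sum to 1,
closure alone induces negative correlation between large shares; only
small-share pairs can look statistically independent. The tests encode
this explicitly.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure of a marine survey:

- per-sample, per-gene hit totals ~ Poisson around design means,
  allocated multinomially across taxa;
- taxon proportions shaped either by a softmax-over-taxa link, linear in
  standardized covariates (depth, temperature, nitrate, season-as-month),
  or by a mixture of ecotype components — softmax over components with
  their own covariate links, Dirichlet noise (concentration 150 by
  default) around each component's centre profile. The mixture mode
  exists so that cluster-recovery checks have exact ground-truth ecotype
  labels; the default demo uses three components (Thaumarchaeota-,
  Cyanobacteria- and Proteobacteria-dominated) whose disjoint dominance
  also plants the either-or exclusion pattern;
- E-values: log₁₀E ~ U(−30, −3) for true hits, U(−5, 2) for a configured
  decoy fraction — both laws put mass on either side of the 10⁻⁶ cutoff;
- taxonomic misassignment of the top BLAST hit with probability
  `p_wrong`, and unclassifiable ORFs (unknown subject or no BLAST row)
  with probability `p_unc`; neither is an estimate of any real survey's
  error rate — they are free simulation parameters;
- under-sampled samples draw a fixed sub-threshold total of 1–9 hits
  rather than a low-mean Poisson, so "the n<10 filter removes exactly the
  planted under-sampled samples" holds with certainty;
- ORF identifiers encode sample and serial number only, and the per-ORF
  gene/taxon assignments are shuffled before serials are assigned, so
  identifiers leak nothing to parsers.

It does **not** simulate nucleotide reads, ORF calling, alignment or
realistic protein sequences; no sequence-level realism is claimed.
Passing tests therefore demonstrate that the *post-search* pipeline is
correct and well calibrated on data with the designed statistical
structure — not that the upstream search tools would behave as modelled
on real reads.

For correlation-recovery checks the generator can plant a link with an
**exact empirical** correlation: the latent proportion vector is built by
Gram–Schmidt so its sample Pearson r with the drawn covariate equals
r_true to machine precision, then mapped affinely into (0.05, 0.95)
(affine maps preserve r) and observed through multinomial counts. At
n = 200 samples the sampling noise of a correlation coefficient is itself
≈ (1−r²)/√n ≈ 0.06, so a ±0.1 recovery band against a population r would
fail even for a perfect estimator; planting the empirical correlation
makes the band test the counting pipeline, which is the thing under
study.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit integer seed; per-sample
generators derive independent streams from (seed, stream, index) tuples,
and all files are written with fixed ordering and formatting, so a fixed
seed fixes every output byte. The pipeline manifest echoes the full
config, per-stage row counts (the E-value and n<10 filters drop data
silently otherwise) and SHA-256 checksums of every output, and contains
no timestamps, so identical config + inputs ⇒ byte-identical bundles.

The packaged checks run at deliberately desk-sized scales chosen as the
smallest sizes at which each property is statistically unambiguous: the
demo study uses 60 samples at ≈ 340 hits/sample; noiseless contribution
recovery uses 10⁴ hits/sample over 4 + 2 samples × 3 seeds (multinomial
error ≲ 0.01 ≪ the 0.02 bound); correlation recovery uses 200 samples ×
400 hits × 100 seeds per effect size; ecotype recovery uses 3 × 20
samples × 5 seeds.

## Known limitations

- Whether a real survey counted an ORF hitting two marker families once
  or twice is not knowable from published text; this package always
  counts once (best family wins), which is the conservative reading.
- The exact gene order of the real archaeal clusters is figure-bound in
  the literature; fixtures plant a documented synthetic order, and no
  packaged check depends on the true Nitrosopumilus order.
- Truncated or mis-annotated genes (e.g. a pathway gene split across two
  ORFs) are out of scope; a dropout shifts route calls by design at most
  one gene's worth.
- The ribosomal baseline uses three families; at very low coverage the
  n < 10 rule can retain a sample's cobalamin profile while dropping its
  ribosomal one (or vice versa), in which case over-representation is
  reported only on the shared retained set.
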