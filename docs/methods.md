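# Methods

`clonaltmb` implements a clonality-aware biomarker analysis for immune
checkpoint inhibitor (ICI) response in tumor exomes: somatic variant
harmonization and filtering, cancer cell fraction (CCF) estimation,
clonal/subclonal tumor mutational burden (TMB), a TMB-threshold response
classifier, APOBEC trinucleotide enrichment, and a mutant-vs-wild-type
neoantigen analysis.  A seeded synthetic cohort generator reproduces the
statistical structure the analysis assumes, so the full pipeline is
exercised end-to-end without patient data.

## Variant ingestion and filtering

Per-caller variant sets (e.g. Mutect2 and Strelka2 output) are keyed by
`(chrom, pos, ref, alt)` with chromosome names normalized by stripping a
leading `chr`, and merged by **intersection** (the high-confidence
default) or **union** (for callers that badly under-call).  When callers
disagree on numeric fields, the first caller in a declared priority list
supplies them.  Filters: gnomAD population allele frequency strictly
below 5% (missing annotation = novel, kept — unannotated variants are
exactly the tumor-specific class of interest), total depth ≥ 30, alt
depth ≥ 3.  The depth filters apply to the tumor sample; whether they
should also gate the matched normal is ambiguous in the underlying
protocol, and tumor-only is the implemented reading.  The non-synonymous
universe entering TMB is {missense, nonsense, frameshift}.  Indels
survive filtering (frameshift TMB needs them) but never enter peptide
enumeration.

## Clonality

Per mutation,

    CCF = VAF / p · (2(1 − p) + c·p)

with tumor purity `p` and local total copy number `c` (ASCAT-like
segments; diploid fallback `c = 2` for uncovered loci).  A mutation is
**clonal** iff CCF > 0.9, strictly.  Design choices:

- CCF is reported un-clamped.  Values above 1 flag purity/copy-number
  misspecification; the classification rule needs only the `> 0.9`
  predicate, so clamping would hide information and change nothing.
- Mutation multiplicity is fixed at 1, as in the formula above; total
  (not major-allele) copy number is used for `c`.
- Sex chromosomes are treated like autosomes by default; a
  per-chromosome ploidy map can override the normal-ploidy term.

## TMB and the threshold classifier

TMB = non-synonymous mutations per Mb of capture (default 50 Mb).  With
clonality annotated, clonal + subclonal TMB = total TMB exactly.  The
threshold model predicts *responder iff TMB ≥ t* over a grid from 0 to
max(TMB)+step in steps of 1 mut/Mb (the `≥` tie rule keeps t = 0
predicting all-responders, so the curve reaches (1,1)); each threshold
yields (sensitivity TP/(TP+FN), specificity TN/(TN+FP)), and the AUC is
the trapezoid under TPR vs 1−TNR with anchors (0,0) and (1,1) appended.
When the grid covers every observed value this equals the rank-based
concordance AUC (ties ½) — asserted against a brute-force pairwise
oracle in the tests.

When purity/copy number are unavailable, the VAF sweep recomputes
per-sample TMB keeping mutations with VAF ≥ v for v = 0.1 … 0.7 (step
0.05, configurable) and reports median(responder TMB)/median(non-responder
TMB), undefined when the denominator is 0.  Medians of even-sized groups
are midpoints of the central pair.

## Statistics

- **Between-group test**: two-sided unpaired rank-sum.  The groups are
  independent and unequal-sized, so the paired signed-rank variant is
  impossible here; the unpaired test is what the comparisons require.
  For combined n ≤ 20 the p-value is exact, by enumeration of all
  group assignments of the (mid)ranks — exact under ties as well; larger
  samples use the tie-corrected normal approximation.  Degenerate input
  (all values equal) returns p = 1.
- **Clonal proportion**: clonal/subclonal counts pooled by response
  group into a 2×2 table, two-sided Fisher exact test
  (point-probability inclusion, the convention of mainstream packages).
  Per-group means of per-sample clonal percentages are reported
  alongside the pooled fractions.
- **Recurrent-gene clonality**: 1-df chi-square goodness of fit of an
  observed clonal/subclonal split against a background clonal fraction.

## APOBEC enrichment

APOBEC-eligible mutations are C>T and C>G SNVs written on the pyrimidine
strand; TCW hits have trinucleotide context T-C-W with W ∈ {A, T}
(configurable; the standard TCW definition).  The background is the
±20 bp reference window around each mutation, with cytosines and TCW
motifs counted on both strands (reverse-complement aware).  Enrichment =
(n_mut_TCW/n_mut_C)/(n_bg_TCW/n_bg_C); over-representation is tested
one-sided (Fisher exact) because enrichment is a directional hypothesis;
a sample is APOBEC-significant iff enrichment > 2 **and** p < 0.05, both
strict.  A zero background TCW count leaves the score undefined (p = 1).
Group comparison: two-sided rank-sum on per-sample scores, on all
mutations or on the clonal subset.

## Neoantigens

All 9-mer windows covering a missense-mutated residue are enumerated
with their wild-type counterparts (window count
min(i, L−k+1) − max(1, i−k+1) + 1; zero when L < 9).  Binding calls come
from a pluggable backend — a table of precomputed NetMHCpan/MHCflurry
predictions, or the mock predictor below — and are categorized as
strong/weak/non-binders with strict cuts: rank < 0.5 / < 2 (primary
scheme) or IC50 < 50 / < 500 nM.  Comparing wild-type and mutant calls
yields gained (NB → binder), lost (binder → NB) or unchanged events.
Differential agretopicity (DAI) defaults to the IC50 ratio wt/mut —
scale-free, which makes the high-DAI cut `> 9` meaningful across
backends — with an absolute-difference mode available since the index's
original form admits both readings.  pMHC stability calls a long binder
at ≥ 1.4 h (inclusive: the threshold names the admitted value).
Neoantigen load counts unique (mutant peptide, allele) binder pairs per
patient by default; the counting unit is a policy argument because
overlapping windows share peptides and the right unit is genuinely
ambiguous.  The amino-acid/position analysis compares the substituted
residue (20 tests) and the within-peptide mutation position (9 tests)
between binder-changing and binder-preserving events with one-sided
Fisher tests and Benjamini–Hochberg adjustment over all 29.

## Synthetic cohorts

Defaults encode the study conditions: 17 responders vs 10
non-responders; per-sample TMB lognormal with median 5 mut/Mb (σ = 0.6)
and mutation count = TMB × 50 Mb; clonal fraction 0.34 (R) vs 0.17 (NR);
purity ~ U(0.3, 0.9); consequence mix missense:nonsense:frameshift ≈
6192:490:130 with a 0.25 synonymous ratio; per-site depth negative
binomial (mean 200, size 10 — exome-like over-dispersion; Poisson
selectable); clonal true CCF = 1, subclonal CCF ~ Beta(2, 4) (mass well
below the 0.9 threshold, keeping label-recovery tests interpretable).
Observed alt counts: expected VAF = CCF·p/(2(1−p)+c·p), alt ~
Binomial(depth, VAF).  APOBEC contexts (TCW, C>T/C>G) are drawn at 0.4
(R) vs 0.1 (NR) for clonal mutations with the NR baseline for subclonal
mutations in both groups — the group contrast is a clonal phenomenon, as
in the cohort being emulated; other SNVs get random central-pyrimidine
contexts.  Every SNV carries a random 41-bp window with its context
embedded, serving as the APOBEC background.  A single seed drives
independent per-sample substreams, so cohorts are bit-for-bit
reproducible and adding a sample never perturbs the others.

The **mock binding predictor** is a synthetic, deterministic stand-in
for an MHC-I predictor: a position-additive score (hashed allele- and
position-specific contributions for the 7 non-anchor residues, plus
allele-weighted Kyte–Doolittle hydrophobicity bonuses at anchor
positions 2 and 9) mapped through a fixed logistic to a percentile-like
rank, an IC50 anchored so rank 0.5 ↔ 50 nM and rank 2 ↔ 500 nM (keeping
the two binder schemes ~consistent), and a stability half-life monotone
in the score.  Constants were set so ~3% of random 9-mers are weak
binders and ~1% strong — the regime the rank thresholds imply.  Being
position-additive, single anchor substitutions move the score far more
than non-anchor ones, so gained binders concentrate at positions 2/9 and
hydrophobic residues, which the enrichment analysis recovers.

### What the generator does not emulate

Real genome coordinates and gene structure, mutational-signature
mixtures beyond the single APOBEC channel, germline contamination,
subclonal population structure (a single Beta, not discrete subclones),
purity/copy-number estimation error (truth is handed to the pipeline),
and learned peptide–MHC chemistry.  Passing tests therefore certify the
*statistical machinery* — estimation, partitioning, testing, counting —
under a known truth, not predictive performance on real tumors.

## Numerical notes and limitations

- All category cuts (CCF 0.9, gnomAD 5%, rank 0.5/2, IC50 50/500,
  enrichment 2) are strict; stability 1.4 h is inclusive.  Boundary
  behavior is pinned by tests.
- Known recovery bias: with binomial read noise at depth ~200, a
  true-clonal mutation (CCF = 1) falls below the strict 0.9 cut with
  probability ~0.2 (averaged over purity 0.3–0.9), so pooled recovered
  clonal fractions run ~0.05–0.06 below truth at study-like parameters.
  This is inherent to hard-thresholding a noisy CCF at 0.9 with no
  shrinkage, and the package deliberately does not correct for it — the
  analysis being reproduced uses the raw rule.  At depth ≥ 500 the bias
  drops below 0.035.
- The rank-sum test saturates quickly at small group sizes (minimum
  two-sided p = 2/C(n, n_a)); comparisons of "which p is smaller"
  between strongly separated subsets are therefore uninformative, and
  effect sizes (score gaps) should be compared instead.
- Exact rank-sum enumeration is O(C(n, n_a)); at the n = 20 switch point
  this is ~1.8·10⁵ subsets, well under a second.
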