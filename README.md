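# clonaltmb

Clonality-aware tumor mutational burden (TMB) and neoantigen biomarkers
for immune checkpoint inhibitor (ICI) response in tumor exomes.

Only a minority of advanced urothelial (and other) cancer patients
respond to anti-PD-1/PD-L1 therapy, and total TMB alone separates
responders from non-responders poorly.  The observation this package
operationalizes is that the *clonal* part of the burden — mutations
present in essentially all tumor cells — carries most of the predictive
signal.  `clonaltmb` provides, as a tested, reusable library:

- **Variant ingestion**: harmonize per-caller somatic callsets
  (intersection/union), apply population-frequency and depth filters
  (gnomAD < 5%, depth ≥ 30, alt depth ≥ 3), select non-synonymous
  mutations.
- **Clonality**: cancer cell fraction per mutation,
  `CCF = VAF/p · (2(1−p) + c·p)` with purity `p` and local copy number
  `c`; clonal iff CCF > 0.9.
- **TMB statistics**: total/clonal/subclonal TMB (mutations per 50 Mb),
  the threshold response classifier (responder iff TMB ≥ t, steps of
  1 mut/Mb) with its ROC/AUC, the VAF-sweep median-TMB ratio for
  cohorts without purity estimates, exact rank-sum / Fisher /
  chi-square group tests.
- **APOBEC**: per-sample enrichment of C>T/C>G mutations at TCW motifs
  against the ±20 bp sequence background (significant iff score > 2 and
  p < 0.05), compared between response groups.
- **Neoantigens**: mutant/wild-type 9-mer pairs for every missense
  mutation, pluggable MHC-I binding backends (prediction tables or a
  deterministic mock predictor), strong/weak binder calls (rank < 0.5/2 %
  or IC50 < 50/500 nM), binder gains and losses, differential
  agretopicity (DAI > 9), pMHC stability (≥ 1.4 h), per-patient loads,
  and amino-acid/position enrichment of binder-changing mutations.
- **Synthetic cohorts**: a fully seeded generator emulating the study
  structure (17 responders vs 10 non-responders, TMB median ~5 mut/Mb,
  clonal fractions 0.34 vs 0.17, purity 0.3–0.9, binomial read noise,
  configurable APOBEC contamination) with ground truth, so every stage
  is testable without controlled-access patient data.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from clonaltmb import (
    CohortSpec, simulate_cohort, annotate_cohort,
    pooled_clonal_fraction_test, threshold_classifier_curve, tmb_table,
)

samples, truth = simulate_cohort(CohortSpec(seed=1))
samples, _ = annotate_cohort(samples, segments_by_sample=truth.segments)

pooled = pooled_clonal_fraction_test(samples)
print(f"clonal fraction R {100*pooled.fraction_R:.1f}% "
      f"vs NR {100*pooled.fraction_NR:.1f}%  (Fisher p={pooled.p_value:.1e})")

table = tmb_table(samples)
for flavor in ("total", "clonal", "subclonal"):
    auc = threshold_classifier_curve(
        table[f"tmb_{flavor}"], table.response.tolist(), step=1.0
    ).auc
    print(f"AUC({flavor}) = {auc:.3f}")
```

prints (seed 1):

```
clonal fraction R 27.5% vs NR 13.2%  (Fisher p=3.5e-69)
AUC(total) = 0.494
AUC(clonal) = 0.791
AUC(subclonal) = 0.429
```

The generator gives both groups the *same* TMB distribution but twice
the clonal fraction in responders, so total and subclonal TMB classify
at chance level while clonal TMB discriminates clearly — the clonality
signal isolated from the burden signal.  (Recovered clonal fractions sit
slightly below the generating values 34%/17%: hard-thresholding a
noisy CCF at 0.9 loses ~20% of true-clonal mutations at depth 200; see
`docs/methods.md`.)

The scripts in `examples/` walk through each capability: cohort
simulation, the clonal-TMB classifier, the VAF sweep, APOBEC
enrichment, and the neoantigen analysis.  A thin CLI mirrors the
file-based workflow:

```sh
clonaltmb simulate --out cohort/
clonaltmb clonality --mutations cohort/mutations.tsv \
    --sample-sheet cohort/sample_sheet.tsv \
    --copy-number cohort/copy_number.tsv --out annotated.tsv
clonaltmb tmb --mutations annotated.tsv \
    --sample-sheet cohort/sample_sheet.tsv --out tmb.tsv
clonaltmb roc --tmb tmb.tsv --flavor clonal --out roc.tsv
```

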