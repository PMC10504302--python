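"""Clonal vs total TMB as a response classifier.

Annotates a simulated cohort with cancer cell fractions
(CCF = VAF/p * (2(1-p) + c*p), clonal iff CCF > 0.9), computes the three
TMB flavors and sweeps TMB thresholds (steps of 1 mut/Mb) to compare how
well each flavor separates responders from non-responders.
"""

from clonaltmb import (
    CohortSpec,
    annotate_cohort,
    pooled_clonal_fraction_test,
    simulate_cohort,
    threshold_classifier_curve,
    tmb_table,
)

samples, truth = simulate_cohort(CohortSpec(seed=1))
samples, summary = annotate_cohort(samples, segments_by_sample=truth.segments)

table = tmb_table(samples)
print(table.head(6).round(2).to_string(index=False), "\n")

pooled = pooled_clonal_fraction_test(samples)
print(f"pooled clonal fraction: responders {100 * pooled.fraction_R:.1f}% "
      f"vs non-responders {100 * pooled.fraction_NR:.1f}% "
      f"(Fisher p = {pooled.p_value:.2e})\n")

for flavor in ("total", "clonal", "subclonal"):
    curve = threshold_classifier_curve(
        table[f"tmb_{flavor}"].to_numpy(), table.response.tolist(), step=1.0
    )
    print(f"AUC({flavor:9s}) = {curve.auc:.3f}")

# With equal TMB distributions in both groups but twice the clonal
# fraction in responders, only the clonal TMB flavor discriminates:
# its AUC is well above 0.5 while total and subclonal TMB hover near
# chance.  That is the clonality signal the biomarker exploits.
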