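"""Mutant vs wild-type neoantigen analysis with the mock predictor.

Enumerates all 9-mer peptides covering each missense mutation, scores
mutant and wild-type peptides on the patient's HLA alleles, counts
binder gains/losses and per-patient neoantigen loads, and asks which
substituted residues and peptide positions drive binder gains.
"""

from clonaltmb import (
    CohortSpec,
    MockBindingPredictor,
    aa_position_enrichment,
    annotate_cohort,
    binding_changes,
    compute_dai,
    high_dai,
    neoantigen_load,
    simulate_cohort,
    simulate_proteome,
)
from clonaltmb.neoantigen import peptides_for_mutation

samples, truth = simulate_cohort(CohortSpec(n_responders=5, n_non_responders=4, seed=2))
samples, _ = annotate_cohort(samples, segments_by_sample=truth.segments)
proteins, samples = simulate_proteome(samples, seed=2)
predictor = MockBindingPredictor(seed=2)

print("sample    response       load(all)  load(clonal)  load(subclonal)")
for s in samples:
    loads = {
        subset: neoantigen_load(s, proteins, predictor, subset=subset)
        for subset in ("all", "clonal", "subclonal")
    }
    print(f"{s.sample_id:8s}  {s.response:13s}  {loads['all']:6d}  "
          f"{loads['clonal']:10d}  {loads['subclonal']:12d}")

pairs = [
    pair
    for s in samples
    for mut in s.mutations
    if mut.consequence == "missense"
    for pair in peptides_for_mutation(mut, proteins)
]
changes = binding_changes(pairs, ["A*02:01", "B*07:02"], predictor)
gains = [c for c in changes if c.change == "gained"]
losses = [c for c in changes if c.change == "lost"]
unchanged = [c for c in changes if c.change.startswith("unchanged")]
print(f"\n{len(pairs)} peptide pairs: {len(gains)} gained binders, "
      f"{len(losses)} lost, {len(unchanged)} unchanged")

dai = compute_dai(ic50_wt=500.0, ic50_mut=45.0)
print(f"example DAI (wt 500 nM -> mut 45 nM): {dai:.1f} "
      f"({'high' if high_dai(dai) else 'not high'} differential agretopicity)")

table = aa_position_enrichment(gains, unchanged)
top = table.sort_values("q_value").head(5)
print("\ntop features enriched in gained binders (BH-adjusted):")
print(top[["feature_type", "feature", "n_changed", "odds_ratio", "q_value"]]
      .to_string(index=False))

# Loads are additive across the clonal/subclonal partition.  Gains
# cluster at peptide anchor positions 2 and 9 and at hydrophobic
# residues -- the preference built into the predictor, recovered here by
# the enrichment analysis.
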