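"""VAF-threshold sweep of the responder/non-responder TMB ratio.

When purity and copy number are unavailable (so CCF cannot be computed),
raw VAF serves as a clonality proxy: per-sample TMB is recomputed keeping
only mutations above a minimum VAF, and the ratio of group median TMBs is
tracked across cuts from 0.1 to 0.7.
"""

from clonaltmb import CohortSpec, simulate_cohort, vaf_sweep_tmb_ratio

samples, _ = simulate_cohort(CohortSpec(seed=1))
sweep = vaf_sweep_tmb_ratio(samples)

print("min VAF   median-TMB ratio (R / NR)")
for v, ratio in sweep:
    bar = "" if ratio is None else "#" * int(ratio * 10)
    print(f"  {v:.2f}    {'undefined' if ratio is None else f'{ratio:.2f}'}  {bar}")

# The ratio rises while the cut enriches for clonal mutations (the
# responders' excess), peaking around 0.2 here.  Beyond that it
# collapses: under the diploid model a clonal mutation's VAF is p/2, so
# once the cut exceeds half a sample's purity even clonal mutations are
# discarded, and with purities drawn from 0.3-0.9 the medians quickly
# empty out (ratio undefined once the non-responder median TMB is 0).
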