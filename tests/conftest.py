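import pytest

from clonaltmb import CohortSpec, SomaticMutation, simulate_cohort, simulate_proteome
from clonaltmb.clonality import annotate_cohort


def make_mut(
    chrom="1",
    pos=100,
    ref="C",
    alt="T",
    total_depth=100,
    alt_depth=40,
    gnomad_af=0.0,
    consequence="missense",
    **kwargs,
):
    return SomaticMutation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        total_depth=total_depth,
        alt_depth=alt_depth,
        gnomad_af=gnomad_af,
        consequence=consequence,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One small annotated synthetic cohort shared across tests."""
    spec = CohortSpec(n_responders=6, n_non_responders=4, seed=42)
    samples, truth = simulate_cohort(spec)
    samples, summary = annotate_cohort(samples, segments_by_sample=truth.segments)
    return samples, truth, summary


@pytest.fixture(scope="session")
def cohort_with_proteome():
    spec = CohortSpec(n_responders=3, n_non_responders=2, tmb_log_mean=0.7, seed=7)
    samples, truth = simulate_cohort(spec)
    samples, _ = annotate_cohort(samples, segments_by_sample=truth.segments)
    proteins, samples = simulate_proteome(samples, seed=7)
    return samples, truth, proteins
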