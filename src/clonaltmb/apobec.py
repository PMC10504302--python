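"""APOBEC mutagenesis enrichment from trinucleotide contexts.

APOBEC cytidine deaminases produce C>T and C>G substitutions at TCW
motifs (W = A or T on the pyrimidine strand).  Per sample, the fraction
of APOBEC-eligible mutations falling in TCW is compared with the
availability of TCW motifs among cytosines in background sequence
(by default the +/-20 bp reference window around each mutation, counted
on both strands)::

    enrichment = (n_mut_tcw / n_mut_c) / (n_bg_tcw / n_bg_c)

Over-representation is tested with a one-sided Fisher exact test; a
sample is called APOBEC-significant when enrichment > 2 and p < 0.05
(both strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .io_filtering import SomaticMutation
from .tmb_stats import NON_RESPONDER, RESPONDER, TumorSample, rank_test

__all__ = [
    "ContextCounts",
    "ApobecResult",
    "count_contexts",
    "enrichment_test",
    "sample_apobec_enrichment",
    "group_apobec_comparison",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

ENRICHMENT_CUTOFF = 2.0
P_CUTOFF = 0.05


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContextCounts:
    """Mutation and background trinucleotide counts for one sample."""

    n_mut_tcw: int  # APOBEC-eligible mutations (C>T/C>G) at TCW
    n_mut_c: int  # all APOBEC-eligible mutations (C>T/C>G at any C)
    n_bg_tcw: int  # TCW motifs in background sequence (both strands)
    n_bg_c: int  # cytosines in background sequence (both strands)

    def __post_init__(self) -> None:
        if min(self.n_mut_tcw, self.n_mut_c, self.n_bg_tcw, self.n_bg_c) < 0:
            raise ValueError("context counts must be non-negative")
        if self.n_mut_tcw > self.n_mut_c or self.n_bg_tcw > self.n_bg_c:
            raise ValueError("TCW counts cannot exceed cytosine counts")


@dataclass(frozen=True)
class ApobecResult:
    """Enrichment score, Fisher p-value and the significance call
    (score > 2 and p < 0.05)."""

    enrichment_score: float | None
    p_value: float
    significant: bool


def _pyrimidine_alleles(ref: str, alt: str) -> tuple[str, str]:
    """Express a substitution on the pyrimidine strand."""
    if ref in "CT":
        return ref, alt
    return ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)


def _count_motifs(seq: str, motifs: Sequence[str]) -> int:
    seq = seq.upper()
    n = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in motifs:
            n += 1
    return n


def count_contexts(
    muts: Iterable[SomaticMutation],
    background: Iterable[str] | None = None,
    w_bases: Sequence[str] = ("A", "T"),
) -> ContextCounts:
    """Count APOBEC-eligible mutations and background motif availability.

    Mutations are APOBEC-eligible when, written on the pyrimidine strand,
    they are C>T or C>G single-nucleotide substitutions; among those, TCW
    hits have context3 T-C-W with W in ``w_bases``.  Background windows
    (defaulting to each mutation's attached ``window_seq``) contribute
    cytosines and TCW motifs counted on both strands.
    """
    w = tuple(b.upper() for b in w_bases)
    tcw_motifs = tuple(f"TC{b}" for b in w)

    n_mut_c = 0
    n_mut_tcw = 0
    windows: list[str] = [] if background is None else list(background)
    for mut in muts:
        if background is None and mut.window_seq:
            windows.append(mut.window_seq)
        if not mut.is_snv:
            continue
        ref_py, alt_py = _pyrimidine_alleles(mut.ref, mut.alt)
        if ref_py != "C" or alt_py not in "TG":
            continue
        if mut.context3 is None:
            continue
        ctx = mut.context3.upper()
        if ctx[1] != "C":
            raise ValueError(
                f"C-class substitution at {mut.chrom}:{mut.pos} has context3 "
                f"{mut.context3!r} whose central base is not C"
            )
        n_mut_c += 1
        if ctx[0] == "T" and ctx[2] in w:
            n_mut_tcw += 1

    n_bg_c = 0
    n_bg_tcw = 0
    for window in windows:
        seq = window.upper()
        n_bg_c += seq.count("C") + seq.count("G")  # cytosines on both strands
        n_bg_tcw += _count_motifs(seq, tcw_motifs) + _count_motifs(
            reverse_complement(seq), tcw_motifs
        )
    return ContextCounts(n_mut_tcw=n_mut_tcw, n_mut_c=n_mut_c, n_bg_tcw=n_bg_tcw, n_bg_c=n_bg_c)


def enrichment_test(counts: ContextCounts) -> ApobecResult:
    """Enrichment score and one-sided Fisher exact p-value for
    over-representation of TCW mutations relative to the background.

    A zero background TCW count leaves the score undefined (reported as
    ``None`` with p = 1).
    """
    if counts.n_mut_c == 0 or counts.n_bg_c == 0:
        raise ValueError("enrichment requires n_mut_c > 0 and n_bg_c > 0")
    if counts.n_bg_tcw == 0:
        return ApobecResult(enrichment_score=None, p_value=1.0, significant=False)
    score = (counts.n_mut_tcw / counts.n_mut_c) / (counts.n_bg_tcw / counts.n_bg_c)
    table = [
        [counts.n_mut_tcw, counts.n_mut_c - counts.n_mut_tcw],
        [counts.n_bg_tcw, counts.n_bg_c - counts.n_bg_tcw],
    ]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return ApobecResult(
        enrichment_score=score,
        p_value=p,
        significant=(score > ENRICHMENT_CUTOFF and p < P_CUTOFF),
    )


def _subset(sample: TumorSample, subset: str) -> list[SomaticMutation]:
    if subset == "all":
        return list(sample.mutations)
    if subset not in {"clonal", "subclonal"}:
        raise ValueError(f"subset must be all/clonal/subclonal, got {subset!r}")
    if sample.clonality_calls is None:
        raise ValueError(f"sample {sample.sample_id}: clonality annotation required")
    return [
        m for m, c in zip(sample.mutations, sample.clonality_calls) if c.label == subset
    ]


def sample_apobec_enrichment(
    sample: TumorSample,
    subset: str = "all",
    w_bases: Sequence[str] = ("A", "T"),
    background: Iterable[str] | None = None,
) -> ApobecResult | None:
    """Per-sample enrichment on the chosen clonality subset; ``None`` when
    the subset carries no APOBEC-eligible mutations or no background."""
    muts = _subset(sample, subset)
    counts = count_contexts(muts, background=background, w_bases=w_bases)
    if counts.n_mut_c == 0 or counts.n_bg_c == 0:
        return None
    return enrichment_test(counts)


def group_apobec_comparison(
    samples: Sequence[TumorSample],
    subset: str = "all",
    w_bases: Sequence[str] = ("A", "T"),
) -> tuple[float, dict[str, list[float]]]:
    """Compare per-sample APOBEC enrichment scores between responders and
    non-responders with the two-sided rank-sum test.

    Samples whose chosen subset yields no computable score are dropped.
    Returns (p_value, scores by response group).
    """
    scores: dict[str, list[float]] = {RESPONDER: [], NON_RESPONDER: []}
    for s in samples:
        result = sample_apobec_enrichment(s, subset=subset, w_bases=w_bases)
        if result is not None and result.enrichment_score is not None:
            scores[s.response].append(result.enrichment_score)
    p = rank_test(scores[RESPONDER], scores[NON_RESPONDER])
    return p, scores
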