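"""Tumor mutational burden (TMB) statistics and the threshold response model.

TMB is the number of non-synonymous somatic mutations per megabase of
captured exome (50 Mb capture by default).  With mutations partitioned into
clonal and subclonal by cancer cell fraction, TMB splits additively into a
clonal and a subclonal component.  This module computes all three flavors,
builds the threshold classifier (predict responder iff TMB >= t, swept in
steps of 1 mut/Mb) with its ROC summary, runs the VAF-sweep TMB-ratio
analysis used when purity/copy number are unavailable, and provides the
group-comparison tests (exact rank-sum, Fisher on pooled clonal
proportions, chi-square on recurrent-gene clonality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_filtering import (
    SomaticMutation,
    mutations_from_frame,
    mutations_to_frame,
    select_nonsynonymous,
)

__all__ = [
    "RESPONDER",
    "NON_RESPONDER",
    "TumorSample",
    "ThresholdCurve",
    "compute_tmb",
    "threshold_classifier_curve",
    "vaf_sweep_tmb_ratio",
    "rank_test",
    "pooled_clonal_fraction_test",
    "ClonalFractionTest",
    "recurrent_gene_clonality_test",
    "ChiSquareResult",
    "tmb_table",
    "read_sample_sheet",
    "build_cohort",
    "cohort_to_frames",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass
class TumorSample:
    """Patient-level record: response label, purity, HLA alleles, capture
    size and the (filtered, annotated) mutation set.

    ``clonality_calls``, when set by the clonality module, is aligned
    index-for-index with ``mutations``.
    """

    sample_id: str
    response: str
    mutations: list[SomaticMutation] = field(default_factory=list)
    clonality_calls: list | None = None
    purity: float | None = None
    hla_alleles: list[str] = field(default_factory=list)
    capture_size_mb: float = 50.0
    sub_response: str | None = None  # e.g. "complete" / "partial"

    def __post_init__(self) -> None:
        if self.capture_size_mb <= 0:
            raise ValueError(f"capture_size_mb must be positive, got {self.capture_size_mb}")
        if self.response not in {RESPONDER, NON_RESPONDER}:
            raise ValueError(
                f"response must be {RESPONDER!r} or {NON_RESPONDER!r}, got {self.response!r}"
            )

    @property
    def is_responder(self) -> bool:
        return self.response == RESPONDER

    def clonality_label(self, index: int) -> str:
        if self.clonality_calls is None:
            raise ValueError(f"sample {self.sample_id}: clonality not annotated")
        return self.clonality_calls[index].label


def _subset_mutations(sample: TumorSample, subset: str) -> list[SomaticMutation]:
    if subset == "all":
        return list(sample.mutations)
    if subset not in {"clonal", "subclonal"}:
        raise ValueError(f"subset must be all/clonal/subclonal, got {subset!r}")
    if sample.clonality_calls is None:
        raise ValueError(
            f"sample {sample.sample_id}: clonality annotation required for subset={subset!r}"
        )
    return [
        m
        for m, call in zip(sample.mutations, sample.clonality_calls)
        if call.label == subset
    ]


def compute_tmb(
    sample: TumorSample | Iterable[SomaticMutation],
    capture_size_mb: float | None = None,
    subset: str = "all",
    nonsynonymous_only: bool = True,
) -> float:
    """Mutations per megabase for the chosen clonality subset.

    Accepts a :class:`TumorSample` (capture size taken from the sample) or
    a plain mutation iterable with an explicit ``capture_size_mb``.  By
    default only non-synonymous mutations are counted.
    """
    if isinstance(sample, TumorSample):
        muts = _subset_mutations(sample, subset)
        capture = sample.capture_size_mb if capture_size_mb is None else capture_size_mb
    else:
        if subset != "all":
            raise ValueError("clonality subsets require a TumorSample with annotation")
        muts = list(sample)
        capture = 50.0 if capture_size_mb is None else capture_size_mb
    if capture <= 0:
        raise ValueError(f"capture_size_mb must be positive, got {capture}")
    if nonsynonymous_only:
        muts = select_nonsynonymous(muts)
    return len(muts) / capture


@dataclass
class ThresholdCurve:
    """Ordered (threshold, sensitivity, specificity) points of the TMB
    threshold classifier, with the trapezoidal area under the ROC curve."""

    points: list[tuple[float, float, float]]
    auc: float

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["threshold", "sensitivity", "specificity"])


def threshold_classifier_curve(
    tmb_by_sample: Sequence[float],
    labels: Sequence[bool | str],
    step: float = 1.0,
    thresholds: Sequence[float] | None = None,
) -> ThresholdCurve:
    """Sweep TMB thresholds and score the classifier "responder iff
    TMB >= t".

    The grid runs from 0 to max(TMB) + ``step`` in increments of ``step``
    (pass ``thresholds`` to override, e.g. with every observed value).  At
    each threshold the true positive rate TP/(TP+FN) and true negative
    rate TN/(TN+FP) are recorded; the AUC is the trapezoidal area under
    TPR vs (1-TNR) with anchor points (0,0) and (1,1) appended.
    """
    tmb = np.asarray(tmb_by_sample, dtype=float)
    is_resp = np.asarray(
        [l == RESPONDER if isinstance(l, str) else bool(l) for l in labels], dtype=bool
    )
    if tmb.shape != is_resp.shape or tmb.ndim != 1:
        raise ValueError("tmb_by_sample and labels must be equal-length 1-D sequences")
    n_pos = int(is_resp.sum())
    n_neg = int((~is_resp).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both response groups must be present (sensitivity/specificity undefined)")

    if thresholds is None:
        if step <= 0:
            raise ValueError("step must be positive")
        grid = np.arange(0.0, tmb.max() + step + 1e-12, step)
    else:
        grid = np.asarray(thresholds, dtype=float)
        if grid.size == 0:
            raise ValueError("thresholds grid is empty")
        if np.any(np.diff(grid) <= 0):
            grid = np.unique(grid)

    points: list[tuple[float, float, float]] = []
    roc: list[tuple[float, float]] = [(0.0, 0.0), (1.0, 1.0)]
    for t in grid:
        pred = tmb >= t
        tp = int((pred & is_resp).sum())
        fn = n_pos - tp
        fp = int((pred & ~is_resp).sum())
        tn = n_neg - fp
        tpr = tp / (tp + fn)
        tnr = tn / (tn + fp)
        points.append((float(t), tpr, tnr))
        roc.append((1.0 - tnr, tpr))

    roc_arr = np.array(sorted(set(roc)))
    auc = float(np.trapezoid(roc_arr[:, 1], roc_arr[:, 0]))
    return ThresholdCurve(points=points, auc=auc)


def vaf_sweep_tmb_ratio(
    samples: Sequence[TumorSample],
    vaf_grid: Sequence[float] | None = None,
    nonsynonymous_only: bool = True,
) -> list[tuple[float, float | None]]:
    """Responder/non-responder median-TMB ratio as a function of the
    minimum VAF required for a mutation to count.

    For each grid value v, per-sample TMB is recomputed from mutations
    with VAF >= v, and the ratio median(responder TMB)/median(non-responder
    TMB) is reported (``None`` when the denominator median is 0).  The
    default grid runs from 0.1 to 0.7 in steps of 0.05.
    """
    if vaf_grid is None:
        vaf_grid = np.round(np.arange(0.10, 0.70 + 1e-9, 0.05), 10)
    grid = [float(v) for v in vaf_grid]
    if not grid:
        raise ValueError("VAF grid is empty")
    groups = {RESPONDER: [], NON_RESPONDER: []}
    for s in samples:
        muts = select_nonsynonymous(s.mutations) if nonsynonymous_only else list(s.mutations)
        groups[s.response].append((np.array([m.vaf for m in muts]), s.capture_size_mb))
    if not groups[RESPONDER] or not groups[NON_RESPONDER]:
        raise ValueError("both response groups must be present")

    out: list[tuple[float, float | None]] = []
    for v in grid:
        medians = {}
        for resp, members in groups.items():
            tmbs = [float((vafs >= v).sum()) / cap for vafs, cap in members]
            medians[resp] = float(np.median(tmbs))
        if medians[NON_RESPONDER] == 0.0:
            out.append((v, None))
        else:
            out.append((v, medians[RESPONDER] / medians[NON_RESPONDER]))
    return out


def rank_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided unpaired rank-sum (Mann-Whitney) p-value between two
    independent groups.

    For combined n <= 20 the p-value is computed by exhaustive enumeration
    of all group assignments of the (mid)ranks -- exact even under ties;
    larger samples use the tie-corrected normal approximation.  Degenerate
    input (all values identical) returns p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = pooled.size
    if n <= 20:
        ranks = stats.rankdata(pooled)
        mu = a.size * (n + 1) / 2.0
        observed = abs(ranks[: a.size].sum() - mu)
        total = 0
        extreme = 0
        for idx in combinations(range(n), a.size):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= observed - 1e-9:
                extreme += 1
        return extreme / total
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


class ClonalFractionTest(NamedTuple):
    """Pooled clonal/subclonal 2x2 comparison between response groups."""

    fraction_R: float  # pooled clonal fraction, responders
    fraction_NR: float  # pooled clonal fraction, non-responders
    p_value: float  # two-sided Fisher exact
    mean_sample_pct_R: float  # mean of per-sample clonal percentages
    mean_sample_pct_NR: float
    table: tuple[tuple[int, int], tuple[int, int]]  # [[clonal, subclonal] x group]


def pooled_clonal_fraction_test(samples: Sequence[TumorSample]) -> ClonalFractionTest:
    """Pool clonal/subclonal counts by response group and test association
    with a two-sided Fisher exact test (hypergeometric point-probability
    inclusion, as in mainstream statistics packages)."""
    counts = {RESPONDER: [0, 0], NON_RESPONDER: [0, 0]}
    sample_pcts = {RESPONDER: [], NON_RESPONDER: []}
    for s in samples:
        if s.clonality_calls is None:
            raise ValueError(f"sample {s.sample_id}: clonality not annotated")
        n_clonal = sum(1 for c in s.clonality_calls if c.label == "clonal")
        n_sub = len(s.clonality_calls) - n_clonal
        counts[s.response][0] += n_clonal
        counts[s.response][1] += n_sub
        if n_clonal + n_sub:
            sample_pcts[s.response].append(100.0 * n_clonal / (n_clonal + n_sub))
    for resp, (c, sub) in counts.items():
        if c + sub == 0:
            raise ValueError(f"no mutations in the {resp} group")
    table = (tuple(counts[RESPONDER]), tuple(counts[NON_RESPONDER]))
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    frac = {
        resp: counts[resp][0] / (counts[resp][0] + counts[resp][1]) for resp in counts
    }
    return ClonalFractionTest(
        fraction_R=frac[RESPONDER],
        fraction_NR=frac[NON_RESPONDER],
        p_value=p,
        mean_sample_pct_R=float(np.mean(sample_pcts[RESPONDER])) if sample_pcts[RESPONDER] else math.nan,
        mean_sample_pct_NR=float(np.mean(sample_pcts[NON_RESPONDER])) if sample_pcts[NON_RESPONDER] else math.nan,
        table=table,
    )


class ChiSquareResult(NamedTuple):
    statistic: float
    p_value: float


def recurrent_gene_clonality_test(
    observed_clonal: int,
    observed_total: int,
    background_clonal_fraction: float,
) -> ChiSquareResult:
    """One-degree-of-freedom chi-square goodness of fit of the observed
    clonal/subclonal split in a gene set against a cohort-wide background
    clonal fraction (e.g. 73 clonal of 137 recurrent-gene mutations
    against a 28% background)."""
    if not 0 <= observed_clonal <= observed_total:
        raise ValueError("require 0 <= observed_clonal <= observed_total")
    if not 0.0 < background_clonal_fraction < 1.0:
        raise ValueError("background_clonal_fraction must be in (0, 1)")
    f = background_clonal_fraction
    expected = [observed_total * f, observed_total * (1 - f)]
    if min(expected) < 1:
        import warnings

        warnings.warn("expected cell count below 1; chi-square approximation unreliable", stacklevel=2)
    observed = [observed_clonal, observed_total - observed_clonal]
    stat, p = stats.chisquare(observed, expected)
    return ChiSquareResult(statistic=float(stat), p_value=float(p))


# ---------------------------------------------------------------------------
# Cohort table IO


def tmb_table(samples: Sequence[TumorSample]) -> pd.DataFrame:
    """Per-sample total/clonal/subclonal TMB table (clonal columns NaN when
    clonality is not annotated)."""
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "response": s.response,
            "tmb_total": compute_tmb(s, subset="all"),
        }
        if s.clonality_calls is not None:
            row["tmb_clonal"] = compute_tmb(s, subset="clonal")
            row["tmb_subclonal"] = compute_tmb(s, subset="subclonal")
        else:
            row["tmb_clonal"] = math.nan
            row["tmb_subclonal"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV (sample_id, response, and optionally
    sub_response, purity, hla_alleles [semicolon-joined], capture_size_mb)."""
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def build_cohort(mutation_frame: pd.DataFrame, sample_sheet: pd.DataFrame) -> list[TumorSample]:
    """Assemble :class:`TumorSample` records from the analysis-ready
    mutation table (must carry a ``sample_id`` column) and the sample sheet."""
    if "sample_id" not in mutation_frame.columns:
        raise ValueError("mutation table must carry a sample_id column")
    by_sample = dict(tuple(mutation_frame.groupby("sample_id", sort=False)))
    samples = []
    for row in sample_sheet.itertuples(index=False):
        sub = by_sample.get(row.sample_id)
        muts = mutations_from_frame(sub.drop(columns=["sample_id"])) if sub is not None else []
        hla_raw = getattr(row, "hla_alleles", None)
        hla = [] if hla_raw is None or pd.isna(hla_raw) else str(hla_raw).split(";")
        purity = getattr(row, "purity", None)
        purity = None if purity is None or pd.isna(purity) else float(purity)
        capture = getattr(row, "capture_size_mb", 50.0)
        capture = 50.0 if capture is None or pd.isna(capture) else float(capture)
        sub_resp = getattr(row, "sub_response", None)
        sub_resp = None if sub_resp is None or pd.isna(sub_resp) else str(sub_resp)
        samples.append(
            TumorSample(
                sample_id=str(row.sample_id),
                response=str(row.response),
                mutations=muts,
                purity=purity,
                hla_alleles=hla,
                capture_size_mb=capture,
                sub_response=sub_resp,
            )
        )
    return samples


def cohort_to_frames(samples: Sequence[TumorSample]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate a cohort as (mutation table, sample sheet).  Clonality
    annotation, when present, is written as ``ccf``/``clonality`` columns."""
    mut_frames = []
    sheet_rows = []
    for s in samples:
        frame = mutations_to_frame(s.mutations)
        frame.insert(0, "sample_id", s.sample_id)
        if s.clonality_calls is not None:
            frame["ccf"] = [c.ccf for c in s.clonality_calls]
            frame["clonality"] = [c.label for c in s.clonality_calls]
        mut_frames.append(frame)
        sheet_rows.append(
            {
                "sample_id": s.sample_id,
                "response": s.response,
                "sub_response": s.sub_response,
                "purity": s.purity,
                "hla_alleles": ";".join(s.hla_alleles),
                "capture_size_mb": s.capture_size_mb,
            }
        )
    mut_df = (
        pd.concat(mut_frames, ignore_index=True)
        if mut_frames
        else pd.DataFrame(columns=["sample_id"])
    )
    return mut_df, pd.DataFrame(sheet_rows)
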