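"""Cancer cell fraction (CCF) estimation and clonal/subclonal partitioning.

The fraction of tumor cells carrying a mutation is estimated from the
observed variant allele frequency corrected for tumor purity p and local
total copy number c::

    CCF = VAF / p * (2 * (1 - p) + c * p)

A mutation is called clonal when CCF > 0.9 (strict), subclonal otherwise.
CCF values are reported un-clamped -- noise, purity or copy-number
misspecification can push them above 1, and hiding that would mask such
problems; classification uses the raw value, and the clonal rule needs
only the > 0.9 predicate.

Assumptions inherited from the formula: a diploid normal admixture (the
"2" term; sex chromosomes are treated like autosomes unless a per-
chromosome ploidy map is supplied) and mutation multiplicity 1 (one
mutated copy).  Uncovered loci fall back to copy number 2.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_filtering import SomaticMutation, normalize_chrom
from .tmb_stats import TumorSample

__all__ = [
    "CopyNumberSegment",
    "ClonalityCall",
    "SegmentIndex",
    "compute_ccf",
    "lookup_copy_number",
    "classify_clonality",
    "annotate_sample",
    "annotate_cohort",
    "read_copy_number_tsv",
    "read_purity_tsv",
    "CLONAL",
    "SUBCLONAL",
    "DEFAULT_CCF_THRESHOLD",
]

CLONAL = "clonal"
SUBCLONAL = "subclonal"
DEFAULT_CCF_THRESHOLD = 0.9


@dataclass(frozen=True)
class CopyNumberSegment:
    """Genomic interval (1-based, inclusive ends) with total copy number."""

    chrom: str
    start: int
    end: int
    total_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.total_cn < 0:
            raise ValueError(f"negative copy number {self.total_cn}")


@dataclass(frozen=True)
class ClonalityCall:
    """Per-mutation CCF and clonal/subclonal label."""

    key: tuple
    ccf: float
    label: str


def compute_ccf(vaf, purity, copy_number):
    """Evaluate CCF = VAF/p * (2*(1-p) + c*p).

    Accepts scalars or numpy arrays (broadcast).  Purity must lie in
    (0, 1]; copy number must be non-negative.  The returned value is not
    clamped and may exceed 1.
    """
    vaf = np.asarray(vaf, dtype=float)
    purity = np.asarray(purity, dtype=float)
    copy_number = np.asarray(copy_number, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("VAF must lie in [0, 1]")
    if np.any(copy_number < 0):
        raise ValueError("copy number must be non-negative")
    ccf = vaf / purity * (2.0 * (1.0 - purity) + copy_number * purity)
    return float(ccf) if ccf.ndim == 0 else ccf


class SegmentIndex:
    """Fast (chrom, pos) -> total copy number lookup over sorted,
    non-overlapping segments."""

    def __init__(self, segments: Iterable[CopyNumberSegment]):
        by_chrom: dict[str, list[CopyNumberSegment]] = {}
        for seg in segments:
            by_chrom.setdefault(normalize_chrom(seg.chrom), []).append(seg)
        self._starts: dict[str, list[int]] = {}
        self._segs: dict[str, list[CopyNumberSegment]] = {}
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for prev, nxt in zip(segs, segs[1:]):
                if nxt.start <= prev.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"[{prev.start},{prev.end}] and [{nxt.start},{nxt.end}]"
                    )
            self._starts[chrom] = [s.start for s in segs]
            self._segs[chrom] = segs

    def query(self, chrom: str, pos: int) -> int | None:
        chrom = normalize_chrom(chrom)
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        seg = self._segs[chrom][i]
        return seg.total_cn if pos <= seg.end else None


def lookup_copy_number(
    mut: SomaticMutation,
    segments: Iterable[CopyNumberSegment] | SegmentIndex,
    default_cn: int = 2,
) -> int:
    """Total copy number of the segment containing the mutation; the
    diploid default for uncovered positions (interval ends inclusive)."""
    index = segments if isinstance(segments, SegmentIndex) else SegmentIndex(segments)
    cn = index.query(mut.chrom, mut.pos)
    return default_cn if cn is None else cn


def classify_clonality(ccf: float, threshold: float = DEFAULT_CCF_THRESHOLD) -> str:
    """Clonal iff CCF strictly exceeds the threshold (default 0.9)."""
    if ccf < 0:
        raise ValueError(f"negative CCF {ccf}")
    return CLONAL if ccf > threshold else SUBCLONAL


def annotate_sample(
    sample: TumorSample,
    segments: Iterable[CopyNumberSegment] | SegmentIndex | None = None,
    purity: float | None = None,
    default_cn: int = 2,
    threshold: float = DEFAULT_CCF_THRESHOLD,
    ploidy_by_chrom: Mapping[str, int] | None = None,
) -> TumorSample:
    """Attach a :class:`ClonalityCall` to every mutation of one sample.

    ``purity`` defaults to ``sample.purity``.  ``ploidy_by_chrom``
    optionally overrides the normal-cell copy number 2 per chromosome
    (off by default: sex chromosomes are treated like autosomes).
    Returns the sample with ``clonality_calls`` set (in place).
    """
    p = sample.purity if purity is None else purity
    if p is None:
        raise ValueError(f"sample {sample.sample_id} has no purity estimate")
    index = (
        segments
        if isinstance(segments, SegmentIndex) or segments is None
        else SegmentIndex(segments)
    )
    calls: list[ClonalityCall] = []
    n_uncovered = 0
    for mut in sample.mutations:
        cn = index.query(mut.chrom, mut.pos) if index is not None else None
        if cn is None:
            cn = default_cn
            n_uncovered += 1
        if ploidy_by_chrom is None:
            ccf = compute_ccf(mut.vaf, p, cn)
        else:
            ploidy = ploidy_by_chrom.get(normalize_chrom(mut.chrom), 2)
            ccf = mut.vaf / p * (ploidy * (1.0 - p) + cn * p)
        calls.append(ClonalityCall(key=mut.key, ccf=ccf, label=classify_clonality(ccf, threshold)))
    sample.clonality_calls = calls
    return sample


def annotate_cohort(
    samples: Sequence[TumorSample],
    segments_by_sample: Mapping[str, Iterable[CopyNumberSegment]] | None = None,
    purity_by_sample: Mapping[str, float] | None = None,
    default_cn: int = 2,
    threshold: float = DEFAULT_CCF_THRESHOLD,
) -> tuple[list[TumorSample], pd.DataFrame]:
    """Annotate every sample's mutations with CCF and clonality.

    Purities come from ``purity_by_sample`` falling back to each sample's
    own ``purity`` field; samples with neither are reported together in a
    single error.  Returns the annotated samples and a per-sample summary
    frame (mutation counts and clonal fraction clonal/(clonal+subclonal)).
    """
    missing = [
        s.sample_id
        for s in samples
        if (purity_by_sample or {}).get(s.sample_id, s.purity) is None
    ]
    if missing:
        raise ValueError(f"samples without purity estimates: {missing}")

    rows = []
    for s in samples:
        purity = (purity_by_sample or {}).get(s.sample_id, s.purity)
        segs = (segments_by_sample or {}).get(s.sample_id)
        annotate_sample(s, segments=segs, purity=purity, default_cn=default_cn, threshold=threshold)
        n_clonal = sum(1 for c in s.clonality_calls if c.label == CLONAL)
        n_total = len(s.clonality_calls)
        rows.append(
            {
                "sample_id": s.sample_id,
                "response": s.response,
                "n_mutations": n_total,
                "n_clonal": n_clonal,
                "n_subclonal": n_total - n_clonal,
                "clonal_fraction": n_clonal / n_total if n_total else float("nan"),
            }
        )
    return list(samples), pd.DataFrame(rows)


def read_copy_number_tsv(path: str | Path) -> dict[str, list[CopyNumberSegment]]:
    """Read ASCAT-like segments (columns: sample, chrom, start, end,
    total_cn) into per-sample segment lists."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    out: dict[str, list[CopyNumberSegment]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(
            CopyNumberSegment(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end), total_cn=int(row.total_cn)
            )
        )
    return out


def read_purity_tsv(path: str | Path) -> dict[str, float]:
    """Read per-sample purity estimates (columns: sample, purity)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return {str(r.sample): float(r.purity) for r in frame.itertuples(index=False)}
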