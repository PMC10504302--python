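"""Ingestion, harmonization and quality filtering of somatic variant calls.

Somatic SNV/indel calls arrive one set per variant caller per patient
(VCF 4.x or a tabular equivalent).  This module merges the per-caller sets
(intersection of callers for high-confidence calls, or union when one
caller under-calls), applies population-frequency and read-depth filters,
and restricts to the non-synonymous consequence classes that enter tumor
mutational burden, producing the analysis-ready mutation table.

Filters applied by :func:`filter_variants`:

* population allele frequency (gnomAD) strictly below 5%,
* total read depth at the site of at least 30,
* at least 3 reads supporting the alternative allele.

Variants missing a population-frequency annotation are treated as novel
(frequency 0) and kept: unannotated variants are exactly the
tumor-specific class of interest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SomaticMutation",
    "CallerCallset",
    "CONSEQUENCES",
    "NONSYNONYMOUS_CONSEQUENCES",
    "harmonize_callsets",
    "filter_variants",
    "select_nonsynonymous",
    "normalize_chrom",
    "normalize_consequence",
    "read_vcf",
    "mutations_from_frame",
    "mutations_to_frame",
    "write_filter_log",
]

#: Closed set of consequence labels.
CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "synonymous", "other"})

#: Consequence classes counted as non-synonymous (the TMB universe).
NONSYNONYMOUS_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift"})

_VALID_BASES = frozenset("ACGT")

# VEP / SnpEff style terms -> internal labels.  Unknown terms map to "other".
_CONSEQUENCE_SYNONYMS = {
    "missense": "missense",
    "missense_variant": "missense",
    "nonsense": "nonsense",
    "stop_gained": "nonsense",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so caller naming dialects agree."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def normalize_consequence(term: str) -> str:
    """Map an annotation term (e.g. VEP's ``missense_variant``) to the
    internal closed label set; unrecognized terms become ``other``."""
    term = term.strip().lower()
    if "&" in term:  # VEP joins multiple terms; take the first mapped one
        for part in term.split("&"):
            mapped = _CONSEQUENCE_SYNONYMS.get(part)
            if mapped is not None:
                return mapped
        return "other"
    return _CONSEQUENCE_SYNONYMS.get(term, "other")


@dataclass(frozen=True)
class SomaticMutation:
    """One filtered somatic variant in a tumor sample.

    Coordinates are 1-based as in VCF.  ``context3`` is the trinucleotide
    context written on the pyrimidine strand (central base C or T), e.g.
    ``"TCA"``.  ``window_seq`` optionally carries the surrounding reference
    sequence window used as the APOBEC enrichment background.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    gnomad_af: float | None = None
    consequence: str = "other"
    gene: str = ""
    context3: str | None = None
    window_seq: str | None = None
    protein_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    def __post_init__(self) -> None:
        if self.total_depth < 0 or self.alt_depth < 0:
            raise ValueError(
                f"negative read depth at {self.chrom}:{self.pos} "
                f"(total={self.total_depth}, alt={self.alt_depth})"
            )
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds total_depth "
                f"{self.total_depth} at {self.chrom}:{self.pos}"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence label {self.consequence!r} at "
                f"{self.chrom}:{self.pos}; expected one of {sorted(CONSEQUENCES)}"
            )
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError(f"gnomad_af {self.gnomad_af} outside [0, 1]")
        if self.context3 is not None:
            ctx = self.context3.upper()
            if len(ctx) != 3 or not set(ctx) <= _VALID_BASES:
                raise ValueError(f"context3 {self.context3!r} is not a trinucleotide")

    @property
    def vaf(self) -> float:
        """Variant allele frequency, alt reads / total reads (0 when uncovered)."""
        return self.alt_depth / self.total_depth if self.total_depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity: (chrom without 'chr', pos, ref, alt)."""
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def with_protein_change(
        self, gene: str, protein_pos: int, aa_ref: str, aa_alt: str
    ) -> "SomaticMutation":
        return replace(
            self, gene=gene, protein_pos=protein_pos, aa_ref=aa_ref, aa_alt=aa_alt
        )


@dataclass
class CallerCallset:
    """The variant set emitted by one caller for one patient, keyed by
    (chrom, pos, ref, alt)."""

    caller_id: str
    variants: dict[tuple, SomaticMutation] = field(default_factory=dict)

    @classmethod
    def from_mutations(
        cls, caller_id: str, mutations: Iterable[SomaticMutation]
    ) -> "CallerCallset":
        variants: dict[tuple, SomaticMutation] = {}
        for mut in mutations:
            if mut.key in variants:
                raise ValueError(
                    f"duplicate variant key {mut.key} in callset {caller_id!r}"
                )
            variants[mut.key] = mut
        return cls(caller_id=caller_id, variants=variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: tuple) -> bool:
        return key in self.variants


def harmonize_callsets(
    callsets: Sequence[CallerCallset],
    mode: str = "intersection",
    priority: Sequence[str] | None = None,
) -> list[SomaticMutation]:
    """Merge per-caller variant sets into one harmonized set.

    ``intersection`` keeps variants called by every caller (the
    high-confidence default when two callers ran); ``union`` keeps variants
    called by any caller (used when one caller badly under-calls).  Numeric
    per-variant fields (depths) are taken from the first caller in
    ``priority`` (defaults to the input order) that carries the variant.

    Returns the merged variants sorted by genomic key.
    """
    if not callsets:
        raise ValueError("at least one callset is required")
    if mode not in {"intersection", "union"}:
        raise ValueError(f"mode must be 'intersection' or 'union', got {mode!r}")
    order = list(priority) if priority is not None else [c.caller_id for c in callsets]
    by_id = {c.caller_id: c for c in callsets}
    unknown = [cid for cid in order if cid not in by_id]
    if unknown:
        raise ValueError(f"priority lists unknown caller ids: {unknown}")

    key_sets = [set(c.variants) for c in callsets]
    keys = set.intersection(*key_sets) if mode == "intersection" else set.union(*key_sets)

    # Same site, different allele representation across callers: surface it.
    if len(callsets) > 1:
        sites: dict[tuple[str, int], set[tuple[str, str]]] = {}
        for cs in callsets:
            for chrom, pos, ref, alt in cs.variants:
                sites.setdefault((chrom, pos), set()).add((ref, alt))
        conflicted = [site for site, alleles in sites.items() if len(alleles) > 1]
        if conflicted:
            warnings.warn(
                f"{len(conflicted)} site(s) with conflicting ref/alt across "
                f"callers; each representation keyed separately, numeric fields "
                f"from the priority caller",
                stacklevel=2,
            )

    merged: list[SomaticMutation] = []
    for key in sorted(keys):
        for cid in order:
            if key in by_id[cid]:
                merged.append(by_id[cid].variants[key])
                break
    return merged


def filter_variants(
    muts: Iterable[SomaticMutation],
    max_pop_af: float = 0.05,
    min_depth: int = 30,
    min_alt_depth: int = 3,
) -> tuple[list[SomaticMutation], dict[str, int]]:
    """Apply the population-frequency and depth filters.

    Keeps variants with gnomAD allele frequency strictly below
    ``max_pop_af`` (missing annotation treated as 0 and kept), total depth
    >= ``min_depth`` and alt-supporting depth >= ``min_alt_depth``.

    Returns ``(kept, log)`` where ``log`` counts, per rule, how many
    variants failed it (a variant failing several rules is counted under
    each), plus ``input`` and ``passed`` totals.
    """
    kept: list[SomaticMutation] = []
    log = {"input": 0, "passed": 0, "population_af": 0, "total_depth": 0, "alt_depth": 0}
    for mut in muts:
        log["input"] += 1
        ok = True
        pop_af = mut.gnomad_af if mut.gnomad_af is not None else 0.0
        if not pop_af < max_pop_af:
            log["population_af"] += 1
            ok = False
        if mut.total_depth < min_depth:
            log["total_depth"] += 1
            ok = False
        if mut.alt_depth < min_alt_depth:
            log["alt_depth"] += 1
            ok = False
        if ok:
            log["passed"] += 1
            kept.append(mut)
    return kept, log


def select_nonsynonymous(muts: Iterable[SomaticMutation]) -> list[SomaticMutation]:
    """Restrict to the non-synonymous classes (missense, nonsense,
    frameshift) that define the TMB universe."""
    out: list[SomaticMutation] = []
    for mut in muts:
        if mut.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence label {mut.consequence!r}")
        if mut.consequence in NONSYNONYMOUS_CONSEQUENCES:
            out.append(mut)
    return out


def read_vcf(
    path: str | Path,
    caller_id: str | None = None,
    tumor_sample: str | None = None,
    pass_only: bool = True,
    gnomad_key: str = "GNOMAD_AF",
    gene_key: str = "GENE",
    consequence_key: str = "CONSEQUENCE",
    context_key: str = "CONTEXT3",
) -> CallerCallset:
    """Read one caller's VCF into a :class:`CallerCallset`.

    Expects per-sample ``AD`` (allele depths) and optionally ``DP``
    (Mutect2/Strelka2-style); tumor depths are taken from ``tumor_sample``
    (default: first sample).  Multi-allelic records are decomposed into
    biallelic records.  Annotation is read from the INFO keys given
    (population frequency, gene symbol, consequence term, trinucleotide
    context); absent keys simply leave the field unset.
    """
    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path))
    if tumor_sample is not None:
        if tumor_sample not in vcf.samples:
            raise ValueError(f"sample {tumor_sample!r} not in {path.name}")
        sample_idx = vcf.samples.index(tumor_sample)
    else:
        sample_idx = 0
    if not vcf.samples:
        raise ValueError(f"{path.name} carries no sample columns (FORMAT AD needed)")

    muts: list[SomaticMutation] = []
    for record in vcf:
        if pass_only and record.FILTER is not None:  # cyvcf2: None means PASS
            continue
        ad = record.format("AD")
        if ad is None:
            raise ValueError(f"{path.name}: FORMAT/AD missing at {record.CHROM}:{record.POS}")
        ad_row = [int(x) for x in ad[sample_idx]]
        dp = record.format("DP")
        total = int(dp[sample_idx][0]) if dp is not None else sum(max(x, 0) for x in ad_row)
        info = dict(record.INFO)
        gnomad = info.get(gnomad_key)
        consequence = normalize_consequence(str(info.get(consequence_key, "other")))
        gene = str(info.get(gene_key, "")) or ""
        context3 = info.get(context_key)
        for alt_i, alt in enumerate(record.ALT):
            alt_depth = ad_row[alt_i + 1] if len(ad_row) > alt_i + 1 else 0
            muts.append(
                SomaticMutation(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    total_depth=max(total, max(alt_depth, 0)),
                    alt_depth=max(alt_depth, 0),
                    gnomad_af=float(gnomad) if gnomad is not None else None,
                    consequence=consequence,
                    gene=gene,
                    context3=str(context3) if context3 is not None else None,
                )
            )
    return CallerCallset.from_mutations(caller_id or path.stem, muts)


_FRAME_COLUMNS = [
    "chrom", "pos", "ref", "alt", "total_depth", "alt_depth", "vaf",
    "gnomad_af", "consequence", "gene", "context3", "window_seq",
    "protein_pos", "aa_ref", "aa_alt",
]


def mutations_to_frame(muts: Iterable[SomaticMutation]) -> pd.DataFrame:
    """Tabulate mutations (one row per variant) as a DataFrame."""
    rows = []
    for m in muts:
        rows.append(
            {
                "chrom": m.chrom, "pos": m.pos, "ref": m.ref, "alt": m.alt,
                "total_depth": m.total_depth, "alt_depth": m.alt_depth,
                "vaf": m.vaf, "gnomad_af": m.gnomad_af,
                "consequence": m.consequence, "gene": m.gene,
                "context3": m.context3, "window_seq": m.window_seq,
                "protein_pos": m.protein_pos, "aa_ref": m.aa_ref,
                "aa_alt": m.aa_alt,
            }
        )
    frame = pd.DataFrame(rows, columns=_FRAME_COLUMNS)
    return frame


def _opt(value, cast=None):
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return cast(value) if cast is not None else value


def mutations_from_frame(frame: pd.DataFrame) -> list[SomaticMutation]:
    """Inverse of :func:`mutations_to_frame` (``vaf`` column, if present,
    is ignored: VAF is always re-derived from the depths)."""
    muts = []
    for row in frame.itertuples(index=False):
        muts.append(
            SomaticMutation(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                total_depth=int(row.total_depth),
                alt_depth=int(row.alt_depth),
                gnomad_af=_opt(getattr(row, "gnomad_af", None), float),
                consequence=str(getattr(row, "consequence", "other")),
                gene=str(getattr(row, "gene", "") or ""),
                context3=_opt(getattr(row, "context3", None), str),
                window_seq=_opt(getattr(row, "window_seq", None), str),
                protein_pos=_opt(getattr(row, "protein_pos", None), lambda x: int(float(x))),
                aa_ref=_opt(getattr(row, "aa_ref", None), str),
                aa_alt=_opt(getattr(row, "aa_alt", None), str),
            )
        )
    return muts


def write_filter_log(log: Mapping[str, int], path: str | Path) -> None:
    """Write the per-rule filter counts as JSON."""
    Path(path).write_text(json.dumps(dict(log), indent=2) + "\n")
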