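"""Mutant vs wild-type neoantigen analysis.

From every missense mutation, all 9-mer peptides covering the mutated
residue are enumerated together with their wild-type counterparts.  A
pluggable predictor (a table of precomputed NetMHCpan/MHCflurry-style
predictions, or the deterministic mock predictor from
:mod:`clonaltmb.synthetic_data`) supplies per peptide-allele percentile
rank, IC50 and optionally pMHC stability.  Peptides are classified as
strong binders (rank < 0.5% or IC50 < 50 nM), weak binders (rank < 2% or
IC50 < 500 nM) or non-binders; comparing the mutant and wild-type calls
yields gained / lost / unchanged binder events.  The module also computes
the differential agretopicity index (DAI, fold improvement of mutant over
wild-type IC50, high when > 9), the pMHC stability filter (long binders
>= 1.4 h) and the amino-acid / peptide-position enrichment comparison of
binder-changing vs binder-preserving mutations.

Only missense SNVs enter peptide enumeration; nonsense and frameshift
mutations have no matched wild-type peptide and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, NamedTuple, Sequence

import pandas as pd
from scipy import stats

from .io_filtering import SomaticMutation
from .tmb_stats import TumorSample

__all__ = [
    "PeptidePair",
    "BindingPrediction",
    "BindingCall",
    "BindingChange",
    "TablePredictor",
    "enumerate_peptides",
    "peptides_for_mutation",
    "predict_binding",
    "classify_binder",
    "classify_change",
    "binding_changes",
    "compute_dai",
    "high_dai",
    "stability_filter",
    "neoantigen_load",
    "aa_position_enrichment",
    "read_protein_fasta",
    "AMINO_ACIDS",
    "HIGH_DAI_THRESHOLD",
    "STABILITY_HOURS_THRESHOLD",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
HIGH_DAI_THRESHOLD = 9.0
STABILITY_HOURS_THRESHOLD = 1.4

SB = "SB"
WB = "WB"
NB = "NB"
_BINDER_CATEGORIES = (SB, WB)


@dataclass(frozen=True)
class PeptidePair:
    """A mutant 9-mer and its wild-type counterpart, differing at exactly
    one residue (``mut_index``, 1-based within the peptide)."""

    gene: str
    protein_pos: int  # 1-based mutated residue in the protein
    wt_peptide: str
    mut_peptide: str
    mut_index: int  # 1-based position of the difference within the peptide

    def __post_init__(self) -> None:
        if len(self.wt_peptide) != len(self.mut_peptide):
            raise ValueError("paired peptides must have equal length")
        diffs = [
            i
            for i, (a, b) in enumerate(zip(self.wt_peptide, self.mut_peptide), start=1)
            if a != b
        ]
        if diffs != [self.mut_index]:
            raise ValueError(
                f"peptides must differ exactly at mut_index {self.mut_index}, "
                f"differ at {diffs}"
            )
        for pep in (self.wt_peptide, self.mut_peptide):
            if not set(pep) <= set(AMINO_ACIDS):
                raise ValueError(f"non-canonical residue in peptide {pep!r}")

    @property
    def mutant_residue(self) -> str:
        return self.mut_peptide[self.mut_index - 1]


class BindingPrediction(NamedTuple):
    """Raw predictor output for one (peptide, allele) query."""

    rank: float
    ic50: float
    stability_hours: float | None = None


@dataclass(frozen=True)
class BindingCall:
    """A prediction plus its binder category under the active scheme."""

    peptide: str
    allele: str
    rank: float
    ic50: float
    stability_hours: float | None
    category: str

    @property
    def is_binder(self) -> bool:
        return self.category in _BINDER_CATEGORIES


@dataclass(frozen=True)
class BindingChange:
    """Mutant-vs-wild-type binder status for one pair and allele."""

    pair: PeptidePair
    allele: str
    change: str  # gained / lost / unchanged_binder / unchanged_nonbinder


def enumerate_peptides(
    protein_seq: str,
    protein_pos: int,
    aa_ref: str,
    aa_alt: str,
    k: int = 9,
    gene: str = "",
) -> list[PeptidePair]:
    """All k-mer windows of the protein covering the mutated residue.

    Windows start at s in [max(1, i-k+1), min(i, L-k+1)] (1-based), giving
    min(i, L-k+1) - max(1, i-k+1) + 1 pairs, and none when the protein is
    shorter than k.  The reference residue must match the sequence.
    """
    seq = protein_seq.upper()
    L = len(seq)
    i = protein_pos
    if not 1 <= i <= L:
        raise ValueError(f"protein_pos {i} outside sequence of length {L} ({gene})")
    if seq[i - 1] != aa_ref.upper():
        raise ValueError(
            f"reference mismatch in {gene or 'protein'} at position {i}: "
            f"sequence has {seq[i - 1]}, mutation says {aa_ref}"
        )
    if aa_alt.upper() == aa_ref.upper():
        raise ValueError("aa_alt must differ from aa_ref")
    if L < k:
        return []
    pairs = []
    for s in range(max(1, i - k + 1), min(i, L - k + 1) + 1):
        wt = seq[s - 1 : s - 1 + k]
        offset = i - s  # 0-based index of mutation within window
        mut = wt[:offset] + aa_alt.upper() + wt[offset + 1 :]
        pairs.append(
            PeptidePair(
                gene=gene,
                protein_pos=i,
                wt_peptide=wt,
                mut_peptide=mut,
                mut_index=offset + 1,
            )
        )
    return pairs


def peptides_for_mutation(
    mut: SomaticMutation, proteins: dict[str, str], k: int = 9
) -> list[PeptidePair]:
    """Enumerate pairs for one missense mutation against its protein."""
    if mut.consequence != "missense":
        raise ValueError("peptide enumeration is defined for missense mutations only")
    if mut.protein_pos is None or mut.aa_ref is None or mut.aa_alt is None:
        raise ValueError(
            f"missense mutation at {mut.chrom}:{mut.pos} lacks protein annotation"
        )
    if mut.gene not in proteins:
        raise KeyError(f"no protein sequence for gene {mut.gene!r}")
    return enumerate_peptides(
        proteins[mut.gene], mut.protein_pos, mut.aa_ref, mut.aa_alt, k=k, gene=mut.gene
    )


def classify_binder(
    rank: float | None = None, ic50: float | None = None, scheme: str = "rank"
) -> str:
    """Binder category under the rank scheme (SB: rank < 0.5, WB: rank < 2)
    or the IC50 scheme (SB: < 50 nM, WB: < 500 nM); all cuts strict."""
    if scheme == "rank":
        if rank is None:
            raise ValueError("rank scheme requires a rank")
        if rank < 0.5:
            return SB
        return WB if rank < 2.0 else NB
    if scheme == "ic50":
        if ic50 is None:
            raise ValueError("ic50 scheme requires an IC50")
        if ic50 < 50.0:
            return SB
        return WB if ic50 < 500.0 else NB
    raise ValueError(f"scheme must be 'rank' or 'ic50', got {scheme!r}")


class TablePredictor:
    """Predictor backed by a table of precomputed predictions (TSV or
    DataFrame with columns peptide, allele, rank, ic50, and optionally
    stability_hours)."""

    def __init__(self, table: pd.DataFrame | str | Path):
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t")
        required = {"peptide", "allele", "rank", "ic50"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"prediction table missing columns: {sorted(missing)}")
        self._table: dict[tuple[str, str], BindingPrediction] = {}
        has_stab = "stability_hours" in table.columns
        for row in table.itertuples(index=False):
            stab = getattr(row, "stability_hours", None) if has_stab else None
            stab = None if stab is None or pd.isna(stab) else float(stab)
            self._table[(str(row.peptide), str(row.allele))] = BindingPrediction(
                rank=float(row.rank), ic50=float(row.ic50), stability_hours=stab
            )

    def __call__(self, peptide: str, allele: str) -> BindingPrediction:
        try:
            return self._table[(peptide, allele)]
        except KeyError:
            raise KeyError((peptide, allele)) from None


def predict_binding(
    peptides: Sequence[str],
    alleles: Sequence[str],
    backend: Callable[[str, str], BindingPrediction],
    scheme: str = "rank",
) -> list[BindingCall]:
    """One :class:`BindingCall` per peptide x allele, via the backend.

    Missing predictions (table backend) are collected and reported in a
    single error listing the offending (peptide, allele) pairs.
    """
    calls: list[BindingCall] = []
    missing: list[tuple[str, str]] = []
    for peptide in peptides:
        for allele in alleles:
            try:
                pred = backend(peptide, allele)
            except KeyError:
                missing.append((peptide, allele))
                continue
            calls.append(
                BindingCall(
                    peptide=peptide,
                    allele=allele,
                    rank=pred.rank,
                    ic50=pred.ic50,
                    stability_hours=pred.stability_hours,
                    category=classify_binder(rank=pred.rank, ic50=pred.ic50, scheme=scheme),
                )
            )
    if missing:
        raise ValueError(f"no prediction available for pairs: {missing}")
    return calls


def classify_change(
    wt_call: BindingCall, mut_call: BindingCall, pair: PeptidePair | None = None
) -> BindingChange:
    """Gained (wild-type non-binder, mutant binder), lost (the reverse),
    or unchanged."""
    if wt_call.allele != mut_call.allele:
        raise ValueError(
            f"allele mismatch: wt {wt_call.allele} vs mut {mut_call.allele}"
        )
    wt_b, mut_b = wt_call.is_binder, mut_call.is_binder
    if not wt_b and mut_b:
        change = "gained"
    elif wt_b and not mut_b:
        change = "lost"
    elif wt_b:
        change = "unchanged_binder"
    else:
        change = "unchanged_nonbinder"
    if pair is None:
        pair = PeptidePair(
            gene="",
            protein_pos=1,
            wt_peptide=wt_call.peptide,
            mut_peptide=mut_call.peptide,
            mut_index=_single_diff_index(wt_call.peptide, mut_call.peptide),
        )
    return BindingChange(pair=pair, allele=wt_call.allele, change=change)


def _single_diff_index(a: str, b: str) -> int:
    diffs = [i for i, (x, y) in enumerate(zip(a, b), start=1) if x != y]
    if len(diffs) != 1:
        raise ValueError("peptides do not differ at exactly one residue")
    return diffs[0]


def binding_changes(
    pairs: Iterable[PeptidePair],
    alleles: Sequence[str],
    backend: Callable[[str, str], BindingPrediction],
    scheme: str = "rank",
) -> list[BindingChange]:
    """Classify the binder-status change of every pair x allele."""
    changes = []
    for pair in pairs:
        calls = predict_binding([pair.wt_peptide, pair.mut_peptide], alleles, backend, scheme)
        by_key = {(c.peptide, c.allele): c for c in calls}
        for allele in alleles:
            wt_call = by_key[(pair.wt_peptide, allele)]
            mut_call = by_key[(pair.mut_peptide, allele)]
            changes.append(classify_change(wt_call, mut_call, pair=pair))
    return changes


def compute_dai(ic50_wt: float, ic50_mut: float, mode: str = "ratio") -> float:
    """Differential agretopicity index: fold (default) or absolute
    improvement of the mutant's predicted IC50 over the wild-type's."""
    if ic50_wt <= 0 or ic50_mut <= 0:
        raise ValueError("IC50 values must be positive")
    if mode == "ratio":
        return ic50_wt / ic50_mut
    if mode == "difference":
        return ic50_wt - ic50_mut
    raise ValueError(f"mode must be 'ratio' or 'difference', got {mode!r}")


def high_dai(dai: float, threshold: float = HIGH_DAI_THRESHOLD) -> bool:
    """High differential binding affinity: DAI strictly above 9."""
    return dai > threshold


def stability_filter(
    stability_hours: float, min_hours: float = STABILITY_HOURS_THRESHOLD
) -> bool:
    """Long pMHC binder: predicted complex half-life of at least 1.4 h
    (inclusive boundary: 1.4 h names the admitted value)."""
    if stability_hours < 0:
        raise ValueError("stability must be non-negative")
    return stability_hours >= min_hours


def neoantigen_load(
    sample: TumorSample,
    proteins: dict[str, str],
    backend: Callable[[str, str], BindingPrediction],
    subset: str = "all",
    scheme: str = "rank",
    dedup: str = "peptide_allele",
    k: int = 9,
) -> int:
    """Number of putative binders (mutant peptides with category SB/WB on
    any of the patient's HLA alleles) arising from missense mutations in
    the chosen clonality subset.

    ``dedup`` fixes the counting unit: unique (mutant peptide, allele)
    pairs (default), unique mutant peptides ("peptide"), or every binder
    event ("event").
    """
    if not sample.hla_alleles:
        raise ValueError(f"sample {sample.sample_id} has no HLA alleles")
    if subset == "all":
        muts = list(sample.mutations)
    elif subset in {"clonal", "subclonal"}:
        if sample.clonality_calls is None:
            raise ValueError(f"sample {sample.sample_id}: clonality annotation required")
        muts = [
            m
            for m, c in zip(sample.mutations, sample.clonality_calls)
            if c.label == subset
        ]
    else:
        raise ValueError(f"subset must be all/clonal/subclonal, got {subset!r}")

    events: list[tuple[str, str]] = []
    for mut in muts:
        if mut.consequence != "missense" or mut.protein_pos is None:
            continue
        for pair in peptides_for_mutation(mut, proteins, k=k):
            calls = predict_binding(
                [pair.mut_peptide], sample.hla_alleles, backend, scheme
            )
            events.extend((c.peptide, c.allele) for c in calls if c.is_binder)

    if dedup == "peptide_allele":
        return len(set(events))
    if dedup == "peptide":
        return len({pep for pep, _ in events})
    if dedup == "event":
        return len(events)
    raise ValueError(f"dedup must be peptide_allele/peptide/event, got {dedup!r}")


def aa_position_enrichment(
    changed: Sequence[BindingChange],
    unchanged: Sequence[BindingChange],
) -> pd.DataFrame:
    """Which substituted residues and peptide positions distinguish
    binder-changing mutations from binder-preserving ones.

    For each of the 20 amino acids (the residue introduced by the
    mutation) and each peptide position 1-9, a one-sided Fisher exact
    test compares its frequency in ``changed`` against ``unchanged``
    (enrichment direction), with Benjamini-Hochberg adjustment across the
    29 tests.  Features absent from both sets get an undefined odds ratio
    but never crash.
    """
    if not changed or not unchanged:
        raise ValueError("both changed and unchanged sets must be non-empty")
    n_changed = len(changed)
    n_unchanged = len(unchanged)

    rows = []
    for feature_type, values, extract in (
        ("amino_acid", list(AMINO_ACIDS), lambda ch: ch.pair.mutant_residue),
        ("position", list(range(1, 10)), lambda ch: ch.pair.mut_index),
    ):
        changed_feats = [extract(ch) for ch in changed]
        unchanged_feats = [extract(ch) for ch in unchanged]
        for value in values:
            a = sum(1 for f in changed_feats if f == value)
            c = sum(1 for f in unchanged_feats if f == value)
            table = [[a, n_changed - a], [c, n_unchanged - c]]
            odds, p = stats.fisher_exact(table, alternative="greater")
            rows.append(
                {
                    "feature_type": feature_type,
                    "feature": value,
                    "n_changed": a,
                    "n_unchanged": c,
                    "odds_ratio": float(odds),
                    "p_value": float(p),
                }
            )
    frame = pd.DataFrame(rows)
    frame["q_value"] = stats.false_discovery_control(frame["p_value"], method="bh")
    return frame


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id (gene or transcript)."""
    from Bio import SeqIO

    return {record.id: str(record.seq).upper() for record in SeqIO.parse(str(path), "fasta")}
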