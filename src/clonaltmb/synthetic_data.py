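"""Synthetic two-group ICI cohorts with known ground truth.

The generator emulates the statistical structure the clonality analysis
assumes: a responder / non-responder cohort whose per-sample mutation
burden is lognormal around ~5 mut/Mb (50 Mb capture), responders carrying
roughly twice the clonal-mutation fraction of non-responders (0.34 vs
0.17), tumor purity uniform on 0.3-0.9, clonal mutations at true cancer
cell fraction 1 and subclonal ones drawn from a Beta distribution
concentrated well below the 0.9 calling threshold.  Observed allele
counts come from inverting the CCF formula to an expected VAF and
sampling alt reads binomially at an (over-dispersed) per-site depth, so
pipeline estimates are noisy in the same way real exomes are.
Trinucleotide contexts carry a configurable per-group APOBEC (TCW
C>T/C>G) fraction; every SNV also gets a random reference window with
the context embedded, which serves as the enrichment background.

A deterministic mock MHC-I binding predictor with hydrophobic
anchor-position preferences (peptide positions 2 and 9) stands in for
NetMHCpan-style backends so the whole neoantigen arm is testable without
external software.  It is a synthetic construct: its scores are hashes,
not learned affinities.

Identical seeds give bitwise-identical cohorts; each sample draws from
an independent substream, so adding a sample never perturbs the others.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from hashlib import blake2b
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clonality import CopyNumberSegment
from .io_filtering import SomaticMutation
from .neoantigen import AMINO_ACIDS, BindingPrediction
from .tmb_stats import NON_RESPONDER, RESPONDER, TumorSample, cohort_to_frames

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "simulate_cohort",
    "simulate_proteome",
    "MockBindingPredictor",
    "write_cohort",
    "HLA_POOL",
]

#: Small class-I allele pool for synthetic patients.
HLA_POOL = ("A*01:01", "A*02:01", "A*24:02", "B*07:02", "B*08:01", "C*07:01")

# Non-synonymous consequence mix observed in urothelial exomes
# (missense : nonsense : frameshift ~ 6192 : 490 : 130).
_CONSEQUENCE_CLASSES = ("missense", "nonsense", "frameshift")
_CONSEQUENCE_WEIGHTS = np.array([6192.0, 490.0, 130.0])
_CONSEQUENCE_WEIGHTS /= _CONSEQUENCE_WEIGHTS.sum()

_BASES = "ACGT"
_CHROM_LENGTH = 200_000_000
_WINDOW_FLANK = 20  # +/-20 bp background window around each mutation


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults reproduce the study conditions: 17 responders vs 10
    non-responders, lognormal TMB with median 5 mut/Mb, clonal fractions
    0.34 / 0.17, purity uniform on (0.3, 0.9), negative-binomial depth
    with mean 200, subclonal CCF ~ Beta(2, 4), and APOBEC context
    fractions 0.4 / 0.1 (the clonal-APOBEC contrast between groups).
    """

    n_responders: int = 17
    n_non_responders: int = 10
    tmb_log_mean: float = math.log(5.0)  # lognormal location (median 5 mut/Mb)
    tmb_log_sd: float = 0.6
    clonal_fraction_R: float = 0.34
    clonal_fraction_NR: float = 0.17
    purity_range: tuple[float, float] = (0.3, 0.9)
    depth_mean: float = 200.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    depth_model: str = "negative_binomial"  # or "poisson"
    subclonal_ccf_shape: tuple[float, float] = (2.0, 4.0)
    apobec_fraction_R: float = 0.4
    apobec_fraction_NR: float = 0.1
    # The APOBEC contrast between groups lives in the clonal mutations
    # (subclonal mutations in both groups use the NR baseline); mirrors the
    # observation that the responder APOBEC excess is a clonal phenomenon.
    apobec_clonal_only: bool = True
    aneuploid_fraction: float = 0.0  # fraction of genome segments at cn != 2
    aneuploid_cn_choices: tuple[int, ...] = (1, 3, 4)
    synonymous_ratio: float = 0.25  # synonymous calls per non-synonymous call
    capture_size_mb: float = 50.0
    n_segments: int = 10
    gene_pool_size: int = 300
    hla_per_sample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "clonal_fraction_R",
            "clonal_fraction_NR",
            "apobec_fraction_R",
            "apobec_fraction_NR",
            "aneuploid_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_responders < 1 or self.n_non_responders < 1:
            raise ValueError("each response group needs at least one sample")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity_range must lie within (0, 1], got {self.purity_range}")
        if self.depth_model not in {"negative_binomial", "poisson"}:
            raise ValueError("depth_model must be 'negative_binomial' or 'poisson'")
        if self.capture_size_mb <= 0:
            raise ValueError("capture_size_mb must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        raw = json.loads(Path(path).read_text())
        for key in ("purity_range", "subclonal_ccf_shape", "aneuploid_cn_choices"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """True per-mutation and per-sample quantities, known by construction.

    ``mutations`` rows align with each sample's mutation list order
    (columns sample_id, mut_index, chrom, pos, ref, alt, true_ccf,
    true_clonal, apobec_origin, true_cn, expected_vaf, consequence).
    """

    mutations: pd.DataFrame
    samples: pd.DataFrame
    segments: dict[str, list[CopyNumberSegment]] = field(default_factory=dict)


def _sample_segments(rng: np.random.Generator, spec: CohortSpec) -> list[CopyNumberSegment]:
    bounds = np.linspace(1, _CHROM_LENGTH, spec.n_segments + 1, dtype=np.int64)
    segments = []
    for i in range(spec.n_segments):
        if rng.random() < spec.aneuploid_fraction:
            cn = int(rng.choice(spec.aneuploid_cn_choices))
        else:
            cn = 2
        segments.append(
            CopyNumberSegment(chrom="1", start=int(bounds[i]), end=int(bounds[i + 1] - 1), total_cn=cn)
        )
    return segments


def _segment_cn(segments: list[CopyNumberSegment], pos: int) -> int:
    for seg in segments:
        if seg.start <= pos <= seg.end:
            return seg.total_cn
    return 2


def _random_window(rng: np.random.Generator, context3: str | None) -> str:
    window = rng.choice(list(_BASES), size=2 * _WINDOW_FLANK + 1)
    window = "".join(window)
    if context3 is None:
        return window
    mid = _WINDOW_FLANK
    return window[: mid - 1] + context3 + window[mid + 2 :]


def _draw_depths(rng: np.random.Generator, spec: CohortSpec, n: int) -> np.ndarray:
    if spec.depth_model == "poisson":
        depths = rng.poisson(spec.depth_mean, size=n)
    else:
        size = spec.depth_dispersion
        p = size / (size + spec.depth_mean)
        depths = rng.negative_binomial(size, p, size=n)
    return np.maximum(depths, 1)


def _simulate_sample(
    sample_id: str,
    response: str,
    rng: np.random.Generator,
    spec: CohortSpec,
) -> tuple[TumorSample, list[dict], list[CopyNumberSegment], dict]:
    responder = response == RESPONDER
    clonal_fraction = spec.clonal_fraction_R if responder else spec.clonal_fraction_NR
    apobec_fraction = spec.apobec_fraction_R if responder else spec.apobec_fraction_NR

    purity = float(rng.uniform(*spec.purity_range))
    hla = [str(a) for a in rng.choice(HLA_POOL, size=spec.hla_per_sample, replace=False)]
    tmb_true = float(rng.lognormal(spec.tmb_log_mean, spec.tmb_log_sd))
    n_nonsyn = max(1, round(tmb_true * spec.capture_size_mb))
    n_syn = round(n_nonsyn * spec.synonymous_ratio)
    n_total = n_nonsyn + n_syn
    segments = _sample_segments(rng, spec)

    positions = np.sort(rng.choice(_CHROM_LENGTH - 100, size=n_total, replace=False) + 50)
    consequences = list(
        rng.choice(_CONSEQUENCE_CLASSES, size=n_nonsyn, p=_CONSEQUENCE_WEIGHTS)
    ) + ["synonymous"] * n_syn
    rng.shuffle(consequences)
    depths = _draw_depths(rng, spec, n_total)

    mutations: list[SomaticMutation] = []
    truth_rows: list[dict] = []
    for i in range(n_total):
        pos = int(positions[i])
        consequence = str(consequences[i])
        is_clonal = bool(rng.random() < clonal_fraction)
        ccf = 1.0 if is_clonal else float(rng.beta(*spec.subclonal_ccf_shape))
        cn = _segment_cn(segments, pos)
        expected_vaf = ccf * purity / (2.0 * (1.0 - purity) + cn * purity)
        if expected_vaf > 1.0:
            warnings.warn(
                f"{sample_id}: expected VAF {expected_vaf:.3f} > 1 clipped "
                f"(purity {purity:.2f}, cn {cn})",
                stacklevel=2,
            )
            expected_vaf = 1.0
        depth = int(depths[i])
        alt = int(rng.binomial(depth, expected_vaf))

        is_snv = consequence != "frameshift"
        apobec_origin = False
        if is_snv:
            if spec.apobec_clonal_only and not is_clonal:
                p_apobec = spec.apobec_fraction_NR
            else:
                p_apobec = apobec_fraction
            if rng.random() < p_apobec:
                apobec_origin = True
                context3 = "TC" + str(rng.choice(["A", "T"]))
                ref = "C"
                alt_base = str(rng.choice(["T", "G"], p=[0.7, 0.3]))
            else:
                ref = str(rng.choice(["C", "T"]))  # pyrimidine-strand reference
                flanks = rng.choice(list(_BASES), size=2)
                context3 = str(flanks[0]) + ref + str(flanks[1])
                alt_base = str(rng.choice([b for b in _BASES if b != ref]))
            ref_allele, alt_allele = ref, alt_base
        else:
            context3 = None
            ref_allele = str(rng.choice(list(_BASES)))
            alt_allele = ref_allele + str(rng.choice(list(_BASES)))

        gene = f"G{int(rng.integers(spec.gene_pool_size)):04d}"
        mutations.append(
            SomaticMutation(
                chrom="1",
                pos=pos,
                ref=ref_allele,
                alt=alt_allele,
                total_depth=depth,
                alt_depth=alt,
                gnomad_af=0.0,
                consequence=consequence,
                gene=gene,
                context3=context3,
                window_seq=_random_window(rng, context3),
            )
        )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "mut_index": i,
                "chrom": "1",
                "pos": pos,
                "ref": ref_allele,
                "alt": alt_allele,
                "consequence": consequence,
                "true_ccf": ccf,
                "true_clonal": is_clonal,
                "apobec_origin": apobec_origin,
                "true_cn": cn,
                "expected_vaf": expected_vaf,
            }
        )

    sample = TumorSample(
        sample_id=sample_id,
        response=response,
        mutations=mutations,
        purity=purity,
        hla_alleles=hla,
        capture_size_mb=spec.capture_size_mb,
    )
    sample_row = {
        "sample_id": sample_id,
        "response": response,
        "purity": purity,
        "tmb_true": tmb_true,
        "n_mutations": n_total,
        "n_nonsynonymous": n_nonsyn,
        "true_clonal_fraction": float(np.mean([r["true_clonal"] for r in truth_rows])),
    }
    return sample, truth_rows, segments, sample_row


def simulate_cohort(spec: CohortSpec | None = None) -> tuple[list[TumorSample], GroundTruth]:
    """Draw a full synthetic cohort; returns (samples, ground truth).

    Reproducible bit-for-bit from ``spec`` (including its seed); sample i
    always consumes the i-th child stream of the root seed sequence.
    """
    spec = spec if spec is not None else CohortSpec()
    n_total = spec.n_responders + spec.n_non_responders
    children = np.random.SeedSequence(spec.seed).spawn(n_total)

    samples: list[TumorSample] = []
    truth_rows: list[dict] = []
    sample_rows: list[dict] = []
    segments: dict[str, list[CopyNumberSegment]] = {}
    labels = [(f"R{i + 1:02d}", RESPONDER) for i in range(spec.n_responders)] + [
        (f"NR{i + 1:02d}", NON_RESPONDER) for i in range(spec.n_non_responders)
    ]
    for idx, (sample_id, response) in enumerate(labels):
        rng = np.random.default_rng(children[idx])
        sample, rows, segs, sample_row = _simulate_sample(sample_id, response, rng, spec)
        samples.append(sample)
        truth_rows.extend(rows)
        segments[sample_id] = segs
        sample_rows.append(sample_row)

    truth = GroundTruth(
        mutations=pd.DataFrame(truth_rows),
        samples=pd.DataFrame(sample_rows),
        segments=segments,
    )
    return samples, truth


def simulate_proteome(
    samples: Sequence[TumorSample],
    length_range: tuple[int, int] = (60, 300),
    seed: int = 0,
) -> tuple[dict[str, str], list[TumorSample]]:
    """Random protein sequences for every gene carrying a missense
    mutation, with each such mutation placed at a concrete residue.

    Each missense mutation gets a protein position, the reference residue
    read from the sequence and a distinct alternative residue, so the
    placements join back to the mutation table with zero mismatches.
    Samples are updated in place and returned.
    """
    lo, hi = length_range
    if lo < 9:
        raise ValueError("proteins must be at least 9 residues for 9-mer windows")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
    genes = sorted(
        {m.gene for s in samples for m in s.mutations if m.consequence == "missense"}
    )
    aa = list(AMINO_ACIDS)
    proteins = {
        gene: "".join(rng.choice(aa, size=int(rng.integers(lo, hi + 1)))) for gene in genes
    }
    for sample in samples:
        new_muts = []
        for mut in sample.mutations:
            if mut.consequence == "missense":
                seq = proteins[mut.gene]
                pos = int(rng.integers(1, len(seq) + 1))
                aa_ref = seq[pos - 1]
                aa_alt = str(rng.choice([a for a in aa if a != aa_ref]))
                mut = mut.with_protein_change(mut.gene, pos, aa_ref, aa_alt)
            new_muts.append(mut)
        sample.mutations = new_muts
    return proteins, list(samples)


# ---------------------------------------------------------------------------
# Mock MHC-I binding predictor

# Kyte-Doolittle hydropathy, rescaled to [0, 1].
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_HYDRO = {aa: (kd + 4.5) / 9.0 for aa, kd in _KD.items()}


def _unit_hash(text: str) -> float:
    digest = blake2b(text.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2.0**64


class MockBindingPredictor:
    """Deterministic stand-in for an MHC-I binding predictor (synthetic).

    The score of a 9-mer is position-additive, like a position weight
    matrix: each non-anchor residue contributes a fixed hashed
    (allele-, position- and residue-specific) term, and the anchor
    positions 2 and 9 contribute allele-weighted hydrophobicity bonuses,
    so anchor substitutions move the score far more than any other single
    substitution.  The score maps through a fixed logistic curve to a
    percentile-like rank in (0, 100), an IC50 in (1, 50000] nM consistent
    with the rank thresholds (rank 0.5 <-> 50 nM, rank 2 <-> 500 nM), and
    a pMHC stability half-life monotone in the score.  No randomness at
    call time: identical (peptide, allele, seed) always give identical
    output.
    """

    #: logistic mapping score -> rank; fixed so category thresholds are
    #: stable across platforms.
    _STEEP = 25.0
    _MID = 0.56
    _ANCHORS = (1, 8)  # 0-based indices of peptide positions 2 and 9

    def __init__(self, seed: int = 0, k: int = 9):
        self.seed = int(seed)
        self.k = int(k)

    def _allele_weights(self, allele: str) -> tuple[float, float]:
        w2 = 0.6 + 0.4 * _unit_hash(f"{self.seed}|w2|{allele}")
        w9 = 0.6 + 0.4 * _unit_hash(f"{self.seed}|w9|{allele}")
        return w2, w9

    def score(self, peptide: str, allele: str) -> float:
        peptide = peptide.upper()
        if len(peptide) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {peptide!r}")
        if not set(peptide) <= set(AMINO_ACIDS):
            raise ValueError(f"non-canonical residue in peptide {peptide!r}")
        base = sum(
            _unit_hash(f"{self.seed}|{allele}|{j}|{peptide[j]}")
            for j in range(self.k)
            if j not in self._ANCHORS
        ) / (self.k - len(self._ANCHORS))
        w2, w9 = self._allele_weights(allele)
        anchor = (w2 * _HYDRO[peptide[1]] + w9 * _HYDRO[peptide[8]]) / (w2 + w9)
        return 0.5 * base + 0.5 * anchor

    def __call__(self, peptide: str, allele: str) -> BindingPrediction:
        s = self.score(peptide, allele)
        rank = 100.0 / (1.0 + math.exp(-self._STEEP * (self._MID - s)))
        ic50 = min(50000.0, max(1.01, 500.0 * (rank / 2.0) ** 1.661))
        stability = 8.0 * s**4
        return BindingPrediction(rank=rank, ic50=ic50, stability_hours=stability)


# ---------------------------------------------------------------------------
# On-disk cohort bundle (CLI `clonaltmb simulate`)


def write_cohort(
    outdir: str | Path,
    samples: Sequence[TumorSample],
    truth: GroundTruth,
    proteins: dict[str, str] | None = None,
    predictor: MockBindingPredictor | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort as plain-text tables.

    Emits mutations.tsv, sample_sheet.tsv, copy_number.tsv, purity.tsv,
    ground-truth TSVs and, when a proteome / predictor are supplied,
    proteins.fasta and predictions.tsv (every mutant and wild-type 9-mer
    of every missense mutation scored against the patient's alleles).
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .neoantigen import peptides_for_mutation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mut_df, sheet_df = cohort_to_frames(samples)
    paths["mutations"] = outdir / "mutations.tsv"
    mut_df.to_csv(paths["mutations"], sep="\t", index=False)
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    sheet_df.to_csv(paths["sample_sheet"], sep="\t", index=False)

    seg_rows = [
        {"sample": sid, "chrom": seg.chrom, "start": seg.start, "end": seg.end, "total_cn": seg.total_cn}
        for sid, segs in truth.segments.items()
        for seg in segs
    ]
    paths["copy_number"] = outdir / "copy_number.tsv"
    pd.DataFrame(seg_rows).to_csv(paths["copy_number"], sep="\t", index=False)
    paths["purity"] = outdir / "purity.tsv"
    pd.DataFrame(
        [{"sample": s.sample_id, "purity": s.purity} for s in samples]
    ).to_csv(paths["purity"], sep="\t", index=False)

    paths["truth_mutations"] = outdir / "truth_mutations.tsv"
    truth.mutations.to_csv(paths["truth_mutations"], sep="\t", index=False)
    paths["truth_samples"] = outdir / "truth_samples.tsv"
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)

    if proteins is not None:
        paths["proteins"] = outdir / "proteins.fasta"
        records = [
            SeqRecord(Seq(seq), id=gene, description="synthetic protein")
            for gene, seq in sorted(proteins.items())
        ]
        SeqIO.write(records, str(paths["proteins"]), "fasta")

    if proteins is not None and predictor is not None:
        rows = []
        seen: set[tuple[str, str]] = set()
        for sample in samples:
            for mut in sample.mutations:
                if mut.consequence != "missense" or mut.protein_pos is None:
                    continue
                for pair in peptides_for_mutation(mut, proteins):
                    for peptide in (pair.wt_peptide, pair.mut_peptide):
                        for allele in sample.hla_alleles:
                            if (peptide, allele) in seen:
                                continue
                            seen.add((peptide, allele))
                            pred = predictor(peptide, allele)
                            rows.append(
                                {
                                    "peptide": peptide,
                                    "allele": allele,
                                    "rank": pred.rank,
                                    "ic50": pred.ic50,
                                    "stability_hours": pred.stability_hours,
                                }
                            )
        paths["predictions"] = outdir / "predictions.tsv"
        pd.DataFrame(rows).to_csv(paths["predictions"], sep="\t", index=False)
    return paths
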