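"""Peptide enumeration, binder classification, DAI/stability, loads and
amino-acid/position enrichment."""

import numpy as np
import pandas as pd
import pytest

from clonaltmb.neoantigen import (
    BindingChange,
    BindingPrediction,
    PeptidePair,
    TablePredictor,
    aa_position_enrichment,
    binding_changes,
    classify_binder,
    classify_change,
    compute_dai,
    enumerate_peptides,
    high_dai,
    neoantigen_load,
    predict_binding,
    stability_filter,
)
from clonaltmb.synthetic_data import MockBindingPredictor

PROTEIN = "ACDEFGHIKLMNPQRSTVWY" * 5  # length 100


def brute_force_windows(L, i, k=9):
    """All k-length substrings of a length-L sequence covering residue i."""
    return [
        s for s in range(1, L - k + 2) if s <= i <= s + k - 1
    ]


class TestEnumerate:
    def test_mid_protein_gives_nine_windows(self):
        pairs = enumerate_peptides(PROTEIN, 50, PROTEIN[49], "A" if PROTEIN[49] != "A" else "C")
        assert len(pairs) == 9

    def test_first_residue_single_window(self):
        pairs = enumerate_peptides(PROTEIN, 1, PROTEIN[0], "W")
        assert len(pairs) == 1
        assert pairs[0].mut_index == 1

    def test_short_protein_no_windows(self):
        assert enumerate_peptides("ACDEFGHI", 4, "E", "K") == []

    def test_window_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for L in range(1, 31):
            seq = "".join(rng.choice(aa, size=L))
            for i in range(1, L + 1):
                ref = seq[i - 1]
                alt = "A" if ref != "A" else "C"
                pairs = enumerate_peptides(seq, i, ref, alt)
                assert len(pairs) == len(brute_force_windows(L, i))

    def test_pairs_differ_exactly_at_mut_index(self):
        pairs = enumerate_peptides(PROTEIN, 42, PROTEIN[41], "W")
        for pair in pairs:
            diffs = [
                j + 1
                for j, (a, b) in enumerate(zip(pair.wt_peptide, pair.mut_peptide))
                if a != b
            ]
            assert diffs == [pair.mut_index]
            assert pair.mut_peptide[pair.mut_index - 1] == "W"

    def test_reference_mismatch_names_gene_and_position(self):
        with pytest.raises(ValueError, match="MYGENE.*position 10"):
            enumerate_peptides(PROTEIN, 10, "W", "A", gene="MYGENE")


class TestClassifyBinder:
    @pytest.mark.parametrize(
        "rank,category", [(0.3, "SB"), (0.5, "WB"), (1.9, "WB"), (2.0, "NB"), (50.0, "NB")]
    )
    def test_rank_scheme_strict_cuts(self, rank, category):
        assert classify_binder(rank=rank) == category

    @pytest.mark.parametrize(
        "ic50,category", [(49.0, "SB"), (50.0, "WB"), (499.0, "WB"), (500.0, "NB")]
    )
    def test_ic50_scheme_strict_cuts(self, ic50, category):
        assert classify_binder(ic50=ic50, scheme="ic50") == category

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError):
            classify_binder(ic50=10.0, scheme="rank")


def call(peptide, allele, rank):
    return predict_binding([peptide], [allele], lambda p, a: BindingPrediction(rank, 100.0))[0]


class TestClassifyChange:
    def test_gain_loss_unchanged(self):
        wt_nb = call("A" * 9, "A*02:01", 5.0)
        mut_wb = call("C" + "A" * 8, "A*02:01", 1.0)
        assert classify_change(wt_nb, mut_wb).change == "gained"
        assert classify_change(mut_wb, wt_nb).change == "lost"
        mut_sb = call("D" + "A" * 8, "A*02:01", 0.3)
        assert classify_change(mut_wb, mut_sb).change == "unchanged_binder"
        wt_nb2 = call("E" + "A" * 8, "A*02:01", 9.0)
        assert classify_change(wt_nb, wt_nb2).change == "unchanged_nonbinder"

    def test_swap_symmetry(self):
        a = call("A" * 9, "B*07:02", 5.0)
        b = call("C" + "A" * 8, "B*07:02", 1.0)
        assert classify_change(a, b).change == "gained"
        assert classify_change(b, a).change == "lost"

    def test_allele_mismatch_rejected(self):
        a = call("A" * 9, "A*02:01", 5.0)
        b = call("C" + "A" * 8, "B*07:02", 1.0)
        with pytest.raises(ValueError, match="allele"):
            classify_change(a, b)


class TestDaiAndStability:
    def test_tenfold_improvement_flagged(self):
        dai = compute_dai(500, 50)
        assert dai == pytest.approx(10.0)
        assert high_dai(dai)

    def test_identity_not_flagged(self):
        assert compute_dai(120, 120) == pytest.approx(1.0)
        assert not high_dai(1.0)

    def test_worsened_binding(self):
        assert compute_dai(50, 500) == pytest.approx(0.1)

    def test_difference_mode(self):
        assert compute_dai(500, 50, mode="difference") == pytest.approx(450.0)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError):
            compute_dai(0.0, 50)

    @pytest.mark.parametrize("hours,stable", [(1.5, True), (0.2, False), (1.4, True)])
    def test_stability_boundary_inclusive(self, hours, stable):
        assert stability_filter(hours) is stable


class TestPredictBinding:
    def test_table_backend_counts(self):
        rows = [
            {"peptide": p, "allele": a, "rank": 1.0, "ic50": 100.0}
            for p in ("AAAAAAAAA", "CCCCCCCCC", "DDDDDDDDD")
            for a in ("A*02:01", "B*07:02")
        ]
        backend = TablePredictor(pd.DataFrame(rows))
        calls = predict_binding(
            ["AAAAAAAAA", "CCCCCCCCC", "DDDDDDDDD"], ["A*02:01", "B*07:02"], backend
        )
        assert len(calls) == 6

    def test_missing_pairs_listed(self):
        backend = TablePredictor(
            pd.DataFrame([{"peptide": "AAAAAAAAA", "allele": "A*02:01", "rank": 1, "ic50": 10}])
        )
        with pytest.raises(ValueError, match="B\\*07:02"):
            predict_binding(["AAAAAAAAA"], ["A*02:01", "B*07:02"], backend)

    def test_mock_backend_deterministic(self):
        pred = MockBindingPredictor(seed=3)
        calls1 = predict_binding(["ALYEWFPNA"], ["A*02:01"], pred)
        calls2 = predict_binding(["ALYEWFPNA"], ["A*02:01"], pred)
        assert calls1 == calls2


class ConstructedPredictor:
    """Predictor making exactly two chosen mutant windows weak binders."""

    def __init__(self, binders):
        self.binders = set(binders)

    def __call__(self, peptide, allele):
        rank = 1.0 if peptide in self.binders else 50.0
        return BindingPrediction(rank=rank, ic50=100.0)


class TestNeoantigenLoad:
    def test_constructed_two_binder_case(self, cohort_with_proteome):
        from clonaltmb.neoantigen import peptides_for_mutation
        from clonaltmb.tmb_stats import TumorSample
        from conftest import make_mut

        proteins = {"G1": PROTEIN}
        mut = make_mut(gene="G1", protein_pos=50, aa_ref=PROTEIN[49],
                       aa_alt="W" if PROTEIN[49] != "W" else "Y")
        pairs = peptides_for_mutation(mut, proteins)
        chosen = [pairs[0].mut_peptide, pairs[4].mut_peptide]
        sample = TumorSample(
            sample_id="s1", response="responder", mutations=[mut],
            hla_alleles=["A*02:01"],
        )
        load = neoantigen_load(sample, proteins, ConstructedPredictor(chosen))
        assert load == 2

    def test_no_binders_zero(self):
        from clonaltmb.tmb_stats import TumorSample
        from conftest import make_mut

        proteins = {"G1": PROTEIN}
        mut = make_mut(gene="G1", protein_pos=10, aa_ref=PROTEIN[9], aa_alt="A")
        sample = TumorSample(
            sample_id="s1", response="responder", mutations=[mut], hla_alleles=["A*02:01"]
        )
        assert neoantigen_load(sample, proteins, ConstructedPredictor([])) == 0

    def test_missing_hla_rejected(self):
        from clonaltmb.tmb_stats import TumorSample

        sample = TumorSample(sample_id="s1", response="responder", mutations=[])
        with pytest.raises(ValueError, match="HLA"):
            neoantigen_load(sample, {}, ConstructedPredictor([]))

    def test_clonal_subclonal_additivity(self, cohort_with_proteome):
        samples, _, proteins = cohort_with_proteome
        predictor = MockBindingPredictor(seed=7)
        for sample in samples[:2]:
            total = neoantigen_load(sample, proteins, predictor, subset="all")
            clonal = neoantigen_load(sample, proteins, predictor, subset="clonal")
            subclonal = neoantigen_load(sample, proteins, predictor, subset="subclonal")
            assert total == clonal + subclonal
            assert min(total, clonal, subclonal) >= 0


def make_change(mut_residue, position, change="gained"):
    wt = "A" * 9
    mut = wt[: position - 1] + mut_residue + wt[position:]
    pair = PeptidePair(gene="", protein_pos=1, wt_peptide=wt, mut_peptide=mut,
                       mut_index=position)
    return BindingChange(pair=pair, allele="A*02:01", change=change)


class TestAaPositionEnrichment:
    def test_constructed_signal_recovered(self):
        rng = np.random.default_rng(4)
        gains = [make_change("L", 9) for _ in range(30)]
        residues = [r for r in "CDEFGHIKMNPQRSTVWY"]
        unchanged = [
            make_change(str(rng.choice(residues)), int(rng.integers(1, 9)),
                        change="unchanged_nonbinder")
            for _ in range(200)
        ]
        table = aa_position_enrichment(gains, unchanged)
        aa_rows = table[table.feature_type == "amino_acid"].sort_values("q_value")
        pos_rows = table[table.feature_type == "position"].sort_values("q_value")
        assert aa_rows.iloc[0].feature == "L"
        assert pos_rows.iloc[0].feature == 9

    def test_null_calibration(self):
        """With changed/unchanged drawn from one distribution, raw one-sided
        Fisher p-values reject at no more than the nominal 5% level."""
        rng = np.random.default_rng(5)
        residues = list("CDEFGHIKLMNPQRSTVWY")  # wt scaffold is poly-A
        n_tests = 0
        n_reject = 0
        for _ in range(40):
            draws = [
                make_change(str(rng.choice(residues)), int(rng.integers(1, 10)))
                for _ in range(60)
            ]
            table = aa_position_enrichment(draws[:20], draws[20:])
            n_tests += len(table)
            n_reject += int((table.p_value < 0.05).sum())
        assert n_reject / n_tests <= 0.06

    def test_singleton_changed_set(self):
        unchanged = [make_change("G", 3, change="unchanged_nonbinder") for _ in range(5)]
        table = aa_position_enrichment([make_change("L", 9)], unchanged)
        assert len(table) == 29
        assert table.p_value.notna().all()

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            aa_position_enrichment([], [make_change("L", 9)])
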