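"""TMB flavors, the threshold ROC model, the VAF sweep and group tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from clonaltmb.tmb_stats import (
    TumorSample,
    compute_tmb,
    pooled_clonal_fraction_test,
    rank_test,
    recurrent_gene_clonality_test,
    threshold_classifier_curve,
    tmb_table,
    vaf_sweep_tmb_ratio,
)

from conftest import make_mut


def vaf_sample(sample_id, response, vafs, capture=50.0):
    muts = [
        make_mut(pos=i + 1, total_depth=1000, alt_depth=int(round(v * 1000)))
        for i, v in enumerate(vafs)
    ]
    return TumorSample(
        sample_id=sample_id, response=response, mutations=muts, capture_size_mb=capture
    )


class TestComputeTmb:
    def test_counts_per_megabase(self):
        muts = [make_mut(pos=i) for i in range(250)]
        assert compute_tmb(muts, capture_size_mb=50) == 5.0
        assert compute_tmb([], capture_size_mb=50) == 0.0

    def test_synonymous_excluded(self):
        muts = [make_mut(pos=1), make_mut(pos=2, consequence="synonymous")]
        assert compute_tmb(muts, capture_size_mb=1) == 1.0

    def test_invalid_capture(self):
        with pytest.raises(ValueError, match="capture"):
            compute_tmb([make_mut()], capture_size_mb=0)

    def test_additivity_on_cohort(self, small_cohort):
        samples, _, _ = small_cohort
        for s in samples:
            total = compute_tmb(s, subset="all")
            clonal = compute_tmb(s, subset="clonal")
            subclonal = compute_tmb(s, subset="subclonal")
            assert clonal + subclonal == pytest.approx(total, abs=1e-12)


def concordance_auc(tmb, labels):
    """Brute-force pairwise probability that a responder outranks a
    non-responder, ties counted 1/2."""
    pos = [t for t, l in zip(tmb, labels) if l]
    neg = [t for t, l in zip(tmb, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestThresholdCurve:
    def test_perfect_separation(self):
        curve = threshold_classifier_curve([10, 12, 1, 2], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)

    def test_no_discrimination(self):
        curve = threshold_classifier_curve([4, 4, 4, 4], [True, True, False, False])
        assert curve.auc == pytest.approx(0.5)

    def test_against_confusion_matrix_oracle(self):
        tmb = [5.0, 1.0, 3.0]
        labels = [True, True, False]
        curve = threshold_classifier_curve(tmb, labels, step=1.0)
        grid = np.arange(0.0, max(tmb) + 1.0 + 1e-12, 1.0)
        for (t, tpr, tnr), g in zip(curve.points, grid):
            pred = [x >= g for x in tmb]
            tp = sum(p and l for p, l in zip(pred, labels))
            fn = sum((not p) and l for p, l in zip(pred, labels))
            tn = sum((not p) and (not l) for p, l in zip(pred, labels))
            fp = sum(p and (not l) for p, l in zip(pred, labels))
            assert t == pytest.approx(g)
            assert tpr == pytest.approx(tp / (tp + fn))
            assert tnr == pytest.approx(tn / (tn + fp))
        # trapezoid over the anchored ROC of this grid
        roc = sorted(
            {(0.0, 0.0), (1.0, 1.0)}
            | {(1 - tnr, tpr) for _, tpr, tnr in curve.points}
        )
        xs, ys = zip(*roc)
        assert curve.auc == pytest.approx(np.trapezoid(ys, xs))

    def test_equals_concordance_when_grid_covers_values(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(4, 15))
            tmb = np.round(rng.uniform(0, 10, n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            curve = threshold_classifier_curve(tmb, labels, thresholds=np.unique(tmb))
            assert curve.auc == pytest.approx(concordance_auc(tmb, labels))

    def test_label_swap_aucs_sum_to_one(self):
        rng = np.random.default_rng(6)
        tmb = rng.uniform(0, 8, 12)
        labels = np.array([True] * 6 + [False] * 6)
        thresholds = np.unique(tmb)
        a = threshold_classifier_curve(tmb, labels, thresholds=thresholds).auc
        b = threshold_classifier_curve(tmb, ~labels, thresholds=thresholds).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            threshold_classifier_curve([1, 2], [True, True])


class TestVafSweep:
    def test_separating_vaf_cut(self):
        samples = [
            vaf_sample("r1", "responder", [0.5] * 10),
            vaf_sample("n1", "non_responder", [0.2] * 10),
        ]
        sweep = dict(vaf_sweep_tmb_ratio(samples))
        assert sweep[0.1] == pytest.approx(1.0)
        assert sweep[0.3] is None  # non-responder median TMB is 0

    def test_identical_cohorts_ratio_one(self):
        vafs = [0.2, 0.45, 0.75]
        samples = [
            vaf_sample("r1", "responder", vafs),
            vaf_sample("n1", "non_responder", vafs),
        ]
        for v, ratio in vaf_sweep_tmb_ratio(samples):
            assert ratio == pytest.approx(1.0)

    def test_double_burden_gives_ratio_two(self):
        vafs = [0.15, 0.3, 0.5, 0.7]
        samples = [
            vaf_sample("r1", "responder", vafs * 2),
            vaf_sample("n1", "non_responder", vafs),
        ]
        for v, ratio in vaf_sweep_tmb_ratio(samples):
            assert ratio == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        vafs_r = list(rng.uniform(0.05, 0.9, 20))
        vafs_n = list(rng.uniform(0.05, 0.9, 15))
        base = [
            vaf_sample("r1", "responder", vafs_r),
            vaf_sample("n1", "non_responder", vafs_n),
        ]
        tripled = [
            vaf_sample("r1", "responder", vafs_r * 3),
            vaf_sample("n1", "non_responder", vafs_n * 3),
        ]
        for (v1, r1), (v2, r2) in zip(vaf_sweep_tmb_ratio(base), vaf_sweep_tmb_ratio(tripled)):
            assert v1 == v2
            if r1 is None:
                assert r2 is None
            else:
                assert r2 == pytest.approx(r1)

    def test_empty_grid_rejected(self):
        samples = [
            vaf_sample("r1", "responder", [0.5]),
            vaf_sample("n1", "non_responder", [0.5]),
        ]
        with pytest.raises(ValueError):
            vaf_sweep_tmb_ratio(samples, vaf_grid=[])


def permutation_oracle(a, b):
    """Two-sided rank-sum p by exhaustive label permutation, scored on the
    Mann-Whitney U statistic (pairwise wins with ties counted 1/2)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in group_a for y in group_b
        )

    mu = n_a * len(b) / 2.0
    observed = abs(u_stat(a, b) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(grp_a, grp_b) - mu) >= observed - 1e-9:
            hits += 1
    return hits / total


class TestRankTest:
    def test_fully_separated_small_groups(self):
        assert rank_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_group_against_itself(self):
        assert rank_test([1, 5, 9], [1, 5, 9]) == 1.0

    def test_two_singletons(self):
        assert rank_test([1], [2]) == 1.0

    def test_all_identical(self):
        assert rank_test([3, 3], [3, 3, 3]) == 1.0

    def test_matches_permutation_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            # small integer support forces ties
            a = list(rng.integers(0, 5, n_a))
            b = list(rng.integers(0, 5, n_b))
            if len(set(a + b)) == 1:
                continue
            assert rank_test(a, b) == pytest.approx(permutation_oracle(a, b))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = rng.permutation(20)[:6].tolist()
            b = [x + 0.5 for x in rng.permutation(20)[:5]]
            expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert rank_test(a, b) == pytest.approx(float(expected))

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 25)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert rank_test(a, b) == pytest.approx(float(expected))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0])


def clonality_sample(sample_id, response, n_clonal, n_subclonal):
    from clonaltmb.clonality import ClonalityCall

    muts = [make_mut(pos=i + 1) for i in range(n_clonal + n_subclonal)]
    sample = TumorSample(sample_id=sample_id, response=response, mutations=muts)
    sample.clonality_calls = [
        ClonalityCall(key=m.key, ccf=1.0 if i < n_clonal else 0.3,
                      label="clonal" if i < n_clonal else "subclonal")
        for i, m in enumerate(muts)
    ]
    return sample


def fisher_oracle(table):
    """Two-sided Fisher p by summing hypergeometric point probabilities no
    larger than the observed table's."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    def pmf(x):
        return (
            math.comb(col1, x) * math.comb(n - col1, row1 - x) / math.comb(n, row1)
        )
    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if pmf(x) <= p_obs * (1 + 1e-9)
    )


class TestPooledClonalFraction:
    def test_no_association(self):
        samples = [
            clonality_sample("r1", "responder", 10, 10),
            clonality_sample("n1", "non_responder", 10, 10),
        ]
        result = pooled_clonal_fraction_test(samples)
        assert result.p_value == pytest.approx(1.0)
        assert result.fraction_R == result.fraction_NR == 0.5

    def test_matches_hypergeometric_oracle(self):
        samples = [
            clonality_sample("r1", "responder", 8, 2),
            clonality_sample("n1", "non_responder", 1, 5),
        ]
        result = pooled_clonal_fraction_test(samples)
        assert result.table == ((8, 2), (1, 5))
        assert result.p_value == pytest.approx(fisher_oracle(result.table))

    def test_enriched_responders_significant(self, small_cohort):
        samples, _, _ = small_cohort
        result = pooled_clonal_fraction_test(samples)
        assert result.fraction_R > result.fraction_NR
        assert result.p_value < 0.05

    def test_empty_group_rejected(self):
        samples = [
            clonality_sample("r1", "responder", 5, 5),
            clonality_sample("n1", "non_responder", 0, 0),
        ]
        with pytest.raises(ValueError):
            pooled_clonal_fraction_test(samples)


class TestRecurrentGeneClonality:
    def test_observed_excess_is_significant(self):
        result = recurrent_gene_clonality_test(73, 137, 0.28)
        assert result.p_value < 1e-4

    def test_exactly_at_expectation(self):
        result = recurrent_gene_clonality_test(50, 100, 0.5)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            recurrent_gene_clonality_test(10, 5, 0.5)
        with pytest.raises(ValueError):
            recurrent_gene_clonality_test(1, 5, 0.0)


def test_tmb_table_columns(small_cohort):
    samples, _, _ = small_cohort
    table = tmb_table(samples)
    assert set(table.columns) >= {"sample_id", "response", "tmb_total", "tmb_clonal", "tmb_subclonal"}
    np.testing.assert_allclose(
        table.tmb_clonal + table.tmb_subclonal, table.tmb_total, atol=1e-12
    )
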