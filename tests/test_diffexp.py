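from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from retorg.config import PipelineConfig
from retorg.datatypes import GeneList, ValidationError, normalize_fraction_umi
from retorg.diffexp import (
    NATIVE_GT_ORGANOID,
    ORGANOID_GT_NATIVE,
    adjust_fdr,
    bootstrap_mean_ci,
    cell_type_specifying,
    condition_contrast,
    rank_sum_test,
    tf_specificity,
)

from conftest import make_cell_table


def enumeration_rank_sum(a, b):
    """Independent oracle: two-sided rank-sum p by full enumeration of the
    C(n+m, n) assignments of the pooled midranks (tie-aware)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = len(a)
    ranks = rankdata(np.concatenate([a, b]))
    center = n * ranks.sum() / len(ranks)
    dev = abs(ranks[:n].sum() - center)
    hits = total = 0
    for combo in combinations(range(len(ranks)), n):
        total += 1
        if abs(sum(ranks[i] for i in combo) - center) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestRankSumTest:
    def test_separated_groups_exact_p(self):
        # 2 of the C(6,3) = 20 orderings are as extreme (two-sided)
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_identical_gives_one(self):
        assert rank_sum_test([5, 5, 5], [5, 5, 5]) == 1.0

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=6)
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a))

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_enumeration_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 8, size=2)
        # draws from a small integer alphabet force ties
        a = rng.integers(0, 4, size=n).astype(float)
        b = rng.integers(0, 4, size=m).astype(float)
        if np.all(np.concatenate([a, b]) == a[0]):
            return
        assert rank_sum_test(a, b) == pytest.approx(
            enumeration_rank_sum(a, b), abs=1e-9)


class TestAdjustFdr:
    def test_step_up_by_hand(self):
        # m=3: q3 = 0.03; q2 = min(0.02*3/2, q3) = 0.03; q1 = min(0.01*3, q2)
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.5])[0] == pytest.approx(0.5)

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_geq_p_and_order_invariance(self, ps):
        p = np.asarray(ps)
        q = adjust_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = adjust_fdr(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


@pytest.fixture(scope="module")
def de_dataset(synth_default):
    table, truth = synth_default
    native = table.condition == "native"
    sub = table.subset_cells(native)
    return table, truth, sub, normalize_fraction_umi(sub)


class TestCellTypeSpecifying:
    def test_planted_markers_detected(self, de_dataset, params):
        table, truth, sub, expr = de_dataset
        recs = cell_type_specifying(expr, sub.cell_type, params)
        found = {(r.gene, r.cell_type) for r in recs}
        hits = sum((g, t) in found for g, t in truth.marker_map.items())
        assert hits / len(truth.marker_map) >= 0.9

    def test_uniform_gene_excluded(self, params):
        counts = np.tile([4, 6], (30, 1))
        table = make_cell_table(counts, cell_type=["NE"] * 15 + ["RGC"] * 15)
        recs = cell_type_specifying(
            normalize_fraction_umi(table), table.cell_type, params)
        assert recs == []

    def test_thresholds_respected(self, de_dataset, params):
        _, _, sub, expr = de_dataset
        recs = cell_type_specifying(expr, sub.cell_type, params)
        assert all(r.log_fold_change >= params.logfc_min for r in recs)
        assert all(r.p_value <= params.p_max for r in recs)


class TestConditionContrast:
    def test_planted_perturbations_detected(self, synth_default, synth_expr,
                                            params):
        table, truth = synth_default
        contrasts = condition_contrast(
            synth_expr, table.cell_type, table.condition, params)
        detected = {(r.gene, r.cell_type): r.contrast
                    for lst in contrasts.values() for r in lst}
        ok = 0
        for gene, (ctype, direction, _) in truth.perturbation_map.items():
            want = ORGANOID_GT_NATIVE if direction == "up" else NATIVE_GT_ORGANOID
            ok += detected.get((gene, ctype)) == want
        assert ok / len(truth.perturbation_map) >= 0.8

    def test_label_swap_antisymmetry(self, params):
        rng = np.random.default_rng(6)
        counts = rng.poisson(5.0, size=(60, 15))
        counts[:30, 0] *= 4  # gene g0 higher in the first condition
        cond = np.array(["native"] * 30 + ["organoid"] * 30, dtype=object)
        table = make_cell_table(counts, condition=list(cond),
                                cell_type=["NE"] * 60)
        expr = normalize_fraction_umi(table)
        fwd = condition_contrast(expr, table.cell_type, cond, params)
        swapped = np.where(cond == "native", "organoid", "native")
        rev = condition_contrast(expr, table.cell_type, swapped, params)

        def key(recs):
            return sorted((r.gene, r.cell_type, round(r.p_value, 12))
                          for r in recs)

        assert key(fwd[NATIVE_GT_ORGANOID]) == key(rev[ORGANOID_GT_NATIVE])
        assert key(fwd[ORGANOID_GT_NATIVE]) == key(rev[NATIVE_GT_ORGANOID])

    def test_shuffled_labels_control_fdr(self, synth_default, synth_expr):
        table, _ = synth_default
        rng = np.random.default_rng(13)
        shuffled = rng.permutation(table.condition)
        cfg = PipelineConfig(rng_seed=0)
        contrasts = condition_contrast(
            synth_expr, table.cell_type, shuffled, cfg)
        n_hits = sum(len(v) for v in contrasts.values())
        n_families = len(set(table.cell_type)) * 2
        # BH at q <= 0.01 keeps the expected false fraction near zero
        assert n_hits <= max(5, n_families)


class TestTfSpecificity:
    def test_fold_ratios(self):
        counts = np.array(
            [[30, 15], [30, 15], [10, 12], [10, 12], [10, 12], [10, 12]])
        table = make_cell_table(
            counts, cell_type=["NE", "NE", "RGC", "RGC", "PRP", "PRP"])
        expr = normalize_fraction_umi(table)
        tfs = GeneList("tf", frozenset({"g0", "g1"}))
        ann = {a.gene: a for a in
               tf_specificity(expr, table.cell_type, tfs, fold=1.5)}
        # g0 fraction: 2/3 in NE vs 10/22 elsewhere -> fold 1.47, not flagged
        assert not ann["g0"].flagged
        assert ann["g0"].specificity_fold == pytest.approx(
            (30 / 45) / (10 / 22), rel=1e-6)

    def test_three_fold_marker_flagged(self):
        counts = np.array([[30, 70], [30, 70], [10, 90], [10, 90],
                           [10, 90], [10, 90]])
        table = make_cell_table(
            counts, cell_type=["NE", "NE", "RGC", "RGC", "PRP", "PRP"])
        ann = tf_specificity(
            normalize_fraction_umi(table), table.cell_type,
            GeneList("tf", frozenset({"g0"})), fold=1.5)
        assert ann[0].flagged and ann[0].top_type == "NE"
        assert ann[0].specificity_fold == pytest.approx(3.0, rel=1e-6)

    def test_planted_marker_tfs_flagged(self, de_dataset):
        table, truth, sub, expr = de_dataset
        marker_tfs = {g for g in truth.tf_genes if g in truth.marker_map}
        ann = tf_specificity(
            expr, sub.cell_type, GeneList("tf", frozenset(truth.tf_genes)))
        flagged = {a.gene for a in ann if a.flagged}
        assert len(marker_tfs & flagged) / len(marker_tfs) >= 0.9


class TestBootstrapMeanCi:
    def test_constant_sample_collapses(self):
        mean, lo, hi = bootstrap_mean_ci([3.0] * 10, seed=0)
        assert mean == lo == hi == 3.0

    def test_seed_contract(self):
        x = np.random.default_rng(1).normal(size=50)
        assert bootstrap_mean_ci(x, seed=7) == bootstrap_mean_ci(x, seed=7)

    def test_interval_brackets_mean(self):
        x = np.random.default_rng(2).normal(size=200)
        mean, lo, hi = bootstrap_mean_ci(x, seed=0)
        assert lo <= mean <= hi
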