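"""Weighted and presence-based enrichment: statistics, filters, pruning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutenrich.enrichment import (
    CHILD_PRUNED,
    FOLD_FILTERED,
    MIN_CONTIG_FILTERED,
    ContigRecord,
    ContingencyTable,
    EnrichmentConfig,
    EnrichmentResult,
    TermGroupStats,
    bh_adjust,
    build_contingency,
    fisher_exact_two_sided,
    fold_and_direction,
    prune_by_children,
    run_qualitative_enrichment,
    run_quantitative_enrichment,
    term_read_summary,
    term_stats,
)
from gutenrich.ontology import propagate_annotations
from gutenrich.synthdata import ContigSimConfig, simulate_contig_experiment, simulate_ontology

from conftest import A, B, C, D, bh_oracle, fisher_oracle


def stats(term="t", group="treated", n=1, reads=0, length=1, scale=1000.0):
    weight = scale * reads / length if length > 0 else 0.0
    return TermGroupStats(term=term, group=group, n_contigs=n, reads_sum=reads,
                          length_sum=length, weight=weight)


class TestTermStats:
    def contigs(self):
        return [
            ContigRecord("c1", "treated", 500, 10),
            ContigRecord("c2", "treated", 1500, 30),
            ContigRecord("c3", "control", 7000, 7),
        ]

    def test_weight_is_reads_per_kilobase(self, diamond):
        annotations = propagate_annotations({"c1": {D}, "c2": {D}, "c3": {D}}, diamond)
        result = term_stats(self.contigs(), annotations, D, "treated", scale=1000)
        assert (result.reads_sum, result.length_sum) == (40, 2000)
        assert result.weight == pytest.approx(20.0)

    def test_empty_term_is_all_zero(self, diamond):
        annotations = propagate_annotations({"c1": {B}}, diamond)
        result = term_stats(self.contigs(), annotations, C, "treated")
        assert (result.n_contigs, result.reads_sum, result.length_sum, result.weight) \
            == (0, 0, 0, 0.0)

    def test_single_contig(self, diamond):
        annotations = propagate_annotations({"c3": {C}}, diamond)
        result = term_stats(self.contigs(), annotations, C, "control", scale=1000)
        assert result.weight == pytest.approx(1.0)


class TestBuildContingency:
    def test_dataset_total_construction(self):
        table = build_contingency(stats(reads=20, length=1000),
                                  stats(group="control", reads=5, length=1000),
                                  total_treated=100.0, total_control=100.0)
        assert (table.a, table.b, table.c, table.d) == (20, 80, 5, 95)

    def test_empty_term(self):
        table = build_contingency(stats(n=0, reads=0, length=0),
                                  stats(group="control", n=0, reads=0, length=0),
                                  total_treated=50.0, total_control=50.0)
        assert (table.a, table.b, table.c, table.d) == (0, 50, 0, 50)

    @pytest.mark.parametrize("weight,expected", [(20.4, 20), (20.5, 20), (21.5, 22)])
    def test_round_half_even(self, weight, expected):
        table = build_contingency(stats(reads=int(weight * 10), length=10000),
                                  stats(group="control", reads=5, length=1000),
                                  total_treated=100.0, total_control=100.0)
        assert table.a == expected

    def test_negative_complement_clamped(self, caplog):
        table = build_contingency(stats(reads=150, length=1000),
                                  stats(group="control", reads=5, length=1000),
                                  total_treated=100.0, total_control=100.0)
        assert (table.a, table.b) == (150, 0)
        assert any("clamped" in r.message for r in caplog.records)

    def test_nonpositive_totals_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(stats(), stats(group="control"), 0.0, 10.0)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((3, 1, 1, 3), 34 / 70),          # enumeration over margins (4,4)/(4,4)
        ((2, 2, 2, 2), 1.0),              # identical proportions
        ((5, 0, 0, 5), 2 / 252),          # enumeration: only the two extremes qualify
    ])
    def test_enumeration_oracle_examples(self, table, expected):
        a, b, c, d = table
        assert fisher_oracle(a, b, c, d) == pytest.approx(expected, rel=1e-12)
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(expected, rel=1e-7)

    def test_degenerate_margins_give_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 0, 0, 0)) == 1.0
        assert fisher_exact_two_sided(ContingencyTable(3, 0, 5, 0)) == 1.0

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_enumeration_on_small_tables(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7)


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.005]) == pytest.approx([0.005])

    def test_hand_worked_step_up(self):
        # q(i) = min_{j >= i} p(j) * m / j applied by hand to the sorted
        # vector (0.005, 0.01, 0.03, 0.04), mapped back to input order
        assert bh_adjust([0.01, 0.04, 0.03, 0.005]) == pytest.approx(
            [0.02, 0.04, 0.04, 0.02])

    def test_clipped_at_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_oracle_and_invariants(self, pvals):
        q = bh_adjust(pvals)
        assert q == pytest.approx(bh_oracle(pvals), rel=1e-12, abs=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestFoldAndDirection:
    def test_fourfold_enrichment(self):
        fold, direction = fold_and_direction(
            stats(reads=20, length=1000), stats(group="control", reads=5, length=1000),
            100.0, 100.0)
        assert fold == pytest.approx(4.0)
        assert direction == "enriched"

    def test_equal_proportions_is_boundary(self):
        fold, direction = fold_and_direction(
            stats(reads=10, length=1000), stats(group="control", reads=10, length=1000),
            100.0, 100.0)
        assert fold == pytest.approx(1.0)

    def test_zero_control_gives_inf_sentinel(self):
        fold, direction = fold_and_direction(
            stats(reads=10, length=1000), stats(group="control", n=0, reads=0, length=0),
            100.0, 100.0)
        assert math.isinf(fold) and direction == "enriched"

    def test_both_zero_is_undefined(self):
        fold, _ = fold_and_direction(
            stats(n=0, reads=0, length=0), stats(group="control", n=0, reads=0, length=0),
            100.0, 100.0)
        assert math.isnan(fold)


def result(term, q, alpha=0.05):
    s = stats(term=term)
    return EnrichmentResult(term=term, name=term, namespace="", stats_control=s,
                            stats_treated=s, table=ContingencyTable(1, 1, 1, 1),
                            p=q, q=q)


class TestPruning:
    def test_significant_ancestor_of_significant_child_is_pruned(self, diamond):
        results = [result(A, 0.01), result(B, 0.01)]
        prune_by_children(results, diamond, alpha=0.05)
        assert CHILD_PRUNED in results[0].flags
        assert CHILD_PRUNED not in results[1].flags

    def test_ancestor_kept_when_child_not_significant(self, diamond):
        results = [result(A, 0.01), result(B, 0.50)]
        prune_by_children(results, diamond, alpha=0.05)
        assert CHILD_PRUNED not in results[0].flags

    def test_only_leaf_significant_leaves_diamond_untouched(self, diamond):
        results = [result(t, 0.50) for t in (A, B, C)] + [result(D, 0.01)]
        prune_by_children(results, diamond, alpha=0.05)
        assert all(CHILD_PRUNED not in r.flags for r in results)

    def test_unknown_term_kept_with_warning(self, diamond, caplog):
        results = [result("GO:zzz", 0.01)]
        prune_by_children(results, diamond, alpha=0.05)
        assert CHILD_PRUNED not in results[0].flags
        assert any("GO:zzz" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(30))
    def test_reported_set_is_an_antichain(self, seed):
        rng = np.random.default_rng(seed)
        ontology = simulate_ontology(40, seed=seed)
        results = [result(t, float(rng.uniform(0, 0.12))) for t in ontology.terms]
        prune_by_children(results, ontology, alpha=0.05)
        reported = {r.term for r in results if r.reported(0.05)}
        for term in reported:
            assert not (ontology.descendants(term) & reported)


def simulated(seed=0, **kwargs):
    ontology = simulate_ontology(kwargs.pop("n_terms", 40), seed=seed)
    config = ContigSimConfig.tiny(seed=seed, **kwargs)
    contigs, direct, truth = simulate_contig_experiment(config, ontology)
    annotations = propagate_annotations(direct, ontology)
    return ontology, contigs, annotations, truth


class TestQuantitativeRun:
    def test_spiked_term_reported_enriched(self):
        ontology, contigs, annotations, truth = simulated(
            seed=3, n_spiked=1, spike_fold=5.0,
            spiked=None)
        results = run_quantitative_enrichment(contigs, annotations, ontology)
        spiked = truth.term.iloc[0]
        by_term = {r.term: r for r in results}
        assert by_term[spiked].reported(0.05)
        assert by_term[spiked].direction == "enriched"

    def test_label_swap_inverts_direction_not_p(self):
        ontology, contigs, annotations, _ = simulated(seed=5, n_spiked=2)
        swapped = [ContigRecord(c.id, "treated" if c.group == "control" else "control",
                                c.length, c.reads) for c in contigs]
        res = {r.term: r for r in run_quantitative_enrichment(contigs, annotations, ontology)}
        res_swapped = {r.term: r
                       for r in run_quantitative_enrichment(swapped, annotations, ontology)}
        assert set(res) == set(res_swapped)
        for term in res:
            assert res[term].p == pytest.approx(res_swapped[term].p, rel=1e-12)
            assert res[term].q == pytest.approx(res_swapped[term].q, rel=1e-12)
            if res[term].direction and not math.isinf(res[term].fold) \
                    and res[term].fold != 1.0:
                assert res[term].direction != res_swapped[term].direction

    def test_single_group_rejected(self, diamond):
        contigs = [ContigRecord("c1", "treated", 100, 10)]
        annotations = propagate_annotations({"c1": {D}}, diamond)
        with pytest.raises(ValueError, match="group"):
            run_quantitative_enrichment(contigs, annotations, diamond)

    def test_deterministic(self):
        ontology, contigs, annotations, _ = simulated(seed=7, n_spiked=2)
        first = run_quantitative_enrichment(contigs, annotations, ontology)
        second = run_quantitative_enrichment(contigs, annotations, ontology)
        assert [(r.term, r.p, r.q, r.fold, tuple(sorted(r.flags))) for r in first] \
            == [(r.term, r.p, r.q, r.fold, tuple(sorted(r.flags))) for r in second]


class TestQualitativeRun:
    def contigs_with(self, n_annotated_treated, n_annotated_control, n_per_group=100):
        contigs, direct = [], {}
        for group, n_annot in (("treated", n_annotated_treated),
                               ("control", n_annotated_control)):
            for i in range(n_per_group):
                cid = f"{group[0]}{i}"
                contigs.append(ContigRecord(cid, group, 500, 10))
                direct[cid] = frozenset([D] if i < n_annot else [B])
        return contigs, direct

    def test_identical_proportions_not_reported(self, diamond):
        contigs, direct = self.contigs_with(10, 10)
        annotations = propagate_annotations(direct, diamond)
        results = {r.term: r for r in run_qualitative_enrichment(contigs, annotations, diamond)}
        assert results[D].p == pytest.approx(1.0)
        assert not results[D].reported(0.05)

    def test_imbalanced_term_reported_with_oracle_p(self, diamond):
        contigs, direct = self.contigs_with(30, 2)
        annotations = propagate_annotations(direct, diamond)
        results = {r.term: r for r in run_qualitative_enrichment(contigs, annotations, diamond)}
        assert results[D].p == pytest.approx(fisher_oracle(30, 70, 2, 98), rel=1e-7)
        assert results[D].reported(0.05)
        assert results[D].direction == "enriched"

    def test_singleton_term_flagged(self, diamond):
        contigs, direct = self.contigs_with(1, 0)
        annotations = propagate_annotations(direct, diamond)
        results = {r.term: r for r in run_qualitative_enrichment(contigs, annotations, diamond)}
        assert MIN_CONTIG_FILTERED in results[D].flags


class TestTermReadSummary:
    def test_treated_only_term(self, diamond):
        contigs = [ContigRecord("t1", "treated", 500, 25),
                   ContigRecord("c1", "control", 500, 30)]
        annotations = propagate_annotations({"t1": {C}, "c1": {B}}, diamond)
        frame = term_read_summary(contigs, annotations, terms=[C])
        row = frame.iloc[0]
        assert row.reads_control == 0 and row.reads_treated == 25

    def test_empty_selection(self, diamond):
        frame = term_read_summary([], propagate_annotations({}, diamond), terms=[])
        assert frame.empty

    def test_keyword_selection_by_name(self, diamond):
        contigs = [ContigRecord("t1", "treated", 500, 25),
                   ContigRecord("c1", "control", 500, 30)]
        annotations = propagate_annotations({"t1": {C}, "c1": {B}}, diamond)
        frame = term_read_summary(contigs, annotations, keyword="right", ontology=diamond)
        assert list(frame.term) == [C]

    def test_read_conservation_with_single_labels(self, diamond):
        # one direct annotation per contig and no propagation: summed term
        # reads equal each group's total annotated reads
        contigs = [ContigRecord(f"x{i}", "treated", 400, 5 + i) for i in range(4)]
        contigs += [ContigRecord(f"y{i}", "control", 400, 3 + i) for i in range(3)]
        direct = {c.id: frozenset([B if i % 2 else C])
                  for i, c in enumerate(contigs)}
        annotations = propagate_annotations(direct, diamond)
        frame = term_read_summary(contigs, annotations, propagated=False)
        assert frame.reads_treated.sum() == sum(5 + i for i in range(4))
        assert frame.reads_control.sum() == sum(3 + i for i in range(3))


class TestConfigValidation:
    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(alpha=1.5)

    def test_bad_scale(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(scale=0)

    def test_fold_filter_on_boundary(self, diamond):
        # equal weights in both groups -> fold exactly 1 -> filtered
        contigs = [ContigRecord("t1", "treated", 1000, 10),
                   ContigRecord("c1", "control", 1000, 10)]
        annotations = propagate_annotations({"t1": {D}, "c1": {D}}, diamond)
        config = EnrichmentConfig(score_threshold=None)
        results = {r.term: r
                   for r in run_quantitative_enrichment(contigs, annotations, diamond, config)}
        assert FOLD_FILTERED in results[D].flags
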