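"""Aggregation of experiments into DTRIs, summaries, and the literature
extrapolation. Summary cells are cross-checked against naive brute-force
filtering of the same records."""

from __future__ import annotations

import math
from collections import Counter

import pytest

from conftest import gene, make_record
from dtrikit.aggregate import (
    ContextCategory,
    ModeSummary,
    SpeciesSupport,
    TfbsSummary,
    aggregate_dtris,
    estimate_remaining,
    resolve_context,
    resolve_mode,
    resolve_species_support,
    resolve_tfbs_class,
    summarize,
)
from dtrikit.records import ExperimentType, Mode, Species, ContextType


class TestAggregateDtris:
    def test_three_types_one_pair_collapse_to_single_dtri(self, dag):
        records = [
            make_record("E1", experiment_type=ExperimentType.PERTURBATION),
            make_record("E2", experiment_type=ExperimentType.BINDING),
            make_record("E3", experiment_type=ExperimentType.REPORTER),
        ]
        dtris = aggregate_dtris(records, dag)
        assert len(dtris) == 1
        assert dtris[0].evidence_types == frozenset(ExperimentType)
        assert dtris[0].n_experiments == 3

    def test_mouse_and_human_records_merge_on_human_pair(self, dag):
        records = [
            make_record("E1", tf=gene(5080), target=gene(429)),
            make_record(
                "E2",
                tf=gene(18505, Species.MOUSE),
                target=gene(11878, Species.MOUSE),
            ),
        ]
        dtris = aggregate_dtris(records, dag)
        assert len(dtris) == 1
        assert dtris[0].tf_human_entrez == 5080
        assert dtris[0].species_support is SpeciesSupport.BOTH

    def test_empty_input_gives_empty_output(self, dag):
        assert aggregate_dtris([], dag) == []

    def test_order_invariant_and_sorted(self, dag):
        records = [
            make_record("E1", tf=gene(2), target=gene(3)),
            make_record("E2", tf=gene(1), target=gene(9)),
            make_record("E3", tf=gene(1), target=gene(4)),
        ]
        forward = aggregate_dtris(records, dag)
        backward = aggregate_dtris(records[::-1], dag)
        assert forward == backward
        assert [(d.tf_human_entrez, d.target_human_entrez) for d in forward] == [
            (1, 4), (1, 9), (2, 3),
        ]

    def test_adding_record_grows_monotonically(self, dag):
        base = [make_record("E1", experiment_type=ExperimentType.BINDING)]
        more = base + [make_record("E2", experiment_type=ExperimentType.REPORTER)]
        d1, = aggregate_dtris(base, dag)
        d2, = aggregate_dtris(more, dag)
        assert d1.evidence_types <= d2.evidence_types
        assert d2.n_experiments == d1.n_experiments + 1


class TestResolvers:
    def test_species_support_cases(self):
        human = make_record("E1")
        mouse = make_record(
            "E2", tf=gene(18505, Species.MOUSE), target=gene(11878, Species.MOUSE)
        )
        mixed = make_record(
            "E3", tf=gene(18505, Species.MOUSE), target=gene(429)
        )
        assert resolve_species_support([human]) is SpeciesSupport.HUMAN_ONLY
        assert resolve_species_support([mouse]) is SpeciesSupport.MOUSE_ONLY
        assert resolve_species_support([human, mouse]) is SpeciesSupport.BOTH
        assert resolve_species_support([mixed]) is SpeciesSupport.MIXED_ONLY
        assert resolve_species_support([human, mixed]) is SpeciesSupport.HUMAN_ONLY

    def test_mode_cases(self):
        act = make_record("E1", mode=Mode.ACTIVATION)
        rep = make_record("E2", mode=Mode.REPRESSION)
        unr = make_record("E3", mode=Mode.UNREPORTED)
        assert resolve_mode([act, unr]) is ModeSummary.ACTIVATION
        assert resolve_mode([act, rep]) is ModeSummary.BOTH
        assert resolve_mode([unr]) is ModeSummary.UNREPORTED
        assert resolve_mode([rep, unr]) is ModeSummary.REPRESSION

    def test_tfbs_union_semantics(self):
        prox = make_record("E1", tfbs_offset_bp=-100)
        dist = make_record("E2", tfbs_offset_bp=9000)
        unr = make_record("E3")
        assert resolve_tfbs_class([prox, unr]) is TfbsSummary.PROXIMAL
        assert resolve_tfbs_class([prox, dist]) is TfbsSummary.BOTH
        assert resolve_tfbs_class([unr]) is TfbsSummary.UNREPORTED

    def test_context_descendant_rule(self, dag):
        cns = make_record(
            "E1",
            context_type=ContextType.PRIMARY,
            context_term="UBERON:0001890",  # forebrain, grandchild of CNS root
            developmental_stage="E12.5",
        )
        category, any_primary, any_cns, any_emb = resolve_context([cns], dag)
        assert category is ContextCategory.CNS
        assert any_primary and any_cns and any_emb

    def test_cns_precedence_over_eye(self, dag):
        cns = make_record(
            "E1", context_type=ContextType.PRIMARY, context_term="UBERON:0000955"
        )
        eye = make_record(
            "E2", context_type=ContextType.PRIMARY, context_term="UBERON:0000966"
        )
        category, *_ = resolve_context([cns, eye], dag)
        assert category is ContextCategory.CNS
        category, *_ = resolve_context([eye], dag)
        assert category is ContextCategory.EYE

    def test_cell_line_never_counts_as_cns(self, dag):
        # a neural cell line term that happens to be in the DAG's CNS branch
        neural_line = make_record(
            "E1", context_type=ContextType.CELL_LINE, context_term="UBERON:0000955"
        )
        category, any_primary, any_cns, any_emb = resolve_context([neural_line], dag)
        assert category is ContextCategory.OTHER
        assert not any_primary and not any_cns and not any_emb

    def test_adult_cns_not_embryonic(self, dag):
        adult = make_record(
            "E1",
            context_type=ContextType.PRIMARY,
            context_term="UBERON:0000955",
            developmental_stage="adult",
        )
        *_, any_emb = resolve_context([adult], dag)
        assert not any_emb


class TestSummarize:
    def _records(self):
        # TF 1 -> targets 10 (triple evidence, CNS), 11 (binding only, proximal)
        # TF 2 -> target 10 (perturbation+reporter, repressive, distal)
        return [
            make_record("E1", 201, gene(1), gene(10), ExperimentType.PERTURBATION,
                        context_type=ContextType.PRIMARY,
                        context_term="UBERON:0001890",
                        developmental_stage="E13.5"),
            make_record("E2", 201, gene(1), gene(10), ExperimentType.BINDING),
            make_record("E3", 202, gene(1), gene(10), ExperimentType.REPORTER),
            make_record("E4", 202, gene(1), gene(11), ExperimentType.BINDING,
                        tfbs_offset_bp=-500),
            make_record("E5", 203, gene(2), gene(10), ExperimentType.PERTURBATION,
                        mode=Mode.REPRESSION),
            make_record("E6", 203, gene(2), gene(10), ExperimentType.REPORTER,
                        mode=Mode.REPRESSION, tfbs_offset_bp=4000),
        ]

    def test_summary_matches_brute_force(self, dag):
        records = self._records()
        dtris = aggregate_dtris(records, dag)
        summary = summarize(dtris, records, n_papers_examined=5)

        assert summary.n_dtris == 3
        assert summary.n_tfs == 2
        assert summary.n_targets == 2
        assert summary.n_multi_evidence == 2  # (1,10) triple and (2,10) double
        assert summary.n_triple_evidence == 1
        assert summary.n_triple_cns == 1
        assert summary.n_with_proximal == 1
        assert summary.n_with_distal == 1
        assert summary.n_position_annotated == 2
        assert summary.n_mode_reported == 3
        assert summary.n_repressive == 1
        assert summary.n_negative_papers == 5 - summary.n_papers_with_dtri

        # brute-force re-derivation of every cross-tab cell
        combos = Counter()
        for d in dtris:
            label = "+".join(
                t.value
                for t in [ExperimentType.PERTURBATION, ExperimentType.BINDING,
                          ExperimentType.REPORTER]
                if t in d.evidence_types
            )
            combos[(label, d.context_category.value)] += 1
        assert summary.evidence_by_context == dict(combos)
        assert sum(summary.evidence_by_context.values()) == summary.n_dtris
        assert sum(summary.per_tf_target_counts.values()) == summary.n_dtris

    def test_mean_dtris_per_positive_paper(self, dag):
        # paper 201 reports 2 DTRIs (via E1 on pair 1-10 and ... ) -- construct
        # two papers reporting 1 and 3 DTRIs: mean 2.0
        records = [
            make_record("A1", 301, gene(1), gene(10)),
            make_record("A2", 302, gene(1), gene(11)),
            make_record("A3", 302, gene(1), gene(12)),
            make_record("A4", 302, gene(2), gene(10)),
        ]
        dtris = aggregate_dtris(records, dag)
        summary = summarize(dtris, records)
        assert summary.per_paper_dtri_counts == {301: 1, 302: 3}
        assert summary.mean_dtris_per_positive_paper == pytest.approx(2.0)

    def test_summary_json_serializes(self, dag):
        records = self._records()
        summary = summarize(aggregate_dtris(records, dag), records)
        import json

        payload = json.loads(summary.to_json())
        assert payload["totals"]["n_dtris"] == 3


class TestEstimateRemaining:
    def test_study_scale_projection_exceeds_printed_bounds(self):
        est = estimate_remaining(1310, 828, 20043, 1.9, 0.27, 0.03, n_current_cns=44)
        assert est.positive_rate == pytest.approx(828 / 1310)
        assert est.projected_positive_papers > 12_000
        assert est.projected_dtris > 22_000
        assert est.projected_triple_evidence_dtris > 6_000
        assert est.projected_cns_dtris > 600
        assert 0.05 < est.captured_fraction_cns < 0.08  # printed as "up to 7%"

    def test_simple_arithmetic(self):
        est = estimate_remaining(100, 50, 200, 2.0, 0.5, 0.1)
        assert est.projected_positive_papers == pytest.approx(100.0)
        assert est.projected_dtris == pytest.approx(200.0)
        assert est.projected_triple_evidence_dtris == pytest.approx(100.0)
        assert est.projected_cns_dtris == pytest.approx(20.0)

    def test_no_remaining_candidates_projects_zero(self):
        est = estimate_remaining(100, 50, 0, 2.0, 0.3, 0.1)
        assert est.projected_dtris == 0.0
        assert est.projected_positive_papers == 0.0

    def test_identity_projected_dtris(self):
        est = estimate_remaining(977, 500, 3000, 1.7, 0.2, 0.05)
        assert est.projected_dtris == pytest.approx(
            est.projected_positive_papers * est.mean_dtris_per_positive_paper
        )

    def test_zero_examined_is_error(self):
        with pytest.raises(ValueError):
            estimate_remaining(0, 0, 10, 1.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            estimate_remaining(10, 11, 10, 1.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            estimate_remaining(10, 5, 10, 1.0, 1.5, 0.1)
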