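"""Shared fixtures: a toy homology table, a toy ontology DAG, and a record
factory covering all three experiment types."""

from __future__ import annotations

import pytest

from dtrikit.ontology import CNS_ROOT, EYE_ROOT, OntologyDag
from dtrikit.records import (
    BindingDetail,
    BindingMethod,
    ContextType,
    EmsaProteinSource,
    ExperimentRecord,
    ExperimentType,
    GeneRef,
    HomologyTable,
    Mode,
    PerturbationDetail,
    PerturbationDirection,
    PerturbationTiming,
    ReporterDetail,
    Species,
    Zygosity,
    to_human_ortholog,
)

# toy homology: two mapped mouse genes, one unmapped (18508)
TOY_HOMOLOGY = {
    (Species.MOUSE, 18505): 5080,  # Pax6 -> PAX6
    (Species.MOUSE, 11878): 429,  # Ascl1 -> ASCL1
}


@pytest.fixture
def homology() -> HomologyTable:
    return HomologyTable(mapping=dict(TOY_HOMOLOGY), provenance="toy")


@pytest.fixture
def dag() -> OntologyDag:
    return OntologyDag.from_edges(
        [
            ("UBERON:0000955", CNS_ROOT),  # brain
            ("UBERON:0001890", "UBERON:0000955"),  # forebrain
            ("UBERON:0000966", EYE_ROOT),  # retina
            ("UBERON:0002107", "UBERON:0000061"),  # liver
            (CNS_ROOT, "UBERON:0000061"),
            (EYE_ROOT, "UBERON:0000061"),
        ]
    )


def gene(entrez: int, species: Species = Species.HUMAN, symbol: str = "G") -> GeneRef:
    g = GeneRef(entrez_id=entrez, symbol=symbol, species=species)
    return to_human_ortholog(g, HomologyTable(mapping=dict(TOY_HOMOLOGY)))


def make_record(
    experiment_id: str = "E1",
    pubmed_id: int = 100,
    tf: GeneRef | None = None,
    target: GeneRef | None = None,
    experiment_type: ExperimentType = ExperimentType.PERTURBATION,
    context_type: ContextType = ContextType.CELL_LINE,
    context_term: str = "CLO:0000031",
    developmental_stage: str | None = None,
    mode: Mode = Mode.ACTIVATION,
    tfbs_offset_bp: int | None = None,
    is_promoter: bool | None = None,
    binding_method: BindingMethod = BindingMethod.CHIP,
) -> ExperimentRecord:
    tf = tf if tf is not None else gene(5080)
    target = target if target is not None else gene(429)
    perturbation = binding = reporter = None
    if experiment_type is ExperimentType.PERTURBATION:
        perturbation = PerturbationDetail(
            direction=PerturbationDirection.KNOCKOUT,
            timing=PerturbationTiming.CONSTITUTIVE,
            zygosity=Zygosity.HOMOZYGOUS,
        )
    elif experiment_type is ExperimentType.BINDING:
        binding = BindingDetail(
            method=binding_method,
            emsa_protein_source=(
                EmsaProteinSource.RECOMBINANT
                if binding_method is BindingMethod.EMSA
                else None
            ),
        )
        if binding_method is BindingMethod.EMSA:
            context_type = ContextType.IN_VITRO
    else:
        reporter = ReporterDetail(cre_mutated=False)
    return ExperimentRecord(
        experiment_id=experiment_id,
        pubmed_id=pubmed_id,
        tf=tf,
        target=target,
        experiment_type=experiment_type,
        context_type=context_type,
        context_term=context_term,
        developmental_stage=developmental_stage,
        mode=mode,
        tfbs_offset_bp=tfbs_offset_bp,
        is_promoter=is_promoter,
        perturbation_detail=perturbation,
        binding_detail=binding,
        reporter_detail=reporter,
    )


THREE_ROW_TABLE = "\t".join(
    [
        "experiment_id", "pubmed_id", "tf_symbol", "tf_entrez", "tf_species",
        "target_symbol", "target_entrez", "target_species", "experiment_type",
        "context_type", "context_term", "developmental_stage", "mode",
        "tfbs_offset_bp", "is_promoter", "perturbation_direction",
        "perturbation_timing", "zygosity", "binding_method",
        "emsa_protein_source", "reporter_cre_mutated", "mutation_binding_verified",
    ]
) + "\n" + "\n".join(
    [
        # one record per experiment type, PAX6 -> NEUROG2-style pair
        "E1\t101\tPAX6\t5080\thuman\tNEUROG2\t63973\thuman\tperturbation\t"
        "primary\tUBERON:0001890\tE12.5\tactivation\tNA\tNA\tknockout\t"
        "constitutive\thomozygous\tNA\tNA\tNA\tNA",
        "E2\t101\tPAX6\t5080\thuman\tNEUROG2\t63973\thuman\tbinding\t"
        "in_vitro\tfreetext:nuclear extract\tNA\tNA\t-1500\tNA\tNA\tNA\tNA\t"
        "emsa\trecombinant\tNA\tNA",
        "E3\t102\tPax6\t18505\tmouse\tAscl1\t11878\tmouse\treporter\t"
        "cell_line\tCLO:0000031\tNA\trepression\tNA\ttrue\tNA\tNA\tNA\tNA\tNA\t"
        "true\tfalse",
    ]
) + "\n"


@pytest.fixture
def three_row_table() -> str:
    return THREE_ROW_TABLE
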