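"""Collapse experiment records into unique DTRIs and summarize the evidence.

An independent regulatory interaction (DTRI) is a unique combination of the
human-ortholog TF and target genes. All experiments for a pair are pooled:
evidence types take union semantics, the mode of regulation and TFBS
position are resolved to activation/repression/both and proximal/distal/
both, species support distinguishes human-only, mouse-only, both, and
pairs supported only by cross-species ("mixed") experiments, and the
cellular context is stratified by anatomical system via ontology descendant
queries (CNS taking precedence over eye so the categories are mutually
exclusive).

The module also provides the literature extrapolation: from the fraction of
examined candidate papers containing at least one interaction and the mean
number of interactions per positive paper, project how many interactions
remain uncurated in the candidate corpus.
"""

from __future__ import annotations

import enum
import json
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .ontology import CNS_ROOT, EYE_ROOT, OntologyDag
from .records import (
    ContextType,
    ExperimentRecord,
    ExperimentType,
    Mode,
    Species,
    TfbsClass,
    classify_tfbs,
)

__all__ = [
    "SpeciesSupport",
    "ModeSummary",
    "TfbsSummary",
    "ContextCategory",
    "DTRI",
    "CurationSummary",
    "LiteratureEstimate",
    "aggregate_dtris",
    "resolve_species_support",
    "resolve_mode",
    "resolve_tfbs_class",
    "resolve_context",
    "summarize",
    "estimate_remaining",
    "write_dtri_table",
    "read_dtri_table",
    "DEFAULT_EMBRYONIC_PATTERNS",
]


class SpeciesSupport(str, enum.Enum):
    HUMAN_ONLY = "human_only"
    MOUSE_ONLY = "mouse_only"
    BOTH = "both"
    MIXED_ONLY = "mixed_only"


class ModeSummary(str, enum.Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    BOTH = "both"
    UNREPORTED = "unreported"


class TfbsSummary(str, enum.Enum):
    PROXIMAL = "proximal"
    DISTAL = "distal"
    BOTH = "both"
    UNREPORTED = "unreported"


class ContextCategory(str, enum.Enum):
    CNS = "CNS"
    EYE = "eye"
    OTHER = "other"


#: Developmental-stage labels treated as embryonic: murine E-day notation
#: ("E12.5"), and labels mentioning embryonic or fetal material.
DEFAULT_EMBRYONIC_PATTERNS = (r"^[Ee]\d", r"embryo", r"fetal")


@dataclass(frozen=True)
class DTRI:
    """A unique human-ortholog TF -> target pair with aggregated evidence."""

    tf_human_entrez: int
    target_human_entrez: int
    evidence_types: frozenset[ExperimentType]
    n_experiments: int
    species_support: SpeciesSupport
    mode: ModeSummary
    tfbs_class: TfbsSummary
    context_category: ContextCategory
    any_primary: bool
    any_cns: bool
    any_embryonic_cns: bool
    pubmed_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.evidence_types:
            raise ValueError("evidence_types must be nonempty")
        if self.n_experiments < len(self.evidence_types):
            raise ValueError("n_experiments smaller than the number of evidence types")


def resolve_species_support(records: Sequence[ExperimentRecord]) -> SpeciesSupport:
    """Species support for one gene pair.

    Only same-species experiments count toward a species; experiments whose
    TF and target genes come from different species (possible in
    overexpression and EMSA designs) are "mixed" and count toward neither.
    """
    if not records:
        raise ValueError("records must be nonempty")
    has_human = has_mouse = False
    for r in records:
        if r.tf.species is not r.target.species:
            continue
        if r.tf.species is Species.HUMAN:
            has_human = True
        else:
            has_mouse = True
    if has_human and has_mouse:
        return SpeciesSupport.BOTH
    if has_human:
        return SpeciesSupport.HUMAN_ONLY
    if has_mouse:
        return SpeciesSupport.MOUSE_ONLY
    return SpeciesSupport.MIXED_ONLY


def resolve_mode(records: Sequence[ExperimentRecord]) -> ModeSummary:
    """Mode of regulation for one pair; unreported experiments are ignored
    unless no experiment reports a mode."""
    if not records:
        raise ValueError("records must be nonempty")
    modes = {r.mode for r in records if r.mode is not Mode.UNREPORTED}
    if not modes:
        return ModeSummary.UNREPORTED
    if modes == {Mode.ACTIVATION}:
        return ModeSummary.ACTIVATION
    if modes == {Mode.REPRESSION}:
        return ModeSummary.REPRESSION
    return ModeSummary.BOTH


def resolve_tfbs_class(
    records: Sequence[ExperimentRecord], threshold_bp: int = 2000
) -> TfbsSummary:
    """TFBS position class for one pair, with union semantics: "both" when
    proximal and distal elements co-occur across experiments."""
    if not records:
        raise ValueError("records must be nonempty")
    classes = {
        classify_tfbs(r.tfbs_offset_bp, r.is_promoter, threshold_bp) for r in records
    }
    classes.discard(TfbsClass.UNREPORTED)
    if not classes:
        return TfbsSummary.UNREPORTED
    if classes == {TfbsClass.PROXIMAL}:
        return TfbsSummary.PROXIMAL
    if classes == {TfbsClass.DISTAL}:
        return TfbsSummary.DISTAL
    return TfbsSummary.BOTH


def _is_embryonic(stage: str | None, patterns: Sequence[str]) -> bool:
    if not stage:
        return False
    return any(re.search(p, stage, flags=re.IGNORECASE) for p in patterns)


def resolve_context(
    records: Sequence[ExperimentRecord],
    dag: OntologyDag,
    cns_root: str = CNS_ROOT,
    eye_root: str = EYE_ROOT,
    embryonic_patterns: Sequence[str] = DEFAULT_EMBRYONIC_PATTERNS,
) -> tuple[ContextCategory, bool, bool, bool]:
    """Context summary (category, any_primary, any_cns, any_embryonic_cns).

    "Tested directly in the CNS" requires a primary-tissue/cell experiment
    whose context term is the CNS root or a descendant; CNS-derived cell
    lines do not qualify. Pairs with both CNS and eye evidence are placed
    only in the CNS category so the categories are mutually exclusive.
    Ontology terms absent from the DAG (including freetext fallbacks) are
    treated as non-matching.
    """
    cns_terms = dag.descendants(cns_root)
    eye_terms = dag.descendants(eye_root)
    any_primary = any_cns = any_eye = any_embryonic_cns = False
    for r in records:
        if r.context_type is not ContextType.PRIMARY:
            continue
        any_primary = True
        if r.context_term in cns_terms:
            any_cns = True
            if _is_embryonic(r.developmental_stage, embryonic_patterns):
                any_embryonic_cns = True
        elif r.context_term in eye_terms:
            any_eye = True
    if any_cns:
        category = ContextCategory.CNS
    elif any_eye:
        category = ContextCategory.EYE
    else:
        category = ContextCategory.OTHER
    return category, any_primary, any_cns, any_embryonic_cns


def aggregate_dtris(
    records: Sequence[ExperimentRecord],
    dag: OntologyDag,
    threshold_bp: int = 2000,
    cns_root: str = CNS_ROOT,
    eye_root: str = EYE_ROOT,
    embryonic_patterns: Sequence[str] = DEFAULT_EMBRYONIC_PATTERNS,
) -> list[DTRI]:
    """One DTRI per distinct (human TF, human target) pair, sorted by pair.

    Every record must already carry human reporting identifiers on both
    genes (see :func:`dtrikit.records.to_human_ortholog`).
    """
    groups: dict[tuple[int, int], list[ExperimentRecord]] = defaultdict(list)
    for r in records:
        if r.tf.human_entrez_id is None or r.target.human_entrez_id is None:
            raise ValueError(
                f"record {r.experiment_id}: human reporting identifiers not populated"
            )
        groups[(r.tf.human_entrez_id, r.target.human_entrez_id)].append(r)

    out: list[DTRI] = []
    for (tf, target), group in sorted(groups.items()):
        category, any_primary, any_cns, any_emb = resolve_context(
            group, dag, cns_root, eye_root, embryonic_patterns
        )
        out.append(
            DTRI(
                tf_human_entrez=tf,
                target_human_entrez=target,
                evidence_types=frozenset(r.experiment_type for r in group),
                n_experiments=len(group),
                species_support=resolve_species_support(group),
                mode=resolve_mode(group),
                tfbs_class=resolve_tfbs_class(group, threshold_bp),
                context_category=category,
                any_primary=any_primary,
                any_cns=any_cns,
                any_embryonic_cns=any_emb,
                pubmed_ids=frozenset(r.pubmed_id for r in group),
            )
        )
    return out


_EVIDENCE_ORDER = [
    ExperimentType.PERTURBATION,
    ExperimentType.BINDING,
    ExperimentType.REPORTER,
]


def evidence_combo_label(types: frozenset[ExperimentType]) -> str:
    return "+".join(t.value for t in _EVIDENCE_ORDER if t in types)


@dataclass
class CurationSummary:
    """Stratified count tables over a DTRI collection."""

    n_dtris: int
    n_tfs: int
    n_targets: int
    n_papers_with_dtri: int
    n_papers_examined: int | None
    n_negative_papers: int | None
    mean_dtris_per_positive_paper: float
    n_multi_evidence: int
    n_triple_evidence: int
    n_triple_primary: int
    n_triple_cns: int
    n_position_annotated: int
    n_with_proximal: int
    n_with_distal: int
    n_mode_reported: int
    n_repressive: int
    evidence_by_context: dict[tuple[str, str], int]
    species_support_counts: dict[str, int]
    mode_by_tfbs: dict[tuple[str, str], int]
    per_tf_target_counts: dict[int, int]
    per_target_regulator_counts: dict[int, int]
    per_paper_dtri_counts: dict[int, int]

    def to_json(self, indent: int | None = 2) -> str:
        def keyed(d: Mapping) -> dict:
            return {
                ("|".join(k) if isinstance(k, tuple) else str(k)): v
                for k, v in sorted(d.items(), key=lambda kv: str(kv[0]))
            }

        payload = {
            "totals": {
                "n_dtris": self.n_dtris,
                "n_tfs": self.n_tfs,
                "n_targets": self.n_targets,
                "n_papers_with_dtri": self.n_papers_with_dtri,
                "n_papers_examined": self.n_papers_examined,
                "n_negative_papers": self.n_negative_papers,
                "mean_dtris_per_positive_paper": self.mean_dtris_per_positive_paper,
            },
            "evidence": {
                "n_multi_evidence": self.n_multi_evidence,
                "n_triple_evidence": self.n_triple_evidence,
                "n_triple_primary": self.n_triple_primary,
                "n_triple_cns": self.n_triple_cns,
            },
            "tfbs": {
                "n_position_annotated": self.n_position_annotated,
                "n_with_proximal": self.n_with_proximal,
                "n_with_distal": self.n_with_distal,
            },
            "mode": {
                "n_mode_reported": self.n_mode_reported,
                "n_repressive": self.n_repressive,
            },
            "evidence_by_context": keyed(self.evidence_by_context),
            "species_support_counts": keyed(self.species_support_counts),
            "mode_by_tfbs": keyed(self.mode_by_tfbs),
            "per_tf_target_counts": keyed(self.per_tf_target_counts),
            "per_target_regulator_counts": keyed(self.per_target_regulator_counts),
            "per_paper_dtri_counts": keyed(self.per_paper_dtri_counts),
        }
        return json.dumps(payload, indent=indent)


def summarize(
    dtris: Sequence[DTRI],
    records: Sequence[ExperimentRecord] | None = None,
    n_papers_examined: int | None = None,
) -> CurationSummary:
    """Cross-tabulate a DTRI collection.

    Per-paper counts are computed over papers contributing at least one
    DTRI; when the number of examined papers is given, papers without any
    DTRI are carried as a separate negative count.
    """
    per_paper: Counter[int] = Counter()
    for d in dtris:
        for pmid in d.pubmed_ids:
            per_paper[pmid] += 1
    n_papers_with_dtri = len(per_paper)
    mean_per_positive = (
        sum(per_paper.values()) / n_papers_with_dtri if n_papers_with_dtri else 0.0
    )

    evidence_by_context: Counter[tuple[str, str]] = Counter()
    mode_by_tfbs: Counter[tuple[str, str]] = Counter()
    species_counts: Counter[str] = Counter()
    per_tf: Counter[int] = Counter()
    per_target: Counter[int] = Counter()
    for d in dtris:
        evidence_by_context[
            (evidence_combo_label(d.evidence_types), d.context_category.value)
        ] += 1
        mode_by_tfbs[(d.mode.value, d.tfbs_class.value)] += 1
        species_counts[d.species_support.value] += 1
        per_tf[d.tf_human_entrez] += 1
        per_target[d.target_human_entrez] += 1

    triple = [d for d in dtris if len(d.evidence_types) == 3]
    annotated = [d for d in dtris if d.tfbs_class is not TfbsSummary.UNREPORTED]
    mode_reported = [d for d in dtris if d.mode is not ModeSummary.UNREPORTED]

    return CurationSummary(
        n_dtris=len(dtris),
        n_tfs=len(per_tf),
        n_targets=len(per_target),
        n_papers_with_dtri=n_papers_with_dtri,
        n_papers_examined=n_papers_examined,
        n_negative_papers=(
            None if n_papers_examined is None else n_papers_examined - n_papers_with_dtri
        ),
        mean_dtris_per_positive_paper=mean_per_positive,
        n_multi_evidence=sum(1 for d in dtris if len(d.evidence_types) >= 2),
        n_triple_evidence=len(triple),
        n_triple_primary=sum(1 for d in triple if d.any_primary),
        n_triple_cns=sum(1 for d in triple if d.any_cns),
        n_position_annotated=len(annotated),
        n_with_proximal=sum(
            1 for d in annotated if d.tfbs_class in (TfbsSummary.PROXIMAL, TfbsSummary.BOTH)
        ),
        n_with_distal=sum(
            1 for d in annotated if d.tfbs_class in (TfbsSummary.DISTAL, TfbsSummary.BOTH)
        ),
        n_mode_reported=len(mode_reported),
        n_repressive=sum(1 for d in mode_reported if d.mode is ModeSummary.REPRESSION),
        evidence_by_context=dict(evidence_by_context),
        species_support_counts=dict(species_counts),
        mode_by_tfbs=dict(mode_by_tfbs),
        per_tf_target_counts=dict(per_tf),
        per_target_regulator_counts=dict(per_target),
        per_paper_dtri_counts=dict(per_paper),
    )


@dataclass(frozen=True)
class LiteratureEstimate:
    """Projection of interactions remaining in the uncurated literature."""

    positive_rate: float
    mean_dtris_per_positive_paper: float
    projected_positive_papers: float
    projected_dtris: float
    projected_triple_evidence_dtris: float
    projected_cns_dtris: float
    captured_fraction_cns: float | None = None


def estimate_remaining(
    n_examined: int,
    n_positive: int,
    n_candidates_remaining: int,
    mean_dtris_per_positive_paper: float,
    frac_triple: float,
    frac_cns: float,
    n_current_cns: int | None = None,
) -> LiteratureEstimate:
    """Extrapolate the curated sample to the remaining candidate corpus.

    The positive rate (fraction of examined papers reporting at least one
    DTRI) scales the remaining candidate papers; the mean number of DTRIs
    per positive paper scales that into projected interactions, and the
    observed triple-evidence and CNS fractions subset the projection.
    Projections are reported unrounded. When the currently curated count of
    CNS-verified interactions is supplied, the captured fraction is
    current / (current + projected).
    """
    if n_examined <= 0:
        raise ValueError("n_examined must be positive (positive rate undefined)")
    if not (0 <= n_positive <= n_examined):
        raise ValueError("n_positive must lie in [0, n_examined]")
    for name, frac in (("frac_triple", frac_triple), ("frac_cns", frac_cns)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    positive_rate = n_positive / n_examined
    projected_papers = positive_rate * n_candidates_remaining
    projected_dtris = projected_papers * mean_dtris_per_positive_paper
    projected_cns = projected_dtris * frac_cns
    captured = None
    if n_current_cns is not None:
        denom = n_current_cns + projected_cns
        captured = n_current_cns / denom if denom > 0 else None
    return LiteratureEstimate(
        positive_rate=positive_rate,
        mean_dtris_per_positive_paper=mean_dtris_per_positive_paper,
        projected_positive_papers=projected_papers,
        projected_dtris=projected_dtris,
        projected_triple_evidence_dtris=projected_dtris * frac_triple,
        projected_cns_dtris=projected_cns,
        captured_fraction_cns=captured,
    )


# ---------------------------------------------------------------------------
# DTRI-level TSV I/O

DTRI_TABLE_COLUMNS = [
    "tf_entrez",
    "target_entrez",
    "evidence_types",
    "n_experiments",
    "species_support",
    "mode",
    "tfbs_class",
    "context_category",
    "any_primary",
    "any_cns",
    "pubmed_ids",
]


def write_dtri_table(dtris: Iterable[DTRI], sink: IO[str]) -> None:
    sink.write("\t".join(DTRI_TABLE_COLUMNS) + "\n")
    for d in dtris:
        row = [
            str(d.tf_human_entrez),
            str(d.target_human_entrez),
            ";".join(
                t.value for t in _EVIDENCE_ORDER if t in d.evidence_types
            ),
            str(d.n_experiments),
            d.species_support.value,
            d.mode.value,
            d.tfbs_class.value,
            d.context_category.value,
            "true" if d.any_primary else "false",
            "true" if d.any_cns else "false",
            ";".join(str(p) for p in sorted(d.pubmed_ids)),
        ]
        sink.write("\t".join(row) + "\n")


def read_dtri_table(source: str | IO[str]) -> list[DTRI]:
    """Read a DTRI-level table in the dialect written by
    :func:`write_dtri_table`. The embryonic-CNS flag is not serialized and
    reads back as False."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in DTRI_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DTRI table missing column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DTRI(
                tf_human_entrez=int(row.tf_entrez),
                target_human_entrez=int(row.target_entrez),
                evidence_types=frozenset(
                    ExperimentType(t) for t in str(row.evidence_types).split(";")
                ),
                n_experiments=int(row.n_experiments),
                species_support=SpeciesSupport(row.species_support),
                mode=ModeSummary(row.mode),
                tfbs_class=TfbsSummary(row.tfbs_class),
                context_category=ContextCategory(row.context_category),
                any_primary=str(row.any_primary).lower() == "true",
                any_cns=str(row.any_cns).lower() == "true",
                any_embryonic_cns=False,
                pubmed_ids=frozenset(
                    int(p) for p in str(row.pubmed_ids).split(";") if p
                ),
            )
        )
    return out
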