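"""Experiment-level curation records for direct transcriptional regulatory
interactions (DTRIs).

A DTRI is a pairwise interaction in which a transcription factor (TF)
modulates a target gene's expression by associating with a cis-regulatory
element. Each low-throughput experiment supporting a DTRI — a TF
perturbation, a TF-DNA binding assay (ChIP or EMSA), or a TF-reporter
assay — is one record, carrying a type-specific detail block, the cellular
context (cell line, primary tissue/cells, or in-vitro for EMSA), the mode
of regulation, and the position of the TF binding site (TFBS) relative to
the target's transcription start site (TSS).

Genes are indexed by Entrez IDs. For aggregation across species, every gene
carries a human reporting identifier obtained by ortholog mapping; a mouse
gene without a human ortholog passes through under its own Entrez ID and is
flagged unmapped.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, replace
from typing import IO, Iterable, Mapping

import pandas as pd

__all__ = [
    "Species",
    "ExperimentType",
    "ContextType",
    "Mode",
    "PerturbationDirection",
    "PerturbationTiming",
    "Zygosity",
    "BindingMethod",
    "EmsaProteinSource",
    "TfbsClass",
    "GeneRef",
    "HomologyTable",
    "PerturbationDetail",
    "BindingDetail",
    "ReporterDetail",
    "ExperimentRecord",
    "ControlledVocabulary",
    "default_vocabulary",
    "CurationFormatError",
    "CurationValidationError",
    "classify_tfbs",
    "to_human_ortholog",
    "validate_record",
    "read_experiment_table",
    "write_experiment_table",
    "EXPERIMENT_TABLE_COLUMNS",
]


class CurationFormatError(ValueError):
    """A table does not conform to the expected dialect (e.g. missing column)."""


class CurationValidationError(ValueError):
    """A row or record violates the controlled vocabulary or a type invariant."""


class Species(str, enum.Enum):
    HUMAN = "human"
    MOUSE = "mouse"


class ExperimentType(str, enum.Enum):
    PERTURBATION = "perturbation"
    BINDING = "binding"
    REPORTER = "reporter"


class ContextType(str, enum.Enum):
    CELL_LINE = "cell_line"
    PRIMARY = "primary"
    IN_VITRO = "in_vitro"


class Mode(str, enum.Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    UNREPORTED = "unreported"


class PerturbationDirection(str, enum.Enum):
    OVEREXPRESSION = "overexpression"
    KNOCKDOWN = "knockdown"
    KNOCKOUT = "knockout"


class PerturbationTiming(str, enum.Enum):
    CONSTITUTIVE = "constitutive"
    INDUCED = "induced"


class Zygosity(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    NOT_APPLICABLE = "not_applicable"


class BindingMethod(str, enum.Enum):
    CHIP = "chip"
    EMSA = "emsa"


class EmsaProteinSource(str, enum.Enum):
    TRANSFECTED_CELL_LINE = "transfected_cell_line"
    PRIMARY_EXTRACT = "primary_extract"
    RECOMBINANT = "recombinant"
    OTHER = "other"


class TfbsClass(str, enum.Enum):
    PROXIMAL = "proximal"
    DISTAL = "distal"
    UNREPORTED = "unreported"


#: Ontology namespaces accepted for context terms; "freetext" marks verbatim
#: names recorded when no ontology term fits, never matched by DAG queries.
ONTOLOGY_NAMESPACES = frozenset({"UBERON", "CL", "CLO", "BTO", "EFO", "freetext"})


@dataclass(frozen=True)
class GeneRef:
    """A gene, indexed by Entrez ID, with its human reporting identifier."""

    entrez_id: int
    symbol: str
    species: Species
    human_entrez_id: int | None = None
    unmapped: bool = False

    def __post_init__(self) -> None:
        if self.entrez_id <= 0:
            raise CurationValidationError(f"entrez_id must be positive, got {self.entrez_id}")
        if not isinstance(self.species, Species):
            raise CurationValidationError(f"unknown species: {self.species!r}")
        if self.human_entrez_id is not None and self.human_entrez_id <= 0:
            raise CurationValidationError("human_entrez_id must be positive when set")


@dataclass(frozen=True)
class HomologyTable:
    """Mapping (species, entrez_id) -> human Entrez ID.

    Human keys map to themselves; each source key maps to at most one human
    id (the mapping is a function).
    """

    mapping: Mapping[tuple[Species, int], int]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for (species, entrez), human in self.mapping.items():
            if species is Species.HUMAN and human != entrez:
                raise CurationValidationError(
                    f"human key {entrez} must map to itself, got {human}"
                )

    def lookup(self, species: Species, entrez_id: int) -> int | None:
        if species is Species.HUMAN:
            return entrez_id
        return self.mapping.get((species, entrez_id))

    @classmethod
    def from_tsv(cls, source: str | IO[str], provenance: str | None = None) -> "HomologyTable":
        """Read a homology TSV with columns species, entrez_id, human_entrez_id."""
        df = _read_tsv(source)
        _require_columns(df, ["species", "entrez_id", "human_entrez_id"])
        mapping: dict[tuple[Species, int], int] = {}
        for i, row in enumerate(df.itertuples(index=False)):
            species = _parse_enum(Species, row.species, "species", i)
            key = (species, _parse_int(row.entrez_id, "entrez_id", i))
            human = _parse_int(row.human_entrez_id, "human_entrez_id", i)
            if key in mapping and mapping[key] != human:
                raise CurationValidationError(
                    f"row {i}: ({species.value}, {key[1]}) maps to both "
                    f"{mapping[key]} and {human}"
                )
            mapping[key] = human
        name = provenance if provenance is not None else getattr(source, "name", "tsv")
        return cls(mapping=mapping, provenance=str(name))

    def to_tsv(self, sink: IO[str]) -> None:
        sink.write("species\tentrez_id\thuman_entrez_id\n")
        for (species, entrez), human in sorted(
            self.mapping.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        ):
            sink.write(f"{species.value}\t{entrez}\t{human}\n")


@dataclass(frozen=True)
class PerturbationDetail:
    direction: PerturbationDirection
    timing: PerturbationTiming
    zygosity: Zygosity


@dataclass(frozen=True)
class BindingDetail:
    method: BindingMethod
    emsa_protein_source: EmsaProteinSource | None = None


@dataclass(frozen=True)
class ReporterDetail:
    cre_mutated: bool
    mutation_binding_verified: bool | None = None


@dataclass(frozen=True)
class ExperimentRecord:
    """One low-throughput experiment supporting one TF -> target interaction."""

    experiment_id: str
    pubmed_id: int
    tf: GeneRef
    target: GeneRef
    experiment_type: ExperimentType
    context_type: ContextType
    context_term: str
    developmental_stage: str | None = None
    mode: Mode = Mode.UNREPORTED
    tfbs_offset_bp: int | None = None
    is_promoter: bool | None = None
    perturbation_detail: PerturbationDetail | None = None
    binding_detail: BindingDetail | None = None
    reporter_detail: ReporterDetail | None = None

    @property
    def detail(self):
        return self.perturbation_detail or self.binding_detail or self.reporter_detail


@dataclass(frozen=True)
class ControlledVocabulary:
    """Named enumerations for every categorical attribute plus accepted
    ontology namespaces. Unknown values are rejected, never coerced."""

    enums: Mapping[str, frozenset[str]]
    namespaces: frozenset[str] = ONTOLOGY_NAMESPACES

    def allows(self, field_name: str, value: str) -> bool:
        allowed = self.enums.get(field_name)
        return allowed is not None and value in allowed

    def allows_namespace(self, curie_or_text: str) -> bool:
        prefix = curie_or_text.split(":", 1)[0] if ":" in curie_or_text else "freetext"
        return prefix in self.namespaces


def default_vocabulary() -> ControlledVocabulary:
    enums = {
        "species": frozenset(e.value for e in Species),
        "experiment_type": frozenset(e.value for e in ExperimentType),
        "context_type": frozenset(e.value for e in ContextType),
        "mode": frozenset(e.value for e in Mode),
        "perturbation_direction": frozenset(e.value for e in PerturbationDirection),
        "perturbation_timing": frozenset(e.value for e in PerturbationTiming),
        "zygosity": frozenset(e.value for e in Zygosity),
        "binding_method": frozenset(e.value for e in BindingMethod),
        "emsa_protein_source": frozenset(e.value for e in EmsaProteinSource),
    }
    return ControlledVocabulary(enums=enums)


def classify_tfbs(
    offset_bp: int | None,
    is_promoter: bool | None,
    threshold_bp: int = 2000,
) -> TfbsClass:
    """Classify a TFBS as proximal or distal to the target TSS.

    Proximal elements are promoters or elements within ``threshold_bp`` of the
    TSS (boundary inclusive, symmetric in sign: only the signed offset of the
    element end closer to the TSS is recorded). With neither input, the
    position is unreported.
    """
    if threshold_bp <= 0:
        raise ValueError("threshold_bp must be positive")
    if is_promoter:
        return TfbsClass.PROXIMAL
    if offset_bp is None:
        return TfbsClass.UNREPORTED
    return TfbsClass.PROXIMAL if abs(offset_bp) <= threshold_bp else TfbsClass.DISTAL


def to_human_ortholog(gene: GeneRef, homology: HomologyTable) -> GeneRef:
    """Populate the human reporting identifier for a gene.

    Human genes map to themselves. Mouse genes map through the homology
    table; when no ortholog exists, the mouse Entrez ID is used directly and
    the gene is flagged unmapped. Idempotent.
    """
    if gene.species is Species.HUMAN:
        return replace(gene, human_entrez_id=gene.entrez_id, unmapped=False)
    human = homology.lookup(gene.species, gene.entrez_id)
    if human is None:
        return replace(gene, human_entrez_id=gene.entrez_id, unmapped=True)
    return replace(gene, human_entrez_id=human, unmapped=False)


def validate_record(
    record: ExperimentRecord, vocab: ControlledVocabulary | None = None
) -> list[str]:
    """Check a record against the controlled vocabulary and type invariants.

    Violations are returned as messages naming the field and rule; an empty
    list means the record is well formed.
    """
    vocab = vocab if vocab is not None else default_vocabulary()
    violations: list[str] = []

    details = {
        ExperimentType.PERTURBATION: record.perturbation_detail,
        ExperimentType.BINDING: record.binding_detail,
        ExperimentType.REPORTER: record.reporter_detail,
    }
    present = [t for t, d in details.items() if d is not None]
    if len(present) != 1:
        violations.append(
            "detail blocks: exactly one of perturbation/binding/reporter detail "
            f"must be present, found {len(present)}"
        )
    elif present[0] is not record.experiment_type:
        violations.append(
            f"detail blocks: {present[0].value} detail present but "
            f"experiment_type={record.experiment_type.value}"
        )

    for name, value in [
        ("experiment_type", record.experiment_type.value),
        ("context_type", record.context_type.value),
        ("mode", record.mode.value),
        ("species", record.tf.species.value),
        ("species", record.target.species.value),
    ]:
        if not vocab.allows(name, value):
            violations.append(f"{name}: value {value!r} not in controlled vocabulary")

    if record.pubmed_id <= 0:
        violations.append("pubmed_id: must be a positive integer")

    if not vocab.allows_namespace(record.context_term):
        violations.append(
            f"context_term: namespace of {record.context_term!r} not accepted"
        )

    is_emsa = (
        record.binding_detail is not None
        and record.binding_detail.method is BindingMethod.EMSA
    )
    if record.context_type is ContextType.IN_VITRO and not is_emsa:
        violations.append(
            "context_type: in_vitro is reserved for EMSA binding experiments"
        )
    if (
        record.binding_detail is not None
        and record.binding_detail.emsa_protein_source is not None
        and record.binding_detail.method is not BindingMethod.EMSA
    ):
        violations.append(
            "emsa_protein_source: present but binding method is not emsa"
        )
    if (
        record.reporter_detail is not None
        and record.reporter_detail.mutation_binding_verified is not None
        and not record.reporter_detail.cre_mutated
    ):
        violations.append(
            "mutation_binding_verified: present but cre_mutated is false"
        )
    return violations


# ---------------------------------------------------------------------------
# Tabular I/O. Dialect: UTF-8, tab-separated, "NA" for absent values.

EXPERIMENT_TABLE_COLUMNS = [
    "experiment_id",
    "pubmed_id",
    "tf_symbol",
    "tf_entrez",
    "tf_species",
    "target_symbol",
    "target_entrez",
    "target_species",
    "experiment_type",
    "context_type",
    "context_term",
    "developmental_stage",
    "mode",
    "tfbs_offset_bp",
    "is_promoter",
    "perturbation_direction",
    "perturbation_timing",
    "zygosity",
    "binding_method",
    "emsa_protein_source",
    "reporter_cre_mutated",
    "mutation_binding_verified",
]

_NA = "NA"


def _read_tsv(source: str | IO[str]) -> pd.DataFrame:
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    return pd.read_csv(
        source,
        sep="\t",
        dtype=str,
        na_values=[_NA],
        keep_default_na=False,
        encoding="utf-8",
    )


def _require_columns(df: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CurationFormatError(f"missing required column(s): {', '.join(missing)}")


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and value != value)


def _parse_int(value, field_name: str, row: int) -> int:
    try:
        return int(str(value))
    except (TypeError, ValueError):
        raise CurationValidationError(
            f"row {row}: {field_name} must be an integer, got {value!r}"
        ) from None


def _parse_enum(enum_cls, value, field_name: str, row: int):
    try:
        return enum_cls(str(value))
    except ValueError:
        raise CurationValidationError(
            f"row {row}: {field_name} value {value!r} outside controlled vocabulary"
        ) from None


def _parse_bool(value, field_name: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in {"true", "1"}:
        return True
    if text in {"false", "0"}:
        return False
    raise CurationValidationError(
        f"row {row}: {field_name} must be true/false, got {value!r}"
    )


def read_experiment_table(
    source: str | IO[str],
    vocab: ControlledVocabulary | None = None,
    homology: HomologyTable | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[ExperimentRecord]:
    """Read an experiment-level curation table into validated records.

    Parameters
    ----------
    source
        Path, open text stream, or TSV content. The header must name the
        columns in :data:`EXPERIMENT_TABLE_COLUMNS` (any order).
    vocab
        Controlled vocabulary; defaults to :func:`default_vocabulary`.
    homology
        Ortholog mapping used to populate human reporting identifiers. When
        omitted, mouse genes pass through under their own IDs (flagged).
    column_map
        Optional adapter renaming the file's headers onto the expected
        dialect, for tables deposited under other column names.

    Row order is preserved; duplicate experiment identifiers are rejected.
    """
    vocab = vocab if vocab is not None else default_vocabulary()
    homology = homology if homology is not None else HomologyTable(mapping={})
    df = _read_tsv(source)
    if column_map:
        df = df.rename(columns=dict(column_map))
    _require_columns(df, EXPERIMENT_TABLE_COLUMNS)

    records: list[ExperimentRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.to_dict(orient="records")):
        experiment_id = row["experiment_id"]
        if _is_na(experiment_id):
            raise CurationValidationError(f"row {i}: experiment_id is missing")
        experiment_id = str(experiment_id)
        if experiment_id in seen_ids:
            raise CurationValidationError(
                f"row {i}: duplicate experiment_id {experiment_id!r}"
            )
        seen_ids.add(experiment_id)

        experiment_type = _parse_enum(
            ExperimentType, row["experiment_type"], "experiment_type", i
        )

        tf = GeneRef(
            entrez_id=_parse_int(row["tf_entrez"], "tf_entrez", i),
            symbol=str(row["tf_symbol"]),
            species=_parse_enum(Species, row["tf_species"], "tf_species", i),
        )
        target = GeneRef(
            entrez_id=_parse_int(row["target_entrez"], "target_entrez", i),
            symbol=str(row["target_symbol"]),
            species=_parse_enum(Species, row["target_species"], "target_species", i),
        )

        perturbation = binding = reporter = None
        if not _is_na(row["perturbation_direction"]):
            perturbation = PerturbationDetail(
                direction=_parse_enum(
                    PerturbationDirection,
                    row["perturbation_direction"],
                    "perturbation_direction",
                    i,
                ),
                timing=_parse_enum(
                    PerturbationTiming, row["perturbation_timing"], "perturbation_timing", i
                ),
                zygosity=_parse_enum(Zygosity, row["zygosity"], "zygosity", i),
            )
        if not _is_na(row["binding_method"]):
            binding = BindingDetail(
                method=_parse_enum(BindingMethod, row["binding_method"], "binding_method", i),
                emsa_protein_source=(
                    None
                    if _is_na(row["emsa_protein_source"])
                    else _parse_enum(
                        EmsaProteinSource,
                        row["emsa_protein_source"],
                        "emsa_protein_source",
                        i,
                    )
                ),
            )
        if not _is_na(row["reporter_cre_mutated"]):
            reporter = ReporterDetail(
                cre_mutated=_parse_bool(
                    row["reporter_cre_mutated"], "reporter_cre_mutated", i
                ),
                mutation_binding_verified=(
                    None
                    if _is_na(row["mutation_binding_verified"])
                    else _parse_bool(
                        row["mutation_binding_verified"], "mutation_binding_verified", i
                    )
                ),
            )

        record = ExperimentRecord(
            experiment_id=experiment_id,
            pubmed_id=_parse_int(row["pubmed_id"], "pubmed_id", i),
            tf=to_human_ortholog(tf, homology),
            target=to_human_ortholog(target, homology),
            experiment_type=experiment_type,
            context_type=_parse_enum(ContextType, row["context_type"], "context_type", i),
            context_term=str(row["context_term"]) if not _is_na(row["context_term"]) else "",
            developmental_stage=(
                None
                if _is_na(row["developmental_stage"])
                else str(row["developmental_stage"])
            ),
            mode=(
                Mode.UNREPORTED
                if _is_na(row["mode"])
                else _parse_enum(Mode, row["mode"], "mode", i)
            ),
            tfbs_offset_bp=(
                None
                if _is_na(row["tfbs_offset_bp"])
                else _parse_int(row["tfbs_offset_bp"], "tfbs_offset_bp", i)
            ),
            is_promoter=(
                None
                if _is_na(row["is_promoter"])
                else _parse_bool(row["is_promoter"], "is_promoter", i)
            ),
            perturbation_detail=perturbation,
            binding_detail=binding,
            reporter_detail=reporter,
        )
        violations = validate_record(record, vocab)
        if violations:
            raise CurationValidationError(
                f"row {i} ({experiment_id}): " + "; ".join(violations)
            )
        records.append(record)
    return records


def _fmt(value) -> str:
    if value is None:
        return _NA
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, enum.Enum):
        return str(value.value)
    return str(value)


def write_experiment_table(records: Iterable[ExperimentRecord], sink: IO[str]) -> None:
    """Write records back to the tab-separated dialect (round-trips with
    :func:`read_experiment_table`)."""
    sink.write("\t".join(EXPERIMENT_TABLE_COLUMNS) + "\n")
    for r in records:
        p, b, rep = r.perturbation_detail, r.binding_detail, r.reporter_detail
        row = [
            r.experiment_id,
            r.pubmed_id,
            r.tf.symbol,
            r.tf.entrez_id,
            r.tf.species,
            r.target.symbol,
            r.target.entrez_id,
            r.target.species,
            r.experiment_type,
            r.context_type,
            r.context_term if r.context_term else None,
            r.developmental_stage,
            r.mode,
            r.tfbs_offset_bp,
            r.is_promoter,
            p.direction if p else None,
            p.timing if p else None,
            p.zygosity if p else None,
            b.method if b else None,
            b.emsa_protein_source if b else None,
            rep.cre_mutated if rep else None,
            rep.mutation_binding_verified if rep else None,
        ]
        sink.write("\t".join(_fmt(v) for v in row) + "\n")
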