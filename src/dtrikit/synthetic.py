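"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical shape of an experiment-level
curation effort over neurodevelopmental transcription factors:

* popularity-skewed TF -> candidate-paper corpora (rank-size power law with
  a configurable fraction of TFs having no papers at all);
* experiment records whose marginal distributions follow the curated
  collection's printed breakdowns (evidence-type combination mixture,
  cell-line / primary / in-vitro context shares, repressive fraction,
  proximal-TFBS fraction, species mixture);
* directed TF -> target networks grown with a tunable target-selection bias
  β: at β = 0 targets are chosen uniformly (a null the degree-preserving
  rewiring test should NOT flag), at β > 0 new studies preferentially
  follow the recent literature — linking the most recently studied
  regulators and their shared targets — which produces connectivity in
  excess of the degree sequence and is flagged by the rewiring null;
* differential-expression screens with a planted fraction ρ of responsive
  curated targets whose p-values are sub-uniform Beta(a, 1) against a
  Uniform(0, 1) background, with per-category effect multipliers and
  per-screen noise.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .aggregate import DTRI
from .benchmark import DEResult, TargetSet
from .corpus import CandidateCorpus
from .netstats import DirectedNetwork
from .ontology import CNS_ROOT, EYE_ROOT, OntologyDag
from .records import (
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
    write_experiment_table,
)

__all__ = [
    "SimulationConfig",
    "generate_fixtures",
    "generate_corpus",
    "generate_experiments",
    "generate_biased_network",
    "generate_de_screens",
    "write_bundle",
]

_COMBOS = (
    "perturbation",
    "binding",
    "reporter",
    "perturbation+binding",
    "perturbation+reporter",
    "binding+reporter",
    "perturbation+binding+reporter",
)

_MOUSE_OFFSET = 100_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults mirror the curated collection's scale and printed marginal
    distributions: 251 TFs, 825 targets, 1,499 interactions; 27% of
    interactions with all three evidence types and 64% with two or more;
    experiment contexts split roughly 60/26/13 between cell lines, primary
    tissue/cells, and in-vitro EMSAs; 24% of mode-annotated interactions
    repressive; 91% of position-annotated interactions proximal; and a
    species mixture of about one third human-only, one half mouse-only and
    14% supported in both.
    """

    seed: int = 0
    # corpus
    n_tfs: int = 251
    n_targets: int = 825
    zipf_exponent: float = 1.0
    zero_paper_fraction: float = 0.34
    popularity_noise: float = 0.3
    corpus_scale: float = 150.0
    # curation records
    n_dtris: int = 1499
    evidence_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "perturbation": 0.13,
            "binding": 0.16,
            "reporter": 0.07,
            "perturbation+binding": 0.16,
            "perturbation+reporter": 0.10,
            "binding+reporter": 0.11,
            "perturbation+binding+reporter": 0.27,
        }
    )
    primary_context_fraction: float = 0.30  # primary vs cell line (non-EMSA)
    emsa_binding_fraction: float = 0.32
    primary_cns_fraction: float = 0.26
    primary_eye_fraction: float = 0.08
    embryonic_fraction: float = 0.74
    mode_reported_fraction: float = 0.88
    repressive_fraction: float = 0.24
    both_mode_fraction: float = 0.015
    position_annotated_fraction: float = 0.44
    proximal_fraction: float = 0.91
    species_mix: Mapping[str, float] = field(
        default_factory=lambda: {"human_only": 0.33, "mouse_only": 0.53, "both": 0.14}
    )
    mixed_species_fraction: float = 0.01
    extra_experiment_rate: float = 0.4
    mean_dtris_per_paper: float = 1.9
    unmapped_fraction: float = 0.05
    # biased network growth
    target_bias: float = 9.0
    out_degree_skew: float = 0.75
    n_network_edges: int | None = None  # defaults to n_dtris
    # differential-expression screens
    universe_size: int = 10_000
    responsive_fraction: float = 0.7
    signal_shape: float = 0.1
    n_screens: int = 3
    screen_noise: float = 0.1
    category_effect: Mapping[str, float] = field(
        default_factory=lambda: {"CNS": 1.0, "eye": 0.7, "other": 0.2}
    )

    def __post_init__(self) -> None:
        for name, probs in (
            ("evidence_mixture", self.evidence_mixture),
            ("species_mix", self.species_mix),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} contains a negative probability")
        if set(self.evidence_mixture) != set(_COMBOS):
            raise ValueError("evidence_mixture must cover the 7 nonempty combinations")
        for name in (
            "zero_paper_fraction",
            "primary_context_fraction",
            "emsa_binding_fraction",
            "primary_cns_fraction",
            "primary_eye_fraction",
            "embryonic_fraction",
            "mode_reported_fraction",
            "repressive_fraction",
            "both_mode_fraction",
            "position_annotated_fraction",
            "proximal_fraction",
            "mixed_species_fraction",
            "unmapped_fraction",
            "responsive_fraction",
            "screen_noise",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.target_bias < 0:
            raise ValueError("target_bias must be nonnegative")
        if self.signal_shape <= 0:
            raise ValueError("signal_shape must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stream generator derived from the seed."""
        digest = hashlib.sha256(f"{self.seed}:{stream}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:4], "big"))

    def tf_ids(self) -> list[int]:
        return [10_001 + i for i in range(self.n_tfs)]

    def target_ids(self) -> list[int]:
        return [20_001 + i for i in range(self.n_targets)]


# ---------------------------------------------------------------------------
# Fixtures: homology table and ontology DAG

_DAG_EDGES = [
    # CNS branch
    ("UBERON:0000955", CNS_ROOT),       # brain
    ("UBERON:0001890", "UBERON:0000955"),  # forebrain
    ("UBERON:0000956", "UBERON:0000955"),  # cerebral cortex
    ("UBERON:0002240", CNS_ROOT),       # spinal cord
    ("CL:0000540", CNS_ROOT),           # neuron
    # eye branch
    ("UBERON:0000966", EYE_ROOT),       # retina
    ("CL:0000573", "UBERON:0000966"),   # retinal cone cell
    # unrelated tissue branches
    ("UBERON:0002107", "UBERON:0000061"),  # liver
    ("UBERON:0000948", "UBERON:0000061"),  # heart
    ("UBERON:0002113", "UBERON:0000061"),  # kidney
    # roots hang off a common anatomical term
    (CNS_ROOT, "UBERON:0000061"),
    (EYE_ROOT, "UBERON:0000061"),
]

#: Cell-line terms deliberately live outside the anatomy branches so a
#: neural cell line never matches a CNS descendant query.
_CELL_LINE_TERMS = ["CLO:0000031", "CLO:0000019", "CLO:0009005"]
_OTHER_TISSUE_TERMS = ["UBERON:0002107", "UBERON:0000948", "UBERON:0002113"]
_CNS_TERMS = ["UBERON:0000955", "UBERON:0001890", "UBERON:0000956", "UBERON:0002240", "CL:0000540"]
_EYE_TERMS = ["UBERON:0000966", "CL:0000573"]


def generate_fixtures(config: SimulationConfig) -> tuple[HomologyTable, OntologyDag]:
    """Toy homology table and ontology DAG.

    Every human gene in the simulated universe gets a paired mouse id
    (human id + 100000); a configurable fraction of the mouse genes is left
    out of the table to exercise the unmapped pass-through rule. The DAG has
    a CNS branch and an eye branch with disjoint descendant sets, unrelated
    tissue branches, and free-standing cell-line terms.
    """
    rng = config.rng("fixtures")
    human_ids = config.tf_ids() + config.target_ids()
    mapping: dict[tuple[Species, int], int] = {}
    for hid in human_ids:
        if rng.random() >= config.unmapped_fraction:
            mapping[(Species.MOUSE, hid + _MOUSE_OFFSET)] = hid
    homology = HomologyTable(mapping=mapping, provenance="synthetic")
    dag = OntologyDag.from_edges(_DAG_EDGES)
    return homology, dag


# ---------------------------------------------------------------------------
# Candidate-paper corpus

def generate_corpus(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CandidateCorpus:
    """Popularity-skewed TF -> paper corpus.

    Per-TF candidate counts follow a rank-size power law with exponent
    ``zipf_exponent`` (larger exponent = steeper skew = fewer top TFs needed
    to cover the corpus); a configurable fraction of TFs has no candidate
    papers. PubMed popularity counts equal the candidate counts scaled by
    multiplicative lognormal noise (zero noise makes the rank correlation
    exactly 1).
    """
    if config.zipf_exponent <= 0:
        raise ValueError("zipf_exponent must be positive")
    rng = rng if rng is not None else config.rng("corpus")
    tfs = config.tf_ids()
    zero_mask = rng.random(len(tfs)) < config.zero_paper_fraction
    papers: dict[int, frozenset[int]] = {}
    popularity: dict[int, int] = {}
    next_pmid = 1_000_001
    for rank, (tf, zero) in enumerate(zip(tfs, zero_mask)):
        if zero:
            continue
        lam = config.corpus_scale * (rank + 1) ** (-config.zipf_exponent)
        count = int(rng.poisson(lam))
        if count == 0:
            continue  # deep-tail TFs can lack candidate papers naturally
        pmids = list(range(next_pmid, next_pmid + count))
        next_pmid += count
        # a slice of papers is shared with the previously drawn TF, so a
        # paper may be assigned to more than one TF
        if papers and count > 1 and rng.random() < 0.5:
            prev = sorted(papers[list(papers)[-1]])
            n_shared = min(len(prev), max(1, count // 10))
            pmids[:n_shared] = prev[:n_shared]
        papers[tf] = frozenset(pmids)
        noise = (
            float(np.exp(rng.normal(0.0, config.popularity_noise)))
            if config.popularity_noise > 0
            else 1.0
        )
        popularity[tf] = max(len(pmids), int(round(len(pmids) * 5 * noise)))
    if not papers:
        raise ValueError("all TFs drew zero papers; lower zero_paper_fraction")
    return CandidateCorpus(source="synthetic", papers=papers, popularity=popularity)


# ---------------------------------------------------------------------------
# Experiment records

def _draw_categorical(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def _gene(hid: int, species: Species, homology: HomologyTable) -> GeneRef:
    if species is Species.HUMAN:
        g = GeneRef(entrez_id=hid, symbol=f"G{hid}", species=species)
    else:
        g = GeneRef(entrez_id=hid + _MOUSE_OFFSET, symbol=f"g{hid}", species=species)
    return to_human_ortholog(g, homology)


def generate_experiments(
    config: SimulationConfig,
    homology: HomologyTable | None = None,
    rng: np.random.Generator | None = None,
) -> list[ExperimentRecord]:
    """Experiment records whose aggregation reproduces the configured
    marginals within multinomial sampling error.

    Per interaction, the evidence-type combination, species support, mode,
    context category and TFBS annotation are drawn from the configured
    mixtures; each evidence type contributes one or more experiments.
    Papers are assigned so that the mean number of interactions per positive
    paper matches ``mean_dtris_per_paper``.
    """
    rng = rng if rng is not None else config.rng("experiments")
    if homology is None:
        homology, _ = generate_fixtures(config)
    tfs = config.tf_ids()
    targets = config.target_ids()
    mapped_mouse = {hid for (sp, mid), hid in homology.mapping.items()}

    # skewed number of interactions per TF, summing to n_dtris
    weights = np.array([(i + 1) ** (-0.8) for i in range(len(tfs))])
    weights /= weights.sum()
    counts = rng.multinomial(config.n_dtris, weights)

    pairs: list[tuple[int, int]] = []
    for tf, c in zip(tfs, counts):
        if c == 0:
            continue
        c = min(c, len(targets))
        chosen = rng.choice(len(targets), size=c, replace=False)
        pairs.extend((tf, targets[j]) for j in chosen)

    # group consecutive interactions into papers (mean interactions/paper)
    paper_of_pair: list[int] = []
    pmid = 2_000_001
    remaining = 0
    for _ in pairs:
        if remaining == 0:
            pmid += 1
            remaining = max(1, rng.poisson(config.mean_dtris_per_paper - 1.0) + 1)
        paper_of_pair.append(pmid)
        remaining -= 1

    records: list[ExperimentRecord] = []
    exp_counter = 0
    for (tf_id, target_id), paper in zip(pairs, paper_of_pair):
        combo = _draw_categorical(rng, config.evidence_mixture)
        types = [ExperimentType(t) for t in combo.split("+")]

        support = _draw_categorical(rng, config.species_mix)
        if support != "human_only" and not (
            tf_id in mapped_mouse and target_id in mapped_mouse
        ):
            support = "human_only"  # mouse counterpart unavailable

        if rng.random() < config.mode_reported_fraction:
            if rng.random() < config.both_mode_fraction:
                dtri_mode = "both"
            elif rng.random() < config.repressive_fraction:
                dtri_mode = Mode.REPRESSION.value
            else:
                dtri_mode = Mode.ACTIVATION.value
        else:
            dtri_mode = Mode.UNREPORTED.value

        annotated = rng.random() < config.position_annotated_fraction
        proximal = rng.random() < config.proximal_fraction

        exp_species: list[tuple[Species, Species]] = []
        type_of_exp: list[ExperimentType] = []
        for t in types:
            n_exp = 1 + rng.poisson(config.extra_experiment_rate)
            for _ in range(n_exp):
                if support == "human_only":
                    sp = Species.HUMAN
                elif support == "mouse_only":
                    sp = Species.MOUSE
                else:
                    sp = Species.HUMAN if rng.random() < 0.5 else Species.MOUSE
                tf_sp = tg_sp = sp
                if (
                    t is not ExperimentType.REPORTER
                    and rng.random() < config.mixed_species_fraction
                ):
                    tf_sp = Species.HUMAN if sp is Species.MOUSE else Species.MOUSE
                    if support == "human_only" and tf_sp is Species.MOUSE:
                        tf_sp = sp  # keep pure-human pairs pure
                exp_species.append((tf_sp, tg_sp))
                type_of_exp.append(t)
        # guarantee the drawn support class is realized
        if support == "both":
            exp_species[0] = (Species.HUMAN, Species.HUMAN)
            exp_species[-1] = (Species.MOUSE, Species.MOUSE)

        for t, (tf_sp, tg_sp) in zip(type_of_exp, exp_species):
            exp_counter += 1
            is_emsa = (
                t is ExperimentType.BINDING
                and rng.random() < config.emsa_binding_fraction
            )
            if is_emsa:
                context_type = ContextType.IN_VITRO
                context_term = "in vitro binding reaction"
                stage = None
            elif rng.random() < config.primary_context_fraction:
                context_type = ContextType.PRIMARY
                u = rng.random()
                if u < config.primary_cns_fraction:
                    context_term = _CNS_TERMS[rng.integers(len(_CNS_TERMS))]
                elif u < config.primary_cns_fraction + config.primary_eye_fraction:
                    context_term = _EYE_TERMS[rng.integers(len(_EYE_TERMS))]
                else:
                    context_term = _OTHER_TISSUE_TERMS[
                        rng.integers(len(_OTHER_TISSUE_TERMS))
                    ]
                stage = (
                    f"E{10 + int(rng.integers(9))}.5"
                    if rng.random() < config.embryonic_fraction
                    else "adult"
                )
            else:
                context_type = ContextType.CELL_LINE
                context_term = _CELL_LINE_TERMS[rng.integers(len(_CELL_LINE_TERMS))]
                stage = None

            if dtri_mode == "both":
                mode = Mode.ACTIVATION if rng.random() < 0.5 else Mode.REPRESSION
            elif t is ExperimentType.BINDING:
                # pure binding evidence carries no direction
                mode = Mode.UNREPORTED if dtri_mode == Mode.UNREPORTED.value else Mode(dtri_mode)
            else:
                mode = Mode(dtri_mode)

            offset = None
            is_promoter = None
            if annotated and t in (ExperimentType.BINDING, ExperimentType.REPORTER):
                if proximal:
                    if rng.random() < 0.4:
                        is_promoter = True
                    else:
                        offset = int(rng.integers(-2000, 2001))
                else:
                    sign = -1 if rng.random() < 0.5 else 1
                    offset = sign * int(rng.integers(2001, 50_001))

            perturbation = binding = reporter = None
            if t is ExperimentType.PERTURBATION:
                if rng.random() < 0.3:
                    direction = PerturbationDirection.OVEREXPRESSION
                elif rng.random() < 0.55:
                    direction = PerturbationDirection.KNOCKOUT
                else:
                    direction = PerturbationDirection.KNOCKDOWN
                perturbation = PerturbationDetail(
                    direction=direction,
                    timing=(
                        PerturbationTiming.CONSTITUTIVE
                        if rng.random() < 0.68
                        else PerturbationTiming.INDUCED
                    ),
                    zygosity=(
                        (
                            Zygosity.HOMOZYGOUS
                            if rng.random() < 0.7
                            else Zygosity.HETEROZYGOUS
                        )
                        if direction is PerturbationDirection.KNOCKOUT
                        else Zygosity.NOT_APPLICABLE
                    ),
                )
            elif t is ExperimentType.BINDING:
                binding = BindingDetail(
                    method=BindingMethod.EMSA if is_emsa else BindingMethod.CHIP,
                    emsa_protein_source=(
                        EmsaProteinSource.TRANSFECTED_CELL_LINE
                        if is_emsa and rng.random() < 0.7
                        else (EmsaProteinSource.PRIMARY_EXTRACT if is_emsa else None)
                    ),
                )
            else:
                cre_mutated = rng.random() < 0.44
                reporter = ReporterDetail(
                    cre_mutated=cre_mutated,
                    mutation_binding_verified=(
                        bool(rng.random() < 0.5) if cre_mutated else None
                    ),
                )

            records.append(
                ExperimentRecord(
                    experiment_id=f"EXP{exp_counter:06d}",
                    pubmed_id=paper,
                    tf=_gene(tf_id, tf_sp, homology),
                    target=_gene(target_id, tg_sp, homology),
                    experiment_type=t,
                    context_type=context_type,
                    context_term=context_term,
                    developmental_stage=stage,
                    mode=mode,
                    tfbs_offset_bp=offset,
                    is_promoter=is_promoter,
                    perturbation_detail=perturbation,
                    binding_detail=binding,
                    reporter_detail=reporter,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Biased network growth

def generate_biased_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[DirectedNetwork, dict]:
    """Directed network grown with target-selection bias β.

    Each source TF receives a skewed out-degree and its edges are placed
    sequentially. With probability β / (1 + β) a TF "follows the
    literature": its first two edges go to the two most recently biased
    multi-target TFs (falling back to an established regulator weighted by
    1 + β · fan-out while that chain is empty), and any remaining edges
    explore genes drawn uniformly from the full candidate pool. This
    triadic "study what was just studied" rule simultaneously closes
    triangles among low-degree regulators, builds deep regulatory cascades,
    and glues small TFs to the network core — connectivity in excess of the
    degree sequence, which a degree-preserving rewiring null flags.
    High-fan-out TFs (above the mean out-degree) always explore, supplying
    the fresh singleton targets the real curation also accumulates.

    β = 0 reduces to uniform target choice with the same fixed out-degree
    sequence, which the rewiring null should not flag. Self-loops and
    duplicate edges are never created.
    """
    beta = config.target_bias
    rng = rng if rng is not None else config.rng("network")
    tfs = config.tf_ids()
    pool = np.array(tfs + config.target_ids(), dtype=np.int64)
    n_edges = config.n_network_edges if config.n_network_edges is not None else config.n_dtris

    weights = np.array(
        [(i + 1) ** (-config.out_degree_skew) for i in range(len(tfs))]
    )
    weights /= weights.sum()
    out_degrees = rng.multinomial(n_edges, weights)
    mean_degree = n_edges / len(tfs)

    fan_out: dict[int, int] = {}
    chain: list[int] = []  # recently biased multi-target TFs
    edges: set[tuple[int, int]] = set()
    p_attach = beta / (1.0 + beta)
    for tf, d in zip(tfs, out_degrees):
        if d == 0:
            continue
        hub = d > mean_degree
        biased = bool(fan_out) and not hub and rng.random() < p_attach
        placed = 0
        for _ in range(d):
            for _attempt in range(1000):
                target = None
                if biased and placed < 2:
                    recent = [
                        x for x in chain[-2:] if x != tf and (tf, x) not in edges
                    ]
                    if recent:
                        target = recent[-1] if placed == 0 else recent[0]
                    elif fan_out:
                        cand = np.fromiter(fan_out.keys(), dtype=np.int64)
                        w = 1.0 + beta * np.fromiter(fan_out.values(), dtype=float)
                        w /= w.sum()
                        target = int(rng.choice(cand, p=w))
                if target is None or target == tf or (tf, target) in edges:
                    target = int(pool[rng.integers(len(pool))])
                if target != tf and (tf, target) not in edges:
                    break
            else:
                continue  # out-degree quietly dropped if pool exhausted
            if biased and placed < 2:
                placed += 1
            edges.add((tf, target))
            fan_out[tf] = fan_out.get(tf, 0) + 1
        if biased and d >= 2:
            chain.append(tf)
    net = DirectedNetwork.from_edges(edges, allow_self_loops=False)
    truth = {
        "beta": beta,
        "n_edges": net.n_edges,
        "n_nodes": net.n_nodes,
        "chain_length": len(chain),
        "out_degree_sequence": [int(d) for d in out_degrees],
    }
    return net, truth


# ---------------------------------------------------------------------------
# Differential-expression screens

def generate_de_screens(
    config: SimulationConfig,
    target_sets: Sequence[TargetSet],
    rng: np.random.Generator | None = None,
) -> tuple[list[DEResult], dict]:
    """DE screens with a planted fraction of responsive curated targets.

    Each target is responsive with probability ρ times its category's
    effect multiplier; responsive genes draw p ~ Beta(a, 1) (sub-uniform),
    every other gene draws p ~ Uniform(0, 1). The responsive set is shared
    across screens; p-values are resampled per screen, and with probability
    ``screen_noise`` a responsive gene reverts to the uniform background in
    that screen. q-values are Benjamini-Hochberg; fold-change magnitudes
    scale with -log10 p and carry random signs.

    Returns the screens and a ground-truth dict with the responsive genes
    per category and the analytic per-category AUROC expectation inputs.
    """
    rng = rng if rng is not None else config.rng("screens")
    rho, a = config.responsive_fraction, config.signal_shape

    target_genes = sorted({g for ts in target_sets for g in ts.genes})
    universe = np.array(
        sorted(set(range(1, config.universe_size + 1)) | set(target_genes)),
        dtype=np.int64,
    )
    n = len(universe)
    gene_index = {int(g): i for i, g in enumerate(universe)}

    responsive: dict[str, set[int]] = {}
    responsive_all: set[int] = set()
    for ts in target_sets:
        mult = config.category_effect.get(ts.category, 1.0)
        rho_eff = min(1.0, rho * mult)
        picked = {g for g in sorted(ts.genes) if rng.random() < rho_eff}
        responsive[ts.category] = picked
        responsive_all |= picked
    responsive_idx = np.array(
        sorted(gene_index[g] for g in responsive_all), dtype=np.int64
    )

    screens: list[DEResult] = []
    for s in range(config.n_screens):
        p = rng.uniform(0.0, 1.0, size=n)
        if responsive_idx.size:
            keep = rng.random(responsive_idx.size) >= config.screen_noise
            idx = responsive_idx[keep]
            p[idx] = rng.beta(a, 1.0, size=idx.size)
        from statsmodels.stats.multitest import multipletests

        q = multipletests(p, method="fdr_bh")[1]
        signs = rng.choice([-1.0, 1.0], size=n)
        log2fc = signs * 0.5 * (-np.log10(np.clip(p, 1e-300, None)))
        screens.append(
            DEResult(
                genes=universe.copy(),
                log2fc=log2fc,
                pvalue=p,
                qvalue=q,
                label=f"screen{s}",
                tf=target_sets[0].tf if target_sets else None,
            )
        )
    truth = {
        "responsive_fraction": rho,
        "signal_shape": a,
        "screen_noise": config.screen_noise,
        "category_effect": dict(config.category_effect),
        "responsive": {c: sorted(g) for c, g in responsive.items()},
        "universe_size": n,
    }
    return screens, truth


# ---------------------------------------------------------------------------
# Bundle writer

def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete input bundle for the pipeline into a directory.

    Artifacts: experiments.tsv, homology.tsv, ontology_edges.tsv,
    corpus.tsv, popularity.tsv, network_edges.tsv, screens/*.tsv with a
    manifest, and ground_truth.json. Byte-identical under a fixed seed.
    """
    from .aggregate import aggregate_dtris
    from .benchmark import TargetSet as TS

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    homology, dag = generate_fixtures(config)

    with open(outdir / "homology.tsv", "w") as fh:
        homology.to_tsv(fh)
    with open(outdir / "ontology_edges.tsv", "w") as fh:
        dag.to_edgelist_tsv(fh)

    records = generate_experiments(config, homology)
    with open(outdir / "experiments.tsv", "w") as fh:
        write_experiment_table(records, fh)

    corpus = generate_corpus(config)
    with open(outdir / "corpus.tsv", "w") as fh:
        fh.write("tf_entrez\tpubmed_id\tsource\n")
        for tf in sorted(corpus.papers):
            for pmid in sorted(corpus.papers[tf]):
                fh.write(f"{tf}\t{pmid}\t{corpus.source}\n")
    with open(outdir / "popularity.tsv", "w") as fh:
        fh.write("tf_entrez\tpopularity_count\n")
        for tf in sorted(corpus.popularity or {}):
            fh.write(f"{tf}\t{corpus.popularity[tf]}\n")

    net, net_truth = generate_biased_network(config)
    with open(outdir / "network_edges.tsv", "w") as fh:
        net.to_edgelist_tsv(fh)

    # screens for the TF with the most curated targets
    dtris = aggregate_dtris(records, dag)
    per_tf: dict[int, int] = {}
    for d in dtris:
        per_tf[d.tf_human_entrez] = per_tf.get(d.tf_human_entrez, 0) + 1
    focal_tf = max(sorted(per_tf), key=lambda t: per_tf[t])
    from .benchmark import subset_targets

    sets = subset_targets(dtris, focal_tf, "context")
    screens, screen_truth = generate_de_screens(config, sets)
    screen_dir = outdir / "screens"
    screen_dir.mkdir(exist_ok=True)
    with open(outdir / "screen_manifest.tsv", "w") as fh:
        fh.write("dataset_id\ttf_entrez\tlabel\n")
        for s in screens:
            path = screen_dir / f"{s.label}.tsv"
            with open(path, "w") as sf:
                s.to_tsv(sf)
            fh.write(f"{s.label}\t{focal_tf}\t{s.label}\n")

    truth = {
        "seed": config.seed,
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "focal_tf": focal_tf,
        "network": net_truth,
        "screens": screen_truth,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    manifest = {
        "experiments": str(outdir / "experiments.tsv"),
        "homology": str(outdir / "homology.tsv"),
        "ontology": str(outdir / "ontology_edges.tsv"),
        "corpus": str(outdir / "corpus.tsv"),
        "popularity": str(outdir / "popularity.tsv"),
        "network_edges": str(outdir / "network_edges.tsv"),
        "screen_manifest": str(outdir / "screen_manifest.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    return manifest
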