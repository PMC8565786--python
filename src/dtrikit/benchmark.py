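"""Benchmark curated target sets against TF-perturbation expression screens.

A high-throughput TF perturbation screen yields, per gene, a differential-
expression p-value; curated direct targets of the perturbed TF should
concentrate at small p-values. Two complementary enrichment readouts are
computed:

* hit-list overrepresentation — genes passing a Benjamini-Hochberg FDR
  cutoff form the hit list; overlap with the curated target set is tested
  with the upper-tail hypergeometric distribution;
* threshold-free AUROC — targets are compared with non-targets on the
  ranking of nominal p-values; the AUROC is the probability that a curated
  target outranks a non-target (Mann-Whitney U), with a percentile
  bootstrap over the target set for uncertainty.

Multiple screens for one TF are combined into a consensus ranking by
averaging each gene's within-screen midrank over the screens, restricted to
genes measured in all of them. Target sets can be subset by cellular
context (CNS / eye / other, mutually exclusive with CNS precedence) or by
evidence depth (multiple vs a single experiment type).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aggregate import DTRI, ContextCategory

__all__ = [
    "DEResult",
    "Ranking",
    "TargetSet",
    "EnrichmentResult",
    "ConsensusRanking",
    "hit_list",
    "hypergeom_overrep",
    "auroc",
    "bootstrap_auroc_ci",
    "consensus_ranking",
    "subset_targets",
    "benchmark_tf",
    "TargetBenchmark",
    "BenchmarkResults",
]

#: Exact Mann-Whitney enumeration is used up to this many target/non-target
#: comparisons (and only in the absence of ties); beyond it, the normal
#: approximation with continuity and tie corrections.
_EXACT_PAIR_LIMIT = 10_000


@dataclass(frozen=True)
class DEResult:
    """Gene-level differential expression for one screen.

    q-values are Benjamini-Hochberg; when a table lacks them they are
    derived from the nominal p-values.
    """

    genes: np.ndarray  # human Entrez ids, one row per gene
    log2fc: np.ndarray
    pvalue: np.ndarray
    qvalue: np.ndarray
    label: str = "screen"
    tf: int | None = None

    def __post_init__(self) -> None:
        n = len(self.genes)
        if not (len(self.log2fc) == len(self.pvalue) == len(self.qvalue) == n):
            raise ValueError("column lengths differ")
        if len(np.unique(self.genes)) != n:
            raise ValueError("one row per gene required (duplicate gene ids)")
        if np.any((self.pvalue < 0) | (self.pvalue > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def universe(self) -> frozenset[int]:
        return frozenset(int(g) for g in self.genes)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, label: str = "screen", tf: int | None = None
    ) -> "DEResult":
        for col in ("gene_entrez", "log2fc", "pvalue"):
            if col not in df.columns:
                raise ValueError(f"DE table missing column {col!r}")
        pvals = df["pvalue"].to_numpy(dtype=float)
        if "qvalue" in df.columns and not df["qvalue"].isna().any():
            qvals = df["qvalue"].to_numpy(dtype=float)
        else:
            qvals = multipletests(pvals, method="fdr_bh")[1]
        return cls(
            genes=df["gene_entrez"].to_numpy(dtype=np.int64),
            log2fc=df["log2fc"].to_numpy(dtype=float),
            pvalue=pvals,
            qvalue=qvals,
            label=label,
            tf=tf,
        )

    @classmethod
    def from_tsv(
        cls, source: str | IO[str], label: str | None = None, tf: int | None = None
    ) -> "DEResult":
        df = pd.read_csv(source, sep="\t")
        if label is None:
            label = str(getattr(source, "name", source))
        return cls.from_frame(df, label=label, tf=tf)

    def to_tsv(self, sink: IO[str]) -> None:
        pd.DataFrame(
            {
                "gene_entrez": self.genes,
                "log2fc": self.log2fc,
                "pvalue": self.pvalue,
                "qvalue": self.qvalue,
            }
        ).to_csv(sink, sep="\t", index=False)


@dataclass(frozen=True)
class Ranking:
    """Genes ordered by a score where smaller is better (nominal p-values,
    or mean ranks for a consensus), with midranks for ties."""

    genes: np.ndarray
    scores: np.ndarray
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores lengths differ")
        object.__setattr__(self, "ranks", stats.rankdata(self.scores, method="average"))

    @classmethod
    def from_de(cls, de: DEResult) -> "Ranking":
        return cls(genes=np.asarray(de.genes, dtype=np.int64), scores=np.asarray(de.pvalue, dtype=float))

    @property
    def universe(self) -> frozenset[int]:
        return frozenset(int(g) for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class TargetSet:
    """A curated target set for one TF under a category label."""

    tf: int
    genes: frozenset[int]
    category: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"target set {self.category!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one enrichment test (AUROC or hypergeometric)."""

    kind: str
    statistic: float | None = None
    p_value: float | None = None
    ci: tuple[float, float] | None = None
    n_targets_in_universe: int | None = None
    k: int | None = None
    K: int | None = None
    n: int | None = None
    N: int | None = None

    def as_dict(self) -> dict:
        out = {"kind": self.kind}
        for name in ("statistic", "p_value", "n_targets_in_universe", "k", "K", "n", "N"):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        if self.ci is not None:
            out["ci"] = list(self.ci)
        return out


def hit_list(de: DEResult, fdr: float = 0.1) -> frozenset[int]:
    """Genes differentially expressed at the given FDR (q <= fdr)."""
    mask = de.qvalue <= fdr
    return frozenset(int(g) for g in de.genes[mask])


def hypergeom_overrep(
    hits: frozenset[int] | set[int],
    targets: frozenset[int] | set[int],
    universe: frozenset[int] | set[int],
) -> EnrichmentResult:
    """Upper-tail hypergeometric overrepresentation of targets in hits.

    Genes outside the universe are dropped from both sets before testing.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    hits_u = set(hits) & set(universe)
    targets_u = set(targets) & set(universe)
    N, K, n = len(universe), len(targets_u), len(hits_u)
    k = len(hits_u & targets_u)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(kind="hypergeometric", p_value=p, k=k, K=K, n=n, N=N)


def _target_mask(ranking: Ranking, targets: frozenset[int] | set[int]) -> np.ndarray:
    target_arr = np.fromiter((int(t) for t in targets), dtype=np.int64)
    return np.isin(ranking.genes, target_arr)


def _placement_scores(ranking: Ranking, mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-target count of non-targets ranked worse (ties count one half)."""
    target_scores = ranking.scores[mask]
    bg = np.sort(ranking.scores[~mask])
    n_bg = bg.size
    right = np.searchsorted(bg, target_scores, side="right")
    left = np.searchsorted(bg, target_scores, side="left")
    c = (n_bg - right) + 0.5 * (right - left)
    return c, n_bg


def auroc(ranking: Ranking, targets: frozenset[int] | set[int]) -> EnrichmentResult:
    """AUROC of a target set on a p-value ranking (1.0 = every target ahead
    of every non-target), with a two-sided Mann-Whitney U p-value."""
    mask = _target_mask(ranking, targets)
    m = int(mask.sum())
    n_bg = int((~mask).sum())
    if m == 0:
        raise ValueError("no targets present in the ranking universe (0 of "
                         f"{len(targets)})")
    if n_bg == 0:
        raise ValueError("ranking universe contains no non-target genes")
    c, _ = _placement_scores(ranking, mask)
    stat = float(c.sum() / (m * n_bg))

    # smaller score = better rank, so negate for the "greater is enriched" test
    x = -ranking.scores[mask]
    y = -ranking.scores[~mask]
    has_ties = len(np.unique(ranking.scores)) < len(ranking.scores)
    method = "exact" if (m * n_bg <= _EXACT_PAIR_LIMIT and not has_ties) else "asymptotic"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return EnrichmentResult(
        kind="auroc", statistic=stat, p_value=p, n_targets_in_universe=m
    )


def bootstrap_auroc_ci(
    ranking: Ranking,
    targets: frozenset[int] | set[int],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Central percentile bootstrap interval for the AUROC.

    The target set is resampled with replacement at its own size (the
    ranking stays fixed), the AUROC is recomputed per replicate, and the
    (1-level)/2 and 1-(1-level)/2 empirical percentiles are returned.
    """
    mask = _target_mask(ranking, targets)
    m = int(mask.sum())
    if m < 2:
        raise ValueError("bootstrap needs at least two targets in the universe")
    c, n_bg = _placement_scores(ranking, mask)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_boot, m))
    replicates = c[idx].mean(axis=1) / n_bg
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(replicates, [alpha, 1.0 - alpha])
    return float(low), float(high)


@dataclass(frozen=True)
class ConsensusRanking:
    """Mean-of-midranks aggregation across screens, restricted to genes
    measured in every screen."""

    genes: np.ndarray  # final order (ascending mean rank, ties by Entrez id)
    mean_ranks: np.ndarray
    members: tuple[str, ...]

    def to_ranking(self) -> Ranking:
        return Ranking(genes=self.genes, scores=self.mean_ranks)


def consensus_ranking(rankings: Sequence[Ranking]) -> ConsensusRanking:
    """Average each gene's within-screen midrank over the screens.

    Ranks are recomputed within the intersected universe before averaging,
    keeping mean ranks comparable across screens with different universe
    sizes. Genes not measured in every screen are dropped.
    """
    if not rankings:
        raise ValueError("at least one ranking required")
    shared: set[int] = set(rankings[0].universe)
    for r in rankings[1:]:
        shared &= r.universe
    if not shared:
        raise ValueError("the rankings share no genes")
    genes = np.array(sorted(shared), dtype=np.int64)
    rank_sum = np.zeros(len(genes), dtype=float)
    for r in rankings:
        order = {int(g): s for g, s in zip(r.genes, r.scores)}
        scores = np.array([order[int(g)] for g in genes], dtype=float)
        rank_sum += stats.rankdata(scores, method="average")
    mean_ranks = rank_sum / len(rankings)
    # ascending mean rank; ties broken by Entrez id (genes is already sorted)
    final = np.lexsort((genes, mean_ranks))
    labels = tuple(
        getattr(r, "label", f"ranking{i}") for i, r in enumerate(rankings)
    )
    return ConsensusRanking(
        genes=genes[final], mean_ranks=mean_ranks[final], members=labels
    )


def subset_targets(
    dtris: Sequence[DTRI], tf: int, scheme: str = "context"
) -> list[TargetSet]:
    """Partition one TF's curated targets.

    scheme="context": CNS / eye / other via each DTRI's context category
    (mutually exclusive, CNS precedence). scheme="evidence_depth":
    multi_evidence (>= 2 experiment types) vs single_evidence. Empty cells
    of the partition are omitted.
    """
    mine = [d for d in dtris if d.tf_human_entrez == tf]
    if not mine:
        raise ValueError(f"TF {tf} has no curated interactions")
    out: list[TargetSet] = []
    if scheme == "context":
        for category in ContextCategory:
            genes = frozenset(
                d.target_human_entrez for d in mine if d.context_category is category
            )
            if genes:
                out.append(TargetSet(tf=tf, genes=genes, category=category.value))
    elif scheme == "evidence_depth":
        multi = frozenset(
            d.target_human_entrez for d in mine if len(d.evidence_types) >= 2
        )
        single = frozenset(
            d.target_human_entrez for d in mine if len(d.evidence_types) == 1
        )
        if multi:
            out.append(TargetSet(tf=tf, genes=multi, category="multi_evidence"))
        if single:
            out.append(TargetSet(tf=tf, genes=single, category="single_evidence"))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return out


def _all_targets(dtris: Sequence[DTRI], tf: int) -> TargetSet:
    genes = frozenset(
        d.target_human_entrez for d in dtris if d.tf_human_entrez == tf
    )
    if not genes:
        raise ValueError(f"TF {tf} has no curated interactions")
    return TargetSet(tf=tf, genes=genes, category="all")


class TargetBenchmark:
    """Enrichment of curated target sets in perturbation screens for one TF.

    Built from the aggregated DTRI collection and one or more DE screens for
    the same TF; :meth:`fit` evaluates the full target set plus the context
    and evidence-depth subsets on the (consensus) p-value ranking.
    """

    def __init__(self, dtris: Sequence[DTRI], screens: Sequence[DEResult], tf: int):
        if not screens:
            raise ValueError("at least one screen required")
        self.dtris = list(dtris)
        self.screens = list(screens)
        self.tf = tf

    def fit(
        self,
        min_targets: int = 10,
        fdr: float = 0.1,
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> "BenchmarkResults":
        consensus = None
        if len(self.screens) > 1:
            consensus = consensus_ranking(
                [Ranking.from_de(s) for s in self.screens]
            )
            ranking = consensus.to_ranking()
        else:
            ranking = Ranking.from_de(self.screens[0])

        target_sets = [_all_targets(self.dtris, self.tf)]
        target_sets += subset_targets(self.dtris, self.tf, "context")
        target_sets += subset_targets(self.dtris, self.tf, "evidence_depth")

        hit_lists = {s.label: hit_list(s, fdr) for s in self.screens}
        rng = np.random.default_rng(seed)
        entries: dict[str, dict] = {}
        for ts in target_sets:
            in_universe = ts.genes & ranking.universe
            n_dropped = len(ts.genes) - len(in_universe)
            entry: dict = {
                "category": ts.category,
                "n_targets": len(ts.genes),
                "n_in_universe": len(in_universe),
                "n_dropped": n_dropped,
            }
            if len(in_universe) < min_targets:
                entry["skipped"] = True
                entries[ts.category] = entry
                continue
            entry["skipped"] = False
            roc = auroc(ranking, in_universe)
            ci = bootstrap_auroc_ci(
                ranking, in_universe, n_boot=n_boot, level=0.95, seed=rng
            )
            entry["auroc"] = roc.statistic
            entry["auroc_p"] = roc.p_value
            entry["ci"] = ci
            entry["hypergeom"] = {
                s.label: hypergeom_overrep(
                    hit_lists[s.label], ts.genes, s.universe
                ).as_dict()
                for s in self.screens
            }
            entries[ts.category] = entry
        return BenchmarkResults(
            model=self,
            entries=entries,
            consensus=consensus,
            params={
                "min_targets": min_targets,
                "fdr": fdr,
                "n_boot": n_boot,
                "seed": seed,
            },
        )


@dataclass
class BenchmarkResults:
    """Per-category enrichment for one TF's curated targets."""

    model: TargetBenchmark
    entries: dict[str, dict]
    consensus: ConsensusRanking | None
    params: dict

    def summary(self) -> pd.DataFrame:
        rows = []
        for category, e in self.entries.items():
            row = {
                "category": category,
                "n_in_universe": e["n_in_universe"],
                "skipped": e["skipped"],
                "auroc": e.get("auroc"),
                "auroc_p": e.get("auroc_p"),
                "ci_low": e["ci"][0] if "ci" in e else None,
                "ci_high": e["ci"][1] if "ci" in e else None,
            }
            rows.append(row)
        return pd.DataFrame(rows).set_index("category")

    def to_report(self) -> dict:
        return {
            "tf": self.model.tf,
            "screens": [s.label for s in self.model.screens],
            "consensus": (
                None
                if self.consensus is None
                else {
                    "members": list(self.consensus.members),
                    "n_genes": int(len(self.consensus.genes)),
                }
            ),
            "params": self.params,
            "target_sets": self.entries,
        }

    def plot(self, ax=None):
        """AUROC point estimates with bootstrap intervals per category."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        cats = [c for c, e in self.entries.items() if not e["skipped"]]
        vals = [self.entries[c]["auroc"] for c in cats]
        los = [self.entries[c]["ci"][0] for c in cats]
        his = [self.entries[c]["ci"][1] for c in cats]
        y = np.arange(len(cats))
        ax.errorbar(
            vals, y,
            xerr=[np.array(vals) - np.array(los), np.array(his) - np.array(vals)],
            fmt="o",
        )
        ax.axvline(0.5, ls=":", color="0.5")
        ax.set_yticks(y, cats)
        ax.set_xlabel("AUROC")
        return ax


def benchmark_tf(
    dtris: Sequence[DTRI],
    screens: Sequence[DEResult],
    tf: int,
    min_targets: int = 10,
    fdr: float = 0.1,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Functional entry point; see :class:`TargetBenchmark`."""
    return (
        TargetBenchmark(dtris, screens, tf)
        .fit(min_targets=min_targets, fdr=fdr, n_boot=n_boot, seed=seed)
        .to_report()
    )
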