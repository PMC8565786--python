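"""Coverage and overlap statistics over TF -> candidate-paper corpora.

Literature-curated interaction resources assemble, for each transcription
factor, the set of publications that may report supporting experiments. The
distribution of papers over TFs is heavily skewed toward a few well-studied
genes; the statistics here quantify that skew (top-k coverage), the
concordance of "top TF" sets across corpora (Jaccard), the asymmetric
sharing of papers between resources, and the association between a TF's
overall PubMed popularity and its candidate-paper count (Spearman).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "CandidateCorpus",
    "coverage_topk",
    "jaccard",
    "pairwise_overlap_fraction",
    "popularity_correlation",
]


@dataclass(frozen=True)
class CandidateCorpus:
    """TF (human Entrez) -> candidate-paper (PubMed id) assignments.

    A paper may be assigned to more than one TF. Popularity counts, when
    present, are the total number of PubMed papers mentioning the TF symbol
    regardless of relevance to regulation.
    """

    source: str
    papers: Mapping[int, frozenset[int]]
    popularity: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        for tf, pmids in self.papers.items():
            for p in pmids:
                if p <= 0:
                    raise ValueError(f"TF {tf}: paper id {p} is not a positive integer")

    @property
    def all_papers(self) -> frozenset[int]:
        out: set[int] = set()
        for pmids in self.papers.values():
            out |= pmids
        return frozenset(out)

    @classmethod
    def from_tsv(
        cls,
        source: str | IO[str],
        popularity_source: str | IO[str] | None = None,
        label: str | None = None,
    ) -> "CandidateCorpus":
        """Read assignment TSV (tf_entrez, pubmed_id, source) and optional
        popularity TSV (tf_entrez, popularity_count)."""
        df = pd.read_csv(source, sep="\t")
        for col in ("tf_entrez", "pubmed_id"):
            if col not in df.columns:
                raise ValueError(f"corpus table missing column {col!r}")
        papers: dict[int, set[int]] = {}
        for row in df.itertuples(index=False):
            papers.setdefault(int(row.tf_entrez), set()).add(int(row.pubmed_id))
        popularity = None
        if popularity_source is not None:
            pop = pd.read_csv(popularity_source, sep="\t")
            popularity = {
                int(r.tf_entrez): int(r.popularity_count)
                for r in pop.itertuples(index=False)
            }
        if label is None:
            label = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "corpus"
        return cls(
            source=label,
            papers={tf: frozenset(p) for tf, p in papers.items()},
            popularity=popularity,
        )


def coverage_topk(
    corpus: CandidateCorpus, fraction: float = 0.9
) -> tuple[int, list[int]]:
    """Smallest number of top TFs whose pooled papers cover the corpus.

    TFs are ordered by descending paper-set size (ties broken by ascending
    Entrez id); k is the shortest prefix whose union of paper sets covers at
    least ``fraction`` of the corpus's distinct papers. Coverage is counted
    on distinct papers (union), not summed TF-paper assignments. Returns
    (k, the prefix of TFs).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not corpus.papers or not corpus.all_papers:
        raise ValueError("corpus has no paper assignments")
    order = sorted(corpus.papers, key=lambda tf: (-len(corpus.papers[tf]), tf))
    needed = fraction * len(corpus.all_papers)
    covered: set[int] = set()
    for k, tf in enumerate(order, start=1):
        covered |= corpus.papers[tf]
        if len(covered) >= needed:
            return k, order[:k]
    return len(order), order  # fraction of an unreachable total cannot occur


def jaccard(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """|A ∩ B| / |A ∪ B|, defined as 0 when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


def pairwise_overlap_fraction(
    source: CandidateCorpus, target: CandidateCorpus
) -> float:
    """Fraction of the target corpus's papers also present in the source.

    Asymmetric by construction: a large resource can contain most of a small
    one while the small one holds only a sliver of the large one.
    """
    source_papers = source.all_papers
    target_papers = target.all_papers
    if not source_papers or not target_papers:
        raise ValueError("both corpora must be nonempty")
    return len(source_papers & target_papers) / len(target_papers)


def popularity_correlation(corpus: CandidateCorpus) -> float:
    """Spearman rank correlation between per-TF candidate-paper counts and
    overall PubMed popularity counts (midranks for ties)."""
    if corpus.popularity is None:
        raise ValueError("corpus carries no popularity counts")
    tfs = [tf for tf in corpus.papers if tf in corpus.popularity]
    if len(tfs) < 3:
        raise ValueError(
            f"popularity correlation needs >=3 paired observations, got {len(tfs)}"
        )
    candidate = [len(corpus.papers[tf]) for tf in tfs]
    popularity = [corpus.popularity[tf] for tf in tfs]
    rho, _ = stats.spearmanr(candidate, popularity)
    return float(rho)
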