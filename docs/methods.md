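# Methods

## The data model

A curated resource of direct transcriptional regulatory interactions
(DTRIs) is modelled at the level of the individual low-throughput
experiment. Each record carries: the TF and target gene (Entrez IDs with
species), the experiment type (TF perturbation, TF–DNA binding, or
TF-reporter) with a type-specific detail block, the cellular context
(immortalized cell line, primary tissue or cells, or in-vitro — the latter
reserved for EMSA binding reactions), an ontology term for the context
(UBERON/CL/CLO/BTO/EFO namespaces; verbatim free text is stored under a
`freetext` tag and never matched by ontology queries), a developmental
stage where applicable, the mode of regulation (activation, repression, or
unreported), and the TFBS position as a signed base-pair offset from the
target TSS and/or a promoter flag.

Validation is two-layered: controlled vocabularies reject unknown
categorical values outright (no coercion), and structural invariants tie
detail blocks to experiment types (exactly one block, matching the type;
EMSA-only fields require the EMSA method; mutation-verification requires a
mutated construct). Violations are returned as data by `validate_record`;
the table reader raises on the first invalid row with its row number.

**Ortholog mapping.** Genes are reported on human identifiers. Human genes
map to themselves; mouse genes map through a homology table (one human id
per source gene); a mouse gene without an ortholog passes through under
its own Entrez ID with an `unmapped` flag rather than being dropped, so no
evidence is silently lost. Mapping is idempotent.

**Aggregation.** A DTRI is a unique (human TF, human target) pair. Pooling
its experiments: evidence types take union semantics; the mode resolves to
`both` only when activation and repression are both reported (unreported
experiments are ignored unless they are all there is); TFBS position
resolves analogously with a `both` class; species support counts only
same-species experiments, so a pair supported exclusively by
cross-species designs (mouse TF on a human construct, say) is `mixed_only`.
Context stratification requires *primary* tissue or cells: a neural cell
line never counts as CNS evidence. CNS and eye category membership is a
descendant query against UBERON:0001017 and UBERON:0000970 in an is_a
edge-list DAG, with CNS taking precedence so the categories partition the
targets. Embryonic stages are recognized by a configurable label set
(default: `E`+digits murine day notation, or labels containing
"embryo"/"fetal") — no stage grammar exists in the wild, so this is a
pragmatic filter.

**Literature extrapolation.** With `n_pos` of `n_examined` papers positive
and a mean of `m` DTRIs per positive paper, `C` remaining candidate papers
project `(n_pos/n_examined)·C` positive papers and that times `m`
interactions; multiplying by the observed triple-evidence and CNS
fractions subsets the projection. Projections are reported unrounded; the
mean uses only papers contributing at least one DTRI. The captured-CNS
fraction is `current / (current + projected)` and needs the current count
as an extra argument.

## Network connectivity against a rewiring null

The DTRI network is a simple directed graph (self-loops allowed in
observed data — autoregulation is real). Three connectivity statistics:

* **reachable pairs** — ordered pairs (u, v), u ≠ v, with a directed path;
  a self-loop does not make a node reachable from itself;
* **cliques** — all complete subgraphs of ≥ 3 nodes in the undirected
  projection (self-loops removed, reciprocal edges merged); *all* cliques,
  not only maximal ones, which is the graph-library counting convention;
* **weak components** of the undirected projection.

The null fixes every node's in- and out-degree and randomizes everything
else: pairwise edge swaps (a→b, c→d) ⇒ (a→d, c→b), rejecting swaps that
would create a self-loop or duplicate edge, with `swap_multiplier × m`
attempted swaps per permutation (default 10; the sampler provably reaches
every simple degree-compatible configuration on small fixtures, which the
test suite checks by exhaustive enumeration). One-tailed empirical
p-values use the add-one rule `(r+1)/(n+1)` with ties counted as extreme,
so p is never zero and "p < 0.01 at 1,000 permutations" is the attainable
floor. Excess connectivity means: more reachable pairs (tail `greater`),
more cliques (`greater`), fewer components (`less`).

## Benchmarking against perturbation screens

A screen is a per-gene table of log2 fold change, nominal p-value and
Benjamini-Hochberg q-value (derived from the p-values when absent). Hit
lists use q ≤ FDR with FDR = 0.1 by default. Overrepresentation of a
curated target set in the hit list is the upper-tail hypergeometric
probability P(X ≥ k) with the screen's full gene table as the universe;
genes outside the universe are dropped (and counted) first.

The threshold-free statistic is the AUROC of targets versus non-targets on
the ascending nominal-p ranking — the probability that a curated target
outranks a non-target, ties counting one half — computed from per-target
placement counts and identical to the normalized Mann-Whitney U. The
two-sided p-value comes from `scipy.stats.mannwhitneyu`, exact when
m·n ≤ 10,000 and tie-free, otherwise the normal approximation with
continuity and tie corrections. Uncertainty is a central percentile
bootstrap (default 95%, 1,000 replicates) resampling the *target set* with
replacement at its own size while the ranking stays fixed; precomputed
placement counts make each replicate O(m).

Multiple screens for one TF are combined by consensus ranking: restrict to
genes measured in every screen, recompute midranks within the restricted
universe (so mean ranks are comparable across screens of different sizes —
the order of restriction and averaging is a genuine design choice),
average, and re-rank ascending with Entrez-id tie-break. Target sets are
the full curated set plus the context partition (CNS / eye / other) and
the evidence-depth partition (≥ 2 types vs single type); sets with fewer
than `min_targets` (default 10) genes in the universe are reported as
skipped, not tested.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with ground
truth. Defaults are the study-scale conditions: 251 TFs, 825 targets,
1,499 interactions; evidence-combination mixture with 27% triple and 64%
multi-type; context shares ≈ 60% cell line / 26% primary / 13% in-vitro
(EMSA fraction of binding 0.32); repressive fraction 0.24 of
mode-annotated pairs; 44% of pairs position-annotated, 91% of those
proximal; species mixture 33% human-only / 53% mouse-only / 14% both; 1.9
interactions per positive paper; 5% of mouse genes without orthologs.

**Corpora.** Per-TF candidate-paper counts follow a rank-size power law
(Poisson around `scale · rank^-s`), with a forced zero-paper fraction
(default 0.34) plus natural zeros in the deep tail; under the default
s = 1.0, scale = 150 roughly half the TFs end up without papers, which is
the regime the skew statistics are meant to exercise. Popularity counts
are the candidate counts under multiplicative lognormal noise; at zero
noise the rank correlation is exactly 1.

**Screens.** A fraction ρ (default 0.7) of each target category is
responsive, scaled by a per-category effect multiplier (defaults CNS 1.0,
eye 0.7, other 0.2); responsive genes draw p ~ Beta(a, 1) with a = 0.1,
all others Uniform(0, 1). The responsive set is shared across screens;
each screen resamples p-values and reverts each responsive gene to
background with probability `screen_noise` (default 0.1). The implied
AUROC has the closed form `q/(a+1) + (1−q)/2` with
`q = ρ·multiplier·(1−noise)`, which the tests use as an independent
oracle. Fold changes are decorative (sign random, magnitude ∝ −log10 p).

**Biased networks.** The bias mechanism models investigators following the
recent literature rather than sampling genes at random. Out-degrees follow
a rank-size law (exponent 0.75 — the top TF holds a few percent of all
edges, not a quarter). With probability β/(1+β) a below-average-fan-out TF
is "biased": its first two edges go to the two most recently biased
multi-target TFs (falling back to an established regulator weighted by
fan-out while that chain is empty) and its remaining edges explore genes
uniformly; high-fan-out TFs always explore. This single rule produces all
three connectivity excesses at once — guaranteed triangles among
low-degree regulators (which random rewiring cannot reassemble), deep
regulatory cascades (each chain member reaches everything downstream), and
gluing of small TFs to the core (while the rewired null strands their
single edges on singleton targets). At β = 0 the rule vanishes and the
graph is a uniform draw given its degrees, so the permutation test stays
calibrated. A degree-proportional preferential-attachment rule was tried
first and rejected: whatever it adds is largely a property of the degree
sequence, which the null preserves, and the in-degree it piles onto hubs
hands the *null* a dense core of free triangles.

The bias-*detection* design used in the tests and the acceptance script —
120 TFs, an 850-gene fresh-target pool, 420 edges, β ∈ {0, 9}, 200
permutations, 20 replicates — was fixed by a prior power analysis: at
these sizes all three metrics are simultaneously significant (p ≤ 0.05) in
about 97% of strongly biased replicates while the unbiased configuration
yields p-values centered near 0.5.

**What the generator does not emulate.** Real curation noise (identifier
errors, ambiguous assays), correlated evidence within papers, realistic
microarray error structure, sequence-level binding sites, and the
long-tailed co-citation structure of real corpora. Passing tests therefore
demonstrate that the statistical machinery recovers planted structure
under the stated generative model, not that the model captures every
property of real curation data.

## Numerical and interface choices

* The 2 kb proximal boundary is inclusive; only the recorded (closer) end
  of a TFBS is classified; classification is symmetric in sign.
* Tables are UTF-8 TSV with `NA` for absent values; reports are JSON; no
  binary formats anywhere.
* Midranks everywhere for ties; Entrez-id tie-breaks for deterministic
  orderings; aggregation output sorted by (TF, target).
* All randomness flows through `numpy` Generators; module-level seeds are
  derived from a single seed via SHA-256 substreams, so stages are
  independently reproducible.
* Problem sizes in the test suite (universes of 2,000–10,000 genes, target
  sets of 30–300, 200–500 permutations, 20 replicates) are chosen so each
  Monte-Carlo assertion sits several standard errors from its threshold.

## Known limitations

* The curated collection's own published counts can only be reproduced
  with the deposited supplementary tables; the corresponding acceptance
  checks look for them under `data/curated/` and fail informatively when
  absent. The machinery they exercise is covered by oracle-checked tests
  on synthetic data.
* Weighting or scoring of evidence quality is deliberately out of scope:
  the model records categorical attributes and leaves confidence
  assessment to the user.
* The hypergeometric universe is always the screen's gene table as
  provided; no attempt is made to reconstruct pre-filter array universes.
* Consensus ranking drops genes not measured in every screen, which can
  shrink the universe considerably when screens use different platforms.
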