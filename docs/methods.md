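# Methods

This document records the statistical model, numerical conventions and
parameter choices behind the TF-degradation prioritization workflow.

## 1. Evidence tables

Curated literature evidence is a TSV with columns
`drug  target  level  effect  context  source`. Rows are validated
(controlled vocabularies for drug ∈ {thalidomide, lenalidomide,
pomalidomide}, level ∈ {gene, protein}, effect), exact duplicates are
dropped and malformed rows are collected with their line numbers rather
than aborting the parse. Summaries report counts by drug and by level,
distinct targets, targets replicated in ≥ 2 independent sources, and the
gene/protein target overlap.

**Percentages** are reported to one decimal using exact decimal arithmetic
with round-half-even (banker's rounding): `pct = Decimal(num)·100/Decimal(den)`
quantized to 0.1. E.g. 253/407 → 62.2 %.

## 2. Differential expression and vote counting

`call_de_simple` performs a per-gene Welch t-test (unequal variances)
between case and control columns, vectorized over genes; genes with zero
variance in both groups get p = 1 and a `zero_variance` flag. Multiple
testing uses Benjamini–Hochberg (`statsmodels` `fdr_bh`), which the test
suite verifies against the step-up definition.

A gene is **significant** in a dataset when |log2FC| > 1 **and**
p_adj < 0.05 — both inequalities strict, so boundary values (logFC
exactly 1, p_adj exactly 0.05) do not pass. The **frequency score** s(g)
counts the datasets in which g is significant. The **dual-evidence filter**
keeps g when s(g) ≥ 2, or s(g) = 1 and g is a gene-level literature target;
literature genes with s = 0 are ruled out. Symbols are canonicalized
(trimmed, upper-cased) on both sides before matching.

## 3. Enrichment statistics

- **Hypergeometric upper tail**: P(X ≥ k) for k overlaps between a query of
  size n and a set of size K in a universe of size N, computed as
  `scipy.stats.hypergeom.sf(k−1, N, K, n)`.
- **ORA**: one tail test per gene set, BH correction across sets, default
  universe = union of set members and query (an explicit universe is
  recommended and any query symbol outside it is an error, named in the
  message).
- **Regulon screen** (TF prioritization): each TF's regulon is intersected
  with the query; TFs with zero overlap are excluded, and the *selection*
  rule is raw p < 0.05 (strict). A BH-adjusted column is reported alongside
  for transparency, but selection deliberately follows the raw-p convention
  of regulon screens, where the candidate list is a hypothesis-generating
  set later subjected to orthogonal filters. Results are ordered by overlap
  k (descending), then p (ascending), then TF symbol.
- **GSEA** on the vote-count metric: genes are ranked by score descending
  with ties broken alphabetically (deterministic; `tie_shuffle=True`
  randomizes tie order under the seed instead). The running statistic
  increments by score^weight (normalized over hit mass) on hits and
  decrements uniformly on misses; ES is the maximum-magnitude excursion.
  With weight = 0 this reduces to the classical signed Kolmogorov–Smirnov
  statistic. Significance comes from gene-label permutations:
  p = (1 + #{|ES_perm| ≥ |ES|, same sign})/(1 + n_perm), and
  NES = ES / mean |ES_perm| over same-sign permutations. n_perm ≥ 100 is
  enforced. Sets that cover the whole universe, have no ranked members, or
  carry zero hit mass are skipped with a warning.

## 4. Network topology

Interaction edges carry confidence scores in [0, 1]; files using the
integer 0–999 convention are detected (any score > 1) and divided by 1000.
Edges are kept when score **>** threshold (strict; default 0.400), and
duplicate unordered pairs are merged keeping the maximum score. Analysis
restricts to the largest connected component (ties broken by
lexicographically smallest node set).

Four centralities per node:

- **degree** — number of neighbors;
- **closeness** — *harmonic* centrality, Σ 1/d(u,v), which is well defined
  on disconnected remainders;
- **betweenness** — fraction-of-shortest-paths sums over **ordered** pairs
  (s, t), s ≠ v ≠ t; for undirected graphs this is exactly twice the
  conventional unordered value (networkx `normalized=False` ×2);
- **MCC** (Maximal Clique Centrality) — Σ over maximal cliques C containing
  v of (|C|−1)!, computed from Bron–Kerbosch maximal-clique enumeration with
  a configurable budget (default 10⁶ cliques; exceeding it raises
  `CliqueBudgetExceeded` rather than returning a truncated value).

Ranks are **dense** (ties share a rank, no gaps), best = 1. A node is
**essential** when it has rank 1 on all four metrics simultaneously — a
deliberately conservative consensus rule; the report also lists the top-k
per metric. Clustering coefficient is the mean *local* coefficient with
degree < 2 nodes contributing 0; graph transitivity is reported alongside.
Average neighbors = 2E/N. GraphML export sets node size = 10 × MCC.

## 5. Candidate classification and the development filter

Let L = protein-level literature targets, T = enriched TFs, Z = C2H2
zinc-finger TFs. The three-set Venn partition classifies each enriched TF:
T∩Z∩L → `known_C2H2`, T∩L∖Z → `known_nonC2H2`, T∩Z∖L → `novel_C2H2`
(the discovery class), T only → `other`.

The **embryonic-development filter** runs ORA of the candidate TF set
against development gene sets and retains candidates that are members of at
least one BH-significant set. The ORA background is the full annotated TF
list (∪ candidates ∪ set members), not merely the candidates: the question
is whether development annotations concentrate among candidates relative to
TFs at large, and a candidates-only background would make the test
powerless. With no development sets supplied the filter is skipped with a
warning.

The final report orders candidates by class priority
(`known_C2H2` < `novel_C2H2` < `known_nonC2H2` < `other`), then regulon
overlap descending, and annotates each TF's centrality ranks and
essentiality (`both` / `before` / `after` augmentation).

## 6. Synthetic scenario generator

`ScenarioParams` defaults (all validated):

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 2000 | enough background for stable BH behavior, fast tests |
| `n_tfs` | 60 | realistic regulon-database scale relative to `n_genes` |
| `n_degraded_tfs` | 3 | small planted signal, mirrors a focused degrome |
| `n_datasets` | 8 | supports vote counts up to 8; ≥2 needed for the filter |
| `n_case`/`n_control` | 6/6 | typical GEO-series arm sizes; Welch t-test stable |
| `effect_lfc` | 2.0 | clearly above the strict lfc > 1 threshold |
| `detect_prob` | 0.6 | per-dataset response probability; makes vote counts informative rather than saturated |
| `noise_sd` | 0.5 | σ of expression noise; p-values neither trivial nor hopeless |
| `regulon_exponent` | 2.5 | truncated power-law regulon sizes, heavy-tailed like curated databases |
| `regulon_min/max_size` | 10/120 | keeps hypergeometric tests well-posed |
| `ppi_edge_prob` | 0.08 | sparse background interaction network |
| `c2h2_fraction` | 0.4 | minority class, so the Venn partition is non-trivial |
| `lit_coverage` | 0.3 | partial literature coverage exercises the s=1 clause |
| `n_lit_proteins` | 25 | protein-level set L for the network and Venn |

Determinism: all randomness flows from
`numpy.random.SeedSequence(seed).spawn()` substreams, one per concern
(regulons, annotations, expression, evidence, network, gmt), so changing
one component's draws cannot perturb another's.

Planted structure:

- the planted TFs are forced C2H2 and excluded from the protein-level
  literature set, so correct recovery lands in `novel_C2H2`;
- the first planted TF is forced to own the uniquely largest regulon, so
  the top of the final report is predictable;
- a designated hub is attached to (max other degree + 3) partners — the +3
  margin keeps the hub at least two edges ahead even after each partner
  gains the one incident edge from the attachment itself — making it the
  unique essential node;
- development sets contain the planted TFs plus a few extras, and a
  housekeeping control set contains none.

What the generator emulates: multi-dataset DE with partial penetrance,
heavy-tailed regulons, partial literature coverage, a dominant network hub,
ontology sets with a planted signal. What it does **not** emulate:
correlated genes, batch effects, dataset-specific platforms, directionality
of regulation, or realistic interaction-network topology beyond
density + hub.

Ground-truth recovery metrics: precision and recall of the predicted
`novel_C2H2` set against the planted TFs (precision is `None` for an empty
prediction).

## 7. Limitations

- The regulon screen's raw-p selection is intentionally liberal; the BH
  column should be consulted when the TF database is large.
- MCC is exponential in the worst case; the clique budget makes failure
  explicit instead of silent.
- The Welch test assumes approximate normality per gene; the generator
  satisfies this by construction, real data may not.
- Essentiality by simultaneous rank-1 consensus can be empty on graphs with
  no dominant node; the per-metric top-k lists remain informative there.
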