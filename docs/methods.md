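# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic data model, and the design decisions taken where
the problem left room for judgement.

## Knowledge-graph construction

The base graph is assembled from two reference inputs. Cell-type terms and
their `IS_A` hierarchy come from an OBO ontology; obsolete terms are dropped
at load because they cannot be annotation targets, and only `is_a` relations
are imported (`part_of` and other typedefs are ignored — the hierarchy is
the only ontology relation the annotation procedure consumes). Synonyms are
taken from the ontology's synonym lines only. Pathways come from GMT files;
duplicate genes within a line are collapsed, and gene symbols are matched
case-sensitively after whitespace stripping so joins between GMT, expression
and marker files are deterministic.

Storage is in-memory with per-relation adjacency indexes (forward and
reverse), which keeps candidate-centred retrieval proportional to the
candidates' neighbourhoods rather than the graph size. Graphs serialize to
GraphML or a two-file TSV pair (`nodes.tsv`, `edges.tsv` with JSON-encoded
edge attributes); round-trips are exact on nodes, edges, relations and
attributes. A graph-database adapter would satisfy the same retrieval
contracts but is not included: nothing in the library or its tests requires
a server.

## Dataset edge inference

**Normalization.** Counts are scaled per cell to a common total (default
10,000) and transformed with log1p. The recipe is the standard library-size
normalization for UMI data; the target sum only shifts the log values by a
constant per cell and does not affect correlations or ranks.

**Co-expression (`COEXPRESSED_IN`).** Within each cell-type label with ≥ 3
cells, all unordered gene pairs are tested with the Pearson correlation;
p-values use the two-sided t-transform with n − 2 degrees of freedom.
Benjamini–Hochberg adjustment is applied within each label's family of
testable pairs (constant genes are excluded, with a logged count). An edge
is accepted iff |r| > 0.8 and FDR < 0.05; its attributes record r, the
adjusted p and the context cell type. Per-label families were chosen over a
pooled family because the relation is defined within a cell type; pooling
would couple unrelated contexts' multiplicity burdens. The joint gate means
the |r| threshold, not significance, is binding at realistic cell counts.

**Pathway activity (`HAS_ACTIVITY_IN`).** Activity is scored per cell as the
discrete area under the recovery curve: genes are ranked from high to low
expression, the recovery fraction of the gene set is summed over ranks
1..T, and the sum is divided by the maximum attainable area for the set
size and threshold so scores live in [0, 1] (the normalization is
configurable off; the unnormalized integral is also exposed). T defaults to
the top 5% of the gene universe, rounded up. Ranking ties break by
descending expression then ascending gene symbol — a seed-free rule chosen
over randomized tie-breaking so that identical inputs always produce
identical scores. Edges are gated by a one-sided (greater) Wilcoxon
rank-sum test of the target label's scores against all remaining cells,
BH-corrected across the full (pathway × label) family, plus a strictly
positive median gap. One-vs-rest was chosen over all pairwise comparisons
because the claim being tested is "elevated relative to the remaining
cells", and it keeps the test family linear rather than quadratic in the
number of labels.

## Retrieval

Stage-2 evidence is collected per candidate: one level of ontology context
(direct parents and children), marker → pathway → cell-type chains, and
marker pairs co-expressed in the candidate's lineage. Both chain endpoints
and co-expression contexts are scoped to the candidate's *inclusive IS_A
closure*: activity inferred at subtype resolution still supports the
major-type hypothesis, and restricting to the candidate term alone would
discard exactly the evidence the subtype stage later relies on.
`IS_MARKER_FOR` edges are modelled but excluded from bundles unless
explicitly enabled: direct marker assertions tend to dominate a decision
rule by sheer count while carrying no functional context, so they are an
opt-in ablation lever rather than a default signal.

Stage-3 retrieval restricts to the confirmed major type and its descendants.
Candidate subtypes are the domain members reached by a marker chain;
retained edges are the in-domain IS_A edges, the activity edges landing in
the domain from marker-linked pathways, and the membership edges from
markers into those pathways. Co-expression edges are excluded by
construction — they are dense and unspecific, and their absence is what
keeps the focused domain orders of magnitude smaller than the full graph.
Candidate names resolve by exact id, then exact name, then case-insensitive
name/synonym; ambiguity is an error listing all matches.

Evidence renders to deterministic, stable-ordered key:value text blocks
(candidates in input order, links sorted by marker then pathway) so prompts
are reproducible and token-frugal.

## Annotation pipeline

All three stages demand structured JSON responses with up to 2 retries on a
malformed reply; prose-only replies are not testable. Stage-2 decisions must
come from the stage-1 candidate list (strict mode, the default) because
closure violations are precisely the over-extrapolation failure mode the
arbitration exists to prevent; a lenient mode accepts with a warning. Every
emitted ontology id must match the `PREFIX:digits` format, and an id that
exists in the graph under a different name is rejected (strict) or corrected
to the graph name (lenient) — the guard against hallucinated ids.

Mixtures carry at most two components. Each component is subtyped
independently: the markers with pathway chains into the component's lineage
are kept, and the other component's supporting markers are flagged as
background in the prompt.

Defaults: k = 3 candidates, 10 markers, temperature 0.5, batch size 4,
4 workers (a CI-friendly default; the worker count changes throughput only —
results are sorted by cluster id and byte-identical at any worker count).
Per-cluster failures are isolated into an error manifest rather than
aborting the run. With `explain=false` the reasoning and evidence fields are
stripped; labels are unchanged.

**Mock backend.** The offline backend is a pure function of its inputs:
stage 1 answers from a rulebook keyed on the order-insensitive marker-set
fingerprint; stage 2 takes the argmax over (pathway-link count,
co-expression support, better stage-1 rank), declaring a mixture when the
mixture hint is set and ≥ 2 candidates have positive pathway support;
stage 3 takes the argmax over (marker-chain count, hierarchy depth,
lexicographically smaller id). The rules emulate an evidence-following
arbiter, which is the behaviour the pipeline contracts assume; they are not
a model of any particular language model's reasoning. Remote
chat-completion backends satisfy the same `complete(payload, temperature,
seed)` contract but are outside the test surface.

## Agreement scoring

Precedence is fully > partially > mismatch. "Fully" covers the identical
term and exact ontology synonyms. "Partially" covers siblings sharing a
direct parent and direct parent–child pairs: a one-level generalization
(e.g. truth "pre-B cell", prediction "B cell") loses half credit rather
than all of it. Anything else scores 0.0 by default; a configuration flag
(`distant_same_lineage_partial`) instead grants 0.5 to more distant
relations within the same major lineage, for users who prefer a more
permissive reading. Major lineages are a configurable term set defaulting
to the direct children of the ontology root; each term resolves to its
nearest ancestor (inclusive) in that set. Unresolvable predictions are
mismatches, not errors, so a hallucinated label can never abort an
evaluation; an unresolvable truth is an input error. Cohen's d uses the
paired-differences formulation d_z = mean(a−b)/sd(a−b) with the sample
standard deviation; differences constant up to float rounding leave d
undefined and the p-value omitted.

## Synthetic data model

The generator exists so every pipeline contract can be exercised offline
with known ground truth. Baseline counts are negative-binomial
(mean 20, shape 2 by default) — a standard over-dispersed model for UMI
data. Planted co-expression draws a shared standard-normal latent per cell
and gives each pair gene the rate `pair_mean · exp(σ(√ρ·z + √(1−ρ)·ε))`
with Poisson observation noise (mean 80, σ = 1 by default). Poisson noise
and library-size normalization attenuate the realized log-scale correlation
slightly below the latent ρ, so the mixing weight is inflated by a fixed
correction (ρ_latent = target/0.97, capped at 0.99), calibrated once
against the generator itself; with that correction the empirical r of a
pair planted at 0.95 stays within ±0.05 of target at n = 100 cells. Targets
above 0.99 are rejected as infeasible. Planted pathway activity multiplies
the member genes' means (×8 by default) in the target label's cells, which
shifts the median AUCell score by several null standard deviations.

What the generator does *not* model: batch effects, dropout beyond NB
dispersion, library-size variation, correlated background genes, or
realistic marker redundancy. Passing tests therefore demonstrate that the
inference machinery recovers signals of the planted form at the stated
strengths — not that the thresholds are optimal for any particular tissue
or platform.

The canonical fixture world plants eight immune/stromal lineages (each with
a 12-gene pathway active in its truth type, a co-expressed marker pair in
its own label, and a rulebook entry proposing the true lineage first with
two evidence-free distractors) plus a ninth cluster mixing T- and B-cell
markers at 1:9. Marker lists are drawn from the planted pathway members, so
knowledge-graph evidence chains exist by construction. Problem sizes —
480 cells × 136 genes, 60 cells per label, 20-seed recovery sweeps,
600-replicate null calibration — were chosen so the full suite completes in
seconds while keeping every statistical check adequately powered.

## Numerical and degenerate-input choices

- Correlation on a constant vector is an error at the single-pair API and a
  logged exclusion in the all-pairs screen.
- An all-zero cell is an error at normalization (it has no library); an
  all-constant cell yields a tie-break-only ranking with a warning.
- All-identical activity scores produce p = 1 (no evidence), not an error.
- BH-adjusted p-values are never below raw p-values; the accepted set at a
  given α always contains the Bonferroni-accepted set.
- Co-expression edge attributes round r to 6 decimals and the adjusted p to
  10; serialization preserves both exactly.
- Exact duplicate edges (same endpoints, relation and attributes) are
  collapsed; the same gene pair may carry one co-expression edge per
  context.

## Known limitations

- The mock backend's argmax rules make graph evidence decisive; prompt-style
  ablations (neutral / knowledge-biased / model-biased) change rendered
  prompts but cannot change mock decisions, so style effects are only
  observable with a remote backend.
- Stage-2 retrieval cost grows with the candidate's lineage size (closure
  construction), not O(1) in the strictest sense; on ontology-scale graphs
  the closure is still a vanishing fraction of the graph.
- The agreement metric's lineage partition is a modelling choice; scores at
  the 0.0/0.5 boundary depend on it for terms related at distance ≥ 2.
- Expression matrices are dense in memory; the implementation targets
  correctness at fixture scale, not sparse-matrix performance.
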