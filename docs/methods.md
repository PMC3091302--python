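# Methods

This note documents the models, conventions and design choices behind
`domevol`, and what the synthetic-data generators do and do not emulate.

## Hit filtering

A raw hit table assigns each protein a set of scored domain matches with
1-based inclusive envelope coordinates, an independent E-value, a bit
score, and optionally the per-domain gathering (GA), noise (NC) and
trusted (TC) bit-score thresholds curated by the domain database.
Filtering proceeds in three stages:

1. **Cutoff policy.** GA/NC/TC modes keep a hit iff its bit score is at
   least the hit's own domain-level threshold of that kind; a missing
   threshold is an error naming the protein and domain. EVALUE mode
   keeps hits with independent E-value ≤ a uniform threshold; any
   positive threshold is accepted (the 10⁻⁴…10⁻¹⁸ grid and 10⁻⁸ are the
   usual sensitivity-scan values). Domain-level rather than
   sequence-level thresholds are applied: repertoires are defined per
   domain occurrence, and the sequence-level member of each threshold
   pair is parsed but advisory.
2. **Exclusion list.** Accessions of likely viral/phage/transposon
   origin are removed by exact match on version-stripped accessions
   (versions are stripped everywhere so repertoires are comparable
   across database releases). Cutoff filtering and exclusion commute.
3. **Overlap resolution.** Within one protein, hits are ranked by
   (E-value ascending, bit score descending, accession, envelope start)
   and accepted greedily iff they overlap no accepted hit. Overlap means
   ≥ 1 shared residue position — the strictest contiguous-interval
   reading; adjacency is not overlap. The 4-level tie-break makes the
   outcome a total order, hence independent of input order. Resolution
   is global across all domains, not restricted to clan members.

The repertoire is the set of distinct accessions surviving all three
stages; copy number is deliberately discarded. Presence matrices drop
all-absent columns at construction (with a logged warning): a domain
present nowhere admits no gain event and would only distort counts.

## Dollo reconstruction

Under Dollo parsimony each domain is gained exactly once and never
regained. For a presence column the minimum-loss history is unique and
computed directly: the gain node is the MRCA of the carrier leaves; a
node inside the gain clade is present iff its subtree contains a carrier
leaf; each edge from a present node into a carrier-free subtree is one
loss. A short exchange argument shows no single-gain assignment can do
better: every maximal carrier-free subtree hanging off the carrier-
spanning subtree must absorb at least one loss, and this assignment
charges exactly one. The test suite nevertheless verifies equality with
brute-force enumeration over all internal-state assignments on every
rooted tree shape with up to 7 leaves.

Conventions:

* **Cost** is one gain per domain plus all losses, unweighted. Rankings
  of topologies over a fixed leaf set are unaffected by whether gains
  are counted (they sum to the number of domains), but both totals are
  kept in the ledger.
* **Root-origin domains** form a distinguished "ancestral stock" set:
  the root has no parent branch to charge a gain to, and the root
  repertoire — not a gain count — is the quantity of interest there.
* **Polytomies** are handled natively; nothing in the MRCA/subtree logic
  assumes binary nodes. Unnamed internal nodes are auto-named `N1..Nk`
  in preorder, so ledgers are stable across runs.
* **Rootedness** is required; gain/loss direction is meaningless on an
  unrooted tree, and unrooted Newick input must be rooted by the caller.
* Ties never arise: the reconstruction is deterministic by construction,
  and ledgers are byte-identical across runs and input orderings.

Topology comparison evaluates each candidate tree's cost on the same
matrix and sorts ascending (stable). Clade summaries report the gains
and losses on the branch entering the clade root, the clade root's
repertoire size, and the mean and sample standard deviation (n−1) of the
leaf repertoire sizes; for a single-genome clade the SD is reported as
0 with an explicit `sd_defined=False` flag.

## GO layer

Annotations propagate along `is_a` and `part_of` edges only (the
true-path rule); regulates-type edges are ignored. Ontology load rejects
cycles, naming one offending path.

* **Profiles.** For each selected term, the profile records 100 × (domains
  in the repertoire annotated, post-propagation, to the term) / (domains
  with ≥ 1 annotation in that term's namespace). Restricting the
  denominator to annotated domains makes profiles comparable across
  genomes with different annotation coverage; a zero denominator yields
  an explicit undefined flag rather than 0. Nested terms are therefore
  monotone (child ≤ ancestor) within a profile.
* **Category flux.** Along a user-supplied ancestor→descendant chain of
  nodes, each branch contributes the number of gained and lost domains
  annotated to the category; a domain counts once per category no matter
  how many of its terms fall under it. Means are arithmetic over the
  path's branches, and per-branch vectors are exposed for trajectory
  plots. Default category ids — biological regulation (GO:0065007) and
  metabolic process (GO:0008152) — and default profile axes — signal
  transduction (GO:0007165) and catalytic activity (GO:0003824) — are
  configurable everywhere.
* **Clustering.** Profiles over a common term vector are clustered by
  average-linkage on Euclidean distance between percentage vectors.
  Congruence with a reference tree is the unrooted Robinson–Foulds
  distance between dendrogram and reference (restricted to shared
  leaves), normalized by the total number of non-trivial bipartitions in
  both trees, giving a value in [0, 1] with 0 = identical topology.

## Enrichment

All methods test the one-sided upper tail P(X ≥ k) of the
hypergeometric distribution on propagated annotations, with the
population restricted to annotated domains before any sizes are
computed, and are conventionally run per namespace (biological_process
by default in the pipeline).

* **term-for-term** tests every term with population count ≥ 1 against
  the global study/population sizes.
* **elim** processes terms from most specific to least specific
  (descending longest-path depth, ties by term id). A term significant
  at the threshold (default 0.01, the convention of the original elim
  publication) has its annotated domains removed from all ancestors'
  annotation sets before those are tested. As the threshold vanishes,
  elim reduces exactly to term-for-term. Note that elimination removes
  population as well as study domains: an ancestor's p-value therefore
  *usually* rises but can fall slightly when mostly population-side
  domains are removed; the exact guarantees are that study and
  population counts never grow, and p never falls where the population
  count is untouched.
* **parent-child** conditions each term on its parents: the sampling
  universe is the union (or intersection) of the parents' annotation
  pools, and the test asks whether the term's annotations are
  over-represented among study members of that universe. Terms whose
  pool equals a parent's get p = 1 (no refinement); root terms fall back
  to term-for-term. These methods characteristically favor broad terms.
* **Correction** is none by default (raw p-values are the primary
  output; corrections are a sensitivity analysis), with Bonferroni and
  Benjamini–Hochberg available.

## Synthetic data

The generators produce data with exactly the generative structure the
reconstruction assumes, plus controlled violations:

* **Domain evolution.** Each domain originates at a node drawn from the
  origin distribution — by default 0.5 probability at the root and the
  rest uniform over non-root nodes, emulating a large ancestral stock
  plus lineage-specific gains — and is propagated leaf-ward, being lost
  on each branch inside its origin clade with that branch's loss
  probability (global scalar or per-branch map, in [0, 1)); a lost
  subtree stays absent. Domains losing every leaf are retained but
  flagged unobservable: they demonstrate why inferred ancestral
  repertoires are lower bounds that grow with taxon sampling. Every
  simulated truth is itself a feasible single-gain history, so the
  inferred parsimony cost never exceeds the true event count, and the
  inferred gain node is always a descendant-or-self of the true origin.
* **Hit tables.** True hits get E-values around 10⁻¹² (clipped below
  10⁻⁶) and bit scores above a GA threshold of 25, laid out
  non-overlapping on synthetic proteins of 1–3 domains. Decoys either
  overlap a true hit with an E-value at least 10× worse (they lose
  overlap resolution) or sit apart with sub-GA scores and E-values
  ≥ 10⁻³ (they fail cutoffs); optional extra strong hits carry
  accessions destined for an exclusion list. Zero-noise tables therefore
  round-trip exactly; protein-architecture realism is out of scope.
* **GO DAGs.** A layered random DAG (single namespace root, 1–2 parents
  per non-root term from earlier layers, acyclic by construction) with
  uniform background annotations at rate 0.05 per term. A study set of
  30 domains (default) is drawn so that each planted term receives its
  target fraction of study members from its propagated pool — the
  default planted fraction 0.4 against the ~5% background gives roughly
  8-fold enrichment, a deliberately strong single signal. For DAG-aware
  methods, a signal is "specific" only if the planted term is refinable
  relative to its parents, so `choose_plantable_term` picks a childless
  term with an adequate pool whose parents annotate much more than it.

What the simulators do **not** emulate: copy-number variation, domain
architecture and shuffling, horizontal transfer, annotation errors in
the ontology mapping, correlated gain of related domains, and rate
variation over time. Passing tests therefore certify the algorithms and
their contracts under the assumed generative model, not the biological
accuracy of any particular empirical reconstruction, whose absolute
counts are known to depend strongly on the domain database release and
cutoffs used.

## Problem sizes and determinism

The acceptance measurements use: all 143 rooted multifurcating tree
shapes with 2–7 leaves × 200 random columns for the brute-force
equivalence; 50 random 32-leaf trees × 500 domains for ledger
conservation; 2000 domains on 16-leaf trees for recovery; 100 replicates
each for topology ranking (16 leaves, 1000 domains, loss 0.1, one SPR
move), planted-term recovery (four methods, study 30 / population 1000),
and profile clustering (12 leaves, 10 categories × 200 domains,
per-branch category loss rates uniform on [0, 0.4]); and 1000 random
tables for the hypergeometric check. These sizes exercise every code
path at meaningful scale while keeping a full run to about a minute.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); reruns of any simulator, the pipeline, or
the acceptance script with the same seed are byte-identical. Pipeline
outputs carry no timestamps, and the run manifest records SHA-256
digests of every input plus the configuration, so any input change is
visible as a manifest change.
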