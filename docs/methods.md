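# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind panfam, in the spirit of a methods appendix: what is
computed, under what assumptions, and what the tests do and do not show.

## Similarity graph

All-vs-all protein BLAST tabular output (12-column) is reduced to one edge
per ordered protein pair by keeping the highest bit score across multiple
HSPs. Max-collapse was chosen because it is order-independent and does not
require alignment coordinates; summing HSP scores would double-count
overlapping segments. Self-hits are retained as the normalization baseline.

Three self-score-normalized metrics are offered — `maxbit`, `minbit`,
`avgbit` (see README for formulas). `maxbit`, the default, divides by the
larger self score and is the most conservative: a short protein hitting a
domain of a long multi-domain protein scores low, which suppresses
domain-level chaining in the graph. For any pair the raw values order as
maxbit ≤ avgbit ≤ minbit. Scores are clamped to [0, 1]: composition-based
score adjustment can make a cross-hit exceed a self score slightly, and
clustering needs bounded weights. The `minbit`/`avgbit` definitions are this
package's own; users comparing against other toolkits' homology weights
should verify the formulas rather than assume name-level compatibility.

Directed scores are symmetrized by taking the maximum of the two directions
(deterministic, favors sensitivity). Genes lacking a self-hit (which BLAST
can omit under composition-based masking) fall back to their best observed
bit score, logged; genes with no hits at all remain as isolated graph nodes
and end up as singleton families. Coordinates are stored 0-based half-open
internally; every BLAST-dialect reader/writer converts at the boundary from
the 1-based inclusive convention those formats use.

## Markov clustering

The MCL implementation is sparse (scipy CSR/CSC) and from scratch:

1. self-loops set to each node's maximum incident edge weight (1 for
   isolated nodes) — standard preconditioning that damps parity
   oscillation;
2. column normalization to a stochastic matrix;
3. iterate: expansion (matrix square), inflation (entrywise power *r*,
   column renormalization), pruning of entries below `prune_threshold`
   (default 1e-5) with renormalization;
4. stop when the maximum entrywise change falls below `tol` (1e-6) or after
   `max_iter` (100) iterations;
5. read clusters from the converged matrix: rows with a nonzero diagonal
   are attractors; attractors sharing support form one attractor system;
   every other node joins the system(s) flowing into it. A node reachable
   from several systems (rare) is assigned to the one whose
   lexicographically smallest member sorts first, keeping output
   deterministic.

Family ids are canonical: families sorted by size descending, ties broken
by smallest member, numbered consecutively from 0. `singleton_completion`
adds absent group genes as singletons and renumbers so the same ordering
rule holds for the completed run.

The defaults (inflation 2.0, the algorithm's customary default) aim at
algorithmic agreement with the MCL procedure on small instances, not
bit-identity with the original `mcl` binary, whose pruning schedule is more
elaborate. Tests compare against an independently written dense
implementation with identical parameters.

One behavior worth knowing: because self-loops equal the *max incident*
weight, a node attached to the graph only by a weak edge gets a comparably
weak self-loop and is usually absorbed into its neighbor's cluster rather
than left alone (e.g. a path a–b–c with w(a,b)=1.0, w(b,c)=0.1 converges to
one cluster at inflation 2.0). Unit self-loops would instead isolate such
nodes; the max-incident rule was kept as the common preconditioning choice.

## Presence/absence queries

The family × genome matrix holds copy numbers; presence means ≥ 1 copy.
The conservation-fraction threshold uses `ceil(fraction · |group|)`:
"conserved in 90% of 11 genomes" requires 10 genomes, never 9. `only`
(unique genes) requires presence in at least one group genome and absence
outside; compose with `all` for "unique and core".

Clade conservation supports two readings that differ for families patchily
present within a child clade: the default counts families present in
*every genome* under a node; the `children` reading counts families with at
least one representative under *each child* of the node. Both are exposed
because both are defensible definitions of "conserved at a node"; the
per-genome reading is the default as the stricter one, and only it
guarantees conserved(parent) ⊆ conserved(child). Internal nodes without
Newick labels get deterministic post-order ids (`N0`, `N1`, ...) so results
can be tied back to tree positions.

`cross_run_presence` maps each family of run A to the run-B families
sharing at least one gene and reports which focus genomes the mapped
families fail to cover (`missing_in = focus ∖ covered_in_b`). This is the
computation behind comparing a clustering of complete genomes against one
that also includes drafts: a family conserved in the complete set whose
mapped families miss a draft genome is a candidate missing gene call in
that draft, not necessarily a true loss.

## Missing-gene interpretation

tBLASTn hit intervals are normalized to plus-strand 0-based half-open
coordinates before any overlap computation (subject coordinates arrive
1-based with start > end on the minus strand; the frame sign carries
strand). A hit is "to a called gene" when a gene covers ≥ 50% of the hit's
genomic footprint — permissive enough to tolerate boundary disagreement,
strict enough that a hit in an intergenic gap stays uncalled.

Event heuristics (all thresholds configurable):

- **frameshift** — adjacent hits of one query on one contig strand in
  different frames, query gap ≤ 10 aa, genomic gap ≤ 60 nt;
- **insertion** — same frames, genomic gap exceeding the query gap's
  coding length by ≥ 30 nt;
- **nonsense** — a `*` strictly inside a hit's aligned subject translation
  (or, when translations are absent, inside the translation of the hit
  interval from the stored contig sequence); the stop's amino-acid offset
  is mapped back to the nucleotide coordinate respecting strand.

These are geometric reconstructions of what pseudogene-inducing mutations
look like in translated-search output; they flag candidates for human
review, they do not re-annotate. Uncalled hits ending within 100 nt of a
contig edge are flagged as possible fragments running off the assembly.

## GPR evaluation and model propagation

GPR text is parsed with AND binding tighter than OR, case-insensitive
keywords, parentheses overriding — the dominant convention in published
reconstructions. Parsed trees are canonical (nested same-operator nodes
flattened), so `parse(render(parse(s))) == parse(s)` holds structurally.
A reference gene is "present" in a target genome iff its family contains at
least one target gene; no copy-number or score threshold beyond family
co-membership is applied, keeping the call a pure function of the chosen
clustering parameters. Genes missing from the presence map (model/genome id
drift) default to absent with a log message rather than failing the whole
propagation. Reactions with empty GPRs are reported as `no_gene_evidence`:
forcing spontaneous/orphan reactions to present or absent would fabricate
gene-level evidence. The cutoff sweep reports missing gene-associated
reactions per homology cutoff; on separable synthetic data it is
non-decreasing in the cutoff, but that is not claimed as a theorem since
re-clustering is not monotone in general.

SBML model import (reaction ids + GPR strings only) delegates to cobrapy;
the Boolean evaluation itself is always panfam's own, and tests cross-check
it against both an exhaustive truth-table oracle and cobrapy's evaluator.

## Synthetic data generator

The simulator emulates the *combinatorial* structure of a pan-genome, not
molecular evolution. Family content evolves on a rooted tree (random
binary topology with branch lengths U(0.2, 1) unless a Newick string is
given): `n_core` families are present in every leaf; accessory families are
gained along branches as Poisson(gain_rate · branch length) events and
subsequently lost when Poisson(loss_rate · branch length) draws ≥ 1. Copy
number is 1 per genome — paralog handling is exercised with hand-built
matrices in tests instead. Defaults (12 genomes, 250 core families, gain
3.0, loss 0.4 for the large preset; 6 genomes / 30 core for unit-test
scale) give pan-genomes of a few hundred families, the scale at which the
package is meant to operate; problem sizes in tests and the acceptance
script use these presets.

Homology is simulated directly in metric space: each family draws a base
maxbit level uniform in the signal range (default 0.6–0.95), each
within-family pair jitters ±0.02 around it, and the value is back-converted
to a bit score via the pair's self scores (2 bits/residue). Spurious
cross-family pairs land in a disjoint noise range (default 0.05–0.2).
Overlapping ranges are rejected because the separation margin is exactly
what recovery tests rely on. Consequences: passing the recovery tests shows
the graph/clustering machinery is correct on separable inputs; it says
nothing about BLAST statistics, alignment-length effects, domain chaining,
or families straddling the cutoff — real data near the cutoff will not
cluster this cleanly.

Defect injection engineers ground-truth curation cases: an *uncalled* gene
is removed from the call table with its sequence left in the contig; a
*frameshift* is a real 1-nt deletion mid-gene (downstream coordinates
shifted) emitted as a split hit pair in different frames; a *nonsense*
mutation replaces a mid-gene codon with a stop, carried as `*` in the
emitted subject translation. Injection is restricted to plus-strand genes
with a family homolog in another genome (the homolog serves as the tBLASTn
query). All defects are recorded with coordinates so recovery can be scored
exactly.

Fixed reverse-translation codons (one codon per amino acid) make
contig sequences deterministic and exactly decodable; synthetic proteins
are uniform random over 20 amino acids, 80–250 residues.

## Known limitations

- The pruning schedule is a single global threshold; very large graphs may
  need the threshold raised for memory, which can change borderline
  clusters.
- `minbit`/`avgbit` are package-defined formulas (see above); only the
  maxbit-style normalization should be assumed portable across toolkits.
- Insertion/frameshift detection requires the translated search to report
  split hits; a single gapped hit spanning the lesion is invisible to the
  pair heuristics.
- The store keeps whole contig sequences as text rows; it targets desk-scale
  collections (tens to a few hundred genomes), not metagenome-scale data.
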