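# Methods

This note documents the models and procedures implemented in
`cdhsfinder`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Reduced-database homology search

Proteins are partitioned into identity clusters; only representatives are
searched; representative hits are propagated to all cluster members,
which inherit the representative's model, e-value and score (flagged
`propagated=True` — there is no per-member rescoring). The scheme is
exactly equivalent to a full search whenever the backend's hit decision
is constant within a cluster ("cluster consistency"), which high-identity
clustering makes a good approximation for profile and BLAST searches;
the equivalence is asserted in tests with a deterministic motif backend
that is cluster-consistent by construction.

The built-in clusterer is greedy longest-first: sequences are visited
longest first and join the first representative they match at or above
the identity threshold (default **0.9**), else seed a new cluster.
Identity is computed from the global (Needleman–Wunsch) edit distance as
`1 − dist / max(len_a, len_b)` — a conservative lower bound on
alignment-column identity — with an exact-duplicate shortcut and a
length-ratio prefilter. This is a deliberate simplification of
linear-time clustering tools, adequate for the partition contract; the
TSV output of an external clusterer can be ingested instead
(`read_mmseqs_clusters`). One clustering serves two purposes: search
reduction and neighbor-family merging in the network stage.

Hit filtering keeps e-values **strictly below 10⁻¹⁰** by default: a hit
at exactly the cutoff is dropped.

## Quorum system calling

A system definition lists gene roles (essential/accessory, each with one
or more acceptable models), an accessory threshold `min_accessory`, and
an adjacency slack `max_intervening` (default **3** non-member genes
between consecutive members; strict adjacency is `0`, and each definition
may override it). Per replicon and per definition, genes with member-model
hits are split into maximal runs wherever the gap exceeds
`max_intervening`; a run yields a call iff all essential roles are
filled, or — when `min_accessory > 0` — at least that many accessory
roles are filled. All genes of a qualifying run become call members;
consumed genes cannot seed a second call of the same system but may join
a different system's call (multi-system loci are real). Strand is
ignored for membership.

Role assignment within a run is greedy: genes in ordinal order each fill
the first unfilled role (in definition order) their models map to. A
maximum-bipartite-matching assignment would differ only for definitions
where one model serves several roles *and* genes carry overlapping model
sets; the greedy rule is deterministic and sufficient for one-model-per-
role definitions, which is the common case. This is a known limitation.

The caller is validated two ways: exact recovery of the generator's
manifest (precision = recall = 1 on noise-free input, planted decoys
never called), and exact agreement with an independent exhaustive
contiguous-window oracle over thousands of randomized toy replicons.

## Defense diversity

`p_sys` is multiset frequency: every instance counts, including multiple
instances within one genome — this is what a ratio of occurrence
frequencies implies. The per-genome presence variant is kept strictly
separate (`genome_fraction`, with an optional ≥ 1% reporting floor).
Shannon entropy `H = −Σ p log₂ p` is reported in bits per species, for
species with at least `min_genomes` genomes (default **200**; survey
figures sometimes use 500 — the threshold is a parameter, not a
constant). Rarefaction samples genomes without replacement on a 10-point
grid (default 100 replicates, mandatory seed) and reports mean ± sd of
distinct system types; the curve is monotone in expectation, not
necessarily in any finite sample.

## Neighbor network and hubs

For each call, neighbors are the genes overlapping the call span widened
by **5 kb** on each side (a 10 kb total window), minus the call's own
members. Window membership is *any overlap* with gene boundaries —
this maximizes neighbor recall; whether windows should instead be
anchored at gene midpoints is an open convention, and boundary overlap
is the choice made here. Windows clip at linear contig edges and wrap on
circular replicons.

Each distinct neighbor family adds +1 to the (system type, family) edge
per locus; the same family flanking the same system type in another
genome increments the weight. Nodes are keyed by system *type* and
protein family (cluster representative), so a neighbor's degree counts
the number of different immune systems it flanks — instance-level
counting would conflate conservation with abundance. Genes that belong
to a different co-located system call still count as neighbors of the
focal system. Non-coding genes (no protein) are keyed `rna:<product>` so
tRNA/tmRNA flanks can participate. Hub ranking is fully deterministic:
degree desc, total weight desc, family id asc. Graphs export to GraphML
and an edge-list TSV and re-import losslessly.

## Hotspot mapping

A marker pair is two reference sequences (protein, or nucleotide for RNA
markers). The built-in ortholog search accepts a gene at global identity
≥ 0.8 with a length-coverage ratio ≥ 0.8 (both configurable); an external
search can replace the predicate. Only contigs carrying both markers
yield a locus. With paralogous marker copies, the pair minimizing the
inner distance (left before right after orientation normalization) is
chosen — this avoids megabase false loci — and a warning is logged.

Locus size is the **inter-marker gap, exclusive of the marker genes**
(`right.start − left.end − 1`): with ever-present flanks, the variable
quantity is the cargo gap. Locus GC is computed on that cargo span only
and compared with whole-genome GC (all replicons). GC of an empty or
sequence-less span is reported absent, never 0. Occupancy is the
fraction of loci whose cargo shares at least one gene with a system
call; the inventory counts each overlapping call once per locus; the
non-defense fraction is the share of cargo genes in no call.

## Locus evolution

Sketches are bottom-s MinHash over canonical k-mers (k = 21, s = 1000 by
default), where the canonical form is the lexicographic minimum of a
k-mer and its reverse complement on a 2-bit encoding; windows with
ambiguous bases are skipped. Hashing is the splitmix64 finalizer over
the encoded k-mer XOR a seeded constant — fixed, vectorised, and
reproducible (the seed is recorded in sketch files). Jaccard is
estimated on the bottom-s of the sketch union and mapped to distance by
`d = −(1/k)·ln(2j/(1+j))`, with `d = 0` at `j = 1` and capped at 1.0 at
`j = 0` (disjoint sketches carry no resolution beyond "far"). The
estimator is checked against an exact-Jaccard brute-force oracle and
recovers simulated per-base mutation rates of 0.01–0.10 within ±0.01.

Patristic distances are path sums of branch lengths between leaf pairs
of an input newick tree (tree inference itself is out of scope; missing
branch lengths are an error). Pair classification:

* **long-range synteny**: tree distance > 0.35 AND locus Mash
  *similarity* (1 − d) > 0.9;
* **rapid diversification**: tree distance < 0.05 AND locus Mash
  *distance* > 0.38;
* **neither** otherwise. All inequalities strict.

The synteny criterion is deliberately phrased as similarity: the two
rules would contradict each other if both were distances, since a pair
cannot be near-identical and divergent at once; the quadrant meaning —
distant relatives, conserved locus — fixes the reading. Both thresholds
are configuration, not constants.

## Annotation summaries

Domain tallies restrict to cargo genes in no system call, keep hits with
e-value **≤ 0.01** (read as inclusive; configurable), and count genes per
domain plus the no-domain fraction. Mobilome classes are decided by
case-insensitive substring match on the major-category annotation in
fixed priority **integration > phage > conjugation** (multi-keyword
annotations are possible and the priority makes the outcome
deterministic); everything else is `other`. Per locus the set of classes
present is reported, plus the overall fraction of loci with no mobile
gene. External domain/mobilome searches are consumed as tabular input;
they are not executed by the package.

## Synthetic data generator

The generator emulates the features the pipeline's logic depends on:

* many isolates of one species with a conserved backbone (default 20
  genomes, 120 backbone genes, ~150 kb, GC 0.65);
* two hotspots at fixed backbone positions, each bounded by a marker
  pair (one non-coding RNA marker among them), with occupancy 0.8 and
  0.15 and a 4.5 kb spacer between the outer backbone gene and each
  marker so flank signals are attributable;
* cargo sampled from a pool of 10 system types (half requiring two
  essential genes, half exercising the accessory-quorum route), decoys
  missing one essential gene at rate 0.3, and 1–3 neutral filler genes
  per locus;
* cargo GC offset −0.06 relative to the backbone, applied to cargo genes
  and cargo intergenic alike. The cargo is kept under ~7% of the genome
  so the measured locus-minus-genome delta stays within ±0.01 of the
  configured offset despite the cargo's own contribution to genome GC;
* a Yule phylogeny (unit depth) along which backbone and marker
  sequences accumulate substitutions (rate 0.01 per site per unit branch
  length). Substitutions swap bases within their GC class (A↔T, C↔G),
  so divergence accumulates without disturbing the configured GC
  structure. Planted system genes are exact copies across genomes, which
  keeps identity thresholds and hit mocks exactly controllable.

Protein-coding fillers are random sense codons (stop codons repaired by
GC-preserving single-base edits); translations of mutated genes may
contain `X` where a substitution created a stop. The mock hit table
carries one e = 10⁻³⁰ hit per planted system gene (decoys included) and
optional noise hits at e ≥ 10⁻⁸, all of which the strict 10⁻¹⁰ filter
removes.

**What passing tests do and do not show.** The generator has no
recombination, no codon/amino-acid composition realism, no indels, no
gene gain/loss outside the hotspots, no assembly fragmentation and no
annotation error. Exact manifest recovery therefore validates the
*logic* of each stage (grouping, quorum, windowing, boundary and GC
accounting) — not robustness to noisy gene calling, partial hits or
diverged system variants in real data, where recall depends on the
quality of the models supplied to the search backend.

## Numerical and degenerate-input choices

* GC fraction = (G+C)/(A+C+G+T), case-insensitive, ambiguous bases
  excluded from the denominator; empty/all-ambiguous input raises rather
  than returning 0.
* Empty repertoires raise on `p_sys`/entropy (undefined, not 0).
* Adjacent markers yield a valid empty-cargo locus with size ≥ 0.
* Tie-breaks are deterministic everywhere: hub ranking
  (degree → weight → id), call ordering (genome → replicon → start),
  closest-marker-pair selection, greedy role assignment.
* All randomness (generator, rarefaction, sketch hashing) flows from
  explicit integer seeds; fixed seed ⇒ byte-identical outputs.

## Problem sizes used in the test suite

The shipped profile (20 genomes × ~170 genes) and toy fixtures keep the
full suite and the acceptance script to a few minutes on one core:
quorum-oracle agreement uses 1000 randomized replicons of ≤ 50 genes;
Mash accuracy uses 100 kb sequences, 10 replicates per rate; the
search-equivalence check uses ~240 proteins in 25 families. These sizes
were chosen as the smallest at which the checked statistics are stable.
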