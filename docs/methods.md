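# Methods

## The model

The package treats the repetitive fraction of a genome as a set of repeat
families, each with a copy number per 1C genome and a consensus sequence
(satellites: a 50–400 bp monomer arranged tandemly; dispersed elements:
a 300–3000 bp consensus). A species history is a rooted tree with one
flagged allopolyploidy node whose two parents are nodes on the maternal and
paternal lineages. Three processes act on every branch (branches are named
by their child node), in this order:

1. **Copy-number drift** — multiplicative log-normal noise,
   `c' = round(c · exp(N(0, σ_b)))`, with a per-branch σ_b. Multiplicative
   drift keeps abundances positive and heavy-tailed, like real repeat
   landscapes.
2. **Events** — bursts (`c' = round(c · f)`, f > 0) and deletions
   (`c' = round(c · r)`, 0 ≤ r ≤ 1) of named families, modelling episodic
   element activity and removal.
3. **Sequence divergence** — independent per-base substitutions of the
   family consensi and the single-copy background at a per-branch rate.

At the allopolyploidy node the copy numbers are the exact element-wise sum
of the two parental states (additive inheritance); the single-copy
background is the concatenation of both parents' backgrounds. Homeologs are
not tracked separately: the polyploid keeps one consensus per family (the
higher-copy parent's variant, maternal on ties). With per-branch divergence
at the default 0.5% this approximation is far below the 90% clustering
threshold and has no effect downstream; analyses that need
subgenome-of-origin attribution are out of scope.

Read emission draws, per species,
`N = round(coverage × genome_bp / read_len)` reads, allocating them
multinomially across sources in proportion to genomic base pairs. Satellite
reads come from a circular tandem array of the monomer (so junction-spanning
reads exist), dispersed-element and background reads from a uniform start on
the linear sequence; each read receives per-base substitutions at the read
divergence rate (default 2%, emulating within-family heterogeneity plus
sequencing error) and a random orientation. Every read's (species, family)
origin is recorded in a truth table.

## The six-taxon preset (`repandae6`)

The preset mirrors a well-studied allotetraploid system: diploid relatives
of the maternal (SYLV) and paternal (OBTU) progenitors, and four
allotetraploids on the topology `(OBTU,(SYLV,(NUDI,(REPA,(NESO,STOC)))))`.
Its evolutionary scenario: amplification on the maternal lineage before
hybridisation (SYLV larger than OBTU), chromovirus-like bursts plus an ~8×
satellite burst on the stem of (REPA,(NESO,STOC)), further element activity
on the island-pair stem, and broad deletions (genome downsizing, including
near-total satellite loss) on the NUDI branch. Drift σ_b scales roughly
with branch duration — the island pair split very recently, so their tips
get σ = 0.02 while long branches get 0.15–0.30.

Genomes are **miniaturised**: the preset keeps the real system's genome-size
*ratios* (OBTU smallest; SYLV ≈ 1.4× OBTU; NUDI downsized relative to the
other polyploids; REPA/NESO/STOC similar) at megabase scale, so that 0.01×
coverage yields ~4,400 pooled reads and the full pipeline runs in seconds.
There are 24 repeat families at roughly equal genomic shares plus a
plastid-like contaminant family and a 1.2 Mbp single-copy background per
diploid genome. Family count and copy numbers were set once so that (a)
every family is densely tiled by reads at 0.01× (clusters stay connected),
and (b) the character matrix is broad enough for resampling support to be
meaningful — with many fewer characters, symmetric reweighting of a handful
of informative characters makes supports intrinsically volatile regardless
of effect sizes.

The canonical shipped fixture is this preset at its default seed (0).

What the generator does **not** emulate: insertion-site structure,
recombination, indels, paired-end layout, sequencing quality gradients,
homeolog divergence within the polyploid, and the contiguous-genome
structure real reads come from (background loci are a single concatenated
sequence). Tests passing on this fixture therefore show that the analysis
machinery is correct and well-calibrated for abundance-level signal; they do
not certify behaviour on real libraries with adapter artefacts, indel
errors or organellar heterogeneity beyond the single plastid-like family.

## Clustering

The similarity engine seeds candidate pairs by shared 17-mers (canonical
form, so both strands are covered), groups seed diagonals, and runs a
banded Smith–Waterman (band ±10) around each seeded diagonal with
match +1 / mismatch −2 / gap −3. Identity is matches / aligned columns of
the canonical optimal alignment — maximum score, then maximum matches among
co-optimal paths (cell-level preference diagonal > up > left). A pair is an
edge iff identity ≥ 0.90 and aligned columns ≥ ceil(0.55 × shorter read
length) — "over 55%" read strictly, hence the ceiling. With substitution-only
divergence the seeded diagonals contain the optimum, and the engine's hit
sets match a full-matrix brute-force oracle exactly on fixture subsamples
(tested). Clusters are connected components; an optional greedy-modularity
refinement (off by default) can split chimeric components, but at fixture
divergence levels components alone recover the true families.

Cluster ranking is by total read count, ties broken by the smallest member
read id; ids are CL1, CL2, … Genome proportion of a cluster in a species is
100 × (its reads from that species) / (that species' pooled reads), valid
because every species is at equal coverage. The plastid screen removes a
cluster iff ≥ 50% of a size-capped (50) sample of its reads align to the
reference at the clustering thresholds.

**Abundance-matrix floor.** `top_n_matrix` takes the top-n clusters and, in
the shipped pipeline configuration, additionally drops clusters below 0.1%
of the pooled reads. At real data scale the top-1000 clusters sit far above
any such floor, so the floor is inert there; at fixture scale it matters,
because the generator deliberately lets orthologous single-copy loci
co-cluster across species (as real low-copy DNA would), producing 2–3-read
clusters. With only ~23 informative characters, a single such 0/1-valued
noise character measurably erodes the parsimony margin between topologies,
so letting them into the matrix would test noise, not method.

## Parsimony

For a real-valued character under linear (Manhattan) cost, the minimum tree
length is computed by the interval (Farris) algorithm: root the tree at a
leaf for traversal, assign each tip the degenerate interval [v, v], and in
postorder give each internal node the intersection of its children's
intervals — or, when they are disjoint, the interval between them, adding
the gap to the length. The result is exact on binary trees and independent
of the traversal root (tested against exhaustive minimisation over internal
states; for linear cost an optimum always exists with internal states drawn
from the observed tip values, so that restricted enumeration is itself
exact).

Per-edge lengths require choosing a point in each node's optimal interval.
The deterministic convention: in preorder from the traversal root (the
alphabetically first taxon), each node takes the point of its interval
closest to its parent's assigned value. The per-edge decomposition always
sums to the total; only the decomposition, used for drawing, depends on the
convention.

Tree search is exhaustive (stepwise-addition enumeration of all (2n−5)!!
unrooted binary topologies, refused above 9 taxa); all minimum-length trees
are returned, sorted by canonical Newick. Because a character's length on a
fixed topology does not depend on resampling weights, support estimation
precomputes the topology × character length matrix once and evaluates every
replicate as a weighted column sum — 10,000 replicates cost one matrix
product. Ties within 1e−9 (relative) enter the MP set; a replicate supports
an edge iff the strict consensus of its MP set contains the bipartition.
Symmetric resampling uses P(up-weight) = P(down-weight) = p/2 with p = 0.33
by default; the classic bootstrap is also available. The transform is a
pure cube root; an optional linear rescale to [0, 65] exists for matrices
whose maximum count exceeds 274,625 and is logged when applied.

Outgroup rooting places the root on the outgroup's pendant edge, splitting
its length equally (a drawing convention; totals and supports are
unchanged).

## Additivity deviation

Expected cluster sizes are the maternal + paternal counts on the raw
(untransformed) matrix at equal coverage; transformed input is refused.
Curves rank clusters by **expected** size ascending (ties by cluster id),
making the x-axis identical across polyploids that share parents, so curves
overlay and can be compared; ranking by observed size is available as an
option. Both the signed cumulative deviation and the cumulative absolute
deviation are emitted, along with a sign-preserving log transform
`sign(c) · log10(|c| + 1)` for log-scale plotting of signed values. The
pairwise curve distance is the L1 distance between cumulative-deviation
vectors on the shared rank grid.

At copy-number level (simulation truth) a polyploid with zero
post-polyploidy evolution deviates by exactly 0 everywhere; at read level
the deviation is binomial sampling noise, and tests bound it at 3 standard
deviations.

## Pipeline and determinism

Stages communicate only through files in the run directory; one global seed
derives per-stage seeds by stable SHA-256 hashing of the stage name, so
stages are independently reproducible and a rerun with the same config and
seed is byte-identical (checksummed in the run report). The synthetic stage
emits at 0.02× by default so the prep stage's down-sampling to 0.01× is a
real operation rather than a pass-through. Read ids are emitted already
carrying the four-letter species prefix; pooling therefore prefixes only
ids that do not already start with their own library's code, making the
operation idempotent.

## Evaluation choices and problem sizes

- Clustering fidelity is scored as the adjusted Rand index between cluster
  membership and true family over repeat-family reads. Background
  single-copy reads are excluded: at 0.01× coverage they almost never
  overlap, so both the truth and any correct clusterer leave them as
  singletons — including them as one truth class would score an unlearnable
  signal rather than the clusterer.
- Acceptance-scale runs use: 20 seeded preset simulations through the full
  simulate → cluster → screen → matrix → search path for topology
  recovery; 200 symmetric replicates for supports on the canonical fixture;
  100 random character sets × all 3 four-taxon and 15 five-taxon topologies
  for the parsimony oracle; a 200-read fixture subsample for the
  alignment-oracle comparison. These sizes keep a full run in the
  minutes range on a single core while leaving the statistical checks
  well-powered.

## Known limitations

- Exhaustive search only: above 9 taxa the package refuses rather than
  falling back to heuristics (ratchet/TBR are not implemented).
- The banded engine assumes the seeded diagonal contains the optimal local
  alignment; with indel-rich data (not generated by default) the band and
  the seed grouping would need widening.
- Deviation curves inherit the equal-coverage assumption; libraries at
  unequal coverage must be re-down-sampled before comparison.
- Support values on matrices with few characters (tens rather than
  hundreds) are intrinsically volatile under character resampling; the
  fixture was sized so that its supports are stable, but very small
  matrices will show wide support variation across datasets drawn from the
  same process.
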