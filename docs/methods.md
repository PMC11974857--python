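# Methods

This note documents the models, estimators and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Sequence comparison and orthology

All protein comparison uses deterministic global affine-gap alignment
(Needleman–Wunsch) with BLOSUM62, gap open −11 and gap extension −1
(a gap of length L costs 11 + (L−1)). The ambiguous residue X scores 0
against everything. A local heuristic search would be faster on real
data; for full-length single-copy markers the global score ranks
homologs the same way and is exactly reproducible, which is what the
test harness needs. Scores are converted to e-values with the
Karlin–Altschul form E = K·m·n·e^(−λS) using fixed λ = 0.267,
K = 0.041 (the standard gapped BLOSUM62 constants); no per-search
recalibration is done, and the acceptance thresholds (coverage ≥ 60%
of the shorter sequence, identity ≥ 25% over alignment columns,
E ≤ 10⁻⁸) are configurable to compensate.

Two exact bounds keep the all-vs-all comparison affordable without
heuristics: a hit can only pass the e-value gate if its score reaches
ln(K·m·n/E)/λ, and identity cannot exceed min(len)/max(len); candidate
hits are examined in descending score order and the traceback
(identity/coverage) is computed lazily. Results are identical to the
brute-force loop, which the test suite verifies.

Ortholog groups are connected components of the reciprocal-best-hit
graph with an adaptive-best rule: hits within 5% of a gene's best
passing score count as best. Without this, a recently duplicated
in-paralog — which is nobody's unique best hit — would drop out as a
singleton instead of marking its family multi-copy; the multi-copy flag
is what excludes such families from the single-copy marker set. No
spectral refinement of components is performed; on well-separated
families the components equal the family partition exactly.

## Marker pipeline

* **Alignment.** Center-star progressive alignment: the center is the
  sequence with the maximal summed pairwise score (ties by taxon id);
  the others are merged under once-a-gap-always-a-gap, with inserted
  residues left-justified in their insertion slot. The center-star
  score is within a factor 2 of optimal SP score and, importantly here,
  deterministic and dependency-free.
* **Trimming.** Two rules, applied in order: (1) from each alignment
  end, columns are dropped until the first column with occupancy
  (non-gap fraction) ≥ 0.8 — this clips partially aligned N-/C-terminal
  trailing regions; (2) internal columns with occupancy < 0.5 or whose
  most frequent residue (among non-gap rows) falls below 0.5 are
  removed. The thresholds are calibration choices standing in for the
  conventional block-filtering tools, and are configurable. Surviving
  column indices are kept for traceability.
* **Distances.** Poisson-corrected 20-state distances
  d = −(19/20)·ln(1 − (20/19)·p) with p the mismatch fraction over
  shared non-gap columns. Saturated pairs (p ≥ 19/20) get a fixed cap
  d = 10 so neighbor joining stays defined; capped pairs indicate the
  marker is effectively saturated and its tree length will be large,
  which feeds the outlier filter as intended. A pair with zero shared
  columns is an error naming the taxa; an all-zero distance matrix with
  ≥ 3 taxa (no divergence at all) is also an error, because no tree is
  identifiable from it.
* **Neighbor joining.** Standard agglomeration; negative branch-length
  estimates are clamped to zero; additive matrices are recovered
  exactly. Tie-breaking is by matrix order, which is fixed by the
  sorted taxon labels upstream, so runs are reproducible.
* **Outlier dismissal.** For each candidate marker a quick NJ tree is
  built and its summed branch length S recorded; markers with
  S > mean + 2·sd across markers are dismissed. The sample standard
  deviation (n−1) is used. The filter is applied once, not iterated.
  Markers whose alignment shows no divergence at all get S = 0 rather
  than an error — an uninformative marker is not an outlier. The filter
  is computed on the widest candidate set (the largest missing-genome
  tier) before tier selection, so the tier choice does not change which
  markers are dismissed; the alternative order is not distinguishable
  from the sources and this one keeps the tiers nested.
* **Tiers and bootstrap.** Markers are concatenated in lexicographic
  order at tiers k ∈ {0, 1, 3, 15} (markers absent from at most k
  genomes; absent taxa gap-filled), giving nested supermatrices with
  monotone lengths. The species tree is the NJ tree of the full
  supermatrix; supports are the percentage of 250 column-resampling
  replicates containing each bipartition (a 1000-replicate preset is
  also exposed). Note the tiers are absolute counts, chosen for panels
  of hundreds of genomes (15 of 306 ≈ 5%); on small simulated panels a
  proportionally smaller tier (e.g. 1 of 6) should be configured, and
  the demo configurations do so.

## FGC typing and localization

Each gene takes at most one typed hit: its best-scoring reference
member passing the orthology thresholds (ties by identity, then
reference id). Hits are grouped per contig and type along gene order;
a locus breaks when more than `max_gap` = 25 non-matching genes
intervene — wide enough to bridge small insertions, narrow enough to
split a ~100-gene insertion. A locus is called when it matches ≥ 50% of
the reference inventory of its type (majority vote over typed hits in
the span decides the type; ties yield no call). Two merge passes
follow: same-type loci on one contig, then same-type loci across
contigs, are re-tested jointly, so clusters split by large insertions
or assembly fragmentation still yield one call; the census unit is one
system per genome per type. The presence rule (min_fraction, max_gap)
is the package's formalization — the census semantics it reproduces
give no numeric rule — and both knobs are configurable.

Localization uses only replication proteins: if any gene on the call's
contig best-hits a plasmid replication initiator reference (DnaA-like,
RepA, RepB, RepABC; each with subtypes standing for compatibility
groups), the system is plasmid-encoded with that compatibility group;
otherwise chromosome-encoded. Declared replicon kinds in the input are
metadata and never consulted. Two replicase classes on one contig are
both recorded with a warning.

The shipped reference sets are synthetic stand-ins with the real role
inventories (36 fla1 roles including the conserved proteins CP1–4 and
the congruence markers FlhA/FliF/FlgH/FlgI; 46 fla2 and 52 fla3
members) generated from a fixed seed; the congruence markers are drawn
at 280–400 aa, reflecting the real sizes of this protein class, other
members at 80–160 aa. Swapping in real reference proteins is a
supported user step (same table layout); no test depends on real
sequences.

## HOT classification

For each cluster type with ≥ 4 instances, the four congruence markers
are aligned per role across instances, concatenated (missing roles
gap-filled; instances with < 3 of 4 roles are excluded), and an NJ tree
built. The species tree is pruned to the carriers — genomes lacking the
cluster are explained by loss and must not count as conflict. Both
trees then have internal edges shorter than 5% of their own mean
terminal branch length contracted: such edges carry under about one
expected substitution and are soft polytomies, not evidence; counting
them as conflict would misclassify clean vertical histories. The
congruence statistic is the Robinson–Foulds symmetric difference of
non-trivial bipartitions, normalized by its maximum 2(n−3); the type is
vertical iff this is ≤ τ = 0.2. τ was set so that topological noise on
clean vertical simulations stays below it while a single well-nested
transfer among ≥ 6 carriers exceeds it; a sensitivity sweep over τ is a
one-line loop over `classify_inheritance`.

Conflict attribution answers "which carriers are the transfer
recipients". All inclusion-minimal leaf-removal sets of up to four
leaves that restore congruence are enumerated (cheap via bipartition
restriction), and the most *species-isolated* set is chosen: the
minimal species-tree patristic distance from the removed set to the
remaining carriers. The rationale: removing a recipient and removing
its donor-side sister are often RF-equivalent (the unrooted topology
cannot tell them apart), but only the recipient sits far from every
other carrier in the species tree. Serially transferred subtrees
(recipient-of-a-recipient) are misplaced en bloc, which is why removal
units must be sets, not single leaves. When no small exact set exists,
a greedy fallback removes the most isolated strictly-RF-reducing leaf
or gene-tree clade until congruence or no improvement. This search is
exact-minimal rather than purely greedy; it remains a heuristic
attribution (about 1 in 13 simulated two-transfer histories is
genuinely ambiguous, e.g. recipients that are sisters of their donors)
and the classification itself never depends on it.

## Differential expression and the core regulon

Counts are modelled as NB(μ = s_j·m, φ) per gene with library-size
offsets s_j (median-of-ratios factors, geometric mean 1; total-count
fallback when no gene is observed in all samples). Dispersion is
moderated in two steps: a common φ maximizing the exact NB conditional
likelihood given per-group totals (computed on size-factor-normalized,
rounded pseudo-counts; exact for equal library sizes, an approximation
otherwise), and per-gene method-of-moments estimates
φ̂ = (v − m)/(m² − v/n) — numerator and denominator each unbiased —
pooled over groups and shrunk toward the common value with weight
w = 20/(20 + residual df). Everything is floored at 10⁻⁸.

Per contrast (each mutant vs wild type), group means are fitted by
Fisher scoring on the log scale with the dispersion held fixed, and the
likelihood-ratio statistic 2·ΔlogL is referred to χ²₁. The reported
log2 fold change comes from the fitted group means with a 0.5
pseudo-mean floor for all-zero groups (reporting only, never inside the
likelihood). Significance is |log2FC| > 1 **and** BH-FDR < 0.05, both
strict inequalities, with BH applied within each contrast. Under a
global null at φ = 0.1 with 6 vs 6 replicates the raw-p false positive
rate is ≈ 0.054 (the χ² approximation is mildly liberal at this sample
size) and the joint gate is conservative by an order of magnitude.

Cross-species ortholog pairs are bidirectional best hits at
E ≤ 10⁻¹⁰ with the coverage/identity gates disabled. Each pair is
classified per corresponding contrast: **strict** (significant in both
species, same direction), **discordant** (significant in both, opposite
directions), **relaxed** (significant in one, and the other shows a
same-direction near-miss with |log2FC| above 75% of the gate — e.g. a
1.9-fold change next to a 2-fold cutoff), or **species_specific**
(significant in one, no near-miss in the other). Requiring a near-miss
rather than any same-signed estimate is essential: with ~10³ orthologs,
same-signed noise around zero would otherwise flood the relaxed class.
Pairs significant in neither species are not classified. The overlap
tables count shared up/down (strict) and unique calls per contrast, and
per-species tables give the membership pattern of each gene across the
mutant contrasts.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes,
not realistic genomes:

* **Species trees** are Yule (pure-birth) with the intended leaf count,
  rescaled to unit root-to-tip height so that the substitution rate
  alone (default 0.15 substitutions/site over the tree) controls
  divergence.
* **Protein evolution** is the exact 20-state Jukes–Cantor chain:
  along a branch of length t each site changes with probability
  (19/20)(1 − e^(−(20/19)·r·t)), to a uniformly random different
  residue. This composes exactly along paths, giving the closed-form
  expected identity (1/20) + (19/20)·e^(−(20/19)·r·d) at path distance
  d, which calibration tests use directly. No rate heterogeneity,
  indels, domain structure or composition bias — so alignment and
  orthology are easier than on real proteins, and passing tests
  demonstrate the *logic* of the pipeline, not its performance on hard
  real data.
* **fla1** descends from the reference sequences at the root on the
  chromosome and is lost on each branch with `loss_prob_fla1`
  (default 0.05); a deep loss removes a whole clade, as in real
  histories.
* **fla2** arrives on one lineage (an internal clade of 2..n/2 leaves)
  as a plasmid carrying the cluster plus one replication initiator of a
  configured compatibility group, and is copied — whole cluster, with
  the plasmid — into `n_hgt_fla2` recipient lineages (terminal branches
  by default). The transfer genealogy is built explicitly: recipients
  continue evolving from the donor's sequence state at the transfer
  time. Transfers are drawn after the carrier clade's first internal
  divergence and donors restricted to lineages at least two splits
  below the clade root: a recipient grafted onto a root-incident edge
  is, in the unrooted pruned topology, indistinguishable from a
  congruent basal attachment — i.e. not a detectable transfer, and not
  what a planted-transfer experiment means to plant. With
  `hgt_recipient_min_dist` > 0 the origin clade is restricted to
  early-branching edges, which guarantees every recipient is at least
  that patristic distance from the donor clade ("distant recipients").
  The real transfer frequency is not quantified anywhere; the default
  of 3 transfers per 30 taxa is a calibration choice.
* **fla3** is the rarer chromosomal analogue, planted on a smaller
  clade disjoint from fla2 carriers, so the two never co-occur in one
  genome unless configured — matching the observed absence of that
  combination.
* **Xenologous markers** (`n_xenolog_markers`) replace one genome's
  copy of a background family with a copy evolved an extra 1.5
  substitutions/site: the out-of-dataset transfer that inflates a
  marker tree's total length, i.e. exactly what the dismissal filter
  targets. (In-dataset transfers *shorten* marker trees and are the
  congruence stage's job, not the filter's.)
* **Assembly degradation** removes each gene with `dropout_prob` and
  splits contigs at geometric(1/`frag_mean`) boundaries, renumbering
  ordinals; split contigs lose their declared replicon kind, as draft
  assemblies do.
* **Count matrices**: NB counts with lognormal baselines (median 100,
  log-sd 1), uniform library sizes in [0.5, 2], dispersion 0.1, and
  planted log2 effects drawn from ±U(2, 5) (80% down, the activator
  regulon signature): a shared core responding in the same direction in
  both species (magnitudes independent per species, equal across the
  three mutant contrasts) and species-specific sets responding in one.
  Both species are NB RNA-seq-like; the microarray-vs-RNA-seq platform
  asymmetry of a real cross-species comparison is not modelled.

Determinism: every stage draws from its own RNG stream derived from the
master seed by a fixed label, so identical config + seed reproduce
byte-identical outputs, stage by stage.

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale study conditions: orthology oracle equivalence at
10 genomes × 50 genes; species-tree recovery at 12 taxa with 100
markers × 100 aa (the marker-rich core-genome regime — at only 50
markers the shortest Yule internal edges are under-resolved); census
recovery at 6 taxa with one fla2 transfer and one fla3 placement, 20
seeds, with degradation at 10% dropout and ~30-gene contigs; HOT
classification at 16 taxa with 2 distant transfers into a ≥ 4-leaf
donor clade; dispersion/DE calibration at 2000 genes, 6 vs 6
replicates, φ = 0.1; core-regulon recovery with 40 shared and 2 × 30
species-specific planted pairs among 1500 orthologs. The species-tree
acceptance check builds marker alignments from the generator's truth
labels; orthology recovery itself is verified separately, and chaining
it into every tree replicate would test nothing new.

## Known limitations

* NJ replaces maximum-likelihood inference throughout; on real,
  rate-heterogeneous data an ML engine should be swapped in behind the
  same interfaces (`neighbor_joining`, `bootstrap_tree`).
* Center-star alignment degrades on sets with long indels or domain
  rearrangements; the generator produces neither.
* The conflict-set attribution is a heuristic over an unidentifiable
  problem; donor/recipient symmetric cases exist and are documented
  above.
* The conditional-likelihood common dispersion is exact only for equal
  library sizes; with strongly unequal libraries it is a rounded
  pseudo-count approximation.
* Compatibility-group assignment is best-hit-to-subtype, a stated proxy
  for a phylogenetic classification of replicases.
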