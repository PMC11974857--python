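# rhodoflag

Comparative genomics and transcriptomics of flagellar systems in the
bacterial order *Rhodobacterales*, as a reusable, tested pipeline.

Members of the *Rhodobacterales* (the marine roseobacters and their
relatives) carry up to two of three evolutionarily distinct flagellar
gene clusters (FGCs): the archetypal chromosomal **fla1**, the
plasmid-prone **fla2**, and the rare **fla3**. The questions this
package operationalizes are: which genomes carry which cluster and on
which replicon; whether each cluster type was inherited vertically or
spread by **horizontal operon transfer** (HOT, whole-cluster exchange,
often plasmid-mediated); and which genes form the conserved core of the
**CtrA phosphorelay regulon** (CckA → ChpT → CtrA, the master activator
of flagellar genes) across distantly related species.

The pipeline is aimed at microbial comparative genomicists who want the
full analysis chain runnable and testable at desk scale: every stage can
be exercised on synthetic genomes and count matrices with planted ground
truth, without downloading any external data.

## Stages

1. **Orthology** — all-vs-all global protein alignment (BLOSUM62, affine
   gaps −11/−1), Karlin–Altschul e-values, and adaptive reciprocal-best-hit
   ortholog groups at the classical thresholds (coverage ≥ 60%,
   identity ≥ 25%, E ≤ 10⁻⁸).
2. **Marker pipeline** — per-marker center-star alignment, two-rule
   column trimming, per-marker NJ trees, and the summed-branch-length
   dismissal rule: a marker whose tree length S exceeds
   mean(S) + 2·sd(S) across markers is discarded as a likely transfer or
   rate outlier. Surviving single-copy markers are concatenated into
   supermatrices at missing-genome tiers (0/1/3/15) and the species tree
   is inferred by neighbor joining on Poisson-corrected distances
   d = −(19/20)·ln(1 − (20/19)·p), with column-resampling bootstrap
   (250 replicates by default).
3. **FGC typing** — genes are scored against the three reference cluster
   inventories, grouped along gene order into loci (≤ 25 intervening
   non-matching genes), called when ≥ 50% of a reference inventory is
   matched, and localized: a cluster on a contig that also carries a
   plasmid replication initiator (DnaA-like, RepA, RepB or RepABC; the
   subtype is the compatibility group) is plasmid-encoded, all others
   chromosome-encoded.
4. **HOT inference** — per cluster type, a phylogeny of four conserved
   proteins (FlhA, FliF, FlgH, FlgI) is compared with the species tree
   pruned to the cluster carriers (absences are losses, not conflict).
   The congruence statistic is the Robinson–Foulds distance normalized
   by 2(n−3); a type is vertical when it is ≤ τ = 0.2. Conflict taxa —
   the putative transfer recipients — are the most species-isolated
   minimal leaf-removal set restoring congruence.
5. **Regulon comparison** — per-gene negative binomial GLMs with
   likelihood-ratio tests (dispersion moderated toward a common
   conditional-likelihood estimate), the significance gate
   |log2FC| > 1 and BH-FDR < 0.05, bidirectional-best-hit ortholog
   mapping at E ≤ 10⁻¹⁰, and the cross-species core-regulon
   intersection (orthologs changing in the same direction in the
   corresponding phosphorelay mutants of both species).
6. **Synthetic data** — Yule species trees, 20-state Jukes–Cantor
   protein evolution, planted fla1/fla2/fla3 clusters with losses and
   transfers, draft-assembly degradation, and two-species NB count
   matrices with planted shared and species-specific effects; every
   planted feature is recorded in a truth table.

## Worked example

Simulate 8 genomes with two planted fla2 transfers and run every stage:

```sh
rhodoflag all --simulate --config demo.toml --seed 7 --out demo_out
```

with `demo.toml`:

```toml
[simulate]
n_taxa = 8
n_families = 12
n_hgt_fla2 = 2
loss_prob_fla1 = 0.1
fla2_clade_min = 3

[regulon]
n_genes = 500
n_orthologs = 300
n_shared = 10
n_specific = 8
n_replicates = 3

[markers]
tiers = [0, 1]
filter_tier = 1
chosen_tier = 1

[tree]
n_reps = 50
```

`demo_out/fgc/census.tsv` — the per-type census over the 8 genomes
(15 systems; percentages over all detected systems):

```
fla_type	n_systems	pct
fla1	7	46.6667
fla2	6	40
fla3	2	13.3333
```

`demo_out/hot/hot_congruence.tsv` — the inheritance classification:

```
fla_type	n_instances	rf_raw	rf_normalized	classification	conflict_taxa
fla1	7	0	0	vertical	
fla2	6	4	0.666667	horizontal	G006,G007
```

fla1 perfectly mirrors the species tree (vertical; the one absence is a
loss), while fla2 conflicts strongly (normalized RF 0.67) and the
conflict set names exactly the two genomes the generator's truth table
(`demo_out/simulate/truth_hgt_events.tsv`) lists as transfer recipients:

```
fla_type	recipient	donor	time
fla2	G006	G001	0.959756
fla2	G007	G001	0.926664
```

Each stage writes deterministic TSV tables plus a `manifest.json` with
config echo, seed, and file hashes; rerunning with the same config and
seed is byte-identical. The other subcommands (`simulate`, `orthologs`,
`markers`, `tree`, `fgc`, `hot`, `regulon`) run single stages on files.

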