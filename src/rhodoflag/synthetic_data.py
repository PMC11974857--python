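"""Synthetic genomes, flagellar clusters and count matrices with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* a Yule (pure-birth) ultrametric species tree, rescaled to unit
  root-to-tip height so the substitution rate alone controls divergence;
* background single-copy protein families evolving along the tree under
  a 20-state Jukes-Cantor model (uniform replacement), whose pairwise
  identity has the closed form (1/20) + (19/20) exp(-(20/19) r d) at
  path distance d -- used directly by calibration tests;
* the archetypal chromosomal fla1 cluster inserted at the root and
  inherited vertically with per-branch loss; a plasmid-borne fla2
  cluster (with a replicase gene of a configured compatibility group)
  spreading by whole-cluster horizontal operon transfers into randomly
  chosen recipient lineages; a rarer chromosomal fla3 analogue. Cluster
  sequences descend from the shipped reference sets, which is what makes
  planted clusters detectable by the typing stage;
* optional xenologous marker replacements (a background family copy
  diverged an extra ``xenolog_extra`` substitutions/site) -- the kind of
  out-of-order transfer the summed-branch-length filter dismisses;
* draft-assembly degradation: per-gene dropout and geometric contig
  fragmentation;
* two-species negative-binomial count matrices with planted shared
  (same-direction) and species-specific regulon effects.

Every planted feature is recorded in a :class:`TruthTable`. All
randomness flows through per-stage streams derived from the master seed
by fixed labels, so stages are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import AMINO_ACIDS, GeneRecord, GenomeRecord, Replicon, read_newick
from .references import (
    CONGRUENCE_ROLES,
    flagellar_references,
    reference_by_type,
    replicase_references,
)

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

# fixed per-stage RNG stream labels
_STREAM_TREE = 1
_STREAM_PROTEOMES = 2
_STREAM_FGC = 3
_STREAM_DEGRADE = 4
_STREAM_COUNTS = 5


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the genomic simulation.

    Defaults are the package's desk-scale standard conditions: 30 taxa,
    100 background families of 100 aa, rate 0.15 substitutions/site over
    a unit-height tree, occasional fla1 loss, 3 fla2 transfers per 30
    taxa (the transfer rate is a calibration choice; the real frequency
    is not quantified) and one fla3 placement.
    """

    n_taxa: int = 30
    seed: int = 0
    n_families: int = 100
    seq_length: int = 100
    subst_rate: float = 0.15
    loss_prob_fla1: float = 0.05
    n_hgt_fla2: int = 3
    n_hgt_fla3: int = 1
    dropout_prob: float = 0.0
    frag_mean: float = math.inf
    n_xenolog_markers: int = 0
    xenolog_extra: float = 1.5
    fla2_compat: str = "RepABC|1"
    hgt_recipients: str = "leaf"
    fla2_clade_min: int = 2
    hgt_recipient_min_dist: float = 0.0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise DataError("n_taxa must be >= 2")
        for name in ("loss_prob_fla1", "dropout_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise DataError(f"{name} must be in [0, 1]")
        if self.subst_rate <= 0:
            raise DataError("subst_rate must be > 0")
        if self.frag_mean <= 1:
            raise DataError("frag_mean must be > 1 (mean genes per contig)")
        if self.hgt_recipients not in ("leaf", "any"):
            raise DataError("hgt_recipients must be 'leaf' or 'any'")


@dataclass
class TruthTable:
    """Ground truth for everything the generator planted."""

    fgc_inventory: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["genome_id", "fla_type", "contig_id", "replicon_kind", "compat_group"]
        )
    )
    hgt_events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["fla_type", "recipient", "donor", "time"]
        )
    )
    xenolog_markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["family", "genome_id"])
    )
    de_truth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["species", "gene_id", "contrast", "log2fc", "shared", "direction"]
        )
    )


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Yule pure-birth tree with n_taxa leaves, rescaled to unit height.

    Leaves are named G000, G001, ... in order of lineage creation.
    """
    if n_taxa < 2:
        raise DataError("n_taxa must be >= 2")
    rng = np.random.default_rng([seed, _STREAM_TREE])

    class _N:
        __slots__ = ("start", "end", "children", "name")

        def __init__(self, start: float) -> None:
            self.start = start
            self.end: float | None = None
            self.children: list[_N] = []
            self.name: str | None = None

    root = _N(0.0)
    root.end = 0.0
    active = [_N(0.0), _N(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(0, k))
        node = active[i]
        node.end = t
        node.children = [_N(t), _N(t)]
        active = active[:i] + node.children + active[i + 1 :]
    t_end = t + rng.exponential(1.0 / n_taxa)
    for i, leaf in enumerate(active):
        leaf.end = t_end
        leaf.name = f"G{i:03d}"

    def newick(node: _N) -> str:
        length = (node.end - node.start) / t_end if t_end > 0 else 0.0
        if node.children:
            inner = ",".join(newick(c) for c in node.children)
            return f"({inner}):{length:.10g}"
        return f"{node.name}:{length:.10g}"

    inner = ",".join(newick(c) for c in root.children)
    return read_newick(f"({inner});")


class _TreeInfo:
    """Precomputed node depths, clades and stable sort keys."""

    def __init__(self, tree: dendropy.Tree) -> None:
        self.tree = tree
        self.depth: dict[dendropy.Node, float] = {}
        self.clade: dict[dendropy.Node, frozenset[str]] = {}
        self.key: dict[dendropy.Node, str] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            self.depth[node] = (
                0.0 if parent is None else self.depth[parent] + (node.edge.length or 0.0)
            )
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self.clade[node] = frozenset([node.taxon.label])
            else:
                self.clade[node] = frozenset().union(
                    *(self.clade[c] for c in node.child_nodes())
                )
            self.key[node] = ",".join(sorted(self.clade[node]))
        self.height = max(self.depth[l] for l in tree.leaf_node_iter())
        self.leaves = sorted(
            (l.taxon.label for l in tree.leaf_node_iter())
        )
        self._leaf_node = {l.taxon.label: l for l in tree.leaf_node_iter()}

    def leaf_distance(self, a: str, b: str) -> float:
        """Path distance between two leaves."""
        anc_a = {}
        node = self._leaf_node[a]
        while node is not None:
            anc_a[id(node)] = self.depth[node]
            node = node.parent_node
        node = self._leaf_node[b]
        while id(node) not in anc_a:
            node = node.parent_node
        d_mrca = self.depth[node]
        return (
            self.depth[self._leaf_node[a]] + self.depth[self._leaf_node[b]] - 2 * d_mrca
        )

    def children(self, node: dendropy.Node) -> list[dendropy.Node]:
        return sorted(node.child_nodes(), key=lambda c: self.key[c])

    def edges(self) -> list[dendropy.Node]:
        """All edges, identified by their child node, in stable order."""
        out = [n for n in self.tree.preorder_node_iter() if n.parent_node is not None]
        return sorted(out, key=lambda n: self.key[n])


# ---------------------------------------------------------------------------
# sequence evolution


def _mutate(codes: np.ndarray, t: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Exact 20-state Jukes-Cantor transition over branch length t."""
    if t < 0:
        raise DataError("negative branch length")
    p_change = (19.0 / 20.0) * (1.0 - math.exp(-(20.0 / 19.0) * rate * t))
    mask = rng.random(codes.shape) < p_change
    out = codes.copy()
    if mask.any():
        jumps = rng.integers(1, 20, size=int(mask.sum()))
        out[mask] = (out[mask] + jumps) % 20
    return out


def _decode(codes: np.ndarray) -> str:
    return _AA_BYTES[codes].tobytes().decode()


def _encode_seq(seq: str) -> np.ndarray:
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    return np.array([idx[c] for c in seq], dtype=np.int64)


def evolve_proteomes(
    tree: dendropy.Tree,
    n_families: int,
    seq_length: int,
    subst_rate: float,
    seed: int,
) -> list[GenomeRecord]:
    """Evolve single-copy families along the tree; one chromosome per leaf."""
    if seq_length < 10:
        raise DataError("seq_length must be >= 10 (alignment stages need signal)")
    if any(
        n.edge.length is None for n in tree.preorder_node_iter() if n.parent_node is not None
    ):
        raise DataError("tree must have branch lengths")
    rng = np.random.default_rng([seed, _STREAM_PROTEOMES])
    info = _TreeInfo(tree)
    root_state = rng.integers(0, 20, size=(n_families, seq_length))

    leaf_states: dict[str, np.ndarray] = {}

    def walk(node: dendropy.Node, state: np.ndarray) -> None:
        if node.is_leaf():
            leaf_states[node.taxon.label] = state
            return
        for child in info.children(node):
            walk(child, _mutate(state, child.edge.length or 0.0, subst_rate, rng))

    walk(tree.seed_node, root_state)

    genomes = []
    for label in info.leaves:
        genes = [
            GeneRecord(
                gene_id=f"{label}_f{i:04d}",
                genome_id=label,
                contig_id=f"{label}_chr",
                ordinal=i,
                strand="+",
                sequence=_decode(leaf_states[label][i]),
                family_truth=f"fam{i:04d}",
            )
            for i in range(n_families)
        ]
        genomes.append(
            GenomeRecord(
                genome_id=label,
                replicons=[Replicon(f"{label}_chr", "chromosome", genes)],
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# FGC planting


def _evolve_block_vertical(
    info: _TreeInfo,
    root_states: list[np.ndarray],
    loss_prob: float,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, list[np.ndarray]]:
    """Root-planted block inherited vertically with per-branch loss."""
    leaf_states: dict[str, list[np.ndarray]] = {}

    def walk(node: dendropy.Node, state: list[np.ndarray]) -> None:
        if node.is_leaf():
            leaf_states[node.taxon.label] = state
            return
        for child in info.children(node):
            if rng.random() < loss_prob:
                continue
            t = child.edge.length or 0.0
            walk(child, [_mutate(s, t, rate, rng) for s in state])

    walk(info.tree.seed_node, root_states)
    return leaf_states


def _evolve_block_horizontal(
    info: _TreeInfo,
    root_states: list[np.ndarray],
    n_hgt: int,
    rate: float,
    rng: np.random.Generator,
    exclude_leaves: frozenset[str],
    max_clade_frac: float,
    recipients: str,
    min_clade: int = 2,
    recipient_min_dist: float = 0.0,
) -> tuple[dict[str, list[np.ndarray]], list[dict]]:
    """Block arriving on one lineage, spread by whole-cluster transfers.

    Returns per-carrier-leaf states and the transfer event records. The
    block genealogy (origin clade plus transfer attachments) is built
    explicitly and sequences evolved once down it, so recipients are
    genuine sisters of their donor lineage at the transfer time.
    """
    n = len(info.leaves)
    max_clade = max(min_clade, int(n * max_clade_frac))
    # an early-branching origin clade (stem above height - min_dist/2)
    # guarantees every outside leaf is at least min_dist away from it
    max_entry = info.height - recipient_min_dist / 2.0
    def _candidates(lo_size: int, entry_cap: float) -> list:
        return [
            e
            for e in info.edges()
            if lo_size <= len(info.clade[e]) <= max_clade
            and not (info.clade[e] & exclude_leaves)
            and info.depth[e.parent_node] <= entry_cap
            # enough leaves outside the clade must remain as recipients
            and n - len(info.clade[e] | exclude_leaves) >= n_hgt
        ]

    candidates = _candidates(max(2, min_clade), max_entry)
    if not candidates:  # relax the early-branching constraint first
        candidates = _candidates(max(2, min_clade), info.height)
    if not candidates:  # last resort: a single-leaf origin lineage
        candidates = [
            e
            for e in info.edges()
            if e.is_leaf()
            and not (info.clade[e] & exclude_leaves)
            and n - len(info.clade[e] | exclude_leaves) >= n_hgt
        ]
    if not candidates:
        raise DataError("no eligible origin lineage for horizontal cluster")
    origin = candidates[int(rng.integers(0, len(candidates)))]
    parent = origin.parent_node
    origin_entry = info.depth[parent]

    terminal = [e for e in info.edges() if e.is_leaf()]
    eligible0 = [
        e
        for e in terminal
        if info.clade[e].isdisjoint(info.clade[origin] | exclude_leaves)
    ]
    if n_hgt > len(eligible0):
        raise DataError(
            f"n_hgt={n_hgt} exceeds the {len(eligible0)} eligible recipient branches"
        )

    # carriers: edge(child node) -> entry time of the block on that edge
    carriers: dict[dendropy.Node, float] = {origin: origin_entry}

    def add_subtree(node: dendropy.Node) -> None:
        for c in node.child_nodes():
            carriers[c] = info.depth[node]
            add_subtree(c)

    add_subtree(origin)
    carrier_leaves = set(info.clade[origin])
    recipient_edges: set[dendropy.Node] = set()
    events_on: dict[dendropy.Node, list[tuple[float, dendropy.Node]]] = {}
    records: list[dict] = []

    for _ in range(n_hgt):
        pool = terminal if recipients == "leaf" else info.edges()
        elig = [
            e
            for e in pool
            if info.depth[e] > origin_entry
            and info.clade[e].isdisjoint(carrier_leaves | exclude_leaves)
        ]
        if not elig:
            raise DataError("no eligible recipient branch left for a transfer")
        recipient = elig[int(rng.integers(0, len(elig)))]
        # transfers are drawn after the carrier clade's first divergence, so
        # the donor lineage is strictly inside the clade and the recipient
        # nests within it -- the incongruence signature of a real transfer
        lo = max(info.depth[recipient.parent_node], origin_entry)
        if not origin.is_leaf():
            lo = max(lo, info.depth[origin])
            # wait for the first second-level split so a deep donor exists
            inner = [c for c in origin.child_nodes() if not c.is_leaf()]
            if inner:
                lo = max(lo, min(info.depth[c] for c in inner))
        lo = min(lo, info.depth[recipient])
        t = rng.uniform(lo, info.depth[recipient])
        alive = [e for e, entry in carriers.items() if entry <= t < info.depth[e]]
        # prefer donors at least two splits below the clade root (or earlier
        # recipients): a recipient grafted onto a root-incident edge is
        # indistinguishable from a congruent basal attachment in the
        # unrooted topology, i.e. not a detectable transfer
        deep = [
            e
            for e in alive
            if e in recipient_edges
            or (e is not origin and e.parent_node is not origin)
        ]
        donors = sorted(deep or alive, key=lambda e: info.key[e])
        if not donors:
            raise DataError("no carrier lineage alive at a sampled transfer time")
        donor = donors[int(rng.integers(0, len(donors)))]
        recipient_edges.add(recipient)
        events_on.setdefault(donor, []).append((float(t), recipient))
        carriers[recipient] = float(t)
        if not recipient.is_leaf():
            add_subtree(recipient)
            for c in recipient.child_nodes():
                carriers[c] = info.depth[recipient]
        carrier_leaves |= info.clade[recipient]
        records.append(
            {
                "recipient": info.key[recipient],
                "donor": info.key[donor],
                "time": float(t),
            }
        )
    for evs in events_on.values():
        evs.sort(key=lambda e: e[0])

    leaf_states: dict[str, list[np.ndarray]] = {}

    def walk_edge(edge_child: dendropy.Node, entry: float, state: list[np.ndarray]) -> None:
        t = entry
        for ev_t, recipient in events_on.get(edge_child, []):
            state = [_mutate(s, ev_t - t, rate, rng) for s in state]
            t = ev_t
            walk_edge(recipient, ev_t, [s.copy() for s in state])
        state = [_mutate(s, info.depth[edge_child] - t, rate, rng) for s in state]
        if edge_child.is_leaf():
            leaf_states[edge_child.taxon.label] = state
        else:
            for c in info.children(edge_child):
                walk_edge(c, info.depth[edge_child], [s.copy() for s in state])

    walk_edge(origin, origin_entry, [s.copy() for s in root_states])
    return leaf_states, records


def _block_genes(
    genome_id: str,
    contig_id: str,
    fla_type: str,
    roles: list[str],
    states: list[np.ndarray],
) -> list[GeneRecord]:
    return [
        GeneRecord(
            gene_id=f"{genome_id}_{fla_type}_{role}",
            genome_id=genome_id,
            contig_id=contig_id,
            ordinal=0,  # renumbered on insertion
            strand="+",
            sequence=_decode(state),
            family_truth=f"{fla_type}:{role}",
        )
        for role, state in zip(roles, states)
    ]


def _insert_block(genes: list[GeneRecord], block: list[GeneRecord], at: int) -> list[GeneRecord]:
    merged = genes[:at] + block + genes[at:]
    out = []
    for i, g in enumerate(merged):
        out.append(replace(g, ordinal=i, contig_id=genes[0].contig_id if genes else g.contig_id))
    return out


def plant_fgcs(
    genomes: list[GenomeRecord],
    tree: dendropy.Tree,
    config: SimConfig,
    seed: int,
) -> tuple[list[GenomeRecord], TruthTable]:
    """Insert fla1/fla2/fla3 clusters (and optional xenolog markers).

    fla1 descends vertically from the root on the chromosome, with
    per-branch loss. fla2 lives on a plasmid replicon that also carries
    one replicase of the configured compatibility group and spreads by
    ``n_hgt_fla2`` transfers; fla3 is its rarer chromosomal analogue,
    planted disjointly from fla2 (the two never co-occur by default).
    """
    rng = np.random.default_rng([seed, _STREAM_FGC])
    info = _TreeInfo(tree)
    by_id = {g.genome_id: g for g in genomes}
    if set(by_id) != set(info.leaves):
        raise DataError("genomes do not match the tree's leaf set")

    refs = {r.fla_type: r for r in flagellar_references()}
    inv_rows: list[dict] = []
    hgt_rows: list[dict] = []

    # --- fla1: vertical with losses
    fla1_roles = refs["fla1"].roles()
    fla1_root = [_encode_seq(m.sequence) for m in refs["fla1"].members]
    fla1_states = _evolve_block_vertical(
        info, fla1_root, config.loss_prob_fla1, config.subst_rate, rng
    )
    fla1_at = int(rng.integers(0, len(genomes[0].replicons[0].genes) + 1))

    # --- fla2: plasmid-borne, horizontal
    fla2_roles = refs["fla2"].roles()
    rep_ref = next(
        (r for r in replicase_references() if r.ref_id == config.fla2_compat), None
    )
    if rep_ref is None:
        raise DataError(f"unknown fla2 compatibility group {config.fla2_compat}")
    fla2_root = [_encode_seq(m.sequence) for m in refs["fla2"].members]
    fla2_root.append(_encode_seq(rep_ref.sequence))
    fla2_states, fla2_events = _evolve_block_horizontal(
        info,
        fla2_root,
        config.n_hgt_fla2,
        config.subst_rate,
        rng,
        exclude_leaves=frozenset(),
        max_clade_frac=0.5,
        recipients=config.hgt_recipients,
        min_clade=config.fla2_clade_min,
        recipient_min_dist=config.hgt_recipient_min_dist,
    )
    for ev in fla2_events:
        hgt_rows.append({"fla_type": "fla2", **ev})

    # --- fla3: chromosomal, rarer, disjoint from fla2
    fla3_roles = refs["fla3"].roles()
    fla3_root = [_encode_seq(m.sequence) for m in refs["fla3"].members]
    fla3_states, fla3_events = _evolve_block_horizontal(
        info,
        fla3_root,
        config.n_hgt_fla3,
        config.subst_rate,
        rng,
        exclude_leaves=frozenset(fla2_states),
        max_clade_frac=0.2,
        recipients=config.hgt_recipients,
    )
    for ev in fla3_events:
        hgt_rows.append({"fla_type": "fla3", **ev})
    fla3_at = int(rng.integers(0, len(genomes[0].replicons[0].genes) + 1))

    out_genomes = []
    for label in info.leaves:
        genome = by_id[label]
        chrom = genome.replicons[0]
        genes = list(chrom.genes)
        # insert the downstream block first so the first index stays valid
        if label in fla3_states:
            block = _block_genes(label, chrom.contig_id, "fla3", fla3_roles, fla3_states[label])
            genes = _insert_block(genes, block, min(fla3_at, len(genes)))
            inv_rows.append(
                {
                    "genome_id": label,
                    "fla_type": "fla3",
                    "contig_id": chrom.contig_id,
                    "replicon_kind": "chromosome",
                    "compat_group": "",
                }
            )
        if label in fla1_states:
            # shift past an already-inserted fla3 block so neither is split
            at1 = fla1_at
            if label in fla3_states and fla1_at > fla3_at:
                at1 += len(fla3_roles)
            block = _block_genes(label, chrom.contig_id, "fla1", fla1_roles, fla1_states[label])
            genes = _insert_block(genes, block, min(at1, len(genes)))
            inv_rows.append(
                {
                    "genome_id": label,
                    "fla_type": "fla1",
                    "contig_id": chrom.contig_id,
                    "replicon_kind": "chromosome",
                    "compat_group": "",
                }
            )
        replicons = [Replicon(chrom.contig_id, chrom.declared_kind, genes)]
        if label in fla2_states:
            contig = f"{label}_pfla2"
            states = fla2_states[label]
            block = _block_genes(label, contig, "fla2", fla2_roles, states[:-1])
            rep_gene = GeneRecord(
                gene_id=f"{label}_rep",
                genome_id=label,
                contig_id=contig,
                ordinal=0,
                strand="+",
                sequence=_decode(states[-1]),
                family_truth=f"rep:{rep_ref.ref_id}",
            )
            plasmid_genes = [
                replace(g, ordinal=i) for i, g in enumerate(block + [rep_gene])
            ]
            replicons.append(Replicon(contig, "plasmid", plasmid_genes))
            inv_rows.append(
                {
                    "genome_id": label,
                    "fla_type": "fla2",
                    "contig_id": contig,
                    "replicon_kind": "plasmid",
                    "compat_group": rep_ref.ref_id,
                }
            )
        rec = GenomeRecord(genome_id=label, replicons=replicons)
        rec.validate()
        out_genomes.append(rec)

    # --- xenologous marker replacements
    xeno_rows: list[dict] = []
    if config.n_xenolog_markers:
        fams = sorted(
            {g.family_truth for g in genomes[0].replicons[0].genes if g.family_truth}
        )
        if config.n_xenolog_markers > len(fams):
            raise DataError("n_xenolog_markers exceeds number of background families")
        picked = rng.choice(len(fams), size=config.n_xenolog_markers, replace=False)
        for fi in sorted(int(i) for i in picked):
            fam = fams[fi]
            label = info.leaves[int(rng.integers(0, len(info.leaves)))]
            genome = next(g for g in out_genomes if g.genome_id == label)
            for rep in genome.replicons:
                for k, gene in enumerate(rep.genes):
                    if gene.family_truth == fam:
                        codes = _encode_seq(gene.sequence)
                        xeno = _mutate(codes, config.xenolog_extra, 1.0, rng)
                        rep.genes[k] = replace(gene, sequence=_decode(xeno))
            xeno_rows.append({"family": fam, "genome_id": label})

    truth = TruthTable(
        fgc_inventory=pd.DataFrame(
            inv_rows,
            columns=["genome_id", "fla_type", "contig_id", "replicon_kind", "compat_group"],
        ),
        hgt_events=pd.DataFrame(hgt_rows, columns=["fla_type", "recipient", "donor", "time"]),
        xenolog_markers=pd.DataFrame(xeno_rows, columns=["family", "genome_id"]),
    )
    return out_genomes, truth


def truth_instances(
    genomes: list[GenomeRecord], fla_type: str, roles: tuple[str, ...] = CONGRUENCE_ROLES
) -> dict[str, dict[str, str]]:
    """Per-genome congruence-marker sequences read off the truth labels.

    Ground-truth counterpart of the detection-based extraction: maps
    genome_id -> role -> sequence for every planted cluster instance.
    """
    out: dict[str, dict[str, str]] = {}
    prefix = f"{fla_type}:"
    for genome in genomes:
        for rep in genome.replicons:
            for gene in rep.genes:
                if gene.family_truth and gene.family_truth.startswith(prefix):
                    role = gene.family_truth.split(":", 1)[1]
                    if role in roles:
                        out.setdefault(genome.genome_id, {})[role] = gene.sequence
    return out


# ---------------------------------------------------------------------------
# assembly degradation


def degrade_assemblies(
    genomes: list[GenomeRecord],
    dropout_prob: float,
    frag_mean: float,
    seed: int,
) -> list[GenomeRecord]:
    """Emulate draft assemblies: gene dropout and contig fragmentation.

    Each gene is removed independently with ``dropout_prob``; contigs are
    split at geometric(1/frag_mean) boundaries (gene order preserved) and
    ordinals renumbered. Split contigs lose their declared replicon kind.
    """
    if dropout_prob >= 1:
        raise DataError("dropout_prob = 1 would empty every genome")
    if frag_mean <= 1:
        raise DataError("frag_mean must be > 1")
    rng = np.random.default_rng([seed, _STREAM_DEGRADE])
    p_break = 0.0 if math.isinf(frag_mean) else 1.0 / frag_mean
    out = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        replicons = []
        for rep in genome.replicons:
            kept = [
                g for g in rep.genes if dropout_prob == 0 or rng.random() >= dropout_prob
            ]
            if not kept:
                continue
            pieces: list[list[GeneRecord]] = [[]]
            for g in kept:
                pieces[-1].append(g)
                if p_break and rng.random() < p_break:
                    pieces.append([])
            pieces = [p for p in pieces if p]
            if len(pieces) == 1 and len(kept) == len(rep.genes):
                replicons.append(rep)
                continue
            for k, piece in enumerate(pieces):
                contig = rep.contig_id if len(pieces) == 1 else f"{rep.contig_id}_p{k:02d}"
                kind = rep.declared_kind if len(pieces) == 1 else "unknown"
                replicons.append(
                    Replicon(
                        contig,
                        kind,
                        [replace(g, contig_id=contig, ordinal=i) for i, g in enumerate(piece)],
                    )
                )
        if not replicons:
            raise DataError(f"genome {genome.genome_id} lost every gene during degradation")
        rec = GenomeRecord(genome_id=genome.genome_id, replicons=replicons)
        rec.validate()
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# count simulation


@dataclass(frozen=True)
class RegulonConfig:
    """Conditions for the two-species NB count simulation.

    Counts follow NB(mean = libsize * mu_g * 2^(x * beta_g), dispersion
    phi). The shared core responds in the same direction in both species
    (magnitudes drawn independently per species); species-specific sets
    respond in one species only. Effects apply to every contrast.
    """

    n_genes: int = 2000
    n_orthologs: int = 1500
    n_shared: int = 40
    n_specific: int = 30
    contrasts: tuple[str, ...] = ("ctrA", "cckA", "chpT")
    n_replicates: int = 3
    dispersion: float = 0.1
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    libsize_range: tuple[float, float] = (0.5, 2.0)
    effect_low: float = 2.0
    effect_high: float = 5.0
    down_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise DataError("n_replicates must be >= 2")
        if self.dispersion < 0:
            raise DataError("dispersion must be >= 0")
        if self.n_shared + 2 * self.n_specific > self.n_orthologs:
            raise DataError("planted sets exceed the orthologous gene count")
        if self.n_orthologs > self.n_genes:
            raise DataError("n_orthologs exceeds n_genes")
        if not self.contrasts:
            raise DataError("need at least one contrast")


@dataclass
class CountBundle:
    counts_a: pd.DataFrame
    conditions_a: pd.Series
    counts_b: pd.DataFrame
    conditions_b: pd.Series
    ortholog_pairs: list[tuple[str, str]]
    truth: TruthTable


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def simulate_counts(config: RegulonConfig, seed: int) -> CountBundle:
    """Two-species count matrices with planted shared/specific effects."""
    rng = np.random.default_rng([seed, _STREAM_COUNTS])

    shared_idx = np.arange(config.n_shared)
    # shared direction: down with probability down_fraction, same in both species
    shared_dir = np.where(rng.random(config.n_shared) < config.down_fraction, -1.0, 1.0)

    spec_idx = {
        "A": np.arange(config.n_shared, config.n_shared + config.n_specific),
        "B": np.arange(
            config.n_shared + config.n_specific,
            config.n_shared + 2 * config.n_specific,
        ),
    }

    counts = {}
    conditions = {}
    truth_rows = []
    for species in ("A", "B"):
        mu = np.exp(
            rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
        )
        beta = np.zeros((config.n_genes, len(config.contrasts)))
        mags = rng.uniform(config.effect_low, config.effect_high, config.n_shared)
        for ci in range(len(config.contrasts)):
            beta[shared_idx, ci] = shared_dir * mags
        sdir = np.where(rng.random(config.n_specific) < config.down_fraction, -1.0, 1.0)
        smag = rng.uniform(config.effect_low, config.effect_high, config.n_specific)
        for ci in range(len(config.contrasts)):
            beta[spec_idx[species], ci] = sdir * smag

        gene_ids = [f"{species}_g{i:04d}" for i in range(config.n_genes)]
        groups = ["wt"] + list(config.contrasts)
        cols, labels, data = [], [], []
        for gi, group in enumerate(groups):
            for r in range(config.n_replicates):
                lib = rng.uniform(*config.libsize_range)
                b = np.zeros(config.n_genes) if group == "wt" else beta[:, gi - 1]
                mean = lib * mu * np.power(2.0, b)
                data.append(_nb_sample(rng, mean, config.dispersion))
                cols.append(f"{species}_{group}_r{r + 1}")
                labels.append(group)
        counts[species] = pd.DataFrame(
            np.column_stack(data), index=gene_ids, columns=cols
        )
        conditions[species] = pd.Series(labels, index=cols, name="condition")

        for ci, contrast in enumerate(config.contrasts):
            for gi in np.nonzero(beta[:, ci])[0]:
                lfc = beta[gi, ci]
                truth_rows.append(
                    {
                        "species": species,
                        "gene_id": gene_ids[gi],
                        "contrast": contrast,
                        "log2fc": float(lfc),
                        "shared": bool(gi < config.n_shared),
                        "direction": "down" if lfc < 0 else "up",
                    }
                )

    pairs = [
        (f"A_g{i:04d}", f"B_g{i:04d}") for i in range(config.n_orthologs)
    ]
    truth = TruthTable(
        de_truth=pd.DataFrame(
            truth_rows,
            columns=["species", "gene_id", "contrast", "log2fc", "shared", "direction"],
        )
    )
    return CountBundle(
        counts_a=counts["A"],
        conditions_a=conditions["A"],
        counts_b=counts["B"],
        conditions_b=conditions["B"],
        ortholog_pairs=pairs,
        truth=truth,
    )
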