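"""Vertical-vs-horizontal inheritance classification for FGC types.

For each FGC type, a phylogeny is built from four conserved proteins
(FlhA, FliF, FlgH, FlgI) concatenated per cluster instance, and compared
with the species tree pruned to the shared taxa: genomes lacking the
cluster were explained by loss, so they must not count as conflict. The
congruence statistic is the Robinson-Foulds distance normalized by its
maximum 2(n-3); a type is classified vertical when the normalized RF is
at most ``tau`` (default 0.2, chosen so that topological noise on clean
vertical simulations stays below it).

Conflict attribution is a greedy leaf-removal search: repeatedly remove
the leaf whose removal most reduces the raw RF until agreement or no
improvement. It approximates the (NP-hard) maximum agreement subtree;
for small instances an exact search is used as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .errors import DataError
from .fgc_typing import FGCall
from .io_formats import GenomeRecord, read_newick, write_newick
from .marker_pipeline import (
    align_family,
    build_supermatrix,
    neighbor_joining,
    pairwise_distance_matrix,
    tree_bipartitions,
)
from .orthology import AlignParams
from .references import CONGRUENCE_ROLES


@dataclass
class CongruenceResult:
    fla_type: str
    fgc_tree: dendropy.Tree
    pruned_species_tree: dendropy.Tree
    rf_raw: int
    rf_normalized: float
    classification: str  # vertical | horizontal
    conflict_taxa: list[str]


def extract_congruence_markers(
    call: FGCall, genome: GenomeRecord
) -> dict[str, str]:
    """The four congruence-marker sequences of one cluster instance.

    Returns role -> sequence in fixed role order; a missing role maps to
    an empty string (recorded gap partition). Instances matching fewer
    than 3 of the 4 roles are rejected.
    """
    genes = {g.gene_id: g for g in genome.genes()}
    out: dict[str, str] = {}
    n_found = 0
    for role in CONGRUENCE_ROLES:
        ref_id = f"{call.fla_type}|{role}"
        gene_id = call.matched.get(ref_id)
        if gene_id is None:
            out[role] = ""
        else:
            out[role] = genes[gene_id].sequence
            n_found += 1
    if n_found < 3:
        raise DataError(
            f"FGC {call.genome_id}/{call.fla_type}: only {n_found} of 4 congruence "
            "markers matched; instance excluded"
        )
    return out


def build_type_tree(
    instances: dict[str, dict[str, str]],
    fla_type: str = "",
    params: AlignParams = AlignParams(),
) -> dendropy.Tree:
    """NJ tree over cluster instances from the concatenated role alignments.

    ``instances`` maps genome_id -> role -> sequence (empty string for a
    missing role). Each role is aligned across the instances possessing
    it; missing roles are gap-filled via the supermatrix machinery.
    """
    if len(instances) < 4:
        raise DataError(
            f"type tree for {fla_type or 'FGC'} needs >= 4 instances, got {len(instances)}"
        )
    taxa = sorted(instances)
    alignments = {}
    for role in CONGRUENCE_ROLES:
        seqs = {t: instances[t].get(role, "") for t in taxa}
        seqs = {t: s for t, s in seqs.items() if s}
        if len(seqs) < 2:
            continue
        alignments[role] = align_family(seqs, group_id=role, params=params)
    if not alignments:
        raise DataError(f"type tree for {fla_type or 'FGC'}: no alignable role")
    sm = build_supermatrix(alignments, taxa, k_missing=len(taxa))
    from .marker_pipeline import MarkerAlignment

    concat = MarkerAlignment(fla_type or "type", list(sm.taxa), list(sm.rows))
    labels, D = pairwise_distance_matrix(concat)
    return neighbor_joining(labels, D)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Robinson-Foulds symmetric difference and its normalized form."""
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if l1 != l2:
        raise DataError("rf_distance requires identical leaf sets (prune first)")
    n = len(l1)
    if n < 4:
        raise DataError("rf_distance needs >= 4 leaves")
    b1 = tree_bipartitions(t1)
    b2 = tree_bipartitions(t2)
    raw = len(b1 ^ b2)
    return raw, raw / (2.0 * (n - 3))


def _restrict(biparts: set[frozenset[str]], keep: frozenset[str]) -> set[frozenset[str]]:
    """Bipartitions of the tree pruned to ``keep`` (set restriction)."""
    out = set()
    for side in biparts:
        a = side & keep
        b = keep - a
        if len(a) >= 2 and len(b) >= 2:
            out.add(min(a, b, key=sorted))
    return out


def _rf_after(
    bip_f: set[frozenset[str]],
    bip_s: set[frozenset[str]],
    keep: frozenset[str],
) -> int:
    return len(_restrict(bip_f, keep) ^ _restrict(bip_s, keep))


def _pruned(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    clone = read_newick(write_newick(tree))
    clone.retain_taxa_with_labels(sorted(keep))
    return clone


def collapse_short_branches(tree: dendropy.Tree, frac: float = 0.05) -> dendropy.Tree:
    """Contract internal edges far shorter than typical terminal edges.

    An internal edge whose length is below ``frac`` times the mean
    terminal branch length of the same tree carries too little signal to
    call conflict on (often under one expected substitution); it is
    treated as an unresolved soft polytomy. Scale-free: each tree uses
    its own branch-length units.
    """
    clone = read_newick(write_newick(tree))
    terminals = [
        l.edge.length or 0.0 for l in clone.leaf_node_iter() if l.edge.length is not None
    ]
    if not terminals or frac <= 0:
        return clone
    threshold = frac * (sum(terminals) / len(terminals))
    for node in list(clone.postorder_internal_node_iter()):
        if node.parent_node is None:
            continue
        if (node.edge.length or 0.0) < threshold:
            parent = node.parent_node
            for child in list(node.child_nodes()):
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)
    return clone


def _species_distances(species_tree: dendropy.Tree) -> dict[str, dict[str, float]]:
    pdm = species_tree.phylogenetic_distance_matrix()
    taxa = list(species_tree.taxon_namespace)
    out: dict[str, dict[str, float]] = {}
    for t1 in taxa:
        out[t1.label] = {}
        for t2 in taxa:
            if t1 is not t2:
                out[t1.label][t2.label] = pdm.patristic_distance(t1, t2)
    return out


def _isolation(
    unit: tuple[str, ...], others: list[str], spdist: dict[str, dict[str, float]]
) -> float:
    """Species-tree distance between a removal unit and the other carriers.

    A horizontally transferred block is species-distant from every other
    cluster carrier; a donor-side alternative explanation sits right
    next to its true relatives. The minimum cross distance separates the
    two even when their Robinson-Foulds effect is identical.
    """
    dists = [
        spdist[u][v] for u in unit for v in others if v in spdist.get(u, {})
    ]
    return min(dists) if dists else 0.0


_MAX_EXACT_REMOVALS = 4
_MAX_EXACT_TAXA = 16


def _conflict_taxa(
    bip_f: set[frozenset[str]],
    bip_s: set[frozenset[str]],
    taxa: list[str],
    spdist: dict[str, dict[str, float]],
    raw: int,
) -> list[str]:
    """Leaf removals that restore congruence, attributed to transfers.

    All removal sets of up to four leaves that bring the RF distance to
    zero are enumerated; among them the most species-isolated set is
    chosen (see :func:`_isolation`) -- removal alternatives with the
    same RF effect (recipient vs donor-side sister) are separated by the
    recipients sitting far from every other carrier in the species
    tree. Ties break toward fewer removals, then lexicographically.
    When no small exact set exists, a greedy search removes the most
    isolated strictly-RF-reducing leaf or gene-tree clade until
    congruence or no improvement.
    """
    import itertools

    if raw == 0:
        return []
    full = frozenset(taxa)
    n = len(taxa)
    if n <= _MAX_EXACT_TAXA:
        solutions: list[tuple[float, int, tuple[str, ...]]] = []
        seen: list[frozenset[str]] = []
        for k in range(1, min(_MAX_EXACT_REMOVALS, n - 4) + 1):
            for combo in itertools.combinations(taxa, k):
                fs = frozenset(combo)
                # only inclusion-minimal solutions are transfer candidates
                if any(s <= fs for s in seen):
                    continue
                if _rf_after(bip_f, bip_s, full - fs) == 0:
                    iso = _isolation(combo, [t for t in taxa if t not in combo], spdist)
                    solutions.append((iso, k, combo))
                    seen.append(fs)
        if solutions:
            solutions.sort(key=lambda s: (-s[0], s[1], s[2]))
            return sorted(solutions[0][2])

    # greedy fallback: leaves and gene-tree clades as removal units
    conflict: list[str] = []
    cur = list(taxa)
    cur_raw = raw
    while cur_raw > 0 and len(cur) > 4:
        keepset = frozenset(cur)
        units: list[tuple[str, ...]] = [(t,) for t in cur]
        for side in _restrict(bip_f, keepset):
            for unit in (side, keepset - side):
                if len(cur) - len(unit) >= 4:
                    units.append(tuple(sorted(unit)))
        best = None  # (-isolation, size, unit, raw_after)
        for unit in units:
            keep = keepset - frozenset(unit)
            r = _rf_after(bip_f, bip_s, keep)
            if r >= cur_raw:
                continue
            iso = _isolation(unit, [t for t in cur if t not in unit], spdist)
            key = (-iso, len(unit), unit, r)
            if best is None or key[:3] < best[:3]:
                best = key
        if best is None:
            break
        _, _, best_unit, cur_raw = best
        conflict.extend(best_unit)
        cur = [t for t in cur if t not in best_unit]
    return sorted(conflict)


def classify_inheritance(
    fgc_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    fla_type: str = "",
    tau: float = 0.2,
    collapse_frac: float = 0.05,
) -> CongruenceResult:
    """Classify a type's inheritance by tree congruence.

    The species tree is pruned to the FGC tree's taxa (absences are
    losses, not conflict) and near-zero internal edges of both trees are
    collapsed (see :func:`collapse_short_branches`) so unresolvable
    splits do not count as conflict. Vertical iff normalized RF <= tau.
    The conflict set is found greedily: remove the leaf whose removal
    most reduces the raw RF, repeat until RF = 0, fewer than 5 leaves
    remain, or no removal improves.
    """
    fgc_taxa = {l.taxon.label for l in fgc_tree.leaf_node_iter()}
    sp_taxa = {l.taxon.label for l in species_tree.leaf_node_iter()}
    shared = fgc_taxa & sp_taxa
    if len(shared) < 4:
        raise DataError("classify_inheritance needs >= 4 shared leaves")
    ft = collapse_short_branches(_pruned(fgc_tree, shared), collapse_frac)
    st = collapse_short_branches(_pruned(species_tree, shared), collapse_frac)
    raw, norm = rf_distance(ft, st)

    spdist = _species_distances(species_tree)
    bip_f = tree_bipartitions(ft)
    bip_s = tree_bipartitions(st)
    conflict = _conflict_taxa(bip_f, bip_s, sorted(shared), spdist, raw)

    return CongruenceResult(
        fla_type=fla_type,
        fgc_tree=ft,
        pruned_species_tree=st,
        rf_raw=raw,
        rf_normalized=norm,
        classification="vertical" if norm <= tau else "horizontal",
        conflict_taxa=conflict,
    )
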