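"""Per-marker alignment, filtering and supermatrix species-tree inference.

The pipeline mirrors a classical core-genome phylogenomics workflow:

1. each single-copy ortholog family is multiply aligned (center-star
   progressive alignment over the global pairwise aligner),
2. poorly aligned terminal and internal columns are clipped with a
   two-rule occupancy/conservation filter,
3. a quick tree is built per marker and markers whose summed branch
   length exceeds the across-marker mean plus two (sample) standard
   deviations are dismissed as likely transfer or rate outliers,
4. surviving markers are concatenated into supermatrices at increasing
   missing-genome tiers (0/1/3/15), absent taxa gap-filled,
5. the species tree is inferred by neighbor joining on Poisson-corrected
   distances, with column-resampling bootstrap supports (250 replicates
   by default, a 1000-replicate preset is exposed as well).

Trees are returned as dendropy objects; replicate bookkeeping inside the
bootstrap uses raw bipartition sets for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import DataError
from .io_formats import GAP, read_newick
from .orthology import AlignParams, _aligner, align_score

#: Bootstrap replicate presets: the standard rapid-bootstrap count and the
#: ultrafast-approximation count exposed as an alternative.
BOOTSTRAP_PRESETS = {"rapid": 250, "ultrafast": 1000}

#: Cap applied to saturated pairwise distances (p >= 19/20).
DISTANCE_CAP = 10.0


@dataclass
class MarkerAlignment:
    group_id: str
    taxa: list[str]
    rows: list[str]
    column_map: list[int] | None = None  # original column index per surviving column

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def validate(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise DataError(f"marker {self.group_id}: taxa/rows mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise DataError(f"marker {self.group_id}: duplicate taxa")
        if len({len(r) for r in self.rows}) > 1:
            raise DataError(f"marker {self.group_id}: unequal row lengths")


@dataclass(frozen=True)
class TrimParams:
    min_occupancy: float = 0.5
    min_conservation: float = 0.5
    terminal_occupancy: float = 0.8

    def __post_init__(self) -> None:
        for name in ("min_occupancy", "min_conservation", "terminal_occupancy"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise DataError(f"{name} must be in (0, 1]")


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]  # (group_id, start, end) half-open
    tier: int

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _pairwise_gapped(a: str, b: str, params: AlignParams) -> tuple[str, str]:
    aln = _aligner(params).align(a, b)[0]
    ga, gb = [], []
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        if a0 > pa:  # unaligned stretch of a <-> gap in b
            ga.append(a[pa:a0])
            gb.append(GAP * (a0 - pa))
        if b0 > pb:
            ga.append(GAP * (b0 - pb))
            gb.append(b[pb:b0])
        ga.append(a[a0:a1])
        gb.append(b[b0:b1])
        pa, pb = a1, b1
    if pa < len(a):
        ga.append(a[pa:])
        gb.append(GAP * (len(a) - pa))
    if pb < len(b):
        ga.append(GAP * (len(b) - pb))
        gb.append(b[pb:])
    return "".join(ga), "".join(gb)


def align_family(
    group_seqs: dict[str, str],
    group_id: str = "",
    params: AlignParams = AlignParams(),
) -> MarkerAlignment:
    """Center-star progressive multiple alignment of one gene family.

    The center is the sequence maximizing the summed pairwise score to
    all others (ties broken by taxon id); every other sequence is merged
    against it under once-a-gap-always-a-gap. Inserted residues are
    left-justified within their insertion slot.
    """
    if not group_seqs:
        raise DataError("align_family: empty family")
    taxa = sorted(group_seqs)
    seqs = [group_seqs[t] for t in taxa]
    if any(not s for s in seqs):
        raise DataError(f"marker {group_id}: empty sequence")
    if len(taxa) == 1:
        return MarkerAlignment(group_id, taxa, [seqs[0]])

    n = len(taxa)
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = align_score(seqs[i], seqs[j], params)
            sums[i] += s
            sums[j] += s
    center = int(np.lexsort((taxa, -sums))[0])
    c_seq = seqs[center]
    lc = len(c_seq)

    # ins[i][k]: residues of sequence i inserted before center position k
    others = [i for i in range(n) if i != center]
    ins_runs: dict[int, list[str]] = {}
    aligned_to_center: dict[int, list[str]] = {}
    for i in others:
        gc, gs = _pairwise_gapped(c_seq, seqs[i], params)
        runs = [""] * (lc + 1)
        matched = [GAP] * lc
        k = 0
        for cc, sc in zip(gc, gs):
            if cc == GAP:
                if sc != GAP:
                    runs[k] += sc
            else:
                if sc != GAP:
                    matched[k] = sc
                k += 1
        ins_runs[i] = runs
        aligned_to_center[i] = matched

    master_ins = [0] * (lc + 1)
    for i in others:
        for k in range(lc + 1):
            master_ins[k] = max(master_ins[k], len(ins_runs[i][k]))

    def build_row(matched: list[str], runs: list[str]) -> str:
        parts = []
        for k in range(lc):
            parts.append(runs[k].ljust(master_ins[k], GAP))
            parts.append(matched[k])
        parts.append(runs[lc].ljust(master_ins[lc], GAP))
        return "".join(parts)

    rows: list[str] = [""] * n
    rows[center] = build_row(list(c_seq), [""] * (lc + 1))
    for i in others:
        rows[i] = build_row(aligned_to_center[i], ins_runs[i])
    msa = MarkerAlignment(group_id, taxa, rows)
    msa.validate()
    return msa


def _occupancy_conservation(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    mat = np.array([list(r) for r in rows])
    nongap = mat != GAP
    occ = nongap.mean(axis=0)
    cons = np.zeros(mat.shape[1])
    for c in range(mat.shape[1]):
        col = mat[nongap[:, c], c]
        if len(col):
            _, counts = np.unique(col, return_counts=True)
            cons[c] = counts.max() / len(col)
    return occ, cons


def trim_alignment(msa: MarkerAlignment, params: TrimParams = TrimParams()) -> MarkerAlignment:
    """Clip trailing regions, then filter poorly aligned internal columns.

    Rule 1 (terminal): from each end, drop columns up to the first column
    with occupancy >= terminal_occupancy. Rule 2 (internal): drop columns
    with occupancy < min_occupancy or whose most frequent residue (among
    non-gap rows) has a fraction < min_conservation. The surviving
    original column indices are kept in ``column_map``.
    """
    if not msa.rows:
        raise DataError(f"marker {msa.group_id}: empty alignment")
    occ, cons = _occupancy_conservation(msa.rows)
    L = len(occ)
    left = 0
    while left < L and occ[left] < params.terminal_occupancy:
        left += 1
    right = L - 1
    while right >= left and occ[right] < params.terminal_occupancy:
        right -= 1
    keep = [
        c
        for c in range(left, right + 1)
        if occ[c] >= params.min_occupancy and cons[c] >= params.min_conservation
    ]
    if not keep:
        raise DataError(f"marker {msa.group_id}: all columns removed by trimming")
    rows = ["".join(r[c] for c in keep) for r in msa.rows]
    return MarkerAlignment(msa.group_id, list(msa.taxa), rows, column_map=keep)


def _encode(rows: list[str]) -> np.ndarray:
    """Rows as uint8 codes; gap = 255."""
    mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    out = mat.copy()
    out[mat == ord(GAP)] = 255
    return out


def poisson_distance(p: float) -> float:
    """Poisson-corrected 20-state amino-acid distance for mismatch fraction p."""
    if p >= 19.0 / 20.0:
        return DISTANCE_CAP
    return -(19.0 / 20.0) * math.log(1.0 - (20.0 / 19.0) * p)


def _distances_from_codes(codes: np.ndarray, taxa: list[str]) -> np.ndarray:
    n = codes.shape[0]
    D = np.zeros((n, n))
    nongap = codes != 255
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            ns = int(shared.sum())
            if ns == 0:
                raise DataError(
                    f"taxa {taxa[i]} and {taxa[j]} share no aligned columns"
                )
            p = float((codes[i, shared] != codes[j, shared]).sum()) / ns
            D[i, j] = D[j, i] = poisson_distance(p)
    if n >= 3 and D.max() == 0.0:
        raise DataError("degenerate distance matrix: no divergence between any taxa")
    return D


def pairwise_distance_matrix(msa: MarkerAlignment) -> tuple[list[str], np.ndarray]:
    """Poisson-corrected distances over shared non-gap columns per pair."""
    if len(msa.rows) < 2:
        raise DataError(f"marker {msa.group_id}: need >= 2 rows for distances")
    return list(msa.taxa), _distances_from_codes(_encode(msa.rows), list(msa.taxa))


def _nj(labels: list[str], D: np.ndarray) -> tuple[str, set[frozenset[str]]]:
    """Neighbor joining; returns (newick, non-trivial bipartition set).

    Negative branch-length estimates are clamped to zero. Additive
    matrices are recovered exactly.
    """
    n = len(labels)
    if n < 3:
        raise DataError("neighbor joining needs >= 3 taxa")
    D = D.astype(float).copy()
    nodes = [f"{lab}" for lab in labels]  # newick fragments
    clades = [frozenset([lab]) for lab in labels]
    all_taxa = frozenset(labels)
    biparts: set[frozenset[str]] = set()
    active = list(range(n))

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.10g}"

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        i, j = idx[ai], idx[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        new = f"({nodes[i]}:{fmt(li)},{nodes[j]}:{fmt(lj)})"
        newc = clades[i] | clades[j]
        if 2 <= len(newc) <= len(all_taxa) - 2:
            biparts.add(min(newc, all_taxa - newc, key=sorted))
        # distances to the new node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        clades.append(newc)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    newick = (
        f"({nodes[a]}:{fmt(la)},{nodes[b]}:{fmt(lb)},{nodes[c]}:{fmt(lc)});"
    )
    return newick, biparts


def neighbor_joining(labels: list[str], D: np.ndarray) -> dendropy.Tree:
    """NJ tree (unrooted, basal trifurcation) from a symmetric distance matrix."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise DataError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise DataError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise DataError("distance matrix diagonal must be zero")
    newick, _ = _nj(list(labels), D)
    return read_newick(newick)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-name frozensets."""
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(side) <= len(all_taxa) - 2:
            out.add(min(side, all_taxa - side, key=sorted))
    return out


def summed_branch_length(tree: dendropy.Tree) -> float:
    return float(tree.length())


def dismiss_outlier_markers(
    marker_sums: dict[str, float],
) -> tuple[set[str], set[str], float, float]:
    """Dismiss markers whose summed branch length exceeds mean + 2 SD.

    The across-marker sample standard deviation (n-1 denominator) is
    used; the filter is applied once, not iterated.
    """
    if len(marker_sums) < 2:
        raise DataError("outlier dismissal needs >= 2 markers")
    vals = np.array(list(marker_sums.values()), dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    threshold = mean + 2.0 * sd
    dismissed = {m for m, s in marker_sums.items() if s > threshold}
    kept = set(marker_sums) - dismissed
    return kept, dismissed, mean, sd


def build_supermatrix(
    alignments: dict[str, MarkerAlignment], taxa: list[str], k_missing: int
) -> Supermatrix:
    """Concatenate qualifying markers; gap-fill taxa missing a marker.

    A marker qualifies when it is absent from at most ``k_missing`` of
    the given taxa. Markers are concatenated in lexicographic group_id
    order with a partition map of half-open column spans.
    """
    if k_missing < 0:
        raise DataError("k_missing must be >= 0")
    chosen = []
    for gid in sorted(alignments):
        msa = alignments[gid]
        extra = set(msa.taxa) - set(taxa)
        if extra:
            raise DataError(f"marker {gid} has taxa outside the taxon list: {sorted(extra)}")
        if len(taxa) - len(msa.taxa) <= k_missing:
            chosen.append(gid)
    if not chosen:
        raise DataError(f"no markers qualify at k_missing={k_missing}")
    parts = []
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for gid in chosen:
        msa = alignments[gid]
        L = msa.length
        row_of = dict(zip(msa.taxa, msa.rows))
        for t in taxa:
            pieces[t].append(row_of.get(t, GAP * L))
        parts.append((gid, pos, pos + L))
        pos += L
    return Supermatrix(
        taxa=list(taxa),
        rows=["".join(pieces[t]) for t in taxa],
        partitions=parts,
        tier=k_missing,
    )


def bootstrap_tree(
    sm: Supermatrix, n_reps: int = 250, seed: int = 0
) -> dendropy.Tree:
    """Point NJ tree with column-resampling bootstrap supports.

    Supports (percent of replicates containing each point-tree
    bipartition) are attached as internal node labels.
    """
    if n_reps < 1:
        raise DataError("n_reps must be >= 1")
    codes = _encode(sm.rows)
    taxa = list(sm.taxa)
    D = _distances_from_codes(codes, taxa)
    newick, point_biparts = _nj(taxa, D)
    counts = {bp: 0 for bp in point_biparts}
    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        Db = _distances_from_codes(codes[:, cols], taxa)
        _, biparts = _nj(taxa, Db)
        for bp in point_biparts:
            if bp in biparts:
                counts[bp] += 1
    tree = read_newick(newick)
    all_taxa = frozenset(taxa)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(side, all_taxa - side, key=sorted)
        if key in counts:
            node.label = str(round(100.0 * counts[key] / n_reps))
    return tree
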