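"""All-vs-all protein comparison and reciprocal-best-hit orthology.

The comparison primitive is deterministic global affine-gap alignment
(BLOSUM62, gap open -11 / extend -1) instead of a local heuristic search:
for full-length single-copy markers a global score ranks homologs the
same way while being exactly reproducible. Karlin-Altschul statistics
(E = K*m*n*exp(-lambda*S)) translate scores into e-values so the
conventional thresholds (coverage >= 60%, identity >= 25%, E <= 1e-8)
can be applied unchanged.

Ortholog groups are connected components of the reciprocal-best-hit
(RBH) graph; genes without any cross-genome edge are retained as
singleton groups. A group is single-copy when no genome contributes more
than one member; ``n_missing`` counts genomes with no member at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DataError
from .io_formats import GeneRecord, GenomeRecord


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for global affine-gap protein alignment.

    ``lam`` and ``K`` are the Karlin-Altschul parameters used to turn a
    raw score into an e-value; they are fixed constants (per-search
    calibration is deliberately not done -- thresholds are configurable
    to compensate). The ambiguous residue X scores 0 against everything.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise DataError("require gap_open <= gap_extend < 0")
        if self.lam <= 0 or self.K <= 0:
            raise DataError("lambda and K must be > 0")


@dataclass(frozen=True)
class HitThresholds:
    """Hit acceptance gates: coverage and identity in percent, max e-value."""

    min_coverage_pct: float = 60.0
    min_identity_pct: float = 25.0
    max_evalue: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("min_coverage_pct", "min_identity_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise DataError(f"{name} must be in [0, 100]")
        if self.max_evalue <= 0:
            raise DataError("max_evalue must be > 0")


@dataclass
class Hit:
    gene_a: str
    gene_b: str
    score: float
    identity_pct: float
    coverage_pct: float
    evalue: float


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    is_single_copy: bool = True
    n_missing: int = 0

    def size(self) -> int:
        return sum(len(v) for v in self.members.values())


@lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(params.matrix)
    arr = np.array(matrix)
    alphabet = matrix.alphabet
    if "X" in alphabet:
        xi = alphabet.index("X")
        arr[xi, :] = 0.0
        arr[:, xi] = 0.0
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.mode = "global"
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def align_score(a: str, b: str, params: AlignParams = AlignParams()) -> float:
    """Optimal global affine-gap score only (no traceback; fast path)."""
    if not a or not b:
        raise DataError("cannot align an empty sequence")
    return _aligner(params).score(a, b)


def global_align(
    a: str, b: str, params: AlignParams = AlignParams()
) -> tuple[float, float, float]:
    """Return (score, identity_pct, coverage_pct) for a global alignment.

    Identity is computed over all alignment columns (pairwise global
    alignments have no double-gap columns); coverage is the number of
    columns where both sequences have a residue, relative to the shorter
    sequence's length.
    """
    if not a or not b:
        raise DataError("cannot align an empty sequence")
    aln = _aligner(params).align(a, b)[0]
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned_cols += a1 - a0
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if x == y:
                matches += 1
    n_cols = len(a) + len(b) - aligned_cols
    identity = 100.0 * matches / n_cols if n_cols else 0.0
    coverage = 100.0 * aligned_cols / min(len(a), len(b))
    return float(aln.score), identity, coverage


def evalue(score: float, m: int, n: int, params: AlignParams = AlignParams()) -> float:
    """Karlin-Altschul expected number of chance hits at this score."""
    if m < 1 or n < 1:
        raise DataError("sequence lengths must be >= 1")
    return params.K * m * n * math.exp(-params.lam * score)


def min_score_for_evalue(
    m: int, n: int, max_evalue: float, params: AlignParams = AlignParams()
) -> float:
    """Smallest score whose e-value is <= max_evalue (exact gate)."""
    return math.log(params.K * m * n / max_evalue) / params.lam


def _score_matrix(
    seqs_a: list[str], seqs_b: list[str], params: AlignParams
) -> np.ndarray:
    aligner = _aligner(params)
    S = np.empty((len(seqs_a), len(seqs_b)))
    for i, a in enumerate(seqs_a):
        for j, b in enumerate(seqs_b):
            S[i, j] = aligner.score(a, b)
    return S


def _passes(
    a: str, b: str, score: float, thresholds: HitThresholds, params: AlignParams
) -> Hit | None:
    e = evalue(score, len(a), len(b), params)
    if e > thresholds.max_evalue:
        return None
    _, identity, coverage = global_align(a, b, params)
    if identity < thresholds.min_identity_pct:
        return None
    if coverage < thresholds.min_coverage_pct:
        return None
    return Hit("", "", score, identity, coverage, e)


def _best_from_scores(
    ids_a: list[str],
    seqs_a: list[str],
    ids_b: list[str],
    seqs_b: list[str],
    S: np.ndarray,
    thresholds: HitThresholds,
    params: AlignParams,
) -> dict[str, Hit]:
    """Best passing hit in B for each gene of A, from a precomputed score matrix.

    Candidates are visited in descending score order; identity/coverage
    (which need a traceback) are only computed until one candidate
    passes. Two exact dominance bounds prune the rest: a score below the
    e-value gate can never pass, and identity cannot exceed
    min(len)/max(len). Ties on score break by higher identity, then
    lexicographic gene id.
    """
    out: dict[str, Hit] = {}
    len_b = np.array([len(s) for s in seqs_b])
    loosest = math.log(int(len_b.min())) if len(len_b) else 0.0
    for i, gid in enumerate(ids_a):
        la = len(seqs_a[i])
        smin = min_score_for_evalue(la, 1, thresholds.max_evalue, params)
        # evalue grows with n, so the score gate per candidate uses its length
        order = np.argsort(-S[i], kind="stable")
        best: tuple[float, float, str, Hit] | None = None
        for j in order:
            score = S[i, j]
            if best is not None and score < best[0]:
                break
            if score < smin + loosest / params.lam:
                break  # below the loosest possible e-value gate: none left can pass
            lb = int(len_b[j])
            if score < smin + math.log(lb) / params.lam:
                continue
            if thresholds.min_identity_pct > 0:
                ratio = min(la, lb) / max(la, lb)
                if 100.0 * ratio < thresholds.min_identity_pct:
                    continue
            hit = _passes(seqs_a[i], seqs_b[j], score, thresholds, params)
            if hit is None:
                continue
            key = (score, hit.identity_pct, ids_b[j])
            if (
                best is None
                or key[0] > best[0]
                or (key[0] == best[0] and key[1] > best[1])
                or (key[0] == best[0] and key[1] == best[1] and key[2] < best[2])
            ):
                best = (score, hit.identity_pct, ids_b[j], hit)
        if best is not None:
            hit = replace(best[3], gene_a=gid, gene_b=best[2])
            out[gid] = hit
    return out


def _near_best_sets(
    ids_a: list[str],
    seqs_a: list[str],
    ids_b: list[str],
    seqs_b: list[str],
    S: np.ndarray,
    thresholds: HitThresholds,
    params: AlignParams,
    factor: float,
) -> dict[str, set[str]]:
    """Passing hits within ``factor`` of each gene's best passing score.

    Used for co-ortholog edges: an in-paralog scores marginally below
    its twin against the other genome but belongs to the same family.
    """
    best = _best_from_scores(ids_a, seqs_a, ids_b, seqs_b, S, thresholds, params)
    out: dict[str, set[str]] = {}
    for i, gid in enumerate(ids_a):
        hit = best.get(gid)
        if hit is None:
            continue
        band = hit.score - (1.0 - factor) * abs(hit.score)
        accepted = {hit.gene_b}
        for j in np.nonzero(S[i] >= band)[0]:
            if ids_b[j] in accepted:
                continue
            if _passes(seqs_a[i], seqs_b[j], S[i, j], thresholds, params) is not None:
                accepted.add(ids_b[j])
        out[gid] = accepted
    return out


def _proteome(genes: list[GeneRecord]) -> tuple[list[str], list[str]]:
    ids = [g.gene_id for g in genes]
    seqs = [g.sequence for g in genes]
    return ids, seqs


def best_hits(
    proteome_a: list[GeneRecord],
    proteome_b: list[GeneRecord],
    thresholds: HitThresholds = HitThresholds(),
    params: AlignParams = AlignParams(),
) -> dict[str, Hit]:
    """Directed best-hit table: for each gene in A its best passing gene in B."""
    if not proteome_a or not proteome_b:
        return {}
    ids_a, seqs_a = _proteome(proteome_a)
    ids_b, seqs_b = _proteome(proteome_b)
    S = _score_matrix(seqs_a, seqs_b, params)
    return _best_from_scores(ids_a, seqs_a, ids_b, seqs_b, S, thresholds, params)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label becomes root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_ortholog_groups(
    genomes: list[GenomeRecord],
    thresholds: HitThresholds = HitThresholds(),
    params: AlignParams = AlignParams(),
    sim_factor: float = 0.95,
) -> list[OrthologGroup]:
    """Reciprocal-best-hit graph over all genome pairs; connected components.

    Hits within ``sim_factor`` of a gene's best passing score count as
    best (adaptive reciprocal best hits), so recently duplicated
    in-paralogs land in their family's group and mark it multi-copy
    instead of floating off as singletons. Genes with no reciprocal
    edge at all form singleton groups (the ``-singles`` behaviour).
    """
    if len(genomes) < 2:
        raise DataError("need at least 2 genomes for orthology")
    genomes = sorted(genomes, key=lambda g: g.genome_id)
    gene_home = {}
    per_genome: dict[str, tuple[list[str], list[str]]] = {}
    for g in genomes:
        genes = g.genes()
        per_genome[g.genome_id] = _proteome(genes)
        for gene in genes:
            if gene.gene_id in gene_home:
                raise DataError(f"gene_id {gene.gene_id} appears in two genomes")
            gene_home[gene.gene_id] = g.genome_id

    uf = _UnionFind()
    for gid in gene_home:
        uf.find(gid)
    names = [g.genome_id for g in genomes]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ids_a, seqs_a = per_genome[names[i]]
            ids_b, seqs_b = per_genome[names[j]]
            if not ids_a or not ids_b:
                continue
            S = _score_matrix(seqs_a, seqs_b, params)
            fwd = _near_best_sets(
                ids_a, seqs_a, ids_b, seqs_b, S, thresholds, params, sim_factor
            )
            rev = _near_best_sets(
                ids_b, seqs_b, ids_a, seqs_a, S.T, thresholds, params, sim_factor
            )
            for ga, accepted in fwd.items():
                for gb in accepted:
                    if ga in rev.get(gb, ()):
                        uf.union(ga, gb)

    components: dict[str, list[str]] = {}
    for gid in sorted(gene_home):
        components.setdefault(uf.find(gid), []).append(gid)

    n_genomes = len(genomes)
    groups = []
    for idx, root in enumerate(sorted(components, key=lambda r: sorted(components[r]))):
        members: dict[str, list[str]] = {}
        for gid in sorted(components[root]):
            members.setdefault(gene_home[gid], []).append(gid)
        group = OrthologGroup(
            group_id=f"OG{idx:05d}",
            members=members,
            is_single_copy=all(len(v) == 1 for v in members.values()),
            n_missing=n_genomes - len(members),
        )
        groups.append(group)
    return groups


def select_core(groups: list[OrthologGroup], k_missing: int) -> list[OrthologGroup]:
    """Single-copy groups missing from at most ``k_missing`` genomes."""
    if k_missing < 0:
        raise DataError("k_missing must be >= 0")
    return [g for g in groups if g.is_single_copy and g.n_missing <= k_missing]
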