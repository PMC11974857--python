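"""Flagellar gene cluster detection, typing, and replicon localization.

Each genome gene is scored against the three FGC reference sets; typed
hits are grouped along gene order into candidate loci (a locus breaks
when more than ``max_gap`` non-matching genes intervene, and never spans
contigs). A locus becomes an FGC call when it covers at least
``min_fraction`` of the reference inventory of its type. Because draft
assemblies split clusters and some genomes carry large insertions inside
the FGC, sub-threshold loci of one type on one contig are merged and
re-tested, and the census counts one system per genome per type.

Localization follows the replication-protein rule: a call is
plasmid-encoded when any gene on its contig hits a plasmid replicase
reference (DnaA-like, RepA, RepB or RepABC; subtype = compatibility
group by best hit); all other calls are chromosome-encoded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .io_formats import GeneRecord, GenomeRecord
from .orthology import (
    AlignParams,
    HitThresholds,
    _best_from_scores,
    _score_matrix,
)
from .references import (
    FLA_TYPES,
    ReferenceSet,
    ReplicaseRef,
    flagellar_references,
    replicase_references,
)

logger = logging.getLogger(__name__)

FGC_COMBINATIONS = (
    "none",
    "fla1",
    "fla2",
    "fla3",
    "fla1+fla2",
    "fla1+fla3",
    "fla2+fla3",
    "fla1+fla2+fla3",
)


@dataclass(frozen=True)
class CallParams:
    """Presence rule for an FGC call.

    ``min_fraction`` is the fraction of a type's reference members that
    must be matched; ``max_gap`` the number of intervening non-matching
    genes tolerated inside one locus. Both are formalizations -- the
    census semantics give no numeric rule -- and configurable.
    """

    min_fraction: float = 0.5
    max_gap: int = 25
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction <= 1):
            raise DataError("min_fraction must be in (0, 1]")
        if self.max_gap < 0:
            raise DataError("max_gap must be >= 0")


@dataclass
class TypedHit:
    gene_id: str
    contig_id: str
    ordinal: int
    fla_type: str
    ref_gene_id: str
    role: str
    score: float
    identity_pct: float


@dataclass
class Locus:
    contig_id: str
    fla_type: str
    hits: list[TypedHit]

    @property
    def span(self) -> tuple[int, int]:
        ords = [h.ordinal for h in self.hits]
        return min(ords), max(ords)


@dataclass
class FGCall:
    genome_id: str
    contig_id: str
    fla_type: str
    span: tuple[int, int]
    matched: dict[str, str]  # ref_gene_id -> gene_id
    fraction_matched: float
    replicon_kind: str = "chromosome"
    compat_group: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fraction_matched <= 1):
            raise DataError("fraction_matched must be in (0, 1]")


def score_against_references(
    genes: list[GeneRecord],
    references: list[ReferenceSet] | None = None,
    params: CallParams = CallParams(),
) -> dict[str, TypedHit]:
    """Best passing reference member per gene (at most one hit per gene).

    Ties on score break by higher identity, then reference id -- the
    same total order the orthology stage uses.
    """
    if references is None:
        references = list(flagellar_references())
    if not genes:
        return {}
    ref_ids, ref_seqs, ref_type, ref_role = [], [], {}, {}
    for ref in references:
        for m in ref.members:
            ref_ids.append(m.ref_gene_id)
            ref_seqs.append(m.sequence)
            ref_type[m.ref_gene_id] = ref.fla_type
            ref_role[m.ref_gene_id] = m.role
    ids = [g.gene_id for g in genes]
    seqs = [g.sequence for g in genes]
    S = _score_matrix(seqs, ref_seqs, params.align)
    best = _best_from_scores(
        ids, seqs, ref_ids, ref_seqs, S, params.thresholds, params.align
    )
    gene_by_id = {g.gene_id: g for g in genes}
    out = {}
    for gid, hit in best.items():
        g = gene_by_id[gid]
        out[gid] = TypedHit(
            gene_id=gid,
            contig_id=g.contig_id,
            ordinal=g.ordinal,
            fla_type=ref_type[hit.gene_b],
            ref_gene_id=hit.gene_b,
            role=ref_role[hit.gene_b],
            score=hit.score,
            identity_pct=hit.identity_pct,
        )
    return out


def cluster_hits(
    typed_hits: dict[str, TypedHit],
    genome: GenomeRecord,
    params: CallParams = CallParams(),
) -> list[Locus]:
    """Group hits greedily along gene order, per contig and per type."""
    loci: list[Locus] = []
    for rep in sorted(genome.replicons, key=lambda r: r.contig_id):
        per_type: dict[str, list[TypedHit]] = {}
        for gene in rep.genes:
            hit = typed_hits.get(gene.gene_id)
            if hit is not None:
                per_type.setdefault(hit.fla_type, []).append(hit)
        for fla_type in sorted(per_type):
            hits = sorted(per_type[fla_type], key=lambda h: h.ordinal)
            current = [hits[0]]
            for h in hits[1:]:
                if h.ordinal - current[-1].ordinal - 1 > params.max_gap:
                    loci.append(Locus(rep.contig_id, fla_type, current))
                    current = []
                current.append(h)
            loci.append(Locus(rep.contig_id, fla_type, current))
    return loci


def _reference_size(fla_type: str, references: list[ReferenceSet]) -> int:
    for ref in references:
        if ref.fla_type == fla_type:
            return len(ref.members)
    raise DataError(f"no reference set for type {fla_type}")


def call_fgc(
    locus: Locus,
    genome_id: str,
    references: list[ReferenceSet] | None = None,
    params: CallParams = CallParams(),
    all_hits: dict[str, TypedHit] | None = None,
) -> FGCall | None:
    """Emit a call when the locus covers enough of its reference set.

    The call type is the majority vote over all typed hits inside the
    locus span (ties yield no call, logged); the fraction is the number
    of distinct matched reference members over the reference size.
    """
    if references is None:
        references = list(flagellar_references())
    lo, hi = locus.span
    in_span = list(locus.hits)
    if all_hits:
        extra = [
            h
            for h in all_hits.values()
            if h.contig_id == locus.contig_id
            and lo <= h.ordinal <= hi
            and h.fla_type != locus.fla_type
        ]
        in_span += extra
    votes: dict[str, int] = {}
    for h in in_span:
        votes[h.fla_type] = votes.get(h.fla_type, 0) + 1
    top = max(votes.values())
    winners = sorted(t for t, v in votes.items() if v == top)
    if len(winners) > 1:
        logger.warning(
            "locus %s:%s-%s: tied type vote %s, no call", locus.contig_id, lo, hi, winners
        )
        return None
    fla_type = winners[0]
    matched = {
        h.ref_gene_id: h.gene_id for h in in_span if h.fla_type == fla_type
    }
    fraction = len(matched) / _reference_size(fla_type, references)
    if fraction < params.min_fraction:
        return None
    return FGCall(
        genome_id=genome_id,
        contig_id=locus.contig_id,
        fla_type=fla_type,
        span=locus.span,
        matched=matched,
        fraction_matched=fraction,
    )


def assign_replicon(
    call: FGCall,
    genome: GenomeRecord,
    replicase_refs: list[ReplicaseRef] | None = None,
    params: CallParams = CallParams(),
) -> FGCall:
    """Plasmid if any gene on the call's contig hits a replicase reference.

    The compatibility group is the best-hit replicase's class and
    subtype; contigs with no replicase hit are chromosome-encoded. Two
    distinct replicase classes on one contig are both recorded, with a
    warning.
    """
    if replicase_refs is None:
        replicase_refs = list(replicase_references())
    contig_genes = []
    for rep in genome.replicons:
        if rep.contig_id == call.contig_id:
            contig_genes = rep.genes
    ids = [g.gene_id for g in contig_genes]
    seqs = [g.sequence for g in contig_genes]
    ref_ids = [r.ref_id for r in replicase_refs]
    ref_seqs = [r.sequence for r in replicase_refs]
    S = _score_matrix(seqs, ref_seqs, params.align)
    best = _best_from_scores(
        ids, seqs, ref_ids, ref_seqs, S, params.thresholds, params.align
    )
    if not best:
        call.replicon_kind = "chromosome"
        call.compat_group = None
        return call
    groups = sorted({hit.gene_b for hit in best.values()})
    classes = sorted({g.split("|")[0] for g in groups})
    if len(classes) > 1:
        logger.warning(
            "contig %s carries replicases of multiple classes: %s", call.contig_id, classes
        )
    call.replicon_kind = "plasmid"
    call.compat_group = "+".join(groups)
    return call


def call_genome(
    genome: GenomeRecord,
    references: list[ReferenceSet] | None = None,
    replicase_refs: list[ReplicaseRef] | None = None,
    params: CallParams = CallParams(),
) -> list[FGCall]:
    """Full per-genome pipeline: score, cluster, call, merge, localize.

    Sub-threshold loci of the same type on the same contig are merged
    and re-tested jointly (second pass), so a large insertion that
    splits a cluster still yields one call.
    """
    if references is None:
        references = list(flagellar_references())
    hits = score_against_references(genome.genes(), references, params)
    loci = cluster_hits(hits, genome, params)
    calls: list[FGCall] = []
    leftovers: dict[tuple[str, str], list[Locus]] = {}
    for locus in loci:
        call = call_fgc(locus, genome.genome_id, references, params, all_hits=hits)
        if call is not None:
            calls.append(call)
        else:
            leftovers.setdefault((locus.contig_id, locus.fla_type), []).append(locus)
    still_uncalled: dict[str, list[Locus]] = {}
    for (contig, fla_type), group in sorted(leftovers.items()):
        merged_hits = [h for l in group for h in l.hits]
        matched = {h.ref_gene_id: h.gene_id for h in merged_hits}
        fraction = len(matched) / _reference_size(fla_type, references)
        if fraction >= params.min_fraction:
            ords = [h.ordinal for h in merged_hits]
            calls.append(
                FGCall(
                    genome_id=genome.genome_id,
                    contig_id=contig,
                    fla_type=fla_type,
                    span=(min(ords), max(ords)),
                    matched=matched,
                    fraction_matched=fraction,
                )
            )
        else:
            still_uncalled.setdefault(fla_type, []).extend(group)
    # third pass: clusters split across contigs (draft assemblies or
    # inter-replicon recombination) are one system per genome per type
    for fla_type, group in sorted(still_uncalled.items()):
        if any(c.fla_type == fla_type for c in calls):
            continue
        matched = {h.ref_gene_id: h.gene_id for l in group for h in l.hits}
        fraction = len(matched) / _reference_size(fla_type, references)
        if fraction >= params.min_fraction:
            anchor = max(group, key=lambda l: (len(l.hits), l.contig_id))
            calls.append(
                FGCall(
                    genome_id=genome.genome_id,
                    contig_id=anchor.contig_id,
                    fla_type=fla_type,
                    span=anchor.span,
                    matched=matched,
                    fraction_matched=fraction,
                )
            )
    calls = [assign_replicon(c, genome, replicase_refs, params) for c in calls]
    calls.sort(key=lambda c: (c.contig_id, c.fla_type, c.span))
    return calls


def summarize_census(
    calls: list[FGCall], genomes: list[GenomeRecord]
) -> dict[str, pd.DataFrame]:
    """Census tables: per-type counts, per-genome combinations, localization.

    The census unit is one system per genome per type (split or merged
    loci of one type count once). A system is plasmid-localized when any
    of its calls is.
    """
    systems: dict[tuple[str, str], list[FGCall]] = {}
    for call in calls:
        systems.setdefault((call.genome_id, call.fla_type), []).append(call)

    type_counts = {t: 0 for t in FLA_TYPES}
    for (_, t) in systems:
        type_counts[t] += 1
    total = sum(type_counts.values())
    census = pd.DataFrame(
        {
            "fla_type": list(FLA_TYPES),
            "n_systems": [type_counts[t] for t in FLA_TYPES],
            "pct": [
                100.0 * type_counts[t] / total if total else 0.0 for t in FLA_TYPES
            ],
        }
    )

    combo_counts = {c: 0 for c in FGC_COMBINATIONS}
    for genome in genomes:
        present = sorted({t for (gid, t) in systems if gid == genome.genome_id})
        combo = "+".join(present) if present else "none"
        combo_counts[combo] += 1
    combos = pd.DataFrame(
        {"combination": list(FGC_COMBINATIONS), "n_genomes": [combo_counts[c] for c in FGC_COMBINATIONS]}
    )

    loc_rows = []
    for (gid, t), syscalls in sorted(systems.items()):
        plasmid = [c for c in syscalls if c.replicon_kind == "plasmid"]
        loc_rows.append(
            {
                "genome_id": gid,
                "fla_type": t,
                "replicon_kind": "plasmid" if plasmid else "chromosome",
                "compat_group": plasmid[0].compat_group if plasmid else "",
            }
        )
    localization = pd.DataFrame(
        loc_rows, columns=["genome_id", "fla_type", "replicon_kind", "compat_group"]
    )

    assert int(census["n_systems"].sum()) == len(systems)
    assert int(combos["n_genomes"].sum()) == len(genomes)
    return {"census": census, "combinations": combos, "localization": localization}
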