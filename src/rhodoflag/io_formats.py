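"""Readers and writers for the formats every other stage consumes.

Genomes are modelled at the gene level: a genome is a set of replicons
(contigs), each an ordered list of protein-coding genes with amino-acid
sequences. Gene positions are 0-based ordinal indices along their contig
-- the downstream cluster logic only needs gene adjacency, never base
pairs. Strand is carried as metadata but used by no computation.

All writers are deterministic: fixed column order, sorted rows, floats at
six significant digits, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import DataError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted in input sequences (20 canonical + ambiguous X).
ALPHABET = frozenset(AMINO_ACIDS + "X")

GAP = "-"

STRANDS = ("+", "-", "unknown")
REPLICON_KINDS = ("chromosome", "plasmid", "unknown")


@dataclass
class GeneRecord:
    """One protein-coding gene on a contig."""

    gene_id: str
    genome_id: str
    contig_id: str
    ordinal: int
    strand: str = "unknown"
    sequence: str = ""
    family_truth: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise DataError(
                f"gene {self.gene_id}: strand must be one of {STRANDS}, got {self.strand!r}"
            )
        if self.ordinal < 0:
            raise DataError(f"gene {self.gene_id}: ordinal must be >= 0")
        if len(self.sequence) < 1:
            raise DataError(f"gene {self.gene_id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise DataError(
                f"gene {self.gene_id}: invalid residues {sorted(bad)} (alphabet is 20 aa + X)"
            )


@dataclass
class Replicon:
    contig_id: str
    declared_kind: str = "unknown"
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.declared_kind not in REPLICON_KINDS:
            raise DataError(
                f"contig {self.contig_id}: declared_kind must be one of {REPLICON_KINDS}"
            )


@dataclass
class GenomeRecord:
    """A genome: uniquely named replicons, each with ordered genes.

    ``declared_kind`` on replicons is provenance metadata only; replicon
    localization calls must come from :mod:`rhodoflag.fgc_typing`.
    """

    genome_id: str
    replicons: list[Replicon] = field(default_factory=list)

    def genes(self) -> list[GeneRecord]:
        return [g for rep in self.replicons for g in rep.genes]

    def validate(self) -> None:
        seen_contigs: set[str] = set()
        seen_genes: set[str] = set()
        for rep in self.replicons:
            if rep.contig_id in seen_contigs:
                raise DataError(
                    f"genome {self.genome_id}: duplicate contig_id {rep.contig_id}"
                )
            seen_contigs.add(rep.contig_id)
            for i, g in enumerate(rep.genes):
                if g.ordinal != i:
                    raise DataError(
                        f"genome {self.genome_id} contig {rep.contig_id}: ordinals must "
                        f"be consecutive from 0 (gene {g.gene_id} at position {i} has "
                        f"ordinal {g.ordinal})"
                    )
                if g.gene_id in seen_genes:
                    raise DataError(
                        f"genome {self.genome_id}: duplicate gene_id {g.gene_id}"
                    )
                seen_genes.add(g.gene_id)


TABLE_COLUMNS = ["gene_id", "genome_id", "contig_id", "ordinal", "strand"]


def read_proteomes(fasta_paths: list[str], table_path: str) -> list[GenomeRecord]:
    """Join protein FASTA records to a gene coordinate table.

    FASTA headers are gene_ids; the TSV table carries gene_id, genome_id,
    contig_id, ordinal and strand (plus an optional family_truth column
    written by the simulator). Output is independent of input file order:
    genomes sorted by genome_id, genes per contig sorted by ordinal.
    """
    seqs: dict[str, str] = {}
    for path in fasta_paths:
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in seqs:
                raise DataError(f"duplicate FASTA record {rec.id}")
            seqs[rec.id] = str(rec.seq).upper()

    table = pd.read_csv(table_path, sep="\t", dtype=str)
    missing_cols = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise DataError(f"gene table {table_path} lacks columns {missing_cols}")

    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DataError(f"duplicate gene_id {dup} in gene table")
    table_ids = set(table["gene_id"])
    for gid in table["gene_id"]:
        if gid not in seqs:
            raise DataError(f"gene {gid} in table has no FASTA record")
    for gid in seqs:
        if gid not in table_ids:
            raise DataError(f"FASTA record {gid} absent from gene table")

    has_truth = "family_truth" in table.columns
    genomes: dict[str, dict[str, list[GeneRecord]]] = {}
    for row in table.itertuples(index=False):
        truth = getattr(row, "family_truth", None) if has_truth else None
        if isinstance(truth, float) and math.isnan(truth):
            truth = None
        gene = GeneRecord(
            gene_id=row.gene_id,
            genome_id=row.genome_id,
            contig_id=row.contig_id,
            ordinal=int(row.ordinal),
            strand=row.strand,
            sequence=seqs[row.gene_id],
            family_truth=truth,
        )
        genomes.setdefault(row.genome_id, {}).setdefault(row.contig_id, []).append(gene)

    out: list[GenomeRecord] = []
    for genome_id in sorted(genomes):
        replicons = []
        for contig_id in sorted(genomes[genome_id]):
            genes = sorted(genomes[genome_id][contig_id], key=lambda g: g.ordinal)
            replicons.append(Replicon(contig_id=contig_id, genes=genes))
        rec = GenomeRecord(genome_id=genome_id, replicons=replicons)
        rec.validate()
        out.append(rec)
    return out


def write_proteomes(
    genomes: list[GenomeRecord], fasta_path: str, table_path: str
) -> None:
    """Inverse of :func:`read_proteomes` (declared_kind is not persisted)."""
    rows = []
    with open(fasta_path, "w") as fh:
        for genome in sorted(genomes, key=lambda g: g.genome_id):
            for rep in sorted(genome.replicons, key=lambda r: r.contig_id):
                for gene in rep.genes:
                    fh.write(f">{gene.gene_id}\n{gene.sequence}\n")
                    rows.append(
                        {
                            "gene_id": gene.gene_id,
                            "genome_id": gene.genome_id,
                            "contig_id": gene.contig_id,
                            "ordinal": gene.ordinal,
                            "strand": gene.strand,
                            "family_truth": gene.family_truth or "",
                        }
                    )
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; supports as internal node labels are kept."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parser subclasses
        raise DataError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise DataError("duplicate leaf names in Newick tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip() + "\n"


def read_counts(path: str, design_path: str) -> tuple[pd.DataFrame, pd.Series]:
    """Read a gene x sample count TSV and its sample->condition design.

    Entries must be non-negative integers; every sample must appear in
    the design file.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    num = counts.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = num.columns[num.isna().any()][0]
        raise DataError(f"non-numeric count entry in sample {bad}")
    if (num < 0).any().any():
        bad = num.columns[(num < 0).any()][0]
        raise DataError(f"negative count entry in sample {bad}")
    if ((num % 1) != 0).any().any():
        bad = num.columns[((num % 1) != 0).any()][0]
        raise DataError(f"non-integer count entry in sample {bad}")
    counts = num.astype(int)

    design = pd.read_csv(design_path, sep="\t", dtype=str)
    if list(design.columns[:2]) != ["sample", "condition"]:
        raise DataError("design file must have columns: sample, condition")
    cond = design.set_index("sample")["condition"]
    missing = [s for s in counts.columns if s not in cond.index]
    if missing:
        raise DataError(f"samples without condition: {missing}")
    return counts, cond.loc[list(counts.columns)]


def write_counts(
    counts: pd.DataFrame, conditions: pd.Series, path: str, design_path: str
) -> None:
    counts.to_csv(path, sep="\t")
    pd.DataFrame(
        {"sample": list(counts.columns), "condition": [conditions[s] for s in counts.columns]}
    ).to_csv(design_path, sep="\t", index=False)


def _render_table(df: pd.DataFrame) -> str:
    out = df.copy()
    if len(out.columns) and len(out):
        out = out.sort_values(by=list(out.columns), kind="mergesort")
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    return buf.getvalue()


def write_tables(tables: dict[str, pd.DataFrame], outdir: str) -> list[str]:
    """Write stage outputs as deterministic TSVs, one file per table.

    Rows are sorted lexicographically over all columns and floats are
    rendered at 6 significant digits, so the same input always yields
    byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for name in sorted(tables):
        path = os.path.join(outdir, f"{name}.tsv")
        try:
            with open(path, "w") as fh:
                fh.write(_render_table(tables[name]))
        except OSError as exc:
            raise DataError(f"cannot write {path}: {exc}") from exc
        paths.append(path)
    return paths


def write_json(obj: object, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
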