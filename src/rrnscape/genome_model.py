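"""Domain model for linear bacterial chromosomes and their rrn loci.

The central objects are :class:`GeneRecord` (one annotated feature),
:class:`RrnLocus` (a group of co-located rRNA genes forming a complete or
unlinked operon), :class:`GenomeAnnotation` (one linear chromosome) and
:class:`Panel` (a set of genomes, optionally with a phylogeny).

Coordinates are 0-based half-open internally; GFF3 emitted on disk uses the
standard 1-based inclusive convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

GENE_KINDS = ("CDS", "rRNA_16S", "rRNA_23S", "rRNA_5S", "tRNA")
RRNA_KINDS = ("rRNA_16S", "rRNA_23S", "rRNA_5S")

#: GFF3 "product" attribute values mapped to internal rRNA kinds
_RRNA_PRODUCTS = {
    "16S": "rRNA_16S",
    "23S": "rRNA_23S",
    "5S": "rRNA_5S",
}

TSV_COLUMNS = [
    "genome_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "kind",
    "product",
    "orthogroup_id",
]


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated gene on a linear chromosome.

    ``start``/``end`` are 0-based half-open with ``start < end``; ``kind`` is
    one of :data:`GENE_KINDS`.  ``orthogroup_id`` is filled in by the
    orthology stage (or by the synthetic generator as ground truth).
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    kind: str
    product: Optional[str] = None
    orthogroup_id: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene {self.gene_id}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class RrnLocus:
    """A group of rRNA genes forming one rrn locus.

    ``completeness`` is ``"complete"`` when the locus holds at least one each
    of 16S, 23S and 5S genes (a canonical operon) and ``"unlinked"``
    otherwise (e.g. a 16S+23S pair missing its 5S, or a lone 5S gene).
    """

    locus_id: str
    member_gene_ids: tuple
    span: tuple  # (start, end)
    strand: str
    completeness: str
    category_label: Optional[str] = None

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def midpoint(self) -> float:
        return (self.span[0] + self.span[1]) / 2.0

    @property
    def is_complete(self) -> bool:
        return self.completeness == "complete"


@dataclass
class GenomeAnnotation:
    """One linear chromosome: a position-sorted gene list plus rrn loci."""

    genome_id: str
    chromosome_length: int
    genes: list = field(default_factory=list)
    rrn_loci: list = field(default_factory=list)
    dnaA_gene_id: Optional[str] = None
    clade: Optional[str] = None

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.gene_id))
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.genome_id}: duplicate gene ids")
        for g in self.genes:
            if g.end > self.chromosome_length:
                raise ValueError(
                    f"{self.genome_id}: gene {g.gene_id} extends past chromosome end"
                )

    # -- lookups -----------------------------------------------------------

    def gene(self, gene_id: str) -> GeneRecord:
        return self._gene_index[gene_id]

    @property
    def _gene_index(self) -> Mapping[str, GeneRecord]:
        idx = getattr(self, "_gene_index_cache", None)
        if idx is None or len(idx) != len(self.genes):
            idx = {g.gene_id: g for g in self.genes}
            object.__setattr__(self, "_gene_index_cache", idx)
        return idx

    def invalidate_cache(self) -> None:
        object.__setattr__(self, "_gene_index_cache", None)

    @property
    def rrna_genes(self) -> list:
        return [g for g in self.genes if g.kind in RRNA_KINDS]

    @property
    def trna_genes(self) -> list:
        return [g for g in self.genes if g.kind == "tRNA"]

    @property
    def cds_genes(self) -> list:
        return [g for g in self.genes if g.kind == "CDS"]

    @property
    def dnaA(self) -> GeneRecord:
        if self.dnaA_gene_id is None:
            raise ValueError(f"{self.genome_id}: no dnaA gene recorded")
        return self.gene(self.dnaA_gene_id)

    @property
    def oric_position(self) -> float:
        """Replication-origin proxy: the midpoint of the dnaA gene."""
        return self.dnaA.midpoint

    def core_genes(self, core_group_ids: Iterable[str]) -> list:
        core = set(core_group_ids)
        return [g for g in self.genes if g.orthogroup_id in core]


@dataclass
class Panel:
    """A collection of annotated genomes, optionally with a rooted phylogeny."""

    genomes: dict
    tree: Optional[dendropy.Tree] = None

    def __post_init__(self):
        if len(self.genomes) < 2:
            raise ValueError("a panel requires at least 2 genomes")

    @property
    def genome_ids(self) -> list:
        return sorted(self.genomes)

    def __iter__(self):
        return (self.genomes[g] for g in self.genome_ids)

    def __len__(self):
        return len(self.genomes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_gff3_attributes(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def _kind_from_gff3(ftype: str, product: str) -> Optional[str]:
    if ftype == "CDS":
        return "CDS"
    if ftype == "tRNA":
        return "tRNA"
    if ftype == "rRNA":
        for token, kind in _RRNA_PRODUCTS.items():
            if token.lower() in product.lower():
                return kind
        raise ValueError(f"rRNA feature with unrecognized product {product!r}")
    return None


def load_annotation(path, genome_id: Optional[str] = None) -> GenomeAnnotation:
    """Load a genome annotation from GFF3 or from the flat TSV dialect.

    The format is chosen from the file suffix (``.gff``/``.gff3`` vs
    ``.tsv``).  A ``dnaA`` gene (CDS whose product or gene tag is dnaA) must
    be present; a genome without rRNA genes loads with a warning and is
    unusable for compartment-level operations.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        genome = _load_gff3(path, genome_id)
    else:
        genome = _load_tsv(path, genome_id)
    if genome.dnaA_gene_id is None:
        raise ValueError(f"genome {genome.genome_id}: no dnaA gene found in {path}")
    if not genome.rrna_genes:
        warnings.warn(
            f"genome {genome.genome_id}: no rRNA genes; "
            "compartment operations will not be possible",
            stacklevel=2,
        )
    return genome


def _load_gff3(path: Path, genome_id: Optional[str]) -> GenomeAnnotation:
    genes = []
    length = None
    dnaA_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                length = int(parts[3])
                if genome_id is None:
                    genome_id = parts[1]
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
            attributes = _parse_gff3_attributes(attrs)
            product = attributes.get("product", "")
            kind = _kind_from_gff3(ftype, product)
            if kind is None:
                continue
            start = int(start1) - 1  # GFF3 is 1-based inclusive
            end = int(end1)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if genome_id is None:
                genome_id = seqid
            gid = attributes.get("ID") or f"{seqid}_{lineno}"
            try:
                gene = GeneRecord(
                    gene_id=gid,
                    genome_id=genome_id,
                    start=start,
                    end=end,
                    strand=strand,
                    kind=kind,
                    product=product or None,
                    orthogroup_id=attributes.get("orthogroup_id") or None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
            if kind == "CDS" and "dnaa" in (product + attributes.get("gene", "")).lower():
                dnaA_id = gid
    if length is None:
        length = max(g.end for g in genes) if genes else 0
    return GenomeAnnotation(
        genome_id=genome_id or path.stem,
        chromosome_length=length,
        genes=genes,
        dnaA_gene_id=dnaA_id,
    )


def _load_tsv(path: Path, genome_id: Optional[str]) -> GenomeAnnotation:
    import pandas as pd

    length = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#chromosome_length="):
            length = int(first.split("=", 1)[1])
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    genes = []
    dnaA_id = None
    for row_index, row in enumerate(table.itertuples(index=False), start=2):
        start, end = int(row.start), int(row.end)
        if end <= start:
            raise ValueError(f"{path}: row {row_index}: end <= start")
        product = None if pd.isna(row.product) else str(row.product)
        og = None if pd.isna(row.orthogroup_id) else str(row.orthogroup_id)
        gene = GeneRecord(
            gene_id=str(row.gene_id),
            genome_id=genome_id or str(row.genome_id),
            start=start,
            end=end,
            strand=str(row.strand),
            kind=str(row.kind),
            product=product,
            orthogroup_id=og,
        )
        genes.append(gene)
        if gene.kind == "CDS" and product and "dnaa" in product.lower():
            dnaA_id = gene.gene_id
    if genome_id is None and genes:
        genome_id = genes[0].genome_id
    if length is None:
        length = max(g.end for g in genes) if genes else 0
    return GenomeAnnotation(
        genome_id=genome_id or path.stem,
        chromosome_length=length,
        genes=genes,
        dnaA_gene_id=dnaA_id,
    )


def write_annotation(genome: GenomeAnnotation, path) -> None:
    """Write a genome annotation as GFF3 or TSV, chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        _write_gff3(genome, path)
    else:
        _write_tsv(genome, path)


def _write_gff3(genome: GenomeAnnotation, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {genome.genome_id} 1 {genome.chromosome_length}\n"
        )
        for g in genome.genes:
            if g.kind == "CDS":
                ftype = "CDS"
                product = g.product or ""
            elif g.kind == "tRNA":
                ftype = "tRNA"
                product = g.product or "tRNA"
            else:
                ftype = "rRNA"
                token = g.kind.split("_")[1]
                product = g.product or f"{token} ribosomal RNA"
            attrs = [f"ID={g.gene_id}"]
            if product:
                attrs.append(f"product={product}")
            if g.orthogroup_id:
                attrs.append(f"orthogroup_id={g.orthogroup_id}")
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        "rrnscape",
                        ftype,
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def _write_tsv(genome: GenomeAnnotation, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chromosome_length={genome.chromosome_length}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for g in genome.genes:
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        g.gene_id,
                        str(g.start),
                        str(g.end),
                        g.strand,
                        g.kind,
                        g.product or "",
                        g.orthogroup_id or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# rrn locus assembly and coordinate utilities
# ---------------------------------------------------------------------------


def assemble_rrn_loci(genome: GenomeAnnotation, max_gap: int = 2000) -> GenomeAnnotation:
    """Group rRNA genes into rrn loci by single linkage on genomic gaps.

    Successive same-strand rRNA genes whose spans lie at most ``max_gap`` bp
    apart merge into one locus.  A locus is complete when it contains at
    least one each of the 16S, 23S and 5S genes; everything else (split
    operons, lone 5S genes) is flagged unlinked.  Every rRNA gene ends up in
    exactly one locus.
    """
    rrna = sorted(genome.rrna_genes, key=lambda g: g.start)
    loci = []
    cluster: list = []

    def flush(cluster):
        if not cluster:
            return
        kinds = {g.kind for g in cluster}
        completeness = "complete" if kinds >= set(RRNA_KINDS) else "unlinked"
        loci.append(
            RrnLocus(
                locus_id=f"{genome.genome_id}_rrn{len(loci) + 1:02d}",
                member_gene_ids=tuple(g.gene_id for g in cluster),
                span=(min(g.start for g in cluster), max(g.end for g in cluster)),
                strand=cluster[0].strand,
                completeness=completeness,
            )
        )

    for g in rrna:
        if cluster and g.strand == cluster[-1].strand and g.start - max(
            c.end for c in cluster
        ) <= max_gap:
            cluster.append(g)
        else:
            flush(cluster)
            cluster = [g]
    flush(cluster)
    genome.rrn_loci = loci
    return genome


def reverse_complement_annotation(genome: GenomeAnnotation) -> GenomeAnnotation:
    """Return the genome viewed from the opposite strand.

    Coordinates map ``x -> L - x`` (interval endpoints swap), strands flip,
    gene order is re-sorted, and rrn loci are transformed in place.  Applying
    the operation twice restores the original annotation.
    """
    L = genome.chromosome_length
    flip = {"+": "-", "-": "+"}
    genes = [
        replace(g, start=L - g.end, end=L - g.start, strand=flip[g.strand])
        for g in genome.genes
    ]
    loci = [
        RrnLocus(
            locus_id=loc.locus_id,
            member_gene_ids=tuple(reversed(loc.member_gene_ids)),
            span=(L - loc.span[1], L - loc.span[0]),
            strand=flip[loc.strand],
            completeness=loc.completeness,
            category_label=loc.category_label,
        )
        for loc in genome.rrn_loci
    ]
    loci.sort(key=lambda loc: loc.span[0])
    return GenomeAnnotation(
        genome_id=genome.genome_id,
        chromosome_length=L,
        genes=genes,
        rrn_loci=loci,
        dnaA_gene_id=genome.dnaA_gene_id,
        clade=genome.clade,
    )


def distance_to_oric(position: float, genome: GenomeAnnotation) -> float:
    """Signed distance (bp) from a position to the dnaA-midpoint oriC proxy."""
    if not (0 <= position <= genome.chromosome_length):
        raise ValueError(
            f"position {position} outside chromosome [0, {genome.chromosome_length}]"
        )
    return position - genome.oric_position
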