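"""Reciprocal-best-hit orthology, orthogroups, core genome and persistence.

Pairs of genomes are compared through protein similarity tables (BLAST
tabular, outfmt 6).  A hit passes when it reaches 40% identity, 70%
coverage of the shorter sequence and an E-value below 1e-10; a reciprocal
best hit (BBH) joins two genes that are each other's unique best passing
hit.  Orthogroups are connected components of the panel-wide BBH graph
(simple linkage); the core genome keeps the groups that are single-copy in
every genome and whose members form a complete BBH clique.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .genome_model import Panel
from .synthetic_data import OUTFMT6_COLUMNS

MIN_IDENTITY = 40.0
MIN_COVERAGE = 70.0
MAX_EVALUE = 1e-10


@dataclass(frozen=True)
class OrthoGroup:
    group_id: str
    members: Mapping[str, frozenset]  # genome_id -> gene ids
    is_core: bool = False
    persistence: float = 0.0

    def genomes(self):
        return set(self.members)

    def n_genes(self):
        return sum(len(v) for v in self.members.values())


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6 table (no header, 12 standard columns)."""
    return pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS)


def _passing(hits: pd.DataFrame, lengths, min_identity, min_coverage, max_evalue):
    df = hits.copy()
    if lengths is not None:
        short = pd.concat(
            [df.qseqid.map(lengths), df.sseqid.map(lengths)], axis=1
        ).min(axis=1)
        df["coverage"] = 100.0 * df["length"] / short
    else:
        df["coverage"] = 100.0  # lengths unknown: taken at face value
    return df[
        (df.pident >= min_identity)
        & (df.coverage >= min_coverage)
        & (df.evalue <= max_evalue)
    ]


def _best_hits(df: pd.DataFrame) -> dict:
    """query -> unique best subject; ties (bitscore, then evalue, then
    identity) void the entry."""
    if df.empty:
        return {}
    ranked = df.sort_values(
        ["qseqid", "bitscore", "evalue", "pident"],
        ascending=[True, False, True, False],
    )
    top = ranked.drop_duplicates("qseqid", keep="first").set_index("qseqid")
    keys = ["bitscore", "evalue", "pident"]
    joined = ranked.join(top[keys], on="qseqid", rsuffix="_top")
    tied = joined[
        (joined.bitscore == joined.bitscore_top)
        & (joined.evalue == joined.evalue_top)
        & (joined.pident == joined.pident_top)
    ]
    # an unresolved tie among distinct subjects voids the best hit
    resolved = tied.groupby("qseqid").sseqid.nunique()
    winners = resolved[resolved == 1].index
    return top.loc[winners].sseqid.to_dict()


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    lengths: Optional[Mapping[str, int]] = None,
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
    max_evalue: float = MAX_EVALUE,
    known_genes: Optional[set] = None,
) -> set:
    """BBH pairs between two genomes as a set of frozensets {a, b}.

    Thresholds are applied before best-hit selection, so a sub-threshold
    hit can never shadow a passing one.
    """
    for df in (hits_ab, hits_ba):
        if known_genes is not None:
            unknown = (set(df.qseqid) | set(df.sseqid)) - known_genes
            if unknown:
                raise ValueError(f"hits reference unknown genes: {sorted(unknown)[:5]}")
    fab = _passing(hits_ab, lengths, min_identity, min_coverage, max_evalue)
    fba = _passing(hits_ba, lengths, min_identity, min_coverage, max_evalue)
    best_ab = _best_hits(fab)
    best_ba = _best_hits(fba)
    pairs = set()
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            pairs.add(frozenset((a, b)))
    return pairs


def build_orthogroups(
    bbh_pairs: Iterable[frozenset], gene_to_genome: Mapping[str, str]
) -> list:
    """Connected components of the BBH graph, as OrthoGroup records."""
    graph = nx.Graph()
    for pair in bbh_pairs:
        a, b = tuple(pair)
        graph.add_edge(a, b)
    groups = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components, start=1):
        members: dict = {}
        for gene in comp:
            members.setdefault(gene_to_genome[gene], set()).add(gene)
        groups.append(
            OrthoGroup(
                group_id=f"OG{i:05d}",
                members={g: frozenset(v) for g, v in sorted(members.items())},
            )
        )
    return groups


def core_genome(
    groups: Iterable[OrthoGroup],
    panel_genome_ids: Iterable[str],
    bbh_pairs: Iterable[frozenset],
) -> list:
    """Flag core groups: single copy in every genome and a full BBH clique.

    Returns all groups with ``is_core`` and ``persistence`` filled in.
    """
    genome_ids = set(panel_genome_ids)
    pair_set = set(bbh_pairs)
    out = []
    for grp in groups:
        single_copy_everywhere = set(grp.members) == genome_ids and all(
            len(v) == 1 for v in grp.members.values()
        )
        is_core = single_copy_everywhere
        if single_copy_everywhere:
            genes = [next(iter(v)) for v in grp.members.values()]
            for a, b in combinations(genes, 2):
                if frozenset((a, b)) not in pair_set:
                    is_core = False
                    break
        persistence = len(grp.members) / len(genome_ids)
        out.append(
            OrthoGroup(grp.group_id, grp.members, is_core, persistence)
        )
    return out


def persistence_index(groups: Iterable[OrthoGroup], n_genomes: int) -> dict:
    """group_id -> fraction of panel genomes containing at least one member."""
    return {g.group_id: len(g.members) / n_genomes for g in groups}


def orthogroup_table(groups: Iterable[OrthoGroup]) -> pd.DataFrame:
    rows = []
    for grp in groups:
        for genome_id, genes in grp.members.items():
            for gene in sorted(genes):
                rows.append(
                    (grp.group_id, genome_id, gene, grp.is_core, grp.persistence)
                )
    return pd.DataFrame(
        rows, columns=["group_id", "genome_id", "gene_id", "is_core", "persistence"]
    )


def run_orthology(panel: Panel, hits: Mapping, lengths=None, **thresholds):
    """BBH + orthogroups + core flags across a whole panel.

    ``hits`` maps ordered genome pairs (A, B) to a DataFrame holding both
    directions (as produced by the synthetic generator) or to one-way
    tables keyed (A, B)/(B, A).  Returns (groups, bbh_pairs).
    """
    gene_to_genome = {
        g.gene_id: genome.genome_id for genome in panel for g in genome.genes
    }
    known = set(gene_to_genome)
    all_pairs = set()
    ids = panel.genome_ids
    for i, A in enumerate(ids):
        for B in ids[i + 1 :]:
            if (A, B) in hits and (B, A) not in hits:
                df = hits[(A, B)]
                genesA = {g for g, gm in gene_to_genome.items() if gm == A}
                ab = df[df.qseqid.isin(genesA)]
                ba = df[~df.qseqid.isin(genesA)]
            else:
                ab, ba = hits[(A, B)], hits[(B, A)]
            all_pairs |= reciprocal_best_hits(
                ab, ba, lengths, known_genes=known, **thresholds
            )
    groups = build_orthogroups(all_pairs, gene_to_genome)
    groups = core_genome(groups, ids, all_pairs)
    return groups, all_pairs


def truth_orthogroups(panel: Panel) -> list:
    """Orthogroups straight from generator ground truth (orthogroup_id tags)."""
    members: dict = {}
    for genome in panel:
        for g in genome.genes:
            if g.kind == "CDS" and g.orthogroup_id:
                members.setdefault(g.orthogroup_id, {}).setdefault(
                    genome.genome_id, set()
                ).add(g.gene_id)
    n = len(panel)
    groups = []
    ids = set(panel.genome_ids)
    for gid in sorted(members):
        m = members[gid]
        is_core = set(m) == ids and all(len(v) == 1 for v in m.values())
        groups.append(
            OrthoGroup(
                gid,
                {g: frozenset(v) for g, v in sorted(m.items())},
                is_core,
                len(m) / n,
            )
        )
    return groups
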