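"""Chromosome compartments: central compartment, core region, tDNA region.

The central compartment is the interval delimited by the two outermost
("distal") rrn loci (span-inclusive).  The core region spans the outermost
core genes, the tDNA region the outermost tRNA genes; the two terminal
compartments are the complements of the central compartment.  Core groups
are classified as CCC (central-compartment core) when they fall inside the
central compartment in at least a threshold fraction of panel genomes, TCC
when outside at the same threshold, and unstable otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .genome_model import GenomeAnnotation, Panel


@dataclass(frozen=True)
class CompartmentMap:
    genome_id: str
    chromosome_length: int
    central: tuple
    core_region: tuple
    tdna_region: Optional[tuple]
    terminal_left: tuple
    terminal_right: tuple

    @property
    def central_size(self) -> int:
        return self.central[1] - self.central[0]

    @property
    def core_region_size(self) -> int:
        return self.core_region[1] - self.core_region[0]

    @property
    def tdna_size(self) -> Optional[int]:
        if self.tdna_region is None:
            return None
        return self.tdna_region[1] - self.tdna_region[0]

    @property
    def central_fraction(self) -> float:
        return self.central_size / self.chromosome_length

    def in_central(self, position: float) -> bool:
        return self.central[0] <= position <= self.central[1]


def compartment_map(
    genome: GenomeAnnotation,
    core_group_ids: Iterable[str],
    complete_only: bool = False,
) -> CompartmentMap:
    """Delimit the compartments of one genome.

    ``complete_only`` restricts the distal delimiters to complete operons;
    by default every rrn locus (including unlinked and lone-5S loci) counts.
    """
    loci = sorted(genome.rrn_loci, key=lambda l: l.span[0])
    if complete_only:
        loci = [l for l in loci if l.is_complete]
    if len(loci) < 2:
        raise ValueError(
            f"{genome.genome_id}: fewer than 2 rrn loci; the central "
            "compartment is undefined (check rrn annotation or relax "
            "complete_only)"
        )
    central = (loci[0].span[0], loci[-1].span[1])
    core = sorted(genome.core_genes(core_group_ids), key=lambda g: g.start)
    if len(core) < 2:
        raise ValueError(f"{genome.genome_id}: fewer than 2 core genes")
    core_region = (core[0].start, core[-1].end)
    trnas = genome.trna_genes
    tdna = (
        (min(g.start for g in trnas), max(g.end for g in trnas)) if trnas else None
    )
    return CompartmentMap(
        genome_id=genome.genome_id,
        chromosome_length=genome.chromosome_length,
        central=central,
        core_region=core_region,
        tdna_region=tdna,
        terminal_left=(0, central[0]),
        terminal_right=(central[1], genome.chromosome_length),
    )


def core_density(
    interval: tuple, genome: GenomeAnnotation, core_group_ids
) -> float:
    """Core genes per 10 kb within an interval (by gene midpoint)."""
    s, e = interval
    if e <= s:
        raise ValueError(f"empty interval {interval}")
    n = sum(1 for g in genome.core_genes(core_group_ids) if s <= g.midpoint <= e)
    return n / ((e - s) / 10_000.0)


def rrn_positions_summary(genome: GenomeAnnotation) -> pd.DataFrame:
    """Per-locus distance to oriC (bp and % of central size) and side."""
    loci = sorted(genome.rrn_loci, key=lambda l: l.span[0])
    if len(loci) < 2:
        raise ValueError(f"{genome.genome_id}: fewer than 2 rrn loci")
    central_size = loci[-1].span[1] - loci[0].span[0]
    oric = genome.oric_position
    rows = []
    for loc in loci:
        d = loc.midpoint - oric
        side = None if d == 0 else ("left" if d < 0 else "right")
        rows.append(
            (
                loc.locus_id,
                loc.completeness,
                d,
                abs(d),
                100.0 * abs(d) / central_size,
                side,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "completeness",
            "signed_distance_bp",
            "distance_bp",
            "distance_pct_central",
            "side",
        ],
    )


def classify_ccc_tcc(
    panel: Panel,
    maps: Mapping[str, CompartmentMap],
    core_group_ids,
    threshold: float = 0.95,
) -> dict:
    """Per-core-group compartment class: CCC, TCC or unstable.

    A group is CCC when its member lies inside the central compartment in at
    least ``threshold`` of the genomes where it can be assessed, TCC when
    outside at the same threshold, unstable otherwise.
    """
    core = set(core_group_ids)
    inside: dict = {}
    total: dict = {}
    for genome in panel:
        cmap = maps[genome.genome_id]
        for g in genome.genes:
            if g.orthogroup_id in core:
                total[g.orthogroup_id] = total.get(g.orthogroup_id, 0) + 1
                if cmap.in_central(g.midpoint):
                    inside[g.orthogroup_id] = inside.get(g.orthogroup_id, 0) + 1
    out = {}
    for group in sorted(core):
        n = total.get(group, 0)
        if n == 0:
            out[group] = "unstable"
            continue
        frac_in = inside.get(group, 0) / n
        if frac_in >= threshold:
            out[group] = "CCC"
        elif 1 - frac_in >= threshold:
            out[group] = "TCC"
        else:
            out[group] = "unstable"
    return out
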