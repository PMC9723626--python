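"""Detection of large rearrangements in the central compartment.

For every core gene shared by a genome and the reference inside both central
compartments, the positional offset ``delta`` (gene start in the genome
minus gene start in the reference) is computed along the reference order,
then differenced between successive genes (``delta_delta``).  Positions
where ``|delta_delta|`` exceeds 200 kb mark breakpoints; consecutive
breakpoints are paired into events (an inversion when the enclosed segment
runs backwards in the genome, otherwise a displacement), events shared by a
clade are counted once with averaged size and rrn distances, and each event
end is measured against the nearest rrn locus.

Detection resolution is bounded by the local core-gene spacing: a breakpoint
can only be located between two consecutive core genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .genome_model import GenomeAnnotation, reverse_complement_annotation
from .skeleton import synteny_pairs

DEFAULT_THRESHOLD = 200_000.0


@dataclass(frozen=True)
class DeltaTrack:
    genome_id: str
    reference_id: str
    groups: tuple  # shared central core groups, reference chromosomal order
    ref_positions: tuple
    genome_positions: tuple
    flipped: bool  # genome was reverse-complemented to match orientation

    @property
    def delta(self) -> np.ndarray:
        return np.asarray(self.genome_positions, float) - np.asarray(
            self.ref_positions, float
        )

    @property
    def delta_delta(self) -> np.ndarray:
        return np.diff(self.delta)


@dataclass(frozen=True)
class RearrangementEvent:
    event_id: str
    genomes: tuple
    left_boundary_group: Optional[str]
    right_boundary_group: Optional[str]
    segment_groups: tuple
    size: float
    type: str  # inversion | other
    end_positions: tuple  # genome coordinates of the two segment ends
    open_ended: bool = False
    min_distance: Optional[float] = None
    max_distance: Optional[float] = None
    end_details: tuple = ()  # ((nearest label, distance) per end)


def delta_track(
    genome: GenomeAnnotation,
    reference: GenomeAnnotation,
    core_group_ids,
    central_genome: tuple,
    central_reference: tuple,
) -> DeltaTrack:
    """Per-core-gene positional offsets against the reference.

    The genome is auto-flipped when pairwise synteny says it is globally
    inverted relative to the reference; positions are gene starts, restricted
    to groups inside both genomes' central compartments.
    """
    comp = synteny_pairs(genome, reference, core_group_ids)
    flipped = comp.orientation == "inverted"
    if flipped:
        genome = reverse_complement_annotation(genome)
        cg = (
            genome.chromosome_length - central_genome[1],
            genome.chromosome_length - central_genome[0],
        )
    else:
        cg = central_genome
    pos_g = {
        g.orthogroup_id: g.start
        for g in genome.core_genes(core_group_ids)
        if cg[0] <= g.midpoint <= cg[1]
    }
    pos_r = {
        g.orthogroup_id: g.start
        for g in reference.core_genes(core_group_ids)
        if central_reference[0] <= g.midpoint <= central_reference[1]
    }
    shared = [gid for gid in pos_r if gid in pos_g]
    shared.sort(key=lambda gid: pos_r[gid])
    if len(shared) < 10:
        raise ValueError(
            f"{genome.genome_id} vs {reference.genome_id}: fewer than 10 "
            "shared central core genes"
        )
    return DeltaTrack(
        genome_id=genome.genome_id,
        reference_id=reference.genome_id,
        groups=tuple(shared),
        ref_positions=tuple(pos_r[g] for g in shared),
        genome_positions=tuple(pos_g[g] for g in shared),
        flipped=flipped,
    )


def detect_events(track: DeltaTrack, threshold: float = DEFAULT_THRESHOLD) -> list:
    """Pair above-threshold ``delta_delta`` positions into events.

    Breakpoint ``i`` sits between genes ``i`` and ``i+1`` of the reference
    order.  Consecutive breakpoints bound a segment; a segment whose genome
    positions strictly decrease is an inversion, anything else a
    displacement ("other").  An odd trailing breakpoint yields an event with
    one open end.
    """
    dd = track.delta_delta
    breaks = [i for i in range(len(dd)) if abs(dd[i]) > threshold]
    gp = np.asarray(track.genome_positions, float)
    events = []
    i = 0
    while i < len(breaks):
        if i + 1 < len(breaks):
            b1, b2 = breaks[i], breaks[i + 1]
            seg = slice(b1 + 1, b2 + 1)
            seg_pos = gp[seg]
            etype = (
                "inversion"
                if len(seg_pos) >= 2 and np.all(np.diff(seg_pos) < 0)
                else "other"
            )
            events.append(
                RearrangementEvent(
                    event_id=f"{track.genome_id}_ev{len(events) + 1}",
                    genomes=(track.genome_id,),
                    left_boundary_group=track.groups[b1],
                    right_boundary_group=track.groups[b2 + 1],
                    segment_groups=tuple(track.groups[seg]),
                    size=float(seg_pos.max() - seg_pos.min()),
                    type=etype,
                    end_positions=(float(seg_pos.min()), float(seg_pos.max())),
                )
            )
            i += 2
        else:
            b1 = breaks[i]
            seg_pos = gp[b1 + 1 :]
            events.append(
                RearrangementEvent(
                    event_id=f"{track.genome_id}_ev{len(events) + 1}",
                    genomes=(track.genome_id,),
                    left_boundary_group=track.groups[b1],
                    right_boundary_group=None,
                    segment_groups=tuple(track.groups[b1 + 1 :]),
                    size=float(abs(dd[b1])),
                    type="other",
                    end_positions=(float(gp[b1 + 1]),),
                    open_ended=True,
                )
            )
            i += 1
    return events


def distances_to_rrn(event: RearrangementEvent, genome: GenomeAnnotation) -> RearrangementEvent:
    """Fill in per-end nearest-rrn labels and event-level min/max distances."""
    loci = sorted(genome.rrn_loci, key=lambda l: l.span[0])
    if not loci:
        raise ValueError(f"{genome.genome_id}: no rrn loci")
    details = []
    for pos in event.end_positions:
        best = None
        label = None
        for loc in loci:
            if loc.span[0] <= pos <= loc.span[1]:
                d = 0.0
            else:
                d = min(abs(pos - loc.span[0]), abs(pos - loc.span[1]))
            if best is None or d < best:
                best = d
                label = loc.category_label or loc.locus_id
        details.append((label, float(best)))
    dists = [d for _, d in details]
    return replace(
        event,
        min_distance=min(dists),
        max_distance=max(dists),
        end_details=tuple(details),
    )


def _maximal_clades(tree, carriers: set) -> list:
    """Maximal tree nodes whose entire leaf set lies within ``carriers``."""
    from .synthetic_data import _label_nodes

    _label_nodes(tree)
    leafsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = {node._rrn_label}
        else:
            leafsets[id(node)] = set().union(
                *(leafsets[id(c)] for c in node.child_nodes())
            )
    out = []
    for node in tree.preorder_node_iter():
        ls = leafsets[id(node)]
        if not ls <= carriers:
            continue
        parent = node.parent_node
        if parent is None or not leafsets[id(parent)] <= carriers:
            out.append(sorted(ls))
    return out


def deduplicate_events(events: Iterable[RearrangementEvent], tree=None) -> list:
    """Merge the same event observed in related genomes.

    Events sharing both boundary core groups and type merge when their
    carrier genomes form a connected clade of the tree (all carriers merge
    when no tree is given); merged size and rrn distances are arithmetic
    means over the member observations.
    """
    by_key: dict = {}
    for ev in events:
        key = (ev.left_boundary_group, ev.right_boundary_group, ev.type)
        by_key.setdefault(key, []).append(ev)
    merged = []
    for key in sorted(by_key, key=lambda k: (str(k[0]), str(k[1]), k[2])):
        group = by_key[key]
        carriers = sorted({g for ev in group for g in ev.genomes})
        if tree is None:
            clades = [carriers]
        else:
            clades = _maximal_clades(tree, set(carriers))
        for clade in clades:
            members = [ev for ev in group if set(ev.genomes) & set(clade)]
            if not members:
                continue
            sizes = [ev.size for ev in members]
            mins = [ev.min_distance for ev in members if ev.min_distance is not None]
            maxs = [ev.max_distance for ev in members if ev.max_distance is not None]
            merged.append(
                replace(
                    members[0],
                    event_id=f"merged_{len(merged) + 1}",
                    genomes=tuple(clade),
                    size=float(np.mean(sizes)),
                    min_distance=float(np.mean(mins)) if mins else None,
                    max_distance=float(np.mean(maxs)) if maxs else None,
                )
            )
    return merged


def pairwise_events(
    genome: GenomeAnnotation,
    reference: GenomeAnnotation,
    core_group_ids,
    central_genome,
    central_reference,
    threshold: float = DEFAULT_THRESHOLD,
) -> list:
    """delta track -> events -> rrn distances, for one genome/reference pair."""
    track = delta_track(
        genome, reference, core_group_ids, central_genome, central_reference
    )
    target = (
        reverse_complement_annotation(genome) if track.flipped else genome
    )
    return [distances_to_rrn(ev, target) for ev in detect_events(track, threshold)]
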