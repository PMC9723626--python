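"""Synthetic genome panels with known ground truth.

The generator emulates the statistical structure of a panel of linear
actinobacterial chromosomes descending from a six-rrn-operon ancestor:

* a conserved core skeleton of single-copy genes laid down in a fixed
  consensus order, most of it inside the central compartment delimited by
  the two distal rrn operons;
* six complete rrn operons placed asymmetrically around the replication
  origin (about 2/3 on one chromosomal side, 1/3 on the other), co-oriented
  with the direction of continuous replication moving away from oriC;
* pericentric inversions whose breakpoints are drawn from a mixture of a
  uniform background and an exponential kernel around rrn loci;
* rrn duplications (adjacent or ectopic), rrn losses and relocation of 5S
  genes away from their operon (lone-5S loci);
* arm-biased gain and loss of non-core genes;
* all-vs-all protein similarity tables consistent with the planted
  orthology, nucleotide sequences with controlled divergence, and
  negative-binomial expression counts with a central-compartment effect and
  an arm-only distance-to-origin decay.

Every stochastic step is driven by an explicit seed and every applied event
is recorded in a replayable :class:`EventLog`, so downstream detection
stages can be scored against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genome_model import (
    GeneRecord,
    GenomeAnnotation,
    Panel,
    assemble_rrn_loci,
)

# rRNA gene lengths (bp) and intra-operon spacer sizes used throughout
_RRN_LAYOUT = (("rRNA_16S", 1542), ("rRNA_23S", 2904), ("rRNA_5S", 120))
_RRN_GAPS = (150, 80)
_OPERON_SPAN = sum(l for _, l in _RRN_LAYOUT) + sum(_RRN_GAPS)  # 4796
_DNAA_LENGTH = 1350


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class AncestorSpec:
    """Blueprint of the ancestral genome.

    ``rrn_relative_positions`` are signed fractions of the central-
    compartment half-spans around oriC (-1 = left compartment edge, +1 =
    right edge); the default places four operons left of the origin and two
    right of it, the asymmetric ~2:1 split.
    """

    n_core: int = 1017
    n_noncore_central: int = 600
    n_noncore_arm: int = 1400
    n_trna: int = 60
    chromosome_length: int = 8_000_000
    rrn_relative_positions: Sequence[float] = (-1.0, -0.7, -0.45, -0.2, 0.5, 1.0)
    central_span: Sequence[float] = (0.20, 0.80)
    oric_fraction: float = 0.55
    core_span: Sequence[float] = (0.17, 0.84)
    tdna_span: Sequence[float] = (0.15, 0.86)
    arm_gene_span: Sequence[float] = (0.02, 0.98)
    core_in_central_fraction: float = 0.885
    gene_length_mean: float = 900.0
    gene_length_sd: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if len(self.rrn_relative_positions) != 6:
            raise ValueError("the ancestor carries exactly 6 rrn operons")
        if len(set(self.rrn_relative_positions)) != 6:
            raise ValueError("rrn relative positions must be distinct")
        if self.n_core < 10:
            raise ValueError("n_core must be at least 10")


@dataclass
class EvolutionSpec:
    """Per-branch event rates (expected events per unit branch length)."""

    inversion_rate: float = 0.3
    inversion_size_range: Sequence[float] = (250_000.0, 2_000_000.0)
    p_breakpoint_near_rrn: float = 0.7
    breakpoint_kernel_bp: float = 100_000.0
    duplication_rate: float = 0.2
    duplication_adjacent_prob: float = 0.7
    rrn_loss_rate: float = 0.1
    lone_5s_rate: float = 0.05
    gene_gain_rate: float = 4.0
    gene_loss_rate: float = 4.0
    arm_bias: float = 3.0
    jitter_sd: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class Event:
    """One applied (or skipped) evolutionary event with concrete parameters."""

    branch: str
    event_type: str
    params: tuple  # sorted (key, value) pairs; JSON-safe
    skipped: bool = False

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    @staticmethod
    def make(branch, event_type, params, skipped=False) -> "Event":
        items = tuple(sorted((k, _jsonify(v)) for k, v in params.items()))
        return Event(branch, event_type, items, skipped)


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return tuple(_jsonify(x) for x in v)
    return v


class EventLog(list):
    """Ordered record of events; replaying it on the ancestor reproduces
    every leaf genome exactly."""

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "branch": e.branch,
                    "event_type": e.event_type,
                    "params": {k: v for k, v in e.params},
                    "skipped": e.skipped,
                }
                for e in self
            ],
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        out = cls()
        for rec in json.loads(text):
            out.append(
                Event.make(
                    rec["branch"], rec["event_type"], rec["params"], rec["skipped"]
                )
            )
        return out

    def for_branch(self, branch: str) -> list:
        return [e for e in self if e.branch == branch]


@dataclass
class ExpressionSpec:
    """Negative-binomial expression model over one genome.

    Per-CDS mean = ``baseline`` x gene length (kb) x ``central_multiplier``
    (genes inside the distal-rrn interval) x ``exp(-distance_decay * |bp to
    oriC|)`` (arm genes only) x ``exp(persistence_coupling * (persistence -
    0.5))`` x a per-sample depth factor.  ``dispersion`` is the NB alpha
    (variance = mu + alpha * mu^2); zero gives Poisson counts.
    """

    baseline: float = 200.0
    central_multiplier: float = 4.0
    distance_decay: float = 1.0e-6
    dispersion: float = 0.1
    persistence_coupling: float = 0.0
    samples_per_phase: int = 3
    idiophase_factor: float = 0.7
    depth_range: Sequence[float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self):
        if self.central_multiplier < 1:
            raise ValueError("central_multiplier must be >= 1")
        if self.distance_decay < 0:
            raise ValueError("distance_decay must be >= 0")


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------


def _interleave(counts: Mapping[str, int]) -> list:
    """Merge item kinds so each is evenly spread along a zone."""
    entries = []
    for kind, n in counts.items():
        if n <= 0:
            continue
        offs = (np.arange(n) + 0.5) / n
        entries.extend((float(o), kind) for o in offs)
    entries.sort()
    return [kind for _, kind in entries]


def _lay_genes(zone, items, lengths, reserved, rng, min_gap=20, cursor=0):
    """Sweep gene intervals across a zone, dodging reserved windows.

    ``cursor`` carries the sweep position across zones so genes can never
    overlap (distinct starts are what gives well-defined core ranks).
    Returns ``(placed, cursor)``.
    """
    zs, ze = zone
    n = len(items)
    if n == 0:
        return [], cursor
    spacing = (ze - zs) / n
    placed = []
    cursor = max(cursor, zs)
    for i in range(n):
        target = zs + i * spacing + rng.uniform(0, 0.3 * spacing)
        s = max(target, cursor)
        length = int(lengths[i])
        moved = True
        while moved:
            moved = False
            for rs, re_ in reserved:
                if s < re_ and s + length > rs:
                    s = re_ + 50
                    moved = True
        placed.append((int(s), int(s) + length, items[i]))
        cursor = s + length + min_gap
    return placed, cursor


def make_ancestor(spec: AncestorSpec):
    """Build the ancestral genome and its core-order table.

    Returns ``(genome, core_order)`` where ``core_order`` is a DataFrame with
    columns ``rank`` and ``group_id`` (rank 1..n_core along the chromosome).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chromosome_length
    cl, cr = (int(f * L) for f in spec.central_span)
    kl, kr = (int(f * L) for f in spec.core_span)
    tl, tr = (int(f * L) for f in spec.tdna_span)
    al, ar = (int(f * L) for f in spec.arm_gene_span)
    oric = int(spec.oric_fraction * L)
    if not (al < tl < kl < cl < oric < cr < kr < tr < ar):
        raise ValueError("ancestor spans must nest: arm > tdna > core > central")

    total_span = (
        spec.n_core + spec.n_noncore_central + spec.n_noncore_arm + spec.n_trna
    ) * (spec.gene_length_mean + 100) + 6 * _OPERON_SPAN
    if total_span > L:
        raise ValueError("requested genes cannot fit on the chromosome")

    # rrn operon midpoints from signed half-span fractions
    rrn_mid = []
    for f in sorted(spec.rrn_relative_positions):
        half = (oric - cl) if f < 0 else (cr - oric)
        rrn_mid.append(int(oric + f * half))
    half_op = _OPERON_SPAN // 2
    reserved = [(m - half_op - 1000, m + half_op + 1000) for m in rrn_mid]
    dnaa_window = (oric - _DNAA_LENGTH // 2 - 800, oric + _DNAA_LENGTH // 2 + 800)
    reserved.append(dnaa_window)
    reserved.sort()

    # core gene counts per region
    n_central_core = int(round(spec.n_core * spec.core_in_central_fraction)) - 1
    rest = spec.n_core - 1 - n_central_core  # dnaA occupies one central slot
    left_w, right_w = (cl - kl), (kr - cr)
    n_left_core = int(round(rest * left_w / (left_w + right_w)))
    n_right_core = rest - n_left_core

    # non-core arm genes distributed across the four arm zones by length
    zones_arm = [(al, kl), (kl, cl), (cr, kr), (kr, ar)]
    wts = np.array([b - a for a, b in zones_arm], dtype=float)
    arm_counts = np.floor(spec.n_noncore_arm * wts / wts.sum()).astype(int)
    arm_counts[0] += spec.n_noncore_arm - int(arm_counts.sum())

    # tRNAs: two pinned at the tDNA-region edges, the rest spread over it
    n_trna_inner = max(spec.n_trna - 2, 0)
    trna_zone_w = np.array([kl - tl, cl - kl, cr - cl, kr - cr, tr - kr], float)
    trna_counts = np.floor(n_trna_inner * trna_zone_w / trna_zone_w.sum()).astype(int)
    trna_counts[2] += n_trna_inner - int(trna_counts.sum())

    def glen(n):
        return np.clip(
            rng.normal(spec.gene_length_mean, spec.gene_length_sd, n), 200, 3000
        ).astype(int)

    zone_plans = [
        ((al, tl), {"NC": arm_counts[0]}),
        ((tl + 100, kl), {"NC": 0, "tRNA": trna_counts[0]}),
        ((kl, cl), {"CORE": n_left_core, "NC": arm_counts[1], "tRNA": trna_counts[1]}),
        (
            (cl, cr),
            {
                "CORE": n_central_core,
                "NC": spec.n_noncore_central,
                "tRNA": trna_counts[2],
            },
        ),
        ((cr, kr), {"CORE": n_right_core, "NC": arm_counts[2], "tRNA": trna_counts[3]}),
        ((kr, tr - 100), {"NC": 0, "tRNA": trna_counts[4]}),
        ((tr + 100, ar), {"NC": arm_counts[3]}),
    ]

    placed = []  # (start, end, tag)
    cursor = 0
    for zone, counts in zone_plans:
        items = _interleave(counts)
        lengths = [80 if it == "tRNA" else glen(1)[0] for it in items]
        laid, cursor = _lay_genes(zone, items, lengths, reserved, rng, cursor=cursor)
        placed.extend(laid)

    # pinned tDNA-region boundary tRNAs
    placed.append((tl, tl + 80, "tRNA"))
    placed.append((tr - 80, tr, "tRNA"))

    genes = []
    for s, e, tag in placed:
        kind = "tRNA" if tag == "tRNA" else "CDS"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((s, e, kind, strand, tag))
    # dnaA: the core gene pinned at oriC
    genes.append(
        (
            oric - _DNAA_LENGTH // 2,
            oric + _DNAA_LENGTH // 2,
            "CDS",
            "+",
            "DNAA",
        )
    )
    # rrn operons, co-oriented with continuous replication away from oriC
    for m in rrn_mid:
        strand = "+" if m > oric else "-"
        layout = _RRN_LAYOUT if strand == "+" else tuple(reversed(_RRN_LAYOUT))
        gaps = _RRN_GAPS
        pos = m - half_op
        for j, (kind, ln) in enumerate(layout):
            genes.append((pos, pos + ln, kind, strand, "RRN"))
            pos += ln + (gaps[j] if j < len(gaps) else 0)

    genes.sort(key=lambda t: t[0])
    records = []
    dnaa_id = None
    core_items = []
    nog_counter = 0
    for i, (s, e, kind, strand, tag) in enumerate(genes):
        gid = f"ancestor_g{i + 1:05d}"
        product = None
        group = None
        if tag == "DNAA":
            product = "chromosomal replication initiator protein DnaA"
            dnaa_id = gid
            core_items.append((s, gid))
        elif tag == "CORE":
            core_items.append((s, gid))
        elif tag == "NC":
            nog_counter += 1
            group = f"NOG{nog_counter:05d}"
        records.append(
            GeneRecord(gid, "ancestor", s, e, strand, kind, product, group)
        )

    # core group ids follow chromosomal rank
    core_items.sort()
    rank_of = {gid: r + 1 for r, (_, gid) in enumerate(core_items)}
    records = [
        replace(g, orthogroup_id=f"COG{rank_of[g.gene_id]:05d}")
        if g.gene_id in rank_of
        else g
        for g in records
    ]
    genome = GenomeAnnotation(
        genome_id="ancestor",
        chromosome_length=L,
        genes=records,
        dnaA_gene_id=dnaa_id,
    )
    assemble_rrn_loci(genome)
    core_order = pd.DataFrame(
        {
            "rank": range(1, len(core_items) + 1),
            "group_id": [f"COG{r:05d}" for r in range(1, len(core_items) + 1)],
        }
    )
    return genome, core_order


# ---------------------------------------------------------------------------
# Coordinate-editing primitives
# ---------------------------------------------------------------------------


def _uncovered_gaps(genome: GenomeAnnotation) -> list:
    """Maximal intervals covered by no gene (candidate breakpoints)."""
    gaps = []
    cursor = 0
    for g in genome.genes:
        if g.start > cursor:
            gaps.append((cursor, g.start))
        cursor = max(cursor, g.end)
    if cursor < genome.chromosome_length:
        gaps.append((cursor, genome.chromosome_length))
    return gaps


def _snap_to_gap(genome: GenomeAnnotation, x: float) -> int:
    """Nearest coordinate not covered by any gene."""
    best = None
    best_d = None
    for s, e in _uncovered_gaps(genome):
        p = int(min(max(x, s + 1), e - 1)) if e - s > 2 else (s + e) // 2
        d = abs(p - x)
        if best_d is None or d < best_d:
            best, best_d = p, d
    if best is None:
        raise ValueError("no intergenic gap available")
    return best


def _delete_genes(genome: GenomeAnnotation, gene_ids) -> None:
    ids = set(gene_ids)
    doomed = sorted(
        (g for g in genome.genes if g.gene_id in ids), key=lambda g: -g.start
    )
    for d in doomed:
        genome.genes = [
            replace(g, start=g.start - d.length, end=g.end - d.length)
            if g.start >= d.end
            else g
            for g in genome.genes
            if g.gene_id != d.gene_id
        ]
        genome.chromosome_length -= d.length
    genome.genes.sort(key=lambda g: (g.start, g.gene_id))
    genome.invalidate_cache()


def _insert_genes(genome: GenomeAnnotation, pos: int, new_genes, margin=500) -> None:
    """Insert gene records (coordinates relative to 0) at ``pos``."""
    span = max(g.end for g in new_genes)
    seg = span + 2 * margin
    genome.genes = [
        replace(g, start=g.start + seg, end=g.end + seg) if g.start >= pos else g
        for g in genome.genes
    ]
    genome.genes.extend(
        replace(g, start=g.start + pos + margin, end=g.end + pos + margin)
        for g in new_genes
    )
    genome.chromosome_length += seg
    genome.genes.sort(key=lambda g: (g.start, g.gene_id))
    genome.invalidate_cache()


# ---------------------------------------------------------------------------
# Event application (deterministic given concrete parameters)
# ---------------------------------------------------------------------------


def apply_inversion(genome: GenomeAnnotation, left: int, right: int) -> dict:
    """Reverse-complement the segment [left, right); ends snap to gaps."""
    l = _snap_to_gap(genome, left)
    r = _snap_to_gap(genome, right)
    if l > r:
        l, r = r, l
    flip = {"+": "-", "-": "+"}
    genome.genes = [
        replace(
            g, start=l + r - g.end, end=l + r - g.start, strand=flip[g.strand]
        )
        if l <= g.start and g.end <= r
        else g
        for g in genome.genes
    ]
    genome.genes.sort(key=lambda g: (g.start, g.gene_id))
    genome.invalidate_cache()
    assemble_rrn_loci(genome)
    return {"left": l, "right": r}


def _locus_at(genome, span):
    for loc in genome.rrn_loci:
        if loc.span[0] < span[1] and span[0] < loc.span[1]:
            return loc
    raise ValueError(f"no rrn locus overlapping {span}")


def apply_rrn_duplication(genome, source_span, insert_pos, tag) -> dict:
    loc = _locus_at(genome, source_span)
    members = [genome.gene(gid) for gid in loc.member_gene_ids]
    base = min(g.start for g in members)
    copies = [
        replace(
            g,
            gene_id=f"{g.gene_id}__{tag}",
            start=g.start - base,
            end=g.end - base,
        )
        for g in members
    ]
    pos = _snap_to_gap(genome, insert_pos)
    _insert_genes(genome, pos, copies)
    assemble_rrn_loci(genome)
    return {"source_span": tuple(loc.span), "insert_pos": pos, "tag": tag}


def apply_rrn_loss(genome, source_span) -> dict:
    loc = _locus_at(genome, source_span)
    _delete_genes(genome, loc.member_gene_ids)
    assemble_rrn_loci(genome)
    return {"source_span": tuple(loc.span)}


def apply_lone_5s(genome, source_span, target_pos) -> dict:
    loc = _locus_at(genome, source_span)
    five = [
        genome.gene(gid)
        for gid in loc.member_gene_ids
        if genome.gene(gid).kind == "rRNA_5S"
    ]
    if not five:
        raise ValueError("locus has no 5S gene to relocate")
    g5 = five[0]
    rel = replace(g5, start=0, end=g5.length)
    _delete_genes(genome, [g5.gene_id])
    pos = _snap_to_gap(genome, target_pos if target_pos < genome.chromosome_length else genome.chromosome_length - 1)
    _insert_genes(genome, pos, [rel], margin=300)
    assemble_rrn_loci(genome)
    return {"source_span": tuple(loc.span), "target_pos": pos}


def apply_gene_gain(genome, pos, length, strand, group_id, gene_id) -> dict:
    pos = _snap_to_gap(genome, pos)
    rec = GeneRecord(
        gene_id, genome.genome_id, 0, int(length), strand, "CDS", None, group_id
    )
    _insert_genes(genome, pos, [rec], margin=200)
    return {
        "pos": pos,
        "length": int(length),
        "strand": strand,
        "group_id": group_id,
        "gene_id": gene_id,
    }


def apply_gene_loss(genome, gene_id) -> dict:
    _delete_genes(genome, [gene_id])
    return {"gene_id": gene_id}


def apply_jitter(genome, seed, sd) -> dict:
    rng = np.random.default_rng(int(seed))
    shifts = rng.normal(0, sd, len(genome.genes))
    out = []
    for g, dx in zip(genome.genes, shifts):
        s = int(np.clip(g.start + dx, 0, genome.chromosome_length - g.length))
        out.append(replace(g, start=s, end=s + g.length))
    genome.genes = sorted(out, key=lambda g: (g.start, g.gene_id))
    genome.invalidate_cache()
    assemble_rrn_loci(genome)
    return {"seed": int(seed), "sd": float(sd)}


_APPLIERS = {
    "inversion": apply_inversion,
    "rrn_duplication": apply_rrn_duplication,
    "rrn_loss": apply_rrn_loss,
    "lone_5s": apply_lone_5s,
    "gene_gain": apply_gene_gain,
    "gene_loss": apply_gene_loss,
    "jitter": apply_jitter,
}


def apply_event(genome: GenomeAnnotation, event: Event) -> None:
    if event.skipped:
        return
    _APPLIERS[event.event_type](genome, **event.param_dict)


# ---------------------------------------------------------------------------
# Panel evolution
# ---------------------------------------------------------------------------


def random_tree(n_leaves: int, seed: int = 0, branch_range=(0.3, 1.0)) -> dendropy.Tree:
    """Rooted random binary tree with uniform branch lengths (deterministic)."""
    rng = np.random.default_rng(seed)

    def build(labels):
        if len(labels) == 1:
            return labels[0]
        k = int(rng.integers(1, len(labels)))
        bl_l = rng.uniform(*branch_range)
        bl_r = rng.uniform(*branch_range)
        return f"({build(labels[:k])}:{bl_l:.4f},{build(labels[k:])}:{bl_r:.4f})"

    labels = [f"S{i + 1:02d}" for i in range(n_leaves)]
    newick = build(labels) + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


def _label_nodes(tree: dendropy.Tree) -> None:
    counter = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node._rrn_label = node.taxon.label.replace(" ", "_")
        elif node.label:
            node._rrn_label = node.label
        else:
            node._rrn_label = f"N{counter}"
            counter += 1


def _copy_genome(genome: GenomeAnnotation) -> GenomeAnnotation:
    g = GenomeAnnotation(
        genome_id=genome.genome_id,
        chromosome_length=genome.chromosome_length,
        genes=list(genome.genes),
        rrn_loci=list(genome.rrn_loci),
        dnaA_gene_id=genome.dnaA_gene_id,
        clade=genome.clade,
    )
    return g


def _central_interval(genome):
    loci = sorted(genome.rrn_loci, key=lambda l: l.span[0])
    if len(loci) < 2:
        return None
    return loci[0].span[0], loci[-1].span[1]


def _sample_branch_events(genome, spec, rng, branch, counters) -> list:
    """Sample and apply events for one branch; return log entries."""
    entries = []
    blen = counters["blen"]
    order = [
        ("inversion", spec.inversion_rate),
        ("rrn_duplication", spec.duplication_rate),
        ("rrn_loss", spec.rrn_loss_rate),
        ("lone_5s", spec.lone_5s_rate),
        ("gene_gain", spec.gene_gain_rate),
        ("gene_loss", spec.gene_loss_rate),
    ]
    for etype, rate in order:
        n = int(rng.poisson(rate * blen)) if rate > 0 else 0
        for _ in range(n):
            entry = _sample_one(genome, spec, rng, branch, etype, counters)
            if entry is not None:
                entries.append(entry)
    if spec.jitter_sd > 0:
        params = apply_jitter(genome, int(rng.integers(2**31)), spec.jitter_sd)
        entries.append(Event.make(branch, "jitter", params))
    return entries


def _arm_biased_position(genome, rng, bias):
    central = _central_interval(genome)
    L = genome.chromosome_length
    if central is None:
        return float(rng.uniform(0, L))
    cl, cr = central
    in_arm = rng.random() < bias / (bias + 1.0)
    if in_arm:
        left_w = cl
        right_w = L - cr
        if rng.uniform(0, left_w + right_w) < left_w:
            return float(rng.uniform(0.01 * L, cl))
        return float(rng.uniform(cr, 0.99 * L))
    return float(rng.uniform(cl, cr))


def _sample_one(genome, spec, rng, branch, etype, counters):
    central = _central_interval(genome)
    if etype == "inversion":
        if central is None:
            return Event.make(branch, etype, {"reason": "no central"}, skipped=True)
        cl, cr = central
        oric = genome.oric_position
        loci = list(genome.rrn_loci)
        for _ in range(300):
            ends = []
            for _ in range(2):
                if rng.random() < spec.p_breakpoint_near_rrn and loci:
                    loc = loci[int(rng.integers(len(loci)))]
                    sgn = 1.0 if rng.random() < 0.5 else -1.0
                    x = loc.midpoint + sgn * rng.exponential(spec.breakpoint_kernel_bp)
                else:
                    x = rng.uniform(cl, cr)
                ends.append(x)
            lo, hi = sorted(ends)
            size = hi - lo
            if (
                spec.inversion_size_range[0] <= size <= spec.inversion_size_range[1]
                and lo < oric < hi
                and cl <= lo
                and hi <= cr
            ):
                params = apply_inversion(genome, int(lo), int(hi))
                return Event.make(branch, etype, params)
        return Event.make(branch, etype, {"reason": "no valid breakpoints"}, skipped=True)
    if etype == "rrn_duplication":
        if not genome.rrn_loci:
            return Event.make(branch, etype, {"reason": "no locus"}, skipped=True)
        loc = genome.rrn_loci[int(rng.integers(len(genome.rrn_loci)))]
        counters["dup"] += 1
        tag = f"d{counters['dup']}"
        if rng.random() < spec.duplication_adjacent_prob:
            pos = loc.span[1] + 2500.0
        elif central is not None:
            pos = rng.uniform(*central)
        else:
            pos = rng.uniform(0, genome.chromosome_length)
        params = apply_rrn_duplication(genome, tuple(loc.span), int(pos), tag)
        return Event.make(branch, etype, params)
    if etype == "rrn_loss":
        if len(genome.rrn_loci) < 3:
            return Event.make(branch, etype, {"reason": "too few loci"}, skipped=True)
        # never remove a distal delimiter: keep the compartment defined
        inner = sorted(genome.rrn_loci, key=lambda l: l.span[0])[1:-1]
        loc = inner[int(rng.integers(len(inner)))]
        params = apply_rrn_loss(genome, tuple(loc.span))
        return Event.make(branch, etype, params)
    if etype == "lone_5s":
        complete = [l for l in genome.rrn_loci if l.is_complete]
        if not complete:
            return Event.make(branch, etype, {"reason": "no complete locus"}, skipped=True)
        loc = complete[int(rng.integers(len(complete)))]
        target = _arm_biased_position(genome, rng, 1.0)
        params = apply_lone_5s(genome, tuple(loc.span), int(target))
        return Event.make(branch, etype, params)
    if etype == "gene_gain":
        counters["gain"] += 1
        pos = _arm_biased_position(genome, rng, spec.arm_bias)
        params = apply_gene_gain(
            genome,
            int(pos),
            int(rng.integers(400, 1800)),
            "+" if rng.random() < 0.5 else "-",
            f"NOGX_{branch}_{counters['gain']}",
            f"gain_{branch}_{counters['gain']}",
        )
        return Event.make(branch, etype, params)
    if etype == "gene_loss":
        noncore = [
            g
            for g in genome.genes
            if g.kind == "CDS"
            and g.orthogroup_id
            and g.orthogroup_id.startswith("NOG")
        ]
        if not noncore:
            return Event.make(branch, etype, {"reason": "nothing to lose"}, skipped=True)
        if central is not None:
            cl, cr = central
            weights = np.array(
                [
                    spec.arm_bias if (g.end <= cl or g.start >= cr) else 1.0
                    for g in noncore
                ]
            )
        else:
            weights = np.ones(len(noncore))
        weights = weights / weights.sum()
        pick = noncore[int(rng.choice(len(noncore), p=weights))]
        params = apply_gene_loss(genome, pick.gene_id)
        return Event.make(branch, etype, params)
    raise ValueError(etype)


def _materialize_leaf(genome: GenomeAnnotation, leaf_id: str, old_id: str) -> GenomeAnnotation:
    def rename(gid):
        if gid is None:
            return None
        if gid.startswith(old_id + "_"):
            return leaf_id + gid[len(old_id):]
        return f"{leaf_id}_{gid}"

    genes = [
        replace(g, gene_id=rename(g.gene_id), genome_id=leaf_id) for g in genome.genes
    ]
    out = GenomeAnnotation(
        genome_id=leaf_id,
        chromosome_length=genome.chromosome_length,
        genes=genes,
        dnaA_gene_id=rename(genome.dnaA_gene_id),
        clade=genome.clade,
    )
    assemble_rrn_loci(out)
    return out


def evolve_panel(ancestor: GenomeAnnotation, spec: EvolutionSpec, tree=None):
    """Evolve a panel of leaf genomes down a tree; returns (Panel, EventLog).

    Events are sampled per branch (Poisson with the spec's rates times the
    branch length), applied immediately, and logged with their concrete
    parameters so that :func:`replay_events` reproduces every leaf exactly.
    """
    if tree is None:
        raise ValueError("evolve_panel requires a tree (see random_tree)")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    _label_nodes(tree)
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    rng = np.random.default_rng(spec.seed)
    log = EventLog()
    counters = {"dup": 0, "gain": 0, "blen": 1.0}
    genomes = {}
    state = {id(tree.seed_node): _copy_genome(ancestor)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = state[id(node.parent_node)]
        genome = _copy_genome(parent)
        counters["blen"] = float(node.edge.length or 1.0)
        log.extend(
            _sample_branch_events(genome, spec, rng, node._rrn_label, counters)
        )
        state[id(node)] = genome
        if node.is_leaf():
            genomes[node._rrn_label] = _materialize_leaf(
                genome, node._rrn_label, ancestor.genome_id
            )
    return Panel(genomes=genomes, tree=tree), log


def replay_events(ancestor: GenomeAnnotation, tree, log: EventLog) -> Panel:
    """Re-apply a logged history to the ancestor; reproduces the leaves."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    _label_nodes(tree)
    genomes = {}
    state = {id(tree.seed_node): _copy_genome(ancestor)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        genome = _copy_genome(state[id(node.parent_node)])
        for event in log.for_branch(node._rrn_label):
            apply_event(genome, event)
        state[id(node)] = genome
        if node.is_leaf():
            genomes[node._rrn_label] = _materialize_leaf(
                genome, node._rrn_label, ancestor.genome_id
            )
    return Panel(genomes=genomes, tree=tree)


# ---------------------------------------------------------------------------
# Similarity tables
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def emit_similarity_tables(panel: Panel, noise: float = 0.0, seed: int = 0):
    """All-vs-all protein hit tables consistent with planted orthology.

    Returns ``(hits, lengths)``: ``hits`` maps ordered genome pairs (A, B)
    with A < B to a DataFrame holding both directions' rows in BLAST
    tabular (outfmt 6) layout; ``lengths`` maps gene ids to amino-acid
    lengths (the coverage sidecar).  True ortholog pairs receive mutually
    best hits passing the 40/70/1e-10 thresholds; ``noise`` adds decoy rows
    that are either sub-threshold or non-reciprocal and therefore never
    create a reciprocal best hit.
    """
    rng = np.random.default_rng(seed)
    lengths = {}
    by_group = {}  # group -> genome -> [gene]
    for genome in panel:
        for g in genome.genes:
            if g.kind != "CDS":
                continue
            lengths[g.gene_id] = max(g.length // 3, 50)
            if g.orthogroup_id:
                by_group.setdefault(g.orthogroup_id, {}).setdefault(
                    genome.genome_id, []
                ).append(g.gene_id)
    ids = panel.genome_ids
    hits = {}
    for i, A in enumerate(ids):
        for B in ids[i + 1 :]:
            rows = []
            for group in sorted(by_group):
                members = by_group[group]
                if A not in members or B not in members:
                    continue
                ident = float(rng.uniform(55, 92))
                score = float(rng.uniform(400, 900))
                for qa in members[A]:
                    for qb in members[B]:
                        la, lb = lengths[qa], lengths[qb]
                        aln = int(0.85 * min(la, lb))
                        rows.append(
                            (qa, qb, ident, aln, int(aln * (1 - ident / 100)), 0,
                             1, aln, 1, aln, 1e-80, score)
                        )
                        rows.append(
                            (qb, qa, ident, aln, int(aln * (1 - ident / 100)), 0,
                             1, aln, 1, aln, 1e-80, score)
                        )
            if noise > 0 and rows:
                n_decoys = int(noise * len(rows) / 2)
                genesA = sorted(
                    g.gene_id for g in panel.genomes[A].genes if g.kind == "CDS"
                )
                genesB = sorted(
                    g.gene_id for g in panel.genomes[B].genes if g.kind == "CDS"
                )
                for _ in range(n_decoys):
                    qa = genesA[int(rng.integers(len(genesA)))]
                    qb = genesB[int(rng.integers(len(genesB)))]
                    la, lb = lengths[qa], lengths[qb]
                    aln = int(0.8 * min(la, lb))
                    if rng.random() < 0.5:
                        # sub-threshold identity: filtered before best-hit choice
                        ident, ev, score = float(rng.uniform(20, 39.5)), 1e-20, 150.0
                    else:
                        # passing but weak and one-directional: never reciprocal
                        ident, ev, score = float(rng.uniform(41, 50)), 1e-12, 60.0
                    rows.append(
                        (qa, qb, ident, aln, int(aln * (1 - ident / 100)), 0,
                         1, aln, 1, aln, ev, score)
                    )
            hits[(A, B)] = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    return hits, lengths


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(length: int, rng, gc: float = 0.5) -> np.ndarray:
    """Random nucleotide sequence as a uint8 code array (0..3 = ACGT)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def mutate_sequence(seq: np.ndarray, rate: float, rng) -> np.ndarray:
    """Apply i.i.d. substitutions at the given per-site rate."""
    out = seq.copy()
    if rate <= 0:
        return out
    mask = rng.random(len(seq)) < rate
    out[mask] = (out[mask] + rng.integers(1, 4, mask.sum())) % 4
    return out


def codes_to_fasta(codes: np.ndarray, name: str) -> str:
    seq = _ALPHABET[codes].tobytes().decode()
    lines = [f">{name}"]
    lines.extend(seq[i : i + 80] for i in range(0, len(seq), 80))
    return "\n".join(lines) + "\n"


def emit_sequences(panel: Panel, substitution_rate: float, seed: int = 0,
                   length: Optional[int] = None, gc: float = 0.5) -> dict:
    """Divergence-controlled nucleotide sequences, one per genome.

    Each leaf diverges from a common ancestral sequence by i.i.d.
    substitutions with per-site probability ``substitution_rate`` times the
    leaf's root-to-tip distance (1.0 if no tree).  Returns a dict mapping
    genome id to a uint8 code array.
    """
    rng = np.random.default_rng(seed)
    L = length or min(g.chromosome_length for g in panel)
    anc = random_sequence(L, rng, gc)
    depth = {}
    if panel.tree is not None:
        _label_nodes(panel.tree)
        for leaf in panel.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += float(node.edge.length or 1.0)
                node = node.parent_node
            depth[leaf._rrn_label] = d
    out = {}
    for gid in panel.genome_ids:
        d = substitution_rate * depth.get(gid, 1.0)
        out[gid] = mutate_sequence(anc, min(d, 0.95), rng)
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def emit_expression(genome: GenomeAnnotation, spec: ExpressionSpec,
                    persistence: Optional[Mapping[str, float]] = None):
    """Negative-binomial expression counts plus a per-gene truth table.

    Returns ``(counts, truth)``; ``counts`` is a gene x sample DataFrame of
    raw counts, ``truth`` records the per-gene expected mean (at unit
    sequencing depth), compartment membership and distance to oriC.
    """
    rng = np.random.default_rng(spec.seed)
    central = _central_interval(genome)
    if central is None:
        raise ValueError("expression model requires >= 2 rrn loci")
    cl, cr = central
    oric = genome.oric_position
    cds = [g for g in genome.genes if g.kind == "CDS"]
    mu0 = np.empty(len(cds))
    in_central = np.empty(len(cds), dtype=bool)
    dists = np.empty(len(cds))
    for i, g in enumerate(cds):
        mid = g.midpoint
        inside = cl <= mid <= cr
        d = abs(mid - oric)
        mu = spec.baseline * (g.length / 1000.0)
        if inside:
            mu *= spec.central_multiplier
        else:
            mu *= np.exp(-spec.distance_decay * d)
        if persistence is not None and spec.persistence_coupling != 0:
            p = persistence.get(g.orthogroup_id, 0.5)
            mu *= np.exp(spec.persistence_coupling * (p - 0.5))
        mu0[i] = mu
        in_central[i] = inside
        dists[i] = d
    samples = []
    counts = {}
    for phase, factor in (("troph", 1.0), ("idio", spec.idiophase_factor)):
        for s in range(spec.samples_per_phase):
            name = f"{phase}_{s + 1}"
            samples.append(name)
            depth = rng.uniform(*spec.depth_range)
            mu = np.maximum(mu0 * factor * depth, 1e-8)
            if spec.dispersion <= 0:
                counts[name] = rng.poisson(mu)
            else:
                n = 1.0 / spec.dispersion
                counts[name] = rng.negative_binomial(n, n / (n + mu))
    counts = pd.DataFrame(counts, index=[g.gene_id for g in cds])
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in cds],
            "orthogroup_id": [g.orthogroup_id for g in cds],
            "length_bp": [g.length for g in cds],
            "expected_mean": mu0,
            "in_central": in_central,
            "distance_to_oric": dists,
        }
    ).set_index("gene_id")
    return counts, truth


# ---------------------------------------------------------------------------
# Feature panels for the regression study
# ---------------------------------------------------------------------------


def simulate_model_features(
    n_genomes: int = 60,
    seed: int = 0,
    betas=(0.80, 0.06, 0.15, 30_000.0),
    noise_sd: float = 50_000.0,
) -> pd.DataFrame:
    """Per-genome feature table with a known generative model.

    The response ``core_region_size`` is a linear function of the central-
    compartment size, the chromosome size, the maximal distal-rrn-to-oriC
    distance and the rrn gene count (coefficients ``betas``) plus Gaussian
    noise.  The remaining columns (rrn locus count, clade, tDNA-region size,
    terminal compartment sizes) are realistic correlates that carry no
    signal beyond the four generative predictors.
    """
    rng = np.random.default_rng(seed)
    chrom = rng.normal(8.5e6, 6e5, n_genomes)
    central = chrom * rng.uniform(0.50, 0.70, n_genomes)
    d_max = central * rng.uniform(0.50, 0.75, n_genomes)
    n_loci = rng.integers(5, 9, n_genomes)
    n_rrn_genes = 3 * n_loci + rng.integers(-1, 2, n_genomes)
    clade = rng.choice(["1", "2", "O"], n_genomes, p=[0.45, 0.40, 0.15])
    arms = chrom - central
    w = rng.uniform(0.4, 0.6, n_genomes)
    terminal_left = arms * w
    terminal_right = arms * (1 - w)
    tdna = central + arms * rng.uniform(0.3, 0.6, n_genomes)
    b1, b2, b3, b4 = betas
    core_region = (
        b1 * central
        + b2 * chrom
        + b3 * d_max
        + b4 * n_rrn_genes
        + rng.normal(0, noise_sd, n_genomes)
    )
    return pd.DataFrame(
        {
            "core_region_size": core_region,
            "central_size": central,
            "chromosome_size": chrom,
            "d_max_rrn_ori": d_max,
            "n_rrn_genes": n_rrn_genes,
            "n_rrn_loci": n_loci,
            "clade": clade,
            "tdna_size": tdna,
            "terminal_left_size": terminal_left,
            "terminal_right_size": terminal_right,
        }
    )
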