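"""Delta tracks, breakpoint detection, deduplication, rrn distances."""

import numpy as np
import pytest

from rrnscape import (
    compartment_map,
    deduplicate_events,
    delta_track,
    detect_events,
    pairwise_events,
    random_tree,
    replay_events,
)
from rrnscape.rearrangements import DeltaTrack, RearrangementEvent
from rrnscape.synthetic_data import Event, EventLog, _copy_genome, apply_inversion


def _planted(ancestor, core, left, right):
    g = _copy_genome(ancestor)
    g.genome_id = "planted"
    params = apply_inversion(g, left, right)
    return g, params


class TestDeltaTrack:
    def test_identical_genomes_flat_track(self, ancestor_full):
        genome, _, core = ancestor_full
        g = _copy_genome(genome)
        g.genome_id = "twin"
        m = compartment_map(genome, core)
        track = delta_track(g, genome, core, m.central, m.central)
        assert np.all(track.delta == 0)
        assert detect_events(track) == []

    def test_insertion_shifts_downstream_deltas(self, ancestor_full):
        from rrnscape.synthetic_data import apply_gene_gain

        genome, _, core = ancestor_full
        g = _copy_genome(genome)
        g.genome_id = "ins"
        oric = int(genome.oric_position)
        apply_gene_gain(g, oric - 500_000, 50_000, "+", "NOGX_t", "big_insert")
        m = compartment_map(genome, core)
        mg = compartment_map(g, core)
        track = delta_track(g, genome, core, mg.central, m.central)
        dd = track.delta_delta
        spikes = np.where(np.abs(dd) > 40_000)[0]
        assert len(spikes) == 1
        assert dd[spikes[0]] == pytest.approx(50_000, abs=2000)

    def test_globally_inverted_genome_is_autoflipped(self, ancestor_full):
        from rrnscape import reverse_complement_annotation

        genome, _, core = ancestor_full
        g = reverse_complement_annotation(_copy_genome(genome))
        g.genome_id = "flipped"
        m = compartment_map(genome, core)
        mg = compartment_map(g, core)
        track = delta_track(g, genome, core, mg.central, m.central)
        assert track.flipped
        assert detect_events(track) == []


class TestDetectEvents:
    def test_megabase_inversion_recovered_with_tight_boundaries(self, ancestor_full):
        genome, _, core = ancestor_full
        oric = int(genome.oric_position)
        g, params = _planted(genome, core, oric - 400_000, oric + 600_000)
        m = compartment_map(genome, core)
        mg = compartment_map(g, core)
        events = pairwise_events(g, genome, core, mg.central, m.central)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "inversion"
        assert ev.size == pytest.approx(1_000_000, rel=0.05)
        # boundary error bounded by the local core-gene spacing
        core_pos = sorted(
            x.start for x in g.core_genes(core)
        )
        for end, truth in zip(sorted(ev.end_positions), (params["left"], params["right"])):
            i = np.searchsorted(core_pos, truth)
            spacing = core_pos[min(i + 1, len(core_pos) - 1)] - core_pos[max(i - 1, 0)]
            assert abs(end - truth) <= spacing

    def test_sub_threshold_inversion_ignored(self, ancestor_full):
        genome, _, core = ancestor_full
        oric = int(genome.oric_position)
        g, _ = _planted(genome, core, oric - 70_000, oric + 80_000)
        m = compartment_map(genome, core)
        mg = compartment_map(g, core)
        assert pairwise_events(g, genome, core, mg.central, m.central) == []

    def test_two_disjoint_inversions_paired_correctly(self, ancestor_full):
        genome, _, core = ancestor_full
        m = compartment_map(genome, core)
        cl, cr = m.central
        g = _copy_genome(genome)
        g.genome_id = "two"
        apply_inversion(g, cl + 200_000, cl + 550_000)
        apply_inversion(g, cr - 700_000, cr - 300_000)
        mg = compartment_map(g, core)
        events = pairwise_events(g, genome, core, mg.central, m.central)
        assert len(events) == 2
        assert all(ev.type == "inversion" for ev in events)
        sizes = sorted(ev.size for ev in events)
        assert sizes[0] == pytest.approx(350_000, rel=0.1)
        assert sizes[1] == pytest.approx(400_000, rel=0.1)

    def test_matches_brute_force_segmentation_oracle(self):
        """Small synthetic rank tracks: detected segments equal the oracle's
        maximal reversed runs above threshold."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = 40
            spacing = 10_000.0
            ref = np.arange(n) * spacing
            gen = ref.copy()
            # plant 0-2 well-separated reversals; widths chosen so that only
            # the segment-edge jumps ((w-1)*spacing) exceed the threshold,
            # not the interior slope steps (2*spacing)
            for lo, hi in ((2, 14), (20, 33)):
                if rng.random() < 0.2:
                    continue
                s = int(rng.integers(lo, hi))
                w = int(rng.integers(4, 7))
                seg = slice(s, s + w)
                gen[seg] = gen[seg][::-1]
            track = DeltaTrack("g", "r", tuple(f"G{i}" for i in range(n)),
                               tuple(ref), tuple(gen), False)
            thr = 25_000.0
            events = detect_events(track, thr)
            # oracle: maximal strictly-decreasing runs of length >= 2
            runs = []
            i = 0
            while i < n - 1:
                if gen[i + 1] < gen[i]:
                    j = i
                    while j < n - 1 and gen[j + 1] < gen[j]:
                        j += 1
                    runs.append((i, j))
                    i = j + 1
                else:
                    i += 1
            big = [
                (a, b)
                for a, b in runs
                if abs(gen[a] - ref[a]) > thr or abs(gen[b] - ref[b]) > thr
            ]
            got = [
                (
                    track.groups.index(ev.segment_groups[0]),
                    track.groups.index(ev.segment_groups[-1]),
                )
                for ev in events
                if ev.type == "inversion"
            ]
            assert got == big


class TestDeduplication:
    def _event(self, gid, left="GA", right="GB", size=1e6, mn=10_000.0, mx=50_000.0):
        return RearrangementEvent(
            event_id=f"{gid}_e",
            genomes=(gid,),
            left_boundary_group=left,
            right_boundary_group=right,
            segment_groups=("GX",),
            size=size,
            type="inversion",
            end_positions=(0.0, size),
            min_distance=mn,
            max_distance=mx,
        )

    def test_clade_shared_event_counted_once_with_means(self):
        tree = random_tree(6, seed=1)
        leaves = sorted(l.taxon.label for l in tree.leaf_nodes())
        # find an internal clade of >= 2 leaves
        from rrnscape.synthetic_data import _label_nodes

        _label_nodes(tree)
        clade = None
        for node in tree.preorder_node_iter():
            ls = [l.taxon.label for l in node.leaf_iter()]
            if 2 <= len(ls) < len(leaves):
                clade = sorted(ls)
                break
        events = [self._event(g, size=1e6 + i * 2e5) for i, g in enumerate(clade)]
        merged = deduplicate_events(events, tree)
        assert len(merged) == 1
        assert merged[0].genomes == tuple(clade)
        assert merged[0].size == pytest.approx(np.mean([ev.size for ev in events]))
        assert merged[0].min_distance == pytest.approx(10_000.0)

    def test_same_boundaries_on_disjoint_clades_stay_separate(self):
        tree = random_tree(4, seed=2)
        from rrnscape.synthetic_data import _label_nodes

        _label_nodes(tree)
        # pick two leaves that are not sisters if possible, else any two
        leaves = sorted(l.taxon.label for l in tree.leaf_nodes())
        sisters = set()
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                sisters = {k.taxon.label for k in kids}
                break
        pair = [l for l in leaves if l not in sisters][:1] + [
            l for l in leaves if l in sisters
        ][:1]
        events = [self._event(g) for g in pair]
        merged = deduplicate_events(events, tree)
        assert len(merged) == 2

    def test_single_genome_event_unchanged(self):
        ev = self._event("S01")
        merged = deduplicate_events([ev], None)
        assert len(merged) == 1
        assert merged[0].genomes == ("S01",)
        assert merged[0].size == ev.size

    def test_event_planted_on_internal_branch_merges_via_pipeline(
        self, ancestor_full
    ):
        genome, _, core = ancestor_full
        tree = random_tree(5, seed=4)
        from rrnscape.synthetic_data import _label_nodes

        _label_nodes(tree)
        internal = next(
            n
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n is not tree.seed_node
            and len(n.leaf_nodes()) >= 2
        )
        oric = int(genome.oric_position)
        log = EventLog(
            [
                Event.make(
                    internal._rrn_label,
                    "inversion",
                    {"left": oric - 300_000, "right": oric + 400_000},
                )
            ]
        )
        panel = replay_events(genome, tree, log)
        carriers = sorted(l._rrn_label for l in internal.leaf_iter())
        m = compartment_map(genome, core)
        all_events = []
        for leaf in panel:
            mg = compartment_map(leaf, core)
            all_events.extend(
                pairwise_events(leaf, genome, core, mg.central, m.central)
            )
        assert len(all_events) == len(carriers)
        merged = deduplicate_events(all_events, tree)
        assert len(merged) == 1
        assert merged[0].genomes == tuple(carriers)


class TestDistancesToRrn:
    def test_min_max_over_ends(self, ancestor_full):
        from rrnscape.rearrangements import distances_to_rrn

        genome, _, core = ancestor_full
        loci = sorted(genome.rrn_loci, key=lambda l: l.span[0])
        # end A right next to locus 2; end B far from everything
        pos_a = loci[2].span[1] + 5_000
        gaps = [
            (loci[i].span[1], loci[i + 1].span[0]) for i in range(len(loci) - 1)
        ]
        widest = max(gaps, key=lambda g: g[1] - g[0])
        pos_b = (widest[0] + widest[1]) / 2
        ev = RearrangementEvent(
            "e", ("g",), "GA", "GB", (), 1e6, "inversion", (float(pos_a), float(pos_b))
        )
        out = distances_to_rrn(ev, genome)
        assert out.min_distance == pytest.approx(5_000)
        assert out.max_distance == pytest.approx(
            (widest[1] - widest[0]) / 2, rel=0.01
        )
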