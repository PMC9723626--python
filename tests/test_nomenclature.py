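"""Environment triplets, the A-F dictionary, configurations, canonical forms."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrnscape import (
    GeneRecord,
    GenomeAnnotation,
    assemble_rrn_loci,
    build_environment_dictionary,
    canonicalize,
    classify_configuration,
    environment_of,
    environments_of_genome,
    equivalent,
    reverse_complement_annotation,
)
from rrnscape.nomenclature import Configuration
from rrnscape.skeleton import CoreOrder
from rrnscape.synthetic_data import (
    _copy_genome,
    apply_inversion,
    apply_rrn_duplication,
)


def _mini_genome(core_positions, locus_at, order=None):
    """Core genes at given starts plus one rrn locus at ``locus_at``."""
    genes = [GeneRecord("d", "m", 5, 105, "+", "CDS", product="dnaA")]
    for i, p in enumerate(core_positions):
        genes.append(
            GeneRecord(f"c{i}", "m", p, p + 500, "+", "CDS", orthogroup_id=f"G{i}")
        )
    genes += [
        GeneRecord("r16", "m", locus_at, locus_at + 1500, "+", "rRNA_16S"),
        GeneRecord("r23", "m", locus_at + 1600, locus_at + 4600, "+", "rRNA_23S"),
        GeneRecord("r5", "m", locus_at + 4700, locus_at + 4820, "+", "rRNA_5S"),
    ]
    L = max(g.end for g in genes) + 1000
    genome = GenomeAnnotation("m", L, genes, dnaA_gene_id="d")
    assemble_rrn_loci(genome)
    ids = [f"G{i}" for i in range(len(core_positions))]
    return genome, ids, CoreOrder(tuple(order or ids))


class TestEnvironmentOf:
    def test_sense_triplet(self):
        genome, ids, order = _mini_genome([1000, 10_000, 30_000, 50_000], 15_000)
        env = environment_of(genome.rrn_loci[0], genome, ids, order)
        assert (env.prev_core, env.nearest_core, env.next_core) == ("G0", "G1", "G2")
        assert env.orientation == "sense"

    def test_antisense_triplet_gets_asterisk_semantics(self):
        # same genome but consensus order reversed: ranks now decrease
        genome, ids, _ = _mini_genome([1000, 10_000, 30_000, 50_000], 15_000)
        order = CoreOrder(("G3", "G2", "G1", "G0"))
        env = environment_of(genome.rrn_loci[0], genome, ids, order)
        assert env.orientation == "antisense"

    def test_broken_triplet_flagged(self):
        genome, ids, _ = _mini_genome([1000, 10_000, 30_000, 50_000], 15_000)
        order = CoreOrder(("G0", "G2", "G1", "G3"))  # triplet ranks (1, 3, 2)
        env = environment_of(genome.rrn_loci[0], genome, ids, order)
        assert env.orientation == "broken"

    def test_equidistant_tie_breaks_to_lower_rank(self):
        # locus span [20000, 24820]; G1 ends at 10500 -> gap 9500;
        # G2 starts at 34320 -> gap 9500: exact tie, lower rank (G1) wins
        genome, ids, order = _mini_genome([1000, 10_000, 34_320, 50_000], 20_000)
        env = environment_of(genome.rrn_loci[0], genome, ids, order)
        assert env.nearest_core == "G1"

    def test_overlapping_core_gene_wins_with_distance_zero(self):
        genome, ids, order = _mini_genome([1000, 21_000, 40_000, 60_000], 20_000)
        env = environment_of(genome.rrn_loci[0], genome, ids, order)
        assert env.nearest_core == "G1"


@pytest.fixture(scope="module")
def classified_ancestor(request):
    anc, order, core = request.getfixturevalue("ancestor_full")
    envs = {"ancestor": environments_of_genome(anc, core, order)}
    dictionary = build_environment_dictionary(envs, order)
    return anc, order, core, dictionary


class TestDictionaryAndConfiguration:
    def test_ancestor_is_canonical_abcdef(self, classified_ancestor):
        anc, order, core, dictionary = classified_ancestor
        cfg = classify_configuration(anc, dictionary, core, order)
        assert cfg.to_string() == "rrn ABCDEF dnaA+"

    def test_letters_follow_consensus_rank_of_nearest_cores(self, classified_ancestor):
        anc, order, core, dictionary = classified_ancestor
        envs = environments_of_genome(anc, core, order)
        labels = [dictionary.label_for(e) for e in envs]
        assert labels == list("ABCDEF")

    def test_pericentric_de_inversion_string(self, classified_ancestor):
        anc, order, core, dictionary = classified_ancestor
        loci = sorted(anc.rrn_loci, key=lambda l: l.span[0])
        g = _copy_genome(anc)
        apply_inversion(g, loci[3].span[0] - 6000, loci[4].span[1] + 6000)
        cfg = classify_configuration(g, dictionary, core, order)
        assert cfg.to_string() == "rrn ABCE*D*F dnaA-"
        anc_cfg = classify_configuration(anc, dictionary, core, order)
        assert not equivalent(cfg, anc_cfg)

    def test_adjacent_duplication_gets_lowercase_variant(self, classified_ancestor):
        anc, order, core, dictionary = classified_ancestor
        loci = sorted(anc.rrn_loci, key=lambda l: l.span[0])
        g = _copy_genome(anc)
        apply_rrn_duplication(g, tuple(loci[4].span), loci[4].span[1] + 2500, "d1")
        assert len(g.rrn_loci) == 7
        envs = {"ancestor": environments_of_genome(anc, core, order),
                "dup": environments_of_genome(g, core, order)}
        d2 = build_environment_dictionary(envs, order)
        cfg = classify_configuration(g, d2, core, order)
        variant = [t for t in cfg.tokens if t not in set("ABCDEF")]
        assert len(variant) == 1
        assert variant[0].rstrip("*").startswith("e")  # shares a core gene with E

    def test_ectopic_duplication_far_from_canonicals_gets_novel_letter(
        self, classified_ancestor
    ):
        anc, order, core, dictionary = classified_ancestor
        loci = sorted(anc.rrn_loci, key=lambda l: l.span[0])
        g = _copy_genome(anc)
        # midway between loci B and C: far from every canonical triplet
        target = (loci[1].span[1] + loci[2].span[0]) // 2
        apply_rrn_duplication(g, tuple(loci[0].span), target, "d1")
        envs = {"ancestor": environments_of_genome(anc, core, order),
                "dup": environments_of_genome(g, core, order)}
        d2 = build_environment_dictionary(envs, order)
        cfg = classify_configuration(g, d2, core, order)
        variant = [t for t in cfg.tokens if t not in set("ABCDEF")]
        assert variant == ["g1"]

    def test_five_locus_genome_warns_and_classifies(self, classified_ancestor):
        from rrnscape.synthetic_data import apply_rrn_loss

        anc, order, core, dictionary = classified_ancestor
        loci = sorted(anc.rrn_loci, key=lambda l: l.span[0])
        g = _copy_genome(anc)
        apply_rrn_loss(g, tuple(loci[2].span))
        with pytest.warns(UserWarning, match="5 rrn loci"):
            cfg = classify_configuration(g, dictionary, core, order)
        assert len(cfg.tokens) == 5


class TestCanonicalize:
    def test_paper_stated_equivalence_verbatim(self):
        rev = Configuration("x", ("F*", "E*", "D*", "C*", "B*", "A*"), "-")
        assert canonicalize(rev).to_string() == "rrn ABCDEF dnaA+"
        fwd = Configuration("y", tuple("ABCDEF"), "+")
        assert equivalent(rev, fwd)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list("ABCDEF") + ["e2", "g1", "[d/e]"]),
                st.sampled_from(["", "*", "~"]),
            ),
            min_size=1,
            max_size=8,
        ),
        st.sampled_from(["+", "-"]),
    )
    def test_idempotent_and_reversal_invariant(self, tokens, sign):
        cfg = Configuration("t", tuple(l + s for l, s in tokens), sign)
        canon = canonicalize(cfg)
        assert canonicalize(canon).tokens == canon.tokens
        # the explicit reverse-complement form is equivalent
        from rrnscape.nomenclature import _toggle

        rc = Configuration(
            "t",
            tuple(_toggle(t) for t in reversed(cfg.tokens)),
            "-" if sign == "+" else "+",
        )
        assert equivalent(cfg, rc)

    def test_reverse_complement_classification_equivalence(self, classified_ancestor):
        anc, order, core, dictionary = classified_ancestor
        cfg = classify_configuration(anc, dictionary, core, order)
        rc_cfg = classify_configuration(
            reverse_complement_annotation(anc), dictionary, core, order
        )
        assert rc_cfg.to_string() == "rrn F*E*D*C*B*A* dnaA-"
        assert equivalent(cfg, rc_cfg)
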